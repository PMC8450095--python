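import numpy as np
import pytest

from m6akit.synthetic import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale study conditions for fast unit tests."""
    return SimConfig(
        seed=7,
        n_genes=60,
        n_contigs=3,
        n_true_sites=120,
        n_background_peaks=500,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def default_dataset():
    """The standard fixture: 400 genes, 800 true sites, 4,000 background
    peaks, 3+3 replicates, residual methylation 0.1, confounded expression."""
    return simulate_dataset(SimConfig(seed=42))


@pytest.fixture(scope="session")
def default_pipeline(default_dataset):
    """Annotated peaks, bin-based diffmeth results and label sets on the
    standard fixture."""
    from m6akit.pipeline import prepare_labeled_peaks

    peaks, results, pos, neg = prepare_labeled_peaks(default_dataset)
    return {
        "dataset": default_dataset,
        "peaks": peaks,
        "results": results,
        "positives": pos,
        "negatives": neg,
    }


@pytest.fixture(scope="session")
def default_features(default_pipeline):
    """Encoded feature matrix + labels for the diffmeth-derived label sets."""
    from m6akit.features import encode_matrix, extract_features

    ds = default_pipeline["dataset"]
    labeled = default_pipeline["positives"] + default_pipeline["negatives"]
    labels = np.array(
        [1] * len(default_pipeline["positives"]) + [0] * len(default_pipeline["negatives"])
    )
    vectors = [extract_features(p, ds.reference.genome, ctot_count=p.ctot) for p in labeled]
    X, columns = encode_matrix(vectors)
    return {
        "X": X,
        "y": labels,
        "columns": columns,
        "vectors": vectors,
        "windows": [v.seq for v in vectors],
        "peaks": labeled,
    }
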