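"""End-to-end workflow driver: simulate -> peaks -> diffmeth -> features ->
train/evaluate -> profiles, with artifacts and provenance on disk."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from m6akit import __version__
from m6akit.boost import BoostModel, cross_validate, evaluate, run_baselines, split_train_test
from m6akit.diffmeth import BinwiseDiffMeth, compile_label_sets, gene_log2fc, stratify_genes
from m6akit.features import encode_matrix, extract_features
from m6akit.peaks import assign_transcripts, relative_signal_strength
from m6akit.profiles import metagene_density, motif_metaprofile
from m6akit.synthetic import SimConfig, SyntheticDataset, simulate_dataset

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "prepare_labeled_peaks"]

_STAGES = ("simulate", "diffmeth", "features", "train", "profiles")


@dataclass
class RunConfig:
    """Flat, typed run configuration; unknown keys are rejected."""

    outdir: str = "m6akit_run"
    seed: int = 42
    n_bins: int = 20
    min_genes_per_bin: int = 10
    fdr_positive: float = 0.01
    fdr_negative: float = 0.5
    n_rounds: int = 100
    max_depth: int = 3
    test_fraction: float = 0.2
    cv_folds: int = 5
    threshold: float = 0.5
    sim: SimConfig = field(default_factory=SimConfig)

    @classmethod
    def from_dict(cls, d: Dict) -> "RunConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "sim" in d and isinstance(d["sim"], dict):
            sim_known = {f.name for f in dataclasses.fields(SimConfig)}
            sim_unknown = set(d["sim"]) - sim_known
            if sim_unknown:
                raise ValueError(f"unknown sim config keys: {sorted(sim_unknown)}")
            d["sim"] = SimConfig(**d["sim"])
        return cls(**d)

    def config_hash(self) -> str:
        text = json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(text.encode()).hexdigest()[:12]


def prepare_labeled_peaks(dataset: SyntheticDataset, config: Optional[RunConfig] = None):
    """Run annotation, strength, diffmeth and label compilation on a
    synthetic dataset; returns (peaks, results_binbased, positives,
    negatives)."""
    config = config or RunConfig(sim=dataset.config)
    annotation = dataset.reference.annotation
    peaks = dataset.as_peaks()
    peaks = assign_transcripts(peaks, annotation, genome=dataset.reference.genome)
    peaks = relative_signal_strength(peaks, condition="WT")

    lfc = gene_log2fc(
        dataset.counts.expression,
        wt_cols=[c for c, cond in zip(dataset.counts.expression.columns, dataset.counts.sample_conditions) if cond == "WT"],
        ko_cols=[c for c, cond in zip(dataset.counts.expression.columns, dataset.counts.sample_conditions) if cond == "KO"],
    )
    bins = stratify_genes(lfc, n_bins=config.n_bins, min_genes=config.min_genes_per_bin)
    model = BinwiseDiffMeth(
        dataset.counts.peak_counts,
        dataset.counts.sample_conditions,
        peak_genes=dataset.counts.peak_genes,
        bins=bins,
    )
    results = model.fit()
    positives, negatives = compile_label_sets(
        results, peaks, fdr_positive=config.fdr_positive, fdr_negative=config.fdr_negative
    )
    return peaks, results, positives, negatives


@dataclass
class PipelineResult:
    config: RunConfig
    dataset: SyntheticDataset
    diffmeth: object
    model: BoostModel
    reports: Dict[str, object]
    cv_summary: Dict[str, tuple]
    artifacts: List[str]


def run_pipeline(config: RunConfig, stages: Sequence[str] = _STAGES) -> PipelineResult:
    """Execute the requested stages in dependency order, writing artifacts
    and a provenance manifest under ``config.outdir``."""
    stages = list(stages)
    for s in stages:
        if s not in _STAGES:
            raise ValueError(f"unknown stage {s!r}; choose from {_STAGES}")
    os.makedirs(config.outdir, exist_ok=True)
    artifacts: List[str] = []

    sim = SimConfig(**{**dataclasses.asdict(config.sim), "seed": config.seed})
    dataset = simulate_dataset(sim)
    if "simulate" in stages:
        dataset.write(config.outdir)
        artifacts += ["genome.fa", "annotation.gtf", "peak_counts.tsv", "expression.tsv", "transitions.tsv", "truth.bed", "config.json"]

    peaks, results, positives, negatives = prepare_labeled_peaks(dataset, config)
    if "diffmeth" in stages:
        path = os.path.join(config.outdir, "diffmeth.tsv")
        results.table.to_csv(path, sep="\t")
        artifacts.append("diffmeth.tsv")

    labeled = positives + negatives
    labels = np.array([1] * len(positives) + [0] * len(negatives))
    vectors = [extract_features(p, dataset.reference.genome, ctot_count=p.ctot) for p in labeled]
    X, columns = encode_matrix(vectors)
    if "features" in stages:
        path = os.path.join(config.outdir, "features.tsv")
        pd.DataFrame(X, index=[p.peak_id for p in labeled], columns=columns).to_csv(path, sep="\t")
        artifacts.append("features.tsv")

    model = None
    reports: Dict[str, object] = {}
    cv_summary: Dict[str, tuple] = {}
    if "train" in stages:
        X_tr, X_te, y_tr, y_te = split_train_test(X, labels, config.test_fraction, seed=config.seed)
        model = BoostModel.train(
            X_tr, y_tr, columns, n_rounds=config.n_rounds, max_depth=config.max_depth,
            seed=config.seed, threshold=config.threshold,
        )
        model.save(os.path.join(config.outdir, "model.json"))
        reports["test"] = evaluate(model.predict_scores(X_te), y_te, model.threshold)
        windows = [v.seq for v in vectors]
        reports.update(
            run_baselines(X, labels, columns, windows, seed=config.seed,
                          n_rounds=config.n_rounds, max_depth=config.max_depth)
        )
        _, cv_summary = cross_validate(
            X, labels, columns, k=config.cv_folds, seed=config.seed,
            n_rounds=config.n_rounds, max_depth=config.max_depth,
        )
        metrics = {name: rep.metrics() for name, rep in reports.items()}
        metrics["cv"] = {k: {"mean": m, "sd": s} for k, (m, s) in cv_summary.items()}
        with open(os.path.join(config.outdir, "metrics.json"), "w") as fh:
            json.dump(metrics, fh, indent=2)
        artifacts += ["model.json", "metrics.json"]

    if "profiles" in stages:
        pos_sites = [p.site for p in positives]
        motif = motif_metaprofile(pos_sites, dataset.reference.genome, halfwidth=10)
        meta = metagene_density(positives, dataset.reference.annotation)
        pd.DataFrame({"offset": motif.positions, "percent_drach": motif.values}).to_csv(
            os.path.join(config.outdir, "motif_profile.tsv"), sep="\t", index=False
        )
        pd.DataFrame({"position": meta.positions, "density": meta.values}).to_csv(
            os.path.join(config.outdir, "metagene_profile.tsv"), sep="\t", index=False
        )
        artifacts += ["motif_profile.tsv", "metagene_profile.tsv"]

    manifest = {
        "tool": f"m6akit {__version__}",
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "artifacts": artifacts,
    }
    with open(os.path.join(config.outdir, "provenance.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)

    return PipelineResult(
        config=config,
        dataset=dataset,
        diffmeth=results,
        model=model,
        reports=reports,
        cv_summary=cv_summary,
        artifacts=artifacts,
    )
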