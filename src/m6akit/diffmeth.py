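"""Expression-aware differential methylation testing of CLIP peaks.

Antibody CLIP signal scales with transcript abundance, so a naive contrast
of peak counts between wild-type and writer-knockout samples confounds
methylation loss with gene-expression change.  The bin-based strategy
stratifies genes by their expression log2 fold change and tests the peaks
of each stratum together, re-estimating sample normalization factors within
the stratum; the shared expression shift of a stratum is thereby absorbed
into its normalization and only methylation-specific changes remain.

The per-peak test is a negative-binomial Wald test: counts in condition c
are modelled as NB with mean mu_c and variance mu_c + phi * mu_c^2, the
per-peak method-of-moments dispersion is moderated toward the stratum
median, the effect is log2FC = log2((muKO+1)/(muWT+1)) with the standard
error from the delta method, and Benjamini-Hochberg adjustment is applied
across all peaks from all strata pooled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "estimate_size_factors",
    "gene_log2fc",
    "stratify_genes",
    "BinAssignment",
    "BinwiseDiffMeth",
    "DiffMethResults",
    "benjamini_hochberg",
    "compile_label_sets",
]

LN2 = np.log(2.0)
DISPERSION_FLOOR = 1e-8


def estimate_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios per-sample normalization factors.

    For each sample the factor is the median over genes of the ratio of the
    gene's count to its geometric mean across samples, computed on genes
    positive in every sample, then rescaled to geometric mean 1.  When no
    gene is positive everywhere, total-count ratios are used instead (with
    a warning).
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least two samples")
    mat = counts.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if positive.sum() == 0:
        warnings.warn("no gene positive in all samples; falling back to total-count ratios")
        totals = mat.sum(axis=0)
        factors = totals / np.exp(np.mean(np.log(totals)))
    else:
        sub = mat[positive]
        log_geo = np.mean(np.log(sub), axis=1, keepdims=True)
        ratios = np.log(sub) - log_geo
        factors = np.exp(np.median(ratios, axis=0))
        factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def gene_log2fc(
    expression: pd.DataFrame,
    wt_cols: Sequence[str],
    ko_cols: Sequence[str],
    size_factors: Optional[pd.Series] = None,
) -> pd.Series:
    """Per-gene expression log2FC (KO vs WT) on normalized means with a +1
    pseudocount: log2((mean_KO + 1) / (mean_WT + 1))."""
    if size_factors is None:
        size_factors = estimate_size_factors(expression)
    norm = expression / size_factors
    keep = expression.sum(axis=1) > 0
    mean_wt = norm.loc[keep, list(wt_cols)].mean(axis=1)
    mean_ko = norm.loc[keep, list(ko_cols)].mean(axis=1)
    return np.log2((mean_ko + 1.0) / (mean_wt + 1.0)).rename("log2fc")


@dataclass
class BinAssignment:
    """Mapping of genes to expression-change strata."""

    gene_bin: pd.Series  # gene id -> bin index
    edges: np.ndarray  # bin boundaries over gene log2FC, len = n_bins + 1

    @property
    def n_bins(self) -> int:
        return int(self.gene_bin.max()) + 1 if len(self.gene_bin) else 0


def stratify_genes(
    log2fc: pd.Series, n_bins: int = 20, min_genes: int = 10
) -> BinAssignment:
    """Equal-frequency (quantile) strata over gene expression log2FC.

    Ties are assigned to the lower stratum; strata with fewer than
    ``min_genes`` genes are merged with their nearest neighbor.  If there
    are fewer genes than strata, the stratum count is reduced with a
    warning.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    values = log2fc.dropna()
    n = len(values)
    if n == 0:
        raise ValueError("no genes to stratify")
    if n < n_bins:
        warnings.warn(f"only {n} genes; reducing n_bins from {n_bins} to {n}")
        n_bins = n
    qs = np.quantile(values.to_numpy(), np.linspace(0, 1, n_bins + 1))
    qs[0], qs[-1] = -np.inf, np.inf
    # right=True puts values equal to an edge into the lower stratum
    idx = np.searchsorted(qs[1:-1], values.to_numpy(), side="left")
    assign = pd.Series(idx, index=values.index)
    # merge underfilled strata into the nearest neighbor
    while True:
        sizes = assign.value_counts().sort_index()
        small = sizes[sizes < min_genes]
        if small.empty or len(sizes) == 1:
            break
        b = int(small.index[0])
        neighbors = [x for x in sizes.index if x != b]
        target = min(neighbors, key=lambda x: (abs(x - b), x))
        assign[assign == b] = target
    # re-index strata to consecutive integers preserving order
    remap = {old: new for new, old in enumerate(sorted(assign.unique()))}
    assign = assign.map(remap)
    return BinAssignment(gene_bin=assign, edges=qs)


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values; NaNs are excluded from the
    denominator and propagate."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    m = mask.sum()
    if m == 0:
        return out
    ps = p[mask]
    order = np.argsort(ps, kind="mergesort")
    ranked = ps[order] * m / (np.arange(m) + 1)
    # enforce monotonicity from the largest p down
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(ranked, 1.0)
    out[mask] = adj
    return out


@dataclass
class DiffMethResults:
    """Fitted differential-methylation results.

    ``table`` has one row per peak: base_mean, log2fc, se, pvalue, fdr,
    bin, dispersion.
    """

    table: pd.DataFrame
    mode: str
    size_factors: Dict[int, pd.Series] = field(default_factory=dict)

    def significant(self, fdr: float = 0.01, direction: str = "down") -> pd.DataFrame:
        sig = self.table[self.table["fdr"] <= fdr]
        if direction == "down":
            sig = sig[sig["log2fc"] < 0]
        elif direction == "up":
            sig = sig[sig["log2fc"] > 0]
        return sig

    def summary(self) -> str:
        t = self.table
        tested = t["pvalue"].notna().sum()
        lines = [
            f"Differential methylation ({self.mode})",
            "=" * 44,
            f"peaks:            {len(t)}",
            f"tested:           {tested}",
            f"strata:           {t['bin'].nunique()}",
            f"FDR<=0.01 & down: {len(self.significant(0.01))}",
            f"FDR<=0.05 & down: {len(self.significant(0.05))}",
            f"median |log2FC|:  {t['log2fc'].abs().median():.3f}",
        ]
        return "\n".join(lines)


class BinwiseDiffMeth:
    """Negative-binomial differential test of peak counts, stratified by
    host-gene expression change.

    Parameters
    ----------
    peak_counts : DataFrame, peaks x samples (integer counts)
    conditions : sequence of "WT"/"KO" labels, one per sample column
    peak_genes : Series mapping peak id -> host gene id
    bins : BinAssignment from :func:`stratify_genes`, or None for the
        one-run baseline (a single stratum containing all peaks)
    size_factors : optional per-sample factors used as a fallback when a
        stratum is too small for median-of-ratios re-estimation
    """

    def __init__(
        self,
        peak_counts: pd.DataFrame,
        conditions: Sequence[str],
        peak_genes: Optional[pd.Series] = None,
        bins: Optional[BinAssignment] = None,
        size_factors: Optional[pd.Series] = None,
    ):
        if len(conditions) != peak_counts.shape[1]:
            raise ValueError("one condition label per sample column required")
        conditions = list(conditions)
        for cond in ("WT", "KO"):
            if conditions.count(cond) < 2:
                raise ValueError(f"need >= 2 replicates for {cond}")
        self.peak_counts = peak_counts
        self.conditions = np.asarray(conditions)
        self.peak_genes = peak_genes
        self.bins = bins
        self.size_factors = size_factors
        if bins is not None and peak_genes is None:
            raise ValueError("peak_genes required for bin-based testing")

    # -- internals --------------------------------------------------------

    def _peak_bins(self) -> pd.Series:
        if self.bins is None:
            return pd.Series(0, index=self.peak_counts.index)
        mapped = self.peak_genes.reindex(self.peak_counts.index).map(self.bins.gene_bin)
        # peaks on unbinned genes are pooled into their own stratum
        return mapped.fillna(-1).astype(int)

    def _stratum_factors(self, sub: pd.DataFrame) -> pd.Series:
        # median-of-ratios needs enough peaks to separate the shared shift
        # from per-peak effects; tiny strata fall back to supplied factors
        # (or none) rather than totals, which would absorb the effect itself
        expressed = sub[(sub.sum(axis=1) > 0)]
        if len(expressed) >= 5 and ((expressed > 0).all(axis=1)).sum() >= 3:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                return estimate_size_factors(expressed)
        if self.size_factors is not None:
            return self.size_factors
        return pd.Series(1.0, index=sub.columns)

    @staticmethod
    def _mom_dispersion(norm: np.ndarray, wt_mask: np.ndarray, ko_mask: np.ndarray) -> np.ndarray:
        """Per-peak method-of-moments NB dispersion pooled over conditions:
        phi = sum_c (n_c-1)(s2_c - mu_c) / sum_c (n_c-1) mu_c^2, floored."""
        phis = np.zeros(norm.shape[0])
        num = np.zeros(norm.shape[0])
        den = np.zeros(norm.shape[0])
        for mask in (wt_mask, ko_mask):
            sub = norm[:, mask]
            n = sub.shape[1]
            mu = sub.mean(axis=1)
            s2 = sub.var(axis=1, ddof=1)
            num += (n - 1) * (s2 - mu)
            den += (n - 1) * mu**2
        with np.errstate(divide="ignore", invalid="ignore"):
            phis = np.where(den > 0, num / den, 0.0)
        return np.maximum(phis, DISPERSION_FLOOR)

    # -- fitting ----------------------------------------------------------

    def fit(self, dispersion_shrinkage: float = 0.5) -> DiffMethResults:
        """Run the stratified Wald test and pool BH adjustment across all
        peaks.  ``dispersion_shrinkage`` is the weight of the stratum
        median when moderating per-peak dispersions."""
        wt_mask = self.conditions == "WT"
        ko_mask = self.conditions == "KO"
        n_wt, n_ko = int(wt_mask.sum()), int(ko_mask.sum())
        peak_bins = self._peak_bins()

        rows: List[dict] = []
        factors_used: Dict[int, pd.Series] = {}
        for b in sorted(peak_bins.unique()):
            ids = peak_bins.index[peak_bins == b]
            sub = self.peak_counts.loc[ids]
            factors = self._stratum_factors(sub)
            factors_used[int(b)] = factors
            norm = sub.to_numpy(dtype=float) / factors.to_numpy()

            mu_wt = norm[:, wt_mask].mean(axis=1)
            mu_ko = norm[:, ko_mask].mean(axis=1)
            base_mean = norm.mean(axis=1)
            log2fc = np.log2((mu_ko + 1.0) / (mu_wt + 1.0))

            phi = self._mom_dispersion(norm, wt_mask, ko_mask)
            tested = sub.to_numpy().sum(axis=1) > 0
            med = np.median(phi[tested]) if tested.any() else DISPERSION_FLOOR
            w = dispersion_shrinkage
            phi_mod = np.maximum((1 - w) * phi + w * med, DISPERSION_FLOOR)

            # delta method on log2(mean+1): var = var(mean)/((mean+1) ln2)^2,
            # var(mean) = (mu + phi mu^2)/n per NB
            var_wt = (mu_wt + phi_mod * mu_wt**2) / n_wt
            var_ko = (mu_ko + phi_mod * mu_ko**2) / n_ko
            se = np.sqrt(var_wt / (mu_wt + 1.0) ** 2 + var_ko / (mu_ko + 1.0) ** 2) / LN2
            with np.errstate(divide="ignore", invalid="ignore"):
                z = np.where(se > 0, log2fc / se, 0.0)
            pvals = 2.0 * stats.norm.sf(np.abs(z))
            pvals = np.where(tested, pvals, np.nan)

            for i, pid in enumerate(ids):
                rows.append(
                    {
                        "peak_id": pid,
                        "base_mean": base_mean[i],
                        "log2fc": log2fc[i],
                        "se": se[i],
                        "pvalue": pvals[i],
                        "bin": int(b),
                        "dispersion": phi_mod[i],
                    }
                )

        columns = ["peak_id", "base_mean", "log2fc", "se", "pvalue", "bin", "dispersion"]
        table = pd.DataFrame(rows, columns=columns).set_index("peak_id")
        table = table.loc[self.peak_counts.index]
        table["fdr"] = benjamini_hochberg(table["pvalue"].to_numpy())
        mode = "one-run" if self.bins is None else "bin-based"
        return DiffMethResults(table=table, mode=mode, size_factors=factors_used)


def compile_label_sets(
    results: DiffMethResults,
    peaks: Sequence,
    fdr_positive: float = 0.01,
    fdr_negative: float = 0.5,
) -> Tuple[List, List]:
    """Split adenosine peaks into classifier training labels.

    Positive = central base A, log2FC < 0, FDR <= ``fdr_positive``
    (writer-dependent loss); negative = central base A, log2FC >= 0,
    FDR > ``fdr_negative`` (stable background).  Everything else — non-A
    peaks, intermediate FDR, untested peaks — belongs to neither set.
    """
    table = results.table
    positives, negatives = [], []
    for peak in peaks:
        if peak.base != "A" or peak.peak_id not in table.index:
            continue
        rec = table.loc[peak.peak_id]
        if np.isnan(rec["fdr"]):
            continue
        if rec["log2fc"] < 0 and rec["fdr"] <= fdr_positive:
            positives.append(peak)
        elif rec["log2fc"] >= 0 and rec["fdr"] > fdr_negative:
            negatives.append(peak)
    return positives, negatives
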