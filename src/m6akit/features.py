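"""The 27-feature representation of a peak and its numeric encoding.

Each classifiable peak carries 21 sequence features (the bases at offsets
-10..+10 around the central A, transcript orientation), one transcript
region label, the log2 relative signal strength and the log2(1 + n) count
of associated C-to-T transitions: 21 + 4 one-hot region indicators + 2
numeric columns once encoded, 90 matrix columns in total.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from m6akit.io import GenomicSite, fetch_window
from m6akit.peaks import Peak

__all__ = [
    "FeatureVector",
    "extract_features",
    "encode_matrix",
    "decode_sequences",
    "REGIONS",
    "BASES",
    "SEQ_OFFSETS",
]

REGIONS: Tuple[str, ...] = ("5UTR", "CDS", "3UTR", "other")
BASES: Tuple[str, ...] = ("A", "C", "G", "T")
SEQ_OFFSETS: Tuple[int, ...] = tuple(range(-10, 11))


@dataclass
class FeatureVector:
    """Named features for one peak (21-mer + region + 2 numerics)."""

    seq: str  # 21 bases, position 10 is the central A
    region: str
    rel_strength_log2: float
    ctot_log2: float

    def __post_init__(self) -> None:
        if len(self.seq) != 21:
            raise ValueError("sequence window must be 21 nt")
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")

    def named(self) -> dict:
        """The 27 named features as a flat dict: 21 window bases, the 4
        region indicators, and the two numeric features."""
        d = {f"seq[{off:+d}]": b for off, b in zip(SEQ_OFFSETS, self.seq)}
        for r in REGIONS:
            d[f"region={r}"] = int(self.region == r)
        d["rel_strength_log2"] = self.rel_strength_log2
        d["ctot_log2"] = self.ctot_log2
        assert len(d) == 27
        return d


def extract_features(
    peak: Peak,
    genome,
    transition_track=None,
    ctot_offsets: Sequence[int] = (0, 1),
    ctot_count: Optional[int] = None,
) -> FeatureVector:
    """Build the feature vector for an assigned peak.

    C-to-T transitions are summed at ``ctot_offsets`` relative to the peak
    base in transcript orientation (default {0, +1}: the crosslink-prone C
    of the AC dinucleotide sits at +1).  Pass ``ctot_count`` to use a
    precomputed per-peak transition count instead of a track.
    """
    if not peak.assigned:
        raise ValueError(f"peak {peak.peak_id or peak.site} is unassigned; filter before feature extraction")
    if peak.strength is None or peak.strength <= 0:
        raise ValueError(f"peak {peak.peak_id or peak.site}: relative signal strength not set")
    seq = fetch_window(genome, peak.site, flank=10)
    if ctot_count is None:
        total = 0
        if transition_track is not None:
            sign = 1 if peak.site.strand == "+" else -1
            for off in ctot_offsets:
                gpos = peak.site.pos + sign * off
                if gpos >= 0:
                    total += transition_track.transition_count(
                        GenomicSite(peak.site.chrom, gpos, peak.site.strand)
                    )
        else:
            total = peak.ctot
        ctot_count = total
    return FeatureVector(
        seq=seq,
        region=peak.region if peak.region in REGIONS else "other",
        rel_strength_log2=float(np.log2(peak.strength)),
        ctot_log2=float(np.log2(1 + ctot_count)),
    )


def _column_names() -> List[str]:
    cols = [f"seq[{off:+d}]={b}" for off in SEQ_OFFSETS for b in BASES]
    cols += [f"region={r}" for r in REGIONS]
    cols += ["rel_strength_log2", "ctot_log2"]
    return cols


def encode_matrix(vectors: Sequence[FeatureVector]) -> Tuple[np.ndarray, List[str]]:
    """Encode feature vectors as a numeric design matrix.

    Column order is fixed: 84 sequence one-hot columns (offsets -10..+10,
    bases A/C/G/T; an N leaves its block all-zero), 4 region one-hot
    columns, then the two numeric features — 90 columns.
    """
    if len(vectors) == 0:
        raise ValueError("empty feature list")
    cols = _column_names()
    mat = np.zeros((len(vectors), len(cols)), dtype=float)
    base_idx = {b: i for i, b in enumerate(BASES)}
    region_idx = {r: i for i, r in enumerate(REGIONS)}
    for row, fv in enumerate(vectors):
        for k, base in enumerate(fv.seq):
            j = base_idx.get(base)
            if j is not None:
                mat[row, 4 * k + j] = 1.0
        mat[row, 84 + region_idx[fv.region]] = 1.0
        mat[row, 88] = fv.rel_strength_log2
        mat[row, 89] = fv.ctot_log2
    return mat, cols


def decode_sequences(matrix: np.ndarray) -> List[str]:
    """Recover the 21-mers from the one-hot blocks (N where a block is
    all-zero); inverse of the sequence part of :func:`encode_matrix`."""
    out = []
    for row in matrix:
        seq = []
        for k in range(21):
            block = row[4 * k : 4 * k + 4]
            seq.append(BASES[int(np.argmax(block))] if block.sum() > 0 else "N")
        out.append("".join(seq))
    return out
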