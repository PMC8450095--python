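"""Peak consolidation: replicate reproducibility, transcript assignment,
relative signal strength and sequence context."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np

from m6akit.io import AnnotationIndex, GenomicSite, fetch_window

__all__ = [
    "Peak",
    "filter_reproducible",
    "assign_transcripts",
    "relative_signal_strength",
    "match_drach",
    "DRACH_PENTAMERS",
]


@dataclass
class Peak:
    """A single-nucleotide candidate site with its evidence and annotation."""

    site: GenomicSite
    peak_id: str = ""
    base: str = "N"
    counts: Dict[str, np.ndarray] = field(default_factory=dict)  # condition -> per-replicate
    ctot: int = 0
    transcript_id: Optional[str] = None
    gene_id: Optional[str] = None
    region: str = "other"
    strength: Optional[float] = None

    @property
    def assigned(self) -> bool:
        return self.transcript_id is not None

    def pooled_count(self, condition: str) -> float:
        return float(np.sum(self.counts.get(condition, np.zeros(0))))


def filter_reproducible(
    replicate_site_sets: Sequence[Iterable[GenomicSite]], min_rep: int = 2
) -> List[GenomicSite]:
    """Keep sites present (exact chrom+pos+strand identity) in at least
    ``min_rep`` replicate site sets; output sorted by coordinate."""
    if min_rep < 1:
        raise ValueError("min_rep must be >= 1")
    if min_rep > len(replicate_site_sets):
        raise ValueError(f"min_rep={min_rep} exceeds number of replicates ({len(replicate_site_sets)})")
    tally: Counter = Counter()
    exemplar: Dict[tuple, GenomicSite] = {}
    for sites in replicate_site_sets:
        seen = set()
        for s in sites:
            if s.key in seen:
                continue
            seen.add(s.key)
            tally[s.key] += 1
            exemplar.setdefault(s.key, s)
    kept = [exemplar[k] for k, n in tally.items() if n >= min_rep]
    kept.sort()
    return kept


def assign_transcripts(
    peaks: Iterable[Peak], annotation: AnnotationIndex, genome=None
) -> List[Peak]:
    """Assign each peak the longest covering same-strand transcript.

    Ties on spliced length go to the lexicographically smallest transcript
    id.  The region (5UTR/CDS/3UTR/other) is read off the winning model;
    non-overlapping peaks stay unassigned with region "other".  When a
    genome is supplied the central base is annotated strand-aware.
    """
    out = []
    for peak in peaks:
        hits = annotation.overlapping(peak.site)
        if hits:
            best = min(hits, key=lambda tx: (-tx.spliced_length, tx.transcript_id))
            peak.transcript_id = best.transcript_id
            peak.gene_id = best.gene_id
            peak.region = best.region_at(peak.site.pos)
        else:
            peak.transcript_id = None
            peak.gene_id = None
            peak.region = "other"
        if genome is not None:
            peak.base = fetch_window(genome, peak.site, 0)
        out.append(peak)
    return out


def relative_signal_strength(
    peaks: Iterable[Peak], condition: str = "WT", per_replicate: bool = False
) -> List[Peak]:
    """Set each assigned peak's relative signal strength.

    The strength is the peak's pooled truncation count for ``condition``
    divided by the mean pooled count over all peaks on the same transcript,
    which removes transcript-abundance effects (mean-normalization: the
    strengths on a transcript average to 1).  With ``per_replicate`` the
    ratio is computed per replicate and then averaged.
    """
    peaks = list(peaks)
    groups: Dict[str, List[Peak]] = {}
    for p in peaks:
        if p.assigned:
            groups.setdefault(p.transcript_id, []).append(p)
        else:
            p.strength = None
    for tx_id, members in groups.items():
        mat = np.array([m.counts.get(condition, np.zeros(1)) for m in members], dtype=float)
        if per_replicate:
            col_means = mat.mean(axis=0)
            if np.any(col_means == 0):
                raise ValueError(f"transcript {tx_id}: a replicate has all-zero peak counts")
            for m, row in zip(members, mat):
                m.strength = float(np.mean(row / col_means))
        else:
            pooled = mat.sum(axis=1)
            mean = pooled.mean()
            if mean == 0:
                raise ValueError(f"transcript {tx_id}: all-zero pooled counts, cannot normalize")
            for m, val in zip(members, pooled):
                m.strength = float(val / mean)
    return peaks


# ---------------------------------------------------------------------------
# DRACH motif
# ---------------------------------------------------------------------------

_D = set("AGT")  # D: not C
_R = set("AG")
_H = set("ACT")  # H: not G


def match_drach(pentamer: str) -> bool:
    """True iff the 5-mer matches the m6A consensus DRACH (DNA alphabet,
    U==T): positions D R A C H with the candidate A at position 3."""
    if len(pentamer) != 5:
        raise ValueError(f"pentamer must have length 5, got {len(pentamer)}")
    p = pentamer.upper().replace("U", "T")
    return (
        p[0] in _D
        and p[1] in _R
        and p[2] == "A"
        and p[3] == "C"
        and p[4] in _H
    )


def _all_drach() -> List[str]:
    return [
        d + r + "A" + "C" + h
        for d in sorted(_D)
        for r in sorted(_R)
        for h in sorted(_H)
    ]


#: The 18 concrete DRACH pentamers.
DRACH_PENTAMERS: List[str] = _all_drach()
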