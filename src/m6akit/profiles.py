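"""Positional and regional summaries: motif metaprofiles, scaled metagene
densities, and site-overlap statistics."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from m6akit.io import AnnotationIndex, GenomicSite, fetch_window
from m6akit.peaks import Peak, match_drach

__all__ = [
    "MetaProfile",
    "motif_metaprofile",
    "metagene_density",
    "window_overlap",
    "exact_overlap",
    "merge_binding_sites",
]


@dataclass
class MetaProfile:
    """A positional summary: offsets (or scaled bins) and a value per
    position, with the number of sites aggregated."""

    kind: str
    positions: np.ndarray
    values: np.ndarray
    n_sites: int
    region_bins: Optional[Dict[str, int]] = None

    def as_dict(self) -> Dict[float, float]:
        return dict(zip(self.positions.tolist(), self.values.tolist()))


def motif_metaprofile(
    sites: Sequence[GenomicSite],
    genome,
    motif: Callable[[str], bool] = match_drach,
    halfwidth: int = 20,
    motif_len: int = 5,
    anchor: int = 2,
) -> MetaProfile:
    """Percentage of sites whose window carries a motif whose anchor base
    (the A of DRACH) aligns at each offset in [-halfwidth, +halfwidth],
    strand-aware."""
    if halfwidth < motif_len:
        raise ValueError("halfwidth must be >= motif length")
    offsets = np.arange(-halfwidth, halfwidth + 1)
    if len(sites) == 0:
        return MetaProfile("motif", offsets, np.zeros(0), 0)
    hits = np.zeros(len(offsets))
    pad = halfwidth + motif_len  # room for motifs anchored at the edges
    for site in sites:
        window = fetch_window(genome, site, flank=pad)
        center = pad
        for i, off in enumerate(offsets):
            start = center + off - anchor
            if motif(window[start : start + motif_len]):
                hits[i] += 1
    return MetaProfile("motif", offsets, 100.0 * hits / len(sites), len(sites))


def metagene_density(
    peaks: Sequence[Peak],
    annotation: AnnotationIndex,
    bins: Tuple[int, int, int] = (50, 100, 50),
) -> MetaProfile:
    """Site density over scaled 5'UTR/CDS/3'UTR transcript coordinates.

    Each assigned site is mapped to its spliced position on its transcript,
    scaled to [0,1] within its region, and histogrammed with per-region bin
    counts; the three regions occupy [0,1), [1,2), [2,3) of the x-axis and
    the output is normalized so the profile integrates to 1.  Sites on
    transcripts without a CDS (or intronic) are excluded.
    """
    tx_by_id = {tx.transcript_id: tx for tx in annotation.transcripts}
    n5, nc, n3 = bins
    edges = np.concatenate(
        [np.linspace(0, 1, n5, endpoint=False), np.linspace(1, 2, nc, endpoint=False), np.linspace(2, 3, n3 + 1)]
    )
    counts = np.zeros(n5 + nc + n3)
    n_used = 0
    for peak in peaks:
        tx = tx_by_id.get(peak.transcript_id)
        if tx is None or tx.cds_length == 0:
            continue
        sp = tx.genomic_to_spliced(peak.site.pos)
        if sp is None:
            continue
        u5, cd, u3 = tx.utr5_length, tx.cds_length, tx.utr3_length
        if sp < u5:
            x = sp / u5 if u5 else 0.0
        elif sp < u5 + cd:
            x = 1.0 + (sp - u5) / cd
        else:
            x = 2.0 + (sp - u5 - cd) / u3 if u3 else 3.0 - 1e-9
        x = min(x, 3.0 - 1e-12)
        idx = int(np.searchsorted(edges, x, side="right")) - 1
        counts[idx] += 1
        n_used += 1
    widths = np.diff(edges)
    values = counts / (counts.sum() * widths) if n_used else counts
    centers = edges[:-1] + widths / 2
    return MetaProfile(
        "metagene", centers, values, n_used, region_bins={"5UTR": n5, "CDS": nc, "3UTR": n3}
    )


def window_overlap(
    query: Sequence[GenomicSite],
    reference: Sequence[GenomicSite],
    halfwidth: int = 10,
) -> Tuple[MetaProfile, float]:
    """Per-offset percentage of query sites with a reference site at that
    offset (strand-aware, transcript orientation), plus the fraction of
    query sites with at least one reference site within the window."""
    offsets = np.arange(-halfwidth, halfwidth + 1)
    ref_keys = {s.key for s in reference}
    if len(query) == 0:
        return MetaProfile("overlap", offsets, np.zeros(len(offsets)), 0), 0.0
    hits = np.zeros(len(offsets))
    n_with_any = 0
    for q in query:
        sign = 1 if q.strand == "+" else -1
        any_hit = False
        for i, off in enumerate(offsets):
            gpos = q.pos + sign * off
            if gpos >= 0 and (q.chrom, gpos, q.strand) in ref_keys:
                hits[i] += 1
                any_hit = True
        n_with_any += any_hit
    profile = MetaProfile("overlap", offsets, 100.0 * hits / len(query), len(query))
    return profile, n_with_any / len(query)


def exact_overlap(
    a: Iterable[GenomicSite], b: Iterable[GenomicSite]
) -> Tuple[int, int, int]:
    """Single-nucleotide overlap: (|A and B|, |A only|, |B only|) by exact
    chrom+pos+strand identity."""
    ka = {s.key for s in a}
    kb = {s.key for s in b}
    return len(ka & kb), len(ka - kb), len(kb - ka)


def merge_binding_sites(
    sites: Sequence[GenomicSite],
    counts: Optional[Dict[Tuple[str, int, str], float]] = None,
    min_gap: int = 4,
) -> List[GenomicSite]:
    """Merge single-nucleotide peaks closer than ``min_gap`` nt into
    binding sites centred on the position with the highest truncation
    count (ties to the 5'-most position)."""
    by_group: Dict[Tuple[str, str], List[GenomicSite]] = {}
    for s in sites:
        by_group.setdefault((s.chrom, s.strand), []).append(s)
    out: List[GenomicSite] = []
    for (chrom, strand), group in by_group.items():
        group.sort(key=lambda s: s.pos)
        cluster: List[GenomicSite] = []
        for s in group + [None]:
            if s is not None and (not cluster or s.pos - cluster[-1].pos < min_gap):
                cluster.append(s)
                continue
            if cluster:
                def count_of(x: GenomicSite) -> float:
                    return counts.get(x.key, x.score) if counts else x.score
                best_count = max(count_of(x) for x in cluster)
                tied = [x for x in cluster if count_of(x) == best_count]
                center = min(tied, key=lambda x: x.pos) if strand == "+" else max(tied, key=lambda x: x.pos)
                out.append(center)
            cluster = [s] if s is not None else []
    out.sort()
    return out
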