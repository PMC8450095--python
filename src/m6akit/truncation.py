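"""Truncation and C-to-T transition track extraction from CLIP alignments.

Reverse transcription truncates one nucleotide downstream of the crosslinked
base, so for reads without a C-to-T transition the crosslink is recorded one
nucleotide upstream of the read 5' end (pos-1 on the plus strand, 5'end+1 on
the minus strand).  Reads carrying at least one C-to-T transition (read
space: reference C read as T on plus-strand reads, reference G read as A on
minus-strand reads) are the readthrough channel: each such mismatch position
is counted in the transition track and the read contributes no truncation.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import pysam

from m6akit.io import GenomicSite, write_bedgraph

__all__ = ["TruncationTrack", "extract_tracks", "detect_candidates"]

Key = Tuple[str, str]  # (chrom, strand)


@dataclass
class TruncationTrack:
    """Strand-specific sparse per-position truncation and transition counts."""

    sample_id: str
    truncations: Dict[Key, Counter] = field(default_factory=dict)
    transitions: Dict[Key, Counter] = field(default_factory=dict)
    n_reads: int = 0
    n_truncation_reads: int = 0
    n_transition_reads: int = 0
    n_skipped: int = 0
    n_softclipped5: int = 0

    @property
    def total_truncations(self) -> int:
        return sum(sum(c.values()) for c in self.truncations.values())

    def add_truncation(self, chrom: str, strand: str, pos: int, n: int = 1) -> None:
        self.truncations.setdefault((chrom, strand), Counter())[pos] += n

    def add_transition(self, chrom: str, strand: str, pos: int, n: int = 1) -> None:
        self.transitions.setdefault((chrom, strand), Counter())[pos] += n

    def truncation_count(self, site: GenomicSite) -> int:
        return self.truncations.get((site.chrom, site.strand), Counter()).get(site.pos, 0)

    def transition_count(self, site: GenomicSite) -> int:
        return self.transitions.get((site.chrom, site.strand), Counter()).get(site.pos, 0)

    def write_bedgraphs(self, prefix: str) -> List[str]:
        """Write four strand-split bedGraph files (<prefix>.<channel>.<strand>.bedgraph)."""
        paths = []
        for channel, data in (("truncation", self.truncations), ("transition", self.transitions)):
            for strand, tag in (("+", "plus"), ("-", "minus")):
                per_chrom = {
                    chrom: dict(counts)
                    for (chrom, st), counts in data.items()
                    if st == strand and counts
                }
                path = f"{prefix}.{channel}.{tag}.bedgraph"
                write_bedgraph(per_chrom, path)
                paths.append(path)
        return paths


def _read_ct_mismatches(read: pysam.AlignedSegment) -> List[int]:
    """Genomic positions of C-to-T transitions (read space) in one read.

    Requires MD tags (or an attached reference) so mismatched reference
    bases are available; only single-base substitutions inside aligned
    blocks are considered.
    """
    try:
        pairs = read.get_aligned_pairs(with_seq=True)
    except ValueError as exc:
        raise ValueError(
            "alignment lacks mismatch information; regenerate MD tags "
            "(e.g. `samtools calmd`) before track extraction"
        ) from exc
    seq = read.query_sequence
    out: List[int] = []
    for qpos, rpos, rbase in pairs:
        if qpos is None or rpos is None or rbase is None:
            continue
        if rbase.islower():  # lowercase marks a mismatch
            qbase = seq[qpos].upper()
            if not read.is_reverse and rbase.upper() == "C" and qbase == "T":
                out.append(rpos)
            elif read.is_reverse and rbase.upper() == "G" and qbase == "A":
                out.append(rpos)
    return out


def extract_tracks(alignments, sample_id: str = "sample") -> TruncationTrack:
    """Build a :class:`TruncationTrack` from de-duplicated alignments.

    ``alignments`` is a pysam.AlignmentFile, a path to SAM/BAM, or any
    iterable of AlignedSegment.  Unmapped/secondary/supplementary records
    are skipped and counted; reads whose shifted truncation position would
    fall before the start of the contig are skipped too.
    """
    if isinstance(alignments, str):
        alignments = pysam.AlignmentFile(alignments)
    track = TruncationTrack(sample_id=sample_id)
    for read in alignments:
        if read.is_unmapped or read.is_secondary or read.is_supplementary:
            track.n_skipped += 1
            continue
        track.n_reads += 1
        chrom = read.reference_name
        strand = "-" if read.is_reverse else "+"
        cigar = read.cigartuples or []
        # 5' soft clips are prohibited at mapping; tolerate but count them
        if strand == "+" and cigar and cigar[0][0] == 4:
            track.n_softclipped5 += 1
        elif strand == "-" and cigar and cigar[-1][0] == 4:
            track.n_softclipped5 += 1

        ct_positions = _read_ct_mismatches(read)
        if ct_positions:
            track.n_transition_reads += 1
            for pos in ct_positions:
                track.add_transition(chrom, strand, pos)
        else:
            # crosslink = one nt upstream of the read 5' end
            pos = read.reference_start - 1 if strand == "+" else read.reference_end
            if pos < 0:
                track.n_skipped += 1
                track.n_reads -= 1
                continue
            track.n_truncation_reads += 1
            track.add_truncation(chrom, strand, pos)
    return track


def detect_candidates(
    track: TruncationTrack,
    min_count: int = 5,
    local_window: int = 15,
    min_enrichment: float = 2.0,
) -> List[GenomicSite]:
    """Simple single-nucleotide candidate detector on a truncation track.

    A position is reported when its truncation count is at least
    ``min_count``, is a local maximum within ``local_window`` nt (ties
    broken to the 5'-most position in transcript orientation) and exceeds
    ``min_enrichment`` times the local background, defined as
    ``(sum of neighbor counts + 1) / (2 * local_window)``.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    if local_window < 3:
        raise ValueError("local_window must be >= 3")
    out: List[GenomicSite] = []
    for (chrom, strand), counts in track.truncations.items():
        for pos, count in counts.items():
            if count < min_count:
                continue
            neighbor_sum = 0
            is_max = True
            for off in range(-local_window, local_window + 1):
                if off == 0:
                    continue
                other = counts.get(pos + off, 0)
                neighbor_sum += other
                if other > count:
                    is_max = False
                    break
                if other == count:
                    # tie goes to the 5'-most position
                    more_5prime = (off < 0) if strand == "+" else (off > 0)
                    if more_5prime:
                        is_max = False
                        break
            if not is_max:
                continue
            background = (neighbor_sum + 1.0) / (2 * local_window)
            if count > min_enrichment * background:
                out.append(GenomicSite(chrom, pos, strand, score=count))
    out.sort()
    return out
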