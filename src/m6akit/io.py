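"""Reference I/O: genome windows, GENCODE-style annotation, BED and bedGraph.

All internal coordinates are 0-based half-open; a single-nucleotide site is
the offset of the (possibly modified) base itself.  GTF input (1-based
inclusive) is converted on load; BED and bedGraph are native.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from intervaltree import IntervalTree

__all__ = [
    "GenomicSite",
    "TranscriptModel",
    "AnnotationIndex",
    "load_annotation",
    "fetch_window",
    "reverse_complement",
    "read_sites",
    "write_sites",
    "read_bedgraph",
    "write_bedgraph",
    "GtfParseError",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomicSite:
    """A single nucleotide: contig, 0-based offset and strand."""

    chrom: str
    pos: int
    strand: str
    name: str = field(default="", compare=False)
    score: float = field(default=0.0, compare=False)

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"negative position {self.pos} on {self.chrom}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def key(self) -> Tuple[str, int, str]:
        return (self.chrom, self.pos, self.strand)


Interval = Tuple[int, int]


def _total_length(ivs: Sequence[Interval]) -> int:
    return sum(e - s for s, e in ivs)


def _intersect(ivs: Sequence[Interval], start: int, end: int) -> List[Interval]:
    out = []
    for s, e in ivs:
        s2, e2 = max(s, start), min(e, end)
        if s2 < e2:
            out.append((s2, e2))
    return out


@dataclass
class TranscriptModel:
    """A spliced transcript with exon/CDS structure and derived UTRs.

    Exons are sorted, disjoint 0-based half-open genomic intervals; CDS
    intervals are contained in the exons.  UTRs are derived as the exonic
    sequence 5'/3' of the CDS in transcript orientation.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: List[Interval]
    cds: List[Interval] = field(default_factory=list)
    tsl: Optional[int] = None
    level: Optional[int] = None

    def __post_init__(self) -> None:
        self.exons = sorted(tuple(x) for x in self.exons)
        self.cds = sorted(tuple(x) for x in self.cds)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        for s, e in self.cds:
            if not any(s >= xs and e <= xe for xs, xe in self.exons):
                raise ValueError(f"{self.transcript_id}: CDS outside exons")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def spliced_length(self) -> int:
        return _total_length(self.exons)

    def genomic_to_spliced(self, pos: int) -> Optional[int]:
        """Map a genomic position to its 0-based offset along the spliced
        transcript (5' to 3' in transcript orientation), or None if intronic
        or outside the transcript."""
        off = 0
        for s, e in self.exons:
            if s <= pos < e:
                plus_off = off + (pos - s)
                if self.strand == "+":
                    return plus_off
                return self.spliced_length - 1 - plus_off
            off += e - s
        return None

    def spliced_to_genomic(self, offset: int) -> int:
        """Inverse of :meth:`genomic_to_spliced` for exonic offsets."""
        if not 0 <= offset < self.spliced_length:
            raise ValueError(f"spliced offset {offset} out of range")
        plus_off = offset if self.strand == "+" else self.spliced_length - 1 - offset
        for s, e in self.exons:
            if plus_off < e - s:
                return s + plus_off
            plus_off -= e - s
        raise AssertionError("unreachable")

    def _cds_spliced_bounds(self) -> Optional[Tuple[int, int]]:
        if not self.cds:
            return None
        offs = []
        for s, e in self.cds:
            a = self.genomic_to_spliced(s)
            b = self.genomic_to_spliced(e - 1)
            offs.extend([a, b])
        if any(o is None for o in offs):
            return None
        return min(offs), max(offs) + 1  # half-open in spliced coords

    @property
    def utr5_length(self) -> int:
        b = self._cds_spliced_bounds()
        return b[0] if b else 0

    @property
    def cds_length(self) -> int:
        b = self._cds_spliced_bounds()
        return (b[1] - b[0]) if b else 0

    @property
    def utr3_length(self) -> int:
        b = self._cds_spliced_bounds()
        return (self.spliced_length - b[1]) if b else 0

    def region_at(self, pos: int) -> str:
        """Region label at a genomic position: 5UTR / CDS / 3UTR / other."""
        sp = self.genomic_to_spliced(pos)
        if sp is None:
            return "other"
        b = self._cds_spliced_bounds()
        if b is None:
            return "other"
        if sp < b[0]:
            return "5UTR"
        if sp < b[1]:
            return "CDS"
        return "3UTR"


class AnnotationIndex:
    """Point-lookup index over retained transcript models."""

    def __init__(self, transcripts: Iterable[TranscriptModel]):
        self.transcripts: List[TranscriptModel] = list(transcripts)
        self._trees: Dict[str, IntervalTree] = {}
        self.genes: Dict[str, List[TranscriptModel]] = {}
        for tx in self.transcripts:
            self._trees.setdefault(tx.chrom, IntervalTree()).addi(tx.start, tx.end, tx)
            self.genes.setdefault(tx.gene_id, []).append(tx)

    def __len__(self) -> int:
        return len(self.transcripts)

    def overlapping(self, site: GenomicSite, same_strand: bool = True) -> List[TranscriptModel]:
        tree = self._trees.get(site.chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.at(site.pos)]
        if same_strand:
            hits = [tx for tx in hits if tx.strand == site.strand]
        return hits


class GtfParseError(ValueError):
    pass


def _parse_attributes(text: str) -> Dict[str, str]:
    attrs: Dict[str, str] = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if " " not in chunk:
            continue
        key, _, val = chunk.partition(" ")
        attrs[key] = val.strip().strip('"')
    return attrs


def load_annotation(
    gtf_path: str,
    tsl_max: Optional[int] = 3,
    level_max: Optional[int] = 2,
    keep_missing_tsl: bool = False,
) -> AnnotationIndex:
    """Load a GENCODE-dialect GTF into an :class:`AnnotationIndex`.

    Transcripts whose transcript_support_level exceeds ``tsl_max`` are
    dropped, as are transcripts lacking a TSL unless ``keep_missing_tsl``.
    When an annotation ``level`` attribute is present, transcripts with
    level > ``level_max`` are dropped too (set ``level_max=None`` to skip).
    Transcripts whose CDS falls outside their exons are rejected with a
    warning rather than aborting the load.
    """
    exons: Dict[str, List[Interval]] = {}
    cds: Dict[str, List[Interval]] = {}
    meta: Dict[str, Dict[str, object]] = {}

    with open(gtf_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise GtfParseError(f"{gtf_path}:{lineno}: expected 9 tab-separated fields, got {len(parts)}")
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attr_s = parts
            if feature not in ("exon", "CDS", "transcript"):
                continue
            try:
                start, end = int(start_s) - 1, int(end_s)  # 1-based inclusive -> 0-based half-open
            except ValueError as exc:
                raise GtfParseError(f"{gtf_path}:{lineno}: non-integer coordinates") from exc
            if start < 0 or end <= start:
                raise GtfParseError(f"{gtf_path}:{lineno}: invalid interval [{start_s},{end_s}]")
            attrs = _parse_attributes(attr_s)
            tid = attrs.get("transcript_id")
            if tid is None:
                raise GtfParseError(f"{gtf_path}:{lineno}: missing transcript_id attribute")
            if tid not in meta:
                meta[tid] = {
                    "gene_id": attrs.get("gene_id", tid),
                    "chrom": chrom,
                    "strand": strand,
                    "tsl": None,
                    "level": None,
                }
            tsl_raw = attrs.get("transcript_support_level")
            if tsl_raw is not None and tsl_raw.split()[0].isdigit():
                meta[tid]["tsl"] = int(tsl_raw.split()[0])
            if attrs.get("level", "").isdigit():
                meta[tid]["level"] = int(attrs["level"])
            if feature == "exon":
                exons.setdefault(tid, []).append((start, end))
            elif feature == "CDS":
                cds.setdefault(tid, []).append((start, end))

    retained: List[TranscriptModel] = []
    for tid, m in meta.items():
        if tid not in exons:
            continue
        tsl = m["tsl"]
        if tsl_max is not None:
            if tsl is None:
                if not keep_missing_tsl:
                    continue
            elif tsl > tsl_max:
                continue
        if level_max is not None and m["level"] is not None and m["level"] > level_max:
            continue
        try:
            tx = TranscriptModel(
                transcript_id=tid,
                gene_id=m["gene_id"],
                chrom=m["chrom"],
                strand=m["strand"],
                exons=exons[tid],
                cds=cds.get(tid, []),
                tsl=tsl,
                level=m["level"],
            )
        except ValueError as exc:
            warnings.warn(f"rejecting transcript {tid}: {exc}")
            continue
        retained.append(tx)
    return AnnotationIndex(retained)


# ---------------------------------------------------------------------------
# genome windows
# ---------------------------------------------------------------------------

def _contig_seq(genome, chrom: str) -> str:
    """Return the full sequence of a contig from a pyfaidx.Fasta or a plain
    mapping of contig name to sequence string."""
    try:
        rec = genome[chrom]
    except KeyError as exc:
        raise KeyError(f"unknown contig {chrom!r}") from exc
    return str(rec[:]) if hasattr(rec, "__getitem__") and not isinstance(rec, str) else str(rec)


def fetch_window(genome, site: GenomicSite, flank: int) -> str:
    """Fetch ``2*flank+1`` uppercase bases centered on ``site``.

    The window is reverse-complemented for minus-strand sites and padded
    with N beyond contig ends, so position ``flank`` of the result is always
    the site's own base read in transcript orientation.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    seq = _contig_seq(genome, site.chrom)
    start, end = site.pos - flank, site.pos + flank + 1
    left_pad = max(0, -start)
    right_pad = max(0, end - len(seq))
    window = "N" * left_pad + seq[max(0, start):min(len(seq), end)].upper() + "N" * right_pad
    if site.strand == "-":
        window = reverse_complement(window)
    return window


# ---------------------------------------------------------------------------
# BED6 single-nucleotide sites
# ---------------------------------------------------------------------------

def read_sites(bed_path: str) -> List[GenomicSite]:
    """Read single-nucleotide sites from a BED6 file (length-1 intervals)."""
    sites: List[GenomicSite] = []
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise ValueError(f"{bed_path}:{lineno}: BED6 requires 6 columns")
            chrom, start, end, name, score, strand = parts[:6]
            start, end = int(start), int(end)
            if end - start != 1:
                raise ValueError(f"{bed_path}:{lineno}: site records must be length-1 intervals")
            sites.append(GenomicSite(chrom, start, strand, name=name, score=float(score)))
    return sites


def write_sites(sites: Iterable[GenomicSite], bed_path: str) -> None:
    with open(bed_path, "w") as fh:
        for s in sites:
            score = int(s.score) if float(s.score).is_integer() else s.score
            fh.write(f"{s.chrom}\t{s.pos}\t{s.pos + 1}\t{s.name or '.'}\t{score}\t{s.strand}\n")


# ---------------------------------------------------------------------------
# bedGraph (one file per strand)
# ---------------------------------------------------------------------------

def read_bedgraph(path: str) -> Dict[str, Dict[int, float]]:
    """Read a bedGraph file into per-contig sparse position->value maps.

    Runs are expanded to single positions; overlapping intervals are an
    error, as are negative values.
    """
    track: Dict[str, Dict[int, float]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end, value = line.split()[:4]
            start, end, value = int(start), int(end), float(value)
            if value < 0:
                raise ValueError(f"{path}:{lineno}: negative value {value}")
            per = track.setdefault(chrom, {})
            for pos in range(start, end):
                if pos in per:
                    raise ValueError(f"{path}:{lineno}: overlapping interval at {chrom}:{pos}")
                per[pos] = value
    return track


def write_bedgraph(per_chrom: Mapping[str, Mapping[int, float]], path: str) -> None:
    """Write sparse per-position values as a bedGraph, merging adjacent
    equal-value runs."""
    with open(path, "w") as fh:
        for chrom in sorted(per_chrom):
            positions = sorted(per_chrom[chrom])
            i = 0
            while i < len(positions):
                j = i
                val = per_chrom[chrom][positions[i]]
                while (
                    j + 1 < len(positions)
                    and positions[j + 1] == positions[j] + 1
                    and per_chrom[chrom][positions[j + 1]] == val
                ):
                    j += 1
                out_val = int(val) if float(val).is_integer() else val
                fh.write(f"{chrom}\t{positions[i]}\t{positions[j] + 1}\t{out_val}\n")
                i = j + 1
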