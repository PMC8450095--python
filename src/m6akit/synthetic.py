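"""Synthetic antibody-CLIP m6A data with known ground truth.

The generator emulates the statistical structure the pipeline assumes:
a random transcriptome with 5'UTR/CDS/3'UTR genes; true m6A sites planted
on A, concentrated near stop codons, mostly inside DRACH pentamers with a
configurable non-DRACH fraction; a uridine-biased antibody background of
candidate peaks; negative-binomial count noise across replicates; loss of
signal in the knockout restricted to true sites; gene-expression shifts in
the knockout that confound raw peak fold changes; and C-to-T readthrough
transitions at crosslink-adjacent cytosines.

Everything is deterministic under the config seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from m6akit.io import AnnotationIndex, GenomicSite, TranscriptModel, reverse_complement
from m6akit.peaks import DRACH_PENTAMERS, Peak, match_drach

__all__ = [
    "SimConfig",
    "SyntheticReference",
    "SyntheticTruth",
    "SyntheticDataset",
    "simulate_reference",
    "plant_truth",
    "simulate_counts",
    "simulate_dataset",
    "emit_sam",
]

_BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class SimConfig:
    """Study conditions for the synthetic generator.

    Defaults describe the standard desk-scale fixture: 400 genes, 800 true
    sites (6.3% at non-DRACH motifs), 4,000 background peaks, 3+3
    replicates, residual methylation 0.1 in the knockout, a quarter of the
    genes shifted in expression with log2FC ~ Normal(0, 1.5), NB dispersion
    0.1 and a 6% C-to-T readthrough rate.
    """

    seed: int = 42
    n_genes: int = 400
    n_contigs: int = 8
    utr5_range: Tuple[int, int] = (100, 200)
    cds_range: Tuple[int, int] = (300, 1500)  # rounded down to a codon multiple
    utr3_range: Tuple[int, int] = (200, 600)
    intergenic_spacer: int = 100
    n_true_sites: int = 800
    frac_non_drach: float = 0.063
    stop_codon_weight: float = 0.7  # fraction of true sites drawn near the stop codon
    stop_codon_sd: float = 50.0  # spliced-nt spread of the stop-codon component
    n_background_peaks: int = 4000
    background_base_probs: Tuple[Tuple[str, float], ...] = (
        ("T", 0.50),
        ("A", 0.30),
        ("C", 0.10),
        ("G", 0.10),
    )
    frac_background_drach: float = 0.17  # of background A peaks: unmethylated DRACH
    frac_background_ac: float = 0.30  # of remaining background A peaks: AC dinucleotide
    replicates: int = 3
    mean_true_coverage: float = 100.0
    true_coverage_sigma: float = 0.5  # lognormal sigma
    mean_background_coverage: float = 30.0
    background_coverage_sigma: float = 0.8
    dispersion: float = 0.1  # NB: var = mu + phi mu^2
    ko_residual: float = 0.1
    meth_level_range: Tuple[float, float] = (0.6, 1.0)
    frac_genes_shifted: float = 0.25
    shift_sd: float = 1.5  # sd of the Normal log2FC of shifted genes
    expression_mean: float = 500.0
    expression_sigma: float = 1.0
    expression_dispersion: float = 0.05
    ctot_rate: float = 0.06
    background_ctot_rate: float = 0.02  # readthrough at nonspecific crosslinks
    min_site_separation: int = 8

    def __post_init__(self) -> None:
        for name in ("frac_non_drach", "ko_residual", "frac_genes_shifted", "ctot_rate",
                     "frac_background_drach", "frac_background_ac", "stop_codon_weight"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_genes", "n_true_sites", "n_background_peaks", "replicates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=list)


@dataclass
class SyntheticReference:
    genome: Dict[str, str]
    transcripts: List[TranscriptModel]

    @property
    def annotation(self) -> AnnotationIndex:
        return AnnotationIndex(self.transcripts)

    def write_fasta(self, path: str) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.genome):
                fh.write(f">{chrom}\n")
                seq = self.genome[chrom]
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")

    def write_gtf(self, path: str) -> None:
        with open(path, "w") as fh:
            for tx in self.transcripts:
                attrs = (
                    f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}"; '
                    f'transcript_support_level "{tx.tsl}"; level {tx.level};'
                )
                rows = [("transcript", tx.start, tx.end)]
                rows += [("exon", s, e) for s, e in tx.exons]
                rows += [("CDS", s, e) for s, e in tx.cds]
                for feature, s, e in rows:
                    fh.write(
                        f"{tx.chrom}\tsim\t{feature}\t{s + 1}\t{e}\t.\t{tx.strand}\t.\t{attrs}\n"
                    )


@dataclass
class PlantedSite:
    site: GenomicSite
    gene_id: str
    transcript_id: str
    pentamer: str
    is_drach: bool
    is_true: bool
    meth_level: float = 1.0
    base: str = "A"


@dataclass
class SyntheticTruth:
    true_sites: List[PlantedSite]
    background_sites: List[PlantedSite]
    gene_shift_log2: pd.Series  # per-gene expression log2FC planted in the KO

    @property
    def all_sites(self) -> List[PlantedSite]:
        return self.true_sites + self.background_sites


# ---------------------------------------------------------------------------
# reference
# ---------------------------------------------------------------------------

def simulate_reference(config: SimConfig) -> SyntheticReference:
    """Random transcriptome: single-exon genes with UTR/CDS structure laid
    out head-to-tail on a handful of contigs, alternating strands at
    random."""
    rng = np.random.default_rng(config.seed)
    contigs: List[List[str]] = [[] for _ in range(config.n_contigs)]
    offsets = [0] * config.n_contigs
    transcripts: List[TranscriptModel] = []
    for g in range(config.n_genes):
        u5 = int(rng.integers(*config.utr5_range))
        cds = int(rng.integers(*config.cds_range)) // 3 * 3
        u3 = int(rng.integers(*config.utr3_range))
        length = u5 + cds + u3
        c = g % config.n_contigs
        chrom = f"chr{c + 1}"
        start = offsets[c] + config.intergenic_spacer
        seq = "".join(rng.choice(list(_BASES), size=length))
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            cds_iv = (start + u5, start + u5 + cds)
        else:
            cds_iv = (start + u3, start + u3 + cds)
        tx = TranscriptModel(
            transcript_id=f"tx{g:04d}",
            gene_id=f"gene{g:04d}",
            chrom=chrom,
            strand=strand,
            exons=[(start, start + length)],
            cds=[cds_iv],
            tsl=1,
            level=1,
        )
        transcripts.append(tx)
        contigs[c].append("N" * config.intergenic_spacer + seq)
        offsets[c] = start + length
    genome = {f"chr{c + 1}": "".join(parts) for c, parts in enumerate(contigs)}
    # fill the leading N spacers with random sequence so windows stay DNA
    genome = {
        chrom: "".join(
            b if b != "N" else rng.choice(list(_BASES)) for b in seq
        )
        for chrom, seq in genome.items()
    }
    return SyntheticReference(genome=genome, transcripts=transcripts)


# ---------------------------------------------------------------------------
# truth planting
# ---------------------------------------------------------------------------

def _plant_pentamer(genome: Dict[str, List[str]], tx: TranscriptModel, pos: int, pentamer: str) -> None:
    """Write a pentamer into the genome centred at ``pos`` in transcript
    orientation (reverse-complemented on the minus strand)."""
    seq = genome[tx.chrom]
    if tx.strand == "+":
        for off, base in zip(range(-2, 3), pentamer):
            seq[pos + off] = base
    else:
        for off, base in zip(range(-2, 3), pentamer):
            seq[pos - off] = _COMP[base]


def _random_non_drach_A(rng: np.random.Generator, force_ac: bool) -> str:
    """A pentamer with central A that does not match DRACH; with
    ``force_ac`` the +1 base is C (crosslink-prone AC dinucleotide)."""
    while True:
        p = list(rng.choice(list(_BASES), size=5))
        p[2] = "A"
        if force_ac:
            p[3] = "C"
            # break the DRACH consensus elsewhere
            p[0] = "C" if rng.random() < 0.5 else p[0]
            p[1] = str(rng.choice(["C", "T"]))
        pent = "".join(p)
        if not match_drach(pent):
            return pent


_DRACH_WEIGHTS = np.array([3.0 if p == "GGACT" else 2.0 if p in ("GAACT", "AGACT") else 1.0 for p in DRACH_PENTAMERS])
_DRACH_WEIGHTS = _DRACH_WEIGHTS / _DRACH_WEIGHTS.sum()


def plant_truth(reference: SyntheticReference, config: SimConfig) -> SyntheticTruth:
    """Choose and plant true m6A sites and background peaks in the genome.

    True sites are placed on A within transcripts with positional weight
    elevated around the stop codon; the configured fraction is planted at
    non-DRACH pentamers (biased to AC).  Background peaks carry a
    uridine-biased central base; a small fraction of background A peaks
    sit in full (unmethylated) DRACH motifs.  Planting mutates the genome
    in place so every site's sequence context is guaranteed.
    """
    rng = np.random.default_rng(config.seed + 1)
    genome_mut = {c: list(s) for c, s in reference.genome.items()}
    occupied: Dict[str, set] = {c: set() for c in reference.genome}
    txs = reference.transcripts

    def reserve(tx: TranscriptModel, pos: int) -> bool:
        span = range(pos - config.min_site_separation, pos + config.min_site_separation + 1)
        occ = occupied[tx.chrom]
        if any(p in occ for p in span):
            return False
        occ.update(range(pos - 4, pos + 5))
        return True

    def sample_true_position() -> Tuple[TranscriptModel, int]:
        while True:
            tx = txs[int(rng.integers(len(txs)))]
            u5, cd = tx.utr5_length, tx.cds_length
            lo, hi = u5 + 3, tx.spliced_length - 11
            if rng.random() < config.stop_codon_weight:
                sp = int(rng.normal(u5 + cd, config.stop_codon_sd))
            else:
                sp = int(rng.integers(lo, hi))
            if not lo <= sp < hi:
                continue
            pos = tx.spliced_to_genomic(sp)
            if reserve(tx, pos):
                return tx, pos

    def sample_background_position() -> Tuple[TranscriptModel, int]:
        while True:
            tx = txs[int(rng.integers(len(txs)))]
            sp = int(rng.integers(11, tx.spliced_length - 11))
            pos = tx.spliced_to_genomic(sp)
            if reserve(tx, pos):
                return tx, pos

    n_non = int(round(config.n_true_sites * config.frac_non_drach))
    is_non_drach = np.zeros(config.n_true_sites, dtype=bool)
    is_non_drach[rng.choice(config.n_true_sites, size=n_non, replace=False)] = True

    true_sites: List[PlantedSite] = []
    for i in range(config.n_true_sites):
        tx, pos = sample_true_position()
        if is_non_drach[i]:
            pent = _random_non_drach_A(rng, force_ac=rng.random() < 0.7)
        else:
            pent = DRACH_PENTAMERS[int(rng.choice(len(DRACH_PENTAMERS), p=_DRACH_WEIGHTS))]
        _plant_pentamer(genome_mut, tx, pos, pent)
        true_sites.append(
            PlantedSite(
                site=GenomicSite(tx.chrom, pos, tx.strand, name=f"true{i:04d}"),
                gene_id=tx.gene_id,
                transcript_id=tx.transcript_id,
                pentamer=pent,
                is_drach=not is_non_drach[i],
                is_true=True,
                meth_level=float(rng.uniform(*config.meth_level_range)),
            )
        )

    bases, probs = zip(*config.background_base_probs)
    background: List[PlantedSite] = []
    for i in range(config.n_background_peaks):
        tx, pos = sample_background_position()
        base = str(rng.choice(bases, p=np.asarray(probs) / np.sum(probs)))
        if base == "A":
            if rng.random() < config.frac_background_drach:
                pent = DRACH_PENTAMERS[int(rng.choice(len(DRACH_PENTAMERS), p=_DRACH_WEIGHTS))]
                is_drach = True
            else:
                pent = _random_non_drach_A(rng, force_ac=rng.random() < config.frac_background_ac)
                is_drach = False
        else:
            p = list(rng.choice(list(_BASES), size=5))
            p[2] = base
            pent = "".join(p)
            is_drach = False
        _plant_pentamer(genome_mut, tx, pos, pent)
        background.append(
            PlantedSite(
                site=GenomicSite(tx.chrom, pos, tx.strand, name=f"bg{i:05d}"),
                gene_id=tx.gene_id,
                transcript_id=tx.transcript_id,
                pentamer=pent,
                is_drach=is_drach,
                is_true=False,
                base=base,
            )
        )

    reference.genome = {c: "".join(s) for c, s in genome_mut.items()}

    gene_ids = [tx.gene_id for tx in txs]
    shifts = np.zeros(len(gene_ids))
    n_shift = int(round(config.frac_genes_shifted * len(gene_ids)))
    idx = rng.choice(len(gene_ids), size=n_shift, replace=False)
    shifts[idx] = rng.normal(0.0, config.shift_sd, size=n_shift)
    return SyntheticTruth(
        true_sites=true_sites,
        background_sites=background,
        gene_shift_log2=pd.Series(shifts, index=gene_ids),
    )


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def _nb(rng: np.random.Generator, mu: np.ndarray, phi: float, size=None) -> np.ndarray:
    """NB draws with variance mu + phi mu^2 (phi -> 0 recovers Poisson)."""
    mu = np.asarray(mu, dtype=float)
    if phi <= 0:
        return rng.poisson(mu, size=size)
    r = 1.0 / phi
    p = r / (r + mu)
    return rng.negative_binomial(r, p, size=size)


@dataclass
class SimulatedCounts:
    peak_counts: pd.DataFrame  # peaks x samples
    peak_genes: pd.Series
    expression: pd.DataFrame  # genes x samples
    transitions: pd.Series  # pooled WT C-to-T count per peak
    sample_conditions: List[str]
    wt_strength: pd.Series  # expected WT coverage per peak


def simulate_counts(
    reference: SyntheticReference, truth: SyntheticTruth, config: SimConfig
) -> SimulatedCounts:
    """Draw per-replicate peak counts, expression counts and C-to-T
    transition counts consistent with the planted truth.

    A peak's WT mean is its site coverage; in the KO the mean is scaled by
    the gene's planted expression factor and, for true sites only, by the
    residual methylation fraction.  Transitions are Binomial(coverage, r)
    at peaks whose +1 base (transcript orientation) is C.
    """
    rng = np.random.default_rng(config.seed + 2)
    sites = truth.all_sites
    n = len(sites)
    reps = config.replicates
    columns = [f"WT_{i + 1}" for i in range(reps)] + [f"KO_{i + 1}" for i in range(reps)]
    conditions = ["WT"] * reps + ["KO"] * reps

    is_true = np.array([s.is_true for s in sites])
    meth = np.array([s.meth_level for s in sites])
    gene_of = np.array([s.gene_id for s in sites])
    shift = truth.gene_shift_log2.reindex(gene_of).to_numpy()
    ko_expr = 2.0**shift

    strength = np.where(
        is_true,
        rng.lognormal(np.log(config.mean_true_coverage), config.true_coverage_sigma, size=n),
        rng.lognormal(np.log(config.mean_background_coverage), config.background_coverage_sigma, size=n),
    )
    mu_wt = strength * np.where(is_true, meth, 1.0)
    mu_ko = mu_wt * ko_expr * np.where(is_true, config.ko_residual, 1.0)

    counts = np.empty((n, 2 * reps), dtype=int)
    for j in range(reps):
        counts[:, j] = _nb(rng, mu_wt, config.dispersion)
        counts[:, reps + j] = _nb(rng, mu_ko, config.dispersion)
    ids = [s.site.name for s in sites]
    peak_counts = pd.DataFrame(counts, index=ids, columns=columns)

    genes = truth.gene_shift_log2.index
    base_expr = rng.lognormal(np.log(config.expression_mean), config.expression_sigma, size=len(genes))
    expr = np.empty((len(genes), 2 * reps), dtype=int)
    ko_factor = 2.0 ** truth.gene_shift_log2.to_numpy()
    for j in range(reps):
        expr[:, j] = _nb(rng, base_expr, config.expression_dispersion)
        expr[:, reps + j] = _nb(rng, base_expr * ko_factor, config.expression_dispersion)
    expression = pd.DataFrame(expr, index=genes, columns=columns)

    # C-to-T readthrough at the crosslink-adjacent cytosine (+1 in
    # transcript orientation), pooled over WT replicates
    transitions = np.zeros(n, dtype=int)
    for i, s in enumerate(sites):
        gpos = s.site.pos + (1 if s.site.strand == "+" else -1)
        seq = reference.genome[s.site.chrom]
        if 0 <= gpos < len(seq):
            base = seq[gpos] if s.site.strand == "+" else _COMP[seq[gpos]]
            if base == "C":
                cov = int(round(mu_wt[i] * reps))
                rate = config.ctot_rate if s.is_true else config.background_ctot_rate
                transitions[i] = rng.binomial(cov, rate) if cov > 0 else 0

    return SimulatedCounts(
        peak_counts=peak_counts,
        peak_genes=pd.Series(gene_of, index=ids),
        expression=expression,
        transitions=pd.Series(transitions, index=ids),
        sample_conditions=conditions,
        wt_strength=pd.Series(mu_wt, index=ids),
    )


# ---------------------------------------------------------------------------
# one-call dataset
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    config: SimConfig
    reference: SyntheticReference
    truth: SyntheticTruth
    counts: SimulatedCounts

    def as_peaks(self) -> List[Peak]:
        """The planted sites as :class:`Peak` objects carrying replicate
        counts, transition counts, transcript assignment and central base."""
        reps = self.config.replicates
        peaks = []
        for planted in self.truth.all_sites:
            row = self.counts.peak_counts.loc[planted.site.name].to_numpy()
            peaks.append(
                Peak(
                    site=planted.site,
                    peak_id=planted.site.name,
                    base=planted.base,
                    counts={"WT": row[:reps].astype(float), "KO": row[reps:].astype(float)},
                    ctot=int(self.counts.transitions.loc[planted.site.name]),
                    transcript_id=planted.transcript_id,
                    gene_id=planted.gene_id,
                )
            )
        return peaks

    def write(self, outdir: str) -> None:
        import os

        os.makedirs(outdir, exist_ok=True)
        self.reference.write_fasta(os.path.join(outdir, "genome.fa"))
        self.reference.write_gtf(os.path.join(outdir, "annotation.gtf"))
        self.counts.peak_counts.to_csv(os.path.join(outdir, "peak_counts.tsv"), sep="\t")
        self.counts.expression.to_csv(os.path.join(outdir, "expression.tsv"), sep="\t")
        self.counts.transitions.rename("ctot").to_csv(os.path.join(outdir, "transitions.tsv"), sep="\t")
        with open(os.path.join(outdir, "truth.bed"), "w") as fh:
            for s in self.truth.true_sites:
                fh.write(
                    f"{s.site.chrom}\t{s.site.pos}\t{s.site.pos + 1}\t{s.site.name}"
                    f"\t{int(round(100 * s.meth_level))}\t{s.site.strand}\n"
                )
        with open(os.path.join(outdir, "config.json"), "w") as fh:
            fh.write(self.config.to_json())


def simulate_dataset(config: Optional[SimConfig] = None, seed: Optional[int] = None) -> SyntheticDataset:
    """Reference + truth + counts in one deterministic call."""
    if config is None:
        config = SimConfig()
    if seed is not None:
        config = SimConfig(**{**asdict(config), "seed": seed})
    reference = simulate_reference(config)
    truth = plant_truth(reference, config)
    counts = simulate_counts(reference, truth, config)
    return SyntheticDataset(config=config, reference=reference, truth=truth, counts=counts)


# ---------------------------------------------------------------------------
# read-level emitter (for truncation-track testing)
# ---------------------------------------------------------------------------

def _md_tag(ref: str, read: str) -> str:
    """MD tag for an ungapped alignment (substitutions only)."""
    out, run = [], 0
    for r, q in zip(ref, read):
        if r == q:
            run += 1
        else:
            out.append(str(run))
            out.append(r)
            run = 0
    out.append(str(run))
    return "".join(out)


def emit_sam(
    reference: SyntheticReference,
    sites: Sequence[PlantedSite],
    path: str,
    reads_per_site: int = 10,
    read_length: int = 30,
    ctot_fraction: float = 0.1,
    seed: int = 0,
) -> None:
    """Write a small SAM file of reads whose truncations mark the given
    sites, with a fraction of C-to-T readthrough reads.

    Truncated reads start one nucleotide downstream of the site (5' end at
    site+1 in transcript orientation); readthrough reads span the site and
    carry a C-to-T substitution at the first crosslink-adjacent C.
    """
    rng = np.random.default_rng(seed)
    genome = reference.genome
    lines = ["@HD\tVN:1.6\tSO:unknown"]
    for chrom in sorted(genome):
        lines.append(f"@SQ\tSN:{chrom}\tLN:{len(genome[chrom])}")
    rid = 0
    for planted in sites:
        s = planted.site
        seq = genome[s.chrom]
        for k in range(reads_per_site):
            readthrough = rng.random() < ctot_fraction
            if s.strand == "+":
                start = s.pos + 1 - (5 if readthrough else 0)
            else:
                end = s.pos + (5 if readthrough else 0)
                start = end - read_length
            if start < 0 or start + read_length > len(seq):
                continue
            ref_slice = seq[start : start + read_length].upper()
            read = list(ref_slice)
            if readthrough:
                # mutate the first C (plus) / G (minus) to mimic readthrough
                target, repl = ("C", "T") if s.strand == "+" else ("G", "A")
                for i, b in enumerate(read):
                    if b == target:
                        read[i] = repl
                        break
                else:
                    readthrough = False
            read_s = "".join(read)
            flag = 16 if s.strand == "-" else 0
            md = _md_tag(ref_slice, read_s)
            nm = sum(1 for a, b in zip(ref_slice, read_s) if a != b)
            lines.append(
                f"r{rid:06d}\t{flag}\t{s.chrom}\t{start + 1}\t255\t{read_length}M\t*\t0\t0"
                f"\t{read_s}\t{'I' * read_length}\tNM:i:{nm}\tMD:Z:{md}"
            )
            rid += 1
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
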