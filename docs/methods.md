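# Methods

This note documents the models, conventions and design decisions behind
`m6akit`, in the order data flows through the package.

## Coordinates and evidence channels

All internal coordinates are 0-based half-open; a single-nucleotide site is
the offset of the (possibly modified) base itself. GTF input (1-based
inclusive) is converted on load; BED and bedGraph are used natively.

Reads are de-duplicated, uniquely mapped, single-end alignments. Each read
contributes to exactly one of two channels:

- **Truncation channel** — reads without a C-to-T transition. The crosslink
  is recorded one nucleotide upstream of the read 5′ end: `pos − 1` for
  plus-strand reads, `5′end + 1` (i.e. the alignment end) for minus-strand
  reads. The one-base shift is applied in genomic coordinates, strand-aware,
  which is the natural reading of "one base pair upstream" for a 5′-end
  track. Reads whose shifted position would be negative are skipped and
  counted.
- **Transition channel** — reads with ≥ 1 C-to-T transition in read space
  (reference C read as T on plus-strand reads; reference G read as A on
  minus-strand reads). Every such mismatch position is counted at its
  genomic coordinate, unshifted; the read contributes no truncation.
  Classification uses only single-base substitutions inside aligned blocks;
  indels and other mismatches are ignored. Missing mismatch information
  (no MD tag) is an error directing the user to `samtools calmd`.

5′ soft-clipping is expected to be prohibited at mapping; if present the
first aligned base is used and a warning counter increments.

The bundled candidate detector (`detect_candidates`) is plumbing, not a
statistical peak caller: a position is reported when its count reaches
`min_count`, is a local maximum within `±local_window` (ties to the 5′-most
position in transcript orientation) and exceeds `min_enrichment` times the
local background `(Σ neighbors + 1)/(2·local_window)`.

## Annotation and peak annotation

GENCODE-dialect GTFs are filtered on load: transcripts with
transcript_support_level > `tsl_max` (default 3) are dropped, as are
transcripts lacking a TSL (a flag retains them; conservative default) and —
when the attribute is present — transcripts with annotation `level` >
`level_max` (default 2). Both filters are exposed because the combination
"support level ≤ 3 and support level ≤ 2" admits either reading; neither is
assumed correct alone.

Replicate reproducibility is exact single-nucleotide identity
(chrom+pos+strand), default ≥ 2 replicates; no merge radius, so resolution
claims are untouched. Each kept site is assigned the *longest* covering
same-strand transcript (spliced length; ties to the lexicographically
smallest transcript id), and its region read off that model.

**Relative signal strength** of a peak is its pooled truncation count for a
condition divided by the mean pooled count over all peaks on the same
transcript. This removes transcript-abundance effects; strengths on a
transcript average to exactly 1, and the quantity is invariant to library
scaling. Pooling across replicates before normalizing is the default; a
per-replicate-then-average mode is available by flag.

## Differential methylation

The test asks, per peak, whether counts drop in the knockout beyond what
the host gene's expression change explains.

1. **Gene stratification.** Gene expression log2FC (KO vs WT) is computed
   on median-of-ratios-normalized means with a +1 pseudocount, then genes
   are cut into equal-frequency bins (default 20; bins under 10 genes are
   merged with their nearest neighbor; ties go to the lower bin). The bin
   count and minimum are declared defaults, exposed via config.
2. **Per-bin normalization.** Within each bin, sample normalization factors
   are re-estimated from that bin's peak-count submatrix by
   median-of-ratios. This is the step that makes the approach robust to
   expression confounding: genes in a bin share a similar shift, so the
   shift lands in the factors rather than in per-peak fold changes. Strata
   too small for a stable median (fewer than 5 expressed peaks or fewer
   than 3 all-positive peaks) fall back to externally supplied factors or
   to unit factors — never to column totals, which would absorb the effect
   being tested. The *one-run* baseline is the identical procedure with a
   single bin containing all peaks.
3. **NB Wald test.** Counts follow NB with Var = μ + φμ². The per-peak
   method-of-moments dispersion, pooled over conditions as
   φ̂ = Σ_c (n_c−1)(s²_c − μ̂_c) / Σ_c (n_c−1) μ̂²_c, is moderated toward the
   bin median by a weighted mean (weight 0.5, floor 1e−8). The effect is
   log2FC = log₂((μ̂_KO+1)/(μ̂_WT+1)) — the same pseudocount form as the
   gene-level fold change — with SE from the delta method,
   Var(log₂(μ̂+1)) = (μ̂+φμ̂²)/n / ((μ̂+1) ln2)², and a two-sided normal
   p-value on z = log2FC/SE. The +1 pseudocount keeps low-count peaks
   stable at the cost of mild shrinkage of extreme fold changes.
4. **FDR.** Benjamini–Hochberg across all peaks from all bins pooled, so
   one transcriptome-wide FDR per peak. Peaks with zero counts everywhere
   are reported untested (NaN p/FDR) and excluded from the BH denominator.

The Wald test with moderated dispersion is implemented directly rather than
delegated to an external differential-expression framework; its p-values
are validated in the test suite by rank concordance (Spearman ≥ 0.95)
against a negative-binomial likelihood-ratio oracle with closed-form mean
MLEs, and by planted-effect recovery. Exact numerical agreement with any
particular external framework is not a goal.

**Training labels.** Positives are adenosine peaks with log2FC < 0 and
FDR ≤ 0.01; negatives are adenosine peaks with log2FC ≥ 0 and FDR > 0.5.
Non-A peaks, intermediate-FDR peaks and untested peaks belong to neither
set. Thresholds are configurable.

## Features and classifier

Each classifiable (assigned, strength-bearing) peak yields 27 named
features: the 21 bases at offsets −10…+10 in transcript orientation, four
one-hot region indicators (5′UTR/CDS/3′UTR/other), log₂ relative signal
strength, and log₂(1 + C-to-T count). This 21+4+2 composition is the only
decomposition consistent with the stated feature families and the count.
C-to-T transitions are associated to a peak at offsets {0, +1} relative to
the central A — the crosslink-prone C of the AC dinucleotide sits at +1 —
with the window configurable. Encoding is a fixed-order 90-column matrix:
84 sequence one-hot columns (N leaves its block all-zero), 4 region
columns, 2 numerics.

The classifier is discrete two-class AdaBoost: at round *t* a depth-≤3
tree is fitted to the weighted sample (weak learners are scikit-learn
decision trees; the boosting loop, vote weights and score are implemented
here); with weighted error ε_t the vote weight is α_t = ½·ln((1−ε_t)/ε_t),
misclassified weights are multiplied by e^{α_t}, correct ones by e^{−α_t},
then renormalized. Boosting stops early at ε_t ≥ 0.5 (learner discarded) or
ε_t = 0 (perfect learner kept with a capped α). Defaults: 100 rounds,
depth 3 — AdaBoost hyperparameters are not dictated by the method itself,
so these are declared defaults, all exposed. The prediction score is the
α-weighted fraction of positive votes, in [0,1]; threshold 0.5 by default.
Class composition is preserved as given (no re-balancing): background
dominance is part of the problem the classifier must handle. The train/test
split (80/20) is stratified by default with a non-stratified flag. After
training, every tree is flattened to plain arrays and all prediction runs
through an in-package traversal, so the JSON text serialization reloads to
a bit-identical predictor.

Evaluation reports confusion counts and the standard derived metrics
(precision, sensitivity, specificity, accuracy, F1, MCC, error rate) plus a
precision–recall curve integrated without interpolation
(AUC = Σ (R_i − R_{i−1})·P_i over distinct thresholds). Baselines: the
same booster on the 84 sequence columns only ("sequence-only"), on the
region+strength+C-to-T columns only ("feature-only"), and the deterministic
DRACH filter (positive iff the central pentamer matches the consensus),
reported as a single precision/recall point.

## Profiles

- `motif_metaprofile`: per offset in ±halfwidth, the percentage of sites
  whose window contains a motif match anchored (at the A for DRACH) at that
  offset, strand-aware.
- `metagene_density`: sites mapped to spliced coordinates of their assigned
  (longest) transcript, scaled to [0,1] within 5′UTR/CDS/3′UTR, histogrammed
  with 50/100/50 bins (declared defaults) and normalized to integrate to 1
  over the three unit-length regions. Sites on CDS-less transcripts are
  excluded from the scaled profile.
- `window_overlap`: per-offset percentage of query sites with a reference
  site at that offset within a 21-nt window, plus the fraction with ≥ 1 hit.
- `exact_overlap`: single-nucleotide set intersection for Venn-style output.
- `merge_binding_sites`: helper merging peaks closer than 4 nt and centring
  on the maximum-count position (5′-most tie-break).

## Synthetic study conditions

The generator produces a random single-exon transcriptome (UTR5 100–200 nt,
CDS 300–1500 nt rounded to codons, UTR3 200–600 nt) and plants truth into
the genome in place, so every site's sequence context is guaranteed.
Defaults define the standard fixture: seed 42; 400 genes on 8 contigs; 800
true sites; 4,000 background peaks; 3+3 replicates.

- **True sites** sit on A, with 70% of positions drawn from a Gaussian
  (σ = 50 spliced nt) around the stop codon and the rest uniform —
  reproducing the characteristic stop-codon/3′UTR enrichment. 6.3% are
  planted at non-DRACH pentamers (biased toward retaining the AC
  dinucleotide), matching the reported fraction of genuine non-DRACH m⁶A.
  Methylation levels are U(0.6, 1).
- **Background peaks** carry a uridine-biased central base
  (T 50%, A 30%, C 10%, G 10%). Of the background *adenosine* peaks, 17%
  are planted inside full DRACH motifs: this is the unmethylated-DRACH
  background implied by the published composition, where only a minority of
  all DRACH-situated peaks are writer-dependent — it is what makes a plain
  DRACH filter imprecise and the classifier necessary. A further 30% of
  non-DRACH background A peaks keep an AC dinucleotide.
- **Counts** are NB with Var = μ + φμ², φ = 0.1. WT peak means are
  lognormal (median 100 for true sites, 30 for background). KO means are
  scaled by the gene's planted expression factor and, for true sites only,
  by the residual methylation fraction 0.1. A quarter of genes receive an
  expression shift with log2FC ~ N(0, 1.5), applied identically to their
  peaks and to the gene-level expression table (NB, φ = 0.05) — this is the
  confound the bin-based test must absorb.
- **C-to-T transitions** are Binomial(coverage, r) at peaks whose +1 base
  (transcript orientation) is C — readthrough over the crosslink hits the
  C of the AC dinucleotide — with r = 0.06 at true sites (the observed
  overall readthrough fraction) and 0.02 at nonspecific background
  crosslinks. The lower background rate encodes the observation that the
  C-to-T count ranks among the most informative classifier features, which
  requires it to carry information beyond coverage. Sites without a C at +1
  get none.
- An optional read-level emitter writes small SAM files (ungapped reads
  with MD tags) whose truncations and readthrough substitutions mark chosen
  sites, for exercising track extraction.

Everything is deterministic under the config seed (byte-identical outputs).

What the generator does **not** emulate: PCR duplication, mapping error and
multimapping, soft-clipping, indels, intron-containing genes (the
transcript machinery supports them; the generator plants single-exon
genes), the 5′-cap m⁶Am artifact, antibody batch effects, and any
nucleotide-composition realism beyond the planted motifs. Passing tests
therefore demonstrate correctness of the statistical machinery and the
end-to-end logic under the declared generative model — not performance on
real libraries, where background structure is richer.

## Numerical choices and degenerate inputs

- Dispersion floor 1e−8; moderation weight 0.5 toward the stratum median.
- +1 pseudocount on normalized means for all fold changes.
- BH excludes untested peaks from the denominator; their FDR is NaN.
- Quantile-bin ties go to the lower bin; underfilled bins merge nearest.
- All-zero strength groups and single-class training sets raise errors
  rather than producing silent output.
- Window fetches past contig ends are N-padded; N one-hot blocks are
  all-zero and decoding maps them back to N.
- Candidate-detector ties break to the 5′-most position in transcript
  orientation, on both strands.

## Problem sizes

The test suite and the acceptance script run the standard fixture (4,800
peaks, 6 samples, ~1,250 labeled examples) plus smaller per-module
fixtures; these sizes were chosen so the complete workflow — simulation,
two differential-methylation fits, feature extraction, classifier training
with baselines and 5-fold cross-validation — executes in well under a
minute on one core while leaving planted-effect recovery statistically
crisp (hundreds of true sites per measurement).
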