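# m6akit

Single-nucleotide N6-methyladenosine (m⁶A) site calling from antibody-based
CLIP truncation data.

Antibody CLIP protocols map m⁶A at nucleotide resolution through
reverse-transcription truncations: the cDNA 5′ end marks the position one
nucleotide downstream of the crosslinked base, while residual readthrough
events leave C-to-T transitions as a second evidence channel. The catch is
that m⁶A antibodies crosslink promiscuously — most peaks sit on uridines and
unmodified adenosines — so raw peak calls are dominated by background.
`m6akit` implements the two-stage computational strategy for separating
genuine, writer-dependent m⁶A sites from that background:

1. **Expression-aware differential methylation.** Peaks are tested between
   wild-type and methyltransferase-knockout (e.g. *Mettl3* KO) samples with
   a negative-binomial Wald test. Because CLIP signal scales with transcript
   abundance, and the knockout massively remodels gene expression, peaks are
   *stratified into bins of genes with a similar expression change* and each
   bin is normalized and tested on its own. The shared expression shift of a
   bin is absorbed into its normalization factors, so only methylation-
   specific losses remain significant. Per peak the test reports
   log2FC = log₂((μ_KO+1)/(μ_WT+1)) with a delta-method standard error under
   Var(X) = μ + φμ², moderated method-of-moments dispersions, and
   Benjamini–Hochberg adjustment pooled across all bins.
2. **A boosted site classifier.** Knockout-derived labels — adenosine peaks
   with (log2FC < 0, FDR ≤ 0.01) as positives and (log2FC ≥ 0, FDR > 0.5)
   as negatives — train a discrete AdaBoost ensemble of depth-3 trees on 27
   features per peak: the 21-nt sequence window around the central A, the
   transcript region (5′UTR/CDS/3′UTR/other), the log₂ relative signal
   strength, and the log₂ count of associated C-to-T transitions. The
   trained model then predicts m⁶A sites in new datasets *without* a
   knockout, with a [0,1] score whose threshold tunes precision vs recall.

Everything upstream and downstream is included: annotation loading with
transcript-support-level filtering and longest-isoform assignment, track
extraction from SAM/BAM, replicate-reproducibility filtering, relative
signal strength, DRACH-motif utilities (the 18-pentamer
D[A/G/U] R[G/A] A C H[U/A/C] consensus), motif metaprofiles, scaled metagene
densities, site-overlap statistics, and a deterministic synthetic-data
generator that plants known m⁶A sites so the whole workflow is testable at
desk scale.

## Worked example

The `run` subcommand simulates a full study (400 genes, 800 planted m⁶A
sites of which 6.3% at non-DRACH motifs, 4,000 background peaks, 3 WT + 3 KO
replicates, 90% methylation loss in the KO, a quarter of genes with
confounded expression) and pushes it through the whole workflow:

```
$ m6akit run --seed 42 --out demo/
Differential methylation (bin-based)
============================================
peaks:            4800
tested:           4800
strata:           20
FDR<=0.01 & down: 819
FDR<=0.05 & down: 848
median |log2FC|:  0.455
n = 250  (TP 159 / FP 13 / TN 76 / FN 2)
pr_auc       0.9893
f1           0.9550
mcc          0.8697
precision    0.9244
accuracy     0.9400
sensitivity  0.9876
specificity  0.8539
error_rate   0.0600
```

The first block is the knockout contrast: of 4,800 candidate peaks, 819 are
called significantly depleted in the KO at FDR ≤ 0.01 — almost exactly the
800 planted sites, because the bin-based stratification keeps peaks on
down-regulated genes from masquerading as methylation losses. The second
block evaluates the classifier on its held-out 20% test split: the
precision–recall AUC of 0.989 and MCC of 0.87 summarize how well the
27-feature model separates planted sites from antibody background without
using the knockout at prediction time.

The same steps are available as library calls:

```python
from m6akit import SimConfig, simulate_dataset
from m6akit.pipeline import prepare_labeled_peaks

dataset = simulate_dataset(SimConfig(seed=42))
peaks, results, positives, negatives = prepare_labeled_peaks(dataset)
print(results.summary())
```

and as individual subcommands (`m6akit simulate`, `truncate`, `peaks`,
`diffmeth`, `train`, `predict`, `evaluate`, `cv`) operating on standard
formats (SAM/BAM, FASTA, GTF, BED6, bedGraph, TSV).

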