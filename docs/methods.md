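# Methods

This note documents the statistical models, conventions and design
choices behind `methtf`, and what the synthetic validation does and does
not demonstrate.

## Coordinates and overlap semantics

All internal coordinates are 0-based, half-open (BED convention). Vendor
probe-manifest positions, which are 1-based, are converted exactly once at
read time. CpG probes are treated as single-base points at the cytosine
coordinate, not as 50-mer probe bodies: a probe at position *p* overlaps
an interval [s, e) iff s ≤ p < e. Strand is ignored throughout because
CpG methylation is strand-symmetric. Chromosome names are matched by
exact string equality (after trimming); an optional flag adds a "chr"
prefix, but no silent renaming happens by default, so mismatched genomes
surface as zero overlaps rather than wrong ones.

Overlap queries run on sorted start/end arrays of union-merged, disjoint
intervals via binary search; unit and end-to-end tests pin this to the
brute-force all-pairs contract exactly.

## Differential methylation

β values (methylated fraction, [0, 1]) are transformed to M-values,
M = log₂(β′/(1−β′)) with β′ clipped to [ε, 1−ε], ε = 10⁻³ by default.
Arrays do produce β of exactly 0 or 1; the clip keeps M finite while
leaving the interior of the range untouched (the β→M→β round trip is the
identity to 10⁻¹² on [0.01, 0.99]). Testing happens on the M scale, which
is closer to homoscedastic; effects are additionally reported as Δβ for
interpretability.

Each probe is tested for a condition effect with a moderated t. The
paired (donor-blocked) design is the default — each donor contributes one
sample per condition, and the statistic is built on per-donor M
differences — because the intended study design derives both conditions
from the same donors; an unpaired pooled-variance design is available by
flag. Per-probe residual variances s²_g (df d_g) are shrunk toward a
prior: s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g), with t referred to a
t-distribution on d₀ + d_g degrees of freedom. The hyperparameters
(d₀, s₀²) are fitted by method of moments on z = log s²: under the
scaled-F model the excess of Var(z) over the chi-square contribution
trigamma(d_g/2) identifies trigamma(d₀/2), which is inverted by Newton
iteration; a non-positive excess maps to d₀ = 10⁶, representing "infinite"
prior df (complete pooling) without special-casing infinities. With
shrinkage disabled the statistic reduces exactly to the ordinary paired or
two-sample t-test, which the tests verify against an independent
implementation to 10⁻⁸.

Degenerate probes: a probe with missing values is tested on its available
samples and flagged; fewer than two usable values in a condition yields
t = 0, p = 1 and a `low_n` flag rather than an error. A probe with zero
residual variance and zero effect gets t = 0, p = 1; zero variance with a
non-zero effect (only possible without shrinkage) gets ±∞ and a floored
p. P-values are floored at 10⁻³⁰⁰ so downstream logs stay finite.

Multiple testing uses Benjamini–Hochberg by default (Holm/Bonferroni are
configurable); significant probes (adjusted p ≤ α, default 0.05) are
classified hypo or hyper by the sign of Δ mean M. Swapping the condition
labels exactly negates effects and swaps the two classes.

## Genomic context

Both context analyses (CpG-island relation; chromatin state) share one
normalisation: observed percentages are computed within each significant
group — hypo and hyper separately, each summing to 100 — and expected
percentages from all probes on the supplied manifest. The array, not the
genome, is the background, since the array's probe placement is itself
biased. Per category and group, a two-sided Fisher exact test compares
significant in/out of the category against background in/out; BH runs
jointly across the (category × group) family. An empty group reports NA
counts and ratios without erroring.

Chromatin segmentations must be non-overlapping within a chromosome
(violations are a hard error naming the offending pairs); probes outside
every segment fall into an explicit `Unassigned` category so counts always
conserve.

The per-state methylation shift compares per-probe condition means of β,
restricted to probes with |Δβ| ≥ 0.001 (a 0.1% methylation-difference
cutoff), using a two-sided Wilcoxon signed-rank test across probes. The
Wilcoxon choice is for robustness against the skewed, bounded β scale; a
paired t is available by flag. States with fewer than 10 qualifying
probes report NA with a warning instead of an unstable p.

## TFR / RRT

TFR_hypo = 100 · (hypo CpGs inside ≥ 1 binding site of the TF) / (all
hypo CpGs), likewise TFR_hyper; RRT = TFR_hypo/TFR_hyper, reported as
log₂RRT. Conventions:

- Peaks for one TF are union-merged across cell types (overlapping or
  book-ended intervals coalesce). The union is the most inclusive
  aggregation; provenance is retained per source file.
- A CpG inside several sites of one TF counts once for that TF; counting
  is independent across TFs.
- log₂RRT is computed as log₂TFR_hypo − log₂TFR_hyper so that exchanging
  the two CpG classes negates it bit-exactly.
- If either overlap count is zero, both overlap counts receive +0.5
  (totals unchanged) and the row is flagged `pseudocount_used`; this keeps
  every TF finite and rankable instead of silently dropping it.
- Per-TF significance is a two-sided Fisher exact test on
  [[hypo_in, hypo_out], [hyper_in, hyper_out]], BH-adjusted across the
  catalog. Any highlight threshold (e.g. p < 0.001) is an annotation;
  the full table is always emitted.
- Ranking is by log₂RRT descending, ties broken by Fisher p ascending
  then label; rank 1 is the most de-methylation-biased TF.

A multi-signature mode computes (TFR_hypo, TFR_hyper) per TF for several
methylation signatures (e.g. different tissues against a common
reference), flagging signatures with an empty class as NA.

## Methylation–expression link

Pairs are assembled at the (CpG, gene) level: each significant CpG
(optionally restricted to CpGs flagged 5′UTR) contributes one pair per
annotated gene, x = its mean M over the condition's samples, y = the
gene's mean expression over the same samples. No collapsing is applied in
either direction — a gene with several significant CpGs appears once per
CpG. The robust-expression filter keeps pairs whose gene mean exceeds a
fraction (conventionally 1/3) of the maximum gene mean within the
analysed condition, the maximum taken over all genes in the expression
table. Fewer than 3 surviving pairs yields an NA result with a warning.

Inference is Spearman: Pearson correlation of average ranks, with an
exact permutation p (full n! enumeration, two-sided on |ρ|) for n ≤ 9 and
the large-sample t approximation above that; Pearson is selectable. The
lowess smooth (span 2/3) attached to the result is descriptive only.

The RNAPII association is a two-sided Fisher exact test on the
{hypo, hyper} × {overlapping, not overlapping} table, overlap again being
point-in-interval against the merged region set.

## Synthetic data

The generator produces every input the pipeline consumes, with ground
truth, emulating the target study design:

- **Design**: 3 donors × 2 conditions, paired; donor effects (SD 0.1 on
  the M scale) are shared within a pair and cancel in the paired test.
- **Probes**: 10,000 by default on 2 × 1 Mb chromosomes; island-relation
  categories drawn i.i.d. with 450K-like proportions (31% island, 23%
  shore, 10% shelf, 36% open sea). Baseline β is bimodal by category:
  Island ~ Beta(2,10), shores ~ Beta(3,7), shelves ~ Beta(6,4),
  OpenSea ~ Beta(10,2), clipped to [0.01, 0.99].
- **Signal**: 200 planted CpGs (half hypo, half hyper) shifted by
  Δβ = ±0.3 in the treatment baseline, then clipped. Per-sample noise is
  Normal(0, 0.03) on the M scale, added before back-transforming, so β
  stays in range without truncation artifacts.
- **Segmentation**: 15 named states tiling each chromosome in random
  segments of ~5 kb mean length.
- **TF catalog**: per TF, each probe is covered by a peak with a
  class-dependent probability — the default catalog is one planted
  hyper-biased TF (0.15 hypo / 0.6 hyper / 0.15 background) among 20
  decoys at uniform 0.15. Peaks are 41 bp around the probe; the narrow
  width keeps the realised per-class coverage close to the nominal
  probabilities given the ~200 bp probe spacing (wide peaks would
  incidentally cover neighbouring probes and inflate coverage).
- **Expression**: 1,000 genes; 80% of probes are tagged to a random gene
  and 20% of tagged probes flagged 5′UTR. Genes whose 5′UTR carries a
  planted CpG have per-condition mean expression
  10 − 1.5 × (baseline M of that CpG), i.e. negative coupling; other
  genes draw a Uniform(2, 12) baseline. Per-sample noise is
  Normal(0, 1), clipped at 0.
- **RNAPII regions**: cover planted hypo CpGs with probability 0.5,
  planted hyper with 0.2, background probes with 0.05 (±1 kb regions).

One seed drives everything; each component draws from a child generator
with a fixed spawn key, so outputs are individually stable when others are
added. Emitted fixtures are byte-identical across runs and relocatable
(peak paths are stored relative to the fixture directory).

Presets: `tiny` (400 probes, 1 chromosome, 5 TFs — unit tests and smoke
runs), `default` (the conditions above), `null` (5,000 probes, no planted
signal, zero expression coupling — calibration checks).

**What passing tests show, and what they do not.** The generator plants
clean, independent signals: probes are exchangeable within category,
noise is Gaussian on the M scale, peaks are anchored at probes, and no
batch effects, probe cross-hybridisation, SNP artifacts or cell-composition
shifts exist. Recovery on this data validates the statistical machinery
and the plumbing — calibration of the moderated test near the nominal
type-I level, FDR control under BH, exact overlap counting, correct
direction and ranking of a planted TF bias, detection of planted
expression coupling — not performance on real arrays, where correlated
probes, technical covariates and annotation errors will dominate.

## Validation problem sizes

The shipped validation suite runs the overlap oracle on 200 random
instances (up to 2,000 CpGs × 50 TFs × 100 intervals), Fisher exactness
on all 2×2 tables with N ≤ 30 (implementation on all ~41k tables, the
Python-loop oracle on a random 3,000-table subsample), planted-TF
recovery and expression-link recovery on 100 simulation seeds each,
calling calibration on 50 null + 50 signal seeds, and 100 permutation
nulls for the context enrichment; the whole suite completes in a couple
of minutes on one CPU.

## Known limitations

- No raw-array preprocessing: input is a normalised β matrix; IDAT
  handling, normalisation pipelines and batch correction are out of scope.
- Probes map to points; an interval mode for probe bodies would change
  overlap counts near peak edges.
- The per-state shift test treats probes as independent, which real
  spatial correlation of methylation violates; its p-values on real data
  should be read as descriptive.
- The moderated test assumes a common variance model across probes within
  the scaled-F family; heavy-tailed residuals on real arrays may call for
  robust variants not implemented here.
- The expression link uses mean expression per gene and mean M per CpG
  within a condition (n is the number of CpG–gene pairs, not samples), so
  its p-values quantify cross-gene association, not within-donor
  covariation.
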