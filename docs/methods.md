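# Methods

## The model

`methylpc` analyses an N-probe x M-sample matrix **X** of methylation
M-values (M = log2 of the methylated/unmethylated intensity ratio; unitless,
approximately Gaussian per probe, bimodal over probes). The core operation is
*sample-space* PCA:

1. subtract each sample's mean M-value (column mean x̄);
2. form the M x M covariance over probes, with the unbiased 1/(N−1)
   normalisation;
3. eigendecompose: eigenvectors **V** (columns are principal components, one
   pattern value per sample) and eigenvalues σᵢ² (variance carried by each
   pattern);
4. compute probe projections **P = XV**; the projection of probe *i* on PC
   *k* measures how strongly that probe expresses pattern *k*, and the
   projection distribution on PC *k* has variance equal to σₖ²
   (Σᵢ Pᵢₖ² = (N−1)·σₖ² exactly under the 1/(N−1) convention).

Downstream machinery is built on these objects: probes driving a pattern are
selected as |Pᵢₖ| > n·σₖ (projection thresholding); a component's
contribution is removed from the data by rank-1 deflation X′ = X − Pₖvₖᵀ
(e.g. to strip cell-composition variance); and a pattern discovered in one
cohort is *reconstructed* in another as Ṽ = norm(ỸᵀP), treating each probe's
projection as a vote.

### The offset ("zeroth") component

Because M-values are bimodal over probes, the dominant variance component of
column-centered data is a near-uniform vector across samples: a constant
per-probe offset carrying no between-sample information. With
`remove_offset=True` (default) the fit projects out the exact uniform
sample-direction before the eigendecomposition and reports the variance
fraction it carried. Projecting out the uniform direction is algebraically
identical to centering each probe's row, so the offset-removed fit is exactly
(to machine precision) the row-centered fit — a property the test suite
asserts. A separate diagnostic flag (`offset_detected`) records whether the
top raw eigenvector actually resembled the uniform vector (cosine > 0.99),
i.e. whether the data had a bimodal baseline worth deflating. We chose
always-project-out rather than deflate-the-empirical-eigenvector because the
empirical top eigenvector of finite data is never exactly uniform, and
deflating it would leave a residual uniform component that breaks the
row-centering equivalence.

Numerical details: eigendecomposition is `numpy.linalg.eigh` (covariance is
symmetric); with offset removal the problem is solved in an orthonormal basis
of the uniform vector's complement so every returned component is exactly
offset-free; eigenvalues are clipped at zero and sorted descending; each PC's
sign is fixed so its largest-magnitude entry is positive (the sign of a PC is
arbitrary; a convention makes outputs reproducible). Sample-space PCA
requires N ≥ M; fewer probes than samples is rejected.

## The synthetic cohort generator

No cohort data ships with the package, so `simulate_cohort` generates
matched multi-tissue cohorts with known ground truth. The default
configuration mirrors a postmortem brain/blood study design:

- **17 individuals x 4 tissues** (three cortical regions BA10, BA20, BA7,
  plus whole blood WB), with one BA20 and one WB held out → 66 samples;
- ages uniform on **15–87 years**;
- **20,000 probes** with a bimodal baseline (modes at M = −2 and +2, half
  the probes high-methylated, per-probe jitter SD 0.3) — this reproduces the
  offset component;
- i.i.d. Gaussian measurement noise, SD 0.2 M-units (typical replicate-level
  noise for array M-values);
- five planted additive factors, each on its own probe set with
  effect sizes in M-units per SD of the factor score:

| factor | tissues | probe fraction | effect | context bias |
|---|---|---|---|---|
| brain_vs_blood | all | 0.10 | 2.0 | LC 3x |
| neuron fraction | brain only | 0.05 | 1.5 | CH 3x |
| granulocyte fraction | WB only | 0.05 | 1.5 | — |
| ageA (brain-specific aging) | brain only | 0.05 | 0.8 | HC 3x |
| ageB (pan-tissue aging) | all | 0.05 | 0.6 | HC 2x |

Effect sizes are deliberately spaced so the planted factors produce a
separated eigenvalue spectrum (≈29, 6, 2, 1.3, 0.4 against a noise floor of
≈0.04). When two planted directions have nearly equal variance, PCA returns
an arbitrary rotation of their eigenspace and no analysis — by any method —
can attribute the mixed components to individual factors; the separated
spectrum represents the clearly ordered component structure seen in real
multi-tissue methylation data.

Two further design choices make the factors identifiable:

- **Orthogonal age contrast.** The brain-specific age factor (ageA) is
  planted as the brain-restricted age pattern Gram-Schmidt-orthogonalized
  against the pan-tissue age pattern in the realized cohort
  (`FactorSpec.orthogonal_to`). Scientifically this is the "excess aging in
  brain beyond the shared signature" contrast; mechanically it is the only
  way two age-driven patterns can coexist as distinct eigenvectors, since
  eigenvectors are orthogonal by construction. A side effect is that the
  ageA pattern carries an anti-age component in blood within the reference
  cohort; the two age PCs are told apart by the *sign concordance* of their
  brain and blood age slopes (the pan-tissue signature runs in the same
  direction in both tissues).
- **Designed phenotype independence.** Neuron and granulocyte fractions
  (Beta-distributed across individuals, Beta(8,4) and Beta(12,6)) are
  generated exactly decorrelated from age across the cohort's individuals.
  In a 17-person cohort, chance phenotype correlations of |r| ≈ 0.25 are
  typical and would couple planted directions through the strong factors;
  decorrelation makes the generator behave like a designed experiment.

Age scores are standardized before the effect size is applied, so effect
sizes are comparable across configurations. `simulate_validation_cohort`
draws new individuals and ages but re-uses the reference loadings, honouring
each factor's tissue list (a WB validation cohort receives no ageA signal)
— this emulates independent published cohorts sharing probes with the
reference study.

What the generator does **not** emulate: probe-probe spatial correlation
along the genome, batch/chip effects, beta-value heteroscedasticity,
hydroxymethylation, non-Gaussian outliers, and the many weak inter-individual
factors of real cohorts. Passing recovery tests therefore demonstrate the
*pipeline's* correctness under the planted model, not the detectability of
signatures in any particular real data set.

## Factor recovery

`association.recover_planted_factors` maps planted factors to fitted PCs.
Each factor is scored against each PC in its natural sample subset
(brain-vs-blood contrast over all samples; neuron fraction within brain;
granulocyte fraction within blood; age within brain for ageA and within
blood for ageB, with ageB requiring sign-concordant brain and blood slopes
and ageA scored by the brain age strength not explained by a concordant
signature). The factor→PC map is the globally optimal one-to-one assignment
(Hungarian algorithm) on this score matrix rather than independent
per-factor argmaxes: subset-restricted correlations are scale-invariant, so
a weak PC's near-zero sample block can spuriously echo a stronger factor's
signal, and independent argmaxes collide.

## Association, batch and power machinery

Correlations are Pearson, with two-sided p-values from the exact t transform
on n−2 degrees of freedom (scipy). Batch structure is scanned with
two-sample KS tests of each batch level's PC scores against the rest,
Bonferroni-corrected over all (level x PC) tests performed. Per-tissue
variance accounting computes within-tissue probe variances (ddof = 1),
pairwise KS distances between tissue variance distributions, and each
tissue's percent of total variance.

The subsampling power analysis asks: at sample size n, how often does a PCA
screen detect an age-correlated component? Each replicate draws n
individuals without replacement, refits the PCA, and tests every PC against
age at an *uncorrected* per-PC α = 0.01 (the screen's family-wise
multiplicity is real and is measured, not hidden: `null_screen_rate` runs an
independent Monte-Carlo of the same screen on random orthonormal score
matrices, and a Bonferroni variant is available via `bonferroni=True`).
With composition deflation enabled, PCs correlating with supplied cell
proportions at |r| > 0.8 are removed first; the 0.8 threshold is a
documented choice for "this PC *is* the composition pattern".

## Brain–blood concordance

PCs after a cutoff (default: after the tissue and composition PCs) are
screened for shared inter-individual variation: each individual's brain
entries are averaged (unweighted), and a PC is selected when (a) blood and
brain-averaged variances are of comparable magnitude,
|σ²_blood − σ²_brain| < ½(σ²_blood + σ²_brain), and (b) brain and blood
entries correlate across individuals at p < α (default 0.01, Pearson;
Spearman available as an option). Variances use ddof = 1 over individuals;
the brain variance is computed on the averaged values, not pooled raw
entries. The summary reports the eigenvalue fraction of selected PCs among
post-cutoff PCs and the eigenvalue-weighted split between positively and
negatively correlated selections. Individuals missing a brain or blood
sample are dropped with a warning; a PC with both variances zero is "not
comparable".

## Cross-cohort reconstruction

`reconstruct_pcs` computes Ṽ = norm(YᵀP) after giving the target matrix the
same preprocessing as the reference: per-sample (column) mean subtraction,
then removal of the per-probe offset — both computed on the target itself.
Without target-side centering the offset dominates Ṽ. On the reference data
this pipeline returns the fitted components exactly (XᵀXV = (N−1)VΛ and
column normalisation removes the positive scale), which the tests assert to
1e−8 over many seeds. Probes are matched by ID in reference order with a
configurable floor (default 100) on the matched count; reconstruction uses
all matched probes' projections (a thresholded subset is an option, not the
default).

## Context enrichment

Enrichment of a probe subset against a background universe uses a binomial
null with p = n_bg/N_bg: μ = p·N_exp, σ² = (1 − μ/N_exp)·μ,
Z = (n_exp − μ)/σ. Category analyses (CpG-density class HC/IC/ICshore/LC,
intron/exon, CH probes) apply this per category level alongside the fold
ratio; degenerate nulls (category absent from, or filling, the background)
yield Z = NaN with a warning rather than an error, so one flat category
does not abort a table. Spatial enrichment around transcription start sites
restricts both sets to probes mapped to "lone genes" (no second TSS strictly
within 5 kbp; probes assigned within ≤ 2.5 kbp of the TSS, distances signed
by gene strand, ties broken by smaller distance then gene ID), bins signed
distances into 167-bp bins anchored at −2500 bp with the last bin truncated
at +2500 bp (30 bins at the defaults; an exact edge belongs to the bin on
its right), and scores each bin with the same binomial Z. Gene-level
analyses collect genes with ≥1 probe past a ±2σ projection threshold and
compare positive/negative tail overlap with the |a|·|b|/G chance
expectation. Thresholds default to ±1σ for category/spatial analyses and
±2σ for gene sets, both exposed as arguments.

## Clustering

Single-linkage (nearest point) agglomeration over Euclidean distances on a
chosen probe subset, written out explicitly with a deterministic tie rule
(smallest (cluster-id, cluster-id) pair); scipy's implementation serves as
an independent oracle in the tests. Merge heights are non-decreasing (a
single-linkage property, asserted). Dendrograms export as a merge list and
as Newick with branch lengths equal to height differences. `cluster_report`
checks whether a sample grouping (tissue, individual, ...) forms connected
subtrees and compares mean within- vs between-group cophenetic distance.

## Probe filtering

QC filters apply in a fixed order, each probe attributed to the first rule
that removes it (reproducible removal logs): X/Y-chromosome probes;
detection p > 0.01 or bead count < 3 in *any* sample; SNP-genotyping
probes; polymorphic/cross-hybridizing probes (user-supplied list files).
Missing M-values are rejected at load rather than imputed — the PCA
requires complete data and the package takes no position on imputation.
Coordinates are 1-based throughout. A beta→M utility
(M = log2(β/(1−β)), with optional clipping) is provided; array
normalisation is out of scope.

## Problem sizes

The shipped tests and the acceptance script run the full workflow at the
default cohort scale (20,000 probes x 66 samples; 20 seeds for the recovery
and transfer studies) and use reduced probe counts (2,000–6,000) for the
power analysis and pipeline smoke tests, chosen so the whole suite completes
in a few minutes on one CPU while keeping every Monte-Carlo estimate's
binomial error well inside the margins being asserted.

## Known limitations

- Sample-space PCA assumes more probes than samples and complete data.
- The concordance screen assumes each individual has at most one blood
  sample; replicate blood draws would need a pre-averaging step.
- The power analysis treats individuals as exchangeable; it does not model
  family or batch structure in the subsampled sets.
- The generator's identifiability choices (orthogonal age contrast,
  phenotype decorrelation) are idealisations; in real cohorts partially
  confounded factors will produce partially mixed components, and the
  recovery guarantees quantified here do not transfer to that setting.
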