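# Methods

This note documents the models and procedures implemented in `gcresponse`,
the assumptions behind them, the parameters that matter, and the design
choices made where the analysis protocol left the design open. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Expression transforms

Bulk expression enters on an FPKM-UQ-like non-negative scale. The log
transform is `x → ln(x + offset)` with `offset = 0.01` (configurable); the
small offset keeps zero-expression genes finite while preserving the
ordering of low values. Per-gene z-scoring centres each gene across samples
and scales to unit sample standard deviation; constant genes are set to
all-zero rather than NaN. Note that with a finite offset the
log-then-z-score pipeline is only approximately invariant to per-sample
scale factors; the residual deviation is small (regression-pinned in the
tests) and vanishes as the offset goes to zero.

Duplicate gene rows in input files are collapsed by the per-sample maximum:
deterministic, and conservative for signature scoring (a signature can only
gain, never lose, evidence from a duplicate annotation).

## Immune deconvolution

Fractions are estimated per sample by non-negative least squares against a
genes × 6 reference matrix over the genes shared between matrix and
reference (≥ 30 required), then renormalised to the simplex. NNLS is a
standard linear deconvolution estimator; we use it instead of ν-support
vector regression because only *relative* fractions feed the downstream
features, and the estimator is deterministic, dependency-light and
scale-invariant per sample (scaling a sample scales its coefficients, which
renormalisation removes). The per-sample residual norm is returned as a
quality annotation.

The bundled reference is a synthetic 6-cell-type matrix (B, CD4⁺T, CD8⁺T,
NK, monocytes, neutrophils) with block-structured marker genes — a declared
stand-in for a leukocyte signature matrix, which is not redistributable.
Results against real data require supplying a real reference.

Immune subgroups: fractions are column-z-scored (so rare cell types count
equally), clustered by Ward linkage on Euclidean distance, and cut at
`k = 4`; each cluster is named for the cell type with the highest mean
z-score inside it. The subgrouping algorithm was not prescribed; Ward at
k = 4 is the simplest deterministic choice that yields dominant-cell-type
groups, and k is configurable. Which four labels arise is data-dependent.

## Differential ranking and enrichment

Genes are ranked by a per-gene Welch t statistic on log-scale values
(unequal variances; ≥ 3 samples per class), with log2 fold change computed
as the difference of log-scale class means divided by ln 2 and
Benjamini–Hochberg adjustment across genes; the DE flag uses adjusted
p < 0.05 and |log2FC| > 1. This replaces moderated linear-model pipelines:
what the enrichment step consumes is the *ranking*, and the Welch t is a
faithful, dependency-free ranking statistic at these sample sizes.

Enrichment uses the weighted Kolmogorov–Smirnov running sum: walking down
the ranked list, a hit increments the sum proportionally to |t| and a miss
decrements it uniformly, so the sum ends at zero by construction (asserted);
the enrichment score is the maximum signed deviation. The null distribution
comes from gene-label permutations (size-matched random sets), which is
valid at small n and deterministic given the seed; phenotype permutation
would be preferable with many samples but is hopeless at n ≈ 65 with
30/35-ish class balance. The p-value is two-sided on |ES| (calibrated:
uniform under a random-set null — verified by a KS test in the suite); NES
divides ES by the mean |null ES| of the same sign. BH adjustment is applied
across sets.

Signature scores are means of z-scores over the present members of a set,
with missing members logged — an intentionally transparent stand-in for
heavier single-sample enrichment methods.

## Copy-number signatures

Shallow (~1×) WGS yields total-copy-number segments without reliable
allele-specific calls, so the catalogued 48-context scheme (which needs
LOH status) cannot be used. We use a 24-bin scheme: total-CN class
{0, 1, 2, 3–4, 5–8, 9+} × segment-length class {<100 kb, 100 kb–1 Mb,
1–10 Mb, >10 Mb}, with length bins left-closed/right-open (a 100,000 bp
segment falls in the second bin; lengths are end − start + 1 on 1-based
inclusive coordinates). The bundled catalog expresses three processes on
these bins as declared stand-ins: CN1-like (diploid, long near-normal
segments), CN4-like (moderate Mb-scale gains), CN9-like (focal high-level
amplification). Matching real catalogued spectra bit-exactly is impossible
without allele data, and is not attempted.

Extraction is non-negative matrix factorisation with the KL-divergence
objective and multiplicative updates — the standard formulation for count
catalogues — run to tolerance 1e-6 or 2,000 iterations, best of 30 random
restarts (each restart seeded from the run seed). Spectra rows are
normalised to the simplex with exposures rescaled compensatingly, so
exposures stay in segment-count units. Identifiability caveat: when all
samples carry substantial exposure to every signature, the factorisation is
not unique; recovery is reliable when exposures vary across samples
(separability), which both real cohorts and the synthetic generator
provide.

Exposure differences between response groups use the two-sided
Mann–Whitney U test: exact enumeration when both arms have ≤ 8 samples,
tie-corrected normal approximation otherwise.

## Variant, pathogen and association rules

MSI: a sample's status counts distinct mutated markers among BAT25, MS05
and MS11 — 0 → MSS, 1 → MSI-low, ≥ 2 → MSI-high (monotone by
construction). The marker names are treated as opaque labels. PGx: positive
if any variant falls in GSTP1, DPYD, CYP2A6 or UGT1A1 (TYMS and DPYS are
excluded by default). Pathogen positivity operationalises "ten times more
reads than other samples" as count ≥ 10 × the cohort median — robust and
deterministic; when the median is zero the smallest positive count is the
baseline, and an all-zero cohort yields all-negative with a warning.

Fisher association is two-sided by summed hypergeometric probability mass
(the standard convention); the odds ratio applies the Haldane 0.5
correction when any cell is zero so it stays finite.

## Response model

Features from every module are joined on sample ids: numeric features
(fractions, gene-set scores, exposures, age) are median-imputed then
column-standardised; categorical features (immune subgroup, clinical
categories, MSI status) are one-hot encoded with an explicit "NA" level;
binary flags stay 0/1; constant columns are dropped and recorded in the
assembly manifest. Labels map PR (or CR) to Responder and SD/PD to
Non-responder.

Splits are stratified by label (at n = 65 with ~29/36 balance,
unstratified 70/30 splits are unstable), with a 0.30 test fraction.

**Shadow-feature selection.** Every iteration appends an independently
permuted shadow copy of each active feature (minimum five shadow columns,
cycling, so the max-shadow bar stays competitive once most features are
rejected), fits a random forest, and scores a "hit" for each real feature
whose impurity importance beats the best shadow. Hit counts are tested
against Binomial(trials, ½) with two one-sided tails; the significance
threshold is Bonferroni-corrected over features × decision looks
(α / (m · iteration)) because the test recurs every iteration — correcting
over features alone lets chance-correlated noise features through in a
material fraction of all-noise runs. Rejected features leave the forest.
Defaults: α = 0.01, `max_iter` = 200 (configurable up to the
10,000-iteration scale of the original protocol; the heavy-duty aggregate
experiments in the acceptance suite run 25–40 iterations with 60–80-tree
forests, which the recovery results show is already sufficient at these
problem sizes).

**Ensemble and evaluation.** A bagged decision-tree ensemble (500 trees by
default, √p feature subsampling, Gini splits) is trained on the Confirmed
features (fallback to Tentative is explicit, never silent). AUC is the rank
statistic with ties credited ½ — equal to pairwise concordance, verified
against an exhaustive oracle — computed on out-of-bag votes for the
training portion and on vote fractions for held-out data. Accuracy uses the
majority-vote cut at 0.5.

**Distillation.** Candidate trees are ensemble members using at least
`min_top_k = 2` of the top-ranked features (relaxed to best-overlap with a
warning if none qualify). The winner maximises *fidelity* — agreement with
the full ensemble's predictions on held-out data — with ties broken by
fewer nodes, then lower tree index. The winner is then refit as a single
tree on its own features against the ensemble's predicted labels and
pruned by cost-complexity, with the pruning level again chosen by held-out
fidelity; among pruning levels, those retaining ≥ `min_top_k` top features
are preferred, and fidelity ties prefer stronger pruning. This makes the
loosely-specified "select a representative tree and construct a single tree
from it" protocol deterministic and measurable, and covers both readings
(selection and reconstruction).

External validation maps features by name, imputes absent features with
training medians (counted and reported), requires ≥ 50% feature overlap,
and reports the rank AUC plus a five-bin calibration table.

## Survival

Kaplan–Meier uses the product-limit estimator; log-rank accumulates
observed-minus-expected and hypergeometric variance over pooled event
times, with all deaths at a time counted before censorings at that time
(simultaneous-event convention), and refers the statistic to χ²(1). Both
are implemented directly — the formulas are elementary and the calibration
simulations need a fast statistic — and are cross-checked against an
independent survival package in the tests. Score dichotomisation uses a
median split with ties going low (the most common convention, made
explicit); configurable by passing any precomputed grouping.

## Single-cell neutrophil analysis

QC removes genes expressed in fewer than 3 cells, then cells expressing
fewer than 100 genes or with mitochondrial fraction above 0.5 (gene filter
strictly first; boundary cases: a 99-gene cell is removed, a gene seen in
exactly 3 cells is retained). Mitochondrial genes are identified by symbol
prefix (default `MT-`). The filter is idempotent. Normalisation is global
scaling: ln(1 + count × 10,000 / cell total), invariant to sequencing
depth per cell.

Marker scoring averages normalised expression over the present members of
each TAN state panel (TAN1: CXCL8, CXCL1, CXCL2, ICAM1, CD44; TAN2:
HLA-DRA, CD74, HLA-DPB1; TAN3: PLIN2, PLAU; TAN4: RPL10, RPS2/PRS2, RPS18,
RPL3 — both spellings of the ribosomal marker are carried because source
lists disagree; NETosis: PROK2, MME); a fully absent set scores as missing,
not zero. Cluster annotation compares cluster centroids to reference
profiles by cosine similarity over ≥ 20 shared genes with an assignment
threshold of 0.6 (below it: "Unassigned").

Lineage exclusion removes any cell with a nonzero count on CD3E, CD19,
NCAM1, CD8A or CD4, and removes whole clusters whose mean immunoglobulin
count exceeds both the 0.95 quantile of cluster means and an absolute floor
of 1.0 mean counts. The floor is ours: a bare quantile rule degenerates on
IG-silent data, where some cluster is always the maximum.

The square-root-of-product signature is computed in log space,
`exp((1/k) Σ ln(x_i + ε))` with ε = 0.01, to avoid under/overflow in
10-term products. The literal reading (k = 2, the square root of the
product) is the default because that is how the signature is described;
k = number of genes gives the geometric mean and is exposed because the
literal formula is dimensionally odd. The choice is recorded in the output
metadata. The default pro-/anti-tumour role map assigns TAN1-like and
NETosis-like states to pro-tumour and TAN2-like to anti-tumour, with
everything else "other"; the map is a configuration file because it encodes
a biological interpretation, not a formula.

## Synthetic cohort generator

The generator is label-first: a Responder label is drawn per sample
(probability 29/65), and all molecular features are drawn conditional on
it, so the planted effect sizes are directly interpretable. Defaults
emulate a 65-sample advanced gastric cancer cohort:

- **Expression** — reference × fractionsᵀ with per-sample log-normal
  library factors (sd 0.2) and multiplicative log-normal measurement noise
  (sd 0.1). Fractions are Dirichlet; responders' concentrations are tilted
  by e^β on neutrophils (β = +1) and CD4⁺T (β = −1). Inflammation and
  interferon programmes carry per-sample log-normal activity (sd 0.6)
  around class means (responders: e^−0.8 inflammation, e^+0.4 interferon) —
  the per-sample variability matters: without it a single programme score
  would separate the classes deterministically, which no real cohort does.
- **Copy number** — gamma-distributed exposures (shape 4) over two planted
  spectra taken from the bundled catalog (CN9-like mean 20, ×e^0.7 in
  responders; CN1-like mean 40 in both); context counts are Poisson around
  exposures · spectra and realised as concrete non-overlapping segments
  whose lengths are uniform within their length class.
- **Variants** — per-marker MSI mutation probability 0.2 (≈ 11% MSI-high),
  per-gene PGx probability 0.155 (≈ 49% flag-positive), plus TP53 / MUC16 /
  ARID1A drivers with beta-distributed VAFs.
- **Pathogens** — Poisson background (EBV mean 2, H. pylori mean 5) with
  planted positives (probabilities 0.046 and 0.15) at ~50× background.
- **Survival** — exponential with Non-responder median OS 8 months and a
  2.5× hazard ratio versus responders; administrative censoring uniform on
  12–36 months; PFS at twice the hazard.
- **Clinical** — age, gender, histology, tissue type, cT/cN drawn to match
  typical advanced-GC frequencies, with a sprinkle of missing values.

All randomness flows from one integer seed through named streams (one per
component), so components are independently reproducible and cohorts are
byte-identical per (config, seed).

What the generator does *not* emulate: gene-length/GC biases, count-level
(negative-binomial) expression noise, subclonal copy-number mixtures,
realistic linkage between clinical covariates and molecular features, or
informative censoring. Passing recovery tests therefore demonstrates the
*estimators* are correct and well-calibrated under the stated noise model —
not that real-cohort performance will match; the headline AUCs from
controlled-access patient cohorts are not reproducible here and are not
targets of this package.

The single-cell generator draws negative-binomial counts (dispersion 2)
around archetype means (marker genes 8, housekeeping 2, background 0.3,
lineage/immunoglobulin genes 0 in genuine neutrophils), applies Bernoulli
dropout (default 0.3), plants a contaminant fraction expressing lymphoid
lineage markers (default 2%) and a high-mitochondrial tail (default 5%,
Beta-distributed around 0.7).

## Problem sizes and numerical choices

The test and acceptance experiments use desk-scale sizes chosen once:
deconvolution recovery at n = 60; signature recovery at n = 100 with 30 NMF
restarts; selection recovery at n = 200 with 5 informative + 100 noise
features over 20 seeds (40 iterations, 80 trees) and an all-noise null over
50 seeds (25 iterations, 60 trees); distillation fidelity over 20 seeds
(150 trees); calibration with 40,000 Welch null genes, 4,000 Mann–Whitney
and 6,000 log-rank null replicates plus 1,000 power replicates — the
Monte-Carlo standard error of a rejection-rate estimate at these sizes
(≤ 0.003) is small against the 0.04–0.06 tolerance band. Ties in ranks are
mid-ranked; cosine similarity of a zero vector is defined as 0; NMF
restarts and every stochastic stage derive child seeds from the run seed by
name, keeping stages independently reproducible.

## Known limitations

- The bundled immune reference, CN catalog and TAN reference states are
  synthetic stand-ins; swap in real references for real analyses.
- NNLS deconvolution ignores tumour-content dilution (no absolute mode).
- The 24-bin CN scheme cannot distinguish allele-specific events.
- Gene-permutation GSEA tests set coherence against gene exchangeability,
  not phenotype association.
- Single-cell clustering itself is out of scope: cluster ids come from
  upstream tools or planted truth; the package scores and annotates them.
- The selection/distillation pipeline is honest about multiplicity but
  still selects on the training split; external validation on an
  independent cohort remains the arbiter for real deployments.
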