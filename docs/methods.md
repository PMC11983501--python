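# Methods

## The model

All plot-level variation is described by the additive linear model

    Y_ijkl = µ + G_i + E_j + R_k(E_j) + B_l(RE)_jk + GE_ij + ε_ijkl

for genotype *i*, environment (year-season) *j*, replicate *k* within
environment, incomplete block *l* within replicate. Genotype is treated as
fixed when estimating entry means (BLUEs) and as random when partitioning
variance; environments, replicates, blocks, GE interaction and residuals
are random with constant variances. The analysis path assumes a **balanced**
table — every genotype exactly once per (environment, replicate) — and
refuses anything else; `drop_incomplete_genotypes` is the explicit,
user-visible remedy. We deliberately do not impute.

## ANOVA and variance components

On balanced data the environment, replicate-within-environment, genotype
and genotype×environment subspaces are mutually orthogonal, so their sums
of squares are plain group-mean sums of squares. Incomplete blocks are
not orthogonal to genotypes (each block holds a different subset of
entries), and the order and manner of their removal matters:

- Sweeping raw block means *before* genotypes (the naive field-book order)
  folds between-block genotypic variance into the block line and deflates
  the residual mean square by roughly `(df_B/df_res)(σ²_G + σ²_GE)`.
- Subtracting block means of the running residual *after* the genotype and
  GE sweeps under-removes noise, because block indicators overlap the
  already-removed cell-mean space; the residual mean square is then
  inflated by a factor `(df_res + df_B − tr overlap)/df_res`.

`anova_balanced` therefore removes blocks from the running residual by an
exact sequential least-squares step: block indicator columns are projected
onto the orthocomplement of the swept spaces and the running residual is
regressed on them. The six sums of squares add to the total exactly, the
degrees of freedom to N−1, and the residual mean square is an unbiased
estimate of σ²_e.

One bias remains in the naive method-of-moments inversion: block variance
leaks into the genotype and GE mean squares (cell means average only r
block draws). For the genotype line and the GE line the leakage
coefficients are equal in expectation only approximately; we compute them
**exactly for the realized design** as traces `tr(X_Bᵀ P X_B)` of the block
indicator matrix through each sweep projection, estimate σ²_B from the
block line, and subtract the leakage before inverting

    σ̂²_e  = MS_res
    σ̂²_GE = (MS_GxE − MS_res)/r
    σ̂²_G  = (MS_G − MS_GxE)/(r·e)

with negative solutions truncated at zero (matching the convention of
printing `0.00` for vanishing components). On designs without incomplete
blocks the correction vanishes and the textbook closed form is used
verbatim. Monte-Carlo checks at trial scale (192 genotypes × 4 environments
× 2 replicates, 200 seeds) recover all three grain-yield components within
Monte-Carlo error; the test suite re-runs this check.

We use method-of-moments rather than REML on purpose: on balanced data the
two coincide in expectation, and the moment estimator is exactly testable
against independent least-squares oracles. No REML refinement for
unbalanced data is provided; unbalanced tables must be reduced to balance
first. Lattice efficiency adjustment (recovery of inter-block information
for entry means) is likewise out of scope: BLUEs are simple entry means,
which on balanced data with random block allocation have equal expected
block contributions for every entry.

Broad-sense heritability is reported on an entry-mean basis,

    H² = σ²_G / (σ²_G + σ²_GE/e + σ²_e/(e·r)),

bounded to [0, 1] and defined as 0 when all components vanish. The
environment count *e* is taken per trait from the data actually present,
so a trait scored in fewer seasons gets the correct divisor. CV% is
`100·√σ²_e / grand mean`. F tests follow the random-interaction
convention: genotypes against GE, GE against the residual.

"Genotypic correlations" are operationalized as Pearson correlations of
entry-mean BLUEs. These are entry-mean (phenotypic) correlations, not
components-of-covariance genetic correlations; with moderate-to-high H²
they approximate the latter but are attenuated toward zero by GE and
residual noise.

## PC indices

BLUEs are standardized per trait (sample SD, n−1). The trait correlation
matrix is eigendecomposed; components with eigenvalue strictly greater
than one are retained (Kaiser rule; if none qualifies, PC1 is kept with a
warning). Published index columns carry a ±1.00 entry on the dominant
trait, which a unit-norm eigenvector cannot; index weights are therefore
loadings (eigenvector × √eigenvalue) rescaled so the largest magnitude is
exactly 1. Each index is oriented so that larger scores are better: if a
higher-better trait (grain yield) carries |weight| ≥ 0.1 it anchors
non-negative; otherwise the dominant lower-better trait anchors negative.
Equal-eigenvalue ties are broken by orienting each eigenvector so its
largest-magnitude entry is positive, making results deterministic.

Scores are the weighted sum of **standardized** BLUEs by default. A
raw-BLUE basis exists for replication of published index values, but raw
sums are dominated by whichever trait has the largest scale (ear-rot
percent spans 1–31 while scores span 1–9), so standardized is the
scientifically defensible default; affine changes of any trait's units
leave standardized scores unchanged. A fixed-weight mode accepts published
coefficient vectors verbatim (no re-orientation) for replication
experiments. LD_AV is excluded from the PCA — it is an exact linear
combination of LD1–LD3 and would contribute a spurious near-duplicate
dimension — but is tabulated in every gain report.

## Selection gains

Rankings are total orders: descending index score, or a single trait in
its desirable direction, ties broken by genotype identifier. The gain of a
scheme for a trait at selection size k is

    GS = 100 · (X̄_s − X̄_o) · H² / X̄_o   (percent of the grand mean),

with X̄_o the mean BLUE over all entries — checks included, since published
grand means of such trials include the checks among the evaluated entries
(a pool restriction is available). Selecting everyone is treated as an
exact no-op (zero differential by construction). A gain is "desired" when
the differential points in the trait's registered direction; zero
differentials are flagged neutral and counted desired. Relative gain
against a check is `100·(genotype − check)/check`, undefined (refused) for
zero check values. Overlap reports enumerate intersections for every
subset of schemes of size ≥ 2.

## The synthetic generator

`simulate_trial` draws each model term independently in a fixed, documented
order from one root RNG, so a single integer seed reproduces a trial
bit-identically. Genotype effect vectors are jointly multivariate normal
across traits, Σ_G = D·R·D with per-trait genetic SDs D and a target
correlation matrix R; GE effects are independent per (genotype,
environment) and across traits; blocks are formed by permuting genotypes
per replicate and cutting consecutive groups.

Defaults mirror a published four-season screen-house evaluation of 192
maize hybrids (4 checks, 2 replicates, blocks of 48): per-trait grand
means and (σ²_G, σ²_GE, σ²_e) are the published combined-analysis values
(e.g. GY: mean 5.11 t/ha, components 0.88/0.72/1.70, implying H² = 0.69).
The genetic correlation pattern is stylised, not estimated from any
dataset: LD traits mutually +0.70…+0.85, LD vs GY −0.40, ED–ER +0.60,
ED/ER vs GY −0.30, and LD vs ED/ER +0.30 (a moderate value inside the
0.3–0.9 band such trials report, chosen once). Environment SD defaults to
1.0, replicate SD 0.3, block SD 0.2 per trait, each ×10 for ear rot,
which lives on a percent scale; environment main effects are irrelevant to
the downstream H²/BLUE arithmetic on balanced data but give the tables
realistic season-to-season shifts. A per-trait environment count can mask
trailing seasons to emulate traits scored in fewer environments.

What the generator does **not** emulate: ordinal granularity of 1–9 visual
scores (traits are continuous Gaussians on the measurement scale),
bounded/skewed percentages, missing plots, spatial trends, or any
damage-process mechanism. Passing recovery tests therefore certifies the
estimators under the model's own assumptions — not robustness to real
field pathologies. Range clamping is available but off by default because
truncating the Gaussian tails biases variance-component recovery; with
clamping on, recovery guarantees are void (the truth object records this).
Unclamped draws can leave the physical scales (e.g. negative yield in the
far tail), which is why CSV range validation is relaxable when re-reading
synthetic data.

## Numerical conventions and problem sizes

- Eigendecomposition via symmetric `eigh`; PSD is enforced up to a −1e−10
  eigenvalue tolerance and negative eigenvalues are clipped at zero when
  taking matrix square roots.
- CSV outputs carry 6 significant digits; trial tables are written at full
  float precision and re-read with round-trip parsing, so write∘read is
  the identity on values.
- Reports round gains to 2 dp and relative gains to 1 dp; everything is
  full precision internally.
- Monte-Carlo checks use 200 trial-scale replicates for component recovery
  and 100 replicates for the direction-of-gain property; these sizes give
  standard errors an order of magnitude below the tolerances they guard.

## Known limitations

- Balanced designs only; the two-entries-missing-in-one-year situation of
  real multi-year trials must be resolved by dropping entries before
  analysis.
- Entry-mean BLUEs ignore intra-block information; for strongly
  heterogeneous blocks a lattice-adjusted or mixed-model analysis would be
  more efficient.
- The Kaiser threshold is a hard rule; near-threshold second components
  come and go across random realizations, and the builder then constructs
  fewer indices (with a warning) rather than forcing one.
- Published per-hybrid index values cannot be reproduced exactly from
  printed summaries alone (they depend on unrounded per-hybrid entry means
  and on an index basis that published reports leave ambiguous); the
  package therefore exposes both score bases and checks replication
  targets only where printed inputs suffice.
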