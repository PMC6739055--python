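# Methods

This note documents the statistical models implemented in `fatrophic`, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical decisions a maintainer should know
about. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model

A sample's fatty-acid profile is a map from `C:Dn-x` labels to percent of
total fatty acids (0–100 scale). Compositions are analyzed **untransformed**:
no log-ratio transform and no zero replacement, because transforming
percent data inflates the apparent contribution of minor acids, and an
acid that was not detected is treated as a true 0%. Validation requires
non-negative values summing to 100 within a tolerance τ (default 1.0
percentage point, absorbing rounding in published tables; strict values of
τ and exact renormalization are both available). Labels are canonicalized
(whitespace stripped, Unicode dashes mapped to ASCII); saturation class
(SFA/MUFA/PUFA) is derived from the double-bond count, and an omega suffix
is required exactly when the acid is unsaturated.

Peak-area → mass conversion uses a single calibration slope (area per µg)
from a standard-curve fit, exposed as a parameter rather than a constant
because calibration is instrument-specific:
`mass = (area / slope) × V_hexane / m_tissue`, in µg per mg dry tissue.

## Trophic indices

Three established biomarker indices are computed per sample:

1. `18:1n-7 / 18:1n-9` — vaccenic acid derives from elongation of
   photosynthetically produced 16:1n-7, oleic acid is a major acid of
   marine animals; higher values indicate more photosynthesis-derived input.
2. `(16:1n-7 + 18:1n-7) / (18:1n-9 + 20:1n-9 + 22:1n-11)` — the related
   photosynthetic- vs animal-derived input ratio.
3. `ΣLC-MUFA` — the sum of exactly six long-chain monounsaturated isomers
   (20:1n-11, 20:1n-9, 20:1n-7, 22:1n-11, 22:1n-9, 22:1n-7), elevated in
   herbivorous calanoid copepods and hence a copepod-feeding marker. Other
   20:1/22:1/24:1 isomers never enter the sum.

A zero denominator makes a ratio undefined; it is recorded as NaN with a
logged count and dropped pairwise from downstream ANOVA, never raised as an
error, since the source material gives no rule for this case.

## PERMANOVA

Distances default to Bray-Curtis (`Σ|x−y| / Σ(x+y)`), the conventional
resemblance for percent-composition data; Euclidean is selectable. The sum
of squares is partitioned through the Gower-centered matrix
`G = J(−½D²)J` with `J = I − 11ᵀ/n`. For each model term (main effects and
`a:b` interactions of crossed fixed factors, in the order given) a
projector `P_k = H_k − H_{k−1}` is built from orthonormal bases of the
growing design matrix; `SS_k = tr(P_k G)`, `df_k` is the rank increment,
and `pseudo-F_k = (SS_k/df_k)/(SS_res/df_res)`. For balanced designs the
decomposition is orthogonal and order-free; for unbalanced data it is
sequential (type-I) in the stated term order, which suffices for the
balanced designs this package targets.

Significance is assessed by **unrestricted permutation of raw
observations** (rows/columns of `G`), the same permutations scoring every
term, with the add-one estimator `p = (1 + #{F* ≥ F}) / (1 + n_perm)` so p
is never zero. The PRIMER software family defaults to permutation of
residuals under a reduced model; at these sample sizes the two schemes give
closely similar answers, and only the raw-observation scheme is
implemented (the divergence is deliberate and documented here). Default
`n_perm = 9999`. When a single one-way term admits fewer distinct
relabelings than `n_perm`, the test switches to exhaustive enumeration and
reports the exact p (identity included), with a log message.

Two numerical caveats. First, for semi-metric distances (Bray-Curtis) `G`
is not positive semi-definite, so a near-null term's sequential SS can be
slightly negative — a known property of the partition, not a bug; p-values
are unaffected because permuted statistics are computed identically.
Second, F comparisons in the permutation count use a relative tolerance of
1e-9 so that ties (e.g. the identity permutation) are counted
deterministically.

Pairwise follow-ups restrict the distance matrix to each level pair and
rerun the one-way test, which is by construction identical to a fresh
two-level test on that subset. Levels with fewer than two samples are
skipped with a warning.

## PERMDISP

Samples are embedded by principal coordinates of `G`; negative eigenvalues
(possible under Bray-Curtis) contribute "imaginary" axes whose squared
distances are subtracted, with the result clamped at zero. Each sample's
distance to its group centroid is computed in this space, a one-way ANOVA
F is formed on those distances, and significance comes from permuting the
distance values across group labels (add-one estimator). Under Euclidean
distance the embedding is exact and the distances equal direct
distances-to-group-mean, which the tests verify.

## PCA

Data are centered and, by default, standardized (correlation-matrix PCA) —
the convention under which per-variable "contributions" are usually read;
covariance-matrix PCA is available. Decomposition is by SVD; eigenvalues
are `s²/(n−1)`, percent variance per axis sums to 100, and the
contribution of variable j to axis k is `100·loading²_jk / Σ_j loading²_jk`.
Axis signs are fixed by making the largest-magnitude loading on each axis
positive. A constant variable under standardization raises an error naming
the variable; the pipeline pre-drops such acids (e.g. an acid structurally
absent from one tissue) with a warning. Normal-theory 95% confidence
ellipses on scores are provided as a thin optional plotting layer.

## ANOVA, Tukey, regressions

ANOVA is the classical fixed-effects decomposition (statsmodels OLS +
type-I `anova_lm`, matching the sequential PERMANOVA convention; identical
to the unique decomposition on balanced data). A response that is constant
to machine precision returns F = 0, p = 1 rather than the 0/0 artifact.
TukeyHSD adjusted p-values come from the studentized-range distribution;
after a significant interaction, comparisons can be run on combined cell
labels (`cell_labels`) or within factor slices by subsetting — both are
exposed because neither convention is canonical.

Host-vs-symbiont regressions are per-acid OLS of host proportion on
symbiont proportion from the same colony, plus a ΣLC-MUFA row. Pairs are
matched by stripping the trailing `_host`/`_symbiont` token of the sample
id (configurable via a callable); unpaired colonies raise an error listing
the orphans. Adjusted `R² = 1 − (1−R²)(n−1)/(n−2)`. No multiple-testing
correction is applied across the ~30 per-acid models; the table reports raw
p-values with an α = 0.05 flag, and acids constant in the predictor are
skipped with a log entry.

## Bootstrap-LDA attribution

The discriminant model is the Gaussian class-conditional classifier with
per-class means and one pooled within-class covariance (divisor `N − K`).
Because closed compositions are collinear, the covariance is
ridge-regularized with `λ = 1e-6 · tr(Σ)/p` by default (recorded in the
model); an explicit `ridge=0` raises on singularity with instructions.
Priors are **uniform** by default: candidate-source group sizes reflect
literature availability, not prey availability. Arg-max ties are broken
toward the lexicographically smallest class name and logged.

The workflow: (1) leave-one-out cross-validation of the source library,
each sample classified by a model fit on all others; (2) a single pruning
pass removing sources with LOOCV rate < 0.85 (an iterate-to-fixpoint mode
exists but is off by default, as screening is described as one evaluation
step); (3) removal of PUFA absent from every retained source — such an
acid cannot inform attribution — from both sources and hosts; (4) the
bootstrap: per iteration each source group is resampled with replacement
*to its own size*, the model refit, and every host sample classified. A
resample in which a group collapses to one distinct point is redrawn and
counted. The per-iteration "diet combination" of a host species is the
vector of fractions of its samples assigned to each source (exact
multiples of `1/n_hosts`, summing to 1); hard classification is the
default because the procedure counts classified samples, with
posterior-averaging available as an explicit alternative mode. Summaries
are the mean, SD and percentile [2.5, 97.5] interval per source, and
category aggregates (particulate vs symbiont) are formed within each
iteration so they close to 1. Hosts are never resampled and host labels
never enter fitting. Whether the original procedure preserved group sizes,
which priors it used, and how it broke ties is not recorded anywhere
authoritative; the defaults above are this package's documented choices. A
cultured-symbiont variant needs no special code path — it is simply one
more source group in the library.

Resolution note: with `n_hosts = 10` a contribution is estimated on a grid
of 0.1, so bootstrap CIs are step functions of width 0.1; means are much
finer because they average over iterations.

## Synthetic-data generator

Within-group variation is modelled as a Dirichlet draw with parameters
`α = c · m/100` (mean composition `m`, concentration `c`; larger `c` =
tighter). Structural zeros in the mean stay exactly zero in every draw,
matching the true-zero treatment of absent acids. This is a modelling
convenience for closed percent data — the analysis chain makes no
distributional assumption the generator must satisfy — and the generator
is judged by its contracts (valid compositions, seed determinism, exact
degenerate limits), not by biological realism. It does **not** emulate
trophic modification of fatty acids between diet and consumer, lipid-class
structure, or instrument noise; passing recovery tests therefore
demonstrates correctness of the inference machinery, not field accuracy on
real corals.

Generators:

* `simulate_sources` — per-group draws around stated means. The built-in
  source means are loosely patterned on published group contrasts (diatoms
  rich in 20:5n-3; copepods rich in 22:6n-3/20:5n-3; cyanobacteria
  dominated by C18 n-6/n-3; cryptophytes rich in 18:3n-3/18:4n-3;
  symbionts carrying the 18:3n-6 signal), with 18:5n-3 zero in every
  source so the drop-unshared step is exercised. Default concentration 150
  gives leave-one-out rates near 1.0 — "well-separated" fixtures; no
  authoritative within-group variance exists, so the concentration is an
  explicit knob.
* `simulate_host_mixture` — hosts as Dirichlet noise around a convex blend
  of source means (the blend is formed first, so the weights remain the
  estimand; infinite noise concentration yields the blend exactly).
* `simulate_host_memberships` — hosts drawn each from a single source with
  membership counts fixed by largest-remainder rounding, so the true
  fractions sit exactly on the `1/n_hosts` grid that the attribution
  reports on. This is the generator matched to what the classifier
  actually estimates.
* `simulate_factorial` — labelled crossed species × tissue × depth draws
  from per-cell means. `study_factorial_spec` provides the study-shaped
  default: 3 species × {host, symbiont} × 2 depths with 10 samples per
  species/tissue cell split over depths (60 samples; the full three-way
  model then has 11 model df and 48 residual df). Species effects are
  multiplicative tweaks on selected acids (the heterotroph enriched in
  LC-MUFA and 22:5n-3, the autotroph in 18:1n-7) re-closed to 100; a depth
  effect trades 16:0 against 22:6n-3 as a simple light-gradient proxy.

## Pipeline

`run_pipeline` tests depth first in the full three-factor permutation
model and pools depths when the depth term is non-significant at α = 0.05
(`pool_depth` can force either behavior), then runs the crossed
species × tissue model, pairwise tests, dispersion check, indices with
per-tissue ANOVA/Tukey, ordination (full panel and 12-PUFA subset),
colony-paired regressions, and — given a source table — the per-species
attribution with species-specific symbionts added as a source group. Every
stochastic stage derives its seed from the run seed by fixed offsets, and
`report.json` embeds a SHA-256 digest of the configuration, so a rerun of
the same config is byte-identical.

## Problem sizes in the validation suite

The test suite and acceptance script scale the stochastic studies to sizes
chosen for tight-but-cheap statistical resolution: 500 replicates × 199
permutations for null calibration of the permutation test (the binomial
95% band for a true 0.05 rate is then [0.032, 0.071]); 100 random
3-class datasets (d = 7, n = 15/class) for classifier equivalence; and
20–50 replicate recovery runs at 2,000 bootstrap iterations (the analysis
default remains 10,000). These sizes are the package's own validation
choices.

## Known limitations

* Fixed crossed designs only: no nested or random factors, no
  residual-permutation scheme, no nMDS/CAP/SIMPER.
* Attribution assumes source PUFA profiles transfer unmodified to the
  consumer (no calibration coefficients for trophic modification); it is a
  classification-count estimator, not a full mixing model, and inherits
  the `1/n_hosts` resolution described above.
* The literature-screening rules for assembling a real source library
  (marine, non-polar, untreated records, etc.) are treated as properties
  of the input data, not code.
* Chromatogram processing, peak identification and lipid-class separation
  are out of scope; input is the identified percent-composition table.
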