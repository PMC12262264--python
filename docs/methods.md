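# Methods

## Model

`shade` models the spatial arrangement of one *target* cell type in a
tissue image conditional on the observed patterns of one or more *source*
cell types. Given source patterns X_A1..X_AK and an observation window W,
the target pattern is treated as an inhomogeneous Poisson process with
log-linear conditional intensity

    log λ(v) = z(v)ᵀβ + Σ_k q_k(v)ᵀ δ_k ,
    q_k(v)_p = Σ_{x ∈ X_Ak} φ_p(‖v − x‖),

where z(v) are location covariates (an intercept by default) and
{φ_p}_{p=1..P} is a nonnegative, compactly supported distance basis
(cubic B-splines or truncated Gaussian bumps). The derived summary is the
spatial interaction curve (SIC)

    SIC_k(s) = Σ_p δ_kp φ_p(s),

the log-intensity contribution of a single source cell at distance s:
positive values are attraction, negative repulsion. The conditioning is
directional — the curve for A→B is not the curve for B→A.

### Likelihood approximation

The Poisson likelihood integral is avoided by the dummy-point logistic
device: auxiliary points from a homogeneous Poisson process of known
intensity λ_dummy are pooled with the observed target cells, and the label
real-vs-dummy follows a logistic regression with logit
`log λ(v) − log λ_dummy`. Fitting this binary model is equivalent to
fitting the Poisson model in the limit of dense dummies; the package
verifies on simulation that posterior means converge to an independent
quadrature Poisson maximum-likelihood fit as the dummy-to-real ratio grows
(`shade.calibration.logistic_poisson_gap`, and `shade.poisson.fit_poisson_ml`
for the oracle). The default λ_dummy gives an expected dummy count of twice
the observed target count, per image.

### Hierarchy

Interaction coefficients are pooled across the study design: cohort-level
ψ ~ N(0, σ²_cohort), patient-level γ ~ N(ψ_parent, σ²_patient),
image-level δ ~ N(γ_parent, σ²_image), componentwise per source type and
basis index. Partial pooling shrinks noisy image-level estimates toward
their patient and cohort, which matters most for short-range basis
functions, where few cell pairs carry information. The *flat* baseline
drops the hierarchy and gives every image's δ an independent
Normal(0, 5²) prior.

Hyperpriors and defaults (config-exposed in `PriorConfig`):
half-Normal(0, 1) on σ_cohort, σ_patient, σ_image; Normal(0, 5²) on β and
on the flat model's δ. The intercept β is per-image and unpooled (each
image has its own baseline density); an image with zero target cells is
dropped with a warning since its rows would inform only that intercept.

## Sampling

The posterior is explored with a No-U-Turn sampler written for this
package (`shade.nuts`): multinomial tree doubling, dual-averaging step
size (target acceptance 0.9), and Stan-style expanding adaptation windows.
The hierarchy is parameterized non-centrally (standard-normal innovations
scaled by the level σ's), which is posterior-invariant and removes the
funnel geometry. Gradients are analytic; the row-level likelihood/gradient
pass is a fused compiled kernel.

The mass matrix is diagonal by default. For moderate dimension (≤150),
cross-level correlations make a dense metric pay off: it is estimated only
in the final adaptation window (where draws outnumber dimensions) with
off-diagonal shrinkage toward the diagonal, because a dense estimate from
a short early window is rank-deficient and collapses mixing — this failure
mode is why `dense_mass="auto"` is conservative. Sampler defaults are
4 chains × 1000 warmup + 1000 draws; the replicate study harnesses use
1–2 chains × 250–500 iterations, which is sufficient for the posterior
means and 95% quantiles those studies consume. Convergence is reported per
fit (split-R̂ and ESS via arviz, divergence counts); a fit whose post-warmup
transitions all diverge raises.

## Synthetic data

`shade.simulate` generates the study designs used throughout testing:

- hierarchy: 2 cohorts × 20 patients × 4 images by default, balanced;
- truth: cohort SICs on three Gaussian kernels centered at 20/40/60 μm
  (width 10 μm, support truncated at 100 μm), responder cohort
  +(1.5, 1.0, 0.5), non-responder −(1.5, 1.0, 0.5) — strong short-range
  attraction vs repulsion with decaying longer-range structure;
- scatter: σ_patient = 0.2, σ_image = 0.1 on the log-intensity scale,
  modest heterogeneity around the cohort truth;
- patterns: 150 source and 150 target points per image in a
  1500×1500 μm window; source points uniform; target points drawn from the
  density ∝ exp(Σ_k q_kᵀδ_k) by rejection sampling against a lattice-scanned
  upper bound (256×256 grid, 10% inflation), with fixed counts
  (a binomial process) since the study design fixes points per image; a
  Poisson-count mode exists. Acceptance below 10⁻⁴ aborts with advice.

What the generator does *not* emulate: segmentation/typing errors,
irregular tissue windows, first-order intensity trends (supported in the
model as user covariates but not simulated), mark information, and
interactions among source cells themselves. Passing tests therefore show
correctness of the estimator under its own assumptions, not robustness to
the artifacts of real multiplexed images.

## Downstream summaries

- **Credible bands and sign detection.** Per-draw curves are exact linear
  images of coefficient draws; bands are pointwise 2.5/50/97.5% quantiles.
  At a test distance the interaction is "positive" when the lower 95%
  bound exceeds 0, "negative" when the upper bound is below 0, else
  "undetected".
- **Group differences.** Per-draw difference of cohort-level SICs; ranges
  where the absolute posterior median difference exceeds 0.05 (log-intensity
  units) are flagged.
- **Heterogeneity.** Between-patient spread is the MAD (raw, no 1.4826
  consistency factor — it is a descriptive summary; the factor is an
  option) over patients of patient-level posterior-median curves, within
  cohort then averaged over cohorts; between-image spread analogously
  within patients. Summarizing posterior medians (not pooled draws) keeps
  the measure a between-unit spread; a posterior-of-MAD option exists.
- **Prediction.** Posterior-mean intensity surfaces on a lattice (5 μm
  default) and the AUC of real-vs-dummy discrimination, with evaluation
  dummies drawn under a seed distinct from the fitting dummies to avoid
  scoring the exact fitting rows.

## Baselines

G-cross, the nearest-neighbour distance distribution from type A to
type B, with three border corrections: reduced-sample (default),
Kaplan–Meier, none. Reduced-sample is the convention adopted for the
estimates; note it is not guaranteed monotone in r (Kaplan–Meier and the
raw estimator are). Envelope tests resample the target type uniformly with
its observed count, keeping sources fixed — 39 simulations give a
pointwise two-sided 5% test. The cohort screen regresses cohort membership
on per-image G values at 20/40/60 μm (binomial GLM) with
Benjamini–Hochberg control at 0.05 across all (pair, distance) tests;
images are treated as independent observations, a caveat when several
images come from one patient. Complete separation is flagged and reported
as an unbounded log-odds ratio.

## Numerical choices and degenerate inputs

- Distances are Euclidean, in μm, on continuous coordinates; no edge
  correction is applied to interaction features — the conditional-intensity
  formulation conditions on the sources actually observed in the window.
- Feature evaluation prunes pairs beyond the basis support with a KD-tree
  and matches the brute-force double loop to 1e-10 (summation order may
  differ at machine precision).
- B-spline bases use clamped equally spaced knots on [0, r_max]; the
  default basis is cubic with P = 6, r_max = 150 μm; the simulation-study
  basis is the three-kernel RBF set. Scale labels (small/medium/large) come
  from the third of [0, r_max] containing each basis function's center.
- Posterior quantiles use the empirical draws without smoothing.
- Replicate r of a study harness uses seed base_seed + r, so replicate
  sets extend without reshuffling; all generators accept explicit seeds
  and identical seeds reproduce bit-identical studies.

## Problem sizes in the shipped checks

The statistical checks in `tests/test_acceptance.py` and
`scripts/acceptance.py` run reduced designs chosen to exercise every
pipeline stage at desk scale: the pooling-benefit study uses 5 patients
per cohort × 2 images × 100 points over ≥12–20 replicates (the full design
is 20 × 4 × 150 over 100 replicates and reproduces the same ordering, most
pronounced at the small scale); calibration checks use 60–80 null images,
200 CSR curve replicates, and 100–120 envelope tests; recovery uses 12–20
replicates of a 4-patient design. Sampler settings in these harnesses are
1 chain × 250–500 iterations as discussed above.

## Known limitations

- Variational inference, cross-validated prediction, K/L-function
  baselines and global envelope tests are out of scope.
- The logistic approximation inherits dummy-point Monte-Carlo noise at
  small dummy ratios; ratio 2 is the study convention, ratio 8 reduces the
  gap to the Poisson fit markedly.
- The G-cross group screen's independence assumption across images from
  the same patient is a simplification; a clustered-error variant is not
  provided.
- Detection of negative interactions at very low densities is limited for
  all methods; the hierarchical model degrades most gracefully because it
  shares information across images.
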