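# Methods

## Model

### Forward model

The signal in one voxel of one subject follows the ball-and-sticks model
with a single diffusivity shared by ball and sticks:

S(b, g) = S0 [ Σᵢ fᵢ exp(−b·d·(μᵢᵀg)²) + (1 − Σᵢ fᵢ) exp(−b·d) ]

with b in ms/µm², d in µm²/ms, fᵢ ∈ [0, 1] with Σfᵢ ≤ 1, and μᵢ axial unit
vectors (μ and −μ are the same fibre). Noise is additive zero-mean
Gaussian with per-subject variance σₛ². b-values are handled internally in
ms/µm²; readers auto-detect s/mm² files by magnitude and rescale by 1/1000.

### Hierarchy

Per voxel, subject parameters are draws from population distributions:
Gaussian (ν_g, σ_g²) for each scalar, Watson (μ_g, κ_g) for each stick
axis. Watson dispersion is reported as the orientation dispersion index
ODI = (2/π)·arctan(1/κ) ∈ (0, 1). Hyperpriors: a power law on each scalar
group variance, log P(σ_g²) = −(α_g + 1)·log σ_g², which keeps group
variances away from zero and yields the closed-form update below (an
exponential form is available via `group_var_prior_form="exp"` but the
power law is the default and the form the closed-form update assumes);
an exponential prior on the noise variance, log P(σₛ²) = −α_n·σₛ²; flat
priors on group means and on κ within box bounds.

Which parameters join the hierarchy is configurable
(`EMConfig.include_in_hierarchy`). Orientations always do — they are what
makes fibre labels comparable. S0 is excluded by default so that
subject-specific intensity scaling (e.g. bias fields) is not penalised.
Defaults: α_g = 1, α_n = 0. Both act weakly; α_g only matters when the
cross-subject scatter is tiny.

## Inference

Joint MAP over all subject and group parameters, by coordinate ascent with
two alternating stages (we keep the source method's E/M naming, although
its "expectation" stage estimates *group* parameters — the opposite of the
conventional EM assignment):

* **Group stage** — subjects fixed. For each scalar:
  ν_g = (1/n) Σ νₛ,  σ_g² = ½ Σ(ν_g − νₛ)² / (α_g + 1 + n/2),
  the exact stationary point of the conditional posterior (verified in the
  tests against numerical root-finding oracles). For each stick: subject
  axes are sign-aligned to the current group axis and a Watson distribution
  is fitted by moment matching on the scatter matrix — the principal
  eigenvector gives the mean axis, and κ solves E[(μᵀx)²] = mean squared
  projection, box-bounded to [1e−3, 1e4]. The confluent hypergeometric
  normaliser M(1/2, 3/2, κ) switches to its large-argument expansion above
  κ = 700 to avoid overflow.
* **Subject stage** — group fixed. Each subject's (S0, d, f, angles) is
  re-estimated independently by Nelder–Mead on the log posterior
  (likelihood + population priors + noise prior), warm-started from the
  previous fit; σₛ² is profiled out in closed form as the positive root of
  2α_n v² + N v − RSS = 0 (RSS/N when α_n = 0, floored at 1e−12 for
  degenerate noiseless data). If the optimiser fails to improve the
  posterior the previous parameters are kept, so the joint objective is
  non-decreasing across stages by construction (asserted to 1e−6 per step
  in the tests). Subjects are conditionally independent given the group,
  so the stage parallelises and its result is order-independent.

Orientations are optimised as spherical polar angles (removing the norm
constraint); fractions are optimised in natural units with an infeasible-
region penalty (negative fractions or Σf > 1). Positivity of S0 and d is
enforced through log-parameterisation.

**Initialisation.** Per-subject maximum-likelihood fits: a log-linear
tensor fit seeds diffusivity (principal eigenvalue, clipped to
[0.2, 3.5] µm²/ms), stick axes (leading eigenvectors) and fractions
(FA-scaled), followed by `n_starts` Nelder–Mead runs (default 3: tensor
start plus two randomised perturbations; best kept). Initial stick labels
are aligned across subjects by greedy axial matching: the best-likelihood
subject seeds reference axes, each subject takes the stick permutation
minimising summed axial angle to the reference, and the reference is
re-estimated from per-stick scatter (3 rounds). After every group stage,
sticks are relabelled so group-mean fractions are non-increasing — stick 1
is always the population-strongest fibre.

**Convergence.** Relative change of every group and subject scalar below
`tol` (default 1e−4) and every axis rotation below `angle_tol_deg`
(default 0.5°) between consecutive iterations; cap `max_iters` = 50. The
criterion is ours — the quantities, not the thresholds, are dictated by
the method. Non-convergence returns the best state with a flag (and a QC
map in the template pipeline).

**Fibre count.** The model is fitted with k = 1, 2, 3 sticks; the
cohort-summed data log-likelihood (including its Gaussian normalisation
constant, so models of different k are comparable) increases with k, and
thresholds on the 1→2 and 2→3 improvements pick k. No principled default
exists; the pipeline default of 5 log-likelihood units per subject was
calibrated on the synthetic phantoms, where a spurious stick buys ≈1.5
units per subject (three extra parameters) and a real crossing buys tens
to hundreds at the default SNR. Both thresholds are exposed.

**Template as prior.** A fitted template voxel can serve as a fixed prior
for new subjects — a single subject-stage optimisation. By default only
the orientation priors are applied: fraction and diffusivity priors shrink
exactly the quantities one usually compares across subjects, and
diffusivity is acquisition-dependent, so anchoring fibre identity through
orientations alone keeps fraction estimates unbiased (|bias| < 0.02 over
100 simulated subjects in the tests).

## Spatial correspondence

Diffusion data are never resampled. Each reference voxel is paired with
the nearest native voxel through the warp (reference-grid displacement
field, mm, RAS world space, 0-based indices; conventions recorded in every
sidecar), and axes move between frames with the warp's complete local
Jacobian — not just its rotation part, so shears contribute —
J μ / |J μ|. Jacobians come from central finite differences of the
displacement (exact for affine warps; O(h²) otherwise; flat singleton axes
contribute zero gradient). During template fitting, subject axes are
rotated into the reference frame for the group stage and group axes are
rotated back (inverse Jacobian) for each subject's priors; Watson κ is
carried over unchanged, as only the axis is transformed.

## Fixel statistics

Per-fixel OLS with arbitrary confounds; t = cᵀβ̂ / √(cᵀ(XᵀX)⁻¹c·RSS/(n−p)),
perfect fits capped at a configurable t (default 100). Fixels are graph
nodes; edges require voxels sharing ≥1 corner (27-neighbourhood, the own
voxel included) *and* axial angle ≤ threshold (default 45°, a convention —
the angle rule is what keeps roughly orthogonal crossing fibres from
mixing). TFCE integrates e(h)^E·h^H dh up to each fixel's statistic, where
e(h) is its supra-threshold connected-component size; implemented as a
descending-threshold sweep over midpoint steps (default 100 steps up to
the cohort max |t|) with incremental union-find merging, which matches an
independent per-threshold labelling implementation to round-off and the
singleton/2-chain closed forms tᴴ⁺¹/(H+1) and 2ᴱtᴴ⁺¹/(H+1) to <1% at 1000
steps. Negative statistics are enhanced as −t and negated.

Two enhancement-exponent presets are shipped, because the literature on
fixel TFCE states both: the default (E=1, H=3) and a voxel-legacy pair
(E=3, H=2). (Neither equals the original voxel TFCE default E=0.5, H=2;
the discrepancy is inherited from the source material and deliberately
left unresolved — both are available by name.)

Inference permutes the maximum TFCE score over fixels (per tail), giving
familywise control across space: p = (1 + #{perm max ≥ observed})/(n_perm
+ 1). Continuous regressors with confounds use Freedman–Lane residual
permutation (confound-only fit, permute residual rows, add back, re-fit),
restricted to contrasts selecting a single design column. Two-sided
inference enhances +t and −t separately and Bonferroni-doubles the smaller
tail p — slightly conservative, which the familywise calibration test
(empirical FWE ≤ nominal 5% over 200 null cohorts at 200 permutations)
reflects.

## Synthetic data

The single-voxel generator reproduces the reference validation protocol:
30 subjects; two fibres with fractions from Gaussians (means 0.5/0.3, SD
0.1) truncated to [0, 1] *then* rescaled to sum to exactly 0.8 (that
order; since the means already sum to 0.8 the rescaling is mean-preserving
in expectation); per-fibre axes Watson-scattered at ODI 0.1 about mean
axes defaulting to orthogonal x/y (the axes and separation angle are free
parameters — the generating protocol leaves them open); diffusivity
N(1.0, 0.05²) µm²/ms (a physiologically typical choice, not specified by
the protocol); S0 = 1; 5 b0 + 25 directions each at b = 1 and 2 ms/µm²
(electrostatic-repulsion sets shipped as a text fixture); additive
Gaussian noise with σ = S0/SNR at SNR 50, SNR being defined on the b0
signal. All randomness flows through seeded numpy PCG64 generators;
identical seeds reproduce cohorts bit-exactly on any platform.

Multi-voxel phantoms lay coherent "tracts" (slabs along x/y/z crossing in
a central block) on small grids, with optional per-subject random affine
warps (emitted as displacement fields with analytic Jacobians) and an
optional age-like covariate scaling one tract's fraction to plant a known
GLM effect. A fixel-level generator (`simulate_fixel_cohort`) emits
per-fixel fraction tables directly, skipping the diffusion-fitting stage,
for statistics calibration at replicate scale.

What the generators do *not* emulate: Rician noise, motion/eddy artefacts,
susceptibility distortion, realistic anatomy, spatially varying S0/d, or
partial-volume grey matter. Passing tests therefore demonstrate
correctness of the inference machinery under the stated generative
assumptions, not robustness to real-data artefacts.

## Problem sizes and numerical choices

The replicated recovery study uses 20 replicate cohorts of 30 subjects
(the cohort size of the reference protocol); calibration suites use 10,000
fixels (GLM type-I error) and 200 replicate null cohorts × 200
permutations (familywise error); phantom pipeline tests run 4–8 subjects
on ≤6³ grids with ≤2 fibres. These sizes make the full suite a
desk-scale run while keeping Monte-Carlo error well inside the asserted
tolerances. Nelder–Mead tolerances default to xatol 1e−5 / fatol 1e−7 /
maxiter 3000; group variances are floored at 1e−10 when used as prior
variances; κ fitting is bounded to [1e−3, 1e4]; axes are serialised with
the first nonzero component positive (Watson axes are sign-free, so a
deterministic representative is needed on disk).

## Known limitations

* A fixed fibre count per voxel across all subjects (the hierarchy is
  rigid in k); subjects genuinely missing a fibre are shrunk toward the
  group rather than dropped.
* Orientation estimates are mildly biased toward the group mean (visible
  as ODI shrinkage on the weaker fibre in the worked example); orientation
  parameters should not themselves be used as group-comparison metrics.
* Derivative-free optimisation is robust but not fast; very large cohorts
  should use the template-as-prior path after a moderate-cohort template.
* Permutation inference assumes exchangeable subjects (no family/site
  structure) and axis-aligned contrasts.
* Nearest-neighbour correspondence only; no sub-voxel interpolation of
  signals (by design — data are never resampled).
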