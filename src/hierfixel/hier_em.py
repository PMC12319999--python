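"""Hierarchical MAP inference of ball-and-sticks parameters across subjects.

In each voxel, every subject's parameters are treated as draws from a
population distribution: Gaussian for scalars (diffusivity, signal
fractions, optionally S0) and Watson for stick orientations.  The joint
posterior over subject and population parameters is maximised by alternating
two stages until nothing moves:

* the *expectation* stage (the naming of the source method, which estimates
  group parameters with subject parameters held fixed): closed-form updates
  for scalar group means/variances and a numerical Watson fit for each
  stick's group orientation and dispersion;
* the *maximisation* stage: each subject's parameters are re-estimated
  independently by maximising its data log-likelihood plus the population
  log-priors, with the noise variance profiled out in closed form.

Because every subject's stick ``i`` is tied to the same population
orientation prior, fibre labels are consistent across subjects by
construction — no post-hoc fibre matching exists or is needed.

The converged population parameters constitute a fixel template that can be
used as a fixed prior to fit new subjects (:func:`fit_with_template_prior`).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize

from .distributions import (
    Hyperparameters,
    ScalarPopulation,
    WatsonParams,
    canonical_axis,
    fit_watson,
    group_variance_log_prior,
    noise_variance_log_prior,
    watson_log_norm,
)
from .forward_model import (
    AcquisitionScheme,
    BallSticksParams,
    NoiseModel,
    log_likelihood,
    predict_signal,
)

__all__ = [
    "SubjectFit",
    "PopulationModel",
    "EMConfig",
    "fit_subject_ml",
    "estimate_noise_variance",
    "expectation_step",
    "maximisation_step",
    "run_em",
    "joint_log_posterior",
    "select_n_fibres",
    "fit_with_template_prior",
]

_SIGMA_FLOOR = 1e-12
_PENALTY = 1e12


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubjectFit:
    """One subject-voxel fit: parameters, noise variance, data log-likelihood."""

    params: BallSticksParams
    noise: NoiseModel
    log_lik: float
    converged: bool = True

    def __post_init__(self):
        if not np.isfinite(self.log_lik):
            raise ValueError("log_lik must be finite")


@dataclass(frozen=True)
class PopulationModel:
    """Per-voxel population distributions of the ball-and-sticks parameters.

    ``scalar_pops`` holds a :class:`ScalarPopulation` per scalar parameter
    (keys ``"d"``, ``"f1"``..``"fk"``, optionally ``"s0"``); ``orient_pops``
    one :class:`WatsonParams` per stick.  Stick 1 is, by labelling
    convention, the population with the largest group-mean signal fraction.
    ``label_perm`` records the permutation (relative to the input stick
    order) that was applied to enforce that convention.
    """

    scalar_pops: dict
    orient_pops: tuple
    n_fibres: int
    label_perm: tuple | None = None

    def __post_init__(self):
        if self.n_fibres != len(self.orient_pops):
            raise ValueError("n_fibres must match the number of orientation pops")
        f_means = [self.scalar_pops[f"f{i + 1}"].mean for i in range(self.n_fibres)]
        if any(a < b - 1e-12 for a, b in zip(f_means, f_means[1:])):
            raise ValueError(
                "labelling convention violated: group-mean fractions must be "
                "non-increasing in stick index"
            )

    @property
    def mean_fractions(self) -> np.ndarray:
        return np.array(
            [self.scalar_pops[f"f{i + 1}"].mean for i in range(self.n_fibres)]
        )

    @property
    def mean_axes(self) -> np.ndarray:
        return np.array([w.mean_axis for w in self.orient_pops])


@dataclass(frozen=True)
class EMConfig:
    """Knobs of the alternating MAP fit.

    ``include_in_hierarchy`` names the parameters that receive population
    priors; stick orientations must always be in it — they are what makes
    fibre labels comparable across subjects.  S0 is excluded by default to
    tolerate subject-specific intensity scaling.  ``tol`` is a relative
    tolerance on scalar changes between iterations, ``angle_tol_deg`` an
    absolute one on axis rotations.
    """

    max_iters: int = 50
    tol: float = 1e-4
    angle_tol_deg: float = 0.5
    hp: Hyperparameters = field(default_factory=Hyperparameters)
    include_in_hierarchy: frozenset = frozenset({"d", "fractions", "orientations"})
    seed: int = 0
    n_starts: int = 3
    group_var_floor: float = 1e-10
    group_var_prior_form: str = "power"
    nm_options: dict = field(
        default_factory=lambda: {"xatol": 1e-5, "fatol": 1e-7, "maxiter": 3000}
    )

    def __post_init__(self):
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if "orientations" not in self.include_in_hierarchy:
            raise ValueError("orientations must stay in the hierarchy")


# ---------------------------------------------------------------------------
# Parameter vector <-> model parameters
# ---------------------------------------------------------------------------
# optimiser layout: [log S0, log d, f_1..f_k, theta_1, phi_1, ..., theta_k, phi_k]

def _angles_to_axes(angles: np.ndarray) -> np.ndarray:
    th, ph = angles[0::2], angles[1::2]
    st = np.sin(th)
    return np.column_stack([st * np.cos(ph), st * np.sin(ph), np.cos(th)])


def _axes_to_angles(axes: np.ndarray) -> np.ndarray:
    axes = np.atleast_2d(axes)
    out = np.empty(2 * len(axes))
    out[0::2] = np.arccos(np.clip(axes[:, 2], -1.0, 1.0))
    out[1::2] = np.arctan2(axes[:, 1], axes[:, 0])
    return out


def _pack(params: BallSticksParams) -> np.ndarray:
    return np.concatenate(
        [
            [math.log(params.s0), math.log(params.d)],
            params.fractions,
            _axes_to_angles(params.orientations),
        ]
    )


def _unpack(x: np.ndarray, k: int) -> BallSticksParams:
    f = np.clip(x[2 : 2 + k], 0.0, None)
    s = f.sum()
    if s > 1.0:
        f = f / s
    return BallSticksParams(
        s0=math.exp(x[0]),
        d=math.exp(x[1]),
        fractions=f,
        orientations=_angles_to_axes(x[2 + k :]),
    )


def estimate_noise_variance(
    rss: float, n_volumes: int, alpha_n: float, eps: float = _SIGMA_FLOOR
) -> float:
    """MAP noise variance given the residual sum of squares.

    Positive root of ``2 alpha_n v^2 + N v - RSS = 0``; the exponential prior
    shrinks the maximum-likelihood estimate RSS/N.  ``alpha_n = 0`` is the ML
    limit.  A zero RSS (degenerate, noiseless data) is floored at ``eps``.
    """
    if rss < 0:
        raise ValueError("rss must be non-negative")
    if alpha_n == 0:
        v = rss / n_volumes
    else:
        v = (-n_volumes + math.sqrt(n_volumes**2 + 8.0 * alpha_n * rss)) / (
            4.0 * alpha_n
        )
    return max(v, eps)


# ---------------------------------------------------------------------------
# Objective
# ---------------------------------------------------------------------------

def _make_objective(
    data: np.ndarray,
    scheme: AcquisitionScheme,
    k: int,
    hp: Hyperparameters,
    pop: PopulationModel | None,
    include: frozenset,
    var_floor: float,
):
    """Build the negative log-posterior closure for one subject.

    The noise variance is profiled out in closed form; all prior constants
    (Watson normalisers, floored prior variances) are precomputed so each
    optimiser evaluation touches only cheap array arithmetic.  With
    ``pop is None`` this is the maximum-likelihood objective.
    """
    b = scheme.bvals
    g_t = scheme.bvecs.T.copy()  # (3, V)
    n = len(data)
    alpha_n = hp.alpha_n
    half_n = 0.5 * n
    log_2pi = math.log(2.0 * math.pi)

    s0_prior = d_prior = f_means = f_vars = None
    mu_g = kappas = None
    const_orient = 0.0
    if pop is not None:
        if "s0" in include and "s0" in pop.scalar_pops:
            sp = pop.scalar_pops["s0"]
            s0_prior = (sp.mean, max(sp.var, var_floor))
        if "d" in include:
            sp = pop.scalar_pops["d"]
            d_prior = (sp.mean, max(sp.var, var_floor))
        if "fractions" in include:
            f_means = np.array(
                [pop.scalar_pops[f"f{i + 1}"].mean for i in range(k)]
            )
            f_vars = np.array(
                [max(pop.scalar_pops[f"f{i + 1}"].var, var_floor) for i in range(k)]
            )
        mu_g = np.array([w.mean_axis for w in pop.orient_pops])  # (k, 3)
        kappas = np.array([w.kappa for w in pop.orient_pops])
        const_orient = sum(watson_log_norm(w.kappa) for w in pop.orient_pops)

    def objective(x: np.ndarray) -> float:
        f = x[2 : 2 + k]
        violation = float(np.sum(np.clip(-f, 0.0, None))) + max(f.sum() - 1.0, 0.0)
        if violation > 0:
            return _PENALTY * (1.0 + violation)
        if abs(x[0]) > 50 or abs(x[1]) > 50:  # keep exp() finite
            return _PENALTY

        s0 = math.exp(x[0])
        d = math.exp(x[1])
        th = x[2 + k :: 2]
        ph = x[3 + k :: 2]
        st = np.sin(th)
        mu = np.empty((k, 3))
        mu[:, 0] = st * np.cos(ph)
        mu[:, 1] = st * np.sin(ph)
        mu[:, 2] = np.cos(th)
        proj_sq = (mu @ g_t) ** 2  # (k, V)
        bd = b * d
        model = s0 * (f @ np.exp(-bd * proj_sq) + (1.0 - f.sum()) * np.exp(-bd))
        resid = data - model
        rss = float(resid @ resid)
        if alpha_n == 0.0:
            s2 = max(rss / n, _SIGMA_FLOOR)
        else:
            s2 = max(
                (-n + math.sqrt(n * n + 8.0 * alpha_n * rss)) / (4.0 * alpha_n),
                _SIGMA_FLOOR,
            )
        lp = -half_n * (log_2pi + math.log(s2)) - 0.5 * rss / s2 - alpha_n * s2

        if pop is not None:
            if s0_prior is not None:
                m, v = s0_prior
                lp += -0.5 * (log_2pi + math.log(v)) - 0.5 * (s0 - m) ** 2 / v
            if d_prior is not None:
                m, v = d_prior
                lp += -0.5 * (log_2pi + math.log(v)) - 0.5 * (d - m) ** 2 / v
            if f_means is not None:
                lp += float(
                    np.sum(
                        -0.5 * (log_2pi + np.log(f_vars))
                        - 0.5 * (f - f_means) ** 2 / f_vars
                    )
                )
            t2 = np.einsum("ij,ij->i", mu, mu_g) ** 2
            lp += const_orient + float(kappas @ t2)
        return -lp

    return objective


def _neg_log_post(
    x: np.ndarray,
    data: np.ndarray,
    scheme: AcquisitionScheme,
    k: int,
    hp: Hyperparameters,
    pop: PopulationModel | None,
    include: frozenset,
    var_floor: float,
) -> float:
    """Negative log-posterior of one subject (see :func:`_make_objective`)."""
    return _make_objective(data, scheme, k, hp, pop, include, var_floor)(x)


def _gauss_log_prior(value: float, pop: ScalarPopulation, var_floor: float) -> float:
    var = max(pop.var, var_floor)
    return -0.5 * math.log(2.0 * math.pi * var) - 0.5 * (value - pop.mean) ** 2 / var


def _fit_from_x(
    x: np.ndarray,
    data: np.ndarray,
    scheme: AcquisitionScheme,
    k: int,
    alpha_n: float,
    converged: bool = True,
) -> SubjectFit:
    params = _unpack(x, k)
    resid = data - predict_signal(params, scheme)
    rss = float(resid @ resid)
    s2 = estimate_noise_variance(rss, len(data), alpha_n)
    noise = NoiseModel(sigma_sq=s2)
    return SubjectFit(
        params=params,
        noise=noise,
        log_lik=log_likelihood(data, params, noise, scheme),
        converged=converged,
    )


# ---------------------------------------------------------------------------
# Independent (maximum-likelihood) subject fits
# ---------------------------------------------------------------------------

def _dti_init(data: np.ndarray, scheme: AcquisitionScheme, k: int) -> np.ndarray:
    """Tensor-derived starting point: log-linear DTI fit, eigenstructure
    seeds diffusivity, stick axes and fractions."""
    d_floor = max(float(np.max(data)) * 1e-6, 1e-12)
    y = np.log(np.clip(data, d_floor, None))
    b, g = scheme.bvals, scheme.bvecs
    design = np.column_stack(
        [
            np.ones_like(b),
            -b * g[:, 0] ** 2,
            -b * g[:, 1] ** 2,
            -b * g[:, 2] ** 2,
            -2 * b * g[:, 0] * g[:, 1],
            -2 * b * g[:, 0] * g[:, 2],
            -2 * b * g[:, 1] * g[:, 2],
        ]
    )
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    log_s0 = coef[0]
    dxx, dyy, dzz, dxy, dxz, dyz = coef[1:]
    tensor = np.array([[dxx, dxy, dxz], [dxy, dyy, dyz], [dxz, dyz, dzz]])
    evals, evecs = np.linalg.eigh(tensor)
    evals = np.clip(evals[::-1], 1e-4, None)  # descending
    evecs = evecs[:, ::-1]
    d0 = float(np.clip(evals[0], 0.2, 3.5))
    fa_num = np.sqrt(((evals - evals.mean()) ** 2).sum())
    fa = float(fa_num / np.sqrt((evals**2).sum()) * np.sqrt(1.5))
    f_total = float(np.clip(fa, 0.1, 0.9))
    weights = np.array([0.6, 0.3, 0.1][:k])
    f0 = f_total * weights / weights.sum()
    axes = evecs[:, :k].T
    x0 = np.concatenate(
        [[np.clip(log_s0, -20, 20), math.log(d0)], f0, _axes_to_angles(axes)]
    )
    return x0


def fit_subject_ml(
    data: np.ndarray,
    scheme: AcquisitionScheme,
    n_fibres: int,
    n_starts: int = 3,
    seed=None,
    hp: Hyperparameters | None = None,
    nm_options: dict | None = None,
) -> SubjectFit:
    """Best-of-multi-start maximum-likelihood ball-and-sticks fit.

    Start 1 is tensor-derived; further starts perturb it with random stick
    rotations and fraction jitter.  Deterministic given ``seed``.
    """
    if n_fibres not in (1, 2, 3):
        raise ValueError("n_fibres must be 1, 2 or 3")
    data = np.asarray(data, dtype=float).ravel()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hp = hp or Hyperparameters(alpha_g=1.0, alpha_n=0.0)
    options = nm_options or {"xatol": 1e-5, "fatol": 1e-7, "maxiter": 3000}
    k = n_fibres

    x0 = _dti_init(data, scheme, k)
    starts = [x0]
    for _ in range(max(n_starts - 1, 0)):
        xp = x0.copy()
        xp[2 : 2 + k] = np.clip(
            xp[2 : 2 + k] + rng.normal(scale=0.1, size=k), 0.01, None
        )
        if xp[2 : 2 + k].sum() > 0.95:
            xp[2 : 2 + k] *= 0.95 / xp[2 : 2 + k].sum()
        xp[2 + k :] += rng.normal(scale=0.4, size=2 * k)
        xp[1] += rng.normal(scale=0.1)
        starts.append(xp)

    best = None
    any_success = False
    objective = _make_objective(data, scheme, k, hp, None, frozenset(), 1e-10)
    for xs in starts:
        res = minimize(objective, xs, method="Nelder-Mead", options=options)
        any_success = any_success or res.success
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= _PENALTY:
        raise RuntimeError(
            f"all {len(starts)} starts failed to produce a feasible fit "
            f"(best objective {None if best is None else best.fun})"
        )
    return _fit_from_x(best.x, data, scheme, k, hp.alpha_n, converged=any_success)


# ---------------------------------------------------------------------------
# Expectation stage: population parameters from fixed subject fits
# ---------------------------------------------------------------------------

def expectation_step(
    subject_fits: list,
    hp: Hyperparameters,
    include: frozenset = frozenset({"d", "fractions", "orientations"}),
    ref_axes: np.ndarray | None = None,
) -> PopulationModel:
    """Closed-form group updates for scalars; Watson fits for orientations.

    For each scalar: ``mean = (1/n) sum(v_s)`` and
    ``var = (1/2) sum((mean - v_s)^2) / (alpha_g + 1 + n/2)`` — the exact MAP
    under the Gaussian population model with the power-law variance prior.
    Stick axes are sign-aligned to ``ref_axes`` (or the first subject) before
    the Watson fit.  Sticks are relabelled so group-mean fractions are
    non-increasing; the applied permutation is recorded in ``label_perm``.
    """
    n = len(subject_fits)
    if n < 2:
        raise ValueError("need at least 2 subjects")
    k = subject_fits[0].params.n_fibres
    if any(f.params.n_fibres != k for f in subject_fits):
        raise ValueError("all subject fits must share the same number of fibres")

    def scalar_update(values: np.ndarray) -> ScalarPopulation:
        mean = float(values.mean())
        ss = float(((mean - values) ** 2).sum())
        var = 0.5 * ss / (hp.alpha_g + 1.0 + 0.5 * n)
        return ScalarPopulation(mean=mean, var=var)

    scalar_pops = {}
    if "s0" in include:
        scalar_pops["s0"] = scalar_update(
            np.array([f.params.s0 for f in subject_fits])
        )
    scalar_pops["d"] = scalar_update(np.array([f.params.d for f in subject_fits]))
    fracs = np.array([f.params.fractions for f in subject_fits])  # (n, k)
    for i in range(k):
        scalar_pops[f"f{i + 1}"] = scalar_update(fracs[:, i])

    orient_pops = []
    for i in range(k):
        axes = np.array([f.params.orientations[i] for f in subject_fits])
        ref = ref_axes[i] if ref_axes is not None else axes[0]
        signs = np.sign(axes @ ref)
        signs[signs == 0] = 1.0
        axes = axes * signs[:, None]
        orient_pops.append(fit_watson(axes))

    order = tuple(np.argsort(-np.array([scalar_pops[f"f{i+1}"].mean for i in range(k)]), kind="stable"))
    relabelled = {key: val for key, val in scalar_pops.items() if not key.startswith("f")}
    for new_i, old_i in enumerate(order):
        relabelled[f"f{new_i + 1}"] = scalar_pops[f"f{old_i + 1}"]
    orient_pops = tuple(orient_pops[old_i] for old_i in order)
    return PopulationModel(
        scalar_pops=relabelled,
        orient_pops=orient_pops,
        n_fibres=k,
        label_perm=order,
    )


def _permute_fit(fit: SubjectFit, perm: tuple) -> SubjectFit:
    idx = list(perm)
    params = BallSticksParams(
        s0=fit.params.s0,
        d=fit.params.d,
        fractions=fit.params.fractions[idx],
        orientations=fit.params.orientations[idx],
    )
    return replace(fit, params=params)


# ---------------------------------------------------------------------------
# Maximisation stage: subject parameters under fixed population priors
# ---------------------------------------------------------------------------

def maximisation_step(
    data: np.ndarray,
    scheme: AcquisitionScheme,
    pop: PopulationModel,
    warm_start: SubjectFit,
    cfg: EMConfig,
) -> SubjectFit:
    """MAP re-fit of one subject under the current population priors.

    Subjects are conditionally independent given the population model, so
    the result does not depend on the order in which subjects are processed.
    The optimiser is warm-started from the previous fit and the previous fit
    is kept whenever the optimiser fails to improve the posterior (this
    preserves coordinate-ascent monotonicity).
    """
    if pop.n_fibres != warm_start.params.n_fibres:
        raise ValueError("population model and warm start disagree on n_fibres")
    data = np.asarray(data, dtype=float).ravel()
    k = pop.n_fibres
    objective = _make_objective(
        data, scheme, k, cfg.hp, pop, cfg.include_in_hierarchy, cfg.group_var_floor
    )
    x0 = _pack(warm_start.params)
    f0 = objective(x0)
    res = minimize(objective, x0, method="Nelder-Mead", options=cfg.nm_options)
    if not np.isfinite(res.fun) or res.fun > f0:
        x_best, ok = x0, False
    else:
        x_best, ok = res.x, True
    fit = _fit_from_x(x_best, data, scheme, k, cfg.hp.alpha_n, converged=ok)
    # store axes with signs aligned to the group mean axes
    mu = fit.params.orientations.copy()
    for i, w in enumerate(pop.orient_pops):
        if mu[i] @ w.mean_axis < 0:
            mu[i] = -mu[i]
    params = BallSticksParams(
        s0=fit.params.s0, d=fit.params.d, fractions=fit.params.fractions,
        orientations=mu,
    )
    return replace(fit, params=params)


# ---------------------------------------------------------------------------
# Joint objective (for monotonicity diagnostics)
# ---------------------------------------------------------------------------

def _group_var_log_prior_total(pop: PopulationModel, cfg: EMConfig) -> float:
    total = 0.0
    include = cfg.include_in_hierarchy
    for name, sp in pop.scalar_pops.items():
        if name == "s0" and "s0" not in include:
            continue
        if name == "d" and "d" not in include:
            continue
        if name.startswith("f") and "fractions" not in include:
            continue
        total += group_variance_log_prior(
            max(sp.var, cfg.group_var_floor), cfg.hp, cfg.group_var_prior_form
        )
    return total


def joint_log_posterior(
    subject_fits: list, pop: PopulationModel, cfg: EMConfig, all_data, schemes
) -> float:
    """Joint MAP objective: data log-likelihoods + subject priors + group
    variance hyperpriors.  Both alternating stages ascend this quantity."""
    total = 0.0
    for fit, data, scheme in zip(subject_fits, all_data, schemes):
        x = _pack(fit.params)
        total -= _neg_log_post(
            x, np.asarray(data, float).ravel(), scheme, pop.n_fibres, cfg.hp,
            pop, cfg.include_in_hierarchy, cfg.group_var_floor,
        )
    return total + _group_var_log_prior_total(pop, cfg)


# ---------------------------------------------------------------------------
# Initial cross-subject label alignment
# ---------------------------------------------------------------------------

def _align_labels(fits: list, k: int, n_rounds: int = 3):
    """Greedy axial matching of stick labels across independently fitted
    subjects, so the first expectation stage sees coherent fibre clusters.

    The reference starts as the best-likelihood subject's axes; each round
    assigns every subject the stick permutation minimising the summed axial
    angle to the reference, then re-estimates the reference axes as the
    principal eigenvectors of the per-stick scatter.  Returns the chosen
    permutation per subject.
    """
    if k == 1:
        return [(0,)] * len(fits)
    ref_idx = int(np.argmax([f.log_lik for f in fits]))
    ref = fits[ref_idx].params.orientations.copy()
    candidates = list(itertools.permutations(range(k)))
    chosen = [tuple(range(k))] * len(fits)
    for _ in range(n_rounds):
        new = []
        for fit in fits:
            mu = fit.params.orientations
            best_perm, best_cost = None, np.inf
            for perm in candidates:
                cost = -sum(abs(mu[p] @ ref[i]) for i, p in enumerate(perm))
                if cost < best_cost:
                    best_cost, best_perm = cost, perm
            new.append(best_perm)
        chosen = new
        for i in range(k):
            axes = np.array(
                [f.params.orientations[p[i]] for f, p in zip(fits, chosen)]
            )
            scatter = axes.T @ axes
            _, vecs = np.linalg.eigh(scatter)
            ref[i] = vecs[:, 2]
    return chosen


# ---------------------------------------------------------------------------
# Full EM driver
# ---------------------------------------------------------------------------

def localise_population(pop: PopulationModel, jac: np.ndarray) -> PopulationModel:
    """Rotate the population mean axes into a subject's native frame.

    ``jac`` maps native to reference directions; the prior seen by a subject
    uses the inverse mapping on the group mean axes (normalised — only the
    axis is transformed, the Watson concentration is carried over).
    """
    inv = np.linalg.inv(jac)
    orient = []
    for w in pop.orient_pops:
        v = inv @ w.mean_axis
        orient.append(WatsonParams(mean_axis=v / np.linalg.norm(v), kappa=w.kappa))
    return PopulationModel(
        scalar_pops=pop.scalar_pops, orient_pops=tuple(orient),
        n_fibres=pop.n_fibres, label_perm=None,
    )


def _to_reference(fit: SubjectFit, jac: np.ndarray) -> SubjectFit:
    """View of a subject fit with stick axes rotated to the reference frame."""
    mu = fit.params.orientations @ jac.T
    mu /= np.linalg.norm(mu, axis=1, keepdims=True)
    params = BallSticksParams(
        s0=fit.params.s0, d=fit.params.d, fractions=fit.params.fractions,
        orientations=mu,
    )
    return replace(fit, params=params)


def run_em(
    all_data,
    schemes,
    n_fibres: int,
    cfg: EMConfig,
    init_fits: list | None = None,
    jacobians: list | None = None,
):
    """Alternate the two stages from independent ML initialisation.

    ``all_data``: (n_subjects, n_volumes) array or list of signal vectors;
    ``schemes``: one :class:`AcquisitionScheme` shared by all subjects or a
    list with one per subject.  ``jacobians`` (optional, one 3×3 per
    subject) are the local warp Jacobians mapping native to reference
    directions: axes are pooled in the reference frame and priors applied
    in each subject's native frame, so diffusion data are never resampled.

    Returns ``(pop, fits, diagnostics)``: the population model (axes in the
    reference frame), per-subject fits in native space (labels consistent
    with ``pop``) and a diagnostics dict with the per-stage joint
    log-posterior trace (non-decreasing up to optimiser tolerance),
    iteration count and convergence flag.
    """
    all_data = [np.asarray(d, dtype=float).ravel() for d in all_data]
    n = len(all_data)
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if isinstance(schemes, AcquisitionScheme):
        schemes = [schemes] * n
    if len(schemes) != n:
        raise ValueError("need one scheme per subject")
    if jacobians is not None and len(jacobians) != n:
        raise ValueError("need one Jacobian per subject")

    seeds = np.random.SeedSequence(cfg.seed).spawn(n)
    if init_fits is None:
        init_fits = [
            fit_subject_ml(
                d, s, n_fibres, n_starts=cfg.n_starts,
                seed=np.random.default_rng(ss), hp=cfg.hp,
                nm_options=cfg.nm_options,
            )
            for d, s, ss in zip(all_data, schemes, seeds)
        ]

    def ref_view(fits):
        if jacobians is None:
            return fits
        return [_to_reference(f, j) for f, j in zip(fits, jacobians)]

    def subject_pops(pop):
        if jacobians is None:
            return [pop] * n
        return [localise_population(pop, j) for j in jacobians]

    def joint(fits, pop):
        pops = subject_pops(pop)
        total = 0.0
        for fit, data, scheme, p in zip(fits, all_data, schemes, pops):
            x = _pack(fit.params)
            total -= _neg_log_post(
                x, data, scheme, pop.n_fibres, cfg.hp, p,
                cfg.include_in_hierarchy, cfg.group_var_floor,
            )
        total += _group_var_log_prior_total(pop, cfg)
        return total

    perms = _align_labels(ref_view(init_fits), n_fibres)
    fits = [_permute_fit(f, p) for f, p in zip(init_fits, perms)]

    trace = []
    pop = None
    converged = False
    n_iter = 0
    for n_iter in range(1, cfg.max_iters + 1):
        prev_pop = pop
        ref = prev_pop.mean_axes if prev_pop is not None else None
        pop = expectation_step(
            ref_view(fits), cfg.hp, include=cfg.include_in_hierarchy, ref_axes=ref
        )
        if pop.label_perm is not None and tuple(pop.label_perm) != tuple(range(n_fibres)):
            fits = [_permute_fit(f, pop.label_perm) for f in fits]
        trace.append(joint(fits, pop))

        prev_fits = fits
        pops = subject_pops(pop)
        fits = [
            maximisation_step(d, s, p, f, cfg)
            for d, s, p, f in zip(all_data, schemes, pops, prev_fits)
        ]
        trace.append(joint(fits, pop))

        if prev_pop is not None and _converged(prev_pop, pop, prev_fits, fits, cfg):
            converged = True
            break

    if not converged:
        warnings.warn(
            f"EM did not converge within {cfg.max_iters} iterations", RuntimeWarning
        )
    diagnostics = {
        "log_posterior_trace": np.array(trace),
        "n_iter": n_iter,
        "converged": converged,
    }
    return pop, fits, diagnostics


def _rel_change(a: float, b: float) -> float:
    return abs(a - b) / max(abs(a), abs(b), 1e-12)


def _converged(prev_pop, pop, prev_fits, fits, cfg: EMConfig) -> bool:
    angle_tol = math.radians(cfg.angle_tol_deg)
    for key, sp in pop.scalar_pops.items():
        if key not in prev_pop.scalar_pops:
            return False
        if _rel_change(prev_pop.scalar_pops[key].mean, sp.mean) > cfg.tol:
            return False
    for w0, w1 in zip(prev_pop.orient_pops, pop.orient_pops):
        dot = abs(float(w0.mean_axis @ w1.mean_axis))
        if math.acos(min(dot, 1.0)) > angle_tol:
            return False
    for f0, f1 in zip(prev_fits, fits):
        if _rel_change(f0.params.d, f1.params.d) > cfg.tol:
            return False
        for a, b in zip(f0.params.fractions, f1.params.fractions):
            if abs(a - b) > cfg.tol:
                return False
        for m0, m1 in zip(f0.params.orientations, f1.params.orientations):
            dot = abs(float(m0 @ m1))
            if math.acos(min(dot, 1.0)) > angle_tol:
                return False
    return True


# ---------------------------------------------------------------------------
# Fibre-count selection
# ---------------------------------------------------------------------------

def select_n_fibres(ll_by_k: np.ndarray, thr_12: float, thr_23: float):
    """Pick 1, 2 or 3 fibres per voxel from summed log-likelihoods.

    ``ll_by_k``: shape (3,) or (V, 3), the cohort-summed data log-likelihood
    of the 1-, 2- and 3-fibre hierarchical fits.  A voxel keeps one fibre if
    the 1→2 improvement is below ``thr_12``; otherwise two unless the 2→3
    improvement exceeds ``thr_23``.  Log-likelihood should be non-decreasing
    in the number of fibres; a decrease indicates an optimisation failure
    and triggers a warning.
    """
    ll = np.atleast_2d(np.asarray(ll_by_k, dtype=float))
    if ll.shape[1] != 3:
        raise ValueError("ll_by_k must have 3 entries per voxel (k = 1, 2, 3)")
    d12 = ll[:, 1] - ll[:, 0]
    d23 = ll[:, 2] - ll[:, 1]
    if np.any(d12 < -1e-6) or np.any(d23 < -1e-6):
        warnings.warn(
            "log-likelihood decreased when adding a fibre: optimisation failure "
            "in at least one voxel", RuntimeWarning,
        )
    out = np.where(d12 < thr_12, 1, np.where(d23 < thr_23, 2, 3))
    return int(out[0]) if np.asarray(ll_by_k).ndim == 1 else out


# ---------------------------------------------------------------------------
# Template-as-prior fitting of a new subject
# ---------------------------------------------------------------------------

def fit_with_template_prior(
    data: np.ndarray,
    scheme: AcquisitionScheme,
    template_voxel: PopulationModel,
    cfg: EMConfig | None = None,
    warm_start: SubjectFit | None = None,
) -> SubjectFit:
    """Fit one new subject-voxel with a fixed template as the prior.

    By default only the orientation priors are applied (the template's role
    is to anchor fibre identity); diffusivity and fraction priors can be
    re-enabled through ``cfg.include_in_hierarchy``, but leaving them off
    avoids shrinking exactly the quantities one usually wants to compare
    across subjects, and tolerates acquisition-dependent diffusivities.
    """
    if cfg is None:
        cfg = EMConfig(include_in_hierarchy=frozenset({"orientations"}))
    data = np.asarray(data, dtype=float).ravel()
    if warm_start is None:
        pop = template_voxel
        s0 = float(np.mean(data[scheme.b0_mask])) if scheme.b0_mask.any() else float(
            np.max(data)
        )
        s0 = max(s0, 1e-6)
        params = BallSticksParams(
            s0=s0,
            d=pop.scalar_pops["d"].mean,
            fractions=pop.mean_fractions,
            orientations=pop.mean_axes,
        )
        noise = NoiseModel(sigma_sq=max((0.05 * s0) ** 2, _SIGMA_FLOOR))
        warm_start = SubjectFit(
            params=params,
            noise=noise,
            log_lik=log_likelihood(data, params, noise, scheme),
        )
    return maximisation_step(data, scheme, template_voxel, warm_start, cfg)
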