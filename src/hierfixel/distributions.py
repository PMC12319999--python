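"""Watson directional distribution and the scalar hyperprior densities.

The Watson distribution is the axially symmetric analogue of a Gaussian on
the sphere: for a unit axis ``x`` and mean axis ``mu``::

    p(x) = C(kappa) * exp(kappa * (mu . x)^2),
    C(kappa) = [4 pi * M(1/2, 3/2, kappa)]^{-1}

with ``M`` Kummer's confluent hypergeometric function.  Concentration
``kappa`` is reported to users through the orientation dispersion index

    ODI = (2/pi) * arctan(1/kappa),

which maps (0, inf) onto (0, 1): 0 = perfectly aligned axes, 1 = isotropic.

This module also hosts the hyperprior densities used by the hierarchical
model: a power-law prior on group variances, ``log P(var) =
-(alpha_g + 1) * log var`` (the form whose stationarity condition yields the
closed-form group-variance update with denominator ``alpha_g + 1 + n/2``),
and an exponential prior on the subject noise variance, ``log P(var) =
-alpha_n * var``.  An exponential group-variance form is available as a
switch for completeness but the power law is the default used throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import special
from scipy.optimize import brentq

__all__ = [
    "WatsonParams",
    "ScalarPopulation",
    "Hyperparameters",
    "kappa_to_odi",
    "odi_to_kappa",
    "watson_log_norm",
    "watson_log_pdf",
    "watson_sample",
    "fit_watson",
    "group_variance_log_prior",
    "noise_variance_log_prior",
    "canonical_axis",
    "KAPPA_MIN",
    "KAPPA_MAX",
]

# box bounds for kappa during fitting; above _KAPPA_ASYMPT the confluent
# hypergeometric is evaluated through its large-argument expansion
KAPPA_MIN = 1e-3
KAPPA_MAX = 1e4
_KAPPA_ASYMPT = 700.0


def kappa_to_odi(kappa: float) -> float:
    """Orientation dispersion index (2/pi)*arctan(1/kappa)."""
    kappa = float(kappa)
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    return (2.0 / math.pi) * math.atan2(1.0, kappa)


def odi_to_kappa(odi: float) -> float:
    """Exact inverse of :func:`kappa_to_odi`: kappa = 1/tan(pi*ODI/2)."""
    odi = float(odi)
    if not 0.0 < odi < 1.0:
        raise ValueError("ODI must lie in (0, 1)")
    return 1.0 / math.tan(0.5 * math.pi * odi)


def canonical_axis(axis: np.ndarray) -> np.ndarray:
    """Deterministic sign representative of an axial vector.

    The first component whose magnitude exceeds 1e-12 is made positive.
    Watson axes are sign-free; serialisation and comparisons need a unique
    representative.
    """
    axis = np.asarray(axis, dtype=float)
    flat = axis.ravel()
    nz = np.nonzero(np.abs(flat) > 1e-12)[0]
    if len(nz) and flat[nz[0]] < 0:
        return -axis
    return axis.copy()


@dataclass(frozen=True)
class WatsonParams:
    """Mean axis and concentration of a Watson distribution.

    ``odi`` is derived from ``kappa``; the two always satisfy
    ``odi == (2/pi) arctan(1/kappa)``.
    """

    mean_axis: np.ndarray
    kappa: float

    def __post_init__(self):
        axis = np.asarray(self.mean_axis, dtype=float).ravel()
        if axis.shape != (3,):
            raise ValueError("mean_axis must be a 3-vector")
        n = np.linalg.norm(axis)
        if abs(n - 1.0) > 1e-6:
            raise ValueError("mean_axis must be unit norm")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        object.__setattr__(self, "mean_axis", axis / n)

    @property
    def odi(self) -> float:
        return kappa_to_odi(self.kappa)

    @classmethod
    def from_odi(cls, mean_axis, odi: float) -> "WatsonParams":
        return cls(mean_axis=mean_axis, kappa=odi_to_kappa(odi))


@dataclass(frozen=True)
class ScalarPopulation:
    """Gaussian population of a scalar parameter: group mean and variance."""

    mean: float
    var: float

    def __post_init__(self):
        if self.var < 0:
            raise ValueError("population variance must be non-negative")


@dataclass(frozen=True)
class Hyperparameters:
    """User-set hyperparameters of the hierarchical priors.

    ``alpha_g`` penalises small group variances (keeps them away from zero);
    ``alpha_n`` penalises large subject noise variances.
    """

    alpha_g: float = 1.0
    alpha_n: float = 0.0

    def __post_init__(self):
        if self.alpha_g <= 0:
            raise ValueError("alpha_g must be positive")
        if self.alpha_n < 0:
            raise ValueError("alpha_n must be non-negative")


# ---------------------------------------------------------------------------
# Watson density
# ---------------------------------------------------------------------------

def _log_kummer_half(kappa: float) -> float:
    """log M(1/2, 3/2, kappa) for kappa > 0, stable for large kappa.

    M(1/2, 3/2, k) = sqrt(pi) * erfi(sqrt(k)) / (2 sqrt(k)); above the
    overflow point the large-argument series M ~ e^k/(2k) * (1 + 1/(2k) +
    3/(4k^2)) is used.
    """
    if kappa < _KAPPA_ASYMPT:
        return float(np.log(special.hyp1f1(0.5, 1.5, kappa)))
    s = 1.0 + 1.0 / (2.0 * kappa) + 3.0 / (4.0 * kappa**2)
    return kappa - math.log(2.0 * kappa) + math.log(s)


def watson_log_norm(kappa: float) -> float:
    """log C(kappa) = -log(4 pi M(1/2, 3/2, kappa))."""
    return -math.log(4.0 * math.pi) - _log_kummer_half(kappa)


def watson_log_pdf(x: np.ndarray, w: WatsonParams) -> np.ndarray | float:
    """Log-density of unit axis/axes ``x`` under ``w``.

    ``x`` may be a single 3-vector or an (n, 3) array; axes must be unit
    norm.  The density integrates to 1 over the full sphere (antipodal mass
    is counted on both hemispheres).
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    xs = np.atleast_2d(x)
    norms = np.linalg.norm(xs, axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-6):
        raise ValueError("x must be unit norm")
    t2 = (xs @ w.mean_axis) ** 2
    out = watson_log_norm(w.kappa) + w.kappa * t2
    return float(out[0]) if single else out


# ---------------------------------------------------------------------------
# Sampling (exact rejection from an angular-central-Gaussian envelope)
# ---------------------------------------------------------------------------

def _acg_envelope_b(kappa: float) -> float:
    """Envelope parameter b for the bipolar Watson rejection sampler.

    Solves 1/(b - 2k) + 2/b = 1 (three-dimensional case), taking the root
    with b > 2k so the envelope covariance is positive definite.
    """
    return 0.5 * (2.0 * kappa + 3.0 + math.sqrt(4.0 * kappa**2 - 4.0 * kappa + 9.0))


def watson_sample(w: WatsonParams, n: int, seed=None) -> np.ndarray:
    """Draw ``n`` unit axes from the Watson distribution ``w``.

    Exact rejection sampling with an angular-central-Gaussian envelope
    (acceptance probability bounded away from zero for every kappa), so the
    sampler remains practical from the uniform limit up to kappa ~ 1e6.
    Reproducible: ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    kappa = w.kappa
    b = _acg_envelope_b(kappa)
    axial_sd = math.sqrt(b / (b - 2.0 * kappa))
    # log of the rejection bound max_t exp(k t) (1 - 2 k t / b)^{3/2}
    t_star = min(1.0, max(0.0, (b - 3.0) / (2.0 * kappa)))
    log_m = kappa * t_star + 1.5 * math.log1p(-2.0 * kappa * t_star / b)

    out = np.empty((n, 3))
    filled = 0
    while filled < n:
        m = max(n - filled, 16)
        z = rng.standard_normal((m, 3))
        z[:, 2] *= axial_sd
        z /= np.linalg.norm(z, axis=1, keepdims=True)
        t = z[:, 2] ** 2
        log_ratio = kappa * t + 1.5 * np.log1p(-2.0 * kappa * t / b) - log_m
        accept = np.log(rng.uniform(size=m)) < log_ratio
        take = z[accept][: n - filled]
        out[filled : filled + len(take)] = take
        filled += len(take)

    # rotate the pole e3 onto the mean axis
    rot = _rotation_to(w.mean_axis)
    return out @ rot.T


def _rotation_to(axis: np.ndarray) -> np.ndarray:
    """Orthonormal matrix whose third column is ``axis``."""
    e3 = np.asarray(axis, dtype=float)
    helper = np.array([1.0, 0.0, 0.0]) if abs(e3[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(helper, e3)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(e3, e1)
    return np.column_stack([e1, e2, e3])


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _mean_proj_sq(kappa: float) -> float:
    """E[(mu.x)^2] under Watson(kappa) = d/dk log M(1/2, 3/2, k)."""
    if kappa < _KAPPA_ASYMPT:
        m = special.hyp1f1(0.5, 1.5, kappa)
        dm = special.hyp1f1(1.5, 2.5, kappa) / 3.0
        return float(dm / m)
    # derivative of the asymptotic log M
    s = 1.0 + 1.0 / (2.0 * kappa) + 3.0 / (4.0 * kappa**2)
    ds = -1.0 / (2.0 * kappa**2) - 3.0 / (2.0 * kappa**3)
    return 1.0 - 1.0 / kappa + ds / s


def fit_watson(axes: np.ndarray) -> WatsonParams:
    """Maximum-likelihood Watson fit to a set of unit axes.

    The mean axis is the principal eigenvector of the scatter matrix
    ``sum_i x_i x_i^T`` (sign canonicalised); kappa solves the moment
    condition E[(mu.x)^2] = mean squared projection, box-bounded to
    [KAPPA_MIN, KAPPA_MAX].

    Raises ``ValueError`` on isotropic scatter (axis unidentifiable).
    """
    axes = np.atleast_2d(np.asarray(axes, dtype=float))
    if len(axes) < 2:
        raise ValueError("need at least 2 axes to fit a Watson distribution")
    norms = np.linalg.norm(axes, axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-6):
        raise ValueError("axes must be unit norm")

    scatter = axes.T @ axes / len(axes)
    evals, evecs = np.linalg.eigh(scatter)
    if evals[2] - evals[1] < 1e-9:
        raise ValueError(
            "isotropic/degenerate axis scatter: Watson mean axis unidentifiable"
        )
    mean_axis = canonical_axis(evecs[:, 2])
    r_bar = float(evals[2])  # mean squared projection on the principal axis

    lo, hi = KAPPA_MIN, KAPPA_MAX
    if r_bar <= _mean_proj_sq(lo):
        kappa = lo
    elif r_bar >= _mean_proj_sq(hi):
        kappa = hi
    else:
        kappa = brentq(lambda k: _mean_proj_sq(k) - r_bar, lo, hi, xtol=1e-10)
    return WatsonParams(mean_axis=mean_axis, kappa=kappa)


# ---------------------------------------------------------------------------
# Hyperpriors
# ---------------------------------------------------------------------------

def group_variance_log_prior(
    var: float, hp: Hyperparameters, form: str = "power"
) -> float:
    """Log hyperprior of a group variance.

    ``form="power"`` (default): -(alpha_g + 1) * log(var), the power law whose
    MAP update has denominator alpha_g + 1 + n/2.  ``form="exp"`` evaluates
    the alternative exponential form alpha_g * var.
    """
    if var <= 0:
        raise ValueError("variance must be positive")
    if form == "power":
        return -(hp.alpha_g + 1.0) * math.log(var)
    if form == "exp":
        return hp.alpha_g * var
    raise ValueError(f"unknown group-variance prior form {form!r}")


def noise_variance_log_prior(var: float, hp: Hyperparameters) -> float:
    """Exponential log-prior of the subject noise variance: -alpha_n * var."""
    if var <= 0:
        raise ValueError("variance must be positive")
    return -hp.alpha_n * var
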