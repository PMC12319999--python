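"""Ball-and-sticks diffusion signal model and its Gaussian data log-likelihood.

The ball-and-sticks model decomposes the diffusion-weighted MR signal in a
voxel into an isotropic "ball" compartment (free water) and one or more
perfectly anisotropic "stick" compartments, each representing a coherent
fibre population::

    S(b, g) = S0 * [ sum_i f_i * exp(-b * d * (mu_i . g)^2)
                     + (1 - sum_i f_i) * exp(-b * d) ]

where ``b`` is the diffusion weighting (ms/µm²), ``g`` the unit gradient
direction, ``d`` the diffusivity (µm²/ms, shared between ball and sticks),
``f_i`` the signal fraction of stick ``i`` and ``mu_i`` its unit orientation
axis.  Orientations are axial: ``mu`` and ``-mu`` describe the same fibre.

Noise is modelled as additive zero-mean Gaussian with per-subject variance
``sigma_s^2``; :func:`log_likelihood` returns the exact Gaussian log-density
including the normalisation constant, which matters when log-likelihoods of
models with different stick counts are compared.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AcquisitionScheme",
    "BallSticksParams",
    "NoiseModel",
    "predict_signal",
    "log_likelihood",
]

_UNIT_TOL = 1e-6


@dataclass(frozen=True)
class AcquisitionScheme:
    """Diffusion acquisition protocol: b-values (ms/µm²) and unit gradients.

    ``bvecs`` rows with ``bval == 0`` may be zero vectors (a b0 volume has no
    meaningful direction); every diffusion-weighted row must be unit norm.
    """

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self):
        bvals = np.asarray(self.bvals, dtype=float).ravel()
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.ndim != 2 or bvecs.shape[1] != 3:
            raise ValueError(f"bvecs must be (N, 3), got {bvecs.shape}")
        if len(bvals) != len(bvecs):
            raise ValueError(
                f"bvals ({len(bvals)}) and bvecs ({len(bvecs)}) length mismatch"
            )
        if np.any(bvals < 0):
            raise ValueError("b-values must be non-negative")
        dw = bvals > 0
        norms = np.linalg.norm(bvecs[dw], axis=1)
        if np.any(np.abs(norms - 1.0) > _UNIT_TOL):
            raise ValueError("diffusion-weighted bvecs must be unit norm")
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    @property
    def n_volumes(self) -> int:
        return len(self.bvals)

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0


@dataclass(frozen=True)
class BallSticksParams:
    """One subject-voxel parameter set {S0, d, f_i, mu_i}.

    ``orientations`` are axial unit 3-vectors (sign-free); ``fractions`` are
    per-stick signal fractions with ``sum(f) <= 1``.
    """

    s0: float
    d: float
    fractions: np.ndarray
    orientations: np.ndarray

    def __post_init__(self):
        f = np.atleast_1d(np.asarray(self.fractions, dtype=float))
        mu = np.atleast_2d(np.asarray(self.orientations, dtype=float))
        if self.s0 <= 0:
            raise ValueError("S0 must be positive")
        if self.d <= 0:
            raise ValueError("diffusivity d must be positive")
        if np.any(f < 0):
            raise ValueError("signal fractions must be non-negative")
        if f.sum() > 1 + 1e-9:
            raise ValueError(f"signal fractions sum to {f.sum():.6f} > 1")
        if mu.shape != (len(f), 3):
            raise ValueError("need one unit 3-vector orientation per stick")
        norms = np.linalg.norm(mu, axis=1)
        if np.any(np.abs(norms - 1.0) > _UNIT_TOL):
            raise ValueError("orientations must be unit norm")
        object.__setattr__(self, "fractions", f)
        object.__setattr__(self, "orientations", mu)

    @property
    def n_fibres(self) -> int:
        return len(self.fractions)


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian noise with variance ``sigma_sq`` (signal units²)."""

    sigma_sq: float

    def __post_init__(self):
        if self.sigma_sq <= 0:
            raise ValueError("noise variance must be positive")


def predict_signal(params: BallSticksParams, scheme: AcquisitionScheme) -> np.ndarray:
    """Evaluate the ball-and-sticks signal for every volume of ``scheme``.

    Invariant under negation of any stick orientation (axial symmetry).
    """
    b = scheme.bvals  # (V,)
    g = scheme.bvecs  # (V, 3)
    # (k, V): squared projections of gradients on stick axes
    proj_sq = (params.orientations @ g.T) ** 2
    stick_atten = np.exp(-b[None, :] * params.d * proj_sq)
    ball_atten = np.exp(-b * params.d)
    f = params.fractions
    return params.s0 * (f @ stick_atten + (1.0 - f.sum()) * ball_atten)


def log_likelihood(
    data: np.ndarray,
    params: BallSticksParams,
    noise: NoiseModel,
    scheme: AcquisitionScheme,
) -> float:
    """Exact Gaussian log-density of ``data`` under the model prediction.

    Includes the ``-(N/2) log(2 pi sigma^2)`` normalisation so that values are
    comparable across models with different numbers of sticks (fibre-count
    selection relies on this).
    """
    data = np.asarray(data, dtype=float).ravel()
    if len(data) != scheme.n_volumes:
        raise ValueError(
            f"data length {len(data)} does not match scheme ({scheme.n_volumes})"
        )
    if not np.all(np.isfinite(data)):
        raise ValueError("data contains non-finite values")
    resid = data - predict_signal(params, scheme)
    n = len(data)
    s2 = noise.sigma_sq
    return float(-0.5 * n * np.log(2.0 * np.pi * s2) - 0.5 * np.dot(resid, resid) / s2)
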