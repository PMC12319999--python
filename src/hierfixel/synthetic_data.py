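"""Synthetic diffusion cohorts with known ground truth.

Two generators:

* :func:`simulate_population` — a single-voxel cohort whose defaults mirror
  the validation protocol of the source method: 30 subjects, two crossing
  fibre populations with signal fractions drawn from truncated Gaussians
  (means 0.5/0.3, SD 0.1, renormalised to sum to 0.8), Watson-distributed
  stick axes (ODI 0.1 per fibre), a UK-Biobank-like two-shell scheme (5 b0 +
  2x25 directions at b = 1, 2 ms/µm²) and additive Gaussian noise at
  SNR = 50 (SNR defined as S0 over the noise standard deviation).
* :func:`simulate_phantom_volume` — small multi-voxel phantoms (slabs of
  coherent "tracts", optionally crossing) with per-subject affine warps and
  analytic Jacobians, plus an optional age-like covariate that linearly
  scales one tract's signal fraction to plant a known group effect.

Everything is deterministic given the seed (numpy PCG64 generators).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import truncnorm

from .distributions import WatsonParams, odi_to_kappa, watson_sample
from .forward_model import AcquisitionScheme, BallSticksParams, predict_signal

__all__ = [
    "PopulationSpec",
    "GroundTruthTable",
    "PhantomCohort",
    "ukb_like_scheme",
    "simulate_population",
    "simulate_phantom_volume",
    "simulate_fixel_cohort",
    "PHANTOM_LAYOUTS",
]


def ukb_like_scheme(n_b0: int = 5) -> AcquisitionScheme:
    """Two-shell scheme: ``n_b0`` b0 volumes then 25 directions at b = 1 and
    25 at b = 2 ms/µm² (electrostatic-repulsion sets shipped as a fixture)."""
    ref = importlib.resources.files("hierfixel") / "data" / "ukb_like_directions.txt"
    rows = np.loadtxt(str(ref))
    bvals = np.concatenate([np.zeros(n_b0), rows[:, 0]])
    bvecs = np.vstack([np.zeros((n_b0, 3)), rows[:, 1:]])
    return AcquisitionScheme(bvals=bvals, bvecs=bvecs)


@dataclass(frozen=True)
class PopulationSpec:
    """Generating distribution of a single-voxel cohort (defaults: the
    two-fibre validation protocol described in the module docstring)."""

    n_subjects: int = 30
    fraction_means: tuple = (0.5, 0.3)
    fraction_sds: tuple = (0.1, 0.1)
    fraction_sum_target: float = 0.8
    orientation_axes: tuple = ((1.0, 0.0, 0.0), (0.0, 1.0, 0.0))
    odi: tuple = (0.1, 0.1)
    d_mean: float = 1.0
    d_sd: float = 0.05
    s0: float = 1.0
    scheme: AcquisitionScheme = field(default_factory=ukb_like_scheme)
    snr: float = 50.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.fraction_sum_target <= 1.0:
            raise ValueError("fraction_sum_target must be in (0, 1]")
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        k = len(self.fraction_means)
        if not (len(self.fraction_sds) == len(self.orientation_axes) == len(self.odi) == k):
            raise ValueError("per-fibre spec fields must have equal length")

    @property
    def n_fibres(self) -> int:
        return len(self.fraction_means)


@dataclass(frozen=True)
class GroundTruthTable:
    """Per-subject true parameters plus the generating spec."""

    subjects: tuple  # of BallSticksParams
    noise_sigma: float
    spec: PopulationSpec

    def fractions(self) -> np.ndarray:
        return np.array([p.fractions for p in self.subjects])

    def axes(self) -> np.ndarray:
        return np.array([p.orientations for p in self.subjects])

    def diffusivities(self) -> np.ndarray:
        return np.array([p.d for p in self.subjects])


def _sample_truncated_fractions(spec: PopulationSpec, rng: np.random.Generator) -> np.ndarray:
    """Draw per-fibre fractions from [0,1]-truncated Gaussians, then rescale
    each subject so the fractions sum exactly to ``fraction_sum_target``."""
    k = spec.n_fibres
    f = np.empty((spec.n_subjects, k))
    for i in range(k):
        m, s = spec.fraction_means[i], spec.fraction_sds[i]
        a, b = (0.0 - m) / s, (1.0 - m) / s
        f[:, i] = truncnorm.rvs(a, b, loc=m, scale=s, size=spec.n_subjects,
                                random_state=rng)
    f *= spec.fraction_sum_target / f.sum(axis=1, keepdims=True)
    return f


def simulate_population(spec: PopulationSpec):
    """Simulate one single-voxel cohort.

    Returns ``(signals, truth)``: ``signals`` is (n_subjects, n_volumes) with
    additive Gaussian noise of standard deviation ``S0 / snr`` on every
    volume; ``truth`` records each subject's generating parameters.
    """
    rng = np.random.default_rng(spec.seed)
    f = _sample_truncated_fractions(spec, rng)
    d = np.clip(rng.normal(spec.d_mean, spec.d_sd, size=spec.n_subjects), 1e-3, None)
    axes = np.empty((spec.n_subjects, spec.n_fibres, 3))
    for i in range(spec.n_fibres):
        w = WatsonParams(mean_axis=np.asarray(spec.orientation_axes[i], float)
                         / np.linalg.norm(spec.orientation_axes[i]),
                         kappa=odi_to_kappa(spec.odi[i]))
        axes[:, i, :] = watson_sample(w, spec.n_subjects, seed=rng)

    sigma = spec.s0 / spec.snr
    subjects = []
    signals = np.empty((spec.n_subjects, spec.scheme.n_volumes))
    for s in range(spec.n_subjects):
        params = BallSticksParams(s0=spec.s0, d=float(d[s]), fractions=f[s],
                                  orientations=axes[s])
        subjects.append(params)
        clean = predict_signal(params, spec.scheme)
        signals[s] = clean + rng.normal(scale=sigma, size=spec.scheme.n_volumes)
    truth = GroundTruthTable(subjects=tuple(subjects), noise_sigma=sigma, spec=spec)
    return signals, truth


# ---------------------------------------------------------------------------
# Multi-voxel phantoms
# ---------------------------------------------------------------------------

PHANTOM_LAYOUTS = ("single_tract", "orthogonal_crossing", "three_way")

_TRACT_AXES = (
    np.array([1.0, 0.0, 0.0]),
    np.array([0.0, 1.0, 0.0]),
    np.array([0.0, 0.0, 1.0]),
)


def _layout_maps(grid: tuple, layout: str):
    """True per-voxel fibre axes for a named slab layout.

    Returns ``(count, axes, tract_id)``: ``count`` (X,Y,Z) int, ``axes`` a
    list per voxel of (fibre axis, tract index) pairs encoded as arrays.
    Tract 0 runs along x in a slab of central y, tract 1 along y in a slab
    of central x, tract 2 along z in a slab of central y&x; slabs overlap in
    a central block where voxels carry multiple fibres.
    """
    if layout not in PHANTOM_LAYOUTS:
        raise ValueError(f"unknown layout {layout!r}; choose from {PHANTOM_LAYOUTS}")
    nx, ny, nz = grid
    n_tracts = {"single_tract": 1, "orthogonal_crossing": 2, "three_way": 3}[layout]

    def central(n):
        lo = n // 3
        hi = max(lo + 1, n - n // 3)
        return lo, hi

    xlo, xhi = central(nx)
    ylo, yhi = central(ny)
    zlo, zhi = central(nz)
    masks = []
    m0 = np.zeros(grid, dtype=bool)
    m0[:, ylo:yhi, zlo:zhi] = True  # tract 0: along x
    masks.append(m0)
    if n_tracts >= 2:
        m1 = np.zeros(grid, dtype=bool)
        m1[xlo:xhi, :, zlo:zhi] = True  # tract 1: along y
        masks.append(m1)
    if n_tracts >= 3:
        m2 = np.zeros(grid, dtype=bool)
        m2[xlo:xhi, ylo:yhi, :] = True  # tract 2: along z
        masks.append(m2)

    count = np.zeros(grid, dtype=int)
    membership = np.zeros(grid + (n_tracts,), dtype=bool)
    for t, m in enumerate(masks):
        count += m
        membership[..., t] = m
    return count, membership, n_tracts


@dataclass(frozen=True)
class PhantomCohort:
    """Multi-voxel synthetic cohort with ground truth and optional warps."""

    volumes: np.ndarray          # (S, X, Y, Z, V)
    affine: np.ndarray           # shared 4x4 voxel-to-world (mm)
    scheme: AcquisitionScheme
    mask: np.ndarray             # (X, Y, Z) bool: voxels with >= 1 fibre
    true_count: np.ndarray       # (X, Y, Z) int
    membership: np.ndarray       # (X, Y, Z, n_tracts) bool
    tract_axes: np.ndarray       # (n_tracts, 3)
    true_fractions: np.ndarray   # (S, X, Y, Z, n_tracts), 0 where absent
    covariate: np.ndarray | None
    effect_tract: int | None
    warps: tuple | None          # per subject (displacement (X,Y,Z,3) mm, affine 3x3)
    noise_sigma: float


def simulate_phantom_volume(
    grid: tuple = (10, 10, 10),
    tract_layout: str = "orthogonal_crossing",
    n_subjects: int = 8,
    base_fraction: float = 0.35,
    fraction_sd: float = 0.05,
    d_mean: float = 1.0,
    d_sd: float = 0.05,
    s0: float = 1.0,
    odi: float = 0.05,
    snr: float = 50.0,
    scheme: AcquisitionScheme | None = None,
    with_warps: bool = False,
    warp_scale: float = 0.02,
    covariate_slope: float = 0.0,
    effect_tract: int = 0,
    seed: int = 0,
) -> PhantomCohort:
    """Generate a small multi-voxel cohort from a named tract layout.

    Each tract contributes a stick of mean fraction ``base_fraction`` (with
    Gaussian between-subject scatter ``fraction_sd``) to every voxel it
    crosses; stick axes get per-subject Watson scatter at ``odi``.  If
    ``covariate_slope`` is nonzero, an age-like standard-normal covariate
    scales tract ``effect_tract``'s fraction by ``slope * covariate``.  If
    ``with_warps``, each subject receives a random small affine warp emitted
    as a reference-grid displacement field (mm) with its analytic (constant)
    Jacobian.
    """
    rng = np.random.default_rng(seed)
    scheme = scheme or ukb_like_scheme()
    count, membership, n_tracts = _layout_maps(tuple(grid), tract_layout)
    mask = count > 0
    affine = np.eye(4)
    affine[:3, 3] = -np.asarray(grid, float) / 2.0  # centred, 1 mm isotropic

    covariate = rng.standard_normal(n_subjects) if covariate_slope != 0.0 else None
    sigma = s0 / snr
    tract_axes = np.array(_TRACT_AXES[:n_tracts])

    volumes = np.zeros((n_subjects, *grid, scheme.n_volumes))
    true_fracs = np.zeros((n_subjects, *grid, n_tracts))
    warps = [] if with_warps else None

    # per-subject per-tract fraction level and axis (coherent along the tract)
    for s in range(n_subjects):
        frac_level = np.clip(
            base_fraction + rng.normal(scale=fraction_sd, size=n_tracts), 0.02, 0.9
        )
        if covariate is not None:
            frac_level[effect_tract] = np.clip(
                frac_level[effect_tract] + covariate_slope * covariate[s], 0.02, 0.9
            )
        axes = np.array([
            watson_sample(WatsonParams(mean_axis=ax, kappa=odi_to_kappa(odi)),
                          1, seed=rng)[0]
            for ax in tract_axes
        ])
        d_s = float(np.clip(rng.normal(d_mean, d_sd), 1e-3, None))
        for idx in np.argwhere(mask):
            i, j, l = idx
            present = np.nonzero(membership[i, j, l])[0]
            f = frac_level[present]
            if f.sum() > 0.95:
                f = f * 0.95 / f.sum()
            params = BallSticksParams(s0=s0, d=d_s, fractions=f,
                                      orientations=axes[present])
            volumes[s, i, j, l] = predict_signal(params, scheme)
            true_fracs[s, i, j, l, present] = f
        volumes[s] += rng.normal(scale=sigma, size=volumes[s].shape)
        if with_warps:
            a_mat = np.eye(3) + rng.normal(scale=warp_scale, size=(3, 3))
            disp = _affine_displacement(grid, affine, a_mat)
            warps.append((disp, a_mat))

    return PhantomCohort(
        volumes=volumes, affine=affine, scheme=scheme, mask=mask,
        true_count=count, membership=membership, tract_axes=tract_axes,
        true_fractions=true_fracs, covariate=covariate,
        effect_tract=effect_tract if covariate is not None else None,
        warps=tuple(warps) if warps is not None else None, noise_sigma=sigma,
    )


def _affine_displacement(grid, grid_affine, a_mat):
    """Displacement field (mm, on the reference grid) of x -> A x."""
    idx = np.stack(np.meshgrid(*[np.arange(n) for n in grid], indexing="ij"), axis=-1)
    world = idx @ grid_affine[:3, :3].T + grid_affine[:3, 3]
    return world @ (a_mat - np.eye(3)).T


# ---------------------------------------------------------------------------
# Fixel-level cohorts (for GLM / TFCE calibration at scale)
# ---------------------------------------------------------------------------

def simulate_fixel_cohort(
    grid: tuple = (6, 6, 1),
    tract_layout: str = "orthogonal_crossing",
    n_subjects: int = 30,
    base_fraction: float = 0.35,
    noise_sd: float = 0.04,
    covariate_slope: float = 0.0,
    effect_tract: int = 0,
    seed: int = 0,
):
    """Per-fixel signal-fraction data without the diffusion-fitting stage.

    Emulates the statistics-facing output of the pipeline: a fixel list
    (voxel index, stick slot, template axis) over a named tract layout and a
    subjects × fixels response matrix of signal fractions with Gaussian
    between-subject noise, optionally carrying a linear covariate effect on
    one tract.  Returns ``(fixels, response, covariate)`` where ``fixels``
    is a list of (voxel, stick, axis) tuples.
    """
    rng = np.random.default_rng(seed)
    count, membership, n_tracts = _layout_maps(tuple(grid), tract_layout)
    tract_axes = np.array(_TRACT_AXES[:n_tracts])

    fixels = []
    fixel_tract = []
    for idx in np.argwhere(count > 0):
        i, j, l = idx
        present = np.nonzero(membership[i, j, l])[0]
        for slot, t in enumerate(present):
            fixels.append(((int(i), int(j), int(l)), slot, tract_axes[t].copy()))
            fixel_tract.append(t)
    fixel_tract = np.array(fixel_tract)

    covariate = rng.standard_normal(n_subjects)
    response = base_fraction + rng.normal(
        scale=noise_sd, size=(n_subjects, len(fixels))
    )
    if covariate_slope != 0.0:
        on = fixel_tract == effect_tract
        response[:, on] += covariate_slope * covariate[:, None]
    return fixels, response, covariate
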