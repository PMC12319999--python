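"""Subject ↔ reference space mapping for fixel parameters.

The hierarchical fit never resamples diffusion data: each reference-space
voxel is paired with the nearest voxel in every subject's native grid via
the nonlinear warp, and stick orientations are moved between spaces with
the warp's local Jacobian,

    mu_ref = J mu_nat / |J mu_nat|,

using the *complete* Jacobian (not just its rotation component) so that
shears also contribute, followed by re-normalisation.

Conventions: voxel indices are 0-based; world space is RAS in mm; warps are
stored as displacement fields on the reference grid (mm, added to reference
world coordinates to obtain subject world coordinates).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "WarpField",
    "reorient_axis",
    "corresponding_voxel",
    "jacobian_from_displacement",
]


@dataclass
class WarpField:
    """Reference→subject displacement field with its voxel-to-world affine.

    ``displacement``: (X, Y, Z, 3) array in mm on the reference grid;
    ``grid_affine``: 4×4 reference voxel-to-world matrix.  The Jacobian of
    the total mapping (identity + displacement gradient, in world units) is
    derived lazily and cached.
    """

    displacement: np.ndarray
    grid_affine: np.ndarray
    _jacobian: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        disp = np.asarray(self.displacement, dtype=float)
        if disp.ndim != 4 or disp.shape[3] != 3:
            raise ValueError("displacement must be (X, Y, Z, 3)")
        if not np.all(np.isfinite(disp)):
            raise ValueError("displacement field contains non-finite values")
        aff = np.asarray(self.grid_affine, dtype=float)
        if aff.shape != (4, 4):
            raise ValueError("grid_affine must be 4x4")
        self.displacement = disp
        self.grid_affine = aff

    @property
    def jacobian(self) -> np.ndarray:
        if self._jacobian is None:
            self._jacobian = jacobian_from_displacement(self)
        return self._jacobian

    @property
    def shape(self) -> tuple:
        return self.displacement.shape[:3]


def reorient_axis(jac: np.ndarray, axis: np.ndarray) -> np.ndarray:
    """Reorient a unit axis with a local Jacobian: J·axis / |J·axis|.

    Pure rotations act exactly; isotropic scaling cancels; shears tilt the
    axis.  Raises on a (numerically) singular mapping of the axis.
    """
    jac = np.asarray(jac, dtype=float)
    axis = np.asarray(axis, dtype=float)
    if jac.shape != (3, 3):
        raise ValueError("Jacobian must be 3x3")
    if abs(np.linalg.norm(axis) - 1.0) > 1e-6:
        raise ValueError("axis must be unit norm")
    if np.linalg.det(jac) == 0.0:
        raise ValueError("Jacobian is singular")
    v = jac @ axis
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("axis is annihilated by a (near-)singular warp")
    return v / n


def corresponding_voxel(
    ref_index, warp: WarpField, subject_affine: np.ndarray, subject_shape=None
):
    """Nearest-neighbour subject voxel for a reference-grid voxel.

    Reference voxel centre → world (reference affine) → displaced world →
    subject voxel index by rounding through ``inv(subject_affine)``.
    Returns a 3-int tuple, or ``None`` (out of field) when ``subject_shape``
    is given and the index falls outside it.
    """
    ref_index = np.asarray(ref_index, dtype=int)
    shape = warp.shape
    if np.any(ref_index < 0) or np.any(ref_index >= shape):
        raise IndexError(f"reference index {tuple(ref_index)} outside grid {shape}")
    aff = warp.grid_affine
    world = aff[:3, :3] @ ref_index + aff[:3, 3]
    world = world + warp.displacement[tuple(ref_index)]
    inv = np.linalg.inv(np.asarray(subject_affine, dtype=float))
    sub = inv[:3, :3] @ world + inv[:3, 3]
    idx = tuple(int(i) for i in np.rint(sub))
    if subject_shape is not None:
        if any(i < 0 or i >= n for i, n in zip(idx, subject_shape)):
            return None
    return idx


def jacobian_from_displacement(warp: WarpField) -> np.ndarray:
    """Jacobian field of the total mapping x → x + u(x), world units.

    Central finite differences of the displacement along each voxel axis,
    chained with the inverse of the affine's linear part to express the
    gradient per mm of world displacement; exact (to round-off) for linear
    displacement fields at interior voxels, O(h²) otherwise.

    Returns an (X, Y, Z, 3, 3) array.
    """
    disp = warp.displacement
    lin_inv = np.linalg.inv(warp.grid_affine[:3, :3])
    # d u_c / d index_a, then chain through d index / d world
    du_didx = np.zeros(disp.shape[:3] + (3, 3))
    for c in range(3):
        for a in range(3):
            if disp.shape[a] < 2:
                continue  # flat axis: no gradient information
            du_didx[..., c, a] = np.gradient(disp[..., c], axis=a)
    du_dworld = du_didx @ lin_inv  # chain rule: d index / d world
    return np.eye(3) + du_dworld
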