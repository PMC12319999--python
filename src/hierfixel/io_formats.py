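"""Readers and writers for on-disk artefacts.

Formats:

* **Acquisition schemes** — FSL dialect: a one-row whitespace-separated
  ``bval`` file and a three-row ``bvec`` file.  Internal b-units are
  ms/µm²; files in s/mm² (recognised by magnitude) are rescaled by 1/1000.
* **Cohort manifest** — headered TSV with one row per subject:
  ``subject_id  dwi_path  bval_path  bvec_path  [warp_path]``.
* **Template bundle** — a directory of NIfTI volumes (fibre-count map,
  per-parameter mean/variance maps, per-fibre axis 3-vector maps and
  dispersion maps) plus a JSON sidecar recording hyperparameters,
  fibre-count thresholds and conventions (axial vectors, RAS world space,
  0-based voxel indices, b in ms/µm²).
* **Fixel directory** — an index NIfTI (two volumes: per-voxel fixel count
  and offset into the fixel arrays), a ``directions.tsv`` (M×3 axial unit
  vectors) and one M-row TSV per metric.

All writers embed the grid affine; readers validate grids against each
other and refuse silent reinterpretation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .distributions import ScalarPopulation, WatsonParams, canonical_axis, odi_to_kappa
from .forward_model import AcquisitionScheme
from .hier_em import PopulationModel

__all__ = [
    "read_scheme",
    "write_scheme",
    "CohortManifest",
    "TemplateBundle",
    "write_template",
    "read_template",
    "write_fixel_dir",
    "read_fixel_dir",
    "read_design_matrix",
    "write_provenance",
]

_B_UNIT_THRESHOLD = 100.0  # any b above this is taken to be s/mm^2


def read_scheme(bval_path, bvec_path) -> AcquisitionScheme:
    """Read an FSL-style bval/bvec pair into an :class:`AcquisitionScheme`.

    bvecs with nonzero b are re-normalised to unit length; b-values whose
    magnitude indicates s/mm² are rescaled to ms/µm² with a warning.
    """
    bvals = np.loadtxt(bval_path, dtype=float).ravel()
    bvecs = np.loadtxt(bvec_path, dtype=float)
    if bvecs.ndim != 2 or 3 not in bvecs.shape:
        raise ValueError(f"bvec file must be 3xN or Nx3, got {bvecs.shape}")
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    elif bvecs.shape == (3, 3):
        bvecs = bvecs.T  # FSL convention: three rows of N entries
    if len(bvals) != len(bvecs):
        raise ValueError(
            f"bval ({len(bvals)}) and bvec ({len(bvecs)}) volume counts differ"
        )
    if np.nanmax(bvals) > _B_UNIT_THRESHOLD:
        warnings.warn(
            "b-values look like s/mm^2; rescaling by 1/1000 to ms/um^2",
            UserWarning,
        )
        bvals = bvals / 1000.0
    dw = bvals > 0
    norms = np.linalg.norm(bvecs[dw], axis=1)
    if np.any(norms < 1e-12):
        raise ValueError("zero gradient vector with nonzero b-value")
    bvecs = bvecs.copy()
    bvecs[dw] /= norms[:, None]
    return AcquisitionScheme(bvals=bvals, bvecs=bvecs)


def write_scheme(scheme: AcquisitionScheme, bval_path, bvec_path) -> None:
    """Write an FSL-style bval (one row) / bvec (three rows) pair."""
    np.savetxt(bval_path, scheme.bvals[None, :], fmt="%.6g")
    np.savetxt(bvec_path, scheme.bvecs.T, fmt="%.10f")


# ---------------------------------------------------------------------------
# Cohort manifest
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortManifest:
    """Table of per-subject input paths (unique subject ids)."""

    table: pd.DataFrame

    REQUIRED = ("subject_id", "dwi_path", "bval_path", "bvec_path")

    def __post_init__(self):
        t = self.table
        missing = [c for c in self.REQUIRED if c not in t.columns]
        if missing:
            raise ValueError(f"manifest missing columns: {missing}")
        if t["subject_id"].duplicated().any():
            raise ValueError("subject_ids must be unique")
        object.__setattr__(self, "table", t.reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.table)

    @classmethod
    def read(cls, path, check_files: bool = True) -> "CohortManifest":
        path = Path(path)
        t = pd.read_csv(path, sep="\t", dtype=str)
        m = cls(table=t)
        if check_files:
            for _, row in t.iterrows():
                for col in ("dwi_path", "bval_path", "bvec_path", "warp_path"):
                    p = row.get(col)
                    if isinstance(p, str) and p and not Path(p).is_absolute():
                        p = path.parent / p
                    if isinstance(p, (str, Path)) and str(p) and not Path(p).exists():
                        raise FileNotFoundError(f"{col} for {row['subject_id']}: {p}")
        return m

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def resolve(self, col: str, base) -> list:
        out = []
        for p in self.table.get(col, pd.Series([None] * len(self))):
            if p is None or (isinstance(p, float) and np.isnan(p)):
                out.append(None)
            else:
                q = Path(p)
                out.append(q if q.is_absolute() else Path(base) / q)
        return out


# ---------------------------------------------------------------------------
# Template bundle
# ---------------------------------------------------------------------------

@dataclass
class TemplateBundle:
    """Voxel-wise fixel template: fibre counts plus population parameters.

    ``mean_maps``/``var_maps``: per-scalar (X, Y, Z) arrays keyed by
    parameter name (``"d"``, ``"f1"``..); ``axis_maps``: per-fibre
    (X, Y, Z, 3) axial unit-vector fields; ``odi_maps``: per-fibre
    (X, Y, Z) orientation dispersion.  Entries are NaN outside each voxel's
    fibre count.  ``sidecar`` carries hyperparameters, thresholds and
    conventions.
    """

    fibre_count: np.ndarray
    mean_maps: dict
    var_maps: dict
    axis_maps: list
    odi_maps: list
    affine: np.ndarray
    sidecar: dict = field(default_factory=dict)

    def __post_init__(self):
        shape = self.fibre_count.shape
        for name, m in {**self.mean_maps, **self.var_maps}.items():
            if m.shape != shape:
                raise ValueError(f"map {name!r} grid mismatch")
        for a in self.axis_maps:
            if a.shape != shape + (3,):
                raise ValueError("axis map grid mismatch")
        for o in self.odi_maps:
            if o.shape != shape:
                raise ValueError("dispersion map grid mismatch")
        if not np.isin(np.unique(self.fibre_count), [0, 1, 2, 3]).all():
            raise ValueError("fibre counts must be in {0, 1, 2, 3}")

    @property
    def shape(self) -> tuple:
        return self.fibre_count.shape

    @property
    def max_fibres(self) -> int:
        return len(self.axis_maps)

    def population_at(self, index) -> PopulationModel | None:
        """Reconstruct the voxel's :class:`PopulationModel` (None if empty)."""
        idx = tuple(int(i) for i in index)
        k = int(self.fibre_count[idx])
        if k == 0:
            return None
        scalar_pops = {}
        for name in self.mean_maps:
            if name.startswith("f") and int(name[1:]) > k:
                continue
            scalar_pops[name] = ScalarPopulation(
                mean=float(self.mean_maps[name][idx]),
                var=float(max(self.var_maps[name][idx], 0.0)),
            )
        orient_pops = tuple(
            WatsonParams(
                mean_axis=canonical_axis(self.axis_maps[i][idx]),
                kappa=odi_to_kappa(float(np.clip(self.odi_maps[i][idx], 1e-6, 1 - 1e-6))),
            )
            for i in range(k)
        )
        return PopulationModel(
            scalar_pops=scalar_pops, orient_pops=orient_pops, n_fibres=k
        )


def _save_nii(arr: np.ndarray, affine: np.ndarray, path: Path) -> None:
    img = nib.Nifti1Image(np.asarray(arr, dtype=np.float64), affine)
    nib.save(img, str(path))


def write_template(bundle: TemplateBundle, path) -> None:
    """Serialise a template bundle to a directory of NIfTI maps + sidecar."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    aff = bundle.affine
    _save_nii(bundle.fibre_count.astype(np.float64), aff, path / "fibre_count.nii.gz")
    for name, m in bundle.mean_maps.items():
        _save_nii(m, aff, path / f"mean_{name}.nii.gz")
    for name, m in bundle.var_maps.items():
        _save_nii(m, aff, path / f"var_{name}.nii.gz")
    for i, a in enumerate(bundle.axis_maps):
        _save_nii(a, aff, path / f"axis_fibre{i + 1}.nii.gz")
    for i, o in enumerate(bundle.odi_maps):
        _save_nii(o, aff, path / f"odi_fibre{i + 1}.nii.gz")
    sidecar = dict(bundle.sidecar)
    sidecar.setdefault("conventions", {})
    sidecar["conventions"].update(
        {
            "axes": "axial unit vectors, sign canonicalised (first nonzero "
                    "component positive)",
            "world_space": "RAS, mm",
            "voxel_indices": "0-based",
            "b_units": "ms/um^2",
        }
    )
    sidecar["scalar_names"] = sorted(bundle.mean_maps)
    sidecar["max_fibres"] = bundle.max_fibres
    (path / "template.json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))


def read_template(path) -> TemplateBundle:
    """Load a template bundle; axis maps are re-canonicalised on read."""
    path = Path(path)
    sidecar_path = path / "template.json"
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing template sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())

    def load(name):
        img = nib.load(str(path / name))
        return np.asarray(img.get_fdata()), img.affine

    count, affine = load("fibre_count.nii.gz")
    count = count.astype(int)
    mean_maps, var_maps = {}, {}
    for name in sidecar["scalar_names"]:
        m, a1 = load(f"mean_{name}.nii.gz")
        v, a2 = load(f"var_{name}.nii.gz")
        for a in (a1, a2):
            if not np.allclose(a, affine, atol=1e-6):
                raise ValueError(f"affine mismatch in map {name!r}")
        mean_maps[name], var_maps[name] = m, v
    axis_maps, odi_maps = [], []
    for i in range(int(sidecar["max_fibres"])):
        a, aa = load(f"axis_fibre{i + 1}.nii.gz")
        o, ao = load(f"odi_fibre{i + 1}.nii.gz")
        if not (np.allclose(aa, affine, atol=1e-6) and np.allclose(ao, affine, atol=1e-6)):
            raise ValueError(f"affine mismatch in fibre {i + 1} maps")
        flat = a.reshape(-1, 3)
        with np.errstate(invalid="ignore"):
            for j in range(len(flat)):
                if np.all(np.isfinite(flat[j])):
                    flat[j] = canonical_axis(flat[j])
        axis_maps.append(flat.reshape(a.shape))
        odi_maps.append(o)
    return TemplateBundle(
        fibre_count=count, mean_maps=mean_maps, var_maps=var_maps,
        axis_maps=axis_maps, odi_maps=odi_maps, affine=affine, sidecar=sidecar,
    )


# ---------------------------------------------------------------------------
# Fixel directory format
# ---------------------------------------------------------------------------

def write_fixel_dir(
    fixels, metrics: dict, shape, affine, path, extra_sidecar: dict | None = None
) -> None:
    """Write fixels + per-fixel metric vectors to a fixel directory.

    ``fixels``: sequence of :class:`~hierfixel.fixel_stats.FixelIndex` (or
    (voxel, stick, axis) tuples) — must be grouped by voxel; ``metrics``:
    name → length-M arrays.  Layout: ``index.nii.gz`` (4D, volume 0 =
    per-voxel fixel count, volume 1 = offset of the voxel's first fixel, -1
    where empty), ``directions.tsv`` (M×3), ``<metric>.tsv``.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    voxels, axes = [], []
    for f in fixels:
        if hasattr(f, "voxel"):
            voxels.append(tuple(f.voxel)); axes.append(np.asarray(f.axis, float))
        else:
            voxels.append(tuple(f[0])); axes.append(np.asarray(f[2], float))
    m = len(voxels)
    for name, vec in metrics.items():
        if len(vec) != m:
            raise ValueError(f"metric {name!r} length {len(vec)} != fixel count {m}")

    count = np.zeros(shape, dtype=np.int32)
    offset = np.full(shape, -1, dtype=np.int64)
    prev = None
    for i, v in enumerate(voxels):
        if v != prev:
            if count[v] != 0:
                raise ValueError("fixels must be grouped by voxel")
            offset[v] = i
            prev = v
        count[v] += 1
    index = np.stack([count.astype(np.float64), offset.astype(np.float64)], axis=-1)
    _save_nii(index, affine, path / "index.nii.gz")
    np.savetxt(path / "directions.tsv", np.array(axes), fmt="%.10f", delimiter="\t")
    for name, vec in metrics.items():
        np.savetxt(path / f"{name}.tsv", np.asarray(vec, float), fmt="%.17g")
    sidecar = {"n_fixels": m, "metrics": sorted(metrics)}
    sidecar.update(extra_sidecar or {})
    (path / "fixel.json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))


def read_fixel_dir(path):
    """Load a fixel directory; returns ``(fixels, metrics, affine)``.

    ``fixels`` is a list of (voxel, stick, axis) tuples in on-disk order;
    validates that offsets/counts tile the fixel arrays exactly.
    """
    path = Path(path)
    img = nib.load(str(path / "index.nii.gz"))
    index = np.asarray(img.get_fdata())
    count = index[..., 0].astype(int)
    offset = index[..., 1].astype(int)
    sidecar = json.loads((path / "fixel.json").read_text())
    m = int(sidecar["n_fixels"])
    if m > 0:
        dirs = np.atleast_2d(np.loadtxt(path / "directions.tsv", delimiter="\t"))
    else:
        dirs = np.empty((0, 3))
    if len(dirs) != m or int(count.sum()) != m:
        raise ValueError("fixel count mismatch between index, sidecar and directions")
    fixels = []
    seen = np.zeros(m, dtype=bool)
    for v in np.argwhere(count > 0):
        v = tuple(int(i) for i in v)
        off, c = offset[v], count[v]
        if off < 0 or off + c > m:
            raise ValueError(f"dangling fixel offset at voxel {v}")
        for s in range(c):
            fixels.append((v, s, dirs[off + s]))
            seen[off + s] = True
    if m and not seen.all():
        raise ValueError("index does not tile the fixel arrays")
    metrics = {
        name: np.atleast_1d(np.loadtxt(path / f"{name}.tsv"))
        for name in sidecar["metrics"]
    }
    for name, vec in metrics.items():
        if len(vec) != m:
            raise ValueError(f"metric {name!r} length mismatch")
    return fixels, metrics, img.affine


# ---------------------------------------------------------------------------
# Misc
# ---------------------------------------------------------------------------

def read_design_matrix(path, contrast_column: str):
    """Read a headered TSV design matrix.

    Returns ``(design, contrast, names)`` with an intercept column appended
    if none is present; the contrast selects ``contrast_column``.
    """
    t = pd.read_csv(path, sep="\t")
    names = list(t.columns)
    if contrast_column not in names:
        raise ValueError(f"contrast column {contrast_column!r} not in design")
    x = t.to_numpy(dtype=float)
    if not np.any(np.all(x == x[0:1, :], axis=0)):
        x = np.column_stack([x, np.ones(len(x))])
        names.append("intercept")
    contrast = np.array([1.0 if n == contrast_column else 0.0 for n in names])
    return x, contrast, tuple(names)


def write_provenance(path, config: dict, seed, versions: dict | None = None) -> None:
    """Write a provenance JSON (config, seed, package versions)."""
    import hierfixel

    prov = {
        "config": config,
        "seed": int(seed) if seed is not None else None,
        "versions": versions
        or {
            "hierfixel": getattr(hierfixel, "__version__", "unknown"),
            "numpy": np.__version__,
            "nibabel": nib.__version__,
        },
    }
    Path(path).write_text(json.dumps(prov, indent=2, sort_keys=True, default=str))
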