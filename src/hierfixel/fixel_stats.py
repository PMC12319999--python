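"""Fixel-wise GLM, fixel neighbourhood graph, TFCE and permutation inference.

A *fixel* is one fibre population inside a voxel, carrying its own template
axis.  Group statistics on fixel metrics (typically signal fractions) run
through an ordinary per-fixel general linear model; multiple-comparison
control uses threshold-free cluster enhancement (TFCE) generalised to the
fixel graph:

* two fixels are neighbours iff their voxels share at least one corner
  (27-neighbourhood, the central voxel included — two crossing fixels in
  the *same* voxel are only linked if they pass the angle test) and the
  axial angle between their template axes is below a threshold;
* the TFCE score of a fixel with statistic ``t`` is
  ``integral_0^t e(h)^E h^H dh`` where ``e(h)`` is the size of the
  connected component containing the fixel in the supra-threshold subgraph
  ``{t > h}``.

Familywise error over all fixels is controlled by permutation of the
maximum TFCE statistic.  Continuous regressors with confounds are permuted
with the Freedman–Lane residual scheme; two-sided inference enhances the
positive and negative tails separately and Bonferroni-combines them.

``EH_PRESETS`` records the two enhancement-exponent settings in circulation
for fixel data: the default ``(E, H) = (1, 3)`` and the voxel-legacy
``(3, 2)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FixelIndex",
    "FixelGraph",
    "GLMDesign",
    "TFCEResult",
    "EH_PRESETS",
    "fit_glm",
    "build_fixel_graph",
    "tfce_scores",
    "permutation_pvalues",
]

EH_PRESETS = {
    "fixel-default": (1.0, 3.0),   # height-weighted, used for fixel maps
    "voxel-legacy": (3.0, 2.0),    # extent-weighted alternative
}

DEFAULT_ANGLE_THRESHOLD = 45.0  # degrees
DEFAULT_T_CAP = 100.0
DEFAULT_N_STEPS = 100


@dataclass(frozen=True)
class FixelIndex:
    """One fibre population: voxel grid index, stick slot, template axis."""

    voxel: tuple
    stick: int
    axis: np.ndarray

    def __post_init__(self):
        axis = np.asarray(self.axis, dtype=float).ravel()
        if axis.shape != (3,) or abs(np.linalg.norm(axis) - 1.0) > 1e-6:
            raise ValueError("axis must be a unit 3-vector")
        if not 0 <= self.stick <= 2:
            raise ValueError("stick slot must be in {0, 1, 2}")
        object.__setattr__(self, "voxel", tuple(int(v) for v in self.voxel))
        object.__setattr__(self, "axis", axis)


@dataclass(frozen=True)
class FixelGraph:
    """Fixel adjacency: nodes plus a symmetric edge list (i < j pairs)."""

    nodes: tuple
    edges: np.ndarray  # (E, 2) int, i < j
    angle_threshold: float

    @property
    def n_fixels(self) -> int:
        return len(self.nodes)

    def adjacency_lists(self) -> list:
        adj = [[] for _ in range(self.n_fixels)]
        for i, j in self.edges:
            adj[i].append(j)
            adj[j].append(i)
        return adj

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.n_fixels))
        g.add_edges_from(map(tuple, self.edges))
        return g


@dataclass(frozen=True)
class GLMDesign:
    """Per-fixel regression problem.

    ``response``: (subjects, fixels); ``design``: (subjects, regressors)
    including any intercept/confound columns; ``contrast``: weights over
    regressors.  The design must be full column rank.
    """

    response: np.ndarray
    design: np.ndarray
    contrast: np.ndarray
    column_names: tuple | None = None

    def __post_init__(self):
        y = np.atleast_2d(np.asarray(self.response, dtype=float))
        x = np.atleast_2d(np.asarray(self.design, dtype=float))
        c = np.asarray(self.contrast, dtype=float).ravel()
        if y.shape[0] != x.shape[0]:
            raise ValueError("response and design row counts differ")
        if len(c) != x.shape[1]:
            raise ValueError("contrast length must equal the number of regressors")
        names = self.column_names or tuple(f"x{i}" for i in range(x.shape[1]))
        if len(names) != x.shape[1]:
            raise ValueError("column_names length mismatch")
        if np.linalg.matrix_rank(x) < x.shape[1]:
            bad = _dependent_columns(x, names)
            raise ValueError(f"design is rank deficient; dependent columns: {bad}")
        object.__setattr__(self, "response", y)
        object.__setattr__(self, "design", x)
        object.__setattr__(self, "contrast", c)
        object.__setattr__(self, "column_names", tuple(names))

    @property
    def n_subjects(self) -> int:
        return self.design.shape[0]


def _dependent_columns(x: np.ndarray, names) -> list:
    """Greedy identification of columns that are linear combinations of the
    preceding ones (for error messages)."""
    bad = []
    kept = np.empty((x.shape[0], 0))
    for i in range(x.shape[1]):
        cand = np.column_stack([kept, x[:, i]])
        if np.linalg.matrix_rank(cand) == kept.shape[1]:
            bad.append(names[i])
        else:
            kept = cand
    return bad


@dataclass(frozen=True)
class TFCEResult:
    """Per-fixel t, TFCE score and familywise-corrected p-value."""

    t: np.ndarray
    tfce: np.ndarray
    p: np.ndarray
    E: float
    H: float
    dh: float


# ---------------------------------------------------------------------------
# GLM
# ---------------------------------------------------------------------------

def fit_glm(d: GLMDesign, t_cap: float = DEFAULT_T_CAP) -> np.ndarray:
    """Per-fixel OLS t-statistics for the contrast.

    ``t = c' beta / sqrt(c' (X'X)^-1 c * RSS / (n - p))`` computed for every
    fixel column of the response at once.  Perfect fits (zero residual)
    yield infinite t and are capped at ``t_cap`` with their sign kept.
    """
    x, y, c = d.design, d.response, d.contrast
    n, p = x.shape
    if n <= p + 1:
        raise ValueError("need n_subjects > n_regressors + 1")
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ y          # (p, F)
    resid = y - x @ beta
    dof = n - p
    sigma2 = np.einsum("ij,ij->j", resid, resid) / dof
    denom_c = float(c @ xtx_inv @ c)
    effect = c @ beta                 # (F,)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / np.sqrt(denom_c * sigma2)
    t = np.where(np.isfinite(t), t, np.sign(effect) * t_cap)
    return np.clip(t, -t_cap, t_cap)


# ---------------------------------------------------------------------------
# Fixel graph
# ---------------------------------------------------------------------------

def build_fixel_graph(
    fixels, angle_threshold: float = DEFAULT_ANGLE_THRESHOLD
) -> FixelGraph:
    """Connect fixels in 27-neighbouring voxels with axial angle ≤ threshold.

    ``fixels`` is a sequence of :class:`FixelIndex` (or (voxel, stick, axis)
    tuples).  The axial angle is ``arccos(|a·b|)``, so ``mu`` and ``-mu``
    are identical.  Same-voxel fixel pairs are admitted through the same
    angle rule — with crossing fibres roughly orthogonal the angle test is
    what keeps their statistics from mixing.
    """
    nodes = tuple(
        f if isinstance(f, FixelIndex) else FixelIndex(voxel=f[0], stick=f[1], axis=f[2])
        for f in fixels
    )
    cos_thr = math.cos(math.radians(angle_threshold))
    by_voxel: dict = {}
    for i, f in enumerate(nodes):
        by_voxel.setdefault(f.voxel, []).append(i)

    offsets = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
    ]
    edges = []
    for i, f in enumerate(nodes):
        vx, vy, vz = f.voxel
        for dx, dy, dz in offsets:
            for j in by_voxel.get((vx + dx, vy + dy, vz + dz), ()):
                if j <= i:
                    continue
                if abs(float(f.axis @ nodes[j].axis)) >= cos_thr - 1e-12:
                    edges.append((i, j))
    edges_arr = (
        np.array(sorted(set(edges)), dtype=int) if edges else np.empty((0, 2), int)
    )
    return FixelGraph(nodes=nodes, edges=edges_arr, angle_threshold=angle_threshold)


# ---------------------------------------------------------------------------
# TFCE
# ---------------------------------------------------------------------------

class _UnionFind:
    __slots__ = ("parent", "size")

    def __init__(self, n: int):
        self.parent = list(range(n))
        self.size = [1] * n

    def find(self, i: int) -> int:
        parent = self.parent
        root = i
        while parent[root] != root:
            root = parent[root]
        while parent[i] != root:
            parent[i], i = root, parent[i]
        return root

    def union(self, i: int, j: int):
        ri, rj = self.find(i), self.find(j)
        if ri == rj:
            return
        if self.size[ri] < self.size[rj]:
            ri, rj = rj, ri
        self.parent[rj] = ri
        self.size[ri] += self.size[rj]


def _tfce_positive(
    t: np.ndarray, adj: list, E: float, H: float, dh: float, h_max: float
) -> np.ndarray:
    """One-tailed TFCE via descending thresholds and incremental merging.

    Thresholds are midpoints ``(j + 1/2) dh`` (midpoint rule: O(dh²) error
    against the exact integral); sweeping them from high to low lets the
    supra-threshold components grow monotonically, so each step only adds
    nodes/edges to a union-find structure instead of recomputing components.
    """
    n = len(t)
    scores = np.zeros(n)
    if n == 0 or h_max <= 0:
        return scores
    n_steps = int(np.ceil(h_max / dh - 0.5))
    if n_steps <= 0:
        return scores
    hs = (np.arange(n_steps) + 0.5) * dh  # ascending midpoints
    order = np.argsort(-t)  # activate from the largest statistic down
    uf = _UnionFind(n)
    active = np.zeros(n, dtype=bool)
    ptr = 0
    for h in hs[::-1]:
        while ptr < n and t[order[ptr]] > h:
            i = order[ptr]
            active[i] = True
            for j in adj[i]:
                if active[j]:
                    uf.union(i, j)
            ptr += 1
        if ptr == 0:
            continue
        idx = order[:ptr]
        sizes = np.array([uf.size[uf.find(i)] for i in idx], dtype=float)
        scores[idx] += sizes**E * h**H * dh
    return scores


def tfce_scores(
    t: np.ndarray,
    g: FixelGraph,
    E: float = EH_PRESETS["fixel-default"][0],
    H: float = EH_PRESETS["fixel-default"][1],
    dh: float | None = None,
    adj: list | None = None,
) -> np.ndarray:
    """Signed TFCE scores over the fixel graph.

    Positive statistics are enhanced on the ``{t > h}`` subgraphs; negative
    ones by enhancing ``-t`` the same way and negating.  ``dh`` defaults to
    ``max|t| / 100``.
    """
    t = np.asarray(t, dtype=float)
    if len(t) != g.n_fixels:
        raise ValueError("one statistic per fixel required")
    if adj is None:
        adj = g.adjacency_lists()
    t_abs_max = float(np.max(np.abs(t))) if len(t) else 0.0
    if dh is None:
        dh = t_abs_max / DEFAULT_N_STEPS if t_abs_max > 0 else 1.0
    if dh <= 0:
        raise ValueError("dh must be positive")
    pos = _tfce_positive(np.clip(t, 0, None), adj, E, H, dh, float(np.max(t, initial=0.0)))
    neg = _tfce_positive(np.clip(-t, 0, None), adj, E, H, dh, float(np.max(-t, initial=0.0)))
    return pos - neg


# ---------------------------------------------------------------------------
# Permutation inference
# ---------------------------------------------------------------------------

def permutation_pvalues(
    d: GLMDesign,
    g: FixelGraph,
    n_perm: int = 1000,
    E: float = EH_PRESETS["fixel-default"][0],
    H: float = EH_PRESETS["fixel-default"][1],
    dh: float | None = None,
    seed: int | None = None,
    t_cap: float = DEFAULT_T_CAP,
) -> TFCEResult:
    """Familywise-corrected fixel p-values from max-TFCE permutation.

    The null distribution is the permutation distribution of the maximum
    TFCE score over all fixels (per tail), which controls the familywise
    error across space; ``p = (1 + #{perm max >= observed}) / (n_perm + 1)``
    per tail, Bonferroni-doubled for two-sided inference.

    Permutation scheme: the contrast must select a single design column
    (e.g. age); the remaining columns are confounds ``Z``.  Freedman–Lane:
    the response is reduced to residuals of the confound-only fit, the
    residual rows are permuted, the confound fit is added back, and the full
    model is re-fitted — this keeps the confound structure intact under an
    otherwise exchangeable null.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    nz = np.nonzero(d.contrast)[0]
    if len(nz) != 1:
        raise ValueError(
            "permutation inference requires a contrast selecting exactly one "
            "design column"
        )
    n = d.n_subjects
    if n < 6:
        raise ValueError("too few exchangeable units for permutation testing")
    rng = np.random.default_rng(seed)

    t_obs = fit_glm(d, t_cap=t_cap)
    adj = g.adjacency_lists()
    t_abs_max = float(np.max(np.abs(t_obs))) if len(t_obs) else 0.0
    if dh is None:
        dh = t_abs_max / DEFAULT_N_STEPS if t_abs_max > 0 else 1.0
    obs_pos = _tfce_positive(np.clip(t_obs, 0, None), adj, E, H, dh,
                             float(np.max(t_obs, initial=0.0)))
    obs_neg = _tfce_positive(np.clip(-t_obs, 0, None), adj, E, H, dh,
                             float(np.max(-t_obs, initial=0.0)))

    # Freedman-Lane: confound-only fit of the response
    z = d.design[:, [i for i in range(d.design.shape[1]) if i not in nz]]
    if z.shape[1]:
        gamma = np.linalg.lstsq(z, d.response, rcond=None)[0]
        fitted = z @ gamma
    else:
        fitted = np.zeros_like(d.response)
    resid = d.response - fitted

    null_max_pos = np.empty(n_perm)
    null_max_neg = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(n)
        y_star = fitted + resid[perm]
        d_star = GLMDesign(
            response=y_star, design=d.design, contrast=d.contrast,
            column_names=d.column_names,
        )
        t_star = fit_glm(d_star, t_cap=t_cap)
        sp = _tfce_positive(np.clip(t_star, 0, None), adj, E, H, dh,
                            float(np.max(t_star, initial=0.0)))
        sn = _tfce_positive(np.clip(-t_star, 0, None), adj, E, H, dh,
                            float(np.max(-t_star, initial=0.0)))
        null_max_pos[b] = sp.max(initial=0.0)
        null_max_neg[b] = sn.max(initial=0.0)

    p_pos = (1 + np.sum(null_max_pos[None, :] >= obs_pos[:, None], axis=1)) / (
        n_perm + 1
    )
    p_neg = (1 + np.sum(null_max_neg[None, :] >= obs_neg[:, None], axis=1)) / (
        n_perm + 1
    )
    p = np.minimum(1.0, 2.0 * np.minimum(p_pos, p_neg))
    return TFCEResult(t=t_obs, tfce=obs_pos - obs_neg, p=p, E=E, H=H, dh=dh)
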