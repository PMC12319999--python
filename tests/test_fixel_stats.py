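"""Per-fixel GLM, fixel graph, TFCE and permutation inference."""

import numpy as np
import pytest
from scipy import ndimage, stats

from hierfixel import (
    FixelIndex,
    GLMDesign,
    build_fixel_graph,
    fit_glm,
    permutation_pvalues,
    tfce_scores,
)

EX = np.array([1.0, 0.0, 0.0])
EY = np.array([0.0, 1.0, 0.0])


def _chain(n, axis=EX):
    return [((i, 0, 0), 0, axis) for i in range(n)]


class TestFitGLM:
    def test_orthogonal_response_gives_zero_t(self):
        # response explicitly orthogonalised against the contrast column
        rng = np.random.default_rng(0)
        X = np.column_stack([rng.normal(size=12), np.ones(12)])
        noise = rng.normal(size=12)
        y = noise - X @ np.linalg.lstsq(X, noise, rcond=None)[0]
        d = GLMDesign(response=y.reshape(-1, 1), design=X, contrast=[1, 0])
        assert fit_glm(d)[0] == pytest.approx(0.0, abs=1e-8)

    def test_longhand_normal_equations_oracle(self):
        # y=(1..5), x=(1..5), intercept confound: perfect fit, capped t
        d = GLMDesign(response=np.arange(1.0, 6.0).reshape(5, 1),
                      design=np.column_stack([np.arange(1.0, 6.0), np.ones(5)]),
                      contrast=[1, 0])
        assert fit_glm(d, t_cap=100.0)[0] == 100.0

        # noisy version against an explicit normal-equations computation
        rng = np.random.default_rng(1)
        x = np.arange(1.0, 9.0)
        y = 2.0 * x + rng.normal(size=8)
        X = np.column_stack([x, np.ones(8)])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        s2 = resid @ resid / (8 - 2)
        t_hand = beta[0] / np.sqrt(s2 * np.linalg.inv(X.T @ X)[0, 0])
        d2 = GLMDesign(response=y.reshape(-1, 1), design=X, contrast=[1, 0])
        assert fit_glm(d2)[0] == pytest.approx(t_hand, abs=1e-10)

    def test_gaussian_null_type_i_error(self):
        # across 10,000 independent fixels the |t| > t_{0.025, dof} rate
        # must match its nominal 5% level
        rng = np.random.default_rng(42)
        n, n_fixels = 20, 10_000
        x = rng.normal(size=n)
        y = rng.normal(size=(n, n_fixels))
        d = GLMDesign(response=y, design=np.column_stack([x, np.ones(n)]),
                      contrast=[1, 0])
        t = fit_glm(d)
        crit = stats.t.ppf(0.975, df=n - 2)
        rate = np.mean(np.abs(t) > crit)
        assert rate == pytest.approx(0.05, abs=0.006)

    def test_rank_deficient_design_names_columns(self):
        x = np.column_stack([np.ones(8), np.arange(8.0), 2 * np.arange(8.0)])
        with pytest.raises(ValueError, match="dup"):
            GLMDesign(response=np.zeros((8, 1)), design=x, contrast=[0, 1, 0],
                      column_names=("icpt", "age", "dup"))


class TestBuildFixelGraph:
    def test_parallel_neighbours_connected(self):
        g = build_fixel_graph(_chain(2), angle_threshold=45.0)
        assert g.edges.tolist() == [[0, 1]]

    def test_perpendicular_neighbours_not_connected(self):
        fixels = [((0, 0, 0), 0, EX), ((1, 0, 0), 0, EY)]
        g = build_fixel_graph(fixels, angle_threshold=45.0)
        assert len(g.edges) == 0

    def test_same_voxel_fixels_follow_angle_rule(self):
        near = np.array([0.94, 0.342, 0.0])  # ~20 degrees from EX
        near /= np.linalg.norm(near)
        crossing = [((0, 0, 0), 0, EX), ((0, 0, 0), 1, EY)]
        aligned = [((0, 0, 0), 0, EX), ((0, 0, 0), 1, near)]
        assert len(build_fixel_graph(crossing, 45.0).edges) == 0
        assert len(build_fixel_graph(aligned, 45.0).edges) == 1

    def test_two_orthogonal_sheets_two_components(self):
        # 3x3x3 phantom: x-aligned sheet at z=0, y-aligned sheet at z=2;
        # brute-force pairwise check via networkx components
        fixels = []
        for i in range(3):
            for j in range(3):
                fixels.append(((i, j, 0), 0, EX))
                fixels.append(((i, j, 2), 0, EY))
        g = build_fixel_graph(fixels, angle_threshold=45.0)
        import networkx as nx

        comps = list(nx.connected_components(g.to_networkx()))
        assert len(comps) == 2
        # brute force: an edge exists iff Chebyshev distance <= 1 and angle ok
        expected = 0
        for a in range(len(fixels)):
            for b in range(a + 1, len(fixels)):
                va, vb = np.array(fixels[a][0]), np.array(fixels[b][0])
                if np.max(np.abs(va - vb)) > 1:
                    continue
                if abs(float(fixels[a][2] @ fixels[b][2])) >= np.cos(np.radians(45)):
                    expected += 1
        assert len(g.edges) == expected

    def test_symmetry_and_no_self_edges(self):
        g = build_fixel_graph(_chain(5), angle_threshold=45.0)
        assert np.all(g.edges[:, 0] < g.edges[:, 1])


class TestTFCEScores:
    def test_singleton_closed_form(self):
        # isolated fixel, t=1, H=2: integral h^2 dh from 0 to 1 = 1/3
        g = build_fixel_graph(_chain(1))
        for E in (0.5, 1.0, 3.0):
            s = tfce_scores(np.array([1.0]), g, E=E, H=2.0, dh=1e-3)
            assert abs(s[0] - 1.0 / 3.0) / (1.0 / 3.0) < 0.01

    def test_two_chain_closed_form(self):
        # two connected fixels, both t=1, E=1, H=2: e(h)=2 throughout -> 2/3
        g = build_fixel_graph(_chain(2))
        s = tfce_scores(np.ones(2), g, E=1.0, H=2.0, dh=1e-3)
        np.testing.assert_allclose(s, 2.0 / 3.0, rtol=0.01)

    def test_general_exponent_closed_form(self):
        # 2-chain, both t: score -> 2^E t^{H+1}/(H+1)
        g = build_fixel_graph(_chain(2))
        t0, E, H = 1.7, 2.0, 3.0
        s = tfce_scores(np.full(2, t0), g, E=E, H=H, dh=t0 / 1000)
        want = 2.0**E * t0 ** (H + 1) / (H + 1)
        np.testing.assert_allclose(s, want, rtol=0.01)

    def test_non_positive_stats_give_zero_positive_scores(self):
        g = build_fixel_graph(_chain(4))
        t = np.array([-0.5, 0.0, -2.0, -0.1])
        s = tfce_scores(t, g, E=1.0, H=2.0)
        assert np.all(s <= 0)
        assert s[1] == 0.0

    def test_negative_tail_mirrors_positive(self):
        g = build_fixel_graph(_chain(3))
        t = np.array([1.0, 2.0, 0.5])
        sp = tfce_scores(t, g, E=1.0, H=2.0, dh=1e-3)
        sn = tfce_scores(-t, g, E=1.0, H=2.0, dh=1e-3)
        np.testing.assert_allclose(sn, -sp, atol=1e-12)

    def test_monotone_in_single_statistic(self):
        # raising one fixel's t never decreases any score
        rng = np.random.default_rng(3)
        fixels = _chain(8)
        g = build_fixel_graph(fixels)
        t = rng.uniform(0.2, 2.0, size=8)
        base = tfce_scores(t, g, E=1.0, H=2.0, dh=0.005)
        for i in range(8):
            t2 = t.copy()
            t2[i] += 0.5
            bumped = tfce_scores(t2, g, E=1.0, H=2.0, dh=0.005)
            assert np.all(bumped >= base - 1e-9)

    def test_degenerates_to_voxel_tfce(self):
        # angle threshold 180 deg, one fixel per voxel == classic voxel TFCE
        # (oracle: independent scipy.ndimage implementation on the lattice)
        rng = np.random.default_rng(9)
        shape = (4, 4, 2)
        tmap = rng.uniform(0.0, 3.0, size=shape)
        axes = rng.normal(size=shape + (3,))
        axes /= np.linalg.norm(axes, axis=-1, keepdims=True)
        fixels = [
            (tuple(v), 0, axes[tuple(v)]) for v in np.ndindex(*shape)
        ]
        g = build_fixel_graph(fixels, angle_threshold=180.0)
        t_flat = np.array([tmap[f[0]] for f in fixels])
        E, H = 0.5, 2.0
        dh = t_flat.max() / 200
        got = tfce_scores(t_flat, g, E=E, H=H, dh=dh)

        # independent voxel TFCE: per-threshold 26-connected labelling
        want_map = np.zeros(shape)
        hs = (np.arange(200) + 0.5) * dh
        structure = np.ones((3, 3, 3))
        for h in hs:
            supra = tmap > h
            labels, n_lab = ndimage.label(supra, structure=structure)
            if n_lab == 0:
                continue
            sizes = ndimage.sum(supra, labels, index=np.arange(1, n_lab + 1))
            ext = np.zeros(shape)
            for lab, size in enumerate(sizes, start=1):
                ext[labels == lab] = size
            want_map += np.where(supra, ext**E * h**H * dh, 0.0)
        want = np.array([want_map[f[0]] for f in fixels])
        np.testing.assert_allclose(got, want, rtol=1e-10, atol=1e-12)


class TestPermutationPvalues:
    def _design(self, n=24, n_fixels=6, effect=0.0, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        conf = rng.normal(size=n)
        y = effect * x[:, None] + 0.3 * conf[:, None] + rng.normal(size=(n, n_fixels))
        design = np.column_stack([x, conf, np.ones(n)])
        return GLMDesign(response=y, design=design, contrast=[1, 0, 0])

    def test_minimum_possible_pvalue(self):
        # an effect so strong no permutation can beat it
        g = build_fixel_graph(_chain(6))
        d = self._design(effect=5.0, seed=1)
        res = permutation_pvalues(d, g, n_perm=100, seed=0)
        assert res.p.min() == pytest.approx(2.0 / 101.0, abs=1e-12)

    def test_reproducible_given_seed(self):
        g = build_fixel_graph(_chain(6))
        d = self._design(effect=0.5, seed=2)
        a = permutation_pvalues(d, g, n_perm=120, seed=7)
        b = permutation_pvalues(d, g, n_perm=120, seed=7)
        np.testing.assert_array_equal(a.p, b.p)

    def test_rejects_multi_column_contrast(self):
        g = build_fixel_graph(_chain(6))
        d = GLMDesign(response=np.random.default_rng(0).normal(size=(20, 6)),
                      design=np.column_stack([np.arange(20.0), np.ones(20)]),
                      contrast=[1, 1])
        with pytest.raises(ValueError, match="one design column"):
            permutation_pvalues(d, g, n_perm=100)

    def test_rejects_too_few_permutations(self):
        g = build_fixel_graph(_chain(6))
        with pytest.raises(ValueError):
            permutation_pvalues(self._design(), g, n_perm=50)
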