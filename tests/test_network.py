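"""Network construction, TOM, module detection and eigengenes."""

import numpy as np
import pytest

from cwgcna.datamodel import OmicsMatrix
from cwgcna.network import (
    build_adjacency,
    build_modules,
    compute_eigengenes,
    compute_tom,
    detect_modules,
    pick_soft_power,
    scale_free_fit,
    Network,
)
from cwgcna.simulate import simulate_modular_expression


def tom_brute_force(a: np.ndarray) -> np.ndarray:
    """Independent double-loop TOM oracle."""
    n = a.shape[0]
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=0)
    out = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l_ij = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            out[i, j] = (l_ij + a[i, j]) / (min(k[i], k[j]) + 1.0 - a[i, j])
    return out


class TestAdjacency:
    def test_beta_one_is_raw_abs_correlation(self, random_matrix):
        m = random_matrix(25, 15, seed=2)
        dup = OmicsMatrix(
            np.vstack([m.values, m.values[0]]), m.feature_ids + ["g0_dup"],
            m.sample_ids, "RNA",
        )
        net = build_adjacency(dup, beta=1)
        # duplicated feature pair has |cor| = 1
        assert net.adjacency[0, -1] == pytest.approx(1.0, abs=1e-12)
        expected = np.abs(np.corrcoef((dup.values - dup.values.mean(1, keepdims=True))))
        np.testing.assert_allclose(net.adjacency, np.abs(np.corrcoef(dup.values)), atol=1e-10)

    def test_symmetric_unit_diagonal_in_range(self, random_matrix):
        net = compute_tom(build_adjacency(random_matrix(30, 12, seed=4), beta=6))
        for mat in (net.adjacency, net.tom):
            np.testing.assert_allclose(mat, mat.T, atol=1e-10)
            np.testing.assert_allclose(np.diag(mat), 1.0, atol=1e-10)
            assert mat.min() >= -1e-10 and mat.max() <= 1 + 1e-10

    def test_constant_feature_rejected(self):
        m = OmicsMatrix(
            np.vstack([np.ones(10), np.random.default_rng(0).normal(size=(24, 10))]),
            [f"g{i}" for i in range(25)], [f"s{i}" for i in range(10)], "RNA",
        )
        with pytest.raises(ValueError, match="constant"):
            scale_free_fit(m, beta=6)


class TestScaleFreeFit:
    def test_higher_power_shrinks_connectivity_on_noise(self, random_matrix):
        m = random_matrix(200, 200, seed=1)
        _, k6 = scale_free_fit(m, beta=6)
        _, k1 = scale_free_fit(m, beta=1)
        assert k6 < 0.05 * k1

    def test_degenerate_bins_return_zero(self):
        # two perfectly correlated blocks -> connectivity takes 2 atoms -> <3 bins
        rng = np.random.default_rng(5)
        f1, f2 = rng.normal(size=(2, 30))
        vals = np.vstack([np.tile(f1, (50, 1)), np.tile(f2, (50, 1))])  # exact duplicates
        m = OmicsMatrix(vals, [f"g{i}" for i in range(100)],
                        [f"s{i}" for i in range(30)], "RNA")
        r2, _ = scale_free_fit(m, beta=3)
        assert r2 == 0.0

    def test_pick_matches_brute_force(self):
        m, _ = simulate_modular_expression(
            n_samples=60, blocks=[(40, 0.7), (30, 0.7)], n_background=30, seed=7
        )
        candidates = list(range(1, 11))
        chosen = pick_soft_power(m, candidates, r2_cut=0.8)
        fits = [scale_free_fit(m, b)[0] for b in candidates]
        crossing = [b for b, r2 in zip(candidates, fits) if r2 >= 0.8]
        assert chosen == (crossing[0] if crossing else candidates[int(np.argmax(fits))])

    def test_r2_cut_zero_returns_smallest_candidate(self, random_matrix):
        assert pick_soft_power(random_matrix(40, 20, seed=9), [2, 4, 6], r2_cut=0.0) == 2

    def test_all_noise_warns_and_returns_argmax(self, random_matrix):
        m = random_matrix(50, 40, seed=11)
        candidates = [1, 2, 3]
        with pytest.warns(UserWarning, match="argmax"):
            chosen = pick_soft_power(m, candidates, r2_cut=0.999)
        fits = [scale_free_fit(m, b)[0] for b in candidates]
        assert chosen == candidates[int(np.argmax(fits))]


class TestTom:
    def test_complete_graph_gives_unit_overlap(self):
        a = np.ones((3, 3))
        net = compute_tom(Network(a, soft_power=1))
        np.testing.assert_allclose(net.tom, np.ones((3, 3)), atol=1e-12)

    def test_empty_graph_gives_zero_overlap(self):
        net = compute_tom(Network(np.eye(4), soft_power=1))
        np.testing.assert_allclose(net.tom, np.eye(4), atol=1e-12)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(0, 1, size=(6, 6))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        net = compute_tom(Network(a, soft_power=1))
        np.testing.assert_allclose(net.tom, tom_brute_force(a), atol=1e-12)


def rand_index(labels_a: dict, labels_b: dict) -> float:
    keys = sorted(labels_a)
    same_a = np.array([[labels_a[i] == labels_a[j] for j in keys] for i in keys])
    same_b = np.array([[labels_b[i] == labels_b[j] for j in keys] for i in keys])
    iu = np.triu_indices(len(keys), k=1)
    return float((same_a[iu] == same_b[iu]).mean())


class TestDetectModules:
    def test_recovers_two_planted_blocks(self):
        m, truth = simulate_modular_expression(
            n_samples=100, blocks=[(60, 0.8), (40, 0.8)], seed=11
        )
        ms = build_modules(m, beta=6, min_size=30)
        assert sorted(ms.module_labels) == ["ME1", "ME2"]
        assert rand_index(ms.assignment, truth) == 1.0
        # ME1 is the larger block
        assert len(ms.members("ME1")) == 60

    def test_min_size_filter_sends_all_to_me0(self):
        m, _ = simulate_modular_expression(n_samples=50, blocks=[(20, 0.9)], seed=1)
        net = compute_tom(build_adjacency(m, 6))
        assignment = detect_modules(net, min_size=25)
        assert set(assignment.values()) == {"ME0"}

    def test_single_block_single_module(self):
        m, _ = simulate_modular_expression(n_samples=60, blocks=[(40, 0.9)], seed=2)
        net = compute_tom(build_adjacency(m, 6))
        assignment = detect_modules(net, min_size=30)
        assert set(assignment.values()) == {"ME1"}

    def test_feature_order_invariance(self):
        m, _ = simulate_modular_expression(
            n_samples=80, blocks=[(40, 0.8), (35, 0.8)], n_background=20, seed=13
        )
        ms1 = build_modules(m, beta=6)
        rng = np.random.default_rng(0)
        perm = rng.permutation(m.n_features)
        shuffled = OmicsMatrix(
            m.values[perm], [m.feature_ids[i] for i in perm], m.sample_ids, "RNA"
        )
        ms2 = build_modules(shuffled, beta=6)
        assert ms1.assignment == ms2.assignment


class TestEigengenes:
    def test_identical_rows_rank_one(self):
        rng = np.random.default_rng(7)
        profile = rng.normal(size=8)
        # rows are affine images of one profile -> rank-1 after standardization
        m = OmicsMatrix(np.vstack([profile, profile * 3 + 1]), ["g1", "g2"],
                        [f"s{i}" for i in range(8)], "RNA")
        ms = compute_eigengenes(m, {"g1": "ME1", "g2": "ME1"})
        assert ms.variance_explained["ME1"] == pytest.approx(1.0, abs=1e-12)
        std = (profile - profile.mean()) / profile.std(ddof=1)
        np.testing.assert_allclose(ms.eigengenes.loc["ME1"].to_numpy(), std, atol=1e-10)

    def test_matches_svd_oracle(self, small_matrix):
        assignment = {f: "ME1" for f in small_matrix.feature_ids}
        ms = compute_eigengenes(small_matrix, assignment)
        x = small_matrix.values
        x = (x - x.mean(1, keepdims=True)) / x.std(1, ddof=1, keepdims=True)
        _, s, vt = np.linalg.svd(x, full_matrices=False)
        oracle = vt[0] / vt[0].std(ddof=1)
        got = ms.eigengenes.loc["ME1"].to_numpy()
        err = min(np.abs(got - oracle).max(), np.abs(got + oracle).max())
        assert err < 1e-10
        assert ms.variance_explained["ME1"] == pytest.approx(
            s[0] ** 2 / (s**2).sum(), abs=1e-12
        )

    def test_sign_aligned_to_mean_profile(self):
        rng = np.random.default_rng(5)
        f = rng.normal(size=10)
        up = np.vstack([f + 0.1 * rng.normal(size=10) for _ in range(6)])
        down = np.vstack([-f + 0.1 * rng.normal(size=10) for _ in range(4)])
        m = OmicsMatrix(np.vstack([up, down]), [f"g{i}" for i in range(10)],
                        [f"s{i}" for i in range(10)], "RNA")
        ms = compute_eigengenes(m, {f"g{i}": "ME1" for i in range(10)})
        x = (m.values - m.values.mean(1, keepdims=True)) / m.values.std(1, ddof=1, keepdims=True)
        assert np.corrcoef(ms.eigengenes.loc["ME1"], x.mean(axis=0))[0, 1] >= 0

    def test_variance_explained_is_maximal(self, random_matrix):
        m = random_matrix(10, 8, seed=21)
        ms = compute_eigengenes(m, {f: "ME1" for f in m.feature_ids})
        x = (m.values - m.values.mean(1, keepdims=True)) / m.values.std(1, ddof=1, keepdims=True)
        total = (x**2).sum()
        rng = np.random.default_rng(0)
        for _ in range(50):
            v = rng.normal(size=8)
            v /= np.linalg.norm(v)
            frac = ((x @ v) ** 2).sum() / total
            assert frac <= ms.variance_explained["ME1"] + 1e-10
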