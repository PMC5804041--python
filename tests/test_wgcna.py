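"""Soft thresholding, topological overlap, module detection and eigengenes."""

import numpy as np
import pandas as pd
import pytest

from imfnet.wgcna import (
    GREY,
    adjacency,
    detect_modules,
    eigengene,
    eigengenes,
    module_hubs,
    module_membership,
    pick_soft_threshold,
    scale_free_fit,
    signed_similarity,
    tom,
)


def _module_data(rng, sizes, loadings, n_samples=30, noise=0.6):
    """Block data: one latent factor per module plus independent noise."""
    blocks = []
    for size, loading in zip(sizes, loadings):
        f = rng.standard_normal(n_samples)
        blocks.append(loading * f[None, :] + noise * rng.standard_normal((size, n_samples)))
    return np.vstack(blocks)


class TestAdjacency:
    def test_bounds_and_monotone_in_beta(self, rng):
        sim = signed_similarity(rng.standard_normal((10, 20)))
        a2, a6 = adjacency(sim, 2), adjacency(sim, 6)
        for a in (a2, a6):
            assert a.min() >= 0 and a.max() <= 1
        off = ~np.eye(10, dtype=bool)
        assert (a6[off] <= a2[off] + 1e-12).all()

    def test_degenerate_all_ones_flagged(self):
        values = np.tile(np.arange(6.0), (5, 1))  # identical profiles, s == 1
        report = pick_soft_threshold(values, candidates=[1, 2])
        assert report.rule == "auto-max"
        assert report.r2 == [0.0, 0.0]


class TestScaleFreeFit:
    def test_module_plus_background_reaches_cut(self):
        """With a clear module among background features at n=100 samples,
        some power attains signed R^2 > 0.90 and the lowest one is chosen."""
        rng = np.random.default_rng(3)
        n = 100
        f = rng.standard_normal(n)
        values = np.vstack(
            [0.8 * f[None, :] + rng.standard_normal((40, n)), rng.standard_normal((160, n))]
        )
        report = pick_soft_threshold(values)
        assert report.rule == "auto"
        assert report.r2[report.candidates.index(report.beta)] > 0.90
        below = [b for b, r2 in zip(report.candidates, report.r2) if b < report.beta]
        assert all(
            report.r2[report.candidates.index(b)] <= 0.90 for b in below
        )

    def test_mean_connectivity_decreases_with_beta(self, rng):
        values = rng.standard_normal((60, 25))
        report = pick_soft_threshold(values, candidates=range(1, 8))
        assert (np.diff(report.mean_connectivity) < 0).all()

    def test_beta_override_is_honored(self, rng):
        values = rng.standard_normal((30, 12))
        report = pick_soft_threshold(values, beta_override=7)
        assert report.beta == 7 and report.rule == "fixed"


def _tom_reference(a):
    """Scalar triple-loop TOM (definition of record)."""
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    n = a.shape[0]
    k = a.sum(axis=1)
    t = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            t[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return t


class TestTom:
    def test_zero_adjacency_gives_zero_overlap(self):
        t = tom(np.eye(4))
        assert np.allclose(t, np.eye(4))

    def test_complete_graph_saturates_at_one(self):
        t = tom(np.ones((5, 5)))
        assert np.allclose(t, 1.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_scalar_loop_exactly(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(0, 1, (5, 5))
        a = 0.5 * (a + a.T)
        np.fill_diagonal(a, 1.0)
        assert np.allclose(tom(a), _tom_reference(a), atol=1e-12)

    def test_bounds_and_permutation_equivariance(self, rng):
        a = rng.uniform(0, 1, (8, 8))
        a = 0.5 * (a + a.T)
        t = tom(a)
        assert t.min() >= 0 and t.max() <= 1
        perm = rng.permutation(8)
        assert np.allclose(tom(a[np.ix_(perm, perm)]), t[np.ix_(perm, perm)])


class TestEigengene:
    def test_identical_profiles_give_unit_membership(self, rng):
        profile = rng.standard_normal(12)
        values = np.tile(profile, (6, 1)) * rng.uniform(0.5, 2.0, (6, 1))
        me, ve = eigengene(values)
        for row in values:
            assert abs(np.corrcoef(row, me)[0, 1]) == pytest.approx(1.0)
        assert np.mean([np.corrcoef(row, me)[0, 1] for row in values]) > 0

    def test_sign_rule_restores_positive_average_correlation(self, rng):
        values = rng.standard_normal((5, 10)) + 2 * rng.standard_normal(10)[None, :]
        me, _ = eigengene(values)
        me_flipped, _ = eigengene(-values)
        assert np.allclose(me, -me_flipped)

    def test_variance_explained_matches_svd_oracle(self, rng):
        values = rng.standard_normal((7, 15))
        _, ve = eigengene(values)
        z = (values - values.mean(1, keepdims=True)) / values.std(1, keepdims=True)
        s = np.linalg.svd(z, compute_uv=False)
        assert abs(ve - s[0] ** 2 / np.sum(s**2)) < 1e-10

    def test_scaling_a_member_leaves_me_invariant(self, rng):
        values = rng.standard_normal((6, 12)) + rng.standard_normal(12)[None, :]
        me1, _ = eigengene(values)
        scaled = values.copy()
        scaled[2] *= 10
        me2, _ = eigengene(scaled)
        assert np.allclose(me1, me2, atol=1e-12)


class TestDetectModules:
    def test_two_blocks_plus_singletons(self, rng):
        values = np.vstack(
            [
                _module_data(rng, [12, 12], [2.0, 2.0], n_samples=60, noise=0.3),
                rng.standard_normal((3, 60)),
            ]
        )
        ids = [f"f{i:02d}" for i in range(27)]
        sim = signed_similarity(values)
        t = tom(adjacency(sim, 6))
        # blocks cohere below 0.2 dissimilarity; singletons attach above 0.5
        assign, me = detect_modules(values, ids, 1.0 - t, min_size=5, cut_height=0.5)
        labels = {assign[f] for f in ids[:12]}
        assert len(labels) == 1 and GREY not in labels
        labels2 = {assign[f] for f in ids[12:24]}
        assert len(labels2) == 1 and labels2 != labels
        assert all(assign[f] == GREY for f in ids[24:])
        assert me.shape[0] == 2

    def test_same_factor_modules_merge(self, rng):
        f = rng.standard_normal(40)
        values = np.vstack(
            [
                2.0 * f[None, :] + 0.3 * rng.standard_normal((10, 40)),
                2.0 * f[None, :] + 0.3 * rng.standard_normal((10, 40)),
                rng.standard_normal((15, 40)),
            ]
        )
        ids = [f"f{i:02d}" for i in range(35)]
        t = tom(adjacency(signed_similarity(values), 6))
        assign, me = detect_modules(values, ids, 1.0 - t, min_size=5, merge_height=0.25)
        labels = {assign[f] for f in ids[:20]}
        assert len(labels) == 1  # single merged module despite two blocks

    def test_too_few_features_all_grey(self, rng):
        values = rng.standard_normal((4, 10))
        with pytest.warns(UserWarning, match="grey"):
            assign, me = detect_modules(values, ["a", "b", "c", "d"], np.ones((4, 4)), min_size=10)
        assert set(assign.values()) == {GREY}

    def test_min_size_respected_after_merging(self, small_dataset):
        mrna, _, pheno, _ = small_dataset
        from imfnet.diffexpr import normalize, size_factors

        expr = normalize(mrna, size_factors(mrna))
        values = expr.values
        t = tom(adjacency(signed_similarity(values), 12))
        assign, me = detect_modules(values, list(expr.feature_ids), 1.0 - t, min_size=30)
        counts = pd.Series([m for m in assign.values() if m != GREY]).value_counts()
        assert (counts >= 30).all()
        assert set(me.index) == set(counts.index)


class TestModuleMembership:
    def test_perfect_module_has_unit_membership(self, rng):
        profile = rng.standard_normal(10)
        values = np.tile(profile, (5, 1)) + 0.0
        ids = [f"f{i}" for i in range(5)]
        assign = {f: "blue" for f in ids}
        me, _ = eigengenes(values, ids, assign)
        mm = module_membership(values, ids, me)
        assert np.allclose(mm["blue"].abs(), 1.0)

    def test_orthogonal_feature_has_zero_membership(self):
        me = pd.DataFrame([[1.0, 0.0, -1.0, 0.0]], index=["blue"])
        values = np.array([[0.0, 1.0, 0.0, -1.0]])
        mm = module_membership(values, ["f0"], me)
        assert mm.loc["f0", "blue"] == pytest.approx(0.0, abs=1e-12)

    def test_hub_is_strongest_loading_feature(self, rng):
        """The feature wired most tightly to the factor is called hub."""
        hits = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            f = r.standard_normal(25)
            loadings = np.array([2.5] + [0.8] * 9)
            values = loadings[:, None] * f[None, :] + 0.8 * r.standard_normal((10, 25))
            ids = [f"f{i}" for i in range(10)]
            assign = {i: "blue" for i in ids}
            me, _ = eigengenes(values, ids, assign)
            mm = module_membership(values, ids, me)
            hits += module_hubs(mm, assign)["blue"] == "f0"
        assert hits >= 9

    def test_hub_tie_breaks_lexicographically(self):
        me = pd.DataFrame([[1.0, 0.0, -1.0, 0.0]], index=["blue"])
        values = np.array([[1.0, 0, -1, 0], [1.0, 0, -1, 0]])
        mm = module_membership(values, ["fb", "fa"], me)
        assign = {"fb": "blue", "fa": "blue"}
        assert module_hubs(mm, assign)["blue"] == "fa"
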