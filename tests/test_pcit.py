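"""PCIT edge filtering, differential hubbing and neighbor extraction."""

import numpy as np
import pandas as pd
import pytest

from imfnet.data_model import ExpressionMatrix
from imfnet.pcit import (
    CorrelationNetwork,
    correlation_network,
    correlation_p,
    dh_scores,
    hub_neighbors,
    pcit,
    pcit_reference,
    top_dh,
    variance_filter,
)


def _expr(values):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        values,
        [f"f{i}" for i in range(values.shape[0])],
        [f"s{j}" for j in range(values.shape[1])],
        np.ones(values.shape[1]),
    )


def _random_corr(rng, n_features, n_samples=30):
    x = rng.standard_normal((n_features, n_samples))
    r = np.corrcoef(x)
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1, 1)


class TestCorrelationNetwork:
    def test_self_correlation_is_one(self, rng):
        net = correlation_network(_expr(rng.standard_normal((4, 6))), ["s0", "s1", "s2", "s3"], "H")
        assert np.allclose(np.diag(net.r), 1.0)

    def test_orthogonal_vectors_have_zero_correlation(self):
        expr = _expr([[1, 0, -1], [0, 1, 0]])
        net = correlation_network(expr, ["s0", "s1", "s2"], "H")
        assert net.r[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_constant_features_dropped_with_warning(self, rng):
        values = rng.standard_normal((3, 5))
        values[1] = 2.5
        with pytest.warns(UserWarning, match="constant"):
            net = correlation_network(_expr(values), [f"s{j}" for j in range(5)], "H")
        assert net.feature_ids == ["f0", "f2"]

    def test_p_values_match_permutation_null(self, rng):
        """The t-transform p agrees with an empirical permutation p at n=15."""
        n = 15
        x = rng.standard_normal(n)
        y = 0.55 * x + rng.standard_normal(n)  # moderate true correlation
        r_obs = np.corrcoef(x, y)[0, 1]
        p_t = float(correlation_p(np.array(r_obs), n))
        reps = 5000
        perm_r = np.empty(reps)
        for i in range(reps):
            perm_r[i] = np.corrcoef(x, rng.permutation(y))[0, 1]
        p_perm = float((np.abs(perm_r) >= abs(r_obs)).mean())
        mc_sd = np.sqrt(max(p_perm * (1 - p_perm), 1e-6) / reps)
        assert abs(p_t - p_perm) < 4 * mc_sd + 0.01


class TestPcit:
    def test_two_features_single_pair_retained(self):
        r = np.array([[1.0, 0.3], [0.3, 1.0]])
        mask = pcit(r)
        assert mask[0, 1] and mask[1, 0]
        assert not mask[0, 0]

    @pytest.mark.parametrize("seed", range(12))
    def test_vectorized_equals_reference_loop(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 25))
        r = _random_corr(rng, n)
        assert np.array_equal(pcit(r), pcit_reference(r))

    def test_permutation_equivariance(self, rng):
        r = _random_corr(rng, 12)
        perm = rng.permutation(12)
        direct = pcit(r[np.ix_(perm, perm)])
        permuted = pcit(r)[np.ix_(perm, perm)]
        assert np.array_equal(direct, permuted)

    def test_direct_edge_survives_weak_edges_die(self):
        """z = x + noise gives a strong direct x-z edge that always survives;
        chance associations among independent features are mostly eliminated
        once enough control features exist to expose them."""
        xz_retained = 0
        null_elim = null_total = 0
        trials = 20
        for seed in range(trials):
            rng = np.random.default_rng(seed)
            n = 200
            x = rng.standard_normal(n)
            z = x + 0.4 * rng.standard_normal(n)
            indep = rng.standard_normal((10, n))
            r = np.corrcoef(np.vstack([x, z, indep]))
            mask = pcit(r)
            xz_retained += mask[0, 1]
            sub = mask[2:, 2:]
            iu = np.triu_indices(10, 1)
            null_elim += int((~sub[iu]).sum())
            null_total += len(iu[0])
        assert xz_retained == trials
        assert null_elim / null_total > 0.5

    def test_symmetry_and_false_diagonal(self, rng):
        r = _random_corr(rng, 9)
        mask = pcit(r)
        assert np.array_equal(mask, mask.T)
        assert not mask.diagonal().any()


def _net(r, group, n=15):
    n_feat = r.shape[0]
    return CorrelationNetwork(
        group,
        [f"f{i}" for i in range(n_feat)],
        r,
        correlation_p(r, n),
        n,
    )


class TestDh:
    def _two_nets(self, rng, n=10):
        r_h = _random_corr(rng, n)
        r_l = _random_corr(rng, n)
        return _net(r_h, "H"), _net(r_l, "L")

    def test_connection_difference_definition(self):
        r_h = np.eye(3)
        r_h[0, 1] = r_h[1, 0] = 0.95
        r_l = np.eye(3)
        r_l[0, 2] = r_l[2, 0] = 0.95
        r_l[0, 1] = r_l[1, 0] = 0.95
        dh = dh_scores(_net(r_h, "H"), pcit(r_h), _net(r_l, "L"), pcit(r_l))
        row = dh.set_index("feature").loc["f0"]
        assert row["conn_H"] == 1 and row["conn_L"] == 2 and row["dh"] == -1

    def test_identical_networks_give_zero_dh(self, rng):
        r = _random_corr(rng, 8)
        mask = pcit(r)
        dh = dh_scores(_net(r, "H"), mask, _net(r, "L"), mask)
        assert (dh["dh"] == 0).all()

    def test_raising_threshold_never_increases_connections(self, rng):
        net_h, net_l = self._two_nets(rng)
        m_h, m_l = pcit(net_h.r), pcit(net_l.r)
        lo = dh_scores(net_h, m_h, net_l, m_l, edge_threshold=0.2)
        hi = dh_scores(net_h, m_h, net_l, m_l, edge_threshold=0.6)
        assert (hi["conn_H"] <= lo["conn_H"]).all()
        assert (hi["conn_L"] <= lo["conn_L"]).all()

    def test_dh_sum_is_twice_edge_count_difference(self, rng):
        net_h, net_l = self._two_nets(rng)
        m_h, m_l = pcit(net_h.r), pcit(net_l.r)
        thr = 0.3
        dh = dh_scores(net_h, m_h, net_l, m_l, edge_threshold=thr)
        edges_h = np.sum(np.triu(m_h & (np.abs(net_h.r) > thr), 1))
        edges_l = np.sum(np.triu(m_l & (np.abs(net_l.r) > thr), 1))
        assert dh["dh"].sum() == 2 * (edges_h - edges_l)

    def test_mismatched_feature_lists_raise(self, rng):
        net_h, net_l = self._two_nets(rng)
        net_l.feature_ids = list(reversed(net_l.feature_ids))
        with pytest.raises(ValueError, match="feature lists"):
            dh_scores(net_h, pcit(net_h.r), net_l, pcit(net_l.r))


class TestTopDh:
    def _dh(self, values):
        return pd.DataFrame(
            {
                "feature": [f"f{i}" for i in range(len(values))],
                "conn_H": 0,
                "conn_L": 0,
                "dh": values,
            }
        )

    def test_single_extremes(self):
        pos, neg = top_dh(self._dh([5, -2, 0]), k=1)
        assert list(pos["feature"]) == ["f0"]
        assert list(neg["feature"]) == ["f1"]

    def test_all_equal_takes_lexicographic_first(self):
        pos, neg = top_dh(self._dh([3, 3, 3]), k=2)
        assert list(pos["feature"]) == ["f0", "f1"]
        assert list(neg["feature"]) == ["f0", "f1"]

    def test_k_equals_n_gives_opposite_orders(self):
        pos, neg = top_dh(self._dh([1, 2, 3]), k=3)
        assert list(pos["feature"]) == list(reversed(list(neg["feature"])))

    def test_k_too_large_raises(self):
        with pytest.raises(ValueError):
            top_dh(self._dh([1]), k=2)


class TestHubNeighbors:
    def test_no_retained_edges_gives_empty_set(self):
        r = np.eye(3)
        net = _net(r, "H")
        neighbors, edges = hub_neighbors(net, pcit(r), ["f0"])
        assert neighbors == {"f0": set()}
        assert len(edges) == 0

    def test_zero_threshold_gives_all_retained_partners(self, rng):
        r = _random_corr(rng, 6)
        net = _net(r, "H")
        mask = pcit(r)
        neighbors, _ = hub_neighbors(net, mask, ["f2"], corr_threshold=0.0)
        expected = {net.feature_ids[j] for j in np.flatnonzero(mask[2])}
        assert neighbors["f2"] == expected

    def test_neighbor_sets_match_edge_list_filtering(self, rng):
        r = _random_corr(rng, 8)
        net = _net(r, "H")
        mask = pcit(r)
        thr = 0.25
        neighbors, edges = hub_neighbors(net, mask, ["f0", "f5"], corr_threshold=thr)
        for hub in ("f0", "f5"):
            i = net.index_of(hub)
            expected = {
                net.feature_ids[j]
                for j in range(8)
                if mask[i, j] and abs(r[i, j]) > thr
            }
            assert neighbors[hub] == expected
            from_edges = set(edges.loc[edges["hub"] == hub, "neighbor"])
            assert from_edges == expected

    def test_unknown_hub_raises(self, rng):
        r = _random_corr(rng, 4)
        with pytest.raises(KeyError):
            hub_neighbors(_net(r, "H"), pcit(r), ["nope"])


def test_variance_filter_returns_top_by_variance(rng):
    values = rng.standard_normal((5, 20)) * np.array([[1], [5], [0.1], [3], [2]])
    expr = _expr(values)
    assert variance_filter(expr, 2) == ["f1", "f3"]


def test_graphml_export_round_trips_edges(rng, tmp_path):
    import networkx as nx
    from imfnet.pcit import write_edges_graphml

    r = _random_corr(rng, 6)
    net = _net(r, "H")
    mask = pcit(r)
    _, edges = hub_neighbors(net, mask, ["f0", "f1"], corr_threshold=0.2)
    path = tmp_path / "hubs.graphml"
    write_edges_graphml(edges, path)
    g = nx.read_graphml(path)
    unordered = {frozenset((h, n)) for h, n in zip(edges["hub"], edges["neighbor"])}
    assert g.number_of_edges() == len(unordered)
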