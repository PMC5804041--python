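"""Per-group correlation networks, the PCIT edge filter, and differential hubbing.

PCIT (partial correlation with an information-theory-inspired tolerance)
decides, for every pair of features, whether their correlation survives
conditioning on each possible third feature.  For a trio (x, y, z) the three
first-order partial correlations are computed, e.g.

    r_xy.z = (r_xy - r_xz * r_yz) / sqrt((1 - r_xz^2) (1 - r_yz^2))

and the trio tolerance is the mean of the signed partial/direct ratios

    eps = (r_xy.z / r_xy + r_xz.y / r_xz + r_yz.x / r_yz) / 3.

The pair (x, y) is eliminated if some z satisfies both
|r_xy| < |eps * r_xz| and |r_xy| < |eps * r_yz|; otherwise it is retained.
A "connection" for differential hubbing additionally requires the retained
correlation magnitude to exceed an edge threshold (0.9 by default), and the
differential-hubbing score of a feature is its connection count in the High
group minus the count in the Low group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import ExpressionMatrix

__all__ = [
    "CorrelationNetwork",
    "correlation_network",
    "pcit",
    "pcit_reference",
    "dh_scores",
    "top_dh",
    "hub_neighbors",
    "write_edges_graphml",
    "variance_filter",
]

_EPS_DEN = 1e-12  # partials are skipped when a denominator underflows


@dataclass
class CorrelationNetwork:
    """Symmetric Pearson correlation matrix for one group, with t-test p-values."""

    group: str
    feature_ids: list[str]
    r: np.ndarray
    p: np.ndarray
    n_samples: int

    def index_of(self, feature: str) -> int:
        try:
            return self.feature_ids.index(feature)
        except ValueError:
            raise KeyError(f"feature {feature!r} not in network") from None


def correlation_p(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p-value of a Pearson correlation via the t transform (n-2 df)."""
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, np.finfo(float).tiny))
    return 2.0 * stats.t.sf(np.abs(t), df=n - 2)


def correlation_network(
    expr: ExpressionMatrix, group_samples: list[str], group: str
) -> CorrelationNetwork:
    """Pearson correlations across one group's samples on log-normalized expression.

    Constant features cannot be correlated and are dropped with a warning.
    """
    if len(group_samples) < 3:
        raise ValueError("need at least 3 samples per group")
    sub = expr.subset_samples(group_samples)
    sd = np.std(sub.values, axis=1)
    keep = sd > 0
    if not np.all(keep):
        dropped = [f for f, k in zip(sub.feature_ids, keep) if not k]
        warnings.warn(f"dropping {len(dropped)} constant feature(s): {dropped[:5]}...")
    values = sub.values[keep]
    ids = [f for f, k in zip(sub.feature_ids, keep) if k]
    r = np.corrcoef(values)
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)
    p = correlation_p(r, len(group_samples))
    np.fill_diagonal(p, 0.0)
    return CorrelationNetwork(group, ids, r, p, len(group_samples))


def variance_filter(expr: ExpressionMatrix, top: int) -> list[str]:
    """Ids of the ``top`` features by variance across all samples (ties by id)."""
    var = np.var(expr.values, axis=1)
    order = sorted(range(len(var)), key=lambda i: (-var[i], expr.feature_ids[i]))
    return [expr.feature_ids[i] for i in order[: min(top, len(order))]]


def pcit(r: np.ndarray) -> np.ndarray:
    """Vectorized PCIT: boolean mask of retained associations (diagonal False).

    Loops once over the conditioning feature z; for each z all pairwise
    partial-correlation ratios are computed with matrix operations.
    """
    r = np.asarray(r, dtype=float)
    n = r.shape[0]
    if r.shape != (n, n):
        raise ValueError("correlation matrix must be square")
    mask_off = ~np.eye(n, dtype=bool)
    if n < 3:
        return mask_off.copy()

    absr = np.abs(r)
    eliminated = np.zeros((n, n), dtype=bool)
    idx = np.arange(n)
    # guard direct correlations away from zero for the ratio denominators
    safe_r = np.where(absr < _EPS_DEN, _EPS_DEN, r)

    for z in range(n):
        rz = r[:, z]  # r_xz for every x
        one_minus_rz2 = 1.0 - rz**2
        den_z = np.sqrt(np.outer(one_minus_rz2, one_minus_rz2))  # for r_xy.z
        with np.errstate(divide="ignore", invalid="ignore"):
            p_xy_z = (r - np.outer(rz, rz)) / den_z
            # r_xz.y: condition the (x,z) correlation on y (columns index y)
            den_b = np.sqrt((1.0 - r**2) * (1.0 - rz**2)[None, :])
            p_xz_y = (rz[:, None] - r * rz[None, :]) / den_b
            # r_yz.x: condition the (y,z) correlation on x (rows index x)
            den_c = np.sqrt((1.0 - r**2) * (1.0 - rz**2)[:, None])
            p_yz_x = (rz[None, :] - r * rz[:, None]) / den_c

            ratio_a = p_xy_z / safe_r
            ratio_b = p_xz_y / safe_r[:, z][:, None]
            ratio_c = p_yz_x / safe_r[z, :][None, :]

        valid_a = den_z >= _EPS_DEN
        valid_b = den_b >= _EPS_DEN
        valid_c = den_c >= _EPS_DEN
        ratios = np.stack([ratio_a, ratio_b, ratio_c])
        valid = np.stack([valid_a, valid_b, valid_c])
        ratios = np.where(valid, ratios, 0.0)
        n_valid = valid.sum(axis=0)
        with np.errstate(invalid="ignore"):
            eps = np.where(n_valid > 0, ratios.sum(axis=0) / np.maximum(n_valid, 1), np.nan)

        lim_x = np.abs(eps) * absr[:, z][:, None]  # |eps * r_xz|
        lim_y = np.abs(eps) * absr[z, :][None, :]  # |eps * r_yz|
        cond = (absr < lim_x) & (absr < lim_y) & (n_valid > 0)
        cond[z, :] = False
        cond[:, z] = False
        cond[idx, idx] = False
        eliminated |= cond

    retained = mask_off & ~eliminated
    return retained


def pcit_reference(r: np.ndarray) -> np.ndarray:
    """Plain O(n^3) triple-loop PCIT, the definition of record for testing."""
    r = np.asarray(r, dtype=float)
    n = r.shape[0]
    mask_off = ~np.eye(n, dtype=bool)
    if n < 3:
        return mask_off.copy()
    eliminated = np.zeros((n, n), dtype=bool)

    def partial(a: int, b: int, c: int) -> float | None:
        den = (1.0 - r[a, c] ** 2) * (1.0 - r[b, c] ** 2)
        if den < _EPS_DEN**2:
            return None
        return (r[a, b] - r[a, c] * r[b, c]) / np.sqrt(den)

    def safe(v: float) -> float:
        return v if abs(v) >= _EPS_DEN else _EPS_DEN

    for x in range(n):
        for y in range(x + 1, n):
            for z in range(n):
                if z == x or z == y:
                    continue
                p_xy = partial(x, y, z)
                p_xz = partial(x, z, y)
                p_yz = partial(y, z, x)
                ratios = []
                if p_xy is not None:
                    ratios.append(p_xy / safe(r[x, y]))
                if p_xz is not None:
                    ratios.append(p_xz / safe(r[x, z]))
                if p_yz is not None:
                    ratios.append(p_yz / safe(r[y, z]))
                if not ratios:
                    continue
                eps = sum(ratios) / len(ratios)
                if abs(r[x, y]) < abs(eps * r[x, z]) and abs(r[x, y]) < abs(eps * r[y, z]):
                    eliminated[x, y] = eliminated[y, x] = True
    return mask_off & ~eliminated


def dh_scores(
    net_h: CorrelationNetwork,
    mask_h: np.ndarray,
    net_l: CorrelationNetwork,
    mask_l: np.ndarray,
    edge_threshold: float = 0.9,
) -> pd.DataFrame:
    """Differential hubbing: per-feature connection-count difference High - Low.

    A connection in a group requires PCIT retention and |r| above the edge
    threshold.  Negative scores mean more connections in the Low group.
    """
    if net_h.feature_ids != net_l.feature_ids:
        raise ValueError("feature lists differ between the two group networks")
    conn_h = np.sum(mask_h & (np.abs(net_h.r) > edge_threshold), axis=1)
    conn_l = np.sum(mask_l & (np.abs(net_l.r) > edge_threshold), axis=1)
    return pd.DataFrame(
        {
            "feature": net_h.feature_ids,
            "conn_H": conn_h.astype(int),
            "conn_L": conn_l.astype(int),
            "dh": (conn_h - conn_l).astype(int),
        }
    )


def top_dh(dh: pd.DataFrame, k: int = 10) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Top-k most positive and most negative DH features, ties by feature id."""
    if k > len(dh):
        raise ValueError(f"k={k} exceeds number of features ({len(dh)})")
    pos = dh.sort_values(["dh", "feature"], ascending=[False, True]).head(k)
    neg = dh.sort_values(["dh", "feature"], ascending=[True, True]).head(k)
    return pos.reset_index(drop=True), neg.reset_index(drop=True)


def hub_neighbors(
    net: CorrelationNetwork,
    mask: np.ndarray,
    hubs: list[str],
    corr_threshold: float = 0.9,
) -> tuple[dict[str, set[str]], pd.DataFrame]:
    """Retained neighbors of each hub above the correlation threshold.

    Returns per-hub neighbor sets and a signed edge list (hub, neighbor, r,
    sign) for network export.
    """
    rows = []
    neighbors: dict[str, set[str]] = {}
    for hub in hubs:
        i = net.index_of(hub)
        sel = mask[i] & (np.abs(net.r[i]) > corr_threshold)
        ids = {net.feature_ids[j] for j in np.flatnonzero(sel)}
        neighbors[hub] = ids
        for j in sorted(np.flatnonzero(sel)):
            rows.append(
                {
                    "hub": hub,
                    "neighbor": net.feature_ids[j],
                    "r": float(net.r[i, j]),
                    "sign": "+" if net.r[i, j] >= 0 else "-",
                }
            )
    edges = pd.DataFrame(rows, columns=["hub", "neighbor", "r", "sign"])
    return neighbors, edges


def write_edges_graphml(edges: pd.DataFrame, path) -> None:
    """Export a signed hub-neighbor edge list as GraphML for network viewers."""
    import networkx as nx

    g = nx.Graph()
    for _, row in edges.iterrows():
        g.add_edge(row["hub"], row["neighbor"], r=float(row["r"]), sign=str(row["sign"]))
    nx.write_graphml(g, str(path))
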