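"""Signed weighted co-expression modules: soft threshold, TOM, clustering,
eigengenes, merging and module membership.

The signed similarity s_ij = (1 + cor_ij) / 2 is raised to a soft power beta
chosen as the lowest value giving an approximately scale-free connectivity
distribution (signed R^2 > 0.90 on a 10-bin log-log fit).  Topological
overlap of the adjacency is clustered with average linkage; the dendrogram is
cut at a static height (default: the 0.99 quantile of merge heights),
clusters below the minimum size fall into the "grey" catch-all, and modules
whose eigengenes correlate above 1 - merge_height (default merge height
0.25) are merged iteratively.  The eigengene of a module is the first right
singular vector of its standardized expression, with sign fixed so the mean
correlation with member features is positive.  Module membership (MM) is the
correlation of a feature with a module eigengene; the feature with the
highest MM in its own module is the module hub.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "MODULE_COLORS",
    "SoftThresholdReport",
    "signed_similarity",
    "adjacency",
    "pick_soft_threshold",
    "tom",
    "eigengene",
    "eigengenes",
    "detect_modules",
    "module_membership",
    "module_hubs",
]

GREY = "grey"

# conventional color palette, assigned to modules by decreasing size
MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue", "darkred",
    "darkgreen", "darkturquoise", "darkgrey", "orange", "darkorange", "white",
    "skyblue", "saddlebrown", "steelblue", "paleturquoise", "violet",
    "darkolivegreen", "darkmagenta", "sienna3", "yellowgreen", "skyblue3",
    "plum1", "orangered4", "mediumpurple3", "lightsteelblue1", "floralwhite",
    "ivory", "salmon4", "maroon", "lightpink4", "thistle2", "bisque4",
]


def signed_similarity(values: np.ndarray) -> np.ndarray:
    """s_ij = (1 + Pearson correlation) / 2, mapping [-1, 1] to [0, 1]."""
    r = np.corrcoef(values)
    r = np.clip(np.nan_to_num(r, nan=0.0), -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return 0.5 * (1.0 + r)


def adjacency(similarity: np.ndarray, beta: int) -> np.ndarray:
    """Soft-thresholded adjacency a_ij = s_ij ** beta."""
    if beta < 1:
        raise ValueError("beta must be a positive integer")
    return similarity**beta


@dataclass
class SoftThresholdReport:
    candidates: list[int]
    r2: list[float]  # signed scale-free fit R^2 per candidate
    mean_connectivity: list[float]
    beta: int
    rule: str  # "auto" | "auto-max" | "fixed"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"beta": self.candidates, "signed_r2": self.r2, "mean_k": self.mean_connectivity}
        )


def scale_free_fit(adj: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of log10 p(k) on log10 mean(k) over equal-occupancy bins.

    With equal-occupancy bins the connectivity density p(k) is the bin's
    relative frequency divided by its width.  The R^2 is negated when the
    slope is positive, so only decreasing (scale-free-like) degree
    distributions score well.
    """
    a = adj.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    if np.all(k == k[0]):
        return 0.0  # degenerate: all connectivities identical
    order = np.argsort(k, kind="stable")
    bins = np.array_split(order, n_bins)
    xs, ys = [], []
    for b in bins:
        if len(b) == 0:
            continue
        mean_k = float(np.mean(k[b]))
        width = float(np.max(k[b]) - np.min(k[b]))
        if mean_k <= 0 or width <= 0:
            continue
        density = (len(b) / len(k)) / width
        xs.append(np.log10(mean_k))
        ys.append(np.log10(density))
    if len(set(xs)) < 3:
        return 0.0
    x, y = np.asarray(xs), np.asarray(ys)
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return -r2 if slope > 0 else r2


def pick_soft_threshold(
    values: np.ndarray,
    candidates: range | list[int] = range(1, 21),
    r2_cut: float = 0.90,
    beta_override: int | None = None,
) -> SoftThresholdReport:
    """Select the lowest soft power with signed scale-free R^2 above the cut.

    Falls back to the R^2-maximizing power (with a warning) when no candidate
    reaches the cut.  ``beta_override`` short-circuits selection, for runs
    that reuse a previously chosen power.
    """
    sd = np.std(values, axis=1)
    if np.all(sd == 0):
        raise ValueError("all features are constant")
    sim = signed_similarity(values)
    candidates = list(candidates)
    r2s, ks = [], []
    for beta in candidates:
        adj = adjacency(sim, beta)
        a = adj.copy()
        np.fill_diagonal(a, 0.0)
        r2s.append(scale_free_fit(adj))
        ks.append(float(a.sum(axis=1).mean()))
    if beta_override is not None:
        if beta_override not in candidates:
            raise ValueError("beta_override must be among the candidate powers")
        return SoftThresholdReport(candidates, r2s, ks, beta_override, "fixed")
    passing = [b for b, r2 in zip(candidates, r2s) if r2 > r2_cut]
    if passing:
        return SoftThresholdReport(candidates, r2s, ks, passing[0], "auto")
    best = candidates[int(np.argmax(r2s))]
    warnings.warn(
        f"no candidate power reached signed R^2 > {r2_cut}; using beta={best} "
        f"(max R^2 = {max(r2s):.3f})"
    )
    return SoftThresholdReport(candidates, r2s, ks, best, "auto-max")


def tom(adj: np.ndarray) -> np.ndarray:
    """Topological overlap: TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i,k_j) + 1 - a_ij).

    The sum excludes u in {i, j}; TOM_ii = 1 by convention.
    """
    a = np.asarray(adj, dtype=float).copy()
    n = a.shape[0]
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a  # diagonal of a is zero, so u = i and u = j contribute nothing
    num = shared + a
    den = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(den > 0, num / den, 0.0)
    np.fill_diagonal(t, 1.0)
    return np.clip(t, 0.0, 1.0)


def eigengene(values: np.ndarray) -> tuple[np.ndarray, float]:
    """First right singular vector of standardized module expression.

    Returns (eigengene over samples, variance explained).  Zero-variance
    features are dropped (with a warning); the sign is fixed so the average
    correlation with member features is positive.
    """
    sd = values.std(axis=1)
    keep = sd > 0
    if not np.all(keep):
        warnings.warn(f"dropping {np.sum(~keep)} zero-variance feature(s) from eigengene")
    v = values[keep]
    if v.shape[0] == 0:
        raise ValueError("module has no non-constant features")
    z = (v - v.mean(axis=1, keepdims=True)) / v.std(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    me = vt[0]
    var_explained = float(s[0] ** 2 / np.sum(s**2))
    corr = _corr_with_vector(z, me)
    if np.mean(corr) < 0:
        me = -me
    return me, var_explained


def _corr_with_vector(rows: np.ndarray, vec: np.ndarray) -> np.ndarray:
    rz = rows - rows.mean(axis=1, keepdims=True)
    vz = vec - vec.mean()
    den = np.sqrt((rz**2).sum(axis=1) * (vz**2).sum())
    den = np.where(den == 0, np.inf, den)
    return np.clip((rz @ vz) / den, -1.0, 1.0)


def eigengenes(
    values: np.ndarray, feature_ids: list[str], assignment: dict[str, str]
) -> tuple[pd.DataFrame, pd.Series]:
    """Eigengene per non-grey module: (module x sample frame, variance explained)."""
    pos = {f: i for i, f in enumerate(feature_ids)}
    modules = sorted({m for m in assignment.values() if m != GREY})
    rows, var_rows = {}, {}
    for mod in modules:
        members = [f for f in feature_ids if assignment.get(f) == mod]
        if len(members) < 2:
            raise ValueError(f"module {mod!r} has fewer than 2 features")
        me, ve = eigengene(values[[pos[f] for f in members]])
        rows[mod] = me
        var_rows[mod] = ve
    frame = pd.DataFrame(rows).T
    return frame, pd.Series(var_rows, name="variance_explained", dtype=float)


def detect_modules(
    values: np.ndarray,
    feature_ids: list[str],
    tom_diss: np.ndarray,
    min_size: int,
    merge_height: float = 0.25,
    cut_height: float = 0.95,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Average-linkage clustering of the TOM dissimilarity into modules.

    A static cut at ``cut_height`` on the dissimilarity scale (default 0.95,
    the usual static-tree-cut height: module branches in TOM dendrograms sit
    well below it, unclustered features join above it)
    defines initial clusters; clusters below ``min_size`` become grey;
    modules whose eigengene dissimilarity (1 - correlation) is below
    ``merge_height`` are merged until none remain.  Module labels follow the
    conventional color palette by decreasing module size.  Returns the
    feature -> label assignment and the module x sample eigengene frame.
    """
    n = len(feature_ids)
    if n < min_size:
        warnings.warn(f"only {n} features (< min_size={min_size}); all grey")
        return {f: GREY for f in feature_ids}, pd.DataFrame(columns=range(values.shape[1]))
    d = np.asarray(tom_diss, dtype=float)
    d = 0.5 * (d + d.T)
    np.fill_diagonal(d, 0.0)
    link = hierarchy.linkage(squareform(d, checks=False), method="average")
    labels = hierarchy.fcluster(link, t=cut_height, criterion="distance")

    clusters: dict[int, list[str]] = {}
    for f, lab in zip(feature_ids, labels):
        clusters.setdefault(int(lab), []).append(f)
    groups = [members for members in clusters.values() if len(members) >= min_size]

    def build_assignment(groups: list[list[str]]) -> dict[str, str]:
        ordered = sorted(groups, key=lambda g: (-len(g), g[0]))
        assign = {f: GREY for f in feature_ids}
        for idx, members in enumerate(ordered):
            color = (
                MODULE_COLORS[idx]
                if idx < len(MODULE_COLORS)
                else f"module{idx + 1}"
            )
            for f in members:
                assign[f] = color
        return assign

    # iterative eigengene-based merging at the given height
    while len(groups) > 1:
        assign = build_assignment(groups)
        me, _ = eigengenes(values, feature_ids, assign)
        mods = list(me.index)
        cor = np.corrcoef(me.to_numpy())
        np.fill_diagonal(cor, -np.inf)
        i, j = np.unravel_index(np.argmax(cor), cor.shape)
        if 1.0 - cor[i, j] >= merge_height:
            break
        mi, mj = mods[i], mods[j]
        by_color = {assign[g[0]]: g for g in groups}
        merged = by_color[mi] + by_color[mj]
        groups = [g for g in groups if assign[g[0]] not in (mi, mj)] + [merged]

    assign = build_assignment(groups)
    if groups:
        me, _ = eigengenes(values, feature_ids, assign)
    else:
        me = pd.DataFrame(columns=range(values.shape[1]))
    return assign, me


def module_membership(
    values: np.ndarray, feature_ids: list[str], me: pd.DataFrame
) -> pd.DataFrame:
    """MM = correlation of every feature with every module eigengene."""
    out = {}
    for mod in me.index:
        out[mod] = _corr_with_vector(values, me.loc[mod].to_numpy())
    return pd.DataFrame(out, index=feature_ids)


def module_hubs(mm: pd.DataFrame, assignment: dict[str, str]) -> dict[str, str]:
    """Per module, the member feature with the highest MM (ties by feature id)."""
    hubs: dict[str, str] = {}
    for mod in mm.columns:
        members = sorted(f for f, m in assignment.items() if m == mod)
        if not members:
            continue
        hubs[mod] = min(members, key=lambda f: (-mm.loc[f, mod], f))
    return hubs
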