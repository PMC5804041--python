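"""Phenotypic impact factor (PIF) and regulatory impact factors (RIF1/RIF2).

All scores work on log2-normalized expression.  With per-feature group means
mu_H and mu_L, average abundance a = (mu_H + mu_L) / 2 and differential
expression d = mu_H - mu_L:

* PIF_j = a_j * d_j weights a feature's contribution to the phenotype
  contrast by both abundance and change;
* RIF1_i = mean over DE features j of PIF_j * (r_Hij - r_Lij)^2 scores the
  differential wiring of regulator i to the DE features;
* RIF2_i = mean over DE features j of (mu_Hj * r_Hij)^2 - (mu_Lj * r_Lij)^2
  scores the change in the regulator's predictive hold on DE expression.

Raw and z-standardized (over scored regulators) values are both reported,
since the two RIF scales are not comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import ExpressionMatrix, PhenotypeTable

__all__ = ["GroupMeans", "group_means", "pif", "rif_scores", "rank_regulators"]


@dataclass
class GroupMeans:
    """Per-feature mean log2 expression by group, with a = (mu_H+mu_L)/2, d = mu_H-mu_L."""

    feature_ids: list[str]
    mu_h: np.ndarray
    mu_l: np.ndarray

    @property
    def abundance(self) -> np.ndarray:
        return 0.5 * (self.mu_h + self.mu_l)

    @property
    def difference(self) -> np.ndarray:  # High minus Low
        return self.mu_h - self.mu_l


def group_means(expr: ExpressionMatrix, pheno: PhenotypeTable) -> GroupMeans:
    sample_pos = {s: i for i, s in enumerate(expr.sample_ids)}
    idx_h = [sample_pos[s] for s in pheno.samples_in_group("H")]
    idx_l = [sample_pos[s] for s in pheno.samples_in_group("L")]
    return GroupMeans(
        list(expr.feature_ids),
        expr.values[:, idx_h].mean(axis=1),
        expr.values[:, idx_l].mean(axis=1),
    )


def pif(means: GroupMeans) -> pd.Series:
    """PIF_j = average abundance times High-Low expression difference."""
    return pd.Series(means.abundance * means.difference, index=means.feature_ids, name="pif")


def _rows_vs_columns_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row of ``a`` with each row of ``b`` (over columns)."""
    az = a - a.mean(axis=1, keepdims=True)
    bz = b - b.mean(axis=1, keepdims=True)
    asd = np.sqrt((az**2).sum(axis=1))
    bsd = np.sqrt((bz**2).sum(axis=1))
    asd = np.where(asd == 0, np.inf, asd)
    bsd = np.where(bsd == 0, np.inf, bsd)
    return np.clip((az @ bz.T) / np.outer(asd, bsd), -1.0, 1.0)


def rif_scores(
    expr: ExpressionMatrix,
    pheno: PhenotypeTable,
    regulators: list[str],
    de_features: list[str],
    pif_values: pd.Series | None = None,
) -> pd.DataFrame:
    """RIF1 and RIF2 (raw and z-standardized) for each candidate regulator.

    ``de_features`` is normally the FDR<=0.10 set from the DE stage.  PIF
    weights default to those computed from the same expression matrix.
    """
    if not de_features:
        raise ValueError("RIF undefined without DE features")
    missing = [f for f in list(regulators) + list(de_features) if f not in set(expr.feature_ids)]
    if missing:
        raise KeyError(f"features absent from expression matrix: {missing[:5]!r}")
    means = group_means(expr, pheno)
    if pif_values is None:
        pif_values = pif(means)
    mu = pd.DataFrame(
        {"mu_h": means.mu_h, "mu_l": means.mu_l}, index=means.feature_ids
    ).loc[de_features]

    reg_expr = expr.subset_features(regulators)
    de_expr = expr.subset_features(de_features)
    out = {}
    for grp in ("H", "L"):
        samples = pheno.samples_in_group(grp)
        r = _rows_vs_columns_corr(
            reg_expr.subset_samples(samples).values, de_expr.subset_samples(samples).values
        )
        out[grp] = r
    r_h, r_l = out["H"], out["L"]

    weights = pif_values.loc[de_features].to_numpy()
    rif1 = np.mean(weights[None, :] * (r_h - r_l) ** 2, axis=1)
    rif2 = np.mean(
        (mu["mu_h"].to_numpy()[None, :] * r_h) ** 2
        - (mu["mu_l"].to_numpy()[None, :] * r_l) ** 2,
        axis=1,
    )
    reg_pif = pif_values.loc[regulators].to_numpy()

    def zscore(x: np.ndarray) -> np.ndarray:
        sd = np.std(x)
        return (x - np.mean(x)) / sd if sd > 0 else np.zeros_like(x)

    return pd.DataFrame(
        {
            "feature": regulators,
            "pif": reg_pif,
            "rif1": rif1,
            "rif2": rif2,
            "rif1_z": zscore(rif1),
            "rif2_z": zscore(rif2),
        }
    )


def rank_regulators(scores: pd.DataFrame, k: int = 10) -> dict[str, pd.DataFrame]:
    """Top-k most positive and most negative regulators by PIF, RIF1 and RIF2.

    Deterministic: ties are broken by feature id.  Returns a dict keyed by
    ``"<score>_top_positive"`` / ``"<score>_top_negative"``.
    """
    out: dict[str, pd.DataFrame] = {}
    for col in ("pif", "rif1", "rif2"):
        asc = scores.sort_values([col, "feature"], ascending=[True, True])
        desc = scores.sort_values([col, "feature"], ascending=[False, True])
        out[f"{col}_top_positive"] = desc.head(k).reset_index(drop=True)
        out[f"{col}_top_negative"] = asc.head(k).reset_index(drop=True)
    return out
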