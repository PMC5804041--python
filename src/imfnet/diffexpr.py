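"""Library-size normalization and negative-binomial differential expression.

Normalization uses the median-of-ratios size factors classical for bulk
count data.  The DE test fits, per feature, a log-link negative-binomial
regression of counts on group plus optional covariates (age as a numeric
covariate, contemporary group one-hot encoded), with the log size factor as
offset.  Dispersion is estimated per feature by matching the NB Pearson
statistic to its residual degrees of freedom (method of moments); no
information is shared across features.  The group coefficient is tested with
a Wald statistic referred to a t distribution on ``n - p`` degrees of
freedom, a standard small-sample correction.  The group indicator codes the
Low group as 1, so the reported log2 fold change is Low relative to High and
negative values mean lower expression in the Low group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_model import CountMatrix, ExpressionMatrix, PhenotypeTable

__all__ = ["size_factors", "normalize", "de_test", "bh_adjust", "DeTable"]

_MAX_IRLS = 50
_TOL = 1e-8


def size_factors(counts: CountMatrix, allow_pseudo_reference: bool = False) -> np.ndarray:
    """Median-of-ratios size factors, normalized to geometric mean 1.

    Each sample's factor is the median over features of count / geometric
    feature mean, computed over features with positive counts in every
    sample.  With ``allow_pseudo_reference`` the geometric mean is instead
    taken over positive entries only, a fallback for sparse data.
    """
    y = counts.values.astype(float)
    all_positive = np.all(y > 0, axis=1)
    if not allow_pseudo_reference:
        if not np.any(all_positive):
            raise ValueError(
                "no feature has positive counts in all samples; "
                "retry with allow_pseudo_reference=True"
            )
        ref = y[all_positive]
        log_geo = np.mean(np.log(ref), axis=1)
        ratios = np.log(ref) - log_geo[:, None]
    else:
        with np.errstate(divide="ignore"):
            logs = np.where(y > 0, np.log(y), np.nan)
        log_geo = np.nanmean(logs, axis=1)
        ratios = logs - log_geo[:, None]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        log_factors = np.nanmedian(ratios, axis=0)
    if np.any(~np.isfinite(log_factors)):
        raise ValueError("size factors undefined for at least one sample")
    log_factors = log_factors - np.mean(log_factors)  # geometric mean 1
    return np.exp(log_factors)


def normalize(
    counts: CountMatrix, factors: np.ndarray, pseudocount: float = 1.0
) -> ExpressionMatrix:
    """log2(count / size factor + pseudocount)."""
    factors = np.asarray(factors, dtype=float)
    if np.any(factors <= 0):
        raise ValueError("size factors must be positive")
    if factors.shape != (counts.n_samples,):
        raise ValueError("one size factor per sample required")
    values = np.log2(counts.values / factors[None, :] + pseudocount)
    return ExpressionMatrix(
        values,
        list(counts.feature_ids),
        list(counts.sample_ids),
        factors,
        pseudocount,
        counts.layer,
    )


def denormalize(expr: ExpressionMatrix) -> np.ndarray:
    """Invert :func:`normalize` back to normalized counts (count / factor)."""
    return np.exp2(expr.values) - expr.pseudocount


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def _design_matrix(
    pheno: PhenotypeTable, covariates: tuple[str, ...]
) -> tuple[np.ndarray, list[str]]:
    """Intercept + Low-group indicator + covariate columns (categoricals one-hot)."""
    n = len(pheno.frame)
    cols: list[np.ndarray] = [np.ones(n), (pheno.groups == "L").to_numpy(dtype=float)]
    names = ["intercept", "group_L"]
    for cov in covariates:
        col = pheno.column(cov)
        if pd.api.types.is_numeric_dtype(col):
            x = col.to_numpy(dtype=float)
            sd = np.std(x)
            cols.append((x - np.mean(x)) / sd if sd > 0 else np.zeros(n))
            names.append(cov)
        else:
            levels = sorted(col.astype(str).unique())
            for lev in levels[1:]:
                ind = (col.astype(str) == lev).to_numpy(dtype=float)
                for g in ("H", "L"):
                    in_g = ind[(pheno.groups == g).to_numpy()]
                    if in_g.sum() == ind.sum() and ind.sum() > 0:
                        warnings.warn(
                            f"covariate level {cov}={lev} occurs in group {g} only; "
                            "its effect is confounded with group"
                        )
                cols.append(ind)
                names.append(f"{cov}_{lev}")
    return np.column_stack(cols), names


def _batched_wls(X: np.ndarray, w: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Solve per-feature weighted least squares for shared design X.

    ``w`` and ``z`` are (features, samples); returns betas (features, p).
    """
    Xw = w[:, :, None] * X[None, :, :]  # (F, n, p)
    A = np.einsum("fnp,nq->fpq", Xw, X)
    b = np.einsum("fnp,fn->fp", Xw, z)
    return np.linalg.solve(A, b[:, :, None])[:, :, 0]


def _pearson_dispersion(y: np.ndarray, mu: np.ndarray, df_resid: int) -> np.ndarray:
    """Per-feature NB dispersion alpha matching the Pearson chi-square to df.

    Solves sum_j (y - mu)^2 / (mu + alpha mu^2) = df by bisection; alpha = 0
    when the Poisson Pearson statistic is already at or below df.
    """
    resid2 = (y - mu) ** 2

    def pearson(alpha: np.ndarray) -> np.ndarray:
        return np.sum(resid2 / (mu + alpha[:, None] * mu**2), axis=1)

    alpha = np.zeros(y.shape[0])
    need = pearson(alpha) > df_resid
    if not np.any(need):
        return alpha
    lo = np.zeros(need.sum())
    hi = np.full(need.sum(), 1e-4)
    sub_r2, sub_mu = resid2[need], mu[need]

    def pearson_sub(a: np.ndarray) -> np.ndarray:
        return np.sum(sub_r2 / (sub_mu + a[:, None] * sub_mu**2), axis=1)

    # grow hi until the statistic drops below df (alpha capped at 100)
    for _ in range(22):
        still = pearson_sub(hi) > df_resid
        if not np.any(still):
            break
        hi[still] = np.minimum(hi[still] * 10, 100.0)
        if np.all(hi >= 100.0):
            break
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        high_stat = pearson_sub(mid) > df_resid
        lo = np.where(high_stat, mid, lo)
        hi = np.where(high_stat, hi, mid)
    alpha[need] = 0.5 * (lo + hi)
    return alpha


@dataclass
class DeTable:
    """Per-feature DE results (see :func:`de_test`)."""

    frame: pd.DataFrame
    design_columns: list[str]

    @property
    def de_features(self) -> list[str]:
        return list(self.frame.loc[self.frame["de_flag"], "feature"])


def de_test(
    counts: CountMatrix,
    pheno: PhenotypeTable,
    covariates: tuple[str, ...] = (),
    fdr: float = 0.10,
    factors: np.ndarray | None = None,
) -> DeTable:
    """Negative-binomial Wald test of the group effect for every feature.

    Returns a table with per-group mean normalized counts, log2 fold change
    (Low relative to High), raw p, BH-adjusted q and the DE flag at the given
    FDR.  All-zero or non-converged features are flagged untestable with
    ``p = 1`` and ``log2fc = 0``.
    """
    if list(pheno.sample_ids) != list(counts.sample_ids):
        order = {s: i for i, s in enumerate(counts.sample_ids)}
        missing = [s for s in pheno.sample_ids if s not in order]
        if missing or len(pheno.sample_ids) != counts.n_samples:
            raise ValueError("phenotype and count samples do not match")
        idx = [order[s] for s in pheno.sample_ids]
        counts = CountMatrix(
            counts.values[:, idx], list(counts.feature_ids), list(pheno.sample_ids), counts.layer
        )
    if factors is None:
        factors = size_factors(counts)
    X, design_names = _design_matrix(pheno, covariates)
    n, p = X.shape
    if n <= p:
        raise ValueError("more design columns than samples")
    df_resid = n - p
    group_col = design_names.index("group_L")

    y = counts.values.astype(float)
    F = y.shape[0]
    offset = np.log(np.asarray(factors, dtype=float))[None, :]
    norm = y / np.asarray(factors, dtype=float)[None, :]
    is_low = (pheno.groups == "L").to_numpy()
    mean_low = norm[:, is_low].mean(axis=1)
    mean_high = norm[:, ~is_low].mean(axis=1)

    testable = y.sum(axis=1) > 0
    log2fc = np.zeros(F)
    pvals = np.ones(F)
    converged = np.ones(F, dtype=bool)

    if np.any(testable):
        yt = y[testable]
        # initialize on the log scale, then IRLS
        z0 = np.log(yt + 0.5) - offset
        beta = np.linalg.lstsq(X, z0.T, rcond=None)[0].T  # (F, p)

        def irls(beta: np.ndarray, alpha: np.ndarray | None):
            ok = np.ones(beta.shape[0], dtype=bool)
            mu = None
            for _ in range(_MAX_IRLS):
                eta = beta @ X.T + offset
                eta = np.clip(eta, -30, 30)
                mu = np.exp(eta)
                if alpha is None:
                    w = mu
                else:
                    w = mu / (1.0 + alpha[:, None] * mu)
                z = (eta - offset) + (yt - mu) / mu
                try:
                    new_beta = _batched_wls(X, w, z)
                except np.linalg.LinAlgError:
                    # fall back to per-feature pinv on singular systems
                    new_beta = beta.copy()
                    for i in range(beta.shape[0]):
                        Xw = w[i][:, None] * X
                        A = X.T @ (w[i][:, None] * X)
                        try:
                            new_beta[i] = np.linalg.solve(A, Xw.T @ z[i])
                        except np.linalg.LinAlgError:
                            ok[i] = False
                step = np.max(np.abs(new_beta - beta), axis=1)
                beta = new_beta
                if np.max(step) < _TOL:
                    break
            bad = ~np.isfinite(beta).all(axis=1)
            ok &= ~bad
            eta = np.clip(beta @ X.T + offset, -30, 30)
            return beta, np.exp(eta), ok

        beta, mu, ok1 = irls(beta, None)  # Poisson stage to get mu for dispersion
        alpha = _pearson_dispersion(yt, mu, df_resid)
        beta, mu, ok2 = irls(beta, alpha)
        ok = ok1 & ok2

        w = mu / (1.0 + alpha[:, None] * mu)
        Xw = w[:, :, None] * X[None, :, :]
        A = np.einsum("fnp,nq->fpq", Xw, X)
        with np.errstate(invalid="ignore"):
            cov = np.linalg.pinv(A)
        se = np.sqrt(np.maximum(cov[:, group_col, group_col], 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = np.where(se > 0, beta[:, group_col] / se, 0.0)
        pv = 2.0 * stats.t.sf(np.abs(tstat), df=df_resid)
        pv = np.where(ok & np.isfinite(pv), pv, 1.0)
        lfc = np.where(ok, beta[:, group_col] / np.log(2.0), 0.0)

        log2fc[testable] = lfc
        pvals[testable] = pv
        conv = np.ones(F, dtype=bool)
        conv[testable] = ok
        converged = conv

    qvals = bh_adjust(pvals)
    frame = pd.DataFrame(
        {
            "feature": counts.feature_ids,
            "mean_low": mean_low,
            "mean_high": mean_high,
            "log2fc": log2fc,
            "pvalue": pvals,
            "qvalue": qvals,
            "de_flag": qvals <= fdr,
            "untestable": ~testable | ~converged,
        }
    )
    frame.loc[frame["untestable"], "de_flag"] = False
    return DeTable(frame, design_names)
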