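"""In-vitro candidate screening on log2 expression matrices.

Cells are exposed to three ordered LDL conditions (native < moderately
oxidized < highly oxidized); candidate miRNAs are those that respond to
oxidation.  Differential expression against the native condition uses
empirical-Bayes moderated t-statistics (per-feature variances shrunk toward
a common prior fitted by method of moments on the scaled-F distribution of
sample variances), dose-response shape is tested with orthogonal
linear/quadratic polynomial contrasts across the three conditions, and the
selection rule combines effect size, significance and trend.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "fit_variance_prior",
    "moderated_t",
    "trend_test",
    "select_candidates",
    "screen",
    "cross_platform_correlation",
]

CONDITIONS = ("nLDL", "moxLDL", "hoxLDL")
LINEAR_CONTRAST = np.array([-1.0, 0.0, 1.0])
QUADRATIC_CONTRAST = np.array([1.0, -2.0, 1.0])


def _trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if -dif / x < tol:
            break
    return float(x)


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Fit the prior (d0, s0^2) of the scaled-F model s2 ~ s0^2 * F(df, d0).

    Method of moments on log s2: the mean and excess variance of
    log(s2) - digamma(df/2) + log(df/2) identify s0^2 and trigamma(d0/2).
    Returns (inf, exp(mean)) when the empirical spread is no larger than
    the sampling spread (all features share one variance).
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if len(s2) < 2:
        raise ValueError("need at least two positive sample variances")
    e = np.log(s2) - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_2 = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0, s0_2 = np.inf, np.exp(emean)
    return float(d0), float(s0_2)


def _group_stats(values: pd.DataFrame, labels: pd.Series):
    """Per-group means and the pooled one-way residual variance per feature."""
    labels = labels.reindex(values.columns)
    groups = list(pd.unique(labels))
    n = values.shape[1]
    means = {}
    ss = np.zeros(values.shape[0])
    for g in groups:
        cols = labels.index[labels == g]
        if len(cols) < 2:
            raise ValueError(f"condition {g!r} has fewer than 2 replicates")
        block = values[cols].to_numpy(dtype=float)
        mu = block.mean(axis=1)
        means[g] = mu
        ss += ((block - mu[:, None]) ** 2).sum(axis=1)
    df_resid = n - len(groups)
    if df_resid < 1:
        raise ValueError("zero residual degrees of freedom")
    return means, ss / df_resid, df_resid, {g: int((labels == g).sum()) for g in groups}


def moderated_t(
    values: pd.DataFrame,
    labels: pd.Series,
    contrast: tuple[str, str],
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Moderated two-group contrast per feature.

    ``values`` is features x samples log2 expression; ``labels`` assigns
    each sample column to a condition; ``contrast=(A, B)`` tests A - B.
    The residual variance comes from the full one-way layout; the posterior
    variance is (d0*s0^2 + d*s^2)/(d0 + d) with (d0, s0^2) fitted across
    features (or forced via ``prior_df``; 0 recovers the ordinary t-test,
    inf pools every feature to s0^2).

    Returns a DataFrame with log2fc, t, p, and the fitted prior in attrs.
    """
    a, b = contrast
    means, s2, d, counts = _group_stats(values, labels)
    if a not in means or b not in means:
        raise ValueError(f"contrast {contrast} not present in labels")
    if prior_df is None:
        d0, s0_2 = fit_variance_prior(s2, d)
    elif prior_df == 0:
        d0, s0_2 = 0.0, np.nan
    elif np.isinf(prior_df):
        d0, s0_2 = np.inf, fit_variance_prior(s2, d)[1]
    else:
        d0, s0_2 = float(prior_df), fit_variance_prior(s2, d)[1]

    if d0 == 0:
        s2_post = s2
        df_total = d
    elif np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_2 + d * s2) / (d0 + d)
        df_total = d0 + d
    fc = means[a] - means[b]
    se = np.sqrt(s2_post * (1.0 / counts[a] + 1.0 / counts[b]))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = fc / se
    if np.isinf(df_total):
        p = 2 * stats.norm.sf(np.abs(t))
    else:
        p = 2 * stats.t.sf(np.abs(t), df=df_total)
    out = pd.DataFrame({"log2fc": fc, "t": t, "p": p}, index=values.index)
    out.attrs["prior_df"] = d0
    out.attrs["prior_var"] = s0_2
    out.attrs["residual_df"] = d
    return out


def trend_test(values: pd.DataFrame, condition: pd.Series) -> pd.DataFrame:
    """Orthogonal-polynomial trend tests across the three ordered conditions.

    Per feature, a Gaussian linear model with linear (-1, 0, +1) and
    quadratic (+1, -2, +1) contrasts on the ordered condition index is
    fitted by least squares; returns the two contrast estimates and their
    two-sided p-values.
    """
    condition = condition.reindex(values.columns)
    missing = [c for c in CONDITIONS if (condition == c).sum() == 0]
    if missing:
        raise ValueError(f"conditions absent from data: {missing}")
    idx = condition.map({c: i for i, c in enumerate(CONDITIONS)}).to_numpy()
    X = np.column_stack(
        [np.ones(len(idx)), LINEAR_CONTRAST[idx], QUADRATIC_CONTRAST[idx]]
    )
    Y = values.to_numpy(dtype=float).T  # samples x features
    df_resid = X.shape[0] - X.shape[1]
    if df_resid < 1:
        raise ValueError("need more samples than model parameters")
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ Y  # 3 x features
    resid = Y - X @ beta
    s2 = (resid**2).sum(axis=0) / df_resid
    out = {}
    for name, k in (("linear", 1), ("quadratic", 2)):
        se = np.sqrt(s2 * XtX_inv[k, k])
        with np.errstate(divide="ignore", invalid="ignore"):
            t = beta[k] / se
        out[f"{name}_estimate"] = beta[k]
        out[f"trend_p_{name}"] = 2 * stats.t.sf(np.abs(t), df=df_resid)
    return pd.DataFrame(out, index=values.index)


def select_candidates(
    screen_table: pd.DataFrame,
    fc_min: float = 1.5,
    alpha: float = 0.05,
) -> list[str]:
    """Apply the candidate-selection rule and return selected feature names.

    A feature is selected in a cell type when (|fold change| >= ``fc_min``
    on the natural scale AND p < ``alpha``) in the moxLDL-vs-nLDL or the
    hoxLDL-vs-nLDL contrast, AND its linear or quadratic trend p < ``alpha``.
    Selection in at least one cell type suffices.  P-values are unadjusted.
    """
    log2_min = np.log2(fc_min)
    t = screen_table
    contrast_ok = (
        ((t["log2fc_mox"].abs() >= log2_min) & (t["p_mox"] < alpha))
        | ((t["log2fc_hox"].abs() >= log2_min) & (t["p_hox"] < alpha))
    )
    trend_ok = (t["trend_p_linear"] < alpha) | (t["trend_p_quadratic"] < alpha)
    selected = contrast_ok & trend_ok
    t = t.assign(selected=selected)
    hits = t.loc[t["selected"], "feature"]
    # preserve first-appearance order while deduplicating across cell types
    return list(dict.fromkeys(hits))


def screen(
    values: pd.DataFrame,
    condition: pd.Series,
    cell_type: pd.Series,
    fc_min: float = 1.5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Full screen: per cell type, moderated contrasts vs nLDL plus trend
    tests, assembled into one table with the selection flag."""
    rows = []
    for ct in pd.unique(cell_type):
        cols = cell_type.index[cell_type == ct]
        vals = values[cols]
        labels = condition.loc[cols]
        mox = moderated_t(vals, labels, ("moxLDL", "nLDL"))
        hox = moderated_t(vals, labels, ("hoxLDL", "nLDL"))
        trend = trend_test(vals, labels)
        part = pd.DataFrame(
            {
                "feature": vals.index,
                "cell_type": ct,
                "log2fc_mox": mox["log2fc"].to_numpy(),
                "p_mox": mox["p"].to_numpy(),
                "log2fc_hox": hox["log2fc"].to_numpy(),
                "p_hox": hox["p"].to_numpy(),
                "trend_p_linear": trend["trend_p_linear"].to_numpy(),
                "trend_p_quadratic": trend["trend_p_quadratic"].to_numpy(),
            }
        )
        rows.append(part)
    out = pd.concat(rows, ignore_index=True)
    log2_min = np.log2(fc_min)
    out["selected"] = (
        ((out["log2fc_mox"].abs() >= log2_min) & (out["p_mox"] < alpha))
        | ((out["log2fc_hox"].abs() >= log2_min) & (out["p_hox"] < alpha))
    ) & ((out["trend_p_linear"] < alpha) | (out["trend_p_quadratic"] < alpha))
    return out


def cross_platform_correlation(
    array_summary: pd.Series, delta_ct_summary: pd.Series
) -> tuple[float, float]:
    """Spearman correlation of per-feature array expression vs qPCR ΔCt.

    Matched on the shared feature index; needs at least 3 matched features.
    Higher expression should give lower ΔCt, so the expected sign is
    negative.
    """
    common = array_summary.index.intersection(delta_ct_summary.index)
    if len(common) < 3:
        raise ValueError("need at least 3 matched features")
    a = array_summary.loc[common].to_numpy(dtype=float)
    b = delta_ct_summary.loc[common].to_numpy(dtype=float)
    if np.all(a == a[0]) or np.all(b == b[0]):
        raise ValueError("constant vector: Spearman correlation undefined")
    rho, p = stats.spearmanr(a, b)
    return float(rho), float(p)
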