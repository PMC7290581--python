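"""Case-control differential expression on ΔCt with non-detects as
right-censored observations.

A non-detect means the reaction never crossed threshold: the true Ct (hence
ΔCt) lies above everything observed.  Pinning missing values at the
per-miRNA maximum observed ΔCt therefore makes them right-censored on the
ΔCt axis, and group means and two-group comparisons become survival-type
statistics: the Kaplan–Meier restricted mean and the log-rank test, with
ΔCt playing the role of time.  Fold change between groups is
2^(-(mean_case - mean_control)), so FC > 1 means higher expression in cases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test as _ll_logrank
from statsmodels.stats.multitest import multipletests

from .ct import DeltaCtMatrix

__all__ = [
    "CensoredVector",
    "censor_nondetects",
    "km_restricted_mean",
    "logrank_test",
    "fold_change",
    "bh_adjust",
    "run_case_control",
]


@dataclass
class CensoredVector:
    """Per-miRNA ΔCt observations with right-censoring flags and group labels."""

    value: np.ndarray
    censored: np.ndarray
    group: np.ndarray

    def __post_init__(self) -> None:
        self.value = np.asarray(self.value, dtype=float)
        self.censored = np.asarray(self.censored, dtype=bool)
        self.group = np.asarray(self.group)
        if not (len(self.value) == len(self.censored) == len(self.group)):
            raise ValueError("value, censored and group must have equal length")

    def subset(self, mask: np.ndarray) -> "CensoredVector":
        return CensoredVector(self.value[mask], self.censored[mask], self.group[mask])


def censor_nondetects(
    delta_ct: np.ndarray | pd.Series,
    missing: np.ndarray | pd.Series | None = None,
    group: np.ndarray | pd.Series | None = None,
) -> CensoredVector:
    """Pin non-detects at the per-miRNA maximum observed ΔCt, flagged censored.

    ``missing`` defaults to the NaN pattern of ``delta_ct``.
    """
    v = np.asarray(delta_ct, dtype=float)
    miss = np.isnan(v) if missing is None else np.asarray(missing, dtype=bool)
    if miss.all():
        raise ValueError("miRNA has no observed values; it should have been filtered")
    cmax = np.max(v[~miss])
    out = np.where(miss, cmax, v)
    g = np.zeros(len(v)) if group is None else np.asarray(group)
    return CensoredVector(out, miss.copy(), g)


def km_restricted_mean(v: CensoredVector) -> float:
    """Kaplan–Meier restricted mean of a single-group censored vector.

    The product-limit survivor estimate is built on the ΔCt axis (censored
    observations at a tied value remain at risk there, i.e. events precede
    censorings at ties) and integrated from the smallest to the largest
    observation; the restricted mean is that area plus the minimum.  With no
    censoring this equals the arithmetic mean exactly.
    """
    vals, cens = v.value, v.censored
    if cens.all():
        raise ValueError("restricted mean undefined: all observations censored")
    tmin = float(vals.min())
    tmax = float(vals.max())
    if tmax == tmin:
        return tmin
    ev_vals = np.unique(vals[~cens])
    # deaths and at-risk counts at each distinct event value
    d = np.array([np.sum((vals == t) & ~cens) for t in ev_vals], dtype=float)
    n_risk = np.array([np.sum(vals >= t) for t in ev_vals], dtype=float)
    surv = np.cumprod(1.0 - d / n_risk)
    pts = np.concatenate([[tmin], ev_vals, [tmax]])
    seg_s = np.concatenate([[1.0], surv])  # survivor value on [pts[i], pts[i+1])
    return tmin + float(np.sum(seg_s * np.diff(pts)))


def logrank_test(v: CensoredVector) -> tuple[float, float]:
    """Two-group log-rank test on the ΔCt axis.

    Returns (chi-square with 1 df, p-value).  Ties are handled by the
    standard hypergeometric-variance formulation.
    """
    groups = pd.unique(v.group)
    if len(groups) != 2:
        raise ValueError(f"log-rank test needs exactly 2 groups, got {len(groups)}")
    a = v.group == groups[0]
    for mask in (a, ~a):
        if v.censored[mask].all():
            raise ValueError("each group needs at least one uncensored observation")
    shift = v.value.min()  # log-rank is shift-invariant; keep durations >= 0
    res = _ll_logrank(
        v.value[a] - shift,
        v.value[~a] - shift,
        event_observed_A=~v.censored[a],
        event_observed_B=~v.censored[~a],
    )
    return float(res.test_statistic), float(res.p_value)


def fold_change(mean_case: float, mean_control: float) -> float:
    """Fold change 2^(-(mean_case - mean_control)) on the ΔCt scale."""
    return float(2.0 ** (-(mean_case - mean_control)))


def bh_adjust(p: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def run_case_control(
    delta: DeltaCtMatrix,
    groups: pd.Series,
    case_label: str = "case",
    control_label: str = "control",
) -> pd.DataFrame:
    """Per-miRNA censored fold-change analysis between cases and controls.

    For each miRNA: non-detects are censored at the maximum observed ΔCt,
    group means are KM restricted means, the p-value comes from the log-rank
    test, and p-values are BH-adjusted across all analyzed miRNAs.  Per-miRNA
    failures (e.g. a group fully censored) become flagged rows rather than
    aborting the scan.  Rows are sorted by adjusted p.
    """
    groups = groups.reindex(delta.values.index)
    if groups.isna().any():
        raise ValueError("every sample needs a group label")
    rows = []
    for m in delta.values.columns:
        col = delta.values[m]
        rec: dict = {"mirna": m}
        try:
            cv = censor_nondetects(col.to_numpy(), group=groups.to_numpy())
            is_case = cv.group == case_label
            is_ctrl = cv.group == control_label
            mean_case = km_restricted_mean(cv.subset(is_case))
            mean_control = km_restricted_mean(cv.subset(is_ctrl))
            chisq, p = logrank_test(cv.subset(is_case | is_ctrl))
            rec.update(
                mean_case=mean_case,
                mean_control=mean_control,
                fold_change=fold_change(mean_case, mean_control),
                logrank_chisq=chisq,
                p=p,
                n_case=int(is_case.sum()),
                n_control=int(is_ctrl.sum()),
                n_censored=int(cv.censored.sum()),
                status="ok",
            )
        except ValueError as exc:
            rec.update(
                mean_case=np.nan,
                mean_control=np.nan,
                fold_change=np.nan,
                logrank_chisq=np.nan,
                p=np.nan,
                n_case=int((groups == case_label).sum()),
                n_control=int((groups == control_label).sum()),
                n_censored=int(col.isna().sum()),
                status=f"failed: {exc}",
            )
        rows.append(rec)
    out = pd.DataFrame(rows)
    ok = out["status"] == "ok"
    out["p_adj"] = np.nan
    if ok.any():
        out.loc[ok, "p_adj"] = bh_adjust(out.loc[ok, "p"].to_numpy())
    return out.sort_values("p_adj", na_position="last").reset_index(drop=True)
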