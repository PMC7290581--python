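"""Case-cohort weighted Cox proportional-hazards association.

A case-cohort sample contains every incident case plus a random subcohort
drawn from the full cohort.  Analyzing it as if it were a simple cohort
over-represents cases, so person-time is reweighted before fitting.  The
default is Barlow weighting: subcohort person-time while event-free counts
1/f (f = subcohort sampling fraction), each case counts weight 1 in the
risk set just before its own failure, and cases outside the subcohort
contribute no other person-time.  Prentice weighting (subcohort person-time
unweighted) is available behind a flag.

The weighted partial likelihood is maximized by Newton iteration with
Breslow tie handling on counting-process records (entry, stop] so the
split case records enter the risk set late.  Variances are robust
(Lin–Wei sandwich, clustered on subject, since a subject may contribute
two split records).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "CoxFit",
    "assign_casecohort_weights",
    "fit_weighted_cox",
    "run_mirna_scan",
]

_EPS_FRAC = 1e-6  # case risk-interval width, as a fraction of the max time


@dataclass
class CoxFit:
    """Summary of one weighted Cox fit (log-HRs, robust SEs, Wald CIs/p)."""

    coefficients: dict[str, float]
    robust_se: dict[str, float]
    n_events: int
    converged: bool
    baseline_cumhaz: pd.Series | None = field(default=None, repr=False)
    center: dict[str, float] | None = field(default=None, repr=False)

    @property
    def hr(self) -> dict[str, float]:
        return {k: float(np.exp(v)) for k, v in self.coefficients.items()}

    @property
    def ci95(self) -> dict[str, tuple[float, float]]:
        return {
            k: (
                float(np.exp(v - 1.96 * self.robust_se[k])),
                float(np.exp(v + 1.96 * self.robust_se[k])),
            )
            for k, v in self.coefficients.items()
        }

    @property
    def p(self) -> dict[str, float]:
        return {
            k: float(2 * norm.sf(abs(v / self.robust_se[k])))
            if self.robust_se[k] > 0
            else np.nan
            for k, v in self.coefficients.items()
        }

    def baseline_survival(self, horizon: float) -> float:
        """Breslow baseline survivor probability at ``horizon`` for a
        subject at the centering covariate values."""
        if self.baseline_cumhaz is None:
            raise ValueError("fit carries no baseline hazard")
        ch = self.baseline_cumhaz
        mask = ch.index <= horizon
        total = float(ch[mask].sum())
        return float(np.exp(-total))

    def predict_risk(self, covariates: pd.DataFrame, horizon: float) -> np.ndarray:
        """Absolute risk 1 - S0(h)^exp(lp - centered lp) at ``horizon``."""
        from .reclassify import predicted_risk

        return predicted_risk(
            self.coefficients, self.baseline_survival(horizon), covariates,
            center=self.center,
        )


def assign_casecohort_weights(
    records: pd.DataFrame,
    sampling_fraction: float | None = None,
    n_cohort: int | None = None,
    scheme: str = "barlow",
) -> pd.DataFrame:
    """Expand case-cohort records into weighted counting-process rows.

    ``records`` needs columns ``id``, ``time``, ``event``, ``in_subcohort``
    plus covariates.  The output has ``entry`` < ``stop`` intervals and a
    ``weight`` column, ready for :func:`fit_weighted_cox`:

    * subcohort non-case: one row (0, T] with weight 1/f (Barlow) or 1
      (Prentice);
    * case outside the subcohort: one row (T-ε, T] with weight 1 — it
      enters the risk set just before its own failure;
    * case inside the subcohort: an event-free row (0, T-ε] with weight
      1/f (Barlow) or 1 (Prentice), plus the failure row (T-ε, T] with
      weight 1.

    ``sampling_fraction`` defaults to subcohort size / ``n_cohort``.
    """
    if scheme not in ("barlow", "prentice"):
        raise ValueError(f"unknown weighting scheme {scheme!r}")
    req = {"id", "time", "event", "in_subcohort"}
    if not req.issubset(records.columns):
        raise ValueError(f"records must have columns {sorted(req)}")
    if not ((records["event"].astype(bool)) | (records["in_subcohort"].astype(bool))).all():
        raise ValueError("every record must be an event, a subcohort member, or both")
    if (records["time"] <= 0).any():
        raise ValueError("times must be positive")
    if sampling_fraction is None:
        if n_cohort is None:
            raise ValueError("supply sampling_fraction or n_cohort")
        sampling_fraction = records["in_subcohort"].astype(bool).sum() / n_cohort
    if not (0 < sampling_fraction <= 1):
        raise ValueError("sampling_fraction must be in (0, 1]")
    w_sub = 1.0 if scheme == "prentice" else 1.0 / sampling_fraction

    eps = _EPS_FRAC * float(records["time"].max())
    cov_cols = [c for c in records.columns if c not in req]
    ev = records["event"].astype(bool).to_numpy()
    sub = records["in_subcohort"].astype(bool).to_numpy()
    t = records["time"].to_numpy(dtype=float)

    def _block(mask, entry, stop, event, weight):
        blk = records.loc[mask, ["id", *cov_cols]].copy()
        blk["entry"] = entry
        blk["stop"] = stop
        blk["event"] = event
        blk["weight"] = weight
        return blk

    pre_mask = ev & sub & (t - eps > 0)
    parts = [
        # subcohort person-time while event-free
        _block(~ev, 0.0, t[~ev], 0, w_sub),
        _block(pre_mask, 0.0, t[pre_mask] - eps, 0, w_sub),
        # each case in the risk set just before, and at, its own failure
        _block(ev, np.maximum(t[ev] - eps, 0.0), t[ev], 1, 1.0),
    ]
    out = pd.concat(parts, ignore_index=True)
    cols = ["id", "entry", "stop", "event", "weight", *cov_cols]
    return out[cols]


def _newton_breslow(
    X: np.ndarray,
    entry: np.ndarray,
    stop: np.ndarray,
    event: np.ndarray,
    weight: np.ndarray,
    tol: float = 1e-9,
    max_iter: int = 100,
):
    """Maximize the weighted Breslow partial likelihood.

    Returns (beta, information matrix, baseline hazard increments at event
    times, convergence flag).  Risk set at event time t is entry < t <= stop.
    """
    n, p = X.shape
    ev_times = np.unique(stop[event])
    # per event time: weighted event count and weighted covariate sum
    d_w = np.empty(len(ev_times))
    xw_sum = np.empty((len(ev_times), p))
    risk_masks = []
    for k, t in enumerate(ev_times):
        at_ev = event & (stop == t)
        d_w[k] = weight[at_ev].sum()
        xw_sum[k] = (weight[at_ev, None] * X[at_ev]).sum(axis=0)
        risk_masks.append((entry < t) & (stop >= t))

    beta = np.zeros(p)
    ll_prev = -np.inf
    converged = False
    for _ in range(max_iter):
        ll = 0.0
        grad = np.zeros(p)
        info = np.zeros((p, p))
        for k in range(len(ev_times)):
            r = risk_masks[k]
            we = weight[r] * np.exp(X[r] @ beta)
            s0 = we.sum()
            s1 = we @ X[r]
            s2 = (we[:, None] * X[r]).T @ X[r]
            xbar = s1 / s0
            ll += xw_sum[k] @ beta - d_w[k] * np.log(s0)
            grad += xw_sum[k] - d_w[k] * xbar
            info += d_w[k] * (s2 / s0 - np.outer(xbar, xbar))
        step = np.linalg.solve(info, grad)
        # step-halving keeps the likelihood monotone
        alpha = 1.0
        while alpha > 1e-4:
            beta_new = beta + alpha * step
            if _breslow_ll(beta_new, X, risk_masks, weight, xw_sum, d_w) >= ll - 1e-12:
                break
            alpha /= 2.0
        beta = beta + alpha * step
        if abs(ll - ll_prev) < tol * (abs(ll) + 1.0):
            converged = True
            break
        ll_prev = ll
    # final quantities at the solution
    info = np.zeros((p, p))
    dlam = np.empty(len(ev_times))
    for k in range(len(ev_times)):
        r = risk_masks[k]
        we = weight[r] * np.exp(X[r] @ beta)
        s0 = we.sum()
        s1 = we @ X[r]
        s2 = (we[:, None] * X[r]).T @ X[r]
        xbar = s1 / s0
        info += d_w[k] * (s2 / s0 - np.outer(xbar, xbar))
        dlam[k] = d_w[k] / s0
    return beta, info, ev_times, dlam, risk_masks, converged


def _breslow_ll(beta, X, risk_masks, weight, xw_sum, d_w):
    ll = 0.0
    for k, r in enumerate(risk_masks):
        s0 = (weight[r] * np.exp(X[r] @ beta)).sum()
        ll += xw_sum[k] @ beta - d_w[k] * np.log(s0)
    return ll


def _robust_cov(X, entry, stop, event, weight, cluster, beta, info,
                ev_times, dlam, risk_masks):
    """Lin–Wei sandwich with score residuals summed within clusters."""
    n, p = X.shape
    resid = np.zeros((n, p))
    exb = np.exp(X @ beta)
    for k, t in enumerate(ev_times):
        r = risk_masks[k]
        we = weight[r] * exb[r]
        s0 = we.sum()
        xbar = (we @ X[r]) / s0
        at_ev = event & (stop == t)
        resid[at_ev] += weight[at_ev, None] * (X[at_ev] - xbar)
        resid[r] -= (weight[r] * exb[r] * dlam[k])[:, None] * (X[r] - xbar)
    df = pd.DataFrame(resid)
    df["_c"] = cluster
    U = df.groupby("_c").sum().to_numpy()
    meat = U.T @ U
    info_inv = np.linalg.inv(info)
    return info_inv @ meat @ info_inv


def fit_weighted_cox(
    weighted: pd.DataFrame,
    terms: list[str],
    robust: bool = True,
) -> CoxFit:
    """Fit the weighted Cox model over ``terms``.

    ``weighted`` is the output of :func:`assign_casecohort_weights` (or any
    frame with ``entry``/``stop``/``event``/``weight``/``id``).  Covariates
    are centered at their weighted means before fitting (improves
    conditioning; coefficients are unaffected), and the Breslow baseline
    hazard at that centering is stored for absolute-risk prediction.
    Robust sandwich variances are clustered on ``id``; ``robust=False``
    falls back to inverse-information variances.  Collinear or constant
    terms raise with a diagnostic.
    """
    terms = list(terms)
    if int(weighted["event"].sum()) < 1:
        raise ValueError("no events in the data")
    for t in terms:
        if weighted[t].nunique() <= 1:
            raise ValueError(f"term {t!r} has zero variance")
    Xraw = weighted[terms].to_numpy(dtype=float)
    if np.linalg.matrix_rank(Xraw - Xraw.mean(axis=0)) < len(terms):
        raise ValueError("collinear terms detected")

    w = weighted["weight"].to_numpy(dtype=float)
    center = (w @ Xraw) / w.sum()
    X = Xraw - center
    entry = weighted["entry"].to_numpy(dtype=float)
    stop = weighted["stop"].to_numpy(dtype=float)
    event = weighted["event"].to_numpy(dtype=bool)

    beta, info, ev_times, dlam, risk_masks, converged = _newton_breslow(
        X, entry, stop, event, w
    )
    if robust:
        cov = _robust_cov(X, entry, stop, event, w,
                          weighted["id"].to_numpy(), beta, info,
                          ev_times, dlam, risk_masks)
    else:
        cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    return CoxFit(
        coefficients={t: float(b) for t, b in zip(terms, beta)},
        robust_se={t: float(s) for t, s in zip(terms, se)},
        n_events=int(event.sum()),
        converged=bool(converged),
        baseline_cumhaz=pd.Series(dlam, index=ev_times),
        center={t: float(c) for t, c in zip(terms, center)},
    )


def run_mirna_scan(
    records: pd.DataFrame,
    mirnas: list[str],
    base_terms: list[str] = ("age", "sex"),
    full_terms: list[str] | None = None,
    sampling_fraction: float | None = None,
    n_cohort: int | None = None,
    scheme: str = "barlow",
    min_complete: int = 10,
) -> pd.DataFrame:
    """Per-miRNA weighted Cox scan with two adjustment sets.

    For each miRNA, records with a missing value for that miRNA are dropped
    (complete-case analysis), weights are assigned on the remaining records,
    and one model per adjustment set is fitted: ``base`` (age + sex + miRNA
    by default) and ``full`` (all classical risk factors + miRNA).  P-values
    get a per-scan, per-adjustment-set BH column.  miRNAs with fewer than
    ``min_complete`` complete cases, zero variance, or failed fits are
    flagged rather than fitted.
    """
    from .censored import bh_adjust

    if full_terms is None:
        full_terms = [
            c for c in ("age", "sex", "smoking", "cholesterol", "sbp", "diabetes")
            if c in records.columns
        ]
    adjustment_sets = {"base": list(base_terms), "full": list(full_terms)}
    rows = []
    for m in mirnas:
        for label, adj in adjustment_sets.items():
            rec: dict = {"mirna": m, "model": label, "n_events": 0}
            sub = records.dropna(subset=[m])
            if len(sub) < min_complete:
                rec["status"] = f"flagged: <{min_complete} complete cases"
                rec.update(coef=np.nan, se=np.nan, hr=np.nan, ci_low=np.nan,
                           ci_high=np.nan, p=np.nan)
                rows.append(rec)
                continue
            try:
                wdf = assign_casecohort_weights(
                    sub, sampling_fraction=sampling_fraction,
                    n_cohort=n_cohort, scheme=scheme,
                )
                fit = fit_weighted_cox(wdf, [*adj, m])
                rec.update(
                    coef=fit.coefficients[m], se=fit.robust_se[m],
                    hr=fit.hr[m], ci_low=fit.ci95[m][0], ci_high=fit.ci95[m][1],
                    p=fit.p[m], n_events=fit.n_events, status="ok",
                )
            except (ValueError, np.linalg.LinAlgError) as exc:
                rec["status"] = f"flagged: {exc}"
                rec.update(coef=np.nan, se=np.nan, hr=np.nan, ci_low=np.nan,
                           ci_high=np.nan, p=np.nan)
            rows.append(rec)
    out = pd.DataFrame(rows)
    out["p_adj"] = np.nan
    for label in adjustment_sets:
        ok = (out["model"] == label) & (out["status"] == "ok")
        if ok.any():
            out.loc[ok, "p_adj"] = bh_adjust(out.loc[ok, "p"].to_numpy())
    return out
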