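"""Incremental predictive value of a marker over a baseline risk model:
absolute 10-year risk, weighted Harrell concordance, continuous and
categorical net reclassification (NRI), integrated discrimination
improvement (IDI), and percentile-bootstrap confidence intervals.

All metrics accept per-subject weights so a case-cohort sample can stand in
for its cohort (subcohort non-cases carry inverse-sampling-fraction
weights).  NRI values are reported in percent; IDI on the probability
scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import substream

__all__ = [
    "RiskPair",
    "ReclassResult",
    "predicted_risk",
    "continuous_nri",
    "categorical_nri",
    "idi",
    "weighted_cindex",
    "bootstrap_ci",
]


@dataclass
class RiskPair:
    """Baseline and extended predicted risks with outcome, weight, and time."""

    risk_old: np.ndarray
    risk_new: np.ndarray
    event: np.ndarray
    weight: np.ndarray | None = None
    time: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.risk_old = np.asarray(self.risk_old, dtype=float)
        self.risk_new = np.asarray(self.risk_new, dtype=float)
        self.event = np.asarray(self.event, dtype=bool)
        n = len(self.risk_old)
        if self.weight is None:
            self.weight = np.ones(n)
        else:
            self.weight = np.asarray(self.weight, dtype=float)
        if self.time is not None:
            self.time = np.asarray(self.time, dtype=float)
        for arr in (self.risk_new, self.event, self.weight):
            if len(arr) != n:
                raise ValueError("all fields must have equal length")
        for r in (self.risk_old, self.risk_new):
            if ((r < 0) | (r > 1)).any():
                raise ValueError("risks must be probabilities in [0, 1]")
        if (self.weight <= 0).any():
            raise ValueError("weights must be positive")

    def take(self, idx: np.ndarray) -> "RiskPair":
        return RiskPair(
            self.risk_old[idx],
            self.risk_new[idx],
            self.event[idx],
            self.weight[idx],
            None if self.time is None else self.time[idx],
        )


@dataclass
class ReclassResult:
    metric: str
    estimate: float
    ci95: tuple[float, float] | None = None
    p: float | None = None
    n_boot: int = 0
    seed: int | None = None


def predicted_risk(
    coefficients: dict[str, float],
    baseline_survival_at_horizon: float,
    covariates: pd.DataFrame,
    center: dict[str, float] | None = None,
) -> np.ndarray:
    """Absolute risk 1 - S0(h)^exp(lp - lp_center) from a Cox model.

    ``baseline_survival_at_horizon`` is the baseline survivor probability at
    the prediction horizon for a subject at the centering covariate values
    (the training means by default in most Cox software).  ``center`` gives
    those means; omitted terms center at 0.
    """
    s0 = float(baseline_survival_at_horizon)
    if not (0 < s0 <= 1):
        raise ValueError("baseline survival must be in (0, 1]")
    lp = np.zeros(len(covariates))
    for term, beta in coefficients.items():
        x = covariates[term].to_numpy(dtype=float)
        mu = 0.0 if center is None else float(center.get(term, 0.0))
        lp += beta * (x - mu)
    return 1.0 - s0 ** np.exp(lp)


def _require_both_outcomes(pairs: RiskPair) -> None:
    if not pairs.event.any() or pairs.event.all():
        raise ValueError("need at least one event and one non-event")


def continuous_nri(pairs: RiskPair) -> float:
    """Continuous (category-free) NRI in percent.

    NRI = [P(up|event) - P(down|event)] + [P(down|non-event) - P(up|non-event)],
    where up/down mean the extended model's risk is greater/less than the
    baseline model's; exact ties count neither.  Probabilities are weighted.
    """
    _require_both_outcomes(pairs)
    up = pairs.risk_new > pairs.risk_old
    down = pairs.risk_new < pairs.risk_old
    if not up.any() and not down.any():
        warnings.warn("all risk pairs tied; NRI is 0", stacklevel=2)
    w = pairs.weight
    ev, ne = pairs.event, ~pairs.event
    p_up_ev = w[up & ev].sum() / w[ev].sum()
    p_dn_ev = w[down & ev].sum() / w[ev].sum()
    p_up_ne = w[up & ne].sum() / w[ne].sum()
    p_dn_ne = w[down & ne].sum() / w[ne].sum()
    return 100.0 * ((p_up_ev - p_dn_ev) + (p_dn_ne - p_up_ne))


def categorical_nri(pairs: RiskPair, cutoffs: list[float] = (0.10,)) -> float:
    """Categorical NRI in percent with risk categories cut at ``cutoffs``."""
    cutoffs = list(cutoffs)
    if any(not (0 < c < 1) for c in cutoffs):
        # cutting at 0 or 1 leaves a single category: nobody can move
        return 0.0
    if sorted(cutoffs) != cutoffs or len(set(cutoffs)) != len(cutoffs):
        raise ValueError("cutoffs must be strictly increasing")
    _require_both_outcomes(pairs)
    edges = np.array([0.0, *cutoffs, 1.0 + 1e-12])
    cat_old = np.digitize(pairs.risk_old, edges[1:-1], right=False)
    cat_new = np.digitize(pairs.risk_new, edges[1:-1], right=False)
    reclassed = RiskPair(
        risk_old=cat_old / max(len(edges) - 1, 1),
        risk_new=cat_new / max(len(edges) - 1, 1),
        event=pairs.event,
        weight=pairs.weight,
    )
    return continuous_nri(reclassed)


def idi(pairs: RiskPair) -> float:
    """Integrated discrimination improvement (difference of discrimination
    slopes): (mean new - old risk over events) - (same over non-events)."""
    _require_both_outcomes(pairs)
    w = pairs.weight
    ev, ne = pairs.event, ~pairs.event
    diff = pairs.risk_new - pairs.risk_old
    return float(
        np.average(diff[ev], weights=w[ev]) - np.average(diff[ne], weights=w[ne])
    )


def weighted_cindex(pairs: RiskPair, use_new: bool = True) -> float:
    """Weighted Harrell concordance of predicted risk against event times.

    Usable pairs are (i, j) with subject i an event and time_i < time_j;
    a pair is concordant when the event subject has the higher predicted
    risk, ties in risk count half.  Pair weights are products of subject
    weights.  Raises if no pair is usable.
    """
    if pairs.time is None:
        raise ValueError("concordance needs event times")
    risk = pairs.risk_new if use_new else pairs.risk_old
    t, ev, w = pairs.time, pairs.event, pairs.weight
    n = len(t)
    num = den = 0.0
    for i in range(n):
        if not ev[i]:
            continue
        usable = t > t[i]
        if not usable.any():
            continue
        pw = w[i] * w[usable]
        den += pw.sum()
        num += pw[risk[i] > risk[usable]].sum() + 0.5 * pw[risk[i] == risk[usable]].sum()
    if den == 0:
        raise ValueError("no usable pairs for concordance")
    return float(num / den)


def bootstrap_ci(
    metric_fn,
    pairs: RiskPair,
    B: int = 1000,
    seed: int = 0,
    metric_name: str = "metric",
) -> ReclassResult:
    """Percentile-bootstrap CI and two-sided p-value for a reclassification
    metric.

    Subjects are resampled with replacement ``B`` times; the 95% CI is the
    (2.5, 97.5) percentile interval and the p-value is twice the smaller
    tail of the bootstrap distribution around 0.  Fails if the metric is
    undefined in more than 10% of resamples.
    """
    if B < 100:
        raise ValueError("B must be at least 100")
    rng = substream(seed, f"bootstrap:{metric_name}")
    est = metric_fn(pairs)
    n = len(pairs.risk_old)
    stats, failed = [], 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                stats.append(metric_fn(pairs.take(idx)))
        except ValueError:
            failed += 1
    if failed > 0.10 * B:
        raise ValueError(
            f"metric undefined in {failed}/{B} bootstrap resamples"
        )
    stats = np.asarray(stats)
    lo, hi = np.percentile(stats, [2.5, 97.5])
    p = 2 * min((stats <= 0).mean(), (stats >= 0).mean())
    return ReclassResult(
        metric=metric_name,
        estimate=float(est),
        ci95=(float(lo), float(hi)),
        p=float(min(p, 1.0)),
        n_boot=B,
        seed=seed,
    )
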