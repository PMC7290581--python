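"""High-level orchestration of the analysis stages.

`normalize` runs the full Ct-processing chain in its required order;
`reclassification_analysis` fits the baseline and marker-extended
case-cohort Cox models, derives 10-year absolute risks, and computes the
reclassification metrics with bootstrap confidence intervals.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .coxcc import assign_casecohort_weights, fit_weighted_cox
from .ct import (
    CtMatrix,
    DeltaCtMatrix,
    apply_validity_filter,
    correct_plate_effects,
    filter_features,
    filter_samples,
    global_normalize,
)
from .reclassify import (
    ReclassResult,
    RiskPair,
    bootstrap_ci,
    categorical_nri,
    continuous_nri,
    idi,
    weighted_cindex,
)

__all__ = ["normalize", "reclassification_analysis"]


def normalize(
    ct: CtMatrix,
    feature_missing_max: float = 0.90,
    sample_missing_max: float = 0.95,
    plate_correction: bool = True,
) -> tuple[DeltaCtMatrix, dict]:
    """Validity mask -> feature filter -> sample filter -> plate correction
    -> global ΔCt normalization.  Returns the ΔCt matrix and a report of
    exclusions."""
    ct = apply_validity_filter(ct)
    ct, excl_feat = filter_features(ct, feature_missing_max)
    ct, excl_samp = filter_samples(ct, sample_missing_max)
    if ct.n_mirnas == 0 or ct.n_samples == 0:
        raise ValueError("nothing left to normalize after filtering")
    if plate_correction:
        ct = correct_plate_effects(ct)
    delta = global_normalize(ct)
    report = {
        "excluded_features": excl_feat,
        "excluded_samples": excl_samp,
        "history": delta.history,
    }
    return delta, report


def _risks_at_horizon(fit, covariates: pd.DataFrame, horizon: float) -> np.ndarray:
    """10-year absolute risk 1 - S(h | x) from a fitted weighted Cox model."""
    return fit.predict_risk(covariates, horizon)


def reclassification_analysis(
    records: pd.DataFrame,
    mirnas: list[str],
    baseline_terms: list[str] = ("age", "sex", "smoking", "cholesterol", "sbp", "diabetes"),
    horizon: float = 10.0,
    cutoff: float = 0.10,
    n_boot: int = 1000,
    seed: int = 0,
    sampling_fraction: float | None = None,
    n_cohort: int | None = None,
) -> dict[str, ReclassResult]:
    """Incremental value of miRNA ΔCt markers over the classical risk model.

    Fits the baseline weighted Cox model and the model extended with the
    listed miRNAs on the case-cohort records, converts both to 10-year
    absolute risks, and returns continuous NRI (percent), categorical NRI
    at ``cutoff``, IDI, and the concordance change, each with a percentile
    bootstrap CI (except deltaC, reported as a point estimate).
    """
    baseline_terms = [t for t in baseline_terms if t in records.columns]
    sub = records.dropna(subset=list(mirnas)).reset_index(drop=True)
    weighted = assign_casecohort_weights(
        sub, sampling_fraction=sampling_fraction, n_cohort=n_cohort
    )
    fit_old = fit_weighted_cox(weighted, baseline_terms)
    fit_new = fit_weighted_cox(weighted, [*baseline_terms, *mirnas])

    risk_old = _risks_at_horizon(fit_old, sub[baseline_terms], horizon)
    risk_new = _risks_at_horizon(fit_new, sub[[*baseline_terms, *mirnas]], horizon)

    if sampling_fraction is None:
        sampling_fraction = sub["in_subcohort"].astype(bool).sum() / n_cohort
    w = np.where(sub["event"].astype(bool), 1.0, 1.0 / sampling_fraction)
    pairs = RiskPair(
        risk_old=np.clip(risk_old, 0.0, 1.0),
        risk_new=np.clip(risk_new, 0.0, 1.0),
        event=sub["event"].astype(bool).to_numpy(),
        weight=w,
        time=sub["time"].to_numpy(dtype=float),
    )
    results = {
        "cNRI": bootstrap_ci(continuous_nri, pairs, B=n_boot, seed=seed,
                             metric_name="cNRI"),
        "catNRI": bootstrap_ci(
            lambda p: categorical_nri(p, cutoffs=[cutoff]), pairs, B=n_boot,
            seed=seed, metric_name="catNRI",
        ),
        "IDI": bootstrap_ci(idi, pairs, B=n_boot, seed=seed, metric_name="IDI"),
    }
    delta_c = weighted_cindex(pairs, use_new=True) - weighted_cindex(pairs, use_new=False)
    results["deltaC"] = ReclassResult(metric="deltaC", estimate=float(delta_c))
    return results
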