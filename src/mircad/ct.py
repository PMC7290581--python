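"""Raw qPCR Ct processing: validity masking, missingness filters,
empirical-Bayes plate-effect correction, and global mean normalization.

The pipeline order is validity -> feature filter -> sample filter -> plate
correction -> normalization; each step records itself in the matrix's
``history`` so order violations are detectable downstream.

Conventions
-----------
Ct values live in a samples x miRNAs DataFrame with NaN marking non-detects
(reactions with no valid amplification).  Lower Ct means higher abundance.
ΔCt = Ct - (mean Ct of the sample's detected miRNAs), so lower ΔCt means
higher relative expression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CtMatrix",
    "DeltaCtMatrix",
    "apply_validity_filter",
    "filter_features",
    "filter_samples",
    "correct_plate_effects",
    "global_normalize",
]


@dataclass
class CtMatrix:
    """Ct values (samples x miRNAs) with plate labels and a validity mask.

    Parameters
    ----------
    values
        Ct values; NaN marks a non-detect.
    plate
        Plate label per sample (index-aligned with ``values``).
    valid
        Optional boolean mask of per-reaction amplification-curve validity
        (True = curve passed QC).  ``None`` means all reactions valid.
    history
        Ordered names of the processing steps already applied.
    """

    values: pd.DataFrame
    plate: pd.Series
    valid: pd.DataFrame | None = None
    history: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.plate.index):
            self.plate = self.plate.reindex(self.values.index)
        if self.plate.isna().any() or (self.plate.astype(str) == "").any():
            raise ValueError("every sample needs a non-empty plate label")
        if self.valid is not None and self.valid.shape != self.values.shape:
            raise ValueError("valid mask must match the shape of values")

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_mirnas(self) -> int:
        return self.values.shape[1]

    def missing_fraction(self) -> float:
        """Overall fraction of non-detect entries."""
        return float(self.values.isna().to_numpy().mean())

    def _replace(self, values: pd.DataFrame, step: str) -> "CtMatrix":
        valid = None
        if self.valid is not None:
            valid = self.valid.loc[values.index, values.columns]
        return CtMatrix(
            values=values,
            plate=self.plate.loc[values.index],
            valid=valid,
            history=self.history + [step],
        )


@dataclass
class DeltaCtMatrix:
    """Globally normalized ΔCt values with the per-sample reference stored."""

    values: pd.DataFrame
    per_sample_reference: pd.Series
    history: list[str] = field(default_factory=list)

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()


def apply_validity_filter(ct: CtMatrix) -> CtMatrix:
    """Blank out reactions whose amplification curve failed QC.

    Reactions flagged invalid (e.g. poor amplification score or no
    exponential curve) are converted to non-detects; everything else is
    returned unchanged.
    """
    if ct.valid is None:
        out = ct._replace(ct.values.copy(), "validity")
        return out
    vals = ct.values.where(ct.valid)
    n_dropped = int((~ct.valid & ct.values.notna()).to_numpy().sum())
    out = ct._replace(vals, f"validity(dropped={n_dropped})")
    out.valid = None
    return out


def _plate_obs_counts(values: pd.DataFrame, plate: pd.Series) -> pd.DataFrame:
    """Observed-value counts per plate (rows) x miRNA (columns)."""
    return values.notna().groupby(plate.to_numpy()).sum()


def filter_features(
    ct: CtMatrix, max_missing_frac: float = 0.90
) -> tuple[CtMatrix, pd.DataFrame]:
    """Drop miRNAs too missing to analyze or impossible to plate-correct.

    A miRNA is excluded when its missing fraction strictly exceeds
    ``max_missing_frac``, or when some plate carries exactly one observed
    value for it (a per-plate scale parameter then has no variance estimate,
    so plate-effect correction is infeasible).

    Returns the filtered matrix and a table of exclusions with reasons.
    """
    if not (0 < max_missing_frac <= 1):
        raise ValueError("max_missing_frac must be in (0, 1]")
    miss_frac = ct.values.isna().mean(axis=0)
    reasons: list[tuple[str, str]] = []
    for m in ct.values.columns:
        if miss_frac[m] > max_missing_frac:
            reasons.append((m, f"missing fraction {miss_frac[m]:.3f} > {max_missing_frac}"))
    counts = _plate_obs_counts(ct.values, ct.plate)
    flagged = {m for m, _ in reasons}
    for m in ct.values.columns:
        if m in flagged:
            continue
        per_plate = counts[m]
        if ((per_plate > 0) & (per_plate < 2)).any():
            reasons.append((m, "plate-correction infeasible (<2 observations on a plate)"))
    excluded = pd.DataFrame(reasons, columns=["mirna", "reason"])
    keep = [m for m in ct.values.columns if m not in set(excluded["mirna"])]
    out = ct._replace(ct.values[keep], f"filter_features(dropped={len(excluded)})")
    if not keep:
        warnings.warn("all miRNAs excluded by feature filter", stacklevel=2)
    return out, excluded


def filter_samples(
    ct: CtMatrix, max_missing_frac: float = 0.95
) -> tuple[CtMatrix, pd.DataFrame]:
    """Drop samples whose missing fraction strictly exceeds the threshold."""
    if not (0 < max_missing_frac <= 1):
        raise ValueError("max_missing_frac must be in (0, 1]")
    miss_frac = ct.values.isna().mean(axis=1)
    bad = miss_frac[miss_frac > max_missing_frac]
    excluded = pd.DataFrame(
        {"sample": bad.index, "missing_fraction": bad.to_numpy()}
    )
    keep = miss_frac.index[miss_frac <= max_missing_frac]
    out = ct._replace(ct.values.loc[keep], f"filter_samples(dropped={len(bad)})")
    if len(keep) == 0:
        warnings.warn("all samples excluded by sample filter", stacklevel=2)
    return out, excluded


def correct_plate_effects(ct: CtMatrix, eb: bool = True, tol: float = 1e-4) -> CtMatrix:
    """Remove additive and multiplicative plate effects from the Ct matrix.

    Parametric empirical-Bayes location/scale batch adjustment: per miRNA,
    plate means and variances are estimated on standardized data, shrunk
    toward across-miRNA priors (normal prior on the location, inverse-gamma
    on the scale, fitted by method of moments) with the usual fixed-point
    iteration, and divided out.  Missing entries stay missing; the overall
    per-miRNA mean is preserved.

    With a single plate, or with ``eb=False``, no shrinkage is applied
    (``eb=False`` uses the raw per-plate estimates directly).  miRNAs whose
    within-plate variance is zero on some plate get a location-only
    adjustment on that plate, with a warning.
    """
    plates = pd.unique(ct.plate)
    if len(plates) < 2:
        return ct._replace(ct.values.copy(), "plate_correction(identity)")

    X = ct.values.to_numpy(dtype=float)  # samples x genes
    n_samp, n_gene = X.shape
    obs = ~np.isnan(X)
    plate_arr = ct.plate.to_numpy()

    # per-gene batch means and a grand mean weighted by per-batch counts
    batch_rows = {b: np.flatnonzero(plate_arr == b) for b in plates}
    n_gb = np.array([obs[batch_rows[b]].sum(axis=0) for b in plates], float)  # B x G
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_gb = np.array([np.nanmean(X[batch_rows[b]], axis=0) for b in plates])
    n_tot = n_gb.sum(axis=0)
    if (n_gb == 1).any():
        bad = np.flatnonzero((n_gb == 1).any(axis=0))
        names = list(ct.values.columns[bad])
        raise ValueError(
            f"plate correction needs >=2 observations per occupied plate; offending miRNAs: {names}"
        )
    mean_gb_f = np.where(np.isnan(mean_gb), 0.0, mean_gb)
    alpha = (n_gb * mean_gb_f).sum(axis=0) / n_tot  # grand mean per gene

    resid = X - alpha[None, :]
    for bi, b in enumerate(plates):
        rows = batch_rows[b]
        resid[rows] -= (mean_gb_f[bi] - alpha)[None, :]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sigma2 = np.nanmean(resid**2, axis=0)
    sigma2 = np.where(sigma2 <= 0, np.nan, sigma2)
    if np.isnan(sigma2).any():
        warnings.warn(
            "zero pooled variance for some miRNA; location-only adjustment used",
            stacklevel=2,
        )
        sigma2 = np.where(np.isnan(sigma2), 1.0, sigma2)
    sigma = np.sqrt(sigma2)

    Z = (X - alpha[None, :]) / sigma[None, :]

    Xadj = X.copy()
    loc_only_warned = False
    for bi, b in enumerate(plates):
        rows = batch_rows[b]
        Zb = Z[rows]
        nb = n_gb[bi]  # per-gene counts on this plate
        present = nb > 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            gamma_hat = np.nanmean(Zb, axis=0)
            delta_hat = np.nanvar(Zb, axis=0, ddof=1)
        gamma_star = gamma_hat.copy()
        delta_star = delta_hat.copy()

        est_ok = present & np.isfinite(delta_hat) & (delta_hat > 0)
        if eb and est_ok.sum() >= 2:
            g = gamma_hat[est_ok]
            d = delta_hat[est_ok]
            n = nb[est_ok]
            gbar = g.mean()
            tau2 = g.var(ddof=1)
            m, s2 = d.mean(), d.var(ddof=1)
            if tau2 > 0 and s2 > 0:
                lam = (2 * s2 + m**2) / s2
                theta = (m * s2 + m**3) / s2
                g_new, d_new = g.copy(), d.copy()
                sum_z2 = np.array(
                    [np.nansum((Zb[:, j]) ** 2) for j in np.flatnonzero(est_ok)]
                )
                sum_z = np.array(
                    [np.nansum(Zb[:, j]) for j in np.flatnonzero(est_ok)]
                )
                for _ in range(200):
                    g_prev, d_prev = g_new, d_new
                    g_new = (n * tau2 * g + d_prev * gbar) / (n * tau2 + d_prev)
                    ss = sum_z2 - 2 * g_new * sum_z + n * g_new**2
                    d_new = (theta + 0.5 * ss) / (n / 2 + lam - 1)
                    change = max(
                        np.abs(g_new - g_prev).max(initial=0.0),
                        np.abs(d_new - d_prev).max(initial=0.0),
                    )
                    if change < tol:
                        break
                gamma_star[est_ok] = g_new
                delta_star[est_ok] = d_new

        degenerate = present & ~est_ok
        if degenerate.any():
            if not loc_only_warned:
                warnings.warn(
                    "zero within-plate variance for some miRNA/plate; "
                    "location-only adjustment applied there",
                    stacklevel=2,
                )
                loc_only_warned = True
            delta_star[degenerate] = 1.0
            gamma_star[degenerate] = gamma_hat[degenerate]

        scale = np.sqrt(np.where(present, delta_star, 1.0))
        shift = np.where(present, gamma_star, 0.0)
        Zb_adj = (Zb - shift[None, :]) / scale[None, :]
        Xadj[rows] = Zb_adj * sigma[None, :] + alpha[None, :]

    vals = pd.DataFrame(Xadj, index=ct.values.index, columns=ct.values.columns)
    vals = vals.where(ct.values.notna())
    return ct._replace(vals, f"plate_correction(eb={eb})")


def global_normalize(ct: CtMatrix) -> DeltaCtMatrix:
    """ΔCt = Ct minus the mean Ct of the sample's detected miRNAs.

    The per-sample reference (mean of observed entries) is stored alongside
    the normalized matrix.  Samples with no observed miRNA should have been
    removed by :func:`filter_samples`; encountering one here is a
    pipeline-order violation and raises.
    """
    n_obs = ct.values.notna().sum(axis=1)
    if (n_obs == 0).any():
        empty = list(ct.values.index[n_obs == 0])
        raise ValueError(
            f"samples with zero observed miRNAs reached normalization: {empty}; "
            "run filter_samples first"
        )
    ref = ct.values.mean(axis=1)
    delta = ct.values.sub(ref, axis=0)
    return DeltaCtMatrix(
        values=delta,
        per_sample_reference=ref,
        history=ct.history + ["global_normalize"],
    )
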