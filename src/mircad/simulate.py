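"""Synthetic inputs with the statistical structure the pipeline assumes.

Four generators mirror the four arms of the study design:

* a case-control serum qPCR study (Ct matrix with plate effects and a Ct
  limit of detection producing non-detects mechanistically: a reaction
  whose true Ct exceeds the limit is simply never observed, which makes
  the downstream right-censoring assumption literally true);
* a population cohort with proportional-hazards event times, 10-year
  administrative censoring, and a case-cohort subsample (all cases plus a
  random subcohort at a configurable control:case ratio);
* a three-condition (nLDL < moxLDL < hoxLDL), two-cell-type expression
  matrix with planted flat/linear/quadratic dose-response shapes;
* a target-score / gene-set / expressed-gene annotation bundle for the
  enrichment stage.

Case and control covariates are drawn from the same distributions (the
age/sex matching of the source design makes the groups comparable; the
analysis itself is unpaired).  All draws come from named substreams of one
global seed, so each generator is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import substream
from .ct import CtMatrix

__all__ = [
    "CaseControlConfig",
    "CohortConfig",
    "ArrayConfig",
    "generate_case_control",
    "generate_cohort",
    "generate_array",
    "generate_annotation",
]

# Default risk-factor distributions for a middle-aged general population
# (age in years, cholesterol mg/dL, systolic blood pressure mmHg; sex,
# smoking and diabetes are prevalences).
DEFAULT_COVARIATES: dict[str, tuple] = {
    "age": ("normal", 55.0, 10.0),
    "sex": ("bernoulli", 0.5),
    "smoking": ("bernoulli", 0.30),
    "cholesterol": ("normal", 220.0, 40.0),
    "sbp": ("normal", 130.0, 18.0),
    "diabetes": ("bernoulli", 0.12),
}

# Log hazard ratios of the classical risk factors used when simulating
# event times (per year of age, per mg/dL, per mmHg; indicators as-is).
DEFAULT_COVARIATE_LOG_HR: dict[str, float] = {
    "age": 0.06,
    "sex": 0.45,
    "smoking": 0.55,
    "cholesterol": 0.005,
    "sbp": 0.012,
    "diabetes": 0.60,
}


@dataclass
class CaseControlConfig:
    """Serum qPCR case-control design.

    Sample sizes default to the source study's 476 MI cases and 487
    controls measured on a 51-miRNA panel across 8 plates.  A planted log2
    fold change lowers case Ct by that amount (lower Ct = higher
    expression).  Per-plate effects are an additive Ct shift and a
    multiplicative (log-scale) noise inflation.  Any Ct above ``lod_ct``
    becomes a non-detect.
    """

    n_cases: int = 476
    n_controls: int = 487
    n_mirnas: int = 51
    n_plates: int = 8
    true_log2_fc: dict[str, float] = field(default_factory=dict)
    baseline_ct: dict[str, float] = field(default_factory=dict)
    sd_ct: float = 1.5
    plate_shift_sd: float = 0.8
    plate_scale_sd: float = 0.1
    lod_ct: float = 31.0
    invalid_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name, v in (
            ("n_cases", self.n_cases), ("n_controls", self.n_controls),
            ("n_mirnas", self.n_mirnas), ("n_plates", self.n_plates),
        ):
            if v < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.sd_ct <= 0:
            raise ValueError("sd_ct must be positive")
        if self.plate_shift_sd < 0 or self.plate_scale_sd < 0:
            raise ValueError("plate effect SDs must be non-negative")
        if not (0 <= self.invalid_fraction < 1):
            raise ValueError("invalid_fraction must be in [0, 1)")


@dataclass
class CohortConfig:
    """Population cohort with case-cohort subsampling.

    Event times follow a proportional-hazards model (exponential baseline
    by default, Weibull optional) with linear predictor from centered
    classical risk factors and standard-normal miRNA ΔCt-scale values;
    follow-up is administratively censored at ``horizon`` years.  The
    case-cohort table is all events plus a random subcohort of
    ``subcohort_ratio`` x (number of events) members.
    """

    n_cohort: int = 5000
    horizon: float = 10.0
    baseline_hazard: float = 0.002
    covariate_spec: dict[str, tuple] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATES)
    )
    covariate_log_hr: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_LOG_HR)
    )
    mirna_log_hr: dict[str, float] = field(
        default_factory=lambda: {"hsa-miR-143-3p": float(np.log(0.56))}
    )
    subcohort_ratio: int = 4
    weibull_shape: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if self.subcohort_ratio < 1:
            raise ValueError("subcohort_ratio must be >= 1")


@dataclass
class ArrayConfig:
    """Three-condition, two-cell-type in-vitro expression design.

    ``trend_spec`` maps feature name -> (shape, amplitude): ``flat``,
    ``linear`` (monotone change of ``amplitude`` log2 units from nLDL to
    hoxLDL) or ``quadratic`` (mid-condition excursion of ``amplitude``
    with equal endpoints).  ``n_flat_background`` null features are added.
    """

    n_replicates_per_condition: int = 3
    conditions: tuple[str, ...] = ("nLDL", "moxLDL", "hoxLDL")
    cell_types: tuple[str, ...] = ("EC", "VSMC")
    trend_spec: dict[str, tuple[str, float]] = field(default_factory=dict)
    n_flat_background: int = 100
    baseline_log2: float = 7.0
    noise_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.conditions) != 3:
            raise ValueError("exactly 3 ordered conditions required")
        if self.noise_sd > 0 and self.n_replicates_per_condition < 2:
            raise ValueError("need >=2 replicates per condition with noise")
        for name, (shape, _amp) in self.trend_spec.items():
            if shape not in ("flat", "linear", "quadratic"):
                raise ValueError(f"unknown trend shape {shape!r} for {name!r}")


def _mirna_names(config: CaseControlConfig) -> list[str]:
    named = list(dict.fromkeys([*config.true_log2_fc, *config.baseline_ct]))
    extra = config.n_mirnas - len(named)
    if extra < 0:
        raise ValueError("n_mirnas smaller than the number of named miRNAs")
    return named + [f"miR-sim-{i:03d}" for i in range(extra)]


def generate_case_control(
    config: CaseControlConfig,
) -> tuple[CtMatrix, pd.DataFrame, pd.DataFrame]:
    """Simulate the case-control Ct matrix, sample metadata, and truth table.

    Ct(sample i, miRNA j) = baseline_ct[j] - status_i * log2fc[j]
    + plate shift + plate-scaled N(0, sd_ct^2); entries above the limit of
    detection are recorded as non-detects (NaN).  The truth table stores,
    per miRNA, the planted and realized (pre-censoring) fold change and the
    realized non-detect fraction of the emitted matrix.
    """
    rng = substream(config.seed, "case_control")
    mirnas = _mirna_names(config)
    m = len(mirnas)
    n = config.n_cases + config.n_controls
    status = np.concatenate([np.ones(config.n_cases), np.zeros(config.n_controls)])
    sample_ids = [f"S{i:04d}" for i in range(n)]

    baseline = np.array(
        [config.baseline_ct.get(name, np.nan) for name in mirnas]
    )
    unnamed = np.isnan(baseline)
    baseline[unnamed] = rng.uniform(24.0, 30.0, size=int(unnamed.sum()))
    log2fc = np.array([config.true_log2_fc.get(name, 0.0) for name in mirnas])

    plate_labels = np.array([f"P{p}" for p in range(config.n_plates)])
    plate_of = plate_labels[rng.integers(0, config.n_plates, size=n)]
    shift = rng.normal(0.0, config.plate_shift_sd, size=config.n_plates)
    scale = np.exp(rng.normal(0.0, config.plate_scale_sd, size=config.n_plates))
    plate_idx = np.array([int(p[1:]) for p in plate_of])

    noise = rng.normal(0.0, config.sd_ct, size=(n, m))
    ct = (
        baseline[None, :]
        - status[:, None] * log2fc[None, :]
        + shift[plate_idx][:, None]
        + scale[plate_idx][:, None] * noise
    )
    realized_diff = ct[status == 1].mean(axis=0) - ct[status == 0].mean(axis=0)

    nondetect = ct > config.lod_ct
    values = pd.DataFrame(np.where(nondetect, np.nan, ct),
                          index=sample_ids, columns=mirnas)
    valid = None
    if config.invalid_fraction > 0:
        valid = pd.DataFrame(
            rng.random((n, m)) >= config.invalid_fraction,
            index=sample_ids, columns=mirnas,
        )
    plate = pd.Series(plate_of, index=sample_ids, name="plate")

    age = rng.normal(55.0, 10.0, size=n)
    sex = rng.integers(0, 2, size=n)
    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "group": np.where(status == 1, "case", "control"),
            "plate": plate_of,
            "age": np.round(age, 1),
            "sex": sex,
        }
    ).set_index("sample_id")

    truth = pd.DataFrame(
        {
            "mirna": mirnas,
            "baseline_ct": baseline,
            "true_log2_fc": log2fc,
            "true_fold_change": 2.0**log2fc,
            "realized_fold_change": 2.0 ** (-realized_diff),
            "nondetect_fraction": np.isnan(values.to_numpy()).mean(axis=0),
        }
    )
    ctm = CtMatrix(values=values, plate=plate, valid=valid, history=["simulated"])
    return ctm, meta, truth


def _draw_covariates(rng: np.random.Generator, spec: dict, n: int) -> pd.DataFrame:
    cols = {}
    for name, params in spec.items():
        kind = params[0]
        if kind == "normal":
            cols[name] = rng.normal(params[1], params[2], size=n)
        elif kind == "bernoulli":
            cols[name] = (rng.random(n) < params[1]).astype(float)
        elif kind == "uniform":
            cols[name] = rng.uniform(params[1], params[2], size=n)
        else:
            raise ValueError(f"unknown covariate distribution {kind!r}")
    return pd.DataFrame(cols)


def generate_cohort(
    config: CohortConfig, max_attempts: int = 5
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate the full cohort, the case-cohort subsample, and the truth.

    Event times come from the proportional-hazards inversion
    T = H0^{-1}(-log U / exp(lp)) with centered covariates in the linear
    predictor; follow-up is censored at ``horizon``.  If no event is
    realized, the draw is repeated (fresh substream) up to ``max_attempts``
    times before failing with a diagnostic.
    """
    for attempt in range(max_attempts):
        rng = substream(config.seed, f"cohort:{attempt}")
        n = config.n_cohort
        cov = _draw_covariates(rng, config.covariate_spec, n)
        mirna_names = list(config.mirna_log_hr)
        mirna_vals = pd.DataFrame(
            rng.normal(0.0, 1.0, size=(n, len(mirna_names))), columns=mirna_names
        )
        lp = np.zeros(n)
        for name, beta in config.covariate_log_hr.items():
            if name in cov:
                x = cov[name].to_numpy()
                lp += beta * (x - x.mean())
        for name, beta in config.mirna_log_hr.items():
            lp += beta * mirna_vals[name].to_numpy()

        u = rng.random(n)
        base = -np.log(u) / (config.baseline_hazard * np.exp(lp))
        if config.weibull_shape is not None:
            t_event = base ** (1.0 / config.weibull_shape)
        else:
            t_event = base
        time = np.minimum(t_event, config.horizon)
        event = t_event < config.horizon
        n_events = int(event.sum())
        if n_events == 0:
            continue

        n_sub = min(config.subcohort_ratio * n_events, n)
        sub_idx = rng.choice(n, size=n_sub, replace=False)
        in_sub = np.zeros(n, dtype=bool)
        in_sub[sub_idx] = True

        full = pd.concat([cov, mirna_vals], axis=1)
        full.insert(0, "id", [f"C{i:05d}" for i in range(n)])
        full["time"] = np.maximum(time, 1e-6)
        full["event"] = event.astype(int)
        full["in_subcohort"] = in_sub
        cc = full[event | in_sub].reset_index(drop=True)
        truth = {
            "mirna_log_hr": dict(config.mirna_log_hr),
            "covariate_log_hr": dict(config.covariate_log_hr),
            "n_events": n_events,
            "n_subcohort": int(n_sub),
            "sampling_fraction": n_sub / n,
            "n_cohort": n,
        }
        return full, cc, truth
    raise RuntimeError(
        f"no events realized in {max_attempts} attempts; "
        f"baseline_hazard={config.baseline_hazard} is likely too small"
    )


_SHAPE_PROFILE = {
    "flat": np.array([0.0, 0.0, 0.0]),
    "linear": np.array([0.0, 0.5, 1.0]),
    "quadratic": np.array([0.0, 1.0, 0.0]),
}


def generate_array(config: ArrayConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the in-vitro expression matrix and its sample annotation.

    Returns (values, annotation): values is features x samples log2
    expression; annotation has ``condition`` and ``cell_type`` per sample.
    """
    rng = substream(config.seed, "array")
    features = list(config.trend_spec) + [
        f"feat-null-{i:03d}" for i in range(config.n_flat_background)
    ]
    shapes = [config.trend_spec.get(f, ("flat", 0.0)) for f in features]
    reps = config.n_replicates_per_condition
    sample_ids, conds, cts = [], [], []
    for ct in config.cell_types:
        for cond in config.conditions:
            for r in range(reps):
                sample_ids.append(f"{ct}_{cond}_r{r}")
                conds.append(cond)
                cts.append(ct)
    n_samp = len(sample_ids)
    cond_idx = np.array([list(config.conditions).index(c) for c in conds])
    mat = np.empty((len(features), n_samp))
    for fi, (shape, amp) in enumerate(shapes):
        profile = config.baseline_log2 + amp * _SHAPE_PROFILE[shape]
        mat[fi] = profile[cond_idx]
    if config.noise_sd > 0:
        mat += rng.normal(0.0, config.noise_sd, size=mat.shape)
    values = pd.DataFrame(mat, index=features, columns=sample_ids)
    annot = pd.DataFrame(
        {"condition": conds, "cell_type": cts}, index=sample_ids
    )
    return values, annot


def generate_annotation(
    n_genes: int = 500,
    n_sets: int = 10,
    target_fraction: float = 0.2,
    seed: int = 0,
    context_max: float = -0.3,
    aggregate_min: float = 0.3,
    expressed_fraction: float = 0.6,
) -> tuple[pd.DataFrame, "object", dict[str, set[str]]]:
    """Simulate target scores, gene sets (with one planted enriched set),
    and expressed-gene lists per cell type.

    Returns (score table, GeneSetCollection, expressed lists).  Scores span
    the filtering thresholds: a ``target_fraction`` of genes get passing
    scores (context strictly below ``context_max``, aggregate at or above
    ``aggregate_min``), the rest fail at least one threshold.  The gene set
    named ``planted_set`` over-samples passing genes so enrichment is real;
    the remaining sets are uniform draws.
    """
    from .enrichment import GeneSetCollection

    if not (1 <= n_sets <= n_genes):
        raise ValueError("need n_genes >= n_sets >= 1")
    if not (0 < target_fraction <= 1):
        raise ValueError("target_fraction must be in (0, 1]")
    rng = substream(seed, "annotation")
    genes = [f"GENE{i:04d}" for i in range(n_genes)]
    is_target = rng.random(n_genes) < target_fraction
    context = np.where(
        is_target,
        rng.uniform(-0.8, context_max - 1e-9, size=n_genes),
        rng.uniform(context_max, 0.0, size=n_genes),
    )
    aggregate = np.where(
        is_target,
        rng.uniform(aggregate_min, 0.9, size=n_genes),
        rng.uniform(0.0, aggregate_min - 1e-9, size=n_genes),
    )
    # half the non-targets fail only one of the two thresholds
    flip = (~is_target) & (rng.random(n_genes) < 0.5)
    aggregate[flip] = rng.uniform(aggregate_min, 0.9, size=int(flip.sum()))
    scores = pd.DataFrame(
        {"gene": genes, "context_score": context, "aggregate_score": aggregate}
    )

    gene_arr = np.array(genes)
    target_genes = gene_arr[is_target]
    nontarget_genes = gene_arr[~is_target]
    sets: dict[str, set[str]] = {}
    set_size = max(5, n_genes // (2 * n_sets))
    n_from_targets = min(len(target_genes), max(1, int(0.7 * set_size)))
    planted = set(rng.choice(target_genes, size=n_from_targets, replace=False))
    n_fill = set_size - len(planted)
    if n_fill > 0 and len(nontarget_genes) >= n_fill:
        planted |= set(rng.choice(nontarget_genes, size=n_fill, replace=False))
    sets["planted_set"] = planted
    for si in range(n_sets - 1):
        sets[f"set_{si:02d}"] = set(
            rng.choice(gene_arr, size=set_size, replace=False)
        )
    collection = GeneSetCollection(sets=sets, universe=set(genes))

    expressed = {
        ct: set(
            gene_arr[rng.random(n_genes) < expressed_fraction]
        )
        for ct in ("EC", "VSMC")
    }
    return scores, collection, expressed
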