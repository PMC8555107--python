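"""Synthetic worker cohort generator.

Emulates a stratified occupational cohort of carbon nanotube/nanofiber
(CNT/F) manufacturing workers: a High exposure group whose personal
breathing-zone inhalable elemental carbon (EC) exceeds a threshold and a
Low group below the exposure limit of quantification, with lognormal
exposure metrics, binned demographics, health history flags and serum
cumulative inflammatory potential (SCIP) covariates.

Lognormal parameters are moment-matched to published arithmetic group
means and standard errors: for an arithmetic mean ``m`` and standard
deviation ``s`` (``s = SE * sqrt(n)``),

    sigma^2 = ln(1 + s^2 / m^2)
    mu      = ln(m) - sigma^2 / 2

so that ``exp(mu + sigma^2/2) = m`` and the lognormal variance equals
``s^2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

HIGH = "High"
LOW = "Low"
GROUPS = (HIGH, LOW)

EXPOSURE_METRICS = ("inh_ec", "res_ec", "struct_count")
SCIP_GENES = ("IL6", "CCL2", "TNFalpha", "VCAM", "ICAM")

# Reference cohort summary statistics (arithmetic mean, standard error of the
# mean with n = 12 per group) for the three personal breathing-zone exposure
# metrics, in ug/m^3 (EC fractions) and structures/cm^3 (structure counts).
DEFAULT_METRIC_STATS: dict[str, dict[str, tuple[float, float]]] = {
    "inh_ec": {HIGH: (8.706, 5.402), LOW: (0.055, 0.014)},
    "res_ec": {HIGH: (1.564, 0.964), LOW: (0.017, 0.006)},
    "struct_count": {HIGH: (0.442, 0.310), LOW: (0.005, 0.002)},
}

# SCIP endothelial gene-induction covariates, log fold-change (mean, SE).
DEFAULT_SCIP_STATS: dict[str, dict[str, tuple[float, float]]] = {
    "IL6": {HIGH: (0.958, 0.094), LOW: (0.980, 0.069)},
    "CCL2": {HIGH: (0.830, 0.077), LOW: (1.001, 0.099)},
    "TNFalpha": {HIGH: (1.231, 0.187), LOW: (0.950, 0.102)},
    "VCAM": {HIGH: (1.159, 0.178), LOW: (1.154, 0.141)},
    "ICAM": {HIGH: (0.907, 0.128), LOW: (1.228, 0.247)},
}

# Binned covariates: (mean, SE, lower bound, upper bound).
DEFAULT_BIN_STATS: dict[str, dict[str, tuple[float, float, int, int]]] = {
    "age_bin": {HIGH: (3.0, 0.4, 1, 5), LOW: (3.0, 0.3, 1, 5)},
    "education_bin": {HIGH: (2.8, 0.4, 1, 4), LOW: (3.2, 0.3, 1, 4)},
    "duration_bin": {HIGH: (3.3, 0.3, 1, 5), LOW: (2.4, 0.4, 1, 5)},
}

# Bernoulli covariates: probability of a positive flag per group.
DEFAULT_FLAG_PROBS: dict[str, dict[str, float]] = {
    "sex_female": {HIGH: 3 / 12, LOW: 2 / 12},
    "former_smoker": {HIGH: 3 / 12, LOW: 2 / 12},
    "allergies": {HIGH: 5 / 12, LOW: 5 / 12},
    "hypertension": {HIGH: 3 / 12, LOW: 2 / 12},
    "solvent_current": {HIGH: 7 / 12, LOW: 6 / 12},
    "solvent_past": {HIGH: 6 / 12, LOW: 5 / 12},
}

_REFERENCE_N = 12  # group size behind the published standard errors


@dataclass
class ExposureRecord:
    """One worker: exposure metrics, demographics and SCIP covariates."""

    worker_id: str
    group: str
    inh_ec: float
    res_ec: float
    struct_count: float
    duration_bin: int
    age_bin: int
    sex: str
    education_bin: int
    former_smoker: bool
    allergies: bool
    hypertension: bool
    solvent_current: bool
    solvent_past: bool
    scip: dict[str, float]

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown exposure group {self.group!r}")
        for metric in EXPOSURE_METRICS:
            if getattr(self, metric) <= 0:
                raise ValueError(f"{metric} must be strictly positive")


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort.

    ``high_threshold`` and ``exposure_loq`` bound the inhalable EC of the
    High and Low groups respectively (High > 0.5 ug/m^3 inhalable EC; Low
    below the 0.13 ug/m^3 limit of quantification).
    """

    n_per_group: int = 12
    high_threshold: float = 0.5
    exposure_loq: float = 0.13
    metric_stats: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_METRIC_STATS.items()})
    scip_stats: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_SCIP_STATS.items()})
    bin_stats: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_BIN_STATS.items()})
    flag_probs: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_FLAG_PROBS.items()})

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if not self.exposure_loq < self.high_threshold:
            raise ValueError("exposure_loq must be below high_threshold")
        for metric, per_group in self.metric_stats.items():
            for group, (mean, se) in per_group.items():
                if mean <= 0 or se <= 0:
                    raise ValueError(
                        f"non-positive lognormal moments for {metric}/{group}"
                    )


def lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Underlying normal (mu, sigma) matching arithmetic mean and SD."""
    if mean <= 0 or sd <= 0:
        raise ValueError("mean and sd must be positive for moment matching")
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def sample_metric(
    metric: str,
    group: str,
    size: int,
    rng: np.random.Generator,
    config: CohortConfig | None = None,
) -> np.ndarray:
    """Raw (untruncated) lognormal draws of one exposure metric.

    This is the distribution the cohort is built from before the group
    thresholds are enforced by rejection; it is what the moment-matching
    formulas target.
    """
    config = config or CohortConfig()
    mean, se = config.metric_stats[metric][group]
    mu, sigma = lognormal_params(mean, se * math.sqrt(_REFERENCE_N))
    return rng.lognormal(mu, sigma, size=size)


def _draw_bin(rng: np.random.Generator, mean: float, se: float, lo: int, hi: int) -> int:
    value = int(round(rng.normal(mean, se * math.sqrt(_REFERENCE_N))))
    return int(min(max(value, lo), hi))


def _admissible(group: str, inh_ec: float, config: CohortConfig) -> bool:
    if group == HIGH:
        return inh_ec > config.high_threshold
    return inh_ec < config.exposure_loq


def generate_cohort(
    config: CohortConfig | None = None,
    seed: int | np.random.Generator = 0,
) -> list[ExposureRecord]:
    """Generate a stratified synthetic cohort, ``n_per_group`` per group.

    Exposure metrics are drawn independently from the moment-matched
    lognormals; a worker's inhalable EC draw is rejected and redrawn until
    it satisfies the group definition (High above ``high_threshold``, Low
    below ``exposure_loq``), so every record obeys the group invariant.
    Deterministic for a fixed seed.
    """
    config = config or CohortConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    records: list[ExposureRecord] = []
    for group, prefix in ((HIGH, "H"), (LOW, "L")):
        for i in range(config.n_per_group):
            inh = float(sample_metric("inh_ec", group, 1, rng, config)[0])
            while not _admissible(group, inh, config):
                inh = float(sample_metric("inh_ec", group, 1, rng, config)[0])
            res = float(sample_metric("res_ec", group, 1, rng, config)[0])
            sc = float(sample_metric("struct_count", group, 1, rng, config)[0])
            bins = {
                name: _draw_bin(rng, *config.bin_stats[name][group])
                for name in config.bin_stats
            }
            flags = {
                name: bool(rng.random() < config.flag_probs[name][group])
                for name in config.flag_probs
            }
            scip = {
                gene: float(
                    rng.normal(
                        config.scip_stats[gene][group][0],
                        config.scip_stats[gene][group][1] * math.sqrt(_REFERENCE_N),
                    )
                )
                for gene in config.scip_stats
            }
            records.append(
                ExposureRecord(
                    worker_id=f"{prefix}{i + 1:02d}",
                    group=group,
                    inh_ec=inh,
                    res_ec=res,
                    struct_count=sc,
                    duration_bin=bins["duration_bin"],
                    age_bin=bins["age_bin"],
                    sex="F" if flags["sex_female"] else "M",
                    education_bin=bins["education_bin"],
                    former_smoker=flags["former_smoker"],
                    allergies=flags["allergies"],
                    hypertension=flags["hypertension"],
                    solvent_current=flags["solvent_current"],
                    solvent_past=flags["solvent_past"],
                    scip=scip,
                )
            )
    return records


def cohort_to_frame(records: list[ExposureRecord]) -> pd.DataFrame:
    """Tabulate a cohort, one row per worker, SCIP genes as scip_* columns."""
    rows = []
    for r in records:
        row = {
            "worker_id": r.worker_id,
            "group": r.group,
            "inh_ec": r.inh_ec,
            "res_ec": r.res_ec,
            "struct_count": r.struct_count,
            "duration_bin": r.duration_bin,
            "age_bin": r.age_bin,
            "sex": r.sex,
            "education_bin": r.education_bin,
            "former_smoker": r.former_smoker,
            "allergies": r.allergies,
            "hypertension": r.hypertension,
            "solvent_current": r.solvent_current,
            "solvent_past": r.solvent_past,
        }
        for gene in SCIP_GENES:
            row[f"scip_{gene}"] = r.scip[gene]
        rows.append(row)
    return pd.DataFrame(rows).set_index("worker_id")


def frame_to_records(frame: pd.DataFrame) -> list[ExposureRecord]:
    """Inverse of :func:`cohort_to_frame` (index = worker_id)."""
    records = []
    for worker_id, row in frame.iterrows():
        records.append(
            ExposureRecord(
                worker_id=str(worker_id),
                group=str(row["group"]),
                inh_ec=float(row["inh_ec"]),
                res_ec=float(row["res_ec"]),
                struct_count=float(row["struct_count"]),
                duration_bin=int(row["duration_bin"]),
                age_bin=int(row["age_bin"]),
                sex=str(row["sex"]),
                education_bin=int(row["education_bin"]),
                former_smoker=bool(row["former_smoker"]),
                allergies=bool(row["allergies"]),
                hypertension=bool(row["hypertension"]),
                solvent_current=bool(row["solvent_current"]),
                solvent_past=bool(row["solvent_past"]),
                scip={g: float(row[f"scip_{g}"]) for g in SCIP_GENES},
            )
        )
    return records
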