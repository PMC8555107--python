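"""Synthetic serum peptidome generator with planted ground truth.

Produces a peptide x worker raw-intensity matrix whose statistical
structure mirrors what the downstream analysis assumes:

* ``null`` peptides: a per-peptide baseline abundance plus i.i.d. noise —
  no relationship to exposure or covariates.
* ``responsive`` peptides: log2 intensity linear in the worker's composite
  exposure (equal-weight sum of log10 breathing-zone metrics), with the
  noise variance calibrated so the expected coefficient of determination
  against the composite equals ``target_r2``.
* ``top_discriminant`` peptides: exposure markers whose Low-group level
  sits just above the intensity limit of quantification (LOQ) — detected
  but effectively at the quantification floor, with the noise tail
  left-censored — and a High-group mean shift of 10-13 log2 units (3-4
  orders of magnitude).
* ``nuisance`` peptides: linear in a non-exposure covariate (SCIP IL6 or
  age) to exercise the correlation-intersection logic that guards against
  covariate-driven false biomarkers.

Missingness is intensity-dependent (left-censored): cells at or above the
LOQ are always observed; below the LOQ detection follows a logistic
probability in log2 distance from the LOQ, so a masked cell always has a
latent value below the LOQ. A missing-completely-at-random mode is
provided for null calibration experiments.

Noise calibration for responsive peptides solves

    sigma_noise^2 = Var(beta * x) * (1 - r2) / r2

with ``x`` the realized composite values of the cohort, which makes the
expected R^2 of the latent peptide against ``x`` equal ``r2``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import HIGH, ExposureRecord, cohort_to_frame
from .exposure_models import composite_values
from .quant import RAW, QuantMatrix

CLASS_NULL = "null"
CLASS_RESPONSIVE = "responsive"
CLASS_TOP = "top_discriminant"
CLASS_NUISANCE = "nuisance"


@dataclass
class PeptidomeConfig:
    """Generator parameters (intensities in log2 units unless noted)."""

    n_features: int = 12_000
    n_responsive: int = 900          # includes the top-discriminant subset
    n_top_discriminant: int = 41
    top_effect_log2_range: tuple[float, float] = (10.0, 13.0)
    responsive_effect_log2_range: tuple[float, float] = (1.0, 4.0)
    target_r2: float = 0.85
    noise_sd: float = 0.15           # technical noise, ~11% CV
    baseline_log2_mean: float = 18.0
    baseline_log2_sd: float = 3.0
    log2_loq: float = 14.0           # intensity LOQ = 2**log2_loq
    detect_scale: float = 1.0        # logistic detection slope below the LOQ
    worker_offset_sd: float = 0.3    # per-sample depth offset (median centering target)
    n_nuisance: int = 60
    nuisance_effect_log2_range: tuple[float, float] = (1.0, 3.0)
    mcar_rate: float = 0.0           # extra missing-completely-at-random masking
    censor: bool = True              # apply intensity-dependent left-censoring

    def __post_init__(self) -> None:
        if not (self.n_top_discriminant <= self.n_responsive <= self.n_features):
            raise ValueError(
                "require n_top_discriminant <= n_responsive <= n_features"
            )
        if not 0.0 < self.target_r2 < 1.0:
            raise ValueError("target_r2 must be in (0, 1)")
        if self.n_responsive + self.n_nuisance > self.n_features:
            raise ValueError("planted classes exceed n_features")
        if not 0.0 <= self.mcar_rate < 1.0:
            raise ValueError("mcar_rate must be in [0, 1)")


@dataclass
class SyntheticPeptidome:
    """Generated matrix plus everything needed to score recovery."""

    quant: QuantMatrix               # raw intensities, NaN where censored
    latent: pd.DataFrame             # uncensored log2 intensities
    truth: pd.DataFrame              # per-peptide class / effect / beta
    composite: pd.Series             # worker composite exposure (log10 scale)


def _responsive_noise_sd(beta: float, x: np.ndarray, r2: float) -> float:
    signal_var = float(np.var(beta * x, ddof=1))
    return float(np.sqrt(signal_var * (1.0 - r2) / r2))


def generate_peptidome(
    cohort: list[ExposureRecord],
    config: PeptidomeConfig | None = None,
    seed: int | np.random.Generator = 0,
) -> SyntheticPeptidome:
    """Simulate the peptidome of ``cohort`` under ``config``.

    Requires both exposure groups in the cohort (fold standardization to
    the Low-group mean is undefined otherwise). Deterministic for a fixed
    seed.
    """
    config = config or PeptidomeConfig()
    if not cohort:
        raise ValueError("cohort must be non-empty")
    groups = {r.group for r in cohort}
    if len(groups) < 2:
        raise ValueError("cohort must contain both High and Low workers")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    workers = cohort_to_frame(cohort)
    n_workers = len(workers)
    x = composite_values(workers).to_numpy()
    is_high = (workers["group"] == HIGH).to_numpy()

    n = config.n_features
    classes = np.array([CLASS_NULL] * n, dtype=object)
    # Shuffle class placement so peptide index carries no information.
    order = rng.permutation(n)
    top_idx = order[: config.n_top_discriminant]
    resp_idx = order[config.n_top_discriminant : config.n_responsive]
    nuis_idx = order[config.n_responsive : config.n_responsive + config.n_nuisance]
    classes[top_idx] = CLASS_TOP
    classes[resp_idx] = CLASS_RESPONSIVE
    classes[nuis_idx] = CLASS_NUISANCE

    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, size=n)
    latent = baseline[:, None] + rng.normal(0.0, config.noise_sd, size=(n, n_workers))

    beta = np.zeros(n)
    effect = np.zeros(n)
    nuisance_target = np.array([""] * n, dtype=object)

    # Responsive: latent = alpha + beta * (x - mean(x)) + calibrated noise.
    # Effects go in both directions, as in a real volcano plot; this also
    # keeps the sample-median normalization unbiased.
    xc = x - x.mean()
    dx = x[is_high].mean() - x[~is_high].mean()
    for j in resp_idx:
        eff = rng.uniform(*config.responsive_effect_log2_range) * rng.choice((-1.0, 1.0))
        b = eff / dx
        sd = _responsive_noise_sd(b, x, config.target_r2)
        latent[j] = baseline[j] + b * xc + rng.normal(0.0, sd, size=n_workers)
        beta[j] = b
        effect[j] = eff

    # Top discriminant: Low-group level just above the LOQ (detected but
    # effectively at the quantification floor, noise tail censored), High
    # shifted by a 10-13 log2-unit group effect; technical noise only.
    for j in top_idx:
        eff = rng.uniform(*config.top_effect_log2_range)
        alpha = config.log2_loq + rng.uniform(0.5, 1.5)
        latent[j] = alpha + eff * is_high + rng.normal(0.0, config.noise_sd, size=n_workers)
        effect[j] = eff
        beta[j] = eff / dx

    # Nuisance: linear in a non-exposure covariate, scaled so the effect
    # across the covariate's observed span matches the configured range.
    nuis_covariates = {
        "logIL6": workers["scip_IL6"].to_numpy(),
        "age_bin": workers["age_bin"].to_numpy(dtype=float),
    }
    names = list(nuis_covariates)
    for pos, j in enumerate(nuis_idx):
        name = names[pos % len(names)]
        z = nuis_covariates[name]
        span = z.max() - z.min()
        if span == 0:
            continue
        eff = rng.uniform(*config.nuisance_effect_log2_range) * rng.choice((-1.0, 1.0))
        g = eff / span
        latent[j] = (
            baseline[j] + g * (z - z.mean()) + rng.normal(0.0, config.noise_sd, size=n_workers)
        )
        nuisance_target[j] = name
        effect[j] = eff

    # Per-worker sequencing-depth style offsets, removed later by median
    # centering.
    offsets = rng.normal(0.0, config.worker_offset_sd, size=n_workers)
    latent = latent + offsets[None, :]

    # Left-censored detection mask.
    observed = np.ones(latent.shape, dtype=bool)
    if config.censor:
        below = latent < config.log2_loq
        p_detect = 1.0 / (1.0 + np.exp(-(latent - config.log2_loq) / config.detect_scale))
        observed = ~below | (rng.random(latent.shape) < p_detect)
    if config.mcar_rate > 0:
        observed &= rng.random(latent.shape) >= config.mcar_rate

    feature_ids = [f"pep{j:05d}" for j in range(n)]
    values = pd.DataFrame(
        np.where(observed, np.exp2(latent), np.nan),
        index=feature_ids,
        columns=workers.index,
    )
    quant = QuantMatrix(
        values=values, intensity_loq=float(2.0 ** config.log2_loq), scale=RAW
    )
    truth = pd.DataFrame(
        {
            "class": classes,
            "beta": beta,
            "effect_log2": effect,
            "baseline_log2": baseline,
            "nuisance_covariate": nuisance_target,
        },
        index=pd.Index(feature_ids, name="peptide_id"),
    )
    latent_df = pd.DataFrame(latent, index=feature_ids, columns=workers.index)
    return SyntheticPeptidome(
        quant=quant,
        latent=latent_df,
        truth=truth,
        composite=pd.Series(x, index=workers.index, name="composite"),
    )
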