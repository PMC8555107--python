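"""Exposure model building: composites, AICc voting, correlation tiers.

Candidate linear models relate each peptide's log2-fold values to worker
exposure metrics and covariates. Per peptide, every candidate model is
fit by ordinary least squares and scored with the small-sample-corrected
Akaike information criterion (AICc); the number of peptides for which a
model attains the lowest AICc is its "vote" count, whose significance
against the across-model count distribution is assessed with a one-sample
z-test and Benjamini-Hochberg adjustment. Models with significant votes
are then screened per peptide by adjusted R^2 at moderate (>= 0.4) and
strong (>= 0.7) tiers, and the intersection of the strong sets across the
selected model variants yields the peptides carried into discriminant
refinement.

AIC convention: ``AIC = n ln(RSS/n) + 2k`` with ``k`` counting the
regression coefficients, the intercept and the residual-variance
parameter — the standard Gaussian-likelihood AIC up to an additive
constant — and ``AICc = AIC + 2k(k+1)/(n-k-1)``.

The composite exposure value ("log-sum-exposure") of a worker is the
equal-weight sum of log10 breathing-zone metrics; a weighted variant is
available since the published construction is a single combined axis
without stated weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import EXPOSURE_METRICS, ExposureRecord
from .stats import bh_adjust
from scipy import stats as sps

# ---------------------------------------------------------------------------
# Predictor term vocabulary

_METRIC_TERMS = {
    "logInhEC": ("inh_ec",),
    "logResEC": ("res_ec",),
    "logSC": ("struct_count",),
    "logInhResEC": ("inh_ec", "res_ec"),
    "logSumExp": ("inh_ec", "res_ec", "struct_count"),
}
_SCIP_TERMS = {
    "logIL6": "scip_IL6",
    "logCCL2": "scip_CCL2",
    "logTNFalpha": "scip_TNFalpha",
    "logVCAM": "scip_VCAM",
    "logICAM": "scip_ICAM",
}
_NUMERIC_TERMS = ("age_bin", "duration_bin", "education_bin")
_FLAG_TERMS = ("former_smoker", "allergies", "hypertension", "solvent_current", "solvent_past")

KNOWN_TERMS = (
    tuple(_METRIC_TERMS) + tuple(_SCIP_TERMS) + _NUMERIC_TERMS + _FLAG_TERMS + ("sex",)
)


@dataclass(frozen=True)
class ModelSpec:
    """A candidate predictor combination."""

    model_id: str
    predictors: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.predictors:
            raise ValueError("predictor list must be non-empty")
        if len(set(self.predictors)) != len(self.predictors):
            raise ValueError(f"duplicate predictors in model {self.model_id!r}")
        unknown = set(self.predictors) - set(KNOWN_TERMS)
        if unknown:
            raise ValueError(f"unknown predictor terms: {sorted(unknown)}")


@dataclass
class ModelFitResult:
    peptide_id: str
    model_id: str
    rss: float
    k: int          # coefficients + intercept + residual variance
    n: int
    aicc: float
    adj_r2: float
    degenerate: bool = False


@dataclass
class VoteResult:
    model_id: str
    count: float  # fractional under exact-tie splitting
    z: float
    p: float
    q: float


# ---------------------------------------------------------------------------
# Composite exposure

def make_composite(
    record: ExposureRecord,
    metrics: tuple[str, ...] = EXPOSURE_METRICS,
    weights: tuple[float, ...] | None = None,
) -> float:
    """Composite exposure of one worker: sum of (weighted) log10 metrics."""
    values = [getattr(record, m) for m in metrics]
    if any(v <= 0 for v in values):
        raise ValueError("all composite metrics must be strictly positive")
    if weights is None:
        weights = (1.0,) * len(metrics)
    if len(weights) != len(metrics):
        raise ValueError("weights must match metrics")
    return float(sum(w * math.log10(v) for w, v in zip(weights, values)))


def composite_values(
    workers: pd.DataFrame,
    metrics: tuple[str, ...] = EXPOSURE_METRICS,
    weights: tuple[float, ...] | None = None,
) -> pd.Series:
    """Vectorized :func:`make_composite` over a worker table."""
    if weights is None:
        weights = (1.0,) * len(metrics)
    cols = workers[list(metrics)].to_numpy(dtype=float)
    if np.any(cols <= 0):
        raise ValueError("all composite metrics must be strictly positive")
    return pd.Series(
        np.log10(cols) @ np.asarray(weights, dtype=float),
        index=workers.index,
        name="composite",
    )


def design_matrix(workers: pd.DataFrame, predictors: tuple[str, ...]) -> np.ndarray:
    """Design matrix (with leading intercept column) for the given terms."""
    cols = [np.ones(len(workers))]
    for term in predictors:
        if term in _METRIC_TERMS:
            cols.append(composite_values(workers, _METRIC_TERMS[term]).to_numpy())
        elif term in _SCIP_TERMS:
            cols.append(workers[_SCIP_TERMS[term]].to_numpy(dtype=float))
        elif term in _NUMERIC_TERMS:
            cols.append(workers[term].to_numpy(dtype=float))
        elif term == "sex":
            cols.append((workers["sex"] == "F").to_numpy(dtype=float))
        elif term in _FLAG_TERMS:
            cols.append(workers[term].to_numpy(dtype=float))
        else:  # pragma: no cover - ModelSpec already validates
            raise ValueError(f"unknown term {term!r}")
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# Model-space enumeration

def enumerate_models(space: dict) -> list[ModelSpec]:
    """Deterministically enumerate base exposures x covariate subsets.

    ``space`` holds ``bases`` (exposure terms, each becoming the leading
    predictor), ``covariates`` (the pool) and ``max_covariates`` (largest
    subset size). Subsets are ordered by size then pool order.
    """
    bases = list(space.get("bases", []))
    pool = list(space.get("covariates", []))
    max_k = int(space.get("max_covariates", 0))
    if not bases:
        raise ValueError("model space has no base exposure terms")
    specs: list[ModelSpec] = []
    for base in bases:
        for size in range(0, max_k + 1):
            for subset in combinations(pool, size):
                predictors = (base, *subset)
                model_id = "+".join(predictors)
                specs.append(ModelSpec(model_id=model_id, predictors=predictors))
    return specs


def default_model_space() -> dict:
    """The model space shipped with the package (see data/models.yaml)."""
    with resources.files("peptidome_dx.data").joinpath("models.yaml").open() as fh:
        return yaml.safe_load(fh)


def load_model_space(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


# ---------------------------------------------------------------------------
# OLS / AICc scoring

def _aicc_from_rss(
    rss: float, n: int, n_coef: int, rss_floor: float = 0.0
) -> tuple[float, int, bool]:
    k = n_coef + 1  # + residual variance
    if n - k - 1 <= 0:
        raise ValueError(f"need n > k + 1 (n={n}, k={k})")
    if rss <= max(rss_floor, 0.0):
        return -math.inf, k, True
    aic = n * math.log(rss / n) + 2 * k
    return aic + 2 * k * (k + 1) / (n - k - 1), k, False


def fit_aicc(
    y: np.ndarray,
    X: np.ndarray,
    peptide_id: str = "",
    model_id: str = "",
) -> ModelFitResult:
    """OLS fit of one peptide against one design, scored by AICc."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("rank-deficient design matrix")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    # numerically-exact fits count as degenerate (RSS at rounding level)
    floor = np.finfo(float).eps * max(1.0, float(y @ y))
    aicc, k, degenerate = _aicc_from_rss(rss, n, p, rss_floor=floor)
    n_pred = p - 1  # predictors excluding intercept
    if tss == 0:
        adj_r2 = 0.0  # constant response: no variance to explain
    else:
        adj_r2 = 1.0 - (rss / (n - n_pred - 1)) / (tss / (n - 1))
    return ModelFitResult(
        peptide_id=peptide_id,
        model_id=model_id,
        rss=rss,
        k=k,
        n=n,
        aicc=aicc,
        adj_r2=adj_r2,
        degenerate=degenerate,
    )


def _batch_rss(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Row-wise OLS residual sum of squares of Y (peptides x n) on X."""
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("rank-deficient design matrix")
    q, _ = np.linalg.qr(X)
    resid = Y - (Y @ q) @ q.T
    return np.einsum("ij,ij->i", resid, resid)


def aicc_table(
    Y: pd.DataFrame,
    workers: pd.DataFrame,
    models: list[ModelSpec],
) -> pd.DataFrame:
    """AICc of every peptide (rows of ``Y``) under every model (columns)."""
    Yv = Y[workers.index].to_numpy(dtype=float)
    n = Yv.shape[1]
    out = {}
    for spec in models:
        X = design_matrix(workers, spec.predictors)
        rss = _batch_rss(Yv, X)
        k = X.shape[1] + 1
        if n - k - 1 <= 0:
            raise ValueError(f"model {spec.model_id}: need n > k + 1")
        with np.errstate(divide="ignore"):
            aic = n * np.log(rss / n) + 2 * k
        out[spec.model_id] = aic + 2 * k * (k + 1) / (n - k - 1)
    return pd.DataFrame(out, index=Y.index)


def adj_r2_table(
    Y: pd.DataFrame,
    workers: pd.DataFrame,
    models: list[ModelSpec],
) -> pd.DataFrame:
    """Adjusted R^2 of every peptide under every model."""
    Yv = Y[workers.index].to_numpy(dtype=float)
    n = Yv.shape[1]
    tss = ((Yv - Yv.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    out = {}
    for spec in models:
        X = design_matrix(workers, spec.predictors)
        rss = _batch_rss(Yv, X)
        n_pred = X.shape[1] - 1
        with np.errstate(divide="ignore", invalid="ignore"):
            adj = 1.0 - (rss / (n - n_pred - 1)) / (tss / (n - 1))
        adj[tss == 0] = 0.0
        out[spec.model_id] = adj
    return pd.DataFrame(out, index=Y.index)


# ---------------------------------------------------------------------------
# Voting

def vote_models(aicc: pd.DataFrame, delta: float = 0.0) -> list[VoteResult]:
    """Tabulate per-model lowest-AICc peptide counts with z/p/q.

    With ``delta = 0`` each peptide votes for the model with its minimum
    AICc; an exact tie splits the peptide's single vote equally among the
    tied models, so counts always sum to the number of peptides and the
    tabulation is invariant to peptide ordering. With ``delta > 0`` a
    peptide votes (a full count) for every model within ``delta`` AICc
    units of its minimum. The z-score of each count is taken against the
    empirical mean and sample SD of the counts across all models, with a
    one-sided upper p-value and BH adjustment over the model family.
    """
    if aicc.shape[1] < 3:
        raise ValueError("need at least 3 models for the vote z-test")
    if delta < 0:
        raise ValueError("delta must be >= 0")
    scores = aicc.to_numpy(dtype=float)
    counts = np.zeros(aicc.shape[1])
    if len(aicc) > 0:
        mins = scores.min(axis=1, keepdims=True)
        in_tol = scores <= mins + delta
        if delta == 0:
            counts = (in_tol / in_tol.sum(axis=1, keepdims=True)).sum(axis=0)
        else:
            counts = in_tol.sum(axis=0).astype(float)
    sd = counts.std(ddof=1)
    mean = counts.mean()
    if sd == 0:
        z = np.zeros_like(counts, dtype=float)
        p = np.full(counts.shape, 1.0 if len(aicc) else np.nan)
    else:
        z = (counts - mean) / sd
        p = sps.norm.sf(z)
    q = bh_adjust(p) if not np.any(np.isnan(p)) else p
    return [
        VoteResult(model_id=m, count=float(c), z=float(zz), p=float(pp), q=float(qq))
        for m, c, zz, pp, qq in zip(aicc.columns, counts, z, p, q)
    ]


# ---------------------------------------------------------------------------
# Correlation filtering

@dataclass
class CorrelationTiers:
    """R^2-threshold peptide sets per model and their strong intersection."""

    adj_r2: pd.DataFrame                 # peptides x models
    moderate: dict[str, list[str]]       # model -> peptides with adj R2 >= moderate
    strong: dict[str, list[str]]         # model -> peptides with adj R2 >= strong
    common_strong: list[str]             # intersection of strong sets


def correlation_filter(
    Y: pd.DataFrame,
    workers: pd.DataFrame,
    models: list[ModelSpec],
    moderate: float = 0.4,
    strong: float = 0.7,
) -> CorrelationTiers:
    """Tier peptides by adjusted R^2 against each model.

    The ``common_strong`` set is the intersection of the strong sets
    across *all* supplied models, in ``Y`` row order.
    """
    table = adj_r2_table(Y, workers, models)
    moderate_sets = {m: table.index[table[m] >= moderate].tolist() for m in table.columns}
    strong_sets = {m: table.index[table[m] >= strong].tolist() for m in table.columns}
    common: set = set(Y.index)
    for peptides in strong_sets.values():
        common &= set(peptides)
    common_ordered = [p for p in Y.index if p in common]
    return CorrelationTiers(
        adj_r2=table,
        moderate=moderate_sets,
        strong=strong_sets,
        common_strong=common_ordered,
    )
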