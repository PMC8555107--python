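"""Quantitative preprocessing of the aligned peptide matrix.

The chain applied before any statistics: reproducibility filtering on
per-group detection fractions, multiplicative median centering of sample
columns, left-censored imputation at the intensity limit of
quantification (LOQ), log2 transform, and standardization of each peptide
to fold-difference from the Low-group mean.

Median centering rescales each sample column so its observed median
equals the geometric mean of the column medians; the multiplicative form
preserves positivity for the log2 transform and is equivalent to an
additive shift in log space. The default stage order is
center -> impute -> log2/standardize, so imputed cells sit exactly at the
LOQ on the centered scale.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
import pandas as pd

from .alignment import detection_counts
from .cohort import LOW
from .quant import LOG2_FOLD_FROM_LOW, RAW, QuantMatrix

logger = logging.getLogger(__name__)


def filter_by_detection(
    matrix: QuantMatrix,
    groups: dict[str, str] | pd.Series,
    min_frac: float,
    rule: str = "both",
) -> QuantMatrix:
    """Retain peptides detected in at least ``min_frac`` of each group.

    ``rule="both"`` (default) requires the fraction in every group;
    ``rule="either"`` requires it in at least one. Row order is preserved.
    """
    if not 0.0 < min_frac <= 1.0:
        raise ValueError("min_frac must be in (0, 1]")
    if rule not in ("both", "either"):
        raise ValueError("rule must be 'both' or 'either'")
    fractions = detection_counts(matrix, groups)
    ok = fractions.ge(min_frac)
    keep = ok.all(axis=1) if rule == "both" else ok.any(axis=1)
    if not keep.any():
        logger.warning("detection filter at %.2f removed every peptide", min_frac)
    return matrix.select_features(matrix.values.index[keep.to_numpy()])


def median_center(matrix: QuantMatrix) -> QuantMatrix:
    """Scale each sample column to a common median.

    The common target is the geometric mean of the observed column
    medians; each column is multiplied by target / median(column).
    Missing cells are untouched.
    """
    if matrix.scale != RAW:
        raise ValueError("median centering applies to raw-scale intensities")
    medians = matrix.values.median(axis=0, skipna=True)
    if medians.isna().any() or (medians <= 0).any():
        bad = medians.index[medians.isna() | (medians <= 0)].tolist()
        raise ValueError(f"columns without a positive observed median: {bad}")
    target = float(np.exp(np.log(medians).mean()))
    factors = target / medians
    return replace(matrix, values=matrix.values * factors, mask=matrix.mask.copy())


def impute_left_censored(matrix: QuantMatrix) -> QuantMatrix:
    """Replace missing cells with the intensity LOQ.

    Left-censored measurements are not missing at random — they fell below
    the limit of quantification — so they are substituted at that limit.
    The observed-cell mask is retained for provenance; observed values are
    never modified.
    """
    if matrix.intensity_loq is None or not np.isfinite(matrix.intensity_loq):
        raise ValueError("matrix.intensity_loq must be set before imputation")
    values = matrix.values.fillna(matrix.intensity_loq)
    return replace(matrix, values=values, mask=matrix.mask.copy())


def log2_and_standardize(
    matrix: QuantMatrix,
    groups: dict[str, str] | pd.Series,
    reference_group: str = LOW,
) -> QuantMatrix:
    """log2-transform and express each peptide as fold from the Low mean.

    After the transform every value is ``log2(intensity)`` minus the
    peptide's reference-group (Low) mean, so the reference-group mean of
    each peptide is zero. Applying this to an already-standardized matrix
    only repeats the (now zero) mean subtraction, making the operation
    idempotent.
    """
    groups = pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
    groups = groups.loc[matrix.workers]
    ref_cols = groups.index[groups == reference_group].tolist()
    if not ref_cols:
        raise ValueError(f"no workers in reference group {reference_group!r}")

    if matrix.scale == RAW:
        vals = matrix.values.to_numpy(dtype=float)
        if np.nanmin(vals) <= 0:
            raise ValueError("log2 transform requires strictly positive intensities")
        log_values = np.log2(matrix.values)
    else:
        log_values = matrix.values
    ref_mean = log_values[ref_cols].mean(axis=1)
    standardized = log_values.sub(ref_mean, axis=0)
    return replace(
        matrix,
        values=standardized,
        mask=matrix.mask.copy(),
        scale=LOG2_FOLD_FROM_LOW,
    )


def preprocess(
    matrix: QuantMatrix,
    groups: dict[str, str] | pd.Series,
    min_frac: float = 0.75,
    rule: str = "both",
) -> QuantMatrix:
    """Full default chain: filter -> median center -> impute -> log2/fold."""
    out = filter_by_detection(matrix, groups, min_frac=min_frac, rule=rule)
    out = median_center(out)
    out = impute_left_censored(out)
    return log2_and_standardize(out, groups)
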