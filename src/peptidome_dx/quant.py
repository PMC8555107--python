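"""Aligned peptide-by-worker quantitation matrix.

The :class:`QuantMatrix` is the central container of the pipeline: a
features x workers table of ion intensities with an explicit missingness
mask, the intensity limit of quantification (LOQ) used for left-censored
imputation, and a scale flag that tracks the raw -> log2-fold-from-Low
state transition applied by preprocessing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

RAW = "raw"
LOG2_FOLD_FROM_LOW = "log2_fold_from_low"

_SCALES = (RAW, LOG2_FOLD_FROM_LOW)


@dataclass
class QuantMatrix:
    """Peptide x worker intensity matrix with missingness mask.

    Parameters
    ----------
    values
        Features (rows) by workers (columns); ``NaN`` marks a missing cell
        until imputation fills it.
    intensity_loq
        Minimum quantifiable raw intensity. Imputation substitutes this
        value into missing cells.
    scale
        ``"raw"`` for native intensities, ``"log2_fold_from_low"`` after
        log2 transform and standardization to the Low-group mean.
    mask
        Boolean observed-cell mask kept for provenance; defaults to
        ``values.notna()`` at construction and is *not* updated by
        imputation, so the censoring pattern stays recoverable.
    features
        Optional per-feature metadata (e.g. cluster centroids ``mh_plus``,
        ``rt``, ``drift_bin``) indexed like ``values``.
    """

    values: pd.DataFrame
    intensity_loq: float
    scale: str = RAW
    mask: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    features: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.scale not in _SCALES:
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.mask is None:
            self.mask = self.values.notna()
        if not self.mask.index.equals(self.values.index) or not self.mask.columns.equals(
            self.values.columns
        ):
            raise ValueError("mask must be aligned with values")

    # -- basic introspection -------------------------------------------------
    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def workers(self) -> list[str]:
        return list(self.values.columns)

    @property
    def feature_ids(self) -> list:
        return list(self.values.index)

    def copy(self) -> "QuantMatrix":
        return replace(
            self,
            values=self.values.copy(),
            mask=self.mask.copy(),
            features=None if self.features is None else self.features.copy(),
        )

    def select_features(self, ids) -> "QuantMatrix":
        """Row-subset preserving order of ``ids``."""
        return replace(
            self,
            values=self.values.loc[ids],
            mask=self.mask.loc[ids],
            features=None if self.features is None else self.features.loc[ids],
        )

    # -- IO ------------------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        """Write as TSV with empty cells for missing values."""
        self.values.to_csv(path, sep="\t", index_label="peptide_id", na_rep="")

    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        intensity_loq: float | None = None,
        scale: str = RAW,
    ) -> "QuantMatrix":
        """Read a matrix TSV (rows = peptides, columns = workers).

        When ``intensity_loq`` is omitted it defaults to the smallest
        observed intensity, the same convention the alignment stage uses.
        """
        values = pd.read_csv(path, sep="\t", index_col="peptide_id")
        if intensity_loq is None:
            observed = values.to_numpy(dtype=float)
            observed = observed[np.isfinite(observed)]
            if observed.size == 0:
                raise ValueError("cannot infer intensity LOQ from an all-missing matrix")
            intensity_loq = float(observed.min())
        return cls(values=values, intensity_loq=float(intensity_loq), scale=scale)
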