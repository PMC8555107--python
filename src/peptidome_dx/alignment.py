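"""Cross-sample ion-event alignment.

Label-free ion-mobility LC-MS produces, per sample, a list of ion events
(charge-reduced mass MH+, chromatographic retention time, drift-time bin,
intensity). Events from biological replicates are clustered into
cross-sample peptide features using mass (+/- 6 ppm), retention time
(+/- 2 min) and drift time (+/- 4 bins) tolerances.

The clustering is greedy and deterministic: events are processed in
descending intensity; each event joins the existing cluster whose running
intensity-weighted centroid lies within all three tolerances (ties broken
by the smallest mass difference), otherwise it seeds a new cluster. On
well-separated data this reproduces the exhaustive single-linkage
components; the greedy order makes it independent of input ordering.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .quant import RAW, QuantMatrix


@dataclass(frozen=True)
class IonEvent:
    """A single per-sample ion detection."""

    sample_id: str
    mh_plus: float  # charge-reduced ion mass, Da
    rt: float       # retention time, minutes
    drift_bin: int
    intensity: float

    def __post_init__(self) -> None:
        if self.mh_plus <= 0:
            raise ValueError("mh_plus must be positive")
        if self.intensity <= 0:
            raise ValueError("intensity must be positive")


@dataclass(frozen=True)
class AlignmentTolerances:
    """Match tolerances; all inclusive (<=)."""

    rt_tol: float = 2.0        # minutes
    drift_tol: float = 4.0     # bins
    mass_tol_ppm: float = 6.0  # parts per million of the centroid mass

    def __post_init__(self) -> None:
        if min(self.rt_tol, self.drift_tol, self.mass_tol_ppm) <= 0:
            raise ValueError("all tolerances must be strictly positive")


class _Cluster:
    __slots__ = ("mh", "rt", "drift", "weight", "members")

    def __init__(self, event: IonEvent):
        self.mh = event.mh_plus
        self.rt = event.rt
        self.drift = float(event.drift_bin)
        self.weight = event.intensity
        self.members: list[IonEvent] = [event]

    def absorb(self, event: IonEvent) -> None:
        w = self.weight + event.intensity
        f = event.intensity / w
        self.mh += (event.mh_plus - self.mh) * f
        self.rt += (event.rt - self.rt) * f
        self.drift += (event.drift_bin - self.drift) * f
        self.weight = w
        self.members.append(event)


def cluster_ion_events(
    events: list[IonEvent],
    tol: AlignmentTolerances | None = None,
) -> QuantMatrix:
    """Cluster ion events across samples into a :class:`QuantMatrix`.

    Matrix cells hold the summed intensity of a sample's events within a
    cluster and are missing where a sample contributed none. The matrix
    ``intensity_loq`` defaults to the smallest clustered cell intensity.
    """
    if not events:
        raise ValueError("events must be non-empty")
    tol = tol or AlignmentTolerances()

    # Descending intensity; deterministic tie-break on coordinates.
    ordered = sorted(
        events,
        key=lambda e: (-e.intensity, e.mh_plus, e.rt, e.drift_bin, e.sample_id),
    )
    clusters: list[_Cluster] = []
    for event in ordered:
        best: _Cluster | None = None
        best_dm = np.inf
        for cluster in clusters:
            dm = abs(event.mh_plus - cluster.mh)
            if (
                dm / cluster.mh * 1e6 <= tol.mass_tol_ppm
                and abs(event.rt - cluster.rt) <= tol.rt_tol
                and abs(event.drift_bin - cluster.drift) <= tol.drift_tol
                and dm < best_dm
            ):
                best, best_dm = cluster, dm
        if best is None:
            clusters.append(_Cluster(event))
        else:
            best.absorb(event)

    samples = sorted({e.sample_id for e in events})
    feature_ids = [f"feat{i:05d}" for i in range(len(clusters))]
    values = pd.DataFrame(np.nan, index=feature_ids, columns=samples)
    meta = pd.DataFrame(
        {
            "mh_plus": [c.mh for c in clusters],
            "rt": [c.rt for c in clusters],
            "drift_bin": [c.drift for c in clusters],
        },
        index=feature_ids,
    )
    for fid, cluster in zip(feature_ids, clusters):
        for event in cluster.members:
            cell = values.at[fid, event.sample_id]
            values.at[fid, event.sample_id] = (
                event.intensity if np.isnan(cell) else cell + event.intensity
            )

    observed = values.to_numpy()
    loq = float(np.nanmin(observed))
    return QuantMatrix(values=values, intensity_loq=loq, scale=RAW, features=meta)


def detection_counts(
    matrix: QuantMatrix, groups: dict[str, str] | pd.Series
) -> pd.DataFrame:
    """Per-peptide, per-group detection fractions.

    ``groups`` maps every worker column to its group label; the
    denominator of each fraction is that group's size.
    """
    groups = pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
    unknown = set(matrix.workers) - set(groups.index)
    if unknown:
        raise KeyError(f"workers without a group assignment: {sorted(unknown)}")
    groups = groups.loc[matrix.workers]
    observed = matrix.values.notna()
    fractions = {}
    for label, members in groups.groupby(groups).groups.items():
        cols = list(members)
        fractions[label] = observed[cols].sum(axis=1) / len(cols)
    return pd.DataFrame(fractions)


# -- event-list IO -----------------------------------------------------------

_EVENT_COLUMNS = ["sample_id", "mh_plus_da", "rt_min", "drift_bin", "intensity"]


def write_events_tsv(events: list[IonEvent], path: str | Path) -> None:
    pd.DataFrame(
        [
            (e.sample_id, e.mh_plus, e.rt, e.drift_bin, e.intensity)
            for e in events
        ],
        columns=_EVENT_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def read_events_tsv(path: str | Path) -> list[IonEvent]:
    frame = pd.read_csv(path, sep="\t")
    missing = set(_EVENT_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"event TSV missing columns: {sorted(missing)}")
    return [
        IonEvent(
            sample_id=str(row.sample_id),
            mh_plus=float(row.mh_plus_da),
            rt=float(row.rt_min),
            drift_bin=int(row.drift_bin),
            intensity=float(row.intensity),
        )
        for row in frame.itertuples()
    ]
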