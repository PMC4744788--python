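"""Reading and writing monitoring CSVs, truth grids, prediction grids, manifests.

The monitoring interchange format is a comma-separated, UTF-8, '.'-decimal
CSV with columns ``WellName, XCoord, YCoord, SampleDate, Result``.  Dates
are ISO 8601 (date or datetime); on read they become fractional days since
the earliest sample.  Concentrations must be non-negative; censored or
non-detect values are not handled — pre-impute them before fitting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import MonitoringDataset, ResponseTransform
from .model import PredictionGrid
from .simulate import PlumeTruth

__all__ = [
    "read_monitoring_csv",
    "write_monitoring_csv",
    "write_truth_grid",
    "read_truth_grid",
    "write_prediction_grid",
    "read_prediction_grid",
    "write_manifest",
    "read_manifest",
    "TimeMapping",
]

REQUIRED_COLUMNS = ("WellName", "XCoord", "YCoord", "SampleDate", "Result")


@dataclass(frozen=True)
class TimeMapping:
    """Affine map between model time units and calendar dates."""

    origin: str = "2020-01-01"
    days_per_unit: float = 365.25

    def to_dates(self, t: np.ndarray) -> pd.DatetimeIndex:
        base = pd.Timestamp(self.origin)
        return base + pd.to_timedelta(np.asarray(t, float) * self.days_per_unit, unit="D")

    def days_to_units(self, days: np.ndarray, offset_units: float = 0.0) -> np.ndarray:
        return np.asarray(days, float) / self.days_per_unit + offset_units


def _line_no(i: int) -> int:
    # header occupies line 1; data row i (0-based) is file line i + 2
    return i + 2


def read_monitoring_csv(
    path, transform: ResponseTransform | None = None
) -> MonitoringDataset:
    """Read a monitoring CSV into a typed dataset.

    Duplicate (well, date) rows are kept — replicate samples are legitimate.
    Raises with the offending file row on unparseable dates or numbers and
    on negative results.
    """
    transform = transform or ResponseTransform()
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {missing}")
    if len(df) == 0:
        raise ValueError("no data rows")

    dates = pd.to_datetime(df["SampleDate"], errors="coerce", format="ISO8601")
    bad = np.where(dates.isna().to_numpy())[0]
    if len(bad):
        raise ValueError(
            f"unparseable SampleDate {df['SampleDate'].iloc[bad[0]]!r} "
            f"on row {_line_no(bad[0])}"
        )
    numeric = {}
    for col in ("XCoord", "YCoord", "Result"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.where(vals.isna().to_numpy())[0]
        if len(bad):
            raise ValueError(
                f"unparseable {col} {df[col].iloc[bad[0]]!r} on row {_line_no(bad[0])}"
            )
        numeric[col] = vals.to_numpy(dtype=float)
    neg = np.where(numeric["Result"] < 0)[0]
    if len(neg):
        raise ValueError(
            f"negative Result on row {_line_no(neg[0])}; censored/non-detect "
            "values must be pre-imputed"
        )

    t_days = (dates - dates.min()).dt.total_seconds().to_numpy() / 86400.0
    return MonitoringDataset.from_raw(
        well=df["WellName"].astype(str).to_numpy(dtype=object),
        s1=numeric["XCoord"],
        s2=numeric["YCoord"],
        t=t_days,
        raw=numeric["Result"],
        transform=transform,
    )


def write_monitoring_csv(
    data: MonitoringDataset, path, time_mapping: TimeMapping = TimeMapping()
) -> None:
    """Write a dataset in the interchange format (times become ISO datetimes)."""
    if data.raw is None:
        raise ValueError("dataset has no raw concentrations to write")
    dates = time_mapping.to_dates(data.t)
    pd.DataFrame(
        {
            "WellName": [str(w) for w in data.well],
            "XCoord": data.s1,
            "YCoord": data.s2,
            "SampleDate": dates.strftime("%Y-%m-%dT%H:%M:%S.%f"),
            "Result": data.raw,
        }
    ).to_csv(path, index=False)


def write_truth_grid(truth: PlumeTruth, path) -> None:
    """Long-format CSV (s1, s2, t, true_value) of the solved truth field."""
    T, S1, S2 = np.meshgrid(truth.t, truth.s1, truth.s2, indexing="ij")
    pd.DataFrame(
        {
            "s1": S1.ravel(),
            "s2": S2.ravel(),
            "t": T.ravel(),
            "true_value": truth.values.ravel(),
        }
    ).to_csv(path, index=False)


def read_truth_grid(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_prediction_grid(grid: PredictionGrid, path, metadata: dict | None = None) -> None:
    """Long-format prediction CSV with a '#'-prefixed metadata header block."""
    df = pd.DataFrame(
        {
            "s1": grid.s1,
            "s2": grid.s2,
            "t": grid.t,
            "mean": grid.mean,
            "lower": grid.lower,
            "upper": grid.upper,
            "in_hull": (
                grid.in_hull.astype(int)
                if grid.in_hull is not None
                else np.full(len(grid.mean), -1)
            ),
        }
    )
    with open(path, "w", encoding="utf-8") as fh:
        meta = dict(metadata or {})
        meta.setdefault("credible_level", grid.level)
        for key, value in meta.items():
            fh.write(f"# {key}: {json.dumps(value)}\n")
        df.to_csv(fh, index=False, float_format="%.12g")


def read_prediction_grid(path) -> tuple[pd.DataFrame, dict]:
    """Round-trip reader for prediction CSVs: (frame, metadata)."""
    meta = {}
    with open(path, encoding="utf-8") as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, value = line[1:].partition(":")
            meta[key.strip()] = json.loads(value)
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh)
    return df, meta


def write_manifest(path, **entries) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(entries, fh, indent=2, default=str)
        fh.write("\n")


def read_manifest(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
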