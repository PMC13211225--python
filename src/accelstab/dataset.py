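"""Tidy stability-study tables: the universal fitting input.

A :class:`StabilityDataset` holds one row per measurement — assay name,
stress temperature, time under stress, replicate id, response value — for a
multi-temperature accelerated stability study (e.g. 5/25/40/45 °C over 0–3
months).  The on-disk format is a plain CSV with columns
``assay,temp_C,time_months,replicate,value``; temperatures are stored in
Kelvin in memory.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .kinetics import celsius_to_kelvin

CSV_COLUMNS = ["assay", "temp_C", "time_months", "replicate", "value"]
_FRAME_COLUMNS = ["assay", "temp_K", "time_months", "replicate", "value"]


class DatasetError(ValueError):
    """Malformed or insufficient stability data."""


@dataclass(frozen=True)
class StabilityDataset:
    """Long-format stability table with columns
    ``assay, temp_K, time_months, replicate, value``."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in _FRAME_COLUMNS if c not in df.columns]
        if missing:
            raise DatasetError(f"missing columns: {missing}")
        df = df.loc[:, _FRAME_COLUMNS].reset_index(drop=True)
        df["temp_K"] = df["temp_K"].astype(float)
        df["time_months"] = df["time_months"].astype(float)
        df["value"] = df["value"].astype(float)
        if (df["time_months"] < 0).any():
            raise DatasetError("times must be >= 0")
        if (df["temp_K"] <= 0).any():
            raise DatasetError("temperatures must be > 0 K")
        if not np.isfinite(df["value"]).all():
            raise DatasetError("all response values must be finite")
        object.__setattr__(self, "frame", df)

    # -- construction -----------------------------------------------------
    @classmethod
    def from_records(cls, records) -> "StabilityDataset":
        """Build from an iterable of dicts with either temp_K or temp_C."""
        df = pd.DataFrame(list(records))
        if "temp_K" not in df.columns and "temp_C" in df.columns:
            df["temp_K"] = df["temp_C"].astype(float).map(celsius_to_kelvin)
        return cls(df)

    @classmethod
    def from_csv(cls, path: str | Path) -> "StabilityDataset":
        df = pd.read_csv(path)
        missing = [c for c in CSV_COLUMNS if c not in df.columns]
        if missing:
            raise DatasetError(f"CSV {path} missing columns: {missing}")
        df["temp_K"] = df["temp_C"].astype(float).map(celsius_to_kelvin)
        return cls(df)

    def to_csv(self, path: str | Path) -> None:
        out = self.frame.copy()
        out["temp_C"] = out["temp_K"] - 273.15
        out[CSV_COLUMNS].to_csv(path, index=False)

    # -- views -------------------------------------------------------------
    @property
    def assays(self) -> list[str]:
        return sorted(self.frame["assay"].unique())

    def select(self, assay: str) -> "StabilityDataset":
        sub = self.frame[self.frame["assay"] == assay]
        if sub.empty:
            raise DatasetError(f"no rows for assay {assay!r}")
        return StabilityDataset(sub)

    @property
    def temperatures(self) -> np.ndarray:
        return np.sort(self.frame["temp_K"].unique())

    @property
    def n_points(self) -> int:
        return len(self.frame)

    def with_values(self, values: np.ndarray) -> "StabilityDataset":
        """Copy with the response column replaced (row order preserved)."""
        values = np.asarray(values, dtype=float)
        if values.shape != (len(self.frame),):
            raise DatasetError("replacement values must match row count")
        df = self.frame.copy()
        df["value"] = values
        return StabilityDataset(df)

    def groups(self):
        """Yield (temp_K, times, values) per temperature, ascending."""
        for temp_k, sub in self.frame.groupby("temp_K", sort=True):
            yield float(temp_k), sub["time_months"].to_numpy(), sub["value"].to_numpy()

    def require_fittable(self) -> None:
        """Arrhenius fitting needs ≥2 temperatures and ≥3 time points."""
        if len(self.frame["assay"].unique()) != 1:
            raise DatasetError("fit one assay at a time (use .select)")
        if self.frame["temp_K"].nunique() < 2:
            raise DatasetError("need >= 2 distinct temperatures")
        if self.frame["time_months"].nunique() < 3:
            raise DatasetError("need >= 3 distinct time points")
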