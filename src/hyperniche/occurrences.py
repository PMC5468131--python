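"""Occurrence tables: id, longitude, latitude, group label."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import ConfigurationError

COLUMNS = ["id", "lon", "lat", "group"]


@dataclass
class OccurrenceSet:
    """A table of presence records.

    Thin wrapper over a DataFrame with columns ``id, lon, lat, group``;
    longitudes in [-180, 180], latitudes in [-90, 90].  Row order is
    meaningful (per-cell deduplication keeps the first record).
    """

    df: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise ConfigurationError(f"occurrence table missing columns {missing}")
        self.df = self.df[COLUMNS].reset_index(drop=True)
        lon, lat = self.df["lon"], self.df["lat"]
        if ((lon < -180) | (lon > 180)).any() or ((lat < -90) | (lat > 90)).any():
            raise ConfigurationError("occurrence lon/lat outside valid ranges")

    def __len__(self):
        return len(self.df)

    @property
    def groups(self):
        """Group labels in first-appearance order."""
        return list(dict.fromkeys(self.df["group"]))

    def for_group(self, group) -> "OccurrenceSet":
        return OccurrenceSet(self.df[self.df["group"] == group].copy())

    def lonlat(self):
        return self.df["lon"].to_numpy(), self.df["lat"].to_numpy()

    @classmethod
    def concat(cls, parts) -> "OccurrenceSet":
        return cls(pd.concat([p.df for p in parts], ignore_index=True))

    @classmethod
    def read_csv(cls, path) -> "OccurrenceSet":
        return cls(pd.read_csv(path))

    def write_csv(self, path):
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        self.df.to_csv(path, index=False, float_format="%.10g")
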