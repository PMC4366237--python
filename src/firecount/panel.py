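"""Reading, validation and summary of monthly county fire/weather panels.

A panel has one row per (county, year, month) with a non-negative integer
fire count and seven meteorological covariates: monthly maximum and mean
temperature, mean relative humidity, mean and maximum wind speed,
precipitation and evaporation. Counties are the clustering unit for the
mixed models downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "COVARIATES",
    "COLUMNS",
    "FireObservation",
    "PanelDataset",
    "PanelConfigError",
    "PanelValidationError",
    "read_panel",
    "write_panel",
    "summarize_covariates",
]

COVARIATES = (
    "tmax",
    "tmean",
    "humidity",
    "wind_mean",
    "wind_max",
    "precipitation",
    "evaporation",
)
COLUMNS = ("county", "year", "month", "fire_count") + COVARIATES


class PanelConfigError(ValueError):
    """The file/column configuration is unusable (e.g. a missing column)."""


class PanelValidationError(ValueError):
    """One or more rows violate panel invariants; offending rows are listed."""


@dataclass(frozen=True)
class FireObservation:
    """A single (county, year, month) record."""

    county: str
    year: int
    month: int
    fire_count: int
    tmax: float
    tmean: float
    humidity: float
    wind_mean: float
    wind_max: float
    precipitation: float
    evaporation: float


def _validate_frame(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise PanelConfigError(f"missing mandatory column(s): {missing}")
    df = df.loc[:, list(COLUMNS)].copy()
    problems: list[str] = []

    def rows(mask) -> list[int]:
        return df.index[np.asarray(mask)].tolist()

    na_mask = df.isna().any(axis=1)
    if na_mask.any():
        problems.append(f"missing values in rows {rows(na_mask)}")
    cnt = pd.to_numeric(df["fire_count"], errors="coerce")
    bad_cnt = cnt.isna() | (cnt < 0) | (cnt != np.floor(cnt.fillna(0)))
    bad_cnt &= ~df["fire_count"].isna()
    if bad_cnt.any():
        problems.append(
            f"fire_count must be a non-negative integer; bad rows {rows(bad_cnt)}"
        )
    for c in COVARIATES:
        vals = pd.to_numeric(df[c], errors="coerce")
        bad = (vals.isna() | ~np.isfinite(vals)) & ~df[c].isna()
        if bad.any():
            problems.append(f"covariate {c!r} must be finite; bad rows {rows(bad)}")
    if problems:
        raise PanelValidationError("; ".join(problems))

    df["county"] = df["county"].astype(str)
    df["year"] = df["year"].astype(np.int64)
    df["month"] = df["month"].astype(np.int64)
    df["fire_count"] = df["fire_count"].astype(np.int64)
    for c in COVARIATES:
        df[c] = df[c].astype(np.float64)

    high_h = df["humidity"] > 100.0
    if high_h.any():
        # monthly mean relative humidity above 100% does occur in station
        # records; keep the values, never clip
        warnings.warn(
            f"humidity > 100% in rows {rows(high_h)} (accepted, not clipped)",
            stacklevel=3,
        )
    off_season = ~df["month"].between(1, 4)
    if off_season.any():
        warnings.warn(
            f"months outside the spring fire season (1-4) in rows "
            f"{rows(off_season)}",
            stacklevel=3,
        )
    return df


class PanelDataset:
    """A validated panel of fire observations grouped by county.

    Wraps a DataFrame with canonical columns; row order is preserved exactly
    (round-tripping through CSV reproduces every field). Cluster membership
    is exposed via :attr:`clusters`.
    """

    def __init__(self, frame: pd.DataFrame):
        self._frame = _validate_frame(pd.DataFrame(frame).reset_index(drop=True))
        if self._frame.empty:
            raise PanelValidationError("panel has no observations")

    # -- construction ----------------------------------------------------------
    @classmethod
    def from_observations(cls, observations: Iterable[FireObservation]) -> "PanelDataset":
        rows = [vars(o) if isinstance(o, FireObservation) else dict(o) for o in observations]
        df = pd.DataFrame(rows).rename(columns={"county_id": "county"})
        return cls(df)

    # -- views -----------------------------------------------------------------
    @property
    def frame(self) -> pd.DataFrame:
        return self._frame.copy()

    @property
    def n_obs(self) -> int:
        return len(self._frame)

    @property
    def counties(self) -> list[str]:
        return list(dict.fromkeys(self._frame["county"]))

    @property
    def n_clusters(self) -> int:
        return len(self.counties)

    @property
    def clusters(self) -> dict[str, np.ndarray]:
        """Mapping county -> integer row indices of its observations."""
        idx = self._frame.groupby("county", sort=False).indices
        return {k: np.asarray(v) for k, v in idx.items()}

    @property
    def counts(self) -> np.ndarray:
        return self._frame["fire_count"].to_numpy()

    @property
    def observations(self) -> list[FireObservation]:
        return [FireObservation(**rec) for rec in self._frame.to_dict("records")]

    def covariate_matrix(self, names) -> np.ndarray:
        unknown = [n for n in names if n not in COVARIATES]
        if unknown:
            raise PanelConfigError(f"unknown covariate(s): {unknown}")
        return self._frame.loc[:, list(names)].to_numpy()

    def __len__(self) -> int:
        return self.n_obs

    def __repr__(self) -> str:
        return (
            f"PanelDataset(n_obs={self.n_obs}, n_clusters={self.n_clusters}, "
            f"counts 0..{int(self.counts.max())})"
        )


def read_panel(
    path,
    column_map: Mapping[str, str] | None = None,
    delimiter: str = ",",
) -> PanelDataset:
    """Read a delimited panel file into a validated :class:`PanelDataset`.

    ``column_map`` maps file column names to canonical field names
    (``county, year, month, fire_count`` plus :data:`COVARIATES`); columns
    already canonically named need no entry.
    """
    df = pd.read_csv(path, sep=delimiter)
    if column_map:
        missing_src = [c for c in column_map if c not in df.columns]
        if missing_src:
            raise PanelConfigError(
                f"column_map refers to absent file column(s): {missing_src}"
            )
        df = df.rename(columns=dict(column_map))
    return PanelDataset(df)


def write_panel(data: PanelDataset, path, delimiter: str = ",") -> None:
    data.frame.to_csv(path, sep=delimiter, index=False)


def summarize_covariates(data: PanelDataset) -> pd.DataFrame:
    """Per-covariate (min, max, mean, SD) table; SD uses the n-1 denominator."""
    df = data.frame
    out = pd.DataFrame(
        {
            "min": [df[c].min() for c in COVARIATES],
            "max": [df[c].max() for c in COVARIATES],
            "mean": [df[c].mean() for c in COVARIATES],
            "sd": [df[c].std(ddof=1) for c in COVARIATES],
        },
        index=list(COVARIATES),
    )
    out.index.name = "covariate"
    return out
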