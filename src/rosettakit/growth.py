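"""Relative rosette area growth rate between consecutive imaging dates.

The classical relative growth rate: difference of natural-log areas per
unit time, reported at the midpoint of each interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class AreaSeries:
    """Ordered (das, area) observations for one plant."""

    plant_id: str
    das: np.ndarray
    area: np.ndarray

    def __post_init__(self) -> None:
        das = np.asarray(self.das, dtype=float)
        area = np.asarray(self.area, dtype=float)
        if das.shape != area.shape or das.ndim != 1:
            raise ValueError("das and area must be 1-D arrays of equal length")
        if np.any(np.diff(das) <= 0):
            raise ValueError("das must be strictly increasing")
        if np.any(area <= 0) or not np.all(np.isfinite(area)):
            raise ValueError("areas must be finite and > 0")
        object.__setattr__(self, "das", das)
        object.__setattr__(self, "area", area)


@dataclass(frozen=True)
class RragrSeries:
    """Per-interval growth rates (1/day) at interval mid-times."""

    plant_id: str
    mid_das: np.ndarray
    rragr: np.ndarray


def rragr(series: AreaSeries) -> RragrSeries:
    """rragr_i = (ln A_{i+1} - ln A_i) / (t_{i+1} - t_i) at mid-time.

    A single time point yields an empty series.  Missing intermediate
    observations are not interpolated: rates are computed over the
    consecutive pairs that are present.
    """
    t, a = series.das, series.area
    if t.size < 2:
        return RragrSeries(series.plant_id, np.array([]), np.array([]))
    rates = np.diff(np.log(a)) / np.diff(t)
    mids = (t[:-1] + t[1:]) / 2.0
    return RragrSeries(series.plant_id, mids, rates)


def rragr_table(table: pd.DataFrame) -> pd.DataFrame:
    """Per-plant growth rates from a long-format descriptor table.

    Expects columns ``plant_id``, ``ecotype``, ``das``, ``area``; returns
    columns ``plant_id``, ``ecotype``, ``mid_das``, ``rragr``.
    """
    required = {"plant_id", "ecotype", "das", "area"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"missing required column(s): {sorted(missing)}")
    out = []
    for (pid, eco), grp in table.groupby(["plant_id", "ecotype"], sort=True):
        grp = grp.sort_values("das")
        res = rragr(AreaSeries(str(pid), grp["das"].to_numpy(), grp["area"].to_numpy()))
        for m, r in zip(res.mid_das, res.rragr):
            out.append({"plant_id": pid, "ecotype": eco, "mid_das": m, "rragr": r})
    cols = ["plant_id", "ecotype", "mid_das", "rragr"]
    if not out:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(out, columns=cols)


def exponential_area_series(
    plant_id: str, a0: float, k: float, das: np.ndarray
) -> AreaSeries:
    """Analytic A(t) = a0 * exp(k t) series, handy as a closed-form oracle."""
    das = np.asarray(das, dtype=float)
    return AreaSeries(plant_id, das, a0 * np.exp(k * das))


__all__ = ["AreaSeries", "RragrSeries", "rragr", "rragr_table", "exponential_area_series"]
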