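"""Growth-series arithmetic: specific growth rates and dry-weight bookkeeping.

The specific growth rate over an interval is mu = (ln n2 - ln n1)/(t2 - t1)
per day; the culture-level average is the arithmetic mean of the per-interval
rates (e.g. over 0-4, 4-8, 8-12 day blocks), which weights early lag-phase
and late exponential-phase intervals equally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GrowthSeries",
    "GrowthRateResult",
    "specific_growth_rate",
    "interval_growth_rates",
    "dry_weight",
]


@dataclass
class GrowthSeries:
    times: np.ndarray  # days
    cells_per_ml: np.ndarray | None = None
    od440: np.ndarray | None = None  # dilution-corrected
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        for name in ("cells_per_ml", "od440"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, float)
                if len(v) != len(self.times):
                    raise ValueError(f"{name} length must match times")
                setattr(self, name, v)
        if self.cells_per_ml is None and self.od440 is None:
            raise ValueError("at least one of cells_per_ml / od440 is required")


@dataclass
class GrowthRateResult:
    intervals: list[tuple[float, float, float]]  # (t_start, t_end, mu per day)
    mu_avg: float

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.intervals, columns=["t_start_d", "t_end_d", "mu_per_day"])
        return df


def specific_growth_rate(n1: float, t1: float, n2: float, t2: float) -> float:
    """mu = (ln n2 - ln n1)/(t2 - t1), per day."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("cell concentrations must be > 0")
    if t2 <= t1:
        raise ValueError("t2 must exceed t1")
    return (math.log(n2) - math.log(n1)) / (t2 - t1)


def interval_growth_rates(
    series: GrowthSeries, breakpoints, channel: str = "cells_per_ml"
) -> GrowthRateResult:
    """Per-interval growth rates between breakpoints, plus their mean.

    Each breakpoint must coincide with an observed time; the rate for each
    consecutive breakpoint pair uses the observations at its endpoints.
    """
    bp = np.asarray(breakpoints, float)
    if len(bp) < 2:
        raise ValueError("need at least 2 breakpoints")
    values = getattr(series, channel)
    if values is None:
        raise ValueError(f"series has no {channel} channel")
    idx = []
    for b in bp:
        match = np.nonzero(np.isclose(series.times, b, atol=1e-9))[0]
        if len(match) == 0:
            raise ValueError(f"breakpoint {b} has no matching observation time")
        idx.append(int(match[0]))
    intervals = []
    for i0, i1 in zip(idx[:-1], idx[1:]):
        mu = specific_growth_rate(
            values[i0], series.times[i0], values[i1], series.times[i1]
        )
        intervals.append((float(series.times[i0]), float(series.times[i1]), mu))
    mu_avg = float(np.mean([m for _, _, m in intervals]))
    return GrowthRateResult(intervals=intervals, mu_avg=mu_avg)


def dry_weight(filter_tare_mg: float, filter_loaded_mg: float, volume_ml: float) -> float:
    """Gravimetric dry weight in mg/L from pre-/post-filtration filter masses."""
    if volume_ml <= 0:
        raise ValueError("volume must be > 0")
    delta = filter_loaded_mg - filter_tare_mg
    if delta < 0:
        raise ValueError("loaded filter lighter than tare")
    return delta / volume_ml * 1000.0
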