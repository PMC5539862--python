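"""Fixed-width feature extraction from variable-length recordings.

Recordings differ in duration and sampling grid, so multivariate
classifiers cannot consume them directly.  Each recording is reduced to a
fixed vector by:

1. binning each axis's raw samples into per-second bins (t-1, t] for
   t = 1..s_i with s_i = ceil(final timestamp), and per-minute bins
   (t-1, t] in minutes with m_i = ceil(final timestamp / 60) — e.g. a
   recording ending at 800.21 s has 801 second-bins and 14 minute-bins;
2. computing the bin-wise sum, median and mean, giving three aggregate
   series per axis and resolution;
3. summarising every aggregate series by its sum, mean, median, minimum
   and maximum.

That yields 3 axes x 2 resolutions x 3 series x 5 statistics = 90 features
("basic90"), matching the classifier input width downstream.  The
"extended" mode additionally integrates each axis's acceleration twice with
the trapezoidal rule (speed, then displacement) and applies the same
30-feature scheme to both kinematic curves, for 270 features in total.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .errors import DegenerateInputError
from .synthetic import RawRecording

RESOLUTIONS = ("second", "minute")
SERIES = ("sum", "median", "mean")
STATS = ("sum", "mean", "median", "min", "max")
_UNIT = {"second": 1.0, "minute": 60.0}


@dataclass
class AggregateSeries:
    """Bin-wise sum / median / mean of one value series at one resolution."""

    sums: np.ndarray
    medians: np.ndarray
    means: np.ndarray
    resolution: str

    @property
    def n_bins(self) -> int:
        return len(self.sums)

    def series(self, name: str) -> np.ndarray:
        return {"sum": self.sums, "median": self.medians, "mean": self.means}[name]


def bin_count(final_timestamp: float, resolution: str) -> int:
    """Number of bins covering [0, final]: the ceiling in the bin unit."""
    return max(1, math.ceil(final_timestamp / _UNIT[resolution]))


def aggregate_series(
    timestamps: np.ndarray, values: np.ndarray, resolution: str
) -> AggregateSeries:
    """Bin ``values`` into half-open bins (t-1, t] of one second or minute.

    A sample at exactly t = 0 joins the first bin.  Empty bins (possible
    under irregular sampling) carry the previous bin's aggregates forward;
    leading empty bins take the first non-empty bin's values.
    """
    if resolution not in RESOLUTIONS:
        raise ValueError(f"resolution must be in {RESOLUTIONS}")
    t = np.asarray(timestamps, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size == 0:
        raise DegenerateInputError("empty recording")
    n = bin_count(float(t[-1]), resolution)
    bins = np.maximum(np.ceil(t / _UNIT[resolution]).astype(int), 1)
    g = pd.Series(v).groupby(bins).agg(["sum", "median", "mean"])
    g = g.reindex(range(1, n + 1)).ffill().bfill()
    return AggregateSeries(
        g["sum"].to_numpy(), g["median"].to_numpy(), g["mean"].to_numpy(), resolution
    )


def aggregate(rec: RawRecording, resolution: str) -> dict[str, AggregateSeries]:
    """Per-axis aggregate series of a recording's accelerations."""
    if len(rec.timestamps) == 0:
        raise DegenerateInputError("empty recording")
    return {
        a: aggregate_series(rec.timestamps, rec.axis(a), resolution) for a in "xyz"
    }


def summarize(series: np.ndarray) -> tuple[float, float, float, float, float]:
    """(sum, mean, median, min, max) of a series."""
    s = np.asarray(series, dtype=float)
    if s.size == 0:
        raise DegenerateInputError("cannot summarise an empty series")
    return (
        float(s.sum()),
        float(s.mean()),
        float(np.median(s)),
        float(s.min()),
        float(s.max()),
    )


def integrate_kinematics(rec: RawRecording) -> dict[str, dict[str, np.ndarray]]:
    """Cumulative trapezoidal integrals per axis: acceleration -> speed ->
    displacement, both starting at 0, on the raw timestamp grid."""
    if len(rec.timestamps) < 2:
        raise DegenerateInputError("kinematic integration needs >= 2 samples")
    out: dict[str, dict[str, np.ndarray]] = {}
    for a in "xyz":
        speed = cumulative_trapezoid(rec.axis(a), rec.timestamps, initial=0.0)
        space = cumulative_trapezoid(speed, rec.timestamps, initial=0.0)
        out[a] = {"speed": speed, "space": space}
    return out


def feature_names(mode: str = "basic90") -> list[str]:
    """Schema (fixed order) of the feature vector for ``mode``."""
    names = [
        f"{axis}_{res}_{series}_{stat}"
        for axis in "xyz"
        for res in RESOLUTIONS
        for series in SERIES
        for stat in STATS
    ]
    if mode == "basic90":
        return names
    if mode == "extended":
        names += [
            f"{axis}_{curve}_{res}_{series}_{stat}"
            for axis in "xyz"
            for curve in ("speed", "space")
            for res in RESOLUTIONS
            for series in SERIES
            for stat in STATS
        ]
        return names
    raise ValueError(f"mode must be 'basic90' or 'extended', got {mode!r}")


def _block(timestamps: np.ndarray, values: np.ndarray) -> list[float]:
    """The 30 features of one value series: 2 resolutions x 3 series x 5 stats."""
    out: list[float] = []
    for res in RESOLUTIONS:
        agg = aggregate_series(timestamps, values, res)
        for series in SERIES:
            out.extend(summarize(agg.series(series)))
    return out


def extract_features(rec: RawRecording, mode: str = "basic90") -> np.ndarray:
    """Reduce a recording to the fixed-width feature vector (deterministic)."""
    names = feature_names(mode)  # validates mode
    vals: list[float] = []
    for axis in "xyz":
        vals.extend(_block(rec.timestamps, rec.axis(axis)))
    if mode == "extended":
        kin = integrate_kinematics(rec)
        for axis in "xyz":
            for curve in ("speed", "space"):
                vals.extend(_block(rec.timestamps, kin[axis][curve]))
    vec = np.asarray(vals)
    assert vec.size == len(names)
    if not np.all(np.isfinite(vec)):
        raise ValueError("non-finite feature value produced")
    return vec
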