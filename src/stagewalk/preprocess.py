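"""Preprocessing: per-second interpolation and random equal-length windows.

Recordings arrive on irregular ~8 Hz grids with different durations.  Two
steps make them comparable as functional data:

1. each axis is linearly interpolated and evaluated at the integer seconds
   t = 1, ..., T_i, where T_i is the recording's final timestamp rounded to
   the nearest integer (round-half-to-even);
2. with l the length of the shortest interpolated curve, each curve i is
   restricted to the window t = 1 + l_i, ..., l + l_i, where the offset l_i
   is drawn from the discrete uniform distribution on {0, ..., T_i - l}.

Because the within-recording process is stationary, the windowed curves are
exchangeable in distribution across offset draws; downstream analyses are
repeated over many independent draws so no single draw dictates the result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._rng import STREAM_WINDOWS, derive_rng
from .errors import DegenerateInputError
from .synthetic import RawRecording

AXES = ("x", "y", "z")


@dataclass
class InterpolatedCurve:
    """One recording evaluated on the integer-second grid 1..T."""

    patient_id: str
    stage: str
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray

    @property
    def length(self) -> int:
        return len(self.x)

    def axis(self, name: str) -> np.ndarray:
        try:
            return {"x": self.x, "y": self.y, "z": self.z}[name]
        except KeyError:
            raise ValueError(f"unknown axis {name!r}") from None


@dataclass
class WindowedDataset:
    """Equal-length windows for one axis (or xyz concatenation) of n curves."""

    curves: np.ndarray  # shape (n, l) — or (n, 3l) for axis="xyz"
    labels: np.ndarray  # stage per curve
    patient_ids: np.ndarray
    offsets: np.ndarray  # the drawn l_i
    window_length: int  # l
    axis: str
    rep_index: int

    def group(self, stage: str) -> np.ndarray:
        return self.curves[self.labels == stage]


def interpolate_to_seconds(rec: RawRecording) -> InterpolatedCurve:
    """Evaluate each axis at t = 1..T by linear interpolation.

    T is ``round(final timestamp)`` under round-half-to-even.  Grid points
    outside the observed range take the nearest observed value (constant
    extrapolation); with data starting near 0 this only affects t = 1 when
    the first sample arrives after one second, which does not happen at 8 Hz.
    """
    final = float(rec.timestamps[-1])
    ti = int(round(final))  # python round: half-to-even
    if ti < 2:
        raise DegenerateInputError(
            f"recording {rec.patient_id}: duration {final:.2f}s rounds to {ti} < 2 s"
        )
    grid = np.arange(1, ti + 1, dtype=float)
    vals = {
        a: np.interp(grid, rec.timestamps, rec.axis(a)) for a in AXES
    }  # np.interp clamps to the end values == constant extrapolation
    return InterpolatedCurve(rec.patient_id, rec.stage, vals["x"], vals["y"], vals["z"])


def _draw_offsets(lengths: np.ndarray, l: int, rng: np.random.Generator) -> np.ndarray:
    # inclusive upper bound T_i - l
    return rng.integers(0, lengths - l + 1)


def random_windows(
    curves: list[InterpolatedCurve],
    axis: str,
    n_reps: int = 1,
    seed: int = 0,
) -> list[WindowedDataset]:
    """Draw ``n_reps`` windowed datasets for one axis (or ``"xyz"``).

    Offsets are drawn independently per curve and per repetition; repetition
    j uses the stream derived from ``(seed, j)`` so results for earlier
    repetitions do not change when ``n_reps`` grows.  For ``axis="xyz"`` the
    same offset is used on all three axes of a curve and the three windows
    are concatenated into a single vector of length 3l.
    """
    if not curves:
        raise DegenerateInputError("random_windows: empty input")
    if axis not in AXES and axis != "xyz":
        raise ValueError(f"axis must be one of {AXES} or 'xyz', got {axis!r}")
    if len(curves) < 2:
        raise DegenerateInputError("random_windows: need at least 2 curves")

    lengths = np.array([c.length for c in curves])
    l = int(lengths.min())
    if l < 2:
        raise DegenerateInputError(f"window length l={l} < 2")
    labels = np.array([c.stage for c in curves])
    pids = np.array([c.patient_id for c in curves])
    ax_list = list(AXES) if axis == "xyz" else [axis]

    out = []
    for j in range(n_reps):
        rng = derive_rng(seed, STREAM_WINDOWS, j)
        offsets = _draw_offsets(lengths, l, rng)
        mat = np.empty((len(curves), l * len(ax_list)))
        for i, (c, off) in enumerate(zip(curves, offsets)):
            parts = [c.axis(a)[off : off + l] for a in ax_list]
            mat[i] = np.concatenate(parts)
        out.append(
            WindowedDataset(mat, labels, pids, offsets, l, axis, j)
        )
    return out
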