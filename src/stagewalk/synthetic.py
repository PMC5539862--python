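"""Synthetic accelerometer cohorts.

The study population this package targets — dementia patients carrying a
smartphone in a pocket while moving freely — is described by irregularly
sampled three-axis accelerometer logs: one file per recording, a handful of
recordings per patient, and a clinical stage label (early / middle / late,
collapsed from the Global Deterioration Scale) per patient.  No public
dataset with this structure exists, so this module generates cohorts with
the same statistical skeleton:

* 35 patients split 7 (early) / 18 (middle) / 10 (late) by default;
* 2–8 recordings per patient, 187 recordings in total (41/100/46 by stage);
* ~8 Hz sampling on a jittered grid, per-recording durations drawn from a
  wide range (nothing forces recordings to share a time domain);
* per-recording signal = randomly oriented gravity + a stage-dependent
  constant acceleration offset + a stage-modulated sinusoidal gait
  component + stationary AR(1) noise.

The stage effect enters the *mean* of the process and is constant in time,
and the AR(1) noise is initialised from its stationary distribution, so the
within-recording process is strictly stationary apart from the constant —
the property that makes random equal-length windows exchangeable and
justifies the windowed testing scheme downstream.  Stage effects are large
on the x and y axes and weak on z, mirroring the empirical finding that
group differences live in the horizontal plane of movement.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from ._rng import STREAM_COHORT, derive_rng
from .errors import ConfigError, FormatError

STAGES = ("early", "middle", "late")

#: fixed recording schedules (counts per patient, all within 2..8) chosen so
#: the default cohort reproduces the printed study composition 41/100/46
_DEFAULT_SCHEDULES = {
    "early": (6, 6, 6, 6, 6, 6, 5),                                # 41
    "middle": (6, 6, 6, 6, 6, 6, 6, 6, 6, 6, 5, 5, 5, 5, 5, 5, 5, 5),  # 100
    "late": (5, 5, 5, 5, 5, 5, 4, 4, 4, 4),                        # 46
}

#: additive offset level per stage; multiplied by the per-axis effect size
_STAGE_LEVEL = {"early": -1.0, "middle": 0.0, "late": 1.0}

#: gait cadence (Hz) and amplitude factor per stage — cadence slows and the
#: oscillation weakens as the disease progresses
_STAGE_GAIT = {"early": (1.9, 1.0), "middle": (1.7, 0.8), "late": (1.4, 0.6)}


@dataclass
class RawRecording:
    """One accelerometer log: irregular timestamps plus three axis series."""

    patient_id: str
    stage: str
    timestamps: np.ndarray  # seconds, strictly increasing, starting near 0
    ax: np.ndarray  # m/s^2
    ay: np.ndarray
    az: np.ndarray

    def axis(self, name: str) -> np.ndarray:
        try:
            return {"x": self.ax, "y": self.ay, "z": self.az}[name]
        except KeyError:
            raise ValueError(f"unknown axis {name!r}; expected x, y or z") from None

    @property
    def duration(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0])

    def validate(self, rate_hz: float | None = None) -> None:
        n = len(self.timestamps)
        if not (n == len(self.ax) == len(self.ay) == len(self.az)):
            raise FormatError(f"recording {self.patient_id}: axis lengths differ")
        if n < 16:
            raise FormatError(f"recording {self.patient_id}: fewer than 16 samples")
        if self.stage not in STAGES:
            raise FormatError(f"recording {self.patient_id}: unknown stage {self.stage!r}")
        if np.any(np.diff(self.timestamps) <= 0):
            raise FormatError(
                f"recording {self.patient_id}: timestamps not strictly increasing"
            )
        if self.duration <= 0:
            raise FormatError(f"recording {self.patient_id}: non-positive duration")
        if rate_hz is not None:
            mean_dt = self.duration / (n - 1)
            if not 0.5 / rate_hz <= mean_dt <= 2.0 / rate_hz:
                raise FormatError(
                    f"recording {self.patient_id}: mean sampling interval {mean_dt:.4f}s "
                    f"outside [0.5x, 2x] of 1/{rate_hz} Hz"
                )


@dataclass
class Patient:
    patient_id: str
    stage: str
    recordings: list[RawRecording]


@dataclass
class CohortConfig:
    """Generator settings; the defaults reproduce the study composition."""

    n_patients: dict[str, int] = field(
        default_factory=lambda: {"early": 7, "middle": 18, "late": 10}
    )
    recordings_per_patient: dict[str, tuple[int, ...]] | None = None  # default schedules
    sampling_rate_hz: float = 8.0
    timestamp_jitter: float = 0.2  # uniform jitter, fraction of the sampling interval
    duration_range: tuple[float, float] = (120.0, 900.0)  # seconds
    stage_effect: dict[str, float] = field(
        default_factory=lambda: {"x": 1.2, "y": 1.0, "z": 0.15}
    )  # m/s^2 per unit stage level; x/y large, z weak
    gait_amplitude: dict[str, float] = field(
        default_factory=lambda: {"x": 1.0, "y": 1.2, "z": 0.4}
    )  # m/s^2 base amplitude of the periodic gait component
    ar_phi: float = 0.6  # AR(1) autoregression coefficient
    noise_sd: float = 0.5  # AR(1) innovation standard deviation, m/s^2
    gravity: float = 9.81
    orientation_tilt: float = 0.15  # sd of the tilt perturbation around the pocket axis
    seed: int = 0

    def validate(self) -> None:
        if set(self.n_patients) != set(STAGES) or min(self.n_patients.values()) < 1:
            raise ConfigError("n_patients must give a positive count for each stage")
        if self.sampling_rate_hz <= 0:
            raise ConfigError("sampling_rate_hz must be positive")
        lo, hi = self.duration_range
        if not 0 < lo <= hi:
            raise ConfigError("duration_range must satisfy 0 < lo <= hi")
        if not 0 <= self.ar_phi < 1:
            raise ConfigError("ar_phi must lie in [0, 1) for stationarity")
        if self.noise_sd < 0 or self.gravity < 0:
            raise ConfigError("noise_sd and gravity must be non-negative")
        for d in (self.stage_effect, self.gait_amplitude):
            if set(d) != {"x", "y", "z"} or not all(np.isfinite(v) for v in d.values()):
                raise ConfigError("per-axis settings need finite x, y, z entries")
        for stage, sched in self.schedules().items():
            if any(not 2 <= c <= 8 for c in sched):
                raise ConfigError(f"{stage}: recordings per patient must be in [2, 8]")
            if len(sched) != self.n_patients[stage]:
                raise ConfigError(f"{stage}: schedule length != patient count")

    def schedules(self) -> dict[str, tuple[int, ...]]:
        if self.recordings_per_patient is not None:
            return {s: tuple(self.recordings_per_patient[s]) for s in STAGES}
        if all(self.n_patients[s] == len(_DEFAULT_SCHEDULES[s]) for s in STAGES):
            return dict(_DEFAULT_SCHEDULES)
        # non-default cohort size: alternate 3/2 recordings per patient
        return {
            s: tuple(3 if i % 2 == 0 else 2 for i in range(self.n_patients[s]))
            for s in STAGES
        }


@dataclass
class Cohort:
    patients: list[Patient]
    config: CohortConfig | None = None

    def __iter__(self) -> Iterator[Patient]:
        return iter(self.patients)

    @property
    def recordings(self) -> list[RawRecording]:
        return [r for p in self.patients for r in p.recordings]

    def stage_counts(self) -> dict[str, int]:
        out = {s: 0 for s in STAGES}
        for p in self.patients:
            out[p.stage] += 1
        return out

    def recording_counts(self) -> dict[str, int]:
        out = {s: 0 for s in STAGES}
        for p in self.patients:
            out[p.stage] += len(p.recordings)
        return out

    def validate(self) -> None:
        counts = self.stage_counts()
        if min(counts.values()) < 1:
            raise FormatError("all three stage groups must be non-empty")
        for p in self.patients:
            if not 2 <= len(p.recordings) <= 8:
                raise FormatError(
                    f"patient {p.patient_id} has {len(p.recordings)} recordings; "
                    "expected between 2 and 8"
                )
            for r in p.recordings:
                r.validate()


def _pocket_orientation(rng: np.random.Generator, tilt: float) -> np.ndarray:
    """Unit gravity direction: phone roughly upright in a pocket, plus tilt."""
    canonical = np.array([0.15, 0.95, 0.27])
    v = canonical / np.linalg.norm(canonical) + tilt * rng.standard_normal(3)
    return v / np.linalg.norm(v)


def _ar1(rng: np.random.Generator, n: int, phi: float, sd: float) -> np.ndarray:
    """Stationary AR(1) path (initialised from the stationary distribution)."""
    if sd == 0.0:
        return np.zeros(n)
    e = rng.standard_normal(n) * sd
    if phi == 0.0:
        return e
    x0 = rng.standard_normal() * sd / np.sqrt(1.0 - phi**2)
    x, _ = lfilter([1.0], [1.0, -phi], e, zi=np.array([phi * x0]))
    return x


def ar1_curves(
    n_curves: int,
    length: int,
    phi: float = 0.6,
    sd: float = 0.5,
    mean: float = 0.0,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Sample ``n_curves`` independent stationary Gaussian AR(1) curves.

    The one stationary Gaussian process used throughout the calibration
    studies: all curves share mean ``mean`` and autocovariance
    ``sd^2 phi^|k| / (1 - phi^2)``, so any two groups drawn from it satisfy
    the null hypothesis of equal mean curves by construction.
    """
    if rng is None:
        rng = derive_rng(seed, STREAM_COHORT)
    e = rng.standard_normal((n_curves, length)) * sd
    if phi == 0.0 or sd == 0.0:
        return mean + e
    x0 = rng.standard_normal(n_curves) * sd / np.sqrt(1.0 - phi**2)
    x, _ = lfilter([1.0], [1.0, -phi], e, axis=1, zi=(phi * x0)[:, None])
    return mean + x


def _simulate_recording(
    cfg: CohortConfig, stage: str, rng: np.random.Generator
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    duration = rng.uniform(*cfg.duration_range)
    dt = 1.0 / cfg.sampling_rate_hz
    grid = np.arange(0.0, duration, dt)
    t = grid + rng.uniform(-cfg.timestamp_jitter * dt, cfg.timestamp_jitter * dt, grid.size)
    t[0] = abs(t[0])
    t = np.maximum.accumulate(t)  # jitter must not break monotonicity
    t += np.arange(t.size) * 1e-9  # strictly increasing even after clamping

    g_dir = _pocket_orientation(rng, cfg.orientation_tilt)
    freq, amp_factor = _STAGE_GAIT[stage]
    phase = rng.uniform(0.0, 2.0 * np.pi)
    level = _STAGE_LEVEL[stage]

    axes: dict[str, np.ndarray] = {}
    for j, axis in enumerate("xyz"):
        mean = cfg.gravity * g_dir[j] + level * cfg.stage_effect[axis]
        gait = amp_factor * cfg.gait_amplitude[axis] * np.sin(
            2.0 * np.pi * freq * t + phase + j * np.pi / 3.0
        )
        axes[axis] = mean + gait + _ar1(rng, t.size, cfg.ar_phi, cfg.noise_sd)
    return t, axes


def generate_cohort(config: CohortConfig | None = None, seed: int | None = None) -> Cohort:
    """Generate a cohort; deterministic given ``(config, seed)``.

    ``seed`` overrides ``config.seed`` when given.
    """
    cfg = config if config is not None else CohortConfig()
    if seed is not None:
        cfg = dataclasses.replace(cfg, seed=int(seed))
    cfg.validate()
    rng = derive_rng(cfg.seed, STREAM_COHORT)

    patients: list[Patient] = []
    idx = 0
    for stage in STAGES:
        for k, n_rec in enumerate(cfg.schedules()[stage]):
            idx += 1
            pid = f"P{idx:03d}"
            recs = []
            for _ in range(n_rec):
                t, axes = _simulate_recording(cfg, stage, rng)
                recs.append(
                    RawRecording(pid, stage, t, axes["x"], axes["y"], axes["z"])
                )
            patients.append(Patient(pid, stage, recs))
    cohort = Cohort(patients, config=cfg)
    cohort.validate()
    return cohort


def noiseless_mean_curves(
    cfg: CohortConfig, length_s: float = 10.0
) -> dict[str, dict[str, np.ndarray]]:
    """Per-stage, per-axis mean functions with noise, gait phase and gravity
    orientation averaged out (orientation mean = canonical pocket direction).

    Used to inspect the stage-effect geometry of a configuration without
    sampling: the x/y group gaps should dominate the z gap under defaults.
    """
    t = np.arange(0.0, length_s, 1.0 / cfg.sampling_rate_hz)
    canonical = np.array([0.15, 0.95, 0.27])
    canonical = canonical / np.linalg.norm(canonical)
    out: dict[str, dict[str, np.ndarray]] = {}
    for stage in STAGES:
        level = _STAGE_LEVEL[stage]
        out[stage] = {
            axis: np.full_like(
                t, cfg.gravity * canonical[j] + level * cfg.stage_effect[axis]
            )
            for j, axis in enumerate("xyz")
        }
    return out


# ---------------------------------------------------------------------------
# on-disk format: one CSV per recording (t,ax,ay,az) + a manifest CSV

MANIFEST_NAME = "manifest.csv"


def write_cohort(cohort: Cohort, directory: str | Path) -> Path:
    """Write one ``t,ax,ay,az`` CSV per recording plus a manifest; return the
    manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for p in cohort.patients:
        for k, rec in enumerate(p.recordings, start=1):
            fname = f"{p.patient_id}_r{k:02d}.csv"
            df = pd.DataFrame(
                {"t": rec.timestamps, "ax": rec.ax, "ay": rec.ay, "az": rec.az}
            )
            df.to_csv(directory / fname, index=False, float_format="%.12g")
            rows.append({"file": fname, "patient_id": p.patient_id, "stage": p.stage})
    manifest = directory / MANIFEST_NAME
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_cohort(directory: str | Path) -> Cohort:
    """Read a cohort written by :func:`write_cohort`; validates on the way in."""
    directory = Path(directory)
    manifest = directory / MANIFEST_NAME
    if not manifest.exists():
        raise FormatError(f"{manifest}: manifest not found")
    mdf = pd.read_csv(manifest)
    required = {"file", "patient_id", "stage"}
    if not required.issubset(mdf.columns):
        raise FormatError(f"{manifest}: missing columns {required - set(mdf.columns)}")

    patients: dict[str, Patient] = {}
    for line_no, row in enumerate(mdf.itertuples(index=False), start=2):
        path = directory / str(row.file)
        if not path.exists():
            raise FormatError(f"{manifest}:{line_no}: referenced file {row.file} is absent")
        if row.stage not in STAGES:
            raise FormatError(f"{manifest}:{line_no}: unknown stage {row.stage!r}")
        try:
            df = pd.read_csv(path, dtype=float)
        except ValueError as exc:
            raise FormatError(f"{path}: malformed row ({exc})") from exc
        if list(df.columns) != ["t", "ax", "ay", "az"]:
            raise FormatError(f"{path}: expected header t,ax,ay,az, got {list(df.columns)}")
        if df.isna().any().any():
            bad = int(df.isna().any(axis=1).idxmax()) + 2
            raise FormatError(f"{path}:{bad}: missing or non-numeric value")
        rec = RawRecording(
            patient_id=str(row.patient_id),
            stage=str(row.stage),
            timestamps=df["t"].to_numpy(),
            ax=df["ax"].to_numpy(),
            ay=df["ay"].to_numpy(),
            az=df["az"].to_numpy(),
        )
        try:
            rec.validate()
        except FormatError as exc:
            raise FormatError(f"{path}: {exc}") from exc
        patients.setdefault(
            str(row.patient_id), Patient(str(row.patient_id), str(row.stage), [])
        ).recordings.append(rec)
    cohort = Cohort(list(patients.values()))
    cohort.validate()
    return cohort
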