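"""End-to-end orchestration: simulate -> window -> test -> classify.

:func:`run_all` executes the full synthetic study from a single
:class:`RunConfig` and writes every table the analysis produces (test
summaries, depth-classifier report, features, split, layer sweep, ML
reports) plus a machine-readable run manifest.  All randomness flows from
one master seed through derived streams, so a rerun with the same config
reproduces every output byte-for-byte (timings aside).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .depth import lopo_evaluate
from .errors import ConfigError
from .meantests import TestSpec, repeated_test
from .mlclassify import (
    baselines,
    classify_patients,
    feature_table,
    layer_sweep,
    prepare_split,
    split_cohort,
    train_nn,
)
from .preprocess import interpolate_to_seconds
from .synthetic import STAGES, Cohort, CohortConfig, generate_cohort, write_cohort

_STAGE_PAIRS = (("early", "middle"), ("early", "late"), ("middle", "late"))


@dataclass
class RunConfig:
    """Configuration of a full study run (YAML-serialisable)."""

    seed: int | None = None  # master seed; mandatory
    out_dir: str = "stagewalk_run"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    axes: tuple[str, ...] = ("x", "y", "z")
    test_reps: int = 1000  # J for the repeated mean tests
    bootstrap_b: int = 999
    projections_k: int = 30
    depth_axes: tuple[str, ...] = ("x", "y", "xyz")
    depth_reps: int = 10
    feature_mode: str = "basic90"
    test_fraction: float = 0.2
    layer_settings: tuple[int, ...] = tuple(range(1, 12))
    n_networks: int = 100
    total_hidden: int = 175
    nn_output_mode: str = "scalar"
    nn_max_iter: int = 1000

    def validate(self) -> None:
        if self.seed is None:
            raise ConfigError("RunConfig.seed is mandatory; unseeded runs are refused")
        self.cohort.validate()
        for a in self.axes:
            if a not in ("x", "y", "z"):
                raise ConfigError(f"unknown test axis {a!r}")
        for a in self.depth_axes:
            if a not in ("x", "y", "z", "xyz"):
                raise ConfigError(f"unknown depth axis {a!r}")
        for name, v in (
            ("test_reps", self.test_reps),
            ("bootstrap_b", self.bootstrap_b),
            ("projections_k", self.projections_k),
            ("depth_reps", self.depth_reps),
            ("n_networks", self.n_networks),
            ("total_hidden", self.total_hidden),
            ("nn_max_iter", self.nn_max_iter),
        ):
            if int(v) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if not self.layer_settings or min(self.layer_settings) < 1:
            raise ConfigError("layer_settings must be positive depths")
        if self.feature_mode not in ("basic90", "extended"):
            raise ConfigError("feature_mode must be 'basic90' or 'extended'")

    @classmethod
    def smoke(cls, seed: int = 0, out_dir: str = "stagewalk_smoke") -> "RunConfig":
        """A minutes-scale configuration for end-to-end checks."""
        cohort = CohortConfig(
            n_patients={"early": 2, "middle": 2, "late": 2},
            recordings_per_patient={s: (2, 2) for s in STAGES},
            duration_range=(30.0, 60.0),
            seed=seed,
        )
        return cls(
            seed=seed,
            out_dir=out_dir,
            cohort=cohort,
            test_reps=5,
            bootstrap_b=99,
            projections_k=10,
            depth_reps=2,
            layer_settings=(1, 2),
            n_networks=3,
            total_hidden=20,
            nn_max_iter=200,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "cohort" in d and isinstance(d["cohort"], dict):
            c = dict(d["cohort"])
            for key in ("duration_range",):
                if key in c and c[key] is not None:
                    c[key] = tuple(c[key])
            if c.get("recordings_per_patient"):
                c["recordings_per_patient"] = {
                    k: tuple(v) for k, v in c["recordings_per_patient"].items()
                }
            known = {f.name for f in dataclasses.fields(CohortConfig)}
            unknown = set(c) - known
            if unknown:
                raise ConfigError(f"unknown cohort config keys: {sorted(unknown)}")
            d["cohort"] = CohortConfig(**c)
        for key in ("axes", "depth_axes", "layer_settings"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls.from_dict(data)
        cfg.validate()
        return cfg

    def config_hash(self) -> str:
        """Hash of the scientific configuration (the output path is not part
        of what the hash identifies)."""
        d = self.to_dict()
        d.pop("out_dir", None)
        blob = yaml.safe_dump(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _tag(df: pd.DataFrame, cfg: RunConfig) -> pd.DataFrame:
    df = df.copy()
    df["seed"] = cfg.seed
    df["config_hash"] = cfg.config_hash()
    return df


def run_all(config: RunConfig) -> Path:
    """Execute every stage of the study; returns the run directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.seed)  # type: ignore[arg-type]
    timings: dict[str, float] = {}

    def timed(stage: str):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()

            def __exit__(self, exc_type, exc, tb):
                timings[stage] = round(time.perf_counter() - self.t0, 3)
                if exc is not None:
                    raise ConfigError(
                        f"stage {stage!r} failed (config hash "
                        f"{config.config_hash()}): {exc}"
                    ) from exc

        return _T()

    with timed("simulate"):
        cohort_cfg = dataclasses.replace(config.cohort, seed=seed)
        cohort = generate_cohort(cohort_cfg)
        write_cohort(cohort, out / "cohort")

    with timed("preprocess"):
        curves = [
            interpolate_to_seconds(r) for p in cohort.patients for r in p.recordings
        ]

    with timed("mean_tests"):
        rows, raw = [], []
        specs = [
            TestSpec("rp-bonf", k=config.projections_k),
            TestSpec("rp-fdr", k=config.projections_k),
            TestSpec("maxf", B=config.bootstrap_b),
            *(
                TestSpec("l2", B=config.bootstrap_b, pair=pair)
                for pair in _STAGE_PAIRS
            ),
        ]
        for axis in config.axes:
            for spec in specs:
                summ = repeated_test(
                    curves, axis, spec, n_reps=config.test_reps, seed=seed
                )
                pair = "-".join(spec.pair) if spec.pair else ""
                rows.append(
                    {
                        "axis": axis,
                        "test": spec.name,
                        "pair": pair,
                        "mean": summ.mean,
                        "sd": summ.sd,
                        "prop_leq_05": summ.prop_leq_05,
                        "reps": summ.count,
                    }
                )
                raw.append(
                    pd.DataFrame(
                        {
                            "axis": axis,
                            "test": spec.name,
                            "pair": pair,
                            "rep": np.arange(summ.count),
                            "p_value": summ.p_values,
                        }
                    )
                )
        _tag(pd.DataFrame(rows), config).to_csv(out / "test_summaries.csv", index=False)
        _tag(pd.concat(raw, ignore_index=True), config).to_csv(
            out / "test_pvalues.csv", index=False
        )

    with timed("depth_classifier"):
        depth_rows = []
        for axes in config.depth_axes:
            report = lopo_evaluate(
                cohort, axes=axes, n_reps=config.depth_reps, seed=seed
            )
            frame = report.to_frame()
            frame.insert(0, "axes", axes)
            depth_rows.append(frame)
        _tag(pd.concat(depth_rows, ignore_index=True), config).to_csv(
            out / "depth_report.csv", index=False
        )

    with timed("features"):
        features = feature_table(cohort, config.feature_mode)
        _tag(features, config).to_csv(out / "features.csv", index=False)

    with timed("ml_classifiers"):
        spec = split_cohort(cohort, config.test_fraction, seed=seed)
        data = prepare_split(features, spec)
        split_df = pd.DataFrame(
            [
                {
                    "side": side,
                    **{s: counts[s] for s in STAGES},
                    "patients": sum(counts.values()),
                }
                for side, counts in (
                    ("train", spec.train_stage_counts),
                    ("test", spec.test_stage_counts),
                )
            ]
        )
        _tag(split_df, config).to_csv(out / "split.csv", index=False)

        model = train_nn(
            data.x_train,
            data.y_train,
            hidden_spec=(config.total_hidden,),
            seed=seed,
            output_mode=config.nn_output_mode,
            max_iter=config.nn_max_iter,
        )
        reports = {"nn": classify_patients(model, data)}
        reports.update(baselines(data, seed=seed))
        ml_rows = []
        for name, rep in reports.items():
            frame = rep.to_frame()
            frame.insert(0, "method", name)
            ml_rows.append(frame)
        _tag(pd.concat(ml_rows, ignore_index=True), config).to_csv(
            out / "ml_report.csv", index=False
        )

        sweep = layer_sweep(
            data,
            layer_settings=list(config.layer_settings),
            n_networks=config.n_networks,
            seed=seed,
            total_hidden=config.total_hidden,
            output_mode=config.nn_output_mode,
            max_iter=config.nn_max_iter,
        )
        _tag(sweep.to_frame(), config).to_csv(out / "sweep.csv", index=False)

    manifest = {
        "package_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": seed,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "timings_s": timings,
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out
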