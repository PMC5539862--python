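"""Stage classification on extracted features.

The evaluation unit is the patient: a patient's recordings all land on the
same side of any train/test split (grouped splitting), recording-level
predictions are fused per patient by majority vote, and reports count
misclassified patients per stage.

Classifiers:

* a feed-forward network trained by resilient backpropagation (``nn.py``)
  with logistic activations and, by default, a single output unit encoding
  the ordinal stage as early=0, middle=0.5, late=1 with decision thresholds
  at 0.25 and 0.75 (a three-output one-hot variant is available via
  ``output_mode="three_unit"``);
* baselines: decision tree, random forest and support-vector machine with
  library defaults and fixed seeds.

Features are z-scored with statistics estimated on the training recordings
only, so held-out patients never leak into preprocessing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from ._rng import STREAM_NN, STREAM_SPLIT, derive_rng, spawn_seeds
from .depth import ClassificationReport, majority_vote
from .errors import ConfigError
from .features import extract_features, feature_names
from .nn import RpropNet
from .synthetic import STAGES, Cohort

_SCALAR_TARGET = {"early": 0.0, "middle": 0.5, "late": 1.0}


def feature_table(cohort: Cohort, mode: str = "basic90") -> pd.DataFrame:
    """One row per recording: the feature vector plus patient_id and stage."""
    rows = []
    for p in cohort.patients:
        for rec in p.recordings:
            rows.append(
                {
                    **dict(zip(feature_names(mode), extract_features(rec, mode))),
                    "patient_id": p.patient_id,
                    "stage": p.stage,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# patient-grouped splitting


@dataclass
class SplitSpec:
    train_patients: list[str]
    test_patients: list[str]
    train_stage_counts: dict[str, int]
    test_stage_counts: dict[str, int]
    seed: int

    def validate(self) -> None:
        if set(self.train_patients) & set(self.test_patients):
            raise ConfigError("a patient appears on both sides of the split")
        if any(self.train_stage_counts.get(s, 0) == 0 for s in STAGES):
            raise ConfigError("every stage must be present in training")


def split_cohort(
    cohort: Cohort, test_fraction: float = 0.2, seed: int = 0, max_retries: int = 50
) -> SplitSpec:
    """Random patient-grouped split targeting a recording-level test fraction.

    Patients are shuffled and moved to the test side while that brings the
    test side's share of recordings closer to ``test_fraction``; no patient
    is ever split across sides.  If some stage ends up absent from
    training, the draw is retried with a derived seed (bounded retries).
    """
    if not 0 <= test_fraction < 1:
        raise ConfigError("test_fraction must be in [0, 1)")
    n_total = len(cohort.recordings)
    stage_of = {p.patient_id: p.stage for p in cohort.patients}
    n_recs = {p.patient_id: len(p.recordings) for p in cohort.patients}

    for attempt in range(max_retries):
        rng = derive_rng(seed, STREAM_SPLIT, attempt)
        order = list(n_recs)
        rng.shuffle(order)
        test: list[str] = []
        n_test = 0
        for pid in order:
            new = n_test + n_recs[pid]
            if abs(new / n_total - test_fraction) < abs(n_test / n_total - test_fraction):
                test.append(pid)
                n_test = new
        train = [pid for pid in n_recs if pid not in test]
        spec = SplitSpec(
            train,
            test,
            {s: sum(1 for q in train if stage_of[q] == s) for s in STAGES},
            {s: sum(1 for q in test if stage_of[q] == s) for s in STAGES},
            seed,
        )
        try:
            spec.validate()
        except ConfigError:
            continue
        return spec
    raise ConfigError(
        f"could not build a split with all stages in training after {max_retries} tries"
    )


@dataclass
class SplitData:
    """Standardised feature matrices for one split (scaler fit on train only)."""

    x_train: np.ndarray
    y_train: np.ndarray  # stage labels per training recording
    x_test: np.ndarray
    y_test: np.ndarray
    test_patient_ids: np.ndarray
    train_patient_ids: np.ndarray
    scaler_mean: np.ndarray
    scaler_sd: np.ndarray
    spec: SplitSpec


def prepare_split(features: pd.DataFrame, spec: SplitSpec) -> SplitData:
    spec.validate()
    cols = [c for c in features.columns if c not in ("patient_id", "stage")]
    tr = features[features["patient_id"].isin(spec.train_patients)]
    te = features[features["patient_id"].isin(spec.test_patients)]
    mean = tr[cols].to_numpy().mean(axis=0)
    sd = tr[cols].to_numpy().std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return SplitData(
        (tr[cols].to_numpy() - mean) / sd,
        tr["stage"].to_numpy(),
        (te[cols].to_numpy() - mean) / sd,
        te["stage"].to_numpy(),
        te["patient_id"].to_numpy(),
        tr["patient_id"].to_numpy(),
        mean,
        sd,
        spec,
    )


# ---------------------------------------------------------------------------
# neural-network stage model


@dataclass
class StageModel:
    net: RpropNet
    output_mode: str
    train_prevalence: dict[str, int] = field(default_factory=dict)

    @property
    def converged(self) -> bool:
        return self.net.converged

    def predict(self, x: np.ndarray) -> np.ndarray:
        raw = self.net.predict_raw(x)
        if self.output_mode == "scalar":
            out = np.where(
                raw[:, 0] < 0.25, "early", np.where(raw[:, 0] < 0.75, "middle", "late")
            )
            return out.astype(object)
        return np.array([STAGES[i] for i in raw.argmax(axis=1)], dtype=object)


def train_nn(
    x_train: np.ndarray,
    labels: np.ndarray,
    hidden_spec: tuple[int, ...] = (175,),
    seed: int = 0,
    output_mode: str = "scalar",
    max_iter: int = 1000,
    threshold: float = 0.01,
) -> StageModel:
    """Train the Rprop network on standardised features; deterministic per seed."""
    if output_mode not in ("scalar", "three_unit"):
        raise ConfigError("output_mode must be 'scalar' or 'three_unit'")
    labels = np.asarray(labels)
    if not set(labels) <= set(STAGES):
        raise ValueError(f"labels must be within {STAGES}")
    if output_mode == "scalar":
        y = np.array([_SCALAR_TARGET[s] for s in labels])[:, None]
        n_out = 1
    else:
        y = np.stack([(labels == s).astype(float) for s in STAGES], axis=1)
        n_out = 3
    net = RpropNet(
        hidden=tuple(hidden_spec),
        n_outputs=n_out,
        max_iter=max_iter,
        threshold=threshold,
        seed=int(seed),
    ).fit(x_train, y)
    prevalence = {s: int(np.sum(labels == s)) for s in STAGES}
    return StageModel(net, output_mode, prevalence)


def patient_report(
    rec_predictions: np.ndarray,
    patient_ids: np.ndarray,
    true_stages: np.ndarray,
    prevalence: dict[str, int],
    **extra,
) -> ClassificationReport:
    """Fuse recording-level predictions into a patient-level report."""
    df = pd.DataFrame(
        {"patient_id": patient_ids, "true_stage": true_stages, "pred": rec_predictions}
    )
    rows = []
    for pid, sub in df.groupby("patient_id", sort=False):
        rows.append(
            {
                "patient_id": pid,
                "true_stage": sub["true_stage"].iloc[0],
                "predicted_stage": majority_vote(list(sub["pred"]), prevalence),
            }
        )
    return ClassificationReport.from_predictions(pd.DataFrame(rows), **extra)


def classify_patients(model: StageModel, data: SplitData, **extra) -> ClassificationReport:
    """Patient-level report of ``model`` on the split's test side."""
    known = set(data.spec.test_patients)
    unknown = set(data.test_patient_ids) - known
    if unknown:
        raise ValueError(f"unknown patient ids in test features: {sorted(unknown)}")
    preds = model.predict(data.x_test)
    return patient_report(
        preds, data.test_patient_ids, data.y_test, model.train_prevalence, **extra
    )


# ---------------------------------------------------------------------------
# layer sweep and baselines


@dataclass
class SweepResult:
    """Patient-level misclassification rates per hidden-layer setting."""

    rates: dict[int, np.ndarray]  # setting (depth) -> rates over networks
    n_networks: int
    total_hidden: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"layers": k, "network": i, "misclassification_rate": r}
            for k, arr in self.rates.items()
            for i, r in enumerate(arr)
        ]
        return pd.DataFrame(rows)


def hidden_spec_for_depth(depth: int, total_hidden: int = 175) -> tuple[int, ...]:
    """Distribute ~``total_hidden`` neurons over ``depth`` equal layers."""
    if depth < 1:
        raise ConfigError("depth must be >= 1")
    size = max(1, round(total_hidden / depth))
    return (size,) * depth


def layer_sweep(
    data: SplitData,
    layer_settings: range | list[int] = range(1, 12),
    n_networks: int = 100,
    seed: int = 0,
    total_hidden: int = 175,
    output_mode: str = "scalar",
    max_iter: int = 1000,
) -> SweepResult:
    """Train ``n_networks`` differently seeded networks per layer setting and
    record each network's patient-level misclassification rate on the test
    side."""
    rates: dict[int, np.ndarray] = {}
    for depth in layer_settings:
        seeds = spawn_seeds(seed, n_networks, STREAM_NN, depth)
        vals = np.empty(n_networks)
        for i, s in enumerate(seeds):
            model = train_nn(
                data.x_train,
                data.y_train,
                hidden_spec_for_depth(depth, total_hidden),
                seed=int(s),
                output_mode=output_mode,
                max_iter=max_iter,
            )
            report = classify_patients(model, data)
            vals[i] = 1.0 - report.success_rate()
        rates[int(depth)] = vals
    return SweepResult(rates, n_networks, total_hidden)


_BASELINES = ("tree", "forest", "svm")


def baselines(data: SplitData, seed: int = 0) -> dict[str, ClassificationReport]:
    """Decision-tree, random-forest and SVM reports on the same split."""
    prevalence = {s: int(np.sum(data.y_train == s)) for s in STAGES}
    models = {
        "tree": DecisionTreeClassifier(random_state=int(seed)),
        "forest": RandomForestClassifier(random_state=int(seed)),
        "svm": SVC(random_state=int(seed)),
    }
    out = {}
    for name, model in models.items():
        model.fit(data.x_train, data.y_train)
        preds = model.predict(data.x_test)
        out[name] = patient_report(
            preds, data.test_patient_ids, data.y_test, prevalence, method=name
        )
    return out
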