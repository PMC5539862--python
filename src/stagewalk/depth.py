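"""Functional supervised classification via h-mode depth.

A curve's h-mode depth with respect to a sample is the average of a kernel
applied to its distance from each sample curve:

    D(c | X, h) = (1/n) * sum_i K(d(c, x_i) / h),

with K the Gaussian kernel K(u) = exp(-u^2 / 2) (so K(0) = 1) and d the L2
distance on the common grid (trapezoidal quadrature).  The depth is large
near the mode of the sample's distribution and decays with distance.

The classifier reduces each curve to R^3 — its depth with respect to the
early, middle and late training groups — and applies a Nadaraya–Watson
style rule in that space: a Gaussian kernel density estimate per class,
scaled by the empirical class prior, with the predicted stage the argmax.

Evaluation is leave-one-patient-out: all recordings of the held-out patient
are classified against the remaining patients, the patient's label per
repetition is the majority vote over their curves, and the final label is
the majority vote over repetitions of the random windowing.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateInputError
from .preprocess import interpolate_to_seconds, random_windows
from .synthetic import STAGES, Cohort

DEFAULT_H_QUANTILE = 0.15  # bandwidth = this quantile of within-group distances


def l2_distance(a: np.ndarray, b: np.ndarray) -> float:
    """L2 distance between two curves on a common unit-step grid."""
    return float(np.sqrt(np.trapezoid(np.square(a - b), dx=1.0)))


def _pairwise_l2(curves: np.ndarray) -> np.ndarray:
    """All-pairs L2 distance matrix via the trapezoidal inner product."""
    w = np.ones(curves.shape[1])
    w[0] = w[-1] = 0.5  # trapezoid weights on a unit grid
    gram = (curves * w) @ curves.T
    sq = np.diag(gram)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * gram, 0.0)
    return np.sqrt(d2)


def hmode_depth(curve: np.ndarray, reference: np.ndarray, h: float) -> float:
    """h-mode depth of ``curve`` with respect to the ``reference`` sample."""
    if h <= 0:
        raise ValueError("bandwidth h must be positive")
    ref = np.atleast_2d(np.asarray(reference, dtype=float))
    if ref.shape[0] == 0:
        raise DegenerateInputError("reference group is empty")
    d = np.array([l2_distance(curve, r) for r in ref])
    return float(np.mean(np.exp(-0.5 * (d / h) ** 2)))


def group_bandwidth(reference: np.ndarray, quantile: float = DEFAULT_H_QUANTILE) -> float:
    """Bandwidth for one reference group: a low quantile of its pairwise
    L2 distances (floored away from zero for degenerate groups)."""
    ref = np.atleast_2d(reference)
    if ref.shape[0] < 2:
        return 1.0
    d = _pairwise_l2(ref)
    vals = d[np.triu_indices(ref.shape[0], k=1)]
    h = float(np.quantile(vals, quantile))
    return max(h, 1e-8)


@dataclass
class DepthVector:
    """Depths of one curve with respect to the three stage groups."""

    early: float
    middle: float
    late: float

    def as_array(self) -> np.ndarray:
        return np.array([self.early, self.middle, self.late])


def depth_transform(
    curve: np.ndarray,
    groups: dict[str, np.ndarray],
    bandwidths: dict[str, float] | None = None,
    h_quantile: float = DEFAULT_H_QUANTILE,
) -> DepthVector:
    """Reduce a curve to R^3: its h-mode depth w.r.t. each stage group."""
    for s in STAGES:
        if s not in groups or np.atleast_2d(groups[s]).shape[0] == 0:
            raise DegenerateInputError(f"training group {s!r} is empty")
    if bandwidths is None:
        bandwidths = {s: group_bandwidth(groups[s], h_quantile) for s in STAGES}
    vals = {s: hmode_depth(curve, groups[s], bandwidths[s]) for s in STAGES}
    return DepthVector(vals["early"], vals["middle"], vals["late"])


# ---------------------------------------------------------------------------
# Nadaraya-Watson (kernel density x prior) classification in depth space


def _tie_break(candidates: list[str], prevalence: dict[str, int]) -> str:
    """Most prevalent stage first, then fixed order early < middle < late."""
    best = max(prevalence[c] for c in candidates)
    tied = [c for c in candidates if prevalence[c] == best]
    return min(tied, key=STAGES.index)


def _scott_bandwidths(points: np.ndarray, pooled_scale: np.ndarray) -> np.ndarray:
    """Per-dimension Scott's-rule bandwidths for one class's depth vectors.

    Floored at a fraction of the pooled per-dimension spread: a class whose
    depth coordinate is numerically constant (everyone far from some group)
    must not collapse the kernel to a delta and zero out every density.
    """
    n, d = points.shape
    sd = points.std(axis=0, ddof=1) if n > 1 else np.ones(d)
    sd = np.maximum(sd, 1e-3 * pooled_scale + 1e-12)
    return sd * n ** (-1.0 / (d + 4))


def nw_classify(
    dv: DepthVector | np.ndarray,
    train_points: np.ndarray,
    train_labels: np.ndarray,
    bandwidths: dict[str, np.ndarray] | None = None,
) -> str:
    """Predict the stage maximising (class KDE density) x (class prior).

    The KDE is a Gaussian product kernel over that class's training depth
    vectors with per-dimension Scott's-rule bandwidths; the prior is the
    empirical class frequency.  Ties go to the most prevalent stage, then
    to the fixed stage order.
    """
    x = dv.as_array() if isinstance(dv, DepthVector) else np.asarray(dv, dtype=float)
    train_points = np.asarray(train_points, dtype=float)
    train_labels = np.asarray(train_labels)
    prevalence = {s: int(np.sum(train_labels == s)) for s in STAGES}
    if min(prevalence.values()) == 0:
        raise DegenerateInputError("training set must contain all three stages")

    n_total = len(train_labels)
    pooled_scale = train_points.std(axis=0, ddof=1)
    scores: dict[str, float] = {}
    for s in STAGES:
        pts = train_points[train_labels == s]
        bw = (
            bandwidths[s]
            if bandwidths is not None
            else _scott_bandwidths(pts, pooled_scale)
        )
        if np.any(bw <= 0):
            raise ValueError("bandwidths must be positive")
        z = (x[None, :] - pts) / bw[None, :]
        kern = np.exp(-0.5 * np.sum(z**2, axis=1)) / (
            (2.0 * np.pi) ** (pts.shape[1] / 2) * np.prod(bw)
        )
        density = float(kern.mean())
        scores[s] = density * (prevalence[s] / n_total)

    best = max(scores.values())
    winners = [s for s in STAGES if np.isclose(scores[s], best, rtol=1e-12, atol=0.0)]
    return _tie_break(winners, prevalence)


# ---------------------------------------------------------------------------
# leave-one-patient-out evaluation


@dataclass
class ClassificationReport:
    """Per-stage misclassification counts and success rates, patient level."""

    misclassified: dict[str, int]
    totals: dict[str, int]
    predictions: pd.DataFrame  # columns: patient_id, true_stage, predicted_stage
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_predictions(cls, preds: pd.DataFrame, **extra) -> "ClassificationReport":
        mis = {
            s: int(
                (
                    (preds["true_stage"] == s) & (preds["predicted_stage"] != s)
                ).sum()
            )
            for s in STAGES
        }
        tot = {s: int((preds["true_stage"] == s).sum()) for s in STAGES}
        return cls(mis, tot, preds.reset_index(drop=True), extra)

    def success_rate(self, stage: str | None = None) -> float:
        if stage is None:
            total = sum(self.totals.values())
            correct = total - sum(self.misclassified.values())
            return correct / total if total else float("nan")
        if self.totals[stage] == 0:
            return float("nan")
        return (self.totals[stage] - self.misclassified[stage]) / self.totals[stage]

    def to_frame(self) -> pd.DataFrame:
        """Tabular summary: one row per stage plus a total row."""
        rows = []
        for s in STAGES:
            rows.append(
                {
                    "stage": s,
                    "patients": self.totals[s],
                    "misclassified": self.misclassified[s],
                    "success_rate": self.success_rate(s),
                }
            )
        rows.append(
            {
                "stage": "total",
                "patients": sum(self.totals.values()),
                "misclassified": sum(self.misclassified.values()),
                "success_rate": self.success_rate(),
            }
        )
        return pd.DataFrame(rows)


def majority_vote(labels: list[str], prevalence: dict[str, int]) -> str:
    """Majority label with the shared tie-break rule."""
    counts = Counter(labels)
    top = max(counts.values())
    return _tie_break([s for s, c in counts.items() if c == top], prevalence)


def lopo_evaluate(
    cohort: Cohort,
    axes: str = "x",
    n_reps: int = 10,
    seed: int = 0,
    h_quantile: float = DEFAULT_H_QUANTILE,
) -> ClassificationReport:
    """Leave-one-patient-out depth classification of a whole cohort.

    ``axes`` is ``"x"``, ``"y"``, ``"z"`` or ``"xyz"`` (the three per-axis
    windows concatenated into one curve).  Each of the ``n_reps``
    repetitions draws fresh random windows; a patient's final label is the
    majority stage over repetitions of the majority stage over their curves.
    """
    counts = cohort.stage_counts()
    if min(counts.values()) < 2:
        raise DegenerateInputError("need >= 2 patients per stage for leave-one-out")

    # interpolate once; windows are redrawn per repetition
    curves = [
        interpolate_to_seconds(r) for p in cohort.patients for r in p.recordings
    ]
    labels = np.array([c.stage for c in curves])
    pids = np.array([c.patient_id for c in curves])
    patient_stage = {p.patient_id: p.stage for p in cohort.patients}

    votes: dict[str, list[str]] = {p.patient_id: [] for p in cohort.patients}
    datasets = random_windows(curves, axes, n_reps=n_reps, seed=seed)
    for ds in datasets:
        dist = _pairwise_l2(ds.curves)
        for pid in votes:
            test_mask = pids == pid
            train_mask = ~test_mask
            prevalence = {
                s: len({q for q in pids[train_mask & (labels == s)]}) for s in STAGES
            }
            group_cols = {s: np.where(train_mask & (labels == s))[0] for s in STAGES}
            if min(len(v) for v in group_cols.values()) == 0:
                raise DegenerateInputError(f"holding out {pid} empties a stage group")
            hs = {
                s: _submatrix_bandwidth(dist, group_cols[s], h_quantile)
                for s in STAGES
            }
            # depth of every curve w.r.t. each training group, from the
            # precomputed distance matrix
            depth_cols = np.column_stack(
                [
                    np.exp(-0.5 * (dist[:, group_cols[s]] / hs[s]) ** 2).mean(axis=1)
                    for s in STAGES
                ]
            )
            train_pts = depth_cols[train_mask]
            train_lbl = labels[train_mask]
            curve_preds = [
                nw_classify(depth_cols[i], train_pts, train_lbl)
                for i in np.where(test_mask)[0]
            ]
            votes[pid].append(majority_vote(curve_preds, prevalence))

    rows = []
    for pid, stage_votes in votes.items():
        prevalence = {
            s: sum(1 for q, st in patient_stage.items() if st == s and q != pid)
            for s in STAGES
        }
        rows.append(
            {
                "patient_id": pid,
                "true_stage": patient_stage[pid],
                "predicted_stage": majority_vote(stage_votes, prevalence),
            }
        )
    preds = pd.DataFrame(rows)
    return ClassificationReport.from_predictions(
        preds, axes=axes, n_reps=n_reps, seed=seed, h_quantile=h_quantile
    )


def _submatrix_bandwidth(dist: np.ndarray, cols: np.ndarray, quantile: float) -> float:
    if len(cols) < 2:
        return 1.0
    sub = dist[np.ix_(cols, cols)]
    vals = sub[np.triu_indices(len(cols), k=1)]
    return max(float(np.quantile(vals, quantile)), 1e-8)
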