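"""Functional tests of equality of group mean curves.

Three tests of H0: the group mean curves coincide, each applying a classical
one-dimensional statistic to functional data in a different way:

* **random-projection ANOVA** — project every curve onto k random directions
  drawn uniformly on the unit sphere of the grid space, run the parametric
  one-way F-test on each projection, and combine the k p-values with either
  Bonferroni or the Benjamini–Hochberg false discovery rate;
* **max-F ANOVA** — the statistic is the supremum over grid points of the
  pointwise one-way F statistic; its null distribution is estimated by a
  centered bootstrap (curves resampled with replacement within each group,
  each bootstrap group shifted by its original sample mean curve);
* **L2 two-sample test** — the statistic is the integrated squared
  difference of the two sample mean curves, with the analogous centered
  bootstrap.

Bootstrap p-values use the exceedance formula (1 + #{T*_b >= T}) / (B + 1),
so they live in [1/(B+1), 1] and are never exactly zero.

:func:`repeated_test` reruns a chosen test over many independent random
window draws and summarises the resulting p-values (mean, standard
deviation, proportion <= 0.05) — the summary a practitioner tabulates when
every curve lives on its own time domain and no single windowing is
canonical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._rng import STREAM_BOOTSTRAP, STREAM_PROJECTIONS, derive_rng
from .errors import DegenerateInputError, NumericalDegeneracyError
from .preprocess import InterpolatedCurve, WindowedDataset, random_windows
from .synthetic import STAGES

_BOOT_CHUNK = 100  # bootstrap replicates per vectorised chunk (memory bound)


@dataclass
class TestResult:
    p_value: float
    statistic: float
    name: str
    params: dict = field(default_factory=dict)
    seed: int | None = None


@dataclass
class PValueSummary:
    """Mean, sd and proportion <= 0.05 of p-values over repeated windowings."""

    mean: float
    sd: float
    prop_leq_05: float
    count: int
    p_values: np.ndarray

    @classmethod
    def from_pvalues(cls, ps: Sequence[float]) -> "PValueSummary":
        ps = np.asarray(ps, dtype=float)
        sd = float(np.std(ps, ddof=1)) if ps.size > 1 else 0.0
        return cls(float(ps.mean()), sd, float(np.mean(ps <= 0.05)), ps.size, ps)


# ---------------------------------------------------------------------------
# random projections


def sphere_directions(k: int, dim: int, rng: np.random.Generator) -> np.ndarray:
    """k directions uniform on the unit sphere in R^dim (normalised normals)."""
    if dim < 1:
        raise DegenerateInputError("projection dimension must be >= 1")
    v = rng.standard_normal((k, dim))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def random_projections(
    dataset: WindowedDataset | np.ndarray, k: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Project each curve onto k uniform sphere directions.

    Returns ``(projections, directions)`` with projections of shape (n, k).
    """
    curves = dataset.curves if isinstance(dataset, WindowedDataset) else np.asarray(dataset)
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = derive_rng(seed, STREAM_PROJECTIONS)
    dirs = sphere_directions(k, curves.shape[1], rng)
    return curves @ dirs.T, dirs


def anova_rp(
    groups: Sequence[np.ndarray],
    k: int = 30,
    combine: str = "bonferroni",
    seed: int = 0,
) -> TestResult:
    """Random-projection functional ANOVA across three (or more) groups.

    Per projection the parametric one-way F-test p-value is computed; the k
    p-values are combined as min(1, k * min p) (Bonferroni) or as the
    minimum Benjamini–Hochberg-adjusted p-value (FDR).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(g.shape[0] < 2 for g in groups):
        raise DegenerateInputError("each group needs >= 2 curves for the F-test")
    if combine not in ("bonferroni", "fdr"):
        raise ValueError(f"combine must be 'bonferroni' or 'fdr', got {combine!r}")
    l = groups[0].shape[1]
    if any(g.shape[1] != l for g in groups):
        raise ValueError("groups must share a common grid length")

    rng = derive_rng(seed, STREAM_PROJECTIONS)
    dirs = sphere_directions(k, l, rng)
    proj = [g @ dirs.T for g in groups]  # (n_g, k)

    pvals = np.empty(k)
    fstats = np.empty(k)
    for j in range(k):
        samples = [p[:, j] for p in proj]
        if all(np.ptp(s) == 0 for s in samples):
            raise NumericalDegeneracyError(
                f"projection {j}: zero within-group variance in every group"
            )
        f, p = stats.f_oneway(*samples)
        pvals[j], fstats[j] = p, f

    if combine == "bonferroni":
        combined = min(1.0, k * float(pvals.min()))
    else:
        combined = float(multipletests(pvals, method="fdr_bh")[1].min())
    return TestResult(
        combined,
        float(fstats.max()),
        f"rp-{'bonf' if combine == 'bonferroni' else 'fdr'}",
        {"k": k, "raw_p": pvals},
        seed,
    )


# ---------------------------------------------------------------------------
# pointwise F and the max-F bootstrap ANOVA


def pointwise_f(groups: Sequence[np.ndarray], ridge: float = 0.0) -> np.ndarray:
    """One-way F statistic at every grid point; ``groups[g]`` is (n_g, l).

    ``ridge`` is added to the within-group mean square to keep degenerate
    (zero-variance) points finite; callers pass a machine-epsilon-scaled
    value.
    """
    ns = np.array([g.shape[0] for g in groups], dtype=float)
    n_total = ns.sum()
    n_groups = len(groups)
    means = np.stack([g.mean(axis=0) for g in groups])  # (G, l)
    grand = (ns[:, None] * means).sum(axis=0) / n_total
    between = (ns[:, None] * (means - grand) ** 2).sum(axis=0) / (n_groups - 1)
    within = (
        np.stack([(g.shape[0] - 1) * g.var(axis=0, ddof=1) for g in groups]).sum(axis=0)
        / (n_total - n_groups)
    )
    return between / (within + ridge)


def _ridge_for(groups: Sequence[np.ndarray]) -> float:
    scale = max(1.0, max(float(np.mean(np.square(g))) for g in groups))
    return np.finfo(float).eps * scale


def anova_maxF(
    groups: Sequence[np.ndarray], B: int = 999, seed: int = 0
) -> TestResult:
    """Bootstrap functional ANOVA based on the supremum of the pointwise F.

    The observed statistic is max_t F(t).  Each bootstrap replicate
    resamples curves with replacement within every group independently and
    centers the resampled group at its original sample mean curve, so the
    bootstrap world obeys the null; p = (1 + #{T* >= T}) / (B + 1).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(g.shape[0] < 2 for g in groups):
        raise DegenerateInputError("each group needs >= 2 curves")
    l = groups[0].shape[1]
    if any(g.shape[1] != l for g in groups):
        raise ValueError("groups must share a common grid length")

    within_var = np.stack([g.var(axis=0, ddof=1) for g in groups]).sum(axis=0)
    if np.all(within_var == 0):
        raise NumericalDegeneracyError("zero within-group variance at every grid point")
    ridge = _ridge_for(groups)
    if np.any(within_var == 0):
        warnings.warn(
            "zero within-group variance at some grid points; ridge guard applied",
            RuntimeWarning,
            stacklevel=2,
        )

    t_obs = float(pointwise_f(groups, ridge).max())
    rng = derive_rng(seed, STREAM_BOOTSTRAP)
    orig_means = [g.mean(axis=0) for g in groups]
    ns = [g.shape[0] for g in groups]
    n_total = sum(ns)
    n_groups = len(groups)

    exceed = 0
    for start in range(0, B, _BOOT_CHUNK):
        nb = min(_BOOT_CHUNK, B - start)
        between = np.zeros((nb, l))
        within = np.zeros((nb, l))
        boot_means = []
        for g, m0, n_g in zip(groups, orig_means, ns):
            idx = rng.integers(0, n_g, size=(nb, n_g))
            samp = g[idx]  # (nb, n_g, l)
            bm = samp.mean(axis=1) - m0  # centered bootstrap mean
            boot_means.append((n_g, bm))
            within += (n_g - 1) * samp.var(axis=1, ddof=1)
        grand = sum(n_g * bm for n_g, bm in boot_means) / n_total
        between = sum(n_g * (bm - grand) ** 2 for n_g, bm in boot_means) / (
            n_groups - 1
        )
        f = between / (within / (n_total - n_groups) + ridge)
        exceed += int(np.sum(f.max(axis=1) >= t_obs))

    p = (1 + exceed) / (B + 1)
    return TestResult(p, t_obs, "maxf", {"B": B}, seed)


# ---------------------------------------------------------------------------
# L2 two-sample test


def _l2_sq(diff: np.ndarray) -> np.ndarray:
    """Trapezoidal integral of diff^2 along the last axis (unit grid step)."""
    sq = np.square(diff)
    return np.trapezoid(sq, dx=1.0, axis=-1)


def l2_mean_test(
    group1: np.ndarray, group2: np.ndarray, B: int = 999, seed: int = 0
) -> TestResult:
    """Two-sample bootstrap test of equal mean curves based on the L2 norm.

    T = integral of (mean1 - mean2)^2 over the grid (trapezoidal rule);
    bootstrap statistic T*_b recenters each resampled mean at its original
    sample mean; p = (1 + #{T* >= T}) / (B + 1).
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if g1.ndim != 2 or g2.ndim != 2 or g1.shape[1] != g2.shape[1]:
        raise ValueError("groups must be 2-D with a common grid length")
    if g1.shape[0] < 2 or g2.shape[0] < 2:
        raise DegenerateInputError("each group needs >= 2 curves")

    m1, m2 = g1.mean(axis=0), g2.mean(axis=0)
    t_obs = float(_l2_sq(m1 - m2))
    rng = derive_rng(seed, STREAM_BOOTSTRAP)

    exceed = 0
    for start in range(0, B, _BOOT_CHUNK):
        nb = min(_BOOT_CHUNK, B - start)
        idx1 = rng.integers(0, g1.shape[0], size=(nb, g1.shape[0]))
        idx2 = rng.integers(0, g2.shape[0], size=(nb, g2.shape[0]))
        bm1 = g1[idx1].mean(axis=1) - m1
        bm2 = g2[idx2].mean(axis=1) - m2
        exceed += int(np.sum(_l2_sq(bm1 - bm2) >= t_obs))

    p = (1 + exceed) / (B + 1)
    return TestResult(p, t_obs, "l2", {"B": B}, seed)


# ---------------------------------------------------------------------------
# repeated windowed testing


@dataclass
class TestSpec:
    """Which test to run on each windowed dataset.

    ``name``: one of ``rp-bonf``, ``rp-fdr``, ``maxf``, ``l2``.  For ``l2``
    (two-sample) ``pair`` names the two stages under comparison; the ANOVA
    tests compare all three stages.
    """

    name: str
    k: int = 30
    B: int = 999
    pair: tuple[str, str] | None = None

    def validate(self) -> None:
        if self.name not in ("rp-bonf", "rp-fdr", "maxf", "l2"):
            raise ValueError(f"unknown test {self.name!r}")
        if self.name == "l2":
            if self.pair is None or len(self.pair) != 2:
                raise ValueError("l2 test needs a pair of stage labels")
            if any(s not in STAGES for s in self.pair):
                raise ValueError(f"pair must use stages {STAGES}")


def run_test(dataset: WindowedDataset, spec: TestSpec, seed: int = 0) -> TestResult:
    """Run one test on one windowed dataset."""
    spec.validate()
    if spec.name == "l2":
        a, b = spec.pair  # type: ignore[misc]
        return l2_mean_test(dataset.group(a), dataset.group(b), B=spec.B, seed=seed)
    groups = [dataset.group(s) for s in STAGES]
    if spec.name == "maxf":
        return anova_maxF(groups, B=spec.B, seed=seed)
    combine = "bonferroni" if spec.name == "rp-bonf" else "fdr"
    return anova_rp(groups, k=spec.k, combine=combine, seed=seed)


def repeated_test(
    curves: list[InterpolatedCurve],
    axis: str,
    spec: TestSpec,
    n_reps: int = 1000,
    seed: int = 0,
) -> PValueSummary:
    """Run ``spec`` on ``n_reps`` fresh random windowings and summarise.

    Each repetition draws new per-curve offsets and a new test stream, both
    derived from the master seed, so the summary is reproducible and
    repetitions are independent.
    """
    spec.validate()
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    datasets = random_windows(curves, axis, n_reps=n_reps, seed=seed)
    ps = []
    for j, ds in enumerate(datasets):
        try:
            res = run_test(ds, spec, seed=int(derive_rng(seed, STREAM_BOOTSTRAP, j).integers(2**31)))
        except Exception as exc:
            raise type(exc)(f"repetition {j}: {exc}") from exc
        ps.append(res.p_value)
    return PValueSummary.from_pvalues(ps)
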