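"""Monte-Carlo characterisation of the streaming median estimators.

The drivers in this module quantify the trade-offs that motivate the
memory-less estimator: steady-state variance versus buffer length, settling
time after a step change in the input median, robustness to heavy-tailed
contamination, the compression of the buffer contents around the median,
and the detectability of small median shifts (ROC analysis).

Conventions shared by all drivers
---------------------------------
* Repetitions are independent and seeded through a single integer seed via
  ``numpy.random.SeedSequence.spawn``, so every result is reproducible.
* "Steady state" means the first ``10 * L`` estimates of a run are
  discarded before variances are computed.
* The settling time after a step from median ``mu_i`` to ``mu_f`` is the
  first post-step sample at which the estimate touches
  ``mu_f - 0.05 * (mu_f - mu_i)`` (i.e. has covered 95% of the change);
  runs that never touch the level are flagged as not settled (NaN).
* Default repetition counts are desk scale (thousands, not the 1e5-rep
  overnight runs a cluster would use); they are arguments everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .estimators import make_estimator
from .synthetic import (
    FoldedNormal,
    Mixture,
    Normal,
    StepSpec,
    make_distribution,
)

__all__ = [
    "EstimatorConfig",
    "NM63",
    "CMM63",
    "CMM511",
    "settling_time",
    "StepExperimentResult",
    "run_step_experiment",
    "ErrorDistribution",
    "error_distribution",
    "steady_state_variance",
    "outlier_robustness",
    "DensityMatrix",
    "buffer_density",
    "ROCCurve",
    "roc_small_change",
    "settling_vs_amplitude",
]


@dataclass(frozen=True)
class EstimatorConfig:
    """Which estimator to run: backend ``"nm"`` or ``"cmm"`` and buffer length."""

    backend: str
    length: int

    def __post_init__(self):
        if self.backend not in ("nm", "cmm"):
            raise ValueError("backend must be 'nm' or 'cmm'")

    @property
    def label(self) -> str:
        return f"{self.backend.upper()}-{self.length}"

    def build(self):
        return make_estimator(self.backend, self.length)


NM63 = EstimatorConfig("nm", 63)
CMM63 = EstimatorConfig("cmm", 63)
CMM511 = EstimatorConfig("cmm", 511)


def _spawn_rngs(seed, n):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def settling_time(trace, mu_i: float, mu_f: float) -> float:
    """First index at which ``trace`` covers 95% of the median change.

    ``trace`` is the sequence of estimates starting at the step (element 0
    is the estimate after the first post-step sample).  The crossing is
    direction-aware and "first touch": the estimate only has to reach the
    95% level once.  Returns NaN when the level is never reached.
    """
    if mu_f == mu_i:
        raise ValueError("mu_f must differ from mu_i")
    trace = np.asarray(trace, dtype=float)
    target = mu_f - 0.05 * (mu_f - mu_i)
    hits = trace >= target if mu_f > mu_i else trace <= target
    idx = np.flatnonzero(hits)
    return float(idx[0]) if idx.size else float("nan")


@dataclass
class StepExperimentResult:
    """Per-repetition outcomes of a distribution step experiment."""

    config: EstimatorConfig
    spec: StepSpec
    settling_times: np.ndarray  # samples after the step; NaN = never settled
    final_errors: np.ndarray    # last estimate - true post-step median
    final_estimates: np.ndarray
    example_trace: np.ndarray = field(repr=False)  # post-step estimates, first rep

    @property
    def n_not_settled(self) -> int:
        return int(np.isnan(self.settling_times).sum())

    def summary(self) -> dict:
        return {
            "estimator": self.config.label,
            "n_reps": len(self.final_errors),
            "mean_final_estimate": float(self.final_estimates.mean()),
            "mean_final_error": float(self.final_errors.mean()),
            "std_final_error": float(self.final_errors.std(ddof=1)),
            "mean_settling": float(np.nanmean(self.settling_times)),
            "std_settling": float(np.nanstd(self.settling_times, ddof=1)),
            "n_not_settled": self.n_not_settled,
        }


def run_step_experiment(spec: StepSpec, config: EstimatorConfig,
                        n_reps: int = 5000, seed: int | None = None) -> StepExperimentResult:
    """Repeat a step-change run and collect settling times and final errors.

    Each repetition streams ``spec.n_before`` pre-step and ``spec.n_after``
    post-step samples through a fresh estimator (the first ``L`` samples
    fill the buffer, so ``spec.n_before`` must be at least ``L``; use
    ``10 * L`` or more to reach pre-step steady state).  When the two
    distributions share their median, the settling time is 0 by convention.
    """
    before = make_distribution(spec.dist_before)
    after = make_distribution(spec.dist_after)
    if spec.n_before < config.length:
        raise ValueError("n_before must be at least the buffer length")
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    mu_i, mu_f = before.median(), after.median()
    degenerate = mu_f == mu_i
    settling = np.empty(n_reps)
    finals = np.empty(n_reps)
    example = None
    for i, rng in enumerate(_spawn_rngs(spec.seed if seed is None else seed, n_reps)):
        est = config.build()
        est.stream(before.sample(rng, spec.n_before))
        post = est.stream(after.sample(rng, spec.n_after))
        settling[i] = 0.0 if degenerate else settling_time(post, mu_i, mu_f)
        finals[i] = post[-1]
        if example is None:
            example = post
    return StepExperimentResult(config, spec, settling, finals - mu_f, finals, example)


@dataclass
class ErrorDistribution:
    """Across-repetition distribution of the final estimation error."""

    config: EstimatorConfig
    errors: np.ndarray  # final estimate - true median, one per repetition

    @property
    def std(self) -> float:
        return float(self.errors.std(ddof=1))

    def histogram(self, bins=60) -> tuple[np.ndarray, np.ndarray]:
        return np.histogram(self.errors, bins=bins, density=True)


def error_distribution(dist, config: EstimatorConfig, n_reps: int = 2000,
                       run_length: int | None = None, seed: int = 0) -> ErrorDistribution:
    """Distribution of (last estimate - true median) on an i.i.d. stream.

    Each repetition fills the buffer and then runs ``run_length`` further
    samples (default ``20 * L``, well past the ``10 * L`` steady-state
    point) before recording the final estimate.
    """
    dist = make_distribution(dist)
    if run_length is None:
        run_length = 20 * config.length
    if run_length < config.length:
        raise ValueError("run_length must be at least a few buffer lengths")
    true_median = dist.median()
    errors = np.empty(n_reps)
    for i, rng in enumerate(_spawn_rngs(seed, n_reps)):
        est = config.build()
        trace = est.stream(dist.sample(rng, config.length + run_length))
        errors[i] = trace[-1] - true_median
    return ErrorDistribution(config, errors)


def steady_state_variance(dist, config: EstimatorConfig, n_reps: int = 2000,
                          run_length: int | None = None, seed: int = 0) -> float:
    """Steady-state estimator variance on an i.i.d. stream.

    Pools the estimates of all repetitions after discarding the first
    ``10 * L`` of each run (the steady-state convention), so the value is a
    combined time-and-ensemble variance of the estimator output.
    """
    dist = make_distribution(dist)
    L = config.length
    if run_length is None:
        run_length = 20 * L
    discard = 10 * L
    if run_length <= discard:
        raise ValueError("run_length must exceed the 10*L steady-state discard")
    acc_n = 0
    acc_sum = 0.0
    acc_sq = 0.0
    for rng in _spawn_rngs(seed, n_reps):
        est = config.build()
        trace = est.stream(dist.sample(rng, L + run_length))
        tail = trace[L + discard:]
        acc_n += tail.size
        acc_sum += tail.sum()
        acc_sq += (tail ** 2).sum()
    mean = acc_sum / acc_n
    return acc_sq / acc_n - mean ** 2


def outlier_robustness(primary: Normal = Normal(0.0, 1.0),
                       outlier: Normal = Normal(0.0, 10.0),
                       outlier_prob: float = 0.05,
                       configs: tuple = (NM63, CMM63),
                       n_reps: int = 1000, seed: int = 0) -> dict:
    """Steady-state variances on a contaminated Gaussian stream.

    Returns per-estimator variances plus the ratio of the last to the first
    config (baseline over candidate when called with the defaults).
    """
    if not 0 <= outlier_prob < 0.5:
        raise ValueError("outlier_prob must be in [0, 0.5)")
    if outlier_prob == 0:
        dist = primary
    else:
        dist = Mixture((primary, outlier), (1.0 - outlier_prob, outlier_prob))
    variances = {
        cfg.label: steady_state_variance(dist, cfg, n_reps=n_reps, seed=seed + i)
        for i, cfg in enumerate(configs)
    }
    values = list(variances.values())
    return {"variances": variances, "variance_ratio": values[-1] / values[0]}


@dataclass
class DensityMatrix:
    """Buffer-content histograms at successive times, averaged over runs.

    ``density[i]`` is the normalised (rows sum to 1) histogram of the
    buffer contents ``time_points[i]`` samples after the buffer was first
    filled; ``iqr_width[i]`` is the mean interquartile width of the buffer
    contents at that time.
    """

    time_points: np.ndarray
    bin_edges: np.ndarray
    density: np.ndarray
    iqr_width: np.ndarray

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def mode(self, i: int) -> float:
        """Center of the densest bin at time point ``i``."""
        return float(self.bin_centers[np.argmax(self.density[i])])


def buffer_density(dist, length: int = 1023, time_points=(0, 10230, 51150),
                   n_reps: int = 200, seed: int = 0, backend: str = "nm",
                   n_bins: int = 61) -> DensityMatrix:
    """How the estimator's buffer population evolves over time.

    Each repetition fills a fresh buffer with ``length`` i.i.d. samples
    (time 0), then streams further samples, pausing at each requested time
    point to histogram the buffer contents.  For the memory-less estimator
    the initially distribution-shaped population contracts around the true
    median; for the moving-median baseline it stays distribution-shaped.
    """
    dist = make_distribution(dist)
    time_points = np.asarray(time_points, dtype=int)
    if np.any(np.diff(time_points) <= 0):
        raise ValueError("time_points must be strictly increasing")
    if time_points[0] < 0:
        raise ValueError("time_points must be non-negative")
    # common support from the generating distribution's tails
    probe = dist.sample(np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0]), 4096)
    lo, hi = np.quantile(probe, [0.0005, 0.9995])
    pad = 0.1 * (hi - lo)
    bin_edges = np.linspace(lo - pad, hi + pad, n_bins + 1)
    counts = np.zeros((time_points.size, n_bins))
    iqr = np.zeros(time_points.size)
    for rng in _spawn_rngs(seed, n_reps):
        est = make_estimator(backend, length)
        est.stream(dist.sample(rng, length))
        prev = 0
        for j, tp in enumerate(time_points):
            if tp > prev:
                est.stream(dist.sample(rng, tp - prev))
                prev = tp
            buf = est.buffer
            counts[j] += np.histogram(buf, bins=bin_edges)[0]
            q25, q75 = np.percentile(buf, [25, 75])
            iqr[j] += q75 - q25
    density = counts / counts.sum(axis=1, keepdims=True)
    return DensityMatrix(time_points, bin_edges, density, iqr / n_reps)


@dataclass
class ROCCurve:
    """Discrimination of a median shift from single estimator readings."""

    config: EstimatorConfig
    delta_frac: float
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def _auc_from_samples(pre: np.ndarray, post: np.ndarray, increase: bool
                      ) -> tuple[np.ndarray, np.ndarray, float]:
    """Empirical ROC by sweeping a decision threshold over estimate values."""
    sign = 1.0 if increase else -1.0
    pre_s, post_s = sign * pre, sign * post
    thresholds = np.concatenate([[np.inf], np.sort(np.unique(np.concatenate([pre_s, post_s])))[::-1], [-np.inf]])
    tpr = (post_s[None, :] > thresholds[:, None]).mean(axis=1)
    fpr = (pre_s[None, :] > thresholds[:, None]).mean(axis=1)
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


def roc_small_change(delta_fracs=(0.0, 0.03), configs: tuple = (NM63, CMM63),
                     n_reps: int = 400, seed: int = 0,
                     base: Normal = Normal(8.0, 2.0),
                     post_mult: int = 20) -> list[ROCCurve]:
    """ROC analysis of detecting a relative change in the input median.

    For each fractional change ``delta`` the input median steps from ``m``
    to ``m * (1 + delta)`` (the spread is unchanged).  One estimator
    reading is collected per repetition just before the step and again
    ``post_mult * L`` samples after it; sweeping a decision threshold over
    those two ensembles yields the ROC curve and its area (equivalently the
    probability that a post-change reading exceeds a pre-change one).
    """
    results = []
    for cfg in configs:
        L = cfg.length
        for d_idx, delta in enumerate(delta_fracs):
            if delta < 0:
                raise ValueError("median changes must be non-negative fractions")
            shifted = Normal(base.mu * (1.0 + delta), base.sigma)
            pre = np.empty(n_reps)
            post = np.empty(n_reps)
            for i, rng in enumerate(_spawn_rngs(seed + 7919 * d_idx, n_reps)):
                est = cfg.build()
                trace = est.stream(base.sample(rng, 11 * L))
                pre[i] = trace[-1]
                post_trace = est.stream(shifted.sample(rng, post_mult * L))
                post[i] = post_trace[-1]
            fpr, tpr, auc = _auc_from_samples(pre, post, increase=base.mu >= 0)
            results.append(ROCCurve(cfg, float(delta), fpr, tpr, auc))
    return results


#: Post-step target medians used by the folded-normal amplitude sweep; the
#: pre-step input is |N(0,1)| whose median is ~0.6745, and each target
#: median m corresponds to noise sigma = m / 0.6745.
AMPLITUDE_MEDIANS = (1.21, 1.81, 3.01, 4.82, 7.84, 12.66, 20.50)


def settling_vs_amplitude(target_medians=AMPLITUDE_MEDIANS,
                          configs: tuple = (NM63, CMM511),
                          n_reps: int = 500, seed: int = 0,
                          n_after: int | None = None) -> pd.DataFrame:
    """Settling time versus step amplitude on folded-normal input.

    The input starts as ``|N(0,1)|`` and its median steps up to each target
    value; the sweep contrasts a window estimator (settling tied to its
    length) with the memory-less one (settling tied to the amplitude).
    Each run starts from a buffer freshly filled with pre-step samples (the
    fill-moment convention used by all settling experiments here).
    Returns a tidy frame with one row per (estimator, target median).
    """
    before = FoldedNormal(1.0)
    m0 = before.median()
    rows = []
    for cfg in configs:
        length = cfg.length
        post = n_after if n_after is not None else 20 * length
        for j, m_f in enumerate(target_medians):
            if m_f <= m0:
                raise ValueError("target medians must exceed the initial median")
            after = FoldedNormal(m_f / m0)
            spec = StepSpec(before, after, n_before=length, n_after=post,
                            seed=seed + 104729 * j)
            res = run_step_experiment(spec, cfg, n_reps=n_reps)
            rows.append({
                "estimator": cfg.label,
                "target_median": m_f,
                "mean_settling": float(np.nanmean(res.settling_times)),
                "median_settling": float(np.nanmedian(res.settling_times)),
                "std_settling": float(np.nanstd(res.settling_times, ddof=1)),
                "n_not_settled": res.n_not_settled,
            })
    return pd.DataFrame(rows)
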