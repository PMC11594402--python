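"""Synthetic signal generators with exact ground truth.

Everything the simulation experiments consume is generated here: i.i.d.
streams whose distribution steps at a known time, Gaussian-mixture streams
with labelled outliers, and spike-embedded Gaussian noise standing in for a
real extracellular recording.  Each generator is driven by a single integer
seed and returns the analytic ground truth (true medians, planted spike
positions) alongside the samples, so detector and estimator performance can
be scored without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "Normal",
    "Beta",
    "FoldedNormal",
    "Mixture",
    "make_distribution",
    "StepSpec",
    "StepStream",
    "gen_step_stream",
    "SpikeTrainSpec",
    "SpikySignal",
    "biphasic_template",
    "gen_spiky_signal",
    "gen_outlier_mixture",
    "MixtureSample",
]


@dataclass(frozen=True)
class Normal:
    """Gaussian ``N(mu, sigma^2)``; ``sigma=0`` degenerates to a constant."""

    mu: float = 0.0
    sigma: float = 1.0

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.normal(self.mu, self.sigma, n)

    def median(self) -> float:
        return float(self.mu)

    def cdf(self, x):
        return stats.norm.cdf(x, self.mu, self.sigma)

    def to_dict(self) -> dict:
        return {"family": "normal", "mu": self.mu, "sigma": self.sigma}


@dataclass(frozen=True)
class Beta:
    """Beta distribution on (0, 1) with shape parameters ``a`` and ``b``."""

    a: float
    b: float

    def __post_init__(self):
        if self.a <= 0 or self.b <= 0:
            raise ValueError("Beta shape parameters must be positive")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.beta(self.a, self.b, n)

    def median(self) -> float:
        return float(stats.beta.ppf(0.5, self.a, self.b))

    def cdf(self, x):
        return stats.beta.cdf(x, self.a, self.b)

    def to_dict(self) -> dict:
        return {"family": "beta", "a": self.a, "b": self.b}


@dataclass(frozen=True)
class FoldedNormal:
    """Distribution of ``|x|`` for ``x ~ N(0, sigma^2)`` (half-normal).

    Its median is ``sigma * Phi^{-1}(3/4) ≈ 0.6745 sigma`` while its mean is
    ``sigma * sqrt(2/pi) ≈ 0.7979 sigma`` — the gap between the two is what
    makes it the interesting test bed for a median estimator.
    """

    sigma: float = 1.0

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return np.abs(rng.normal(0.0, self.sigma, n))

    def median(self) -> float:
        return float(stats.halfnorm.ppf(0.5, scale=self.sigma))

    def mean(self) -> float:
        return float(stats.halfnorm.mean(scale=self.sigma))

    def cdf(self, x):
        return stats.halfnorm.cdf(x, scale=self.sigma)

    def to_dict(self) -> dict:
        return {"family": "folded_normal", "sigma": self.sigma}


@dataclass(frozen=True)
class Mixture:
    """Finite mixture of component distributions with given weights."""

    components: tuple
    weights: tuple

    def __post_init__(self):
        if len(self.components) != len(self.weights) or not self.components:
            raise ValueError("components and weights must be non-empty and equal length")
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError("weights must be non-negative and sum to 1")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return self.sample_labelled(rng, n)[0]

    def sample_labelled(self, rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
        """Draw ``n`` values plus the index of the component each came from."""
        labels = rng.choice(len(self.components), size=n, p=np.asarray(self.weights, float))
        out = np.empty(n)
        for i, comp in enumerate(self.components):
            mask = labels == i
            out[mask] = comp.sample(rng, int(mask.sum()))
        return out, labels

    def cdf(self, x):
        x = np.asarray(x, dtype=float)
        return sum(w * c.cdf(x) for w, c in zip(self.weights, self.components))

    def median(self) -> float:
        """Numeric root of ``F(x) = 1/2`` over the mixture CDF."""
        lo = min(c.median() for c in self.components) - 1.0
        hi = max(c.median() for c in self.components) + 1.0
        while self.cdf(lo) > 0.5:
            lo -= 10.0
        while self.cdf(hi) < 0.5:
            hi += 10.0
        return float(optimize.brentq(lambda x: self.cdf(x) - 0.5, lo, hi, xtol=1e-12))

    def to_dict(self) -> dict:
        return {
            "family": "mixture",
            "weights": list(self.weights),
            "components": [c.to_dict() for c in self.components],
        }


_FAMILIES = {"normal": Normal, "beta": Beta, "folded_normal": FoldedNormal}


def make_distribution(spec) -> object:
    """Build a distribution from a name/dict, e.g. ``{"family": "normal", "mu": 8, "sigma": 2}``."""
    if hasattr(spec, "sample") and hasattr(spec, "median"):
        return spec
    if not isinstance(spec, dict):
        raise ValueError(f"cannot interpret distribution spec {spec!r}")
    spec = dict(spec)
    family = spec.pop("family", None)
    if family == "mixture":
        comps = tuple(make_distribution(c) for c in spec.pop("components"))
        return Mixture(components=comps, weights=tuple(spec.pop("weights")), **spec)
    if family not in _FAMILIES:
        raise ValueError(f"unknown distribution family {family!r}")
    return _FAMILIES[family](**spec)


# ---------------------------------------------------------------------------
# step-change streams
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StepSpec:
    """An i.i.d. stream whose distribution switches once.

    ``n_before`` samples are drawn from ``dist_before``, then ``n_after``
    from ``dist_after``; the step therefore sits at sample index
    ``n_before``.  True medians come from the families' quantile functions,
    never from the realised samples.
    """

    dist_before: object
    dist_after: object
    n_before: int
    n_after: int
    seed: int = 0

    def __post_init__(self):
        if self.n_before <= 0 or self.n_after <= 0:
            raise ValueError("sample counts must be positive")


@dataclass(frozen=True)
class StepStream:
    samples: np.ndarray
    median_before: float
    median_after: float
    step_index: int


def gen_step_stream(spec: StepSpec, rng: np.random.Generator | None = None) -> StepStream:
    """Realise a :class:`StepSpec` (reproducible from ``spec.seed``)."""
    before = make_distribution(spec.dist_before)
    after = make_distribution(spec.dist_after)
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    samples = np.concatenate(
        [before.sample(rng, spec.n_before), after.sample(rng, spec.n_after)]
    )
    return StepStream(samples, before.median(), after.median(), spec.n_before)


# ---------------------------------------------------------------------------
# spike-embedded noise
# ---------------------------------------------------------------------------

def biphasic_template(width: int = 36) -> np.ndarray:
    """Unit biphasic spike waveform: a sharp negative lobe then a smaller
    positive rebound, normalised so the (negative) peak has magnitude 1.

    The default width of 36 samples corresponds to ~1.2 ms at a nominal
    30 kHz sampling rate; the trough occupies ~a quarter of that (~0.3 ms),
    matching the sharp depolarisation of an extracellular action potential.
    """
    if width < 4:
        raise ValueError("template width must be at least 4 samples")
    n_neg = max(3, int(round(width * 0.25)))
    n_pos = width - n_neg
    phase_neg = np.sin(np.pi * (np.arange(n_neg) + 0.5) / n_neg) ** 2
    phase_pos = np.sin(np.pi * (np.arange(n_pos) + 0.5) / n_pos)
    tpl = np.concatenate([-phase_neg, 0.3 * phase_pos])
    return tpl / np.abs(tpl.min())


@dataclass(frozen=True)
class SpikeTrainSpec:
    """Spike-embedded Gaussian noise with recorded ground truth.

    ``snr`` is the planted peak amplitude divided by ``noise_sigma`` (the
    conventional peak-over-noise signal-to-noise ratio); ``spike_rate`` is
    the expected number of events per 1,000 samples.  Planted events are
    negative-going and separated by at least one template width.
    """

    n_samples: int
    noise_sigma: float = 1.0
    snr: float = 8.0
    spike_rate: float = 2.0
    template_width: int = 36
    seed: int = 0

    def __post_init__(self):
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        if self.noise_sigma <= 0:
            raise ValueError("noise_sigma must be positive")
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if self.spike_rate < 0:
            raise ValueError("spike_rate must be non-negative")


@dataclass(frozen=True)
class SpikySignal:
    samples: np.ndarray
    event_indices: np.ndarray  # position of each planted (negative) peak
    template: np.ndarray
    amplitude: float  # peak magnitude of the planted waveform, signal units


def gen_spiky_signal(spec: SpikeTrainSpec) -> SpikySignal:
    """Plant scaled biphasic templates in white Gaussian noise.

    Candidate onsets are drawn uniformly and thinned to enforce the minimum
    inter-spike gap, so the realised event count can fall slightly below
    the nominal ``spike_rate``; the returned ``event_indices`` are the
    ground truth actually planted.
    """
    rng = np.random.default_rng(spec.seed)
    samples = rng.normal(0.0, spec.noise_sigma, spec.n_samples)
    tpl = biphasic_template(spec.template_width)
    amplitude = spec.snr * spec.noise_sigma
    width = tpl.shape[0]
    n_events = int(round(spec.n_samples * spec.spike_rate / 1000.0))
    peaks = []
    if n_events > 0 and spec.n_samples > 2 * width:
        starts = np.sort(rng.integers(0, spec.n_samples - width, size=n_events))
        last_end = -width
        peak_off = int(np.argmin(tpl))
        for s in starts:
            if s >= last_end + width:
                samples[s : s + width] += amplitude * tpl
                peaks.append(s + peak_off)
                last_end = s
    return SpikySignal(samples, np.asarray(peaks, dtype=int), tpl, amplitude)


# ---------------------------------------------------------------------------
# outlier mixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MixtureSample:
    samples: np.ndarray
    labels: np.ndarray  # True where the sample came from the outlier component
    mixture: Mixture = field(repr=False)


def gen_outlier_mixture(
    n: int,
    primary: Normal = Normal(0.0, 1.0),
    outlier: Normal = Normal(0.0, 10.0),
    outlier_prob: float = 0.05,
    seed: int = 0,
) -> MixtureSample:
    """i.i.d. draws from a two-component Gaussian contamination mixture.

    Models a clean recording polluted by an occasional broad "noise"
    component; component labels are kept for diagnostics.
    """
    if not 0 <= outlier_prob < 0.5:
        raise ValueError("outlier_prob must be in [0, 0.5)")
    mixture = Mixture((primary, outlier), (1.0 - outlier_prob, outlier_prob))
    rng = np.random.default_rng(seed)
    samples, labels = mixture.sample_labelled(rng, n)
    return MixtureSample(samples, labels == 1, mixture)
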