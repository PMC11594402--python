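"""Noise-floor estimation and threshold-crossing spike detection.

Extracellular background noise is close to Gaussian (it is the summed
activity of many distant sources), so its standard deviation can be
recovered robustly from the median of the rectified signal: for
``x ~ N(0, sigma^2)`` the median of ``|x|`` equals
``sigma * sqrt(2) * erfinv(1/2) ≈ 0.675 sigma``.  Unlike a running RMS,
the median of ``|x|`` is barely perturbed by the spikes themselves, which
is exactly why median-based thresholds are the standard front end of spike
sorting pipelines.

The streaming threshold tracks ``K * sigma_noise`` online by feeding
``|x|`` through one of the two streaming median estimators in
:mod:`medstream.estimators`, and the detector reports threshold crossings
as discrete events with a refractory period.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import erfinv

from .estimators import make_estimator

__all__ = [
    "MEDIAN_TO_SIGMA",
    "sigma_from_median",
    "ThresholdConfig",
    "SpikeEvent",
    "streaming_threshold",
    "detect_crossings",
    "detect_spikes",
    "events_to_frame",
]

#: median{|x|} / sigma for zero-mean Gaussian x: sqrt(2) * erfinv(1/2) = Phi^-1(3/4)
MEDIAN_TO_SIGMA = float(np.sqrt(2.0) * erfinv(0.5))

_POLARITIES = ("negative", "positive", "absolute")


def sigma_from_median(med_abs: float) -> float:
    """Noise standard deviation from the median of the rectified signal."""
    med_abs = np.asarray(med_abs, dtype=float)
    if np.any(med_abs < 0):
        raise ValueError("the median of |x| cannot be negative")
    out = med_abs / MEDIAN_TO_SIGMA
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ThresholdConfig:
    """Configuration of the streaming detection threshold.

    ``k`` is the threshold height in units of the running noise sigma (the
    conventional choice is 4); ``polarity`` selects which excursions count
    as events; ``refractory`` is the minimum spacing between events in
    samples (30 samples ≈ 1 ms at 30 kHz).
    """

    k: float = 4.0
    length: int = 63
    polarity: str = "negative"
    refractory: int = 30
    backend: str = "nm"

    def __post_init__(self):
        if self.k <= 0:
            raise ValueError("k must be positive")
        if self.refractory < 0:
            raise ValueError("refractory must be non-negative")
        if self.polarity not in _POLARITIES:
            raise ValueError(f"polarity must be one of {_POLARITIES}")
        if self.backend not in ("nm", "cmm"):
            raise ValueError("backend must be 'nm' or 'cmm'")


@dataclass(frozen=True)
class SpikeEvent:
    """A detected threshold crossing.

    ``index`` is the 0-based position of the event's extremum, ``peak`` the
    raw (signed) signal value there, and ``threshold`` the running
    threshold magnitude in force when the excursion opened.
    """

    index: int
    peak: float
    threshold: float


def streaming_threshold(signal, cfg: ThresholdConfig = ThresholdConfig()) -> np.ndarray:
    """Per-sample detection threshold ``K * sigma_noise`` (signal units).

    The configured estimator consumes the rectified signal ``|x|``; element
    ``k`` of the result is derived from its median estimate after sample
    ``k`` (warm-up estimates come from the partial buffer).  The threshold
    is a magnitude: for ``polarity="negative"`` the detector applies it to
    ``-x``.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.shape[0] < cfg.length:
        raise ValueError("signal shorter than the estimator buffer")
    est = make_estimator(cfg.backend, cfg.length)
    med = est.stream(np.abs(signal))
    return cfg.k * med / MEDIAN_TO_SIGMA


def _transform(signal: np.ndarray, polarity: str) -> np.ndarray:
    if polarity == "negative":
        return -signal
    if polarity == "positive":
        return signal
    if polarity == "absolute":
        return np.abs(signal)
    raise ValueError(f"polarity must be one of {_POLARITIES}")


def detect_crossings(signal, thresholds, polarity: str = "negative",
                     refractory: int = 30) -> list[SpikeEvent]:
    """Turn threshold crossings into discrete spike events.

    An event opens when the polarity-transformed signal exceeds the running
    threshold; its index and peak are taken at the extremum reached before
    the signal falls back below threshold.  An excursion opening within
    ``refractory`` samples of the previous event's peak is suppressed, so
    accepted events are separated by at least ``refractory`` samples.
    """
    signal = np.asarray(signal, dtype=float)
    thresholds = np.asarray(thresholds, dtype=float)
    if signal.shape != thresholds.shape:
        raise ValueError("signal and thresholds must have the same length")
    if refractory < 0:
        raise ValueError("refractory must be non-negative")
    t = _transform(signal, polarity)
    above = t > thresholds
    if not above.any():
        return []
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.concatenate([[0], starts])
    if above[-1]:
        ends = np.concatenate([ends, [signal.shape[0]]])
    events: list[SpikeEvent] = []
    last_peak = -np.inf
    for s, e in zip(starts, ends):
        if s < last_peak + refractory:
            continue
        peak_idx = s + int(np.argmax(t[s:e]))
        events.append(SpikeEvent(int(peak_idx), float(signal[peak_idx]),
                                 float(thresholds[s])))
        last_peak = peak_idx
    return events


def detect_spikes(signal, cfg: ThresholdConfig = ThresholdConfig()
                  ) -> tuple[list[SpikeEvent], np.ndarray]:
    """Streaming threshold plus crossing detection in one call."""
    thresholds = streaming_threshold(signal, cfg)
    events = detect_crossings(signal, thresholds, cfg.polarity, cfg.refractory)
    return events, thresholds


def events_to_frame(events) -> pd.DataFrame:
    """Tabulate events with the CSV column layout ``index,peak,threshold``."""
    return pd.DataFrame(
        [(e.index, e.peak, e.threshold) for e in events],
        columns=["index", "peak", "threshold"],
    )
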