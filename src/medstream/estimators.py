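"""Streaming median estimators.

Two estimators share the same interface:

``NMEstimator``
    A memory-less streaming median.  It keeps a fixed-length, always-sorted
    buffer of odd length ``L = 2m + 1`` whose central element is the
    estimate.  Every new sample is inserted at its sorted position; the
    buffer then sheds the extreme on the *opposite* side of the center (the
    maximum when the sample falls below the current estimate, the minimum
    when it falls above).  No arrival times are stored, which is what makes
    the estimator memory-less: eviction depends only on where a value sits
    in the order, not on when it arrived.  Over time the buffer contracts
    around the running median, which sharply reduces estimator variance at a
    given buffer length at the cost of a slower response to distribution
    changes.

``MovingMedian``
    The classical moving median: the exact median of the last ``L``
    samples, with eviction by arrival age.  It is the baseline every
    comparison in :mod:`medstream.experiments` is made against.

When a new sample exactly equals the central value, the sample takes the
center and either the first or the last element is dropped.  The side is
chosen by a single alternating bit by default (sufficient to keep the
estimator unbiased); a seeded random bit is available via
``tie_break="random"``.

A truth-table-level model of the sorting cell array used by hardware
realisations of the estimator (`MedianCellArray`) and a cascade of three
estimators producing running quartiles (`QuantileCascade`) complete the
module.
"""

from __future__ import annotations

import math
from bisect import bisect_right, insort_right

import numpy as np

from ._kernels import cmm_stream, nm_stream

__all__ = [
    "NMEstimator",
    "MovingMedian",
    "MedianCellArray",
    "QuantileCascade",
    "sliding_median_oracle",
    "make_estimator",
]

_EMPTY_BITS = np.empty(0, dtype=np.uint8)


def _check_length(length) -> int:
    if not isinstance(length, (int, np.integer)):
        raise ValueError(f"buffer length must be an integer, got {length!r}")
    length = int(length)
    if length < 3 or length % 2 == 0:
        raise ValueError(f"buffer length must be an odd integer >= 3, got {length}")
    return length


def _check_finite(x) -> float:
    x = float(x)
    if not math.isfinite(x):
        raise ValueError(f"samples must be finite, got {x}")
    return x


class _StreamingMedianBase:
    """Shared warm-up and streaming plumbing for both estimators."""

    def __init__(self, length: int):
        self.length = _check_length(length)
        self._m = self.length // 2
        self.n_seen = 0

    @property
    def is_full(self) -> bool:
        return self.n_seen >= self.length

    @classmethod
    def from_samples(cls, samples, **kwargs):
        """Build an estimator of ``len(samples)`` already filled with them."""
        samples = np.asarray(samples, dtype=float)
        est = cls(len(samples), **kwargs)
        est.stream(samples)
        return est

    def push(self, x: float) -> float:
        x = _check_finite(x)
        if not self.is_full:
            return self._push_warmup(x)
        return self._push_full(x)

    def stream(self, xs) -> np.ndarray:
        """Consume ``xs`` and return the estimate after every sample.

        During warm-up (fewer than ``length`` samples seen) the estimate is
        the lower middle of the sorted partial buffer; afterwards the
        compiled kernel takes over.
        """
        xs = np.ascontiguousarray(xs, dtype=np.float64)
        if xs.ndim != 1:
            raise ValueError("signal must be one-dimensional")
        if not np.all(np.isfinite(xs)):
            raise ValueError("samples must be finite (no NaN/Inf)")
        out = np.empty(xs.shape[0])
        k = 0
        while not self.is_full and k < xs.shape[0]:
            out[k] = self._push_warmup(xs[k])
            k += 1
        if k < xs.shape[0]:
            self._stream_full(xs[k:], out[k:])
        return out


class NMEstimator(_StreamingMedianBase):
    """Memory-less streaming median over a sorted buffer of odd length.

    Parameters
    ----------
    length : int
        Odd buffer length ``L >= 3``.
    tie_break : {"alternate", "random"}
        How to pick the dropped extreme when a sample equals the central
        value.  ``"alternate"`` flips a single bit per tie; ``"random"``
        draws a seeded bit per sample (consumed only at ties).
    seed : int, optional
        Seed for ``tie_break="random"``.
    """

    def __init__(self, length: int, *, tie_break: str = "alternate", seed=None):
        super().__init__(length)
        if tie_break not in ("alternate", "random"):
            raise ValueError(f"tie_break must be 'alternate' or 'random', got {tie_break!r}")
        self.tie_break = tie_break
        self.tie_toggle = 0
        self._rng = np.random.default_rng(seed) if tie_break == "random" else None
        self._values: list[float] = []
        self.last_drop: str | None = None  # "min", "max" or None; side shed by the last update

    @property
    def buffer(self) -> np.ndarray:
        """Copy of the sorted buffer contents."""
        return np.array(self._values)

    @property
    def estimate(self) -> float:
        if self.n_seen == 0:
            raise ValueError("no samples consumed yet")
        return self._values[(len(self._values) - 1) // 2]

    def _push_warmup(self, x: float) -> float:
        insort_right(self._values, x)
        self.n_seen += 1
        return self._values[(len(self._values) - 1) // 2]

    def _tie_drop_first(self, bit=None) -> bool:
        if self._rng is not None:
            return bool(bit if bit is not None else self._rng.integers(0, 2))
        drop_first = bool(self.tie_toggle)
        self.tie_toggle ^= 1
        return drop_first

    def _push_full(self, x: float) -> float:
        # one bit per sample (used only at ties) keeps the push and stream
        # paths consuming the generator identically in random mode
        tie_bit = int(self._rng.integers(0, 2)) if self._rng is not None else None
        values = self._values
        m = self._m
        center = values[m]
        if x < center:
            values.pop()
            insort_right(values, x)
            self.last_drop = "max"
        elif x > center:
            values.pop(0)
            insort_right(values, x)
            self.last_drop = "min"
        else:
            if self._tie_drop_first(tie_bit):
                values.pop(0)
                self.last_drop = "min"
            else:
                values.pop()
                self.last_drop = "max"
            values.insert(m, x)
        self.n_seen += 1
        return values[m]

    def _stream_full(self, xs: np.ndarray, out: np.ndarray) -> None:
        buf = np.array(self._values)
        if self._rng is not None:
            bits = self._rng.integers(0, 2, xs.shape[0]).astype(np.uint8)
        else:
            bits = _EMPTY_BITS
        self.tie_toggle = int(nm_stream(buf, self.tie_toggle, xs, out, bits))
        self._values = buf.tolist()
        self.n_seen += xs.shape[0]


class MovingMedian(_StreamingMedianBase):
    """Exact median of the last ``length`` samples (classical moving median).

    Keeps the window both in arrival order (for age-based eviction) and
    sorted (for O(log L) median queries).  Eviction of duplicated values is
    by arrival index; insertion is stable, which leaves the window multiset
    — and therefore the median — exact.
    """

    def __init__(self, length: int):
        super().__init__(length)
        self._window: list[float] = []   # arrival order, oldest first
        self._values: list[float] = []   # sorted

    @property
    def buffer(self) -> np.ndarray:
        """Copy of the sorted window contents."""
        return np.array(self._values)

    @property
    def window(self) -> np.ndarray:
        """Copy of the window in arrival order (oldest first)."""
        return np.array(self._window)

    @property
    def estimate(self) -> float:
        if self.n_seen == 0:
            raise ValueError("no samples consumed yet")
        return self._values[(len(self._values) - 1) // 2]

    def _push_warmup(self, x: float) -> float:
        self._window.append(x)
        insort_right(self._values, x)
        self.n_seen += 1
        return self._values[(len(self._values) - 1) // 2]

    def _push_full(self, x: float) -> float:
        old = self._window.pop(0)
        self._window.append(x)
        values = self._values
        del values[bisect_right(values, old) - 1]
        insort_right(values, x)
        self.n_seen += 1
        return values[self._m]

    def _stream_full(self, xs: np.ndarray, out: np.ndarray) -> None:
        window = np.array(self._window)
        sbuf = np.array(self._values)
        head = int(cmm_stream(sbuf, window, 0, xs, out))
        self._window = np.roll(window, -head).tolist()
        self._values = sbuf.tolist()
        self.n_seen += xs.shape[0]


def make_estimator(backend: str, length: int, **kwargs):
    """Instantiate an estimator from its short name (``"nm"`` or ``"cmm"``)."""
    backend = backend.lower()
    if backend == "nm":
        return NMEstimator(length, **kwargs)
    if backend == "cmm":
        if kwargs:
            raise TypeError("MovingMedian accepts no extra options")
        return MovingMedian(length)
    raise ValueError(f"unknown backend {backend!r}; expected 'nm' or 'cmm'")


def sliding_median_oracle(signal, length: int) -> np.ndarray:
    """Exact sliding-window medians by re-sorting every window.

    Element ``k`` of the result is the median of ``signal[k : k + length]``,
    i.e. the window median aligned with input sample ``k + length - 1``.
    Deliberately brute force: this is the reference the fast
    ``MovingMedian`` implementation is validated against.
    """
    length = _check_length(length)
    signal = np.asarray(signal, dtype=float)
    if signal.shape[0] < length:
        raise ValueError("signal shorter than the window")
    windows = np.lib.stride_tricks.sliding_window_view(signal, length)
    return np.median(windows, axis=1)


class MedianCellArray:
    """Truth-table model of the sorting cell array behind ``NMEstimator``.

    Each of the ``L`` cells holds a register ``R_i`` and a comparator
    ``C_i = 1`` iff ``R_i > X`` for the incoming sample ``X``.  The central
    cell has a full comparator producing the mutually exclusive signals
    ``X < M``, ``X = M``, ``X > M``.  On every clock, a per-cell multiplexer
    selects one of {keep ``R_i``, take ``X``, take ``R_{i-1}``, take
    ``R_{i+1}``} according to the section's truth table (left side, center,
    right side).  The first cell sees a hard-wired neighbour comparator of
    0 and the last cell one of 1.

    The model steps one sample per call and must match ``NMEstimator``
    register-for-register when both consume the same stream and the same
    tie decisions — that equivalence is asserted in the test suite.  Values
    are kept as floats here; a hardware register would quantise them, which
    changes nothing about the control logic.
    """

    def __init__(self, registers):
        registers = np.asarray(registers, dtype=float)
        _check_length(registers.shape[0])
        if np.any(np.diff(registers) < 0):
            raise ValueError("registers must be sorted (non-decreasing)")
        self.registers = registers.copy()

    @property
    def estimate(self) -> float:
        return float(self.registers[self.registers.shape[0] // 2])

    def comparators(self, x: float) -> np.ndarray:
        """Per-cell comparator outputs ``C_i`` (1 iff ``R_i > X``)."""
        return (self.registers > x).astype(np.uint8)

    def central_signals(self, x: float) -> tuple[bool, bool, bool]:
        """The full comparator of the central cell: (X < M, X = M, X > M)."""
        center = self.registers[self.registers.shape[0] // 2]
        return (x < center, x == center, x > center)

    def step(self, x: float, s: int = 0) -> float:
        """Clock one sample through the array; return the new estimate.

        ``s`` is the tie-branch select used only when ``X = M``:
        0 drops the last register (the right half shifts right),
        1 drops the first (the left half shifts left).
        """
        x = _check_finite(x)
        R = self.registers
        L = R.shape[0]
        m = L // 2
        C = R > x
        lt, eq, gt = self.central_signals(x)
        new = R.copy()
        for i in range(m):  # left section, neighbour comparator C_{i-1}
            cn = C[i - 1] if i > 0 else False
            if lt:
                if not C[i]:
                    new[i] = R[i]
                elif cn:
                    new[i] = R[i - 1]
                else:
                    new[i] = x
            elif gt:
                new[i] = R[i + 1]
            else:
                new[i] = R[i + 1] if s else R[i]
        for i in range(m + 1, L):  # right section, neighbour comparator C_{i+1}
            cn = C[i + 1] if i < L - 1 else True
            if gt:
                if C[i]:
                    new[i] = R[i]
                elif cn:
                    new[i] = x
                else:
                    new[i] = R[i + 1]
            elif lt:
                new[i] = R[i - 1]
            else:
                new[i] = R[i] if s else R[i - 1]
        if lt:
            new[m] = R[m - 1] if C[m - 1] else x
        elif gt:
            new[m] = x if C[m + 1] else R[m + 1]
        else:
            new[m] = x
        self.registers = new
        return float(new[m])


class QuantileCascade:
    """Running quartiles from a cascade of three median estimators.

    The primary estimator tracks the median of the full stream.  Each
    sample is additionally routed to exactly one sub-estimator: the lower
    one when the sample falls below the primary's current estimate, the
    upper one when it falls above.  The sub-estimators therefore track the
    medians of the lower and upper halves of the distribution — the first
    and third quartiles.  A sample exactly equal to the primary estimate
    follows the primary's tie branch: it goes to the lower cascade when the
    primary dropped its maximum, to the upper one otherwise.  Recursing the
    construction segments the distribution at any power-of-two level.
    """

    def __init__(self, length: int, *, tie_break: str = "alternate", seed=None):
        seeds = np.random.SeedSequence(seed).spawn(3) if tie_break == "random" else (None,) * 3
        self.primary = NMEstimator(length, tie_break=tie_break, seed=seeds[0])
        self.lower = NMEstimator(length, tie_break=tie_break, seed=seeds[1])
        self.upper = NMEstimator(length, tie_break=tie_break, seed=seeds[2])

    def push(self, x: float) -> tuple[float, float, float]:
        """Consume one sample; return the (q25, q50, q75) estimates."""
        x = _check_finite(x)
        reference = self.primary.estimate if self.primary.n_seen else x
        q50 = self.primary.push(x)
        if x < reference:
            self.lower.push(x)
        elif x > reference:
            self.upper.push(x)
        elif self.primary.last_drop == "max" or not self.primary.is_full:
            self.lower.push(x)
        else:
            self.upper.push(x)
        q25 = self.lower.estimate if self.lower.n_seen else q50
        q75 = self.upper.estimate if self.upper.n_seen else q50
        return q25, q50, q75

    @property
    def quartiles(self) -> tuple[float, float, float]:
        return (self.lower.estimate, self.primary.estimate, self.upper.estimate)
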