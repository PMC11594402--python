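"""Compiled streaming loops for the two median estimators.

These kernels mutate their buffer arguments in place and fill a preallocated
output trace, so a long recording can be consumed in segments without losing
estimator state.  They are an exact, fast mirror of the pure-Python update
methods in :mod:`medstream.estimators`; the test suite locks the two paths
together sample by sample.
"""

import numpy as np
from numba import njit

__all__ = ["nm_stream", "cmm_stream"]


@njit(cache=True)
def nm_stream(buf, toggle, xs, out, tie_bits):  # pragma: no cover - compiled
    """Run the drop-from-the-extreme median update over ``xs``.

    Parameters
    ----------
    buf : float64[L]
        Sorted buffer, modified in place. ``L`` must be odd.
    toggle : int
        Current tie-breaking bit (0 -> drop the maximum, 1 -> drop the
        minimum when the new sample equals the central value).
    xs : float64[n]
        Samples to consume.
    out : float64[n]
        Receives the estimate (central buffer element) after each sample.
    tie_bits : uint8[n] or empty
        When non-empty, ``tie_bits[t]`` decides the tie branch for sample
        ``t`` instead of the alternating bit.

    Returns
    -------
    int
        The tie toggle after the last sample.
    """
    L = buf.shape[0]
    m = L // 2
    use_bits = tie_bits.shape[0] > 0
    for t in range(xs.shape[0]):
        x = xs[t]
        center = buf[m]
        if x < center:
            # insert on the low side (after any equal values), drop the max
            pos = np.searchsorted(buf, x, side="right")
            for j in range(L - 1, pos, -1):
                buf[j] = buf[j - 1]
            buf[pos] = x
        elif x > center:
            # insert on the high side, drop the min
            pos = np.searchsorted(buf, x, side="right")
            for j in range(0, pos - 1):
                buf[j] = buf[j + 1]
            buf[pos - 1] = x
        else:
            if use_bits:
                drop_first = tie_bits[t]
            else:
                drop_first = toggle
                toggle = 1 - toggle
            if drop_first:
                for j in range(0, m):
                    buf[j] = buf[j + 1]
            else:
                for j in range(L - 1, m, -1):
                    buf[j] = buf[j - 1]
            buf[m] = x
        out[t] = buf[m]
    return toggle


@njit(cache=True)
def cmm_stream(sbuf, window, head, xs, out):  # pragma: no cover - compiled
    """Run the exact sliding-window median over ``xs``.

    ``sbuf`` holds the window contents sorted; ``window`` holds them in
    arrival order as a circular array with ``head`` pointing at the oldest
    sample.  Both arrays are modified in place.

    Returns
    -------
    int
        The circular-buffer head after the last sample.
    """
    L = sbuf.shape[0]
    m = L // 2
    for t in range(xs.shape[0]):
        x = xs[t]
        old = window[head]
        window[head] = x
        head += 1
        if head == L:
            head = 0
        p = np.searchsorted(sbuf, old, side="left")   # evict oldest
        q = np.searchsorted(sbuf, x, side="right")    # stable insert
        if q <= p:
            for j in range(p, q, -1):
                sbuf[j] = sbuf[j - 1]
            sbuf[q] = x
        else:
            for j in range(p, q - 1):
                sbuf[j] = sbuf[j + 1]
            sbuf[q - 1] = x
        out[t] = sbuf[m]
    return head
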