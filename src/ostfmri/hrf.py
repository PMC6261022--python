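"""Canonical hemodynamic response function and drift basis.

The double-gamma HRF (response gamma with shape 6, undershoot gamma with
shape 16, undershoot ratio 1/6, unit rate) is evaluated in continuous time
so that event regressors can be sampled exactly at volume acquisition
times; the peak is normalized to 1.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["hrf", "hrf_kernel", "event_regressor", "cosine_drift_basis"]

_PEAK_SHAPE = 6.0
_UNDERSHOOT_SHAPE = 16.0
_UNDERSHOOT_RATIO = 1.0 / 6.0

# peak value of the unnormalized double-gamma, computed once on a dense grid
_grid = np.linspace(0.0, 30.0, 30001)
_raw = (
    stats.gamma.pdf(_grid, _PEAK_SHAPE)
    - _UNDERSHOOT_RATIO * stats.gamma.pdf(_grid, _UNDERSHOOT_SHAPE)
)
_PEAK_VALUE = float(_raw.max())
del _grid, _raw


def hrf(t: np.ndarray | float) -> np.ndarray:
    """Double-gamma HRF evaluated at time ``t`` (seconds), peak-normalized.

    Causal: exactly zero for t <= 0.
    """
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    out[pos] = (
        stats.gamma.pdf(tp, _PEAK_SHAPE)
        - _UNDERSHOOT_RATIO * stats.gamma.pdf(tp, _UNDERSHOOT_SHAPE)
    ) / _PEAK_VALUE
    return out


def hrf_kernel(tr: float, duration: float = 32.0) -> np.ndarray:
    """HRF sampled at multiples of ``tr`` over ``[0, duration]``."""
    if tr <= 0:
        raise ValueError(f"tr must be positive, got {tr}")
    times = np.arange(0.0, duration + 1e-9, tr)
    return hrf(times)


def event_regressor(
    onsets: np.ndarray,
    n_volumes: int,
    tr: float,
    amplitudes: np.ndarray | None = None,
) -> np.ndarray:
    """HRF response to unit impulses at ``onsets`` sampled at volume times.

    Volume t (1-based) is sampled at its acquisition start (t-1)*tr, so the
    regressor is exactly the impulse train convolved with the continuous
    HRF and read out on the volume grid.
    """
    onsets = np.asarray(onsets, dtype=float)
    if amplitudes is None:
        amplitudes = np.ones_like(onsets)
    vol_times = np.arange(n_volumes) * tr
    # [n_volumes, n_events] lags
    lags = vol_times[:, None] - onsets[None, :]
    return hrf(lags) @ np.asarray(amplitudes, dtype=float)


def cosine_drift_basis(n_volumes: int, tr: float, cutoff_hz: float = 1.0 / 128.0) -> np.ndarray:
    """DCT-II low-frequency drift basis up to ``cutoff_hz`` (intercept excluded).

    Column k has period 2*N*tr/k; columns are included while their
    frequency k/(2*N*tr) stays below the cutoff.
    """
    total = n_volumes * tr
    k_max = int(np.floor(2.0 * total * cutoff_hz))
    v = np.arange(n_volumes)
    cols = [
        np.sqrt(2.0 / n_volumes) * np.cos(np.pi * (2 * v + 1) * k / (2.0 * n_volumes))
        for k in range(1, k_max + 1)
    ]
    if not cols:
        return np.empty((n_volumes, 0))
    return np.column_stack(cols)
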