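"""Separation of each trial/channel signal into trend and oscillation.

The slow, non-oscillatory component is estimated by local linear regression
(first-degree weighted least squares with tricube weights — classic lowess,
no robustness iterations; default window 100 points of a 1-s trial at
250 Hz, i.e. 40% of the trial). The trend is then
regressed onto the signal (single-predictor least squares, no intercept,
after per-trial standardization upstream when desired) and the residual is
the detrended oscillatory component. The two components are exactly
uncorrelated within each trial/channel by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .synthgen import EpochSet

__all__ = [
    "SignalComponents",
    "lowpass_filter",
    "decimate",
    "loess_trend",
    "split_components",
    "component_spectra",
    "count_peaks",
]


@dataclass
class SignalComponents:
    """Trend / oscillatory split of an EpochSet, plus the regression scales."""

    trend: np.ndarray  # (N, C, T) scaled trend (the non-oscillatory component)
    oscillatory: np.ndarray  # (N, C, T) residual
    scale: np.ndarray  # (N, C) least-squares coefficient of raw trend on signal
    fs: float
    labels: np.ndarray | None = None
    attributes: dict | None = None

    @property
    def n_time(self) -> int:
        return self.trend.shape[2]


def lowpass_filter(epochs: EpochSet, cutoff: float = 10.0, order: int = 5) -> EpochSet:
    """Zero-phase Butterworth low-pass along time.

    Forward-backward filtering (``sosfiltfilt``) keeps the phase of the
    passband untouched, which the downstream phase analyses rely on.
    """
    nyq = epochs.fs / 2.0
    if cutoff >= nyq:
        raise ValueError(f"cutoff {cutoff} Hz must be below Nyquist {nyq} Hz")
    sos = sps.butter(order, cutoff, btype="low", fs=epochs.fs, output="sos")
    out = sps.sosfiltfilt(sos, epochs.data, axis=-1)
    return epochs.copy_with(out)


def decimate(epochs: EpochSet, factor: int) -> EpochSet:
    """Anti-aliased integer decimation (for imported data at higher rates)."""
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be a positive integer")
    if factor == 1:
        return epochs.copy_with(epochs.data.copy())
    out = sps.decimate(epochs.data, int(factor), axis=-1, zero_phase=True)
    dec = epochs.copy_with(out)
    dec.fs = epochs.fs / factor
    return dec


def loess_trend(x: np.ndarray, span_frac: float = 0.4) -> np.ndarray:
    """Local linear (first-degree) tricube-weighted trend of a 1-D signal.

    ``span_frac`` is the fraction of the trial used in each local fit; the
    default 0.4 corresponds to a 100-point window on a 1-s trial at 250 Hz,
    wide enough (~2.8 theta cycles) that the local linear fit cannot track
    the carrier. No robustness iterations are applied.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("loess_trend expects a 1-D signal")
    t = x.size
    if not 0 < span_frac <= 1:
        raise ValueError("span_frac must be in (0, 1]")
    if np.any(~np.isfinite(x)):
        raise ValueError("NaN/Inf in input")
    window = max(int(np.ceil(span_frac * t)), 2)
    if t < window:
        raise ValueError(f"signal length {t} shorter than window {window}")
    grid = np.arange(t, dtype=float)
    return _sm_lowess(
        x, grid, frac=window / t, it=0, delta=0.0, return_sorted=False
    )


def split_components(
    epochs: EpochSet, span_frac: float = 0.4, standardize: bool = False
) -> SignalComponents:
    """Per trial/channel: lowess trend, regress it out, keep the residual.

    The regression scale is the no-intercept least-squares coefficient of the
    trend on the signal; the stored trend is already scaled, so
    ``trend + oscillatory == input`` to numerical precision and the two parts
    have exactly zero sample correlation.
    """
    data = epochs.data
    if standardize:
        mu = data.mean(axis=-1, keepdims=True)
        sd = data.std(axis=-1, keepdims=True)
        data = np.where(sd > 0, (data - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    n, c, t = data.shape
    trend = np.empty_like(data)
    flat = data.reshape(n * c, t)
    tr = trend.reshape(n * c, t)
    for i in range(n * c):
        tr[i] = loess_trend(flat[i], span_frac)
    # regress the (centered) trend out of the signal without intercept:
    # remove the projection on [1, trend'] so the residual is orthogonal to
    # both the mean and the trend fluctuation
    tc = tr - tr.mean(axis=1, keepdims=True)
    denom = np.einsum("it,it->i", tc, tc)
    num = np.einsum("it,it->i", tc, flat)
    scale = np.where(denom > 1e-12 * t, num / np.where(denom > 0, denom, 1.0), 0.0)
    fitted = flat.mean(axis=1, keepdims=True) + scale[:, None] * tc
    resid = flat - fitted
    return SignalComponents(
        trend=fitted.reshape(n, c, t),
        oscillatory=resid.reshape(n, c, t),
        scale=scale.reshape(n, c),
        fs=epochs.fs,
        labels=epochs.labels.copy(),
        attributes={k: v.copy() for k, v in epochs.attributes.items()},
    )


def component_spectra(
    components: SignalComponents, nperseg: int | None = None
) -> dict[str, np.ndarray]:
    """Welch spectra of both components, averaged over trials and channels.

    Returns ``{"freqs", "trend", "oscillatory"}`` with per-channel power
    averaged across trials (shape channels x freqs).
    """
    t = components.n_time
    if nperseg is None:
        nperseg = t
    if t < nperseg:
        raise ValueError(f"trial length {t} shorter than one window ({nperseg})")
    out = {}
    for name in ("trend", "oscillatory"):
        arr = getattr(components, name)
        freqs, pxx = sps.welch(arr, fs=components.fs, nperseg=nperseg, axis=-1)
        out[name] = pxx.mean(axis=0)  # (C, F)
    out["freqs"] = freqs
    return out


def count_peaks(x: np.ndarray) -> int:
    """Number of strict interior local maxima of a 1-D signal.

    Plateaus count once (at their left edge); endpoints are excluded.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("need a 1-D signal of length >= 3")
    # collapse exact plateaus so a flat top counts once
    keep = np.concatenate([[True], np.diff(x) != 0])
    xc = x[keep]
    if xc.size < 3:
        return 0
    interior = (xc[1:-1] > xc[:-2]) & (xc[1:-1] > xc[2:])
    return int(interior.sum())
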