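"""Instantaneous phase/amplitude and the phase-locking factor (PLF).

The oscillatory component is band-limited (< 10 Hz) by construction, so its
instantaneous phase and amplitude come straight from the analytic signal,
with no further narrowband filtering. PLF_tj = |mean_n exp(i * phi_tnj)|
measures how concentrated the across-trial phase distribution is at time t
and channel j: 1 for perfect locking, ~1/sqrt(N) for uniform phase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

__all__ = ["PhaseTensor", "analytic_phase", "plf", "decoder_aligned_phases"]


@dataclass
class PhaseTensor:
    """Instantaneous phase (rad, wrapped to (-pi, pi]) and amplitude envelope.

    ``edge_frac`` of the trial at each end is flagged unreliable (analytic
    signal edge effects) and excluded from PLF summaries by default.
    """

    phase: np.ndarray  # (N, C, T)
    envelope: np.ndarray  # (N, C, T)
    fs: float
    edge_frac: float = 0.05

    @property
    def interior(self) -> slice:
        t = self.phase.shape[-1]
        k = int(np.floor(self.edge_frac * t))
        return slice(k, t - k if k else t)

    @property
    def reliable_mask(self) -> np.ndarray:
        t = self.phase.shape[-1]
        m = np.zeros(t, dtype=bool)
        m[self.interior] = True
        return m


def analytic_phase(oscillatory: np.ndarray, fs: float, edge_frac: float = 0.05) -> PhaseTensor:
    """Phase and envelope of the analytic signal, per trial and channel."""
    arr = np.asarray(oscillatory, dtype=float)
    if np.allclose(arr, 0):
        raise ValueError("all-zero signal: phase undefined")
    z = hilbert(arr, axis=-1)
    return PhaseTensor(phase=np.angle(z), envelope=np.abs(z), fs=fs, edge_frac=edge_frac)


def plf(phases: np.ndarray, axis: int = 0) -> np.ndarray:
    """Modulus of the mean unit phasor across trials.

    ``phases`` in radians; the trial axis defaults to the first. Returns a
    value in [0, 1] per remaining index, e.g. a (C, T) matrix from an
    (N, C, T) tensor.
    """
    return np.abs(np.exp(1j * np.asarray(phases)).mean(axis=axis))


def decoder_aligned_phases(
    phases: np.ndarray,
    gamma: np.ndarray,
    state: int,
    resample_len: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Extract each trial's state-k window of phases, resampled to a common
    length by nearest-index picking.

    ``phases``: (N, C, T); ``gamma``: (T, N, K) state responsibilities. The
    window of trial n is the set of time points where argmax_k gamma = state.
    Nearest-index resampling (rather than interpolation) avoids averaging
    wrapped angles across the +/-pi branch cut. Trials where the state never
    activates are excluded.

    Returns ``(aligned, included)``: aligned is (N_inc, C, resample_len),
    included the boolean inclusion mask over trials.
    """
    if resample_len < 1:
        raise ValueError("resample_len must be >= 1")
    n, c, t = phases.shape
    hard = np.argmax(gamma, axis=2)  # (T, N), ties -> lowest k
    out = []
    included = np.zeros(n, dtype=bool)
    for i in range(n):
        idx = np.flatnonzero(hard[:, i] == state)
        if idx.size == 0:
            continue
        included[i] = True
        pick = idx[np.round(np.linspace(0, idx.size - 1, resample_len)).astype(int)]
        out.append(phases[i, :, pick].T)  # (C, L)
    aligned = np.stack(out) if out else np.empty((0, c, resample_len))
    return aligned, included
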