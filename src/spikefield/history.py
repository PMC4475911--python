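"""Raised-cosine spike-history basis in logarithmically scaled lag time.

A neuron's own recent spiking (refractoriness, recovery, bursting,
rhythmicity) is summarized by convolving the spike train with ten smooth
raised-cosine bumps whose peaks are evenly spaced in log(lag + offset) over
the past 100 ms: early bumps are narrow (fine resolution where refractory
effects live), late bumps broad.  The resulting columns at time t depend on
spikes strictly *before* t, so the model never predicts a spike from itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core import BinnedSpikeTrain, FeatureBlock

HISTORY_WINDOW_MS = 100
N_BASIS = 10


@dataclass
class HistoryBasis:
    """Basis matrix over lags 1..window_ms (1 ms resolution), peak-normalized."""

    matrix: np.ndarray  # (n_basis, window_ms); column j-1 is lag j ms
    centers_ms: np.ndarray  # peak lags, ms

    @property
    def n_basis(self) -> int:
        return self.matrix.shape[0]

    @property
    def window_ms(self) -> int:
        return self.matrix.shape[1]


def raised_cosine_basis(
    n_basis: int = N_BASIS,
    window_ms: int = HISTORY_WINDOW_MS,
    *,
    first_peak_ms: float = 2.0,
    last_peak_ms: float = 80.0,
    log_offset_ms: float = 1.0,
) -> HistoryBasis:
    """Log-spaced raised-cosine bumps covering lags 1..``window_ms`` ms.

    Bump j is 0.5*(1 + cos(u)) for |u| <= pi with
    u = (phi(t) - c_j) * pi / (2 d), phi(t) = log(t + ``log_offset_ms``), the
    centers c_j evenly spaced between phi(first peak) and phi(last peak) with
    spacing d.  Peaks are normalized to 1 on the 1 ms grid.
    """
    if n_basis < 1:
        raise ValueError("n_basis must be >= 1")
    if window_ms < n_basis:
        raise ValueError("window_ms must be >= n_basis")
    if not (0 < first_peak_ms < last_peak_ms <= window_ms):
        raise ValueError("peak lags must satisfy 0 < first < last <= window")

    lags = np.arange(1, window_ms + 1, dtype=float)
    phi = np.log(lags + log_offset_ms)
    c = np.linspace(
        np.log(first_peak_ms + log_offset_ms),
        np.log(last_peak_ms + log_offset_ms),
        n_basis,
    )
    d = c[1] - c[0] if n_basis > 1 else (phi[-1] - phi[0]) / 2
    u = (phi[None, :] - c[:, None]) * np.pi / (2 * d)
    mat = 0.5 * (1 + np.cos(np.clip(u, -np.pi, np.pi)))
    mat[np.abs(u) >= np.pi] = 0.0
    peaks = mat.max(axis=1)
    mat /= peaks[:, None]
    centers = lags[np.argmax(mat, axis=1)]
    return HistoryBasis(matrix=mat, centers_ms=centers)


def history_columns(spikes: BinnedSpikeTrain, basis: HistoryBasis) -> FeatureBlock:
    """Causal convolution of the spike train with each basis function.

    Column j at time t is sum_{tau=1..W} phi_j(tau) * Y_{t-tau}; the current
    bin Y_t is strictly excluded.
    """
    y = spikes.values.astype(float)
    T = y.size
    cols = np.empty((T, basis.n_basis))
    for j in range(basis.n_basis):
        kernel = np.concatenate([[0.0], basis.matrix[j]])  # lag-0 weight is zero
        full = sps.fftconvolve(y, kernel)
        cols[:, j] = full[:T]
    # fftconvolve round-off can produce tiny negatives; features are >= 0
    np.clip(cols, 0.0, None, out=cols)
    labels = [f"hist_b{j}" for j in range(basis.n_basis)]
    return FeatureBlock(cols, labels, group="hist")
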