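"""Savitzky-Golay kinematic smoothing and trajectory ("pathlet") features.

Motion-capture channels (wrist x/y/z and grasp aperture, 240 frames/s) are
smoothed and differentiated with a 5th-order Savitzky-Golay kernel extending
25 samples to either side, which attenuates content above ~20 Hz and makes
the velocities smooth enough to resample at 40 samples/s.

A pathlet summarizes movement around a model time point ``t``: the smoothed
velocities sampled every 25 ms from 100 ms before to 300 ms after ``t``
(17 lags x 4 channels), L2-normalized separately for the wrist-3D and
aperture groups, plus the mean speed over the window and the zero-lag
positions.  Note that pathlets deliberately include *future* kinematics —
lag sign is encoded in the column labels so the model assembly can never
confuse them with the strictly causal spike-history features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core import FeatureBlock, KinematicRecord

KIN_FS_HZ = 240.0
FEATURE_FS_HZ = 40.0
#: pathlet lag grid in ms: 100 ms back to 300 ms ahead, every 25 ms
PATHLET_LAGS_MS = tuple(range(-100, 301, 25))
_LAG_STEP_MS = 25

_CHANNELS = ("x", "y", "z", "ap")


@dataclass(frozen=True)
class SavGolKernels:
    """Symmetric FIR smoothing and differentiation kernels.

    ``deriv`` has units 1/sample; apply by correlation with a window of
    2*halfwidth+1 samples centred on the output sample.
    """

    smooth: np.ndarray
    deriv: np.ndarray
    poly_order: int
    halfwidth: int


def savgol_derivative_filter(
    poly_order: int = 5, halfwidth_samples: int = 25
) -> SavGolKernels:
    """Least-squares polynomial smoothing/differentiation kernels."""
    if poly_order < 1:
        raise ValueError("poly_order must be >= 1")
    window = 2 * halfwidth_samples + 1
    if window <= poly_order:
        raise ValueError("window too short for polynomial order")
    smooth = sps.savgol_coeffs(window, poly_order, deriv=0, use="dot")
    deriv = sps.savgol_coeffs(window, poly_order, deriv=1, use="dot")
    return SavGolKernels(smooth, deriv, poly_order, halfwidth_samples)


@dataclass
class SmoothedKinematics:
    """Smoothed positions (mm) and velocities (mm/s) at 40 samples/s."""

    pos: np.ndarray  # (n, 4): x, y, z, aperture
    vel: np.ndarray  # (n, 4)
    fs_hz: float
    t0_ms: float


def smooth_velocity(
    record: KinematicRecord,
    *,
    poly_order: int = 5,
    halfwidth_samples: int = 25,
) -> SmoothedKinematics:
    """Savitzky-Golay smooth + differentiate, then subsample to 40 S/s."""
    fs = record.fs_hz
    step = fs / FEATURE_FS_HZ
    if abs(step - round(step)) > 1e-9:
        raise ValueError("kinematic rate must be an integer multiple of 40 S/s")
    step = int(round(step))
    X = record.as_array()
    if not np.all(np.isfinite(X)):
        raise ValueError("kinematic record contains missing samples")
    window = 2 * halfwidth_samples + 1
    if X.shape[0] < window:
        raise ValueError("record shorter than the smoothing window")
    pos = sps.savgol_filter(X, window, poly_order, deriv=0, axis=0, mode="interp")
    vel = sps.savgol_filter(
        X, window, poly_order, deriv=1, delta=1.0 / fs, axis=0, mode="interp"
    )
    return SmoothedKinematics(
        pos=pos[::step], vel=vel[::step], fs_hz=FEATURE_FS_HZ,
        t0_ms=record.wrist_xyz[0].t0_ms,
    )


def _lag_columns(labels_prefix: str) -> list[str]:
    return [
        f"{labels_prefix}{ch}_lag{lag:+d}"
        for ch in _CHANNELS
        for lag in PATHLET_LAGS_MS
    ]


def _trajectory_rows(series: np.ndarray, ks: np.ndarray) -> np.ndarray:
    """Gather (len(ks), 4*17) lagged samples from a (n40, 4) series."""
    offsets = np.array(PATHLET_LAGS_MS) // _LAG_STEP_MS
    idx = ks[:, None] + offsets[None, :]  # (n, 17)
    out = np.empty((ks.size, 4 * offsets.size))
    for c in range(4):
        out[:, c * offsets.size : (c + 1) * offsets.size] = series[idx, c]
    return out


def _model_time_indices(model_times_ms: np.ndarray, n40: int) -> np.ndarray:
    """40 S/s sample index for each model time (sample-and-hold)."""
    ks = np.floor(np.asarray(model_times_ms, dtype=float) / _LAG_STEP_MS).astype(int)
    offsets = np.array(PATHLET_LAGS_MS) // _LAG_STEP_MS
    if ks.min() + offsets.min() < 0 or ks.max() + offsets.max() >= n40:
        raise ValueError(
            "model times extend beyond the record span minus the (-100, +300) ms "
            "pathlet margins"
        )
    return ks


def pathlet_features(
    record: KinematicRecord,
    model_times_ms,
    *,
    smoothed: SmoothedKinematics | None = None,
) -> FeatureBlock:
    """Normalized velocity-trajectory features at the given model times.

    Per row: 68 lagged-velocity columns (wrist-3D group of 51 values and
    aperture group of 17 values, each L2-normalized; zero-norm groups map to
    zeros), wrist and aperture mean speed over the 17-lag window, and the
    4 zero-lag positions.  Rows between 25 ms grid points repeat the most
    recent grid value (sample-and-hold).
    """
    sm = smoothed if smoothed is not None else smooth_velocity(record)
    ks_all = _model_time_indices(model_times_ms, sm.vel.shape[0])
    ks, inverse = np.unique(ks_all, return_inverse=True)

    raw = _trajectory_rows(sm.vel, ks)  # (n, 68): x|y|z|ap blocks of 17
    nlag = len(PATHLET_LAGS_MS)
    wrist = raw[:, : 3 * nlag]
    ap = raw[:, 3 * nlag :]

    # trajectories with norms below numerical noise (mm/s) map to zeros
    norm_eps = 1e-6
    wrist_norm = np.linalg.norm(wrist, axis=1, keepdims=True)
    ap_norm = np.linalg.norm(ap, axis=1, keepdims=True)
    wrist_n = np.divide(wrist, wrist_norm, out=np.zeros_like(wrist),
                        where=wrist_norm > norm_eps)
    ap_n = np.divide(ap, ap_norm, out=np.zeros_like(ap),
                     where=ap_norm > norm_eps)

    # mean Euclidean wrist speed and mean |aperture velocity| over the window
    speed = np.sqrt(
        wrist[:, :nlag] ** 2 + wrist[:, nlag : 2 * nlag] ** 2
        + wrist[:, 2 * nlag :] ** 2
    )
    mean_speed_wrist = speed.mean(axis=1, keepdims=True)
    mean_speed_ap = np.abs(ap).mean(axis=1, keepdims=True)

    pos0 = sm.pos[ks]  # zero-lag positions (n, 4)

    values = np.hstack([wrist_n, ap_n, mean_speed_wrist, mean_speed_ap, pos0])
    labels = (
        _lag_columns("v")
        + ["wrist_mean_speed", "ap_mean_speed"]
        + [f"pos_{ch}" for ch in _CHANNELS]
    )
    return FeatureBlock(values[inverse], labels, group="kin")


def position_trajectory_features(
    record: KinematicRecord,
    model_times_ms,
    *,
    smoothed: SmoothedKinematics | None = None,
) -> FeatureBlock:
    """Un-normalized smoothed-position trajectories over the same lag grid."""
    sm = smoothed if smoothed is not None else smooth_velocity(record)
    ks_all = _model_time_indices(model_times_ms, sm.pos.shape[0])
    ks, inverse = np.unique(ks_all, return_inverse=True)
    raw = _trajectory_rows(sm.pos, ks)
    return FeatureBlock(raw[inverse], _lag_columns("p"), group="kin")
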