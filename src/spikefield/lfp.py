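"""Causal multiband LFP filtering and Hilbert analytic-signal features.

The filter bank covers eight bands spanning slow motor-evoked potentials
(0.3-2 Hz) up to multi-unit-dominated activity (200-400 Hz).  Band-limited
signals are obtained with causal (forward-only) Butterworth band-pass filters
so that a spike waveform can only contaminate the filtered trace *after* the
spike.  The analytic signal z(t) is computed with the discrete (FFT) Hilbert
transform over the whole recording block; its modulus is the instantaneous
amplitude envelope and its argument the instantaneous phase.  All features
are additionally delayed by 1 ms as a safeguard against residual spike-time
imprecision.

The Hilbert transform itself is non-causal; :func:`causality_audit` measures
what fraction of the composite impulse response (band-pass -> Hilbert ->
delay, imaginary path) lies at negative lags.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core import ContinuousSignal, FeatureBlock

#: model sampling rate for the point-process design (samples per second)
MODEL_FS_HZ = 1000.0

#: features are shifted by this delay before entering the design
FEATURE_DELAY_MS = 1

#: band-pass filtered data within this margin of a block edge is dominated by
#: filter/Hilbert transients and is discarded from model fitting
EDGE_MARGIN_MS = 2000


@dataclass(frozen=True)
class BandDefinition:
    """One LFP frequency band.

    ``kind`` is "narrow" (amplitude, analytic signal and phase features) for
    bands up to 30 Hz, else "broad" (amplitude and analytic signal only).
    """

    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not (0 <= self.low_hz < self.high_hz):
            raise ValueError(f"invalid band corners for {self.name!r}")

    @property
    def kind(self) -> str:
        return "narrow" if self.high_hz <= 30 else "broad"


DEFAULT_BANDS = (
    BandDefinition("delta", 0.3, 2.0),
    BandDefinition("theta", 2.0, 7.0),
    BandDefinition("alpha", 7.0, 15.0),
    BandDefinition("beta", 15.0, 30.0),
    BandDefinition("gamma1", 30.0, 60.0),
    BandDefinition("gamma2", 60.0, 100.0),
    BandDefinition("mua1", 100.0, 200.0),
    BandDefinition("mua2", 200.0, 400.0),
)

NARROW_FEATURES = ("amp", "re", "im", "cosph", "sinph")
BROAD_FEATURES = ("amp", "re", "im")


def design_band_filter(band: BandDefinition, fs_hz: float):
    """Causal fourth-order Butterworth band-pass for ``band`` at ``fs_hz``.

    Returns second-order sections (stable by construction; all poles strictly
    inside the unit circle).  "Fourth-order" refers to the low-pass prototype,
    i.e. the band-pass transfer function has eight poles.
    """
    if band.high_hz >= fs_hz / 2:
        raise ValueError(
            f"band {band.name!r} upper corner {band.high_hz} Hz is at or above "
            f"Nyquist for fs={fs_hz}"
        )
    sos = sps.butter(
        4, [band.low_hz, band.high_hz], btype="bandpass", fs=fs_hz, output="sos"
    )
    # pole radii from each biquad section
    for section in sos:
        poles = np.roots(section[3:])
        if np.any(np.abs(poles) >= 1.0):
            raise RuntimeError(f"unstable filter designed for band {band.name!r}")
    return sos


def _filter_time_constant_samples(sos: np.ndarray) -> float:
    """Slowest exponential decay (samples) of the filter's impulse response."""
    radii = [np.max(np.abs(np.roots(sec[3:]))) for sec in sos]
    r = max(radii)
    return -1.0 / np.log(max(r, 1e-12))


@dataclass
class AnalyticFeatureSet:
    """Per-band analytic-signal features on the 1 ms model grid."""

    band: BandDefinition
    amplitude: np.ndarray
    phase: np.ndarray
    real: np.ndarray
    imag: np.ndarray
    delay_ms: int = FEATURE_DELAY_MS
    t0_ms: float = 0.0

    def __post_init__(self) -> None:
        n = {len(self.amplitude), len(self.phase), len(self.real), len(self.imag)}
        if len(n) != 1:
            raise ValueError("feature series must share length")

    @property
    def n_samples(self) -> int:
        return len(self.amplitude)


def analytic_features(
    signal: ContinuousSignal,
    band: BandDefinition,
    *,
    delay_ms: int = FEATURE_DELAY_MS,
) -> AnalyticFeatureSet:
    """Causal band-pass -> Hilbert analytic signal -> 1 ms delay -> 1 kS/s.

    The band-pass is run forward only.  The analytic signal is computed over
    the full block with the FFT Hilbert transform, every feature is shifted by
    ``delay_ms`` (the first delayed samples are zero-filled), and the result
    is decimated to the 1 kS/s model grid by plain subsampling — the band
    filter itself provides the anti-aliasing for all default bands.
    """
    fs = signal.fs_hz
    if fs < MODEL_FS_HZ:
        raise ValueError("LFP must be sampled at >= 1 kS/s")
    step = fs / MODEL_FS_HZ
    if abs(step - round(step)) > 1e-9:
        raise ValueError("fs_hz must be an integer multiple of 1000")
    step = int(round(step))

    sos = design_band_filter(band, fs)
    tau = _filter_time_constant_samples(sos)
    if signal.n_samples < 10 * tau:
        warnings.warn(
            f"signal ({signal.n_samples} samples) shorter than 10 time constants "
            f"of the {band.name} filter ({tau:.0f} samples); transient dominates",
            stacklevel=2,
        )
    y = sps.sosfilt(sos, signal.samples)
    z = sps.hilbert(y)

    d = int(round(delay_ms * fs / 1000.0))
    zd = np.zeros_like(z)
    if d > 0:
        zd[d:] = z[:-d]
    else:
        zd = z
    zd = zd[::step]
    return AnalyticFeatureSet(
        band=band,
        amplitude=np.abs(zd),
        phase=np.angle(zd),
        real=np.real(zd),
        imag=np.imag(zd),
        delay_ms=delay_ms,
        t0_ms=signal.t0_ms,
    )


def causality_audit(
    band: BandDefinition,
    fs_hz: float,
    *,
    delay_ms: int = FEATURE_DELAY_MS,
    component: str = "imag",
    zero_phase: bool = False,
    window: int = 2**17,
) -> float:
    """Percent of the composite impulse response's absolute area at lags < 0.

    The composite is: band-pass filter (causal, or forward-backward when
    ``zero_phase``) -> FFT Hilbert transform -> ``delay_ms`` delay, taking the
    requested ``component`` ("imag" or "re") of the analytic signal.  The
    impulse sits at the centre of a ``window``-sample block so that both tails
    are fully captured.
    """
    sos = design_band_filter(band, fs_hz)
    n0 = window // 2
    x = np.zeros(window)
    x[n0] = 1.0
    y = sps.sosfiltfilt(sos, x) if zero_phase else sps.sosfilt(sos, x)
    if component == "imag":
        comp = np.imag(sps.hilbert(y))
    else:
        comp = y  # Re z(t) is the band-passed signal itself
    d = int(round(delay_ms * fs_hz / 1000.0))
    h = np.zeros(window)
    if d > 0:
        h[d:] = comp[: window - d]
    else:
        h = comp
    a = np.abs(h)
    total = a.sum()
    if total == 0:
        return 0.0
    # sanity: the window must capture essentially the whole response
    tail = a[-window // 100 :].sum() / total
    if tail > 1e-4:
        warnings.warn(
            f"audit window may be too short for band {band.name}: "
            f"tail fraction {tail:.2e}",
            stacklevel=2,
        )
    return 100.0 * a[:n0].sum() / total


def lfp_design_columns(features: list[AnalyticFeatureSet]) -> FeatureBlock:
    """Stack per-band analytic features into labeled design columns.

    Narrow bands contribute five columns (|z|, Re z, Im z, cos Arg z,
    sin Arg z) so that a fitted cos/sin pair realizes cosine tuning to a
    preferred phase; broad bands contribute amplitude and analytic signal
    only (three columns).  Eight default bands -> 32 columns per electrode.
    """
    if not features:
        return FeatureBlock(np.empty((0, 0)), [], group="lfp")
    n = {f.n_samples for f in features}
    t0 = {f.t0_ms for f in features}
    if len(n) != 1 or len(t0) != 1:
        raise ValueError("analytic feature sets must share a time base")
    cols, labels = [], []
    for f in features:
        per_band = {
            "amp": f.amplitude,
            "re": f.real,
            "im": f.imag,
            "cosph": np.cos(f.phase),
            "sinph": np.sin(f.phase),
        }
        names = NARROW_FEATURES if f.band.kind == "narrow" else BROAD_FEATURES
        for name in names:
            cols.append(per_band[name])
            labels.append(f"{f.band.name}_{name}")
    return FeatureBlock(np.column_stack(cols), labels, group="lfp")


def lfp_feature_blocks(
    lfp: ContinuousSignal,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    *,
    delay_ms: int = FEATURE_DELAY_MS,
) -> FeatureBlock:
    """Convenience: full filter bank on one electrode -> one labeled block."""
    feats = [analytic_features(lfp, b, delay_ms=delay_ms) for b in bands]
    return lfp_design_columns(feats)
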