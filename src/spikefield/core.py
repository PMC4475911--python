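"""Core containers shared across the feature-extraction and modeling modules.

Time conventions used throughout the package:

* the point-process model operates on 1 ms bins ("model bins"); bin ``t``
  covers ``[t0_ms + t, t0_ms + t + 1)`` ms,
* continuous channels (LFP in microvolts, kinematics in millimetres) carry
  their own sampling rate and are aligned to the same ``t0_ms`` origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: model bin width in seconds (1 ms); per-bin spike probability is lambda*DELTA_S
DELTA_MS = 1.0
DELTA_S = 1e-3


@dataclass
class BinnedSpikeTrain:
    """Binary spike indicator per 1 ms bin."""

    values: np.ndarray
    bin_width_ms: float = DELTA_MS
    t0_ms: float = 0.0
    label: str = "unit"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("spike train must be a non-empty 1-D sequence")
        if self.bin_width_ms != DELTA_MS:
            raise ValueError("model resolution is fixed at 1 ms bins")
        vals = np.unique(self.values)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("spike train values must be binary (0/1)")
        self.values = self.values.astype(np.int8)

    @property
    def n_bins(self) -> int:
        return self.values.size

    @property
    def n_spikes(self) -> int:
        return int(self.values.sum())

    def spike_times_ms(self) -> np.ndarray:
        """Event times (bin left edges, ms) for CSV serialization."""
        return np.flatnonzero(self.values).astype(float) + self.t0_ms


@dataclass
class ContinuousSignal:
    """Uniformly sampled real-valued channel (LFP or kinematic marker)."""

    samples: np.ndarray
    fs_hz: float
    t0_ms: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if self.samples.ndim != 1:
            raise ValueError("samples must be 1-D")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError(f"channel {self.label!r} contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def times_ms(self) -> np.ndarray:
        return self.t0_ms + np.arange(self.n_samples) * (1000.0 / self.fs_hz)


@dataclass
class KinematicRecord:
    """Wrist 3-D position plus thumb-forefinger aperture, shared sampling grid."""

    wrist_xyz: list  # three ContinuousSignal, mm
    aperture: ContinuousSignal  # mm

    def __post_init__(self) -> None:
        if len(self.wrist_xyz) != 3:
            raise ValueError("wrist_xyz must contain exactly three channels")
        chans = list(self.wrist_xyz) + [self.aperture]
        fs = {c.fs_hz for c in chans}
        ns = {c.n_samples for c in chans}
        t0 = {c.t0_ms for c in chans}
        if len(fs) != 1 or len(ns) != 1 or len(t0) != 1:
            raise ValueError("kinematic channels must share fs, span and origin")

    @property
    def fs_hz(self) -> float:
        return self.wrist_xyz[0].fs_hz

    @property
    def n_samples(self) -> int:
        return self.wrist_xyz[0].n_samples

    def as_array(self) -> np.ndarray:
        """(n_samples, 4) array with columns x, y, z, aperture."""
        return np.column_stack(
            [c.samples for c in self.wrist_xyz] + [self.aperture.samples]
        )


@dataclass
class FeatureBlock:
    """A labeled group of design-matrix columns on the 1 ms model grid.

    ``group`` tags the provenance of the columns ("lfp", "kin" or "hist") so
    that downstream model assembly can keep feature families apart.
    """

    values: np.ndarray  # (T, p)
    labels: list = field(default_factory=list)
    group: str = ""

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values))
        if self.values.ndim != 2:
            raise ValueError("feature block must be 2-D (time x columns)")
        if len(self.labels) != self.values.shape[1]:
            raise ValueError("one label per column required")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def sliced(self, rows) -> "FeatureBlock":
        return FeatureBlock(self.values[rows], list(self.labels), self.group)
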