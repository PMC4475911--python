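"""Synthetic reach-and-grasp sessions with known ground truth.

No public dataset accompanies the analysis this package implements, so every
downstream stage is exercised on simulated sessions that carry the
statistical structure the models assume:

* **LFP** (1 kS/s, microvolts): a sum over the eight analysis bands of
  narrowband carriers (band-pass filtered Gaussian noise) modulated by
  slowly varying amplitude envelopes (rectified 0.5 Hz low-pass noise), plus
  1/f background.  The 0.3-2 Hz (delta) component can be driven by the
  wrist speed: with coupling c, a fraction c of the delta-band variance is
  the band-passed kinematic speed signal — emulating the strong correlation
  between slow motor-evoked potentials and movement, and making
  LFP/kinematics redundancy detectable by construction.
* **Kinematics** (240 frames/s, mm): minimum-jerk point-to-point wrist
  reaches at random intervals within a ~30 cm workspace, with a grasp
  aperture profile that opens during the reach and closes around its end.
* **Spikes** (1 ms bins): Bernoulli samples from a log-linear conditional
  intensity combining z-scored LFP features, z-scored pathlet features and
  raw spike-history features, with the history term updated recursively from
  the emitted spikes (refractoriness/bursting).

Default session length is 600 s, matching the ~10 min of task data per
recording session the analysis design assumes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .core import DELTA_S, BinnedSpikeTrain, ContinuousSignal, KinematicRecord
from .history import HistoryBasis, raised_cosine_basis
from .kinematics import pathlet_features, smooth_velocity
from .lfp import DEFAULT_BANDS, EDGE_MARGIN_MS, design_band_filter, lfp_feature_blocks
from .ppglm import FeatureMatrix, assemble_design

KIN_FS_HZ = 240.0
LFP_FS_HZ = 1000.0

#: band RMS amplitudes (microvolts) for the default synthetic LFP; slow bands
#: dominate, as in motor-cortex recordings
DEFAULT_BAND_AMPLITUDES = {
    "delta": 40.0, "theta": 20.0, "alpha": 12.0, "beta": 10.0,
    "gamma1": 6.0, "gamma2": 4.0, "mua1": 3.0, "mua2": 2.0,
}


@dataclass
class GroundTruthSpec:
    """Generative parameters for one synthetic unit and its session.

    Weights act on the same features the analysis pipeline extracts:
    ``lfp_weights`` and ``kin_weights`` are keyed by design-column label and
    apply to the z-scored column (units: log-rate change per SD);
    ``history_weights`` (one per raised-cosine basis) apply to the raw,
    peak-normalized history features.  ``coupling`` is the fraction of
    delta-band LFP variance driven by the kinematic speed.
    """

    mu: float = float(np.log(15.0))  # log spikes/s
    lfp_weights: dict = field(default_factory=dict)
    kin_weights: dict = field(default_factory=dict)
    history_weights: np.ndarray = field(default_factory=lambda: np.zeros(10))
    coupling: float = 0.0
    #: high-frequency bands whose amplitude envelope is movement-modulated
    #: (multi-unit activity tracks the population drive); same fraction as
    #: ``coupling``
    envelope_coupled_bands: tuple = ("mua1", "mua2")
    band_amplitudes_uv: dict = field(
        default_factory=lambda: dict(DEFAULT_BAND_AMPLITUDES)
    )
    background_uv: float = 8.0
    reach_rate_hz: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        self.history_weights = np.asarray(self.history_weights, dtype=float)
        if not (0.0 <= self.coupling <= 1.0):
            raise ValueError("coupling must lie in [0, 1]")
        allw = (
            [self.mu]
            + list(self.lfp_weights.values())
            + list(self.kin_weights.values())
            + list(self.history_weights)
        )
        if not np.all(np.isfinite(allw)):
            raise ValueError("all generative weights must be finite")

    def to_dict(self) -> dict:
        return {
            "mu": self.mu,
            "lfp_weights": dict(self.lfp_weights),
            "kin_weights": dict(self.kin_weights),
            "history_weights": self.history_weights.tolist(),
            "coupling": self.coupling,
            "envelope_coupled_bands": list(self.envelope_coupled_bands),
            "band_amplitudes_uv": dict(self.band_amplitudes_uv),
            "background_uv": self.background_uv,
            "reach_rate_hz": self.reach_rate_hz,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruthSpec":
        d = dict(d)
        d["history_weights"] = np.asarray(d["history_weights"])
        if "envelope_coupled_bands" in d:
            d["envelope_coupled_bands"] = tuple(d["envelope_coupled_bands"])
        return cls(**d)


@dataclass
class SyntheticSession:
    """One generated session: LFP, kinematics, spike trains, ground truth."""

    lfp: list  # ContinuousSignal
    kinematics: KinematicRecord
    spikes: list  # BinnedSpikeTrain
    truth: list  # GroundTruthSpec per unit
    intensity: list | None = None  # realized lambda*Delta per unit

    def __post_init__(self) -> None:
        dur = {round(c.duration_s, 6) for c in self.lfp}
        dur.add(round(self.kinematics.n_samples / self.kinematics.fs_hz, 6))
        dur.add(round(self.spikes[0].n_bins * 1e-3, 6))
        if len(dur) != 1:
            raise ValueError("session members do not span the same interval")

    @property
    def duration_s(self) -> float:
        return self.spikes[0].n_bins * 1e-3


def _minjerk(t: np.ndarray) -> np.ndarray:
    """Minimum-jerk position profile on normalized time in [0, 1]."""
    t = np.clip(t, 0.0, 1.0)
    return 10 * t**3 - 15 * t**4 + 6 * t**5


def generate_kinematics(
    duration_s: float,
    reach_rate_hz: float = 0.4,
    seed: int = 0,
    *,
    fs_hz: float = KIN_FS_HZ,
) -> KinematicRecord:
    """Minimum-jerk 3-D reaches plus a grasp-aperture profile at 240 f/s.

    Reaches to uniform random targets in a 300 mm cube start at exponential
    intervals (~``reach_rate_hz`` events/s) and last 0.5-0.9 s; the aperture
    opens from its 20 mm baseline to 60-90 mm during the reach and closes
    shortly after the reach ends.  ``reach_rate_hz = 0`` yields a motionless
    record.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if reach_rate_hz < 0:
        raise ValueError("reach_rate_hz must be >= 0")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs_hz))
    t = np.arange(n) / fs_hz

    pos = np.zeros((n, 3))
    aperture = np.full(n, 20.0)
    current = np.array([0.0, 0.0, 0.0])
    pos[:] = current

    if reach_rate_hz > 0:
        t_next = rng.exponential(1.0 / reach_rate_hz)
        while t_next < duration_s - 1.2:
            T_reach = rng.uniform(0.5, 0.9)
            target = rng.uniform(-150.0, 150.0, size=3)
            i0 = int(t_next * fs_hz)
            i1 = int((t_next + T_reach) * fs_hz)
            tau = (t[i0:i1] - t_next) / T_reach
            pos[i0:i1] = current + np.outer(_minjerk(tau), target - current)
            pos[i1:] = target
            # aperture: open over the first 70% of the reach, close by +0.25 s
            a_max = rng.uniform(60.0, 90.0)
            t_open_end = t_next + 0.7 * T_reach
            t_close_end = t_next + T_reach + 0.25
            jo0, jo1 = i0, int(t_open_end * fs_hz)
            jc1 = int(t_close_end * fs_hz)
            tau_o = (t[jo0:jo1] - t_next) / (0.7 * T_reach)
            aperture[jo0:jo1] = 20.0 + (a_max - 20.0) * _minjerk(tau_o)
            tau_c = (t[jo1:jc1] - t_open_end) / (t_close_end - t_open_end)
            aperture[jo1:jc1] = a_max + (20.0 - a_max) * _minjerk(tau_c)
            aperture[jc1:] = 20.0
            current = target
            t_next = t_close_end + rng.exponential(1.0 / reach_rate_hz)

    chans = [
        ContinuousSignal(pos[:, i], fs_hz, label=f"wrist_{ax}")
        for i, ax in enumerate("xyz")
    ]
    ap = ContinuousSignal(aperture, fs_hz, label="aperture")
    return KinematicRecord(wrist_xyz=chans, aperture=ap)


def _unit_rms(x: np.ndarray) -> np.ndarray:
    r = np.sqrt(np.mean(x**2))
    return x / r if r > 0 else x


def wrist_speed(record: KinematicRecord) -> ContinuousSignal:
    """Smoothed wrist speed (mm/s) at 40 S/s."""
    sm = smooth_velocity(record)
    sp = np.linalg.norm(sm.vel[:, :3], axis=1)
    return ContinuousSignal(sp, sm.fs_hz, label="wrist_speed")


def generate_lfp(
    spec: GroundTruthSpec,
    duration_s: float,
    fs_hz: float = LFP_FS_HZ,
    *,
    speed: ContinuousSignal | None = None,
    rng: np.random.Generator | None = None,
) -> ContinuousSignal:
    """Multiband synthetic LFP (microvolts) with envelope dynamics.

    Each band contributes ``amp * envelope * carrier`` with a unit-RMS
    band-pass noise carrier and a rectified 0.5 Hz low-pass noise envelope
    (product normalized to unit RMS).  Movement coupling (fraction
    c = ``spec.coupling``) enters two ways, both zero-phase on the
    generator side — the slow motor potential and multi-unit modulation are
    *cotemporal* with movement, since cortical drive, LFP and kinematics
    share a common cause; the analysis filters then add their own (causal)
    delays:

    * the delta band is a sqrt(1-c)/sqrt(c) amplitude mixture of the
      independent component and the delta-band (zero-phase) filtered,
      unit-RMS kinematic ``speed``;
    * the amplitude envelopes of ``spec.envelope_coupled_bands`` (the
      multi-unit bands by default) are (1-c)/c mixtures of the noise
      envelope and the low-passed speed — movement-modulated MUA.

    A 1/f-power background of RMS ``spec.background_uv`` is added.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if fs_hz < 1000:
        raise ValueError("fs_hz must be >= 1000")
    if spec.coupling > 0 and speed is None:
        raise ValueError("coupling > 0 requires the kinematic speed signal")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n = int(round(duration_s * fs_hz))
    out = np.zeros(n)

    sp1k = env_speed = None
    if spec.coupling > 0:
        sp1k = np.interp(
            np.arange(n) / fs_hz,
            np.arange(speed.n_samples) / speed.fs_hz,
            speed.samples,
        )
        lp_sos = sps.butter(2, 2.0, btype="lowpass", fs=fs_hz, output="sos")
        env_speed = np.clip(sps.sosfiltfilt(lp_sos, sp1k), 0.0, None)
        m = env_speed.mean()
        if m > 0:
            env_speed = env_speed / m

    env_sos = sps.butter(2, 0.5, btype="lowpass", fs=fs_hz, output="sos")
    for band in DEFAULT_BANDS:
        amp = float(spec.band_amplitudes_uv.get(band.name, 0.0))
        if amp == 0.0:
            continue
        sos = design_band_filter(band, fs_hz)
        carrier = sps.sosfilt(sos, rng.standard_normal(n))
        env = np.abs(sps.sosfilt(env_sos, rng.standard_normal(n)))
        env = env / max(env.mean(), 1e-12)
        if (
            spec.coupling > 0
            and band.name in spec.envelope_coupled_bands
        ):
            env = (1.0 - spec.coupling) * env + spec.coupling * env_speed
        comp = _unit_rms(carrier * env)
        if band.name == "delta" and spec.coupling > 0:
            sp_band = _unit_rms(sps.sosfiltfilt(sos, sp1k))
            comp = (
                np.sqrt(1.0 - spec.coupling) * comp
                + np.sqrt(spec.coupling) * sp_band
            )
        out += amp * comp

    if spec.background_uv > 0:
        white = rng.standard_normal(n)
        F = np.fft.rfft(white)
        f = np.fft.rfftfreq(n, d=1.0 / fs_hz)
        shape = np.ones_like(f)
        nz = f > 0.1
        shape[nz] = (0.1 / f[nz]) ** 0.5  # 1/f power spectrum
        shape[0] = 0.0
        bg = np.fft.irfft(F * shape, n=n)
        out += spec.background_uv * _unit_rms(bg)

    return ContinuousSignal(out, fs_hz, label="lfp0")


def _eta_base(spec: GroundTruthSpec, X: FeatureMatrix) -> np.ndarray:
    """mu + weighted sum of the named (z-scored) design columns."""
    eta = np.full(X.T, spec.mu)
    pos = {lb: i for i, lb in enumerate(X.labels)}
    for wdict in (spec.lfp_weights, spec.kin_weights):
        for lb, w in wdict.items():
            if lb not in pos:
                raise KeyError(f"ground-truth weight targets unknown column {lb!r}")
            eta += w * X.X[:, pos[lb]]
    return eta


def generate_spikes(
    truth: GroundTruthSpec,
    X: FeatureMatrix,
    seed: int = 0,
    *,
    basis: HistoryBasis | None = None,
    return_intensity: bool = False,
):
    """Bernoulli spike train from the log-linear intensity, history included.

    Per-bin spike probability is min(lambda_t * Delta, 1) with
    ln(lambda_t) = mu + A.X_t + history(t), the history term accumulating
    the basis-filter response of previously *emitted* spikes — so
    refractoriness and bursting shape the train recursively.  Warns when the
    Bernoulli approximation is strained (lambda*Delta > 1 in > 0.1% of
    bins).
    """
    if basis is None:
        basis = raised_cosine_basis()
    eta = _eta_base(truth, X)
    T = eta.size
    rng = np.random.default_rng(seed)
    u = rng.random(T)
    p_base = np.exp(eta) * DELTA_S

    hw = np.asarray(truth.history_weights, dtype=float)
    if hw.size != basis.n_basis:
        raise ValueError("history_weights length must match the basis")
    kernel = basis.matrix.T @ hw  # (window_ms,)
    W = kernel.size

    spikes = np.zeros(T, dtype=np.int8)
    hbuf = np.zeros(T + W + 1)
    has_hist = np.any(hw != 0)
    chunk = 512
    t = 0
    while t < T:
        end = min(t + chunk, T)
        if has_hist:
            seg = p_base[t:end] * np.exp(hbuf[t:end])
        else:
            seg = p_base[t:end].copy()
        np.minimum(seg, 1.0, out=seg)
        hits = np.flatnonzero(u[t:end] < seg)
        if hits.size == 0:
            t = end
        else:
            s = t + int(hits[0])
            spikes[s] = 1
            if has_hist:
                hbuf[s + 1 : s + 1 + W] += kernel
            t = s + 1

    lam_delta = np.minimum(p_base * np.exp(hbuf[:T]), 1.0)
    over = np.mean(p_base * np.exp(hbuf[:T]) > 1.0)
    if over > 1e-3:
        warnings.warn(
            f"lambda*Delta exceeded 1 in {100 * over:.2f}% of bins; the "
            "Bernoulli approximation is strained",
            stacklevel=2,
        )
    train = BinnedSpikeTrain(spikes, label=f"unit_seed{seed}")
    if return_intensity:
        return train, lam_delta
    return train


def session_design(
    lfp: ContinuousSignal,
    kinematics: KinematicRecord,
    *,
    bands=DEFAULT_BANDS,
):
    """Full-session z-scored design used by the generator.

    Returns (FeatureMatrix over all T bins, usable slice).  Feature z-scores
    use the usable window (2 s edge margins discarded) so that edge
    transients do not leak into the scaling; rows outside the pathlet-valid
    range hold the nearest valid pathlet (only edge rows, excluded from
    fitting anyway).
    """
    T = int(round(lfp.duration_s * 1000))
    usable = slice(EDGE_MARGIN_MS, T - EDGE_MARGIN_MS)
    lfp_block = lfp_feature_blocks(lfp, tuple(bands))
    n40 = int(T // 25)
    tmin, tmax = 4 * 25, (n40 - 13) * 25
    times = np.clip(np.arange(T), tmin, tmax)
    sm = smooth_velocity(kinematics)
    kin_block = pathlet_features(kinematics, times, smoothed=sm)

    raw = np.hstack([lfp_block.values, kin_block.values])
    labels = list(lfp_block.labels) + list(kin_block.labels)
    groups = ["lfp"] * lfp_block.n_cols + ["kin"] * kin_block.n_cols
    m = raw[usable].mean(axis=0)
    s = raw[usable].std(axis=0)
    s = np.where(s > 1e-12, s, 1.0)
    Z = (raw - m) / s
    return FeatureMatrix(Z, labels, groups, m, s), usable


def generate_session(
    truths,
    duration_s: float = 600.0,
    *,
    basis: HistoryBasis | None = None,
    return_intensity: bool = False,
) -> SyntheticSession:
    """Generate a full session for one or more units.

    Session-level structure (kinematics, LFP, coupling) comes from the first
    spec; per-unit specs control only the intensity model.  Everything is
    derived deterministically from the first spec's seed.
    """
    if isinstance(truths, GroundTruthSpec):
        truths = [truths]
    lead = truths[0]
    ss = np.random.SeedSequence(lead.seed)
    kin_seed, lfp_seed, *unit_seeds = ss.spawn(2 + len(truths))

    kin = generate_kinematics(
        duration_s, lead.reach_rate_hz,
        seed=int(kin_seed.generate_state(1)[0] % 2**31),
    )
    speed = wrist_speed(kin)
    lfp = generate_lfp(
        lead, duration_s, LFP_FS_HZ, speed=speed,
        rng=np.random.default_rng(lfp_seed),
    )
    X, usable = session_design(lfp, kin)
    if basis is None:
        basis = raised_cosine_basis()

    spikes, lams = [], []
    for u, (truth, useed) in enumerate(zip(truths, unit_seeds)):
        train, lam = generate_spikes(
            truth, X, seed=int(useed.generate_state(1)[0] % 2**31),
            basis=basis, return_intensity=True,
        )
        train.label = f"unit{u:02d}"
        spikes.append(train)
        lams.append(lam)
    return SyntheticSession(
        lfp=[lfp], kinematics=kin, spikes=spikes, truth=list(truths),
        intensity=lams if return_intensity else None,
    )


# ---------------------------------------------------------------------------
# canonical study populations

#: refractory + bursting history filter on the 10 default bases: strong
#: suppression at the shortest lags, mild facilitation at ~5-15 ms
REFRACTORY_HISTORY = np.array(
    [-6.0, -2.5, 0.6, 0.5, 0.0, -0.2, -0.1, 0.0, 0.0, 0.0]
)


def recovery_truth(seed: int = 0) -> GroundTruthSpec:
    """Single-unit ground truth for parameter-recovery studies.

    Delta-band cosine phase tuning with preferred phase 2*pi/3 and depth
    0.3, a delta analytic-signal weight, a *negative* beta-amplitude weight
    (beta suppression precedes firing), a high-band amplitude weight,
    speed/velocity/position kinematic tuning, and the refractory history
    filter.
    """
    theta0 = 2 * np.pi / 3
    return GroundTruthSpec(
        mu=float(np.log(15.0)),
        lfp_weights={
            "delta_cosph": 0.3 * float(np.cos(theta0)),
            "delta_sinph": 0.3 * float(np.sin(theta0)),
            "delta_re": 0.15,
            "beta_amp": -0.2,
            "mua2_amp": 0.1,
        },
        kin_weights={
            "wrist_mean_speed": 0.3,
            "vx_lag+0": 0.15,
            "vz_lag+100": -0.1,
            "pos_ap": 0.1,
        },
        history_weights=REFRACTORY_HISTORY,
        coupling=0.5,
        seed=seed,
    )


def population_truths(
    seed: int,
    n_units: int,
    *,
    coupling: float = 1.0,
) -> list[GroundTruthSpec]:
    """A speed-tuned unit population for the redundancy study.

    Every unit is driven by kinematics (wrist speed plus a random sprinkling
    of velocity-pathlet and position weights) and by its own refractory/
    bursting history — *not* directly by the LFP.  With ``coupling = 1`` the
    delta-band LFP is itself a function of the wrist speed, so LFP features
    predict spiking through the shared drive while carrying no information
    beyond the kinematics: the redundancy structure is true by construction.
    """
    rng = np.random.default_rng(seed)
    vel_labels = [
        f"v{ch}_lag{lag:+d}" for ch in ("x", "y", "z", "ap")
        for lag in range(-100, 301, 25)
    ]
    truths = []
    for u in range(n_units):
        kin_w = {"wrist_mean_speed": float(rng.uniform(0.35, 0.7))}
        for lb in rng.choice(vel_labels, size=6, replace=False):
            kin_w[str(lb)] = float(rng.normal(0.0, 0.12))
        kin_w["pos_" + str(rng.choice(["x", "y", "z", "ap"]))] = float(
            rng.normal(0.0, 0.05)
        )
        hw = REFRACTORY_HISTORY + rng.normal(0.0, 0.15, size=10) * np.array(
            [1, 1, 0.5, 0.5, 0.3, 0.3, 0.2, 0.2, 0.1, 0.1]
        )
        hw[0] = min(hw[0], -4.0)  # keep the refractory floor
        truths.append(
            GroundTruthSpec(
                mu=float(np.log(rng.uniform(10.0, 25.0))),
                kin_weights=kin_w,
                history_weights=hw,
                coupling=coupling,
                seed=seed,
            )
        )
    return truths


# ---------------------------------------------------------------------------
# session I/O: delimited text per channel + JSON manifest

def save_session(session: SyntheticSession, outdir) -> None:
    """Write a session as CSV channels plus a JSON manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "duration_s": session.duration_s,
        "lfp": [],
        "kinematics": "kinematics.csv",
        "spikes": [],
        "truth": [t.to_dict() for t in session.truth],
    }
    for sig in session.lfp:
        fn = f"lfp_{sig.label}.csv"
        np.savetxt(out / fn, sig.samples, fmt="%.6f", header="uv", comments="")
        manifest["lfp"].append({"file": fn, "fs_hz": sig.fs_hz,
                                "t0_ms": sig.t0_ms, "label": sig.label})
    kin = session.kinematics
    tms = kin.wrist_xyz[0].times_ms()
    arr = np.column_stack([tms, kin.as_array()])
    np.savetxt(out / "kinematics.csv", arr, fmt="%.6f",
               header="t_ms,x,y,z,aperture", delimiter=",", comments="")
    manifest["kin_fs_hz"] = kin.fs_hz
    for tr in session.spikes:
        fn = f"spikes_{tr.label}.csv"
        np.savetxt(out / fn, tr.spike_times_ms(), fmt="%.1f",
                   header="t_ms", comments="")
        manifest["spikes"].append({"file": fn, "label": tr.label,
                                   "n_bins": tr.n_bins})
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_session(indir) -> SyntheticSession:
    """Read a session previously written by :func:`save_session`."""
    src = Path(indir)
    mf = src / "manifest.json"
    if not mf.exists():
        raise FileNotFoundError(f"session manifest not found: {mf}")
    manifest = json.loads(mf.read_text())
    lfp = []
    for entry in manifest["lfp"]:
        path = src / entry["file"]
        if not path.exists():
            raise FileNotFoundError(f"missing LFP channel file: {path}")
        samples = np.loadtxt(path, skiprows=1)
        lfp.append(ContinuousSignal(samples, entry["fs_hz"],
                                    entry["t0_ms"], entry["label"]))
    kin_arr = np.loadtxt(src / manifest["kinematics"], delimiter=",",
                         skiprows=1)
    fs = manifest["kin_fs_hz"]
    chans = [
        ContinuousSignal(kin_arr[:, i + 1], fs, label=f"wrist_{ax}")
        for i, ax in enumerate("xyz")
    ]
    ap = ContinuousSignal(kin_arr[:, 4], fs, label="aperture")
    kin = KinematicRecord(chans, ap)
    spikes = []
    for entry in manifest["spikes"]:
        path = src / entry["file"]
        if not path.exists():
            raise FileNotFoundError(f"missing spike file: {path}")
        times = np.atleast_1d(np.loadtxt(path, skiprows=1))
        vals = np.zeros(entry["n_bins"], dtype=np.int8)
        vals[times.astype(int)] = 1
        spikes.append(BinnedSpikeTrain(vals, label=entry["label"]))
    truths = [GroundTruthSpec.from_dict(d) for d in manifest["truth"]]
    return SyntheticSession(lfp=lfp, kinematics=kin, spikes=spikes,
                            truth=truths)
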