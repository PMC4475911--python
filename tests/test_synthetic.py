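"""Ground-truth session generation: LFP, kinematics, spikes, and I/O."""

import numpy as np
import pytest
from scipy import signal as sps

import spikefield as sf
from spikefield import GroundTruthSpec, generate_kinematics, generate_lfp
from spikefield.core import DELTA_S
from spikefield.lfp import DEFAULT_BANDS, design_band_filter
from spikefield.ppglm import FeatureMatrix
from spikefield.synthetic import generate_spikes, wrist_speed


def bands_only(*names, amp=20.0):
    amps = {b.name: 0.0 for b in DEFAULT_BANDS}
    for n in names:
        amps[n] = amp
    return amps


class TestGenerateLfp:
    def test_delta_only_power_concentrated_at_slow_frequencies(self):
        # the 4th-order band edge holds ~10% of carrier power near/above the
        # 2 Hz corner, and envelope modulation adds ~0.5 Hz sidebands, so
        # the concentration is asserted just above the band corner
        spec = GroundTruthSpec(
            band_amplitudes_uv=bands_only("delta"), background_uv=0.0, seed=0
        )
        lfp = generate_lfp(spec, 60.0)
        f, p = sps.periodogram(lfp.samples, fs=1000.0)
        assert p[f <= 2.5].sum() / p.sum() >= 0.90
        assert p[f <= 2.0].sum() / p.sum() >= 0.80

    def test_all_zero_amplitudes_zero_signal(self):
        spec = GroundTruthSpec(band_amplitudes_uv=bands_only(),
                               background_uv=0.0, seed=0)
        lfp = generate_lfp(spec, 10.0)
        assert np.allclose(lfp.samples, 0.0)

    def test_full_coupling_delta_tracks_speed(self):
        kin = generate_kinematics(120.0, 0.4, seed=4)
        speed = wrist_speed(kin)
        spec = GroundTruthSpec(coupling=1.0, seed=4)
        lfp = generate_lfp(spec, 120.0, speed=speed)
        sos = design_band_filter(DEFAULT_BANDS[0], 1000.0)
        d_lfp = sps.sosfilt(sos, lfp.samples)[5000:]
        sp1k = np.interp(np.arange(120000) / 1000.0,
                         np.arange(speed.n_samples) / 40.0, speed.samples)
        d_speed = sps.sosfilt(sos, sps.sosfiltfilt(sos, sp1k))[5000:]
        assert np.corrcoef(d_lfp, d_speed)[0, 1] > 0.9

    def test_coupling_monotone_in_c(self):
        kin = generate_kinematics(60.0, 0.4, seed=9)
        speed = wrist_speed(kin)
        sos = design_band_filter(DEFAULT_BANDS[0], 1000.0)
        sp1k = np.interp(np.arange(60000) / 1000.0,
                         np.arange(speed.n_samples) / 40.0, speed.samples)
        ref = sps.sosfilt(sos, sps.sosfiltfilt(sos, sp1k))[5000:]
        cors = []
        for c in (0.0, 0.5, 1.0):
            spec = GroundTruthSpec(coupling=c, seed=9)
            lfp = generate_lfp(spec, 60.0, speed=speed,
                               rng=np.random.default_rng(42))
            d = sps.sosfilt(sos, lfp.samples)[5000:]
            cors.append(np.corrcoef(d, ref)[0, 1])
        assert cors[0] <= cors[1] <= cors[2]

    def test_coupling_without_speed_rejected(self):
        with pytest.raises(ValueError):
            generate_lfp(GroundTruthSpec(coupling=0.5, seed=0), 10.0)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            generate_lfp(GroundTruthSpec(seed=0), -5.0)
        with pytest.raises(ValueError):
            generate_lfp(GroundTruthSpec(seed=0), 10.0, fs_hz=500.0)


class TestGenerateKinematics:
    def test_zero_rate_motionless(self):
        rec = generate_kinematics(20.0, 0.0, seed=0)
        assert np.allclose(np.std(rec.as_array(), axis=0), 0.0)

    def test_smoothness_second_difference_bounded(self):
        rec = generate_kinematics(60.0, 0.5, seed=2)
        arr = rec.as_array()
        dd = np.abs(np.diff(arr, n=2, axis=0))
        assert dd.max() < 5.0  # mm per frame^2

    def test_determinism(self):
        a = generate_kinematics(15.0, 0.4, seed=11).as_array()
        b = generate_kinematics(15.0, 0.4, seed=11).as_array()
        assert np.array_equal(a, b)

    def test_reaches_move_the_wrist(self):
        rec = generate_kinematics(60.0, 0.4, seed=3)
        assert np.std(rec.as_array()[:, 0]) > 10.0  # mm


def homogeneous_design(T):
    return FeatureMatrix(np.zeros((T, 0)), [], [])


class TestGenerateSpikes:
    def test_homogeneous_count_within_binomial_interval(self):
        truth = GroundTruthSpec(mu=float(np.log(10.0)), seed=0)
        X = homogeneous_design(100_000)
        train = generate_spikes(truth, X, seed=123)
        n = train.n_spikes
        p = 10.0 * DELTA_S
        sd = np.sqrt(100_000 * p * (1 - p))
        assert abs(n - 1000) < 2.58 * sd

    def test_binary_values(self):
        truth = GroundTruthSpec(mu=float(np.log(30.0)), seed=0)
        train = generate_spikes(truth, homogeneous_design(20000), seed=1)
        assert set(np.unique(train.values)).issubset({0, 1})

    def test_determinism(self):
        truth = GroundTruthSpec(mu=float(np.log(20.0)),
                                history_weights=sf.synthetic.REFRACTORY_HISTORY,
                                seed=0)
        a = generate_spikes(truth, homogeneous_design(30000), seed=9)
        b = generate_spikes(truth, homogeneous_design(30000), seed=9)
        assert np.array_equal(a.values, b.values)

    def test_refractory_history_suppresses_short_isis(self):
        hw = np.zeros(10)
        hw[0] = -20.0
        hw[1] = -10.0
        X = homogeneous_design(100_000)
        t_ref = generate_spikes(
            GroundTruthSpec(mu=float(np.log(50.0)), history_weights=hw,
                            seed=0), X, seed=21)
        t_free = generate_spikes(
            GroundTruthSpec(mu=float(np.log(50.0)), seed=0), X, seed=22)

        def short_isi_frac(train, ms=2):
            isi = np.diff(np.flatnonzero(train.values))
            return np.mean(isi < ms) if isi.size else 0.0

        free_frac = short_isi_frac(t_free)
        assert free_frac > 0.0
        assert short_isi_frac(t_ref) < 0.01 * free_frac + 1e-12

    def test_excessive_intensity_warns(self):
        truth = GroundTruthSpec(mu=float(np.log(2000.0)), seed=0)
        with pytest.warns(UserWarning, match="Bernoulli"):
            generate_spikes(truth, homogeneous_design(5000), seed=2)


class TestSession:
    def test_rate_conservation(self, tiny_session):
        for train, lam in zip(tiny_session.spikes, tiny_session.intensity):
            expected = lam.sum()
            se = np.sqrt(np.sum(lam * (1 - lam)))
            assert abs(train.n_spikes - expected) < 3 * se

    def test_members_share_span(self, tiny_session):
        assert tiny_session.duration_s == 60.0
        assert tiny_session.kinematics.n_samples == 60 * 240
        assert tiny_session.lfp[0].n_samples == 60000

    def test_determinism_bit_identical(self):
        truths = sf.population_truths(3, 1, coupling=0.5)
        a = sf.generate_session(truths, 12.0)
        b = sf.generate_session(truths, 12.0)
        assert np.array_equal(a.spikes[0].values, b.spikes[0].values)
        assert np.array_equal(a.lfp[0].samples, b.lfp[0].samples)
        assert np.array_equal(a.kinematics.as_array(), b.kinematics.as_array())


class TestSessionIO:
    def test_roundtrip(self, tmp_path):
        truths = sf.population_truths(5, 2, coupling=0.3)
        ses = sf.generate_session(truths, 10.0)
        sf.save_session(ses, tmp_path / "s1")
        back = sf.load_session(tmp_path / "s1")
        assert len(back.spikes) == 2
        for a, b in zip(ses.spikes, back.spikes):
            assert np.array_equal(a.values, b.values)
        assert np.allclose(back.lfp[0].samples, ses.lfp[0].samples, atol=1e-5)
        assert np.allclose(back.kinematics.as_array(),
                           ses.kinematics.as_array(), atol=1e-5)
        assert back.truth[0].to_dict() == ses.truth[0].to_dict()

    def test_missing_manifest_reports_path(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="manifest"):
            sf.load_session(tmp_path / "nope")
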