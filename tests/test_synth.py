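import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from taskbold.config import (
    ConditionParams,
    IRFSpec,
    NoiseSpec,
    ParameterError,
    ProtocolConfig,
)
from taskbold.synth import (
    apply_amplitude_jitter,
    generate_heart_rate,
    generate_pupil_session,
    generate_session,
    generate_trial_train,
    make_irf,
    make_voxel_meta,
    one_over_f_noise,
    train_to_bold,
    PupilParams,
)


class TestMakeIrf:
    def test_peak_location_variant_a(self):
        spec = IRFSpec.from_variant("A")
        irf = make_irf(spec, 0.15, 30.0)
        assert abs(np.argmax(irf) * 0.15 - spec.peak_delay) <= 0.15
        assert irf.max() == 1.0

    def test_variants_differ(self):
        a = make_irf(IRFSpec.from_variant("A"), 0.15, 30.0)
        b = make_irf(IRFSpec.from_variant("B"), 0.15, 30.0)
        assert np.abs(a - b).max() > 0

    def test_zero_undershoot_is_nonnegative(self):
        # oracle: with zero second term the double gamma is a scaled gamma
        # density, nonnegative by definition
        spec = IRFSpec(undershoot_ratio=0.0)
        irf = make_irf(spec, 0.15, 30.0)
        assert np.all(irf >= 0)

    def test_returns_near_zero_at_end(self):
        irf = make_irf(IRFSpec.from_variant("A"), 0.15, 40.0)
        assert abs(irf[-1]) < 0.01

    def test_nonpositive_dispersion_rejected(self):
        with pytest.raises(ParameterError):
            IRFSpec(peak_disp=0.0)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ParameterError):
            IRFSpec.from_variant("C")


class TestTrialTrain:
    def test_zero_noise_impulses_on_grid(self, protocol, rng):
        train, truth = generate_trial_train(protocol, NoiseSpec(), rng)
        idx = np.flatnonzero(train)
        expected = (np.arange(16) * 15.0 / 0.15).astype(int)
        np.testing.assert_array_equal(idx, expected)
        assert np.allclose(train[idx], train[idx][0])

    def test_sixteen_impulses_per_run(self, protocol, rng):
        train, truth = generate_trial_train(
            protocol, NoiseSpec(temporal_jitter_sd=0.5), rng
        )
        assert len(truth) == 16
        assert train.sum() == pytest.approx(truth["amplitude"].sum())

    def test_jitter_sd_recovered(self):
        # Monte-Carlo check of the generator against its stated distribution
        protocol = ProtocolConfig(trials_per_run=10_000)
        rng = np.random.default_rng(7)
        _, truth = generate_trial_train(
            protocol, NoiseSpec(temporal_jitter_sd=1.0), rng
        )
        assert truth["jitter_s"].std() == pytest.approx(1.0, abs=0.03)

    def test_clamping_recorded(self):
        protocol = ProtocolConfig(trials_per_run=4)
        rng = np.random.default_rng(0)
        # enormous jitter guarantees out-of-run onsets
        _, truth = generate_trial_train(
            protocol, NoiseSpec(temporal_jitter_sd=100.0), rng
        )
        clamped = truth[truth["clamped"]]
        assert len(clamped) > 0
        assert truth["onset_s"].between(0, protocol.run_duration).all()


class TestAmplitudeJitter:
    def test_mean_is_base(self, rng):
        amps = apply_amplitude_jitter(2.0, 1.0, rng, 200_000)
        assert amps.mean() == pytest.approx(2.0, rel=0.01)

    def test_positive_and_bounded(self, rng):
        amps = apply_amplitude_jitter(1.0, 3.0, rng, 10_000)
        assert np.all(amps > 0)
        assert np.all(amps < 2.0)

    def test_zero_sd_is_constant(self, rng):
        amps = apply_amplitude_jitter(1.5, 0.0, rng, 10)
        np.testing.assert_allclose(amps, 1.5)


class TestOneOverFNoise:
    def test_sd_exact(self, rng):
        x = one_over_f_noise(1024, 1.5, rng, sd=0.7)
        assert x.std() == pytest.approx(0.7)

    def test_spectral_slope(self):
        # 1/f contract: average log-power/log-frequency slope is -1
        rng = np.random.default_rng(11)
        n, dt = 2048, 1.5
        freqs = np.fft.rfftfreq(n, dt)[1:]
        psd = np.zeros(len(freqs))
        for _ in range(200):
            x = one_over_f_noise(n, dt, rng)
            psd += np.abs(np.fft.rfft(x)[1:]) ** 2
        psd /= 200
        # one decade within the resolved band
        lo, hi = 0.002, 0.02
        sel = (freqs >= lo) & (freqs <= hi)
        slope = np.polyfit(np.log10(freqs[sel]), np.log10(psd[sel]), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.15)

    def test_zero_mean(self, rng):
        x = one_over_f_noise(512, 1.0, rng)
        assert abs(x.mean()) < 1e-12


class TestGenerateSession:
    def test_noiseless_standard_and_inverted(self, small_protocol,
                                             quiet_conditions, rng):
        meta = make_voxel_meta(6, rng, latency_sd_s=0.0, frac_outside=0.0)
        meta["phase_group"] = ["standard"] * 3 + ["foveal_inverted"] * 3
        session = generate_session(
            small_protocol, quiet_conditions, meta, rng,
            include_physio=False, baseline=0.0, global_sd=0.0,
        )
        run = session.runs[0].data
        template = session.noiseless["high"]
        for v in range(3):
            np.testing.assert_allclose(run[v], template, atol=1e-12)
            np.testing.assert_allclose(run[3 + v], -template, atol=1e-12)

    def test_run_has_160_columns(self, default_session):
        assert default_session.runs[0].data.shape[1] == 160

    def test_seed_reproducibility(self, small_protocol):
        out = []
        for _ in range(2):
            rng = np.random.default_rng(99)
            meta = make_voxel_meta(10, rng)
            out.append(generate_session(small_protocol, None, meta, rng))
        for r1, r2 in zip(out[0].runs, out[1].runs):
            np.testing.assert_array_equal(r1.data, r2.data)
        pd.testing.assert_frame_equal(out[0].ground_truth,
                                      out[1].ground_truth)

    def test_ground_truth_rows(self, default_session, small_protocol):
        n_runs = len(default_session.runs)
        assert len(default_session.ground_truth) == (
            n_runs * small_protocol.trials_per_run
        )

    def test_noiseless_run_is_periodic(self, small_protocol,
                                       quiet_conditions, rng):
        meta = make_voxel_meta(2, rng, latency_sd_s=0.0, frac_outside=0.0)
        meta["phase_group"] = "standard"
        session = generate_session(
            small_protocol, quiet_conditions, meta, rng,
            include_physio=False, baseline=0.0, global_sd=0.0,
        )
        x = session.runs[0].data[0]
        shifted = np.roll(x, small_protocol.trial_volumes)
        # identical except the run edges, where the IRF is still ramping up
        interior = slice(3 * small_protocol.trial_volumes, None)
        np.testing.assert_allclose(x[interior], shifted[interior], atol=1e-9)

    def test_missing_condition_rejected(self, small_protocol, rng):
        meta = make_voxel_meta(4, rng)
        with pytest.raises(ParameterError):
            generate_session(
                small_protocol,
                {"high": ConditionParams()},
                meta, rng,
            )

    def test_pulse_component_is_global(self, small_protocol, rng):
        """With no voxel noise the pulse component is identical everywhere."""
        meta = make_voxel_meta(4, rng, latency_sd_s=0.0, frac_outside=0.0)
        meta["gain"] = 0.0
        spec = NoiseSpec()
        params = {c: ConditionParams(amplitude=0.0, noise=spec)
                  for c in ("high", "low")}
        session = generate_session(small_protocol, params, meta, rng,
                                   include_physio=True, baseline=0.0,
                                   global_sd=0.0)
        run = session.runs[0].data
        for v in range(1, 4):
            np.testing.assert_allclose(run[v], run[0])
        assert run[0].std() > 0


class TestVoxelMeta:
    def test_outside_voxels_flagged(self, rng):
        meta = make_voxel_meta(20, rng, frac_outside=1.0)
        assert (~meta["in_evc"]).sum() == 20
        assert (meta.loc[~meta["in_evc"], "gain"] == 0).all()

    def test_foveal_cutoff(self, rng):
        meta = make_voxel_meta(200, rng)
        evc = meta[meta["in_evc"]]
        inv = evc["phase_group"] == "foveal_inverted"
        assert (evc.loc[inv, "eccentricity_deg"] < 1.0).all()
        assert (evc.loc[~inv, "eccentricity_deg"] >= 1.0).all()

    def test_empty_rejected(self, rng):
        with pytest.raises(ParameterError):
            make_voxel_meta(0, rng)


class TestHeartRate:
    def test_peak_times_increasing(self, small_protocol, rng):
        _, _, peaks = generate_heart_rate(small_protocol, rng)
        assert np.all(np.diff(peaks) > 0)

    def test_constant_rate_intervals(self, small_protocol, rng):
        _, rate, peaks = generate_heart_rate(
            small_protocol, rng, baseline_bpm=60.0, bump_amp_bpm=0.0,
            fluctuation_sd_bpm=0.0,
        )
        np.testing.assert_allclose(rate, 60.0)
        np.testing.assert_allclose(np.diff(peaks), 1.0, atol=1e-6)


class TestPupil:
    def test_constant_at_tonic_without_noise(self, small_protocol, rng):
        params = PupilParams(tonic=4.2, phasic_amplitude=0.0, noise_sd=0.0,
                             blink_rate_hz=0.0)
        traces = generate_pupil_session(
            small_protocol, {"high": params, "low": params}, rng
        )
        np.testing.assert_allclose(traces[0].samples, 4.2)

    def test_sample_count_4s_at_500hz(self, small_protocol, rng):
        traces = generate_pupil_session(
            small_protocol,
            {"high": PupilParams(), "low": PupilParams()},
            rng,
        )
        t = traces[0]
        assert int(round(4.0 * t.fs)) == 2000
        assert len(t.samples) == int(small_protocol.run_duration * t.fs)

    def test_short_trial_rejected(self, rng):
        protocol = ProtocolConfig(trial_len=3.0, tr=1.5)
        with pytest.raises(ParameterError):
            generate_pupil_session(
                protocol, {"high": PupilParams(), "low": PupilParams()}, rng
            )


@settings(max_examples=20, deadline=None)
@given(seed=st.integers(0, 2**31 - 1))
def test_train_determinism_property(seed):
    protocol = ProtocolConfig()
    spec = NoiseSpec(temporal_jitter_sd=0.8, amp_jitter_sd=0.5)
    t1, g1 = generate_trial_train(protocol, spec,
                                  np.random.default_rng(seed))
    t2, g2 = generate_trial_train(protocol, spec,
                                  np.random.default_rng(seed))
    np.testing.assert_array_equal(t1, t2)
    pd.testing.assert_frame_equal(g1, g2)
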