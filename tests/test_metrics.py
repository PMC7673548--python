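import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from taskbold.config import ParameterError
from taskbold.metrics import (
    TrialMatrix,
    amplitude_std,
    bin_and_average,
    cosine_fit,
    fourier_trial_metrics,
    make_eccentricity_bins,
    trial_average,
)
from taskbold.preprocess import InputError


def naive_dft_coefficient(x, k):
    """O(N^2)-style direct DFT sum, independent of np.fft."""
    n = len(x)
    c = 0.0 + 0.0j
    for t in range(n):
        c += x[t] * np.exp(-2j * np.pi * k * t / n)
    return c


def cosine_fit_oracle(x, period):
    """Brute-force oracle: explicit quadrature coefficients at 1/period.

    For an integer number of cycles, cos and sin are orthogonal with energy
    N/2, so the least-squares amplitude is hypot(a, b) with a, b computed by
    direct sums, and r = A * sqrt(N/2) / ||x - mean||.
    """
    n = len(x)
    t = np.arange(n)
    a = 2.0 / n * sum(x[i] * np.cos(2 * np.pi * t[i] / period)
                      for i in range(n))
    b = 2.0 / n * sum(x[i] * np.sin(2 * np.pi * t[i] / period)
                      for i in range(n))
    amp = np.hypot(a, b)
    resid = x - x.mean()
    r = amp * np.sqrt(n / 2.0) / np.sqrt((resid ** 2).sum())
    ph = np.mod(np.arctan2(b, a), 2 * np.pi)
    return r, ph, amp


class TestCosineFit:
    def test_pure_cosine(self):
        t = np.arange(150)
        fit = cosine_fit(np.cos(2 * np.pi * t / 10), 10)
        assert fit.r == pytest.approx(1.0)
        assert fit.ph == pytest.approx(0.0, abs=1e-9)

    def test_lag_convention(self):
        t = np.arange(150)
        fit = cosine_fit(np.cos(2 * np.pi * t / 10 - np.pi / 2), 10)
        assert fit.ph == pytest.approx(np.pi / 2)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            x = rng.normal(size=150)
            fit = cosine_fit(x, 10)
            r_o, ph_o, amp_o = cosine_fit_oracle(x, 10)
            assert fit.r == pytest.approx(r_o, abs=1e-6)
            assert fit.amplitude == pytest.approx(amp_o, abs=1e-9)
            assert np.mod(fit.ph - ph_o, 2 * np.pi) == pytest.approx(
                0.0, abs=1e-9
            ) or np.mod(fit.ph - ph_o, 2 * np.pi) == pytest.approx(
                2 * np.pi, abs=1e-9
            )

    def test_phase_grid_search_agrees(self):
        # second, coarser independent check: best correlation over a dense
        # phase grid occurs at the fitted phase
        rng = np.random.default_rng(3)
        x = rng.normal(size=150)
        fit = cosine_fit(x, 10)
        t = np.arange(150)
        grid = np.linspace(0, 2 * np.pi, 3600, endpoint=False)
        corrs = [np.corrcoef(x, np.cos(2 * np.pi * t / 10 - g))[0, 1]
                 for g in grid]
        best = grid[int(np.argmax(corrs))]
        assert np.cos(best - fit.ph) > 0.9999
        assert max(corrs) == pytest.approx(fit.r, abs=1e-5)

    def test_zero_variance_flagged(self):
        fit = cosine_fit(np.zeros(30), 10)
        assert fit.degenerate
        assert fit.r == 0.0

    def test_affine_invariance(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=100)
        f1 = cosine_fit(x, 10)
        f2 = cosine_fit(3.5 * x + 7.0, 10)
        assert f2.r == pytest.approx(f1.r, abs=1e-12)
        assert f2.ph == pytest.approx(f1.ph, abs=1e-9)

    def test_non_multiple_period_rejected(self):
        with pytest.raises(InputError):
            cosine_fit(np.zeros(101), 10)


class TestTrialAverage:
    def test_identical_trials(self):
        tm = TrialMatrix(values=np.tile(np.arange(10.0), (5, 1)), tr=1.5)
        np.testing.assert_array_equal(trial_average(tm), np.arange(10.0))

    def test_opposite_trials_cancel(self):
        x = np.random.default_rng(0).normal(size=10)
        tm = TrialMatrix(values=np.vstack([x, -x]), tr=1.5)
        np.testing.assert_allclose(trial_average(tm), 0.0, atol=1e-15)

    def test_recovers_noiseless_template(self, quiet_conditions):
        from taskbold.config import ProtocolConfig
        from taskbold.preprocess import concatenate_and_segment
        from taskbold.synth import generate_session, make_voxel_meta

        protocol = ProtocolConfig(runs_per_condition=3)
        rng = np.random.default_rng(21)
        meta = make_voxel_meta(1, rng, latency_sd_s=0.0, frac_outside=0.0)
        meta["phase_group"] = "standard"
        session = generate_session(protocol, quiet_conditions, meta, rng,
                                   include_physio=False, baseline=0.0,
                                   global_sd=0.0)
        from taskbold.preprocess import RunTimeSeries

        runs = [RunTimeSeries(data=r.data[:, 10:], tr=1.5,
                              condition=r.condition)
                for r in session.runs if r.condition == "high"]
        trials = concatenate_and_segment(runs, 10)
        mean_trial = trials.mean(axis=0)
        template = session.noiseless["high"][10:20]
        np.testing.assert_allclose(mean_trial, template, atol=1e-9)


class TestAmplitudeStd:
    def test_zero_vector(self):
        assert amplitude_std(np.zeros(10)) == 0.0

    def test_cosine_matches_enumeration(self):
        x = np.cos(2 * np.pi * np.arange(10) / 10)
        expected = float(np.sqrt(((x - x.mean()) ** 2).mean()))
        assert amplitude_std(x) == pytest.approx(expected, abs=1e-15)

    def test_homogeneity(self):
        x = np.random.default_rng(0).normal(size=10)
        assert amplitude_std(-2.5 * x) == pytest.approx(
            2.5 * amplitude_std(x)
        )


class TestFourierTrialMetrics:
    def test_unit_cosine(self):
        x = np.cos(2 * np.pi * np.arange(10) / 10)
        amp, ph = fourier_trial_metrics(x)
        assert amp == pytest.approx(1.0)
        assert ph == pytest.approx(0.0, abs=1e-12)

    def test_constant_gives_zero(self):
        amp, _ = fourier_trial_metrics(np.full(10, 3.3))
        assert amp == pytest.approx(0.0, abs=1e-14)

    def test_matches_naive_dft(self):
        rng = np.random.default_rng(17)
        for _ in range(5):
            x = rng.normal(size=10)
            amp, ph = fourier_trial_metrics(x)
            c = naive_dft_coefficient(x, 1)
            assert amp == pytest.approx(2 * abs(c) / 10, abs=1e-10)
            assert np.mod(ph + np.angle(c), 2 * np.pi) == pytest.approx(
                0.0, abs=1e-10
            ) or np.mod(ph + np.angle(c), 2 * np.pi) == pytest.approx(
                2 * np.pi, abs=1e-10
            )

    def test_parseval_relation_pure_cosine(self):
        x = 2.0 * np.cos(2 * np.pi * np.arange(10) / 10 - 0.7)
        amp, _ = fourier_trial_metrics(x)
        assert amp == pytest.approx(np.sqrt(2) * amplitude_std(x), rel=1e-9)


class TestEccentricityBins:
    def test_paper_configuration(self):
        bins = make_eccentricity_bins(0.2, 70.0, 12)
        assert bins.n_bins == 12
        assert bins.edges[0] == 0.2
        assert bins.edges[-1] == 70.0

    def test_single_bin(self):
        bins = make_eccentricity_bins(1.0, 2.0, 1)
        np.testing.assert_allclose(bins.edges, [1.0, 2.0])

    def test_constant_edge_ratio(self):
        bins = make_eccentricity_bins(0.2, 70.0, 12)
        ratios = bins.edges[1:] / bins.edges[:-1]
        np.testing.assert_allclose(ratios, 350.0 ** (1 / 12), rtol=1e-12)

    def test_assignment_boundaries(self):
        bins = make_eccentricity_bins(0.2, 70.0, 12)
        idx = bins.assign(np.array([0.2, 70.0, 0.1, 80.0, np.nan]))
        assert idx[0] == 0
        assert idx[1] == 11
        assert idx[2] == -1 and idx[3] == -1 and idx[4] == -1

    def test_invalid_range_rejected(self):
        with pytest.raises(ParameterError):
            make_eccentricity_bins(5.0, 1.0, 3)


class TestBinAndAverage:
    def _session_runs(self, meta, rng, protocol=None, **kw):
        from taskbold.config import ProtocolConfig
        from taskbold.preprocess import preprocess_session
        from taskbold.synth import generate_session

        protocol = protocol or ProtocolConfig(runs_per_condition=2)
        session = generate_session(protocol, None, meta, rng, **kw)
        return session, preprocess_session(session)

    def test_single_bin_equals_roi_average(self, rng):
        from taskbold.preprocess import concatenate_and_segment
        from taskbold.synth import make_voxel_meta

        meta = make_voxel_meta(8, rng, ecc_range=(1.0, 5.0),
                               frac_outside=0.0)
        session, runs = self._session_runs(meta, rng, include_physio=False)
        bins = make_eccentricity_bins(0.5, 10.0, 1)
        per_bin = bin_and_average(runs, meta, bins, "high", 10)
        roi = concatenate_and_segment(
            [r for r in runs if r.condition == "high"], 10
        )
        np.testing.assert_allclose(per_bin[0].values, roi)

    def test_inverted_vs_standard_phase_opposition(self, rng):
        import pandas as pd

        from taskbold.synth import make_voxel_meta

        from taskbold.config import ProtocolConfig

        meta = make_voxel_meta(80, rng)
        session, runs = self._session_runs(
            meta, rng, protocol=ProtocolConfig(runs_per_condition=3),
            include_physio=True,
        )
        evc = meta[meta["in_evc"]]
        inv = evc[evc["phase_group"] == "foveal_inverted"]
        std = evc[evc["phase_group"] == "standard"]
        phases = {}
        for name, group in (("inv", inv), ("std", std)):
            sub = meta.copy()
            sub.loc[~sub["voxel_id"].isin(group["voxel_id"]), "in_evc"] = False
            one_bin = make_eccentricity_bins(0.2, 70.0, 1)
            per_bin = bin_and_average(runs, sub, one_bin, "high", 10)
            mt = trial_average(per_bin[0])
            phases[name] = fourier_trial_metrics(mt)[1]
        diff = np.angle(np.exp(1j * (phases["inv"] - phases["std"])))
        assert abs(abs(diff) - np.pi) < 0.2

    def test_equal_mix_cancels(self, quiet_conditions):
        import pandas as pd

        from taskbold.config import ProtocolConfig
        from taskbold.preprocess import RunTimeSeries
        from taskbold.synth import generate_session, make_voxel_meta

        rng = np.random.default_rng(2)
        meta = make_voxel_meta(4, rng, ecc_range=(1.0, 2.0),
                               latency_sd_s=0.0, frac_outside=0.0)
        meta["phase_group"] = ["standard", "standard",
                               "foveal_inverted", "foveal_inverted"]
        meta["gain"] = 1.0
        session = generate_session(
            ProtocolConfig(runs_per_condition=1), quiet_conditions, meta,
            rng, include_physio=False, baseline=0.0, global_sd=0.0,
        )
        runs = [RunTimeSeries(data=r.data, tr=1.5, condition=r.condition)
                for r in session.runs]
        bins = make_eccentricity_bins(0.5, 3.0, 1)
        per_bin = bin_and_average(runs, meta, bins, "high", 10)
        assert amplitude_std(trial_average(per_bin[0])) < 1e-12

    def test_empty_bin_warned_and_omitted(self, rng):
        from taskbold.synth import make_voxel_meta

        meta = make_voxel_meta(6, rng, ecc_range=(1.0, 2.0),
                               frac_outside=0.0)
        session, runs = self._session_runs(meta, rng, include_physio=False)
        bins = make_eccentricity_bins(0.2, 70.0, 12)
        with pytest.warns(UserWarning, match="empty"):
            per_bin = bin_and_average(runs, meta, bins, "high", 10)
        assert 0 not in per_bin  # nothing below 1 deg


@settings(max_examples=25, deadline=None)
@given(scale=st.floats(0.1, 50.0), shift=st.floats(-10.0, 10.0),
       seed=st.integers(0, 10_000))
def test_cosine_r_affine_invariant_property(scale, shift, seed):
    x = np.random.default_rng(seed).normal(size=60)
    f1 = cosine_fit(x, 10)
    f2 = cosine_fit(scale * x + shift, 10)
    assert f2.r == pytest.approx(f1.r, abs=1e-9)
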