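"""Generative model of trial-entrained BOLD sessions with known ground truth.

Sessions are built on a fine time grid (``ProtocolConfig.fine_dt``): one
impulse per trial, jittered in onset and amplitude, convolved with a
double-gamma impulse response, then downsampled to the TR grid.  Three noise
sources are dissociable by construction: per-voxel 1/f noise ("independent"),
per-trial amplitude jitter (sigmoid-transformed gaussian), and per-trial onset
jitter (gaussian, seconds).  A globally shared, heart-rate-driven component
and white measurement noise can be added on top.  Every random draw is
recorded as ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats

from taskbold.config import (
    CONDITIONS,
    ConditionParams,
    IRFSpec,
    NoiseSpec,
    ParameterError,
    ProtocolConfig,
)

__all__ = [
    "PhysioTrace",
    "PupilParams",
    "PupilTrace",
    "RunData",
    "SessionData",
    "apply_amplitude_jitter",
    "generate_pupil_session",
    "generate_session",
    "generate_trial_train",
    "make_irf",
    "make_voxel_meta",
    "one_over_f_noise",
]


# ---------------------------------------------------------------------------
# impulse response


def make_irf(spec: IRFSpec, fine_dt: float, duration: float = 30.0) -> np.ndarray:
    """Sample a double-gamma impulse response on the fine grid, unit peak.

    The positive lobe is a gamma density with mode at ``spec.peak_delay``;
    the undershoot is a second gamma with mode at ``spec.undershoot_delay``,
    scaled by ``spec.undershoot_ratio`` and subtracted.  The result is
    normalized so its maximum is exactly 1.
    """
    if fine_dt <= 0:
        raise ParameterError("fine_dt must be positive")
    if duration < 2 * spec.peak_delay:
        raise ParameterError("duration must be at least twice the peak delay")
    t = np.arange(0.0, duration, fine_dt)
    # shape a, scale b gamma density has its mode at (a - 1) * b
    a1 = spec.peak_delay / spec.peak_disp + 1.0
    a2 = spec.undershoot_delay / spec.undershoot_disp + 1.0
    peak = stats.gamma.pdf(t, a1, scale=spec.peak_disp)
    peak /= peak.max()
    under = stats.gamma.pdf(t, a2, scale=spec.undershoot_disp)
    under /= under.max()
    kernel = peak - spec.undershoot_ratio * under
    return kernel / kernel.max()


# ---------------------------------------------------------------------------
# noise primitives


def one_over_f_noise(
    n: int, dt: float, rng: np.random.Generator, sd: float = 1.0
) -> np.ndarray:
    """Spectrally synthesized 1/f noise: power ~ 1/f, random phases, DC = 0.

    The series is rescaled to population sd ``sd`` (exactly, unless sd == 0).
    """
    if n < 2:
        raise ParameterError("need at least 2 samples")
    freqs = np.fft.rfftfreq(n, d=dt)
    coefs = np.zeros(len(freqs), dtype=complex)
    k = np.arange(1, len(freqs))
    mag = freqs[k] ** -0.5
    coefs[k] = mag * (rng.standard_normal(len(k)) + 1j * rng.standard_normal(len(k)))
    x = np.fft.irfft(coefs, n=n)
    s = x.std()
    if s > 0:
        x *= sd / s
    return x


def apply_amplitude_jitter(
    base: float, sd: float, rng: np.random.Generator, n: int
) -> np.ndarray:
    """Per-trial amplitudes: ``base * 2 / (1 + exp(-x))``, x ~ N(0, sd).

    The logistic transform keeps amplitudes positive and bounded in
    (0, 2*base) with mean exactly ``base`` (the transform is symmetric about
    1 for symmetric x).
    """
    x = rng.normal(0.0, sd, size=n) if sd > 0 else np.zeros(n)
    return base * 2.0 / (1.0 + np.exp(-x))


# ---------------------------------------------------------------------------
# trial train


def generate_trial_train(
    protocol: ProtocolConfig,
    noise: NoiseSpec,
    rng: np.random.Generator,
    amplitude: float = 1.0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Fine-grid impulse series for one run, plus per-trial ground truth.

    One impulse per trial at ``k * trial_len + jitter_k`` rounded to the fine
    grid, with jitter_k ~ N(0, temporal_jitter_sd) and sigmoid-jittered
    heights.  Onsets pushed outside the run are clamped and flagged.
    """
    n_trials = protocol.trials_per_run
    nominal = np.arange(n_trials) * protocol.trial_len
    if noise.temporal_jitter_sd > 0:
        jitter = rng.normal(0.0, noise.temporal_jitter_sd, size=n_trials)
    else:
        jitter = np.zeros(n_trials)
    onsets = nominal + jitter
    hi = protocol.run_duration - protocol.fine_dt
    clamped = (onsets < 0) | (onsets > hi)
    onsets = np.clip(onsets, 0.0, hi)
    heights = apply_amplitude_jitter(amplitude, noise.amp_jitter_sd, rng, n_trials)

    train = np.zeros(protocol.fine_samples)
    idx = np.rint(onsets / protocol.fine_dt).astype(int)
    idx = np.clip(idx, 0, protocol.fine_samples - 1)
    np.add.at(train, idx, heights)

    truth = pd.DataFrame(
        {
            "trial": np.arange(n_trials),
            "onset_s": onsets,
            "jitter_s": jitter,
            "amplitude": heights,
            "clamped": clamped,
        }
    )
    return train, truth


def train_to_bold(
    train: np.ndarray, irf: np.ndarray, protocol: ProtocolConfig
) -> np.ndarray:
    """Convolve a fine-grid train with the IRF and sample at volume times."""
    fine = signal.fftconvolve(train, irf)[: protocol.fine_samples]
    return fine[:: protocol.fine_per_tr].copy()


# ---------------------------------------------------------------------------
# physiology ground truth


@dataclass
class PhysioTrace:
    """Pulse-oximeter peak events plus generator ground truth for one run."""

    peak_times: np.ndarray
    hr_fs: float = 50.0
    injected_kernel: np.ndarray | None = None
    rate_times: np.ndarray | None = None
    rate_bpm: np.ndarray | None = None
    condition: str | None = None

    def __post_init__(self) -> None:
        pt = np.asarray(self.peak_times, dtype=float)
        if pt.ndim != 1 or (len(pt) > 1 and np.any(np.diff(pt) <= 0)):
            raise ParameterError("peak_times must be 1-D and strictly increasing")
        self.peak_times = pt


def default_pulse_kernel(tr: float, duration: float = 24.0) -> np.ndarray:
    """Ground-truth pulse-to-BOLD kernel sampled on the TR grid.

    A smooth biphasic shape (difference of gammas) in z-units per bpm; the
    exact shape is a free parameter of the generator and is recorded so that
    FIR deconvolution can be validated against it.
    """
    lags = np.arange(0.0, duration + tr / 2, tr)
    k = stats.gamma.pdf(lags, 3.0, scale=1.5) - 0.6 * stats.gamma.pdf(
        lags, 6.0, scale=2.0
    )
    return 0.05 * k / np.abs(k).max()


def generate_heart_rate(
    protocol: ProtocolConfig,
    rng: np.random.Generator,
    baseline_bpm: float = 60.0,
    offset_bpm: float = 0.0,
    bump_amp_bpm: float = 1.0,
    bump_peak_s: float = 2.0,
    bump_sd_s: float = 1.0,
    fluctuation_sd_bpm: float = 0.5,
    hr_fs: float = 50.0,
    notch_task_freq: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Instantaneous rate on a 50 Hz grid and pulse peak times for one run.

    Rate = baseline + condition offset + a trial-locked gaussian bump, plus a
    small smooth fluctuation.  Peak times are found by integrating the
    instantaneous rate and locating integer beat counts.

    ``notch_task_freq`` removes the fluctuation's energy at the task
    frequency and its first harmonics, producing a pulse component that is
    task-unrelated by construction (used by oracle tests of global-signal
    regression).
    """
    t = np.arange(0.0, protocol.run_duration, 1.0 / hr_fs)
    phase_in_trial = np.mod(t, protocol.trial_len)
    bump = np.exp(-0.5 * ((phase_in_trial - bump_peak_s) / bump_sd_s) ** 2)
    rate = baseline_bpm + offset_bpm + bump_amp_bpm * bump
    if fluctuation_sd_bpm > 0:
        slow = one_over_f_noise(len(t), 1.0 / hr_fs, rng, sd=fluctuation_sd_bpm)
        # smooth to sub-0.1 Hz so the fluctuation looks physiological
        win = int(hr_fs * 5)
        slow = np.convolve(slow, np.ones(win) / win, mode="same")
        if notch_task_freq:
            coefs = np.fft.rfft(slow)
            freqs = np.fft.rfftfreq(len(slow), 1.0 / hr_fs)
            f0 = 1.0 / protocol.trial_len
            for harmonic in (1, 2, 3):
                band = np.abs(freqs - harmonic * f0) < 0.35 * f0
                coefs[band] = 0.0
            slow = np.fft.irfft(coefs, n=len(slow))
        rate = rate + slow
    rate = np.maximum(rate, 30.0)

    beats = np.cumsum(rate / 60.0) / hr_fs
    n_beats = int(np.floor(beats[-1]))
    targets = np.arange(1, n_beats + 1, dtype=float)
    peak_times = np.interp(targets, beats, t)
    return t, rate, peak_times


# ---------------------------------------------------------------------------
# pupil ground truth


@dataclass(frozen=True)
class PupilParams:
    """Per-condition pupil generative parameters (arbitrary units)."""

    tonic: float = 5.0
    phasic_amplitude: float = 1.0
    noise_sd: float = 0.05
    blink_rate_hz: float = 0.1


@dataclass
class PupilTrace:
    """500 Hz pupil samples with a blink mask for one run."""

    samples: np.ndarray
    blink_mask: np.ndarray
    trial_onsets: np.ndarray
    fs: float = 500.0
    condition: str | None = None
    ground_truth: dict = field(default_factory=dict)

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.fs


def _phasic_waveform(t: np.ndarray) -> np.ndarray:
    """Unit-peak gamma-shaped dilation, peaking near 1 s, ~0 by 4 s."""
    w = stats.gamma.pdf(t, 3.0, scale=0.5)
    return w / w.max()


def generate_pupil_run(
    protocol: ProtocolConfig,
    params: PupilParams,
    rng: np.random.Generator,
    condition: str | None = None,
    fs: float = 500.0,
) -> PupilTrace:
    """One run of tonic + phasic pupil samples with flagged blink dropouts."""
    n = int(round(protocol.run_duration * fs))
    t = np.arange(n) / fs
    onsets = np.arange(protocol.trials_per_run) * protocol.trial_len
    trace = np.full(n, params.tonic, dtype=float)
    wave_t = np.arange(0.0, protocol.trial_len, 1.0 / fs)
    wave = _phasic_waveform(wave_t)
    for onset in onsets:
        i0 = int(round(onset * fs))
        seg = min(len(wave), n - i0)
        trace[i0 : i0 + seg] += params.phasic_amplitude * wave[:seg]
    if params.noise_sd > 0:
        trace += rng.normal(0.0, params.noise_sd, size=n)

    blink_mask = np.zeros(n, dtype=bool)
    if params.blink_rate_hz > 0:
        n_blinks = rng.poisson(params.blink_rate_hz * protocol.run_duration)
        starts = rng.uniform(0.0, protocol.run_duration, size=n_blinks)
        durs = rng.uniform(0.1, 0.3, size=n_blinks)
        for s, d in zip(starts, durs):
            i0 = int(round(s * fs))
            i1 = min(n, int(round((s + d) * fs)))
            blink_mask[i0:i1] = True

    return PupilTrace(
        samples=trace,
        blink_mask=blink_mask,
        trial_onsets=onsets,
        fs=fs,
        condition=condition,
        ground_truth={
            "tonic": params.tonic,
            "phasic_amplitude": params.phasic_amplitude,
        },
    )


def generate_pupil_session(
    protocol: ProtocolConfig,
    condition_params: dict[str, PupilParams],
    rng: np.random.Generator,
) -> list[PupilTrace]:
    """One PupilTrace per run, alternating conditions as in the scanner."""
    if protocol.trial_len < 4.0:
        raise ParameterError("trial analysis window requires trial_len >= 4 s")
    missing = set(CONDITIONS) - set(condition_params)
    if missing:
        raise ParameterError(f"missing pupil condition params: {sorted(missing)}")
    traces = []
    for _ in range(protocol.runs_per_condition):
        for cond in CONDITIONS:
            traces.append(
                generate_pupil_run(protocol, condition_params[cond], rng, cond)
            )
    return traces


# ---------------------------------------------------------------------------
# voxel metadata and session assembly


def make_voxel_meta(
    n_voxels: int,
    rng: np.random.Generator,
    ecc_range: tuple[float, float] = (0.2, 70.0),
    foveal_cutoff: float = 1.0,
    gain_sd: float = 0.0,
    latency_sd_s: float = 1.0,
    frac_outside: float = 12.0,
) -> pd.DataFrame:
    """Random voxel metadata: log-uniform eccentricity, random ROI and polar
    angle, sign-inverting phase group below ``foveal_cutoff`` degrees.

    ``latency_sd_s`` spreads a fixed per-voxel response latency (gaussian,
    seconds) around zero.  This phase heterogeneity is what lets the
    trial-locked response survive global-signal regression, which removes
    any component shared in proportion across all voxels.

    ``frac_outside`` adds non-task-responsive "scanned volume" voxels
    (``in_evc`` False, roi 0, gain 0).  They contribute to the global mean
    (and therefore to global-signal regression) but are excluded from EVC
    analyses — without such voxels the post-regression whole-volume average
    is identically zero and no ROI statistic can survive; diluting the task
    component of the global mean is also what keeps bin amplitudes near
    intact under regression.
    """
    if n_voxels < 1:
        raise ParameterError("need at least one voxel")
    lo, hi = ecc_range
    ecc = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_voxels))
    theta = rng.uniform(0.0, 2 * np.pi, size=n_voxels)
    roi = rng.integers(1, 4, size=n_voxels)
    gain = np.ones(n_voxels)
    if gain_sd > 0:
        gain = np.abs(rng.normal(1.0, gain_sd, size=n_voxels))
    latency = (rng.normal(0.0, latency_sd_s, size=n_voxels)
               if latency_sd_s > 0 else np.zeros(n_voxels))
    evc = pd.DataFrame(
        {
            "voxel_id": np.arange(n_voxels),
            "eccentricity_deg": ecc,
            "roi": roi,
            "prf_x_deg": ecc * np.cos(theta),
            "prf_y_deg": ecc * np.sin(theta),
            "phase_group": np.where(
                ecc < foveal_cutoff, "foveal_inverted", "standard"
            ),
            "gain": gain,
            "latency_s": latency,
            "in_evc": True,
        }
    )
    if frac_outside <= 0:
        return evc
    n_out = max(1, int(round(frac_outside * n_voxels)))
    outside = pd.DataFrame(
        {
            "voxel_id": n_voxels + np.arange(n_out),
            "eccentricity_deg": np.full(n_out, np.nan),
            "roi": np.zeros(n_out, dtype=int),
            "prf_x_deg": np.full(n_out, np.nan),
            "prf_y_deg": np.full(n_out, np.nan),
            "phase_group": "standard",
            "gain": np.zeros(n_out),
            "latency_s": np.zeros(n_out),
            "in_evc": False,
        }
    )
    return pd.concat([evc, outside], ignore_index=True)


@dataclass
class RunData:
    """One run's voxel-by-volume matrix with its condition label."""

    data: np.ndarray
    condition: str


@dataclass
class SessionData:
    """A full synthetic session with complete generative ground truth."""

    runs: list[RunData]
    voxel_meta: pd.DataFrame
    protocol: ProtocolConfig
    physio: list[PhysioTrace] = field(default_factory=list)
    pupil: list[PupilTrace] | None = None
    ground_truth: pd.DataFrame | None = None
    condition_params: dict[str, ConditionParams] | None = None
    baseline: float = 100.0
    noiseless: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        shapes = {run.data.shape for run in self.runs}
        if len(shapes) > 1:
            raise ParameterError(f"runs have inconsistent shapes: {shapes}")

    @property
    def n_voxels(self) -> int:
        return self.runs[0].data.shape[0]

    def runs_for(self, condition: str) -> list[np.ndarray]:
        return [r.data for r in self.runs if r.condition == condition]


def generate_session(
    protocol: ProtocolConfig,
    condition_params: dict[str, ConditionParams] | None,
    voxel_meta: pd.DataFrame,
    rng: np.random.Generator,
    irf_spec: IRFSpec | None = None,
    include_physio: bool = True,
    include_pupil: bool = False,
    pupil_params: dict[str, PupilParams] | None = None,
    baseline: float = 100.0,
    global_sd: float = 0.2,
    hr_bump_amp_bpm: float = 0.5,
    hr_fluctuation_sd_bpm: float = 0.5,
    hr_notch_task_freq: bool = False,
    pulse_kernel: np.ndarray | None = None,
) -> SessionData:
    """Generate a full session: per-voxel BOLD runs, physio, ground truth.

    Per run: one shared fine-grid trial train (the endogenous response is a
    single session-wide event sequence), convolved with the IRF, downsampled
    to TR, scaled by per-voxel gain, sign-flipped for the foveal_inverted
    group, plus per-voxel 1/f noise, plus two globally shared components
    added identically to every voxel — a pulse-driven series (heart rate
    convolved with the injected kernel) and a respiration-like 1/f
    fluctuation of sd ``global_sd`` — plus white measurement noise and a
    positive baseline.
    """
    from taskbold.config import default_condition_params

    if condition_params is None:
        condition_params = default_condition_params()
    missing = set(CONDITIONS) - set(condition_params)
    if missing:
        raise ParameterError(f"missing condition params: {sorted(missing)}")
    if len(voxel_meta) == 0:
        raise ParameterError("voxel_meta is empty")
    if irf_spec is None:
        irf_spec = IRFSpec.from_variant("A")

    irf = make_irf(irf_spec, protocol.fine_dt)
    n_vox = len(voxel_meta)
    sign = np.where(voxel_meta["phase_group"].to_numpy() == "foveal_inverted", -1.0, 1.0)
    gain = voxel_meta.get("gain", pd.Series(np.ones(n_vox))).to_numpy()
    if "latency_s" in voxel_meta:
        shifts = np.rint(
            voxel_meta["latency_s"].to_numpy() / protocol.fine_dt
        ).astype(int)
    else:
        shifts = np.zeros(n_vox, dtype=int)
    kernel = (default_pulse_kernel(protocol.tr) if pulse_kernel is None
              else np.asarray(pulse_kernel, dtype=float))

    runs: list[RunData] = []
    physio: list[PhysioTrace] = []
    truth_rows = []
    noiseless: dict[str, np.ndarray] = {}

    # noiseless per-condition template at TR resolution (standard voxel, unit gain)
    for cond in CONDITIONS:
        cp = condition_params[cond]
        clean_train, _ = generate_trial_train(
            protocol, NoiseSpec(), rng, amplitude=cp.amplitude
        )
        noiseless[cond] = train_to_bold(clean_train, irf, protocol)

    run_index = 0
    for _ in range(protocol.runs_per_condition):
        for cond in CONDITIONS:
            cp = condition_params[cond]
            train, truth = generate_trial_train(
                protocol, cp.noise, rng, amplitude=cp.amplitude
            )
            fine = signal.fftconvolve(train, irf)[: protocol.fine_samples]
            if np.any(shifts):
                # fixed per-voxel latency, circular on the (periodic) run
                data = np.empty((n_vox, protocol.run_volumes))
                for v in range(n_vox):
                    data[v] = np.roll(fine, shifts[v])[:: protocol.fine_per_tr]
                data *= (gain * sign)[:, None]
            else:
                base_sig = fine[:: protocol.fine_per_tr].copy()
                data = (gain * sign)[:, None] * base_sig[None, :]

            if cp.noise.independent_sd > 0:
                for v in range(n_vox):
                    data[v] += one_over_f_noise(
                        protocol.run_volumes, protocol.tr, rng,
                        sd=cp.noise.independent_sd,
                    )
            if global_sd > 0:
                shared = one_over_f_noise(
                    protocol.run_volumes, protocol.tr, rng, sd=global_sd
                )
                data += shared[None, :]
            if include_physio:
                t50, rate, peaks = generate_heart_rate(
                    protocol, rng, offset_bpm=cp.hr_offset_bpm,
                    bump_amp_bpm=hr_bump_amp_bpm,
                    fluctuation_sd_bpm=hr_fluctuation_sd_bpm,
                    notch_task_freq=hr_notch_task_freq,
                )
                n_per_tr = int(round(50.0 * protocol.tr))
                hr_tr = rate[: protocol.run_volumes * n_per_tr].reshape(
                    protocol.run_volumes, n_per_tr
                ).mean(axis=1)
                pulse = signal.fftconvolve(hr_tr - hr_tr.mean(), kernel)[
                    : protocol.run_volumes
                ]
                data += pulse[None, :]
                physio.append(
                    PhysioTrace(
                        peak_times=peaks,
                        injected_kernel=kernel,
                        rate_times=t50,
                        rate_bpm=rate,
                        condition=cond,
                    )
                )
            if cp.noise.measurement_sd > 0:
                data += rng.normal(
                    0.0, cp.noise.measurement_sd, size=data.shape
                )
            data += baseline
            runs.append(RunData(data=data, condition=cond))
            truth = truth.assign(run=run_index, condition=cond)
            truth_rows.append(truth)
            run_index += 1

    ground_truth = pd.concat(truth_rows, ignore_index=True)

    pupil = None
    if include_pupil:
        if pupil_params is None:
            pupil_params = {
                "high": PupilParams(tonic=5.3, phasic_amplitude=1.5),
                "low": PupilParams(tonic=5.0, phasic_amplitude=1.0),
            }
        pupil = generate_pupil_session(protocol, pupil_params, rng)

    return SessionData(
        runs=runs,
        voxel_meta=voxel_meta,
        protocol=protocol,
        physio=physio,
        pupil=pupil,
        ground_truth=ground_truth,
        condition_params=condition_params,
        baseline=baseline,
        noiseless=noiseless,
    )
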