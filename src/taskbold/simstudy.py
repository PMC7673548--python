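"""Noise-source simulation study: sweep independent noise, amplitude jitter,
and temporal jitter across levels and summarize their signatures.

Each noise source leaves a distinct fingerprint: independent noise produces a
flat time-point-variability curve and no amplitude trend; amplitude jitter a
response-shaped variability curve and no amplitude trend; temporal jitter a
shaped variability curve together with a monotone decline of the mean-trial
amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from taskbold.config import IRFSpec, NoiseSpec, ParameterError, ProtocolConfig
from taskbold.metrics import TrialMatrix, amplitude_std, trial_average
from taskbold.preprocess import InputError
from taskbold.synth import generate_trial_train, make_irf, one_over_f_noise
from taskbold.variability import timepoint_variability

__all__ = [
    "DEFAULT_LEVELS",
    "SweepConfig",
    "SweepResult",
    "classify_noise_signature",
    "flatness_index",
    "highpass_filter",
    "run_sweep",
]

NOISE_TYPES = ("independent", "amplitude", "temporal")

#: Default 6-level grids, level 1 = zero noise, spanning negligible to severe.
#: Temporal jitter is capped at 2 s: beyond ~3 s (a fifth of the trial) the
#: onsets approach uniform placement and the variability curve flattens,
#: destroying the shaped-curve signature that separates it from independent
#: noise.  Independent noise is capped at 1.2 z to keep the positive small-
#: sample bias of the mean-trial amplitude well below Monte-Carlo error.
DEFAULT_LEVELS = {
    "independent": (0.0, 0.1, 0.2, 0.4, 0.8, 1.2),    # z-units
    "amplitude": (0.0, 0.25, 0.5, 1.0, 2.0, 4.0),     # pre-sigmoid sd
    "temporal": (0.0, 0.25, 0.5, 1.0, 1.5, 2.0),      # seconds
}


@dataclass(frozen=True)
class SweepConfig:
    """Configuration of one noise sweep."""

    noise_type: str = "temporal"
    irf_variant: str = "A"
    levels: tuple = None
    runs_per_level: int = 100
    trials_per_run: int = 16
    timepoints: int = 10
    tr: float = 1.5
    highpass_cutoff_hz: float = 1.0 / 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_type not in NOISE_TYPES:
            raise ParameterError(
                f"noise_type must be one of {NOISE_TYPES}, got "
                f"{self.noise_type!r}"
            )
        if self.runs_per_level < 1:
            raise ParameterError("runs_per_level must be >= 1")
        if self.levels is None:
            object.__setattr__(
                self, "levels", DEFAULT_LEVELS[self.noise_type]
            )
        if self.levels[0] != 0:
            raise ParameterError("levels[0] must be zero noise")

    @property
    def protocol(self) -> ProtocolConfig:
        return ProtocolConfig(
            tr=self.tr,
            trial_len=self.timepoints * self.tr,
            trials_per_run=self.trials_per_run,
            fine_dt=self.tr / 10.0,
            seed=self.seed,
        )


@dataclass
class SweepResult:
    """Per-level mean trials, variability curves, and normalized amplitudes."""

    config: SweepConfig
    levels: np.ndarray
    mean_trials: np.ndarray        # (n_levels, timepoints)
    var_curves: np.ndarray         # (n_levels, timepoints)
    norm_amplitude: np.ndarray     # (n_levels,), level 1 == 1 exactly
    raw_amplitude: np.ndarray


def _noise_spec(noise_type: str, level: float) -> NoiseSpec:
    if noise_type == "independent":
        return NoiseSpec(independent_sd=level)
    if noise_type == "amplitude":
        return NoiseSpec(amp_jitter_sd=level)
    return NoiseSpec(temporal_jitter_sd=level)


def highpass_basis(n: int, tr: float, cutoff_hz: float) -> np.ndarray:
    """Intercept + linear trend + DCT-II components below ``cutoff_hz``."""
    t = np.arange(n)
    cols = [np.ones(n), t - t.mean()]
    k_max = int(np.floor(2.0 * n * tr * cutoff_hz))
    for k in range(1, k_max + 1):
        cols.append(np.cos(np.pi * k * (2 * t + 1) / (2 * n)))
    return np.column_stack(cols)


def highpass_filter(data: np.ndarray, tr: float, cutoff_hz: float) -> np.ndarray:
    """Remove DC, linear trend and slow DCT components from each row."""
    arr = np.atleast_2d(np.asarray(data, dtype=float))
    basis = highpass_basis(arr.shape[1], tr, cutoff_hz)
    beta, *_ = np.linalg.lstsq(basis, arr.T, rcond=None)
    resid = arr - (basis @ beta).T
    return resid if data.ndim == 2 else resid[0]


def run_sweep(cfg: SweepConfig) -> SweepResult:
    """Run one noise sweep and summarize each level.

    For each level: generate runs with only the configured noise source,
    drop the first trial, high-pass filter, concatenate, segment into
    trials, then compute the mean trial, the time-point variability curve,
    and the mean-trial amplitude normalized to the zero-noise level.
    """
    protocol = cfg.protocol
    irf = make_irf(IRFSpec.from_variant(cfg.irf_variant), protocol.fine_dt)
    rng = np.random.default_rng(cfg.seed)
    tp = cfg.timepoints

    mean_trials, var_curves, raw_amp = [], [], []
    for level in cfg.levels:
        spec = _noise_spec(cfg.noise_type, level)
        all_trials = []
        for _ in range(cfg.runs_per_level):
            train, _truth = generate_trial_train(protocol, spec, rng)
            fine = signal.fftconvolve(train, irf)[: protocol.fine_samples]
            bold = fine[:: protocol.fine_per_tr].copy()
            if spec.independent_sd > 0:
                bold += one_over_f_noise(
                    protocol.run_volumes, protocol.tr, rng,
                    sd=spec.independent_sd,
                )
            bold = bold[tp:]  # first trial removed
            bold = highpass_filter(bold, protocol.tr, cfg.highpass_cutoff_hz)
            all_trials.append(bold.reshape(-1, tp))
        trials = np.concatenate(all_trials, axis=0)
        tm = TrialMatrix(values=trials, tr=protocol.tr)
        mt = trial_average(tm)
        curve, _ = timepoint_variability(tm)
        mean_trials.append(mt)
        var_curves.append(curve)
        raw_amp.append(amplitude_std(mt))

    raw_amp = np.asarray(raw_amp)
    norm = raw_amp / raw_amp[0]
    norm[0] = 1.0
    return SweepResult(
        config=cfg,
        levels=np.asarray(cfg.levels, dtype=float),
        mean_trials=np.asarray(mean_trials),
        var_curves=np.asarray(var_curves),
        norm_amplitude=norm,
        raw_amplitude=raw_amp,
    )


def flatness_index(variability_curve: np.ndarray) -> float:
    """(max - min) / mean of a variability curve; 0 for a flat curve."""
    c = np.asarray(variability_curve, dtype=float)
    m = c.mean()
    if m <= 0:
        raise InputError("variability curve has nonpositive mean")
    return float((c.max() - c.min()) / m)


def _shape_correlation(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def classify_noise_signature(
    observed_mean_trial: np.ndarray,
    observed_var_curve: np.ndarray,
    observed_amp_change: float,
    reference: dict[str, SweepResult] | None = None,
    reference_seed: int = 12345,
    irf_variant: str = "A",
) -> list[tuple[str, float]]:
    """Rank the three noise sources by similarity to an observed signature.

    Each source is scored by distance between the observed features and that
    source's sweep-derived top-level features: variability-curve flatness,
    variability-curve shape correlation, and fractional amplitude change.
    Lower scores rank first.
    """
    vc = np.asarray(observed_var_curve, dtype=float)
    if vc.size == 0 or np.all(vc < 1e-10):
        raise InputError("observed variability curve is degenerate (all ~0)")
    if reference is None:
        reference = {
            nt: run_sweep(SweepConfig(noise_type=nt, irf_variant=irf_variant,
                                      runs_per_level=50,
                                      seed=reference_seed + i))
            for i, nt in enumerate(NOISE_TYPES)
        }
    obs_flat = flatness_index(vc)

    feats = {
        nt: (
            flatness_index(reference[nt].var_curves[-1]),
            float(reference[nt].norm_amplitude[-1] - 1.0),
            reference[nt].var_curves[-1],
        )
        for nt in NOISE_TYPES
    }
    # normalize flatness/amplitude distances by their spread across the
    # three signatures; shape correlation is down-weighted because it is
    # uninformative (pure noise) when the observed curve is flat
    flat_spread = max(f[0] for f in feats.values()) - min(
        f[0] for f in feats.values()) or 1.0
    amp_spread = max(f[1] for f in feats.values()) - min(
        f[1] for f in feats.values()) or 1.0
    scores = []
    for nt in NOISE_TYPES:
        ref_flat, ref_amp, ref_curve = feats[nt]
        score = (
            abs(obs_flat - ref_flat) / flat_spread
            + abs(observed_amp_change - ref_amp) / amp_spread
            + 0.5 * (1.0 - _shape_correlation(vc, ref_curve))
        )
        scores.append((nt, float(score)))
    return sorted(scores, key=lambda kv: kv[1])
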