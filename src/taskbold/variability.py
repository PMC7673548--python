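"""Trial-to-trial variability statistics: time-point, amplitude, temporal.

Time-point variability is the sd of each time point across trials, averaged
over time points.  Amplitude variability is the sd across trials of per-trial
amplitudes (each trial's population sd).  Temporal variability is the
circular sd of per-trial one-cycle Fourier phases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from taskbold.metrics import TrialMatrix, fourier_trial_metrics
from taskbold.preprocess import InputError

__all__ = [
    "VariabilitySummary",
    "amplitude_variability",
    "circular_std",
    "summarize_variability",
    "temporal_variability",
    "timepoint_variability",
]

#: trials whose one-cycle Fourier amplitude is below this are phase-undefined
ZERO_AMP_THRESHOLD = 1e-12


def timepoint_variability(tm: TrialMatrix) -> tuple[np.ndarray, float]:
    """Per-timepoint sd across trials and its mean over timepoints."""
    if tm.n_trials < 2:
        raise InputError("time-point variability needs >= 2 trials")
    curve = tm.values.std(axis=0)
    return curve, float(curve.mean())


def amplitude_variability(tm: TrialMatrix) -> float:
    """Sd across trials of per-trial amplitudes (population sd per trial)."""
    if tm.n_trials < 2:
        raise InputError("amplitude variability needs >= 2 trials")
    per_trial = tm.values.std(axis=1)
    return float(per_trial.std())


def circular_std(angles: np.ndarray) -> float:
    """Circular standard deviation ``sqrt(-2 ln R)`` in radians.

    R is the resultant length of the unit phasors.  Returns 0 iff all angles
    coincide modulo 2*pi; antipodal/uniform angle sets (R == 0) return the
    +inf sentinel with a warning.
    """
    a = np.asarray(angles, dtype=float)
    if a.size == 0:
        raise InputError("angles must be nonempty")
    resultant = np.abs(np.exp(1j * a).mean())
    if resultant <= 1e-15:
        warnings.warn("resultant length is 0; circular std is undefined "
                      "(+inf sentinel)", stacklevel=2)
        return float("inf")
    if resultant >= 1.0 - 1e-12:  # identical angles up to fp noise
        return 0.0
    return float(np.sqrt(-2.0 * np.log(resultant)))


def temporal_variability(tm: TrialMatrix) -> float:
    """Circular sd of per-trial one-cycle Fourier phases.

    Trials with (near) zero one-cycle amplitude have undefined phase and are
    excluded with a warning.
    """
    if tm.n_trials < 2:
        raise InputError("temporal variability needs >= 2 trials")
    phases = []
    n_excluded = 0
    for trial in tm.values:
        amp, ph = fourier_trial_metrics(trial)
        if amp < ZERO_AMP_THRESHOLD:
            n_excluded += 1
            continue
        phases.append(ph)
    if n_excluded:
        warnings.warn(
            f"excluded {n_excluded} zero-amplitude trials from temporal "
            "variability", stacklevel=2,
        )
    if len(phases) < 2:
        raise InputError("fewer than 2 trials with defined phase")
    return circular_std(np.asarray(phases))


@dataclass(frozen=True)
class VariabilitySummary:
    """The three variability measures for one bin/ROI and condition."""

    timepoint_var_curve: np.ndarray
    timepoint_var_mean: float
    amp_var: float
    temporal_var: float
    n_trials: int
    condition: str | None = None


def summarize_variability(tm: TrialMatrix) -> VariabilitySummary:
    """All three variability measures for one trial matrix."""
    curve, mean = timepoint_variability(tm)
    return VariabilitySummary(
        timepoint_var_curve=curve,
        timepoint_var_mean=mean,
        amp_var=amplitude_variability(tm),
        temporal_var=temporal_variability(tm),
        n_trials=tm.n_trials,
        condition=tm.condition,
    )
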