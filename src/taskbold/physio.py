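"""Cardiac analyses: instantaneous heart rate from pulse peaks, trial-locked
heart-rate responses, and the lagged pulse-to-BOLD kernel."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from taskbold.config import ParameterError, ProtocolConfig
from taskbold.preprocess import InputError

__all__ = [
    "HeartRateTrace",
    "PulseKernel",
    "hr_trial_response",
    "instantaneous_hr",
    "pulse_to_bold_kernel",
    "resample_hr_to_tr",
]


@dataclass
class HeartRateTrace:
    """Piecewise-linear instantaneous heart rate in bpm.

    Each inter-peak interval contributes one anchor at its midpoint with rate
    60 / interval; queries are linearly interpolated between anchors and
    clamped to the end anchors outside them.
    """

    anchor_times: np.ndarray
    anchor_rates: np.ndarray
    t_start: float
    t_end: float

    def sample(self, times: np.ndarray) -> np.ndarray:
        return np.interp(np.asarray(times, dtype=float),
                         self.anchor_times, self.anchor_rates)

    @property
    def mean_rate(self) -> float:
        return float(self.anchor_rates.mean())


def instantaneous_hr(
    peak_times: np.ndarray, artifact_interval_s: float = 0.25
) -> HeartRateTrace:
    """Instantaneous heart rate from pulse-oximeter peak times.

    The reciprocal of each inter-peak interval (in bpm) anchors the rate at
    the interval midpoint; the trace is linear between anchors.  Intervals
    shorter than ``artifact_interval_s`` (240 bpm) are flagged as artifacts.
    """
    t = np.asarray(peak_times, dtype=float)
    if t.ndim != 1 or len(t) < 3:
        raise InputError("need at least 3 strictly increasing peak times")
    intervals = np.diff(t)
    if np.any(intervals <= 0):
        raise InputError("peak times must be strictly increasing")
    short = intervals < artifact_interval_s
    if short.any():
        warnings.warn(
            f"{int(short.sum())} inter-peak intervals shorter than "
            f"{artifact_interval_s} s flagged as artifacts", stacklevel=2,
        )
    mid = t[:-1] + intervals / 2.0
    rates = 60.0 / intervals
    return HeartRateTrace(
        anchor_times=mid, anchor_rates=rates, t_start=float(t[0]),
        t_end=float(t[-1]),
    )


def resample_hr_to_tr(
    trace: HeartRateTrace, tr: float, n_volumes: int, fs: float = 50.0
) -> np.ndarray:
    """Heart rate on the TR grid: average of ``fs``-rate samples per volume."""
    n_sub = int(round(fs * tr))
    t = (np.arange(n_volumes * n_sub) + 0.5) / fs
    fine = trace.sample(t)
    return fine.reshape(n_volumes, n_sub).mean(axis=1)


def hr_trial_response(
    trace: HeartRateTrace, protocol: ProtocolConfig
) -> tuple[np.ndarray, float]:
    """Mean trial-locked heart-rate curve and the run-mean rate.

    The trace must cover the full run; it is resampled to the TR grid,
    segmented into trials, and averaged.
    """
    if trace.t_end < protocol.run_duration - protocol.trial_len:
        raise InputError("heart-rate trace does not cover the run")
    hr = resample_hr_to_tr(trace, protocol.tr, protocol.run_volumes)
    trials = hr.reshape(protocol.trials_per_run, protocol.trial_volumes)
    return trials.mean(axis=0), float(hr.mean())


@dataclass
class PulseKernel:
    """FIR weights mapping lagged heart rate to BOLD, plus their amplitude."""

    lags: np.ndarray
    weights: np.ndarray
    amplitude: float


def pulse_to_bold_kernel(
    bold_series: np.ndarray,
    hr_resampled: np.ndarray,
    tr: float,
    max_lag: float = 30.0,
) -> PulseKernel:
    """Least-squares FIR kernel from mean-centered heart rate to BOLD.

    ``bold_series`` and ``hr_resampled`` must share the TR grid.  The design
    holds heart rate at lags 0 .. max_lag (multiples of tr); only rows with a
    full lag history are used.  Amplitude is the sd of the weights.
    """
    bold = np.asarray(bold_series, dtype=float)
    hr = np.asarray(hr_resampled, dtype=float)
    if bold.shape != hr.shape or bold.ndim != 1:
        raise InputError("bold and heart rate must be aligned 1-D series")
    n_lag = int(round(max_lag / tr))
    if abs(n_lag * tr - max_lag) > 1e-9:
        raise InputError("max_lag must be a multiple of tr")
    if hr.std() == 0:
        raise InputError("constant heart rate: singular design")
    n = len(bold)
    if n <= n_lag + 2:
        raise InputError("series too short for the requested max_lag")
    hr_c = hr - hr.mean()
    bold_c = bold - bold.mean()
    rows = n - n_lag
    design = np.empty((rows, n_lag + 1))
    for j in range(n_lag + 1):
        design[:, j] = hr_c[n_lag - j : n - j]
    weights, *_ = np.linalg.lstsq(design, bold_c[n_lag:], rcond=None)
    lags = np.arange(n_lag + 1) * tr
    return PulseKernel(lags=lags, weights=weights,
                       amplitude=float(weights.std()))
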