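"""Pupillometry: blink removal, trial segmentation, tonic and phasic size."""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np
from scipy.ndimage import binary_dilation

from taskbold.preprocess import InputError
from taskbold.synth import PupilTrace

__all__ = [
    "phasic_size",
    "remove_blinks",
    "segment_pupil_trials",
    "tonic_size",
]


def remove_blinks(trace: PupilTrace, pad_samples: int = 3) -> PupilTrace:
    """Invalidate every blink sample plus ``pad_samples`` on each side.

    Sample values are untouched; only the mask widens.  Padding is clipped at
    the trace bounds.
    """
    if pad_samples < 0:
        raise InputError("pad_samples must be >= 0")
    mask = np.asarray(trace.blink_mask, dtype=bool)
    if pad_samples > 0 and mask.any():
        structure = np.ones(2 * pad_samples + 1, dtype=bool)
        mask = binary_dilation(mask, structure=structure)
    return replace(trace, blink_mask=mask)


def segment_pupil_trials(
    trace: PupilTrace,
    window_ms: float = 4000.0,
    response_flags: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Cut the trace into per-trial windows from each onset.

    Returns ``(samples, valid)`` of shape (trials, window samples); ``valid``
    is False where a (padded) blink was flagged.  Trials whose window extends
    past the trace end are dropped with a warning; trials with a False
    response flag are excluded; fully invalid trials are dropped.
    """
    if window_ms <= 0:
        raise InputError("window_ms must be positive")
    n_win = int(round(window_ms / 1000.0 * trace.fs))
    onsets = np.asarray(trace.trial_onsets, dtype=float)
    if response_flags is not None:
        flags = np.asarray(response_flags, dtype=bool)
        if len(flags) != len(onsets):
            raise InputError("response_flags length must match trial count")
        onsets = onsets[flags]
    rows, valid_rows = [], []
    n_dropped = 0
    for onset in onsets:
        i0 = int(round(onset * trace.fs))
        if i0 + n_win > len(trace.samples):
            n_dropped += 1
            continue
        seg_valid = ~trace.blink_mask[i0 : i0 + n_win]
        if not seg_valid.any():
            n_dropped += 1
            continue
        rows.append(trace.samples[i0 : i0 + n_win])
        valid_rows.append(seg_valid)
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} trials (incomplete window or "
                      "fully invalid)", stacklevel=2)
    if not rows:
        raise InputError("no usable trials")
    return np.asarray(rows), np.asarray(valid_rows)


def tonic_size(
    samples: np.ndarray,
    valid: np.ndarray | None = None,
    fs: float = 500.0,
    baseline_ms: float = 50.0,
) -> float:
    """Mean pupil size over the first ``baseline_ms`` of each trial, averaged
    across trials.  Trials with no valid baseline sample are excluded."""
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    if valid is None:
        valid = np.ones_like(samples, dtype=bool)
    valid = np.atleast_2d(np.asarray(valid, dtype=bool))
    n_base = int(round(baseline_ms / 1000.0 * fs))
    per_trial = []
    for row, v in zip(samples, valid):
        vb = v[:n_base]
        if not vb.any():
            continue
        per_trial.append(row[:n_base][vb].mean())
    if not per_trial:
        raise InputError("no trial has a valid baseline sample")
    return float(np.mean(per_trial))


def phasic_size(
    samples: np.ndarray, valid: np.ndarray | None = None
) -> float:
    """Population sd of each trial's valid samples, averaged across trials."""
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    if valid is None:
        valid = np.ones_like(samples, dtype=bool)
    valid = np.atleast_2d(np.asarray(valid, dtype=bool))
    per_trial = []
    for row, v in zip(samples, valid):
        if v.sum() < 2:
            continue
        per_trial.append(row[v].std())
    if not per_trial:
        raise InputError("no trial has >= 2 valid samples")
    return float(np.mean(per_trial))


def per_trial_tonic(samples: np.ndarray, valid: np.ndarray,
                    fs: float = 500.0, baseline_ms: float = 50.0) -> np.ndarray:
    """Per-trial baseline means (NaN where no valid baseline sample)."""
    n_base = int(round(baseline_ms / 1000.0 * fs))
    out = np.full(samples.shape[0], np.nan)
    for i, (row, v) in enumerate(zip(samples, valid)):
        vb = v[:n_base]
        if vb.any():
            out[i] = row[:n_base][vb].mean()
    return out


def per_trial_phasic(samples: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Per-trial sd of valid samples (NaN where < 2 valid samples)."""
    out = np.full(samples.shape[0], np.nan)
    for i, (row, v) in enumerate(zip(samples, valid)):
        if v.sum() >= 2:
            out[i] = row[v].std()
    return out
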