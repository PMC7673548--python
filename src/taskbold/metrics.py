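"""Per-voxel cosine fitting and trial-averaged amplitude/latency measures.

Phase convention throughout: phase measures response *lag*, so a larger phase
means a later response.  A series ``cos(2*pi*t/period - ph)`` has phase
``ph``; the mapping to seconds is ``ph / (2*pi) * trial_len``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from taskbold.config import ParameterError
from taskbold.preprocess import InputError, RunTimeSeries, concatenate_and_segment

__all__ = [
    "CosineFit",
    "EccBins",
    "TrialMatrix",
    "amplitude_std",
    "bin_and_average",
    "cosine_fit",
    "cosine_fit_voxels",
    "evc_indices",
    "fourier_trial_metrics",
    "make_eccentricity_bins",
    "trial_average",
]


def _wrap_phase(ph: float) -> float:
    """Map to [0, 2*pi), collapsing values within fp noise of 2*pi to 0."""
    ph = float(np.mod(ph, 2 * np.pi))
    return 0.0 if ph > 2 * np.pi - 1e-9 else ph


@dataclass(frozen=True)
class CosineFit:
    """Best-fitting cosine at one period: coherence r, phase, amplitude."""

    r: float
    ph: float
    amplitude: float
    period: float
    degenerate: bool = False


@dataclass
class TrialMatrix:
    """Trials-by-timepoints array for one ROI/bin and condition."""

    values: np.ndarray
    tr: float
    condition: str | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2:
            raise InputError("values must be 2-D (trials x timepoints)")
        self.values = arr

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]


def cosine_fit(series: np.ndarray, period: float) -> CosineFit:
    """Least-squares cosine fit at frequency 1/period (period in samples).

    Fits ``a + b*cos(2*pi*t/period) + c*sin(2*pi*t/period)``; the returned
    phase is the lag of ``A*cos(2*pi*t/period - ph)`` in [0, 2*pi) and r is
    the Pearson correlation between the series and the fitted cosine (always
    >= 0, the unsigned coherence convention).  A zero-variance or zero
    amplitude series returns r = 0 with the degenerate flag set.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < 3:
        raise InputError("series too short for a cosine fit")
    cycles = n / period
    if abs(cycles - round(cycles)) > 1e-9:
        raise InputError(
            f"series length {n} is not an integer multiple of period {period}"
        )
    t = np.arange(n)
    omega = 2 * np.pi / period
    cos_t, sin_t = np.cos(omega * t), np.sin(omega * t)
    design = np.column_stack([np.ones(n), cos_t, sin_t])
    beta, *_ = np.linalg.lstsq(design, x, rcond=None)
    b, c = beta[1], beta[2]
    amplitude = float(np.hypot(b, c))
    if x.std() == 0 or amplitude < 1e-300:
        return CosineFit(r=0.0, ph=np.nan, amplitude=0.0, period=period,
                         degenerate=True)
    ph = _wrap_phase(np.arctan2(c, b))
    fitted = b * cos_t + c * sin_t
    r = float(np.corrcoef(x, fitted)[0, 1])
    # least-squares fit guarantees non-negative correlation; clip fp noise
    r = float(np.clip(r, 0.0, 1.0))
    return CosineFit(r=r, ph=ph, amplitude=amplitude, period=period)


def cosine_fit_voxels(runs: list[RunTimeSeries], period: float) -> np.ndarray:
    """Per-voxel cosine fits on the run-averaged series.

    Runs are averaged (regardless of condition, as for coherence/phase maps)
    and each voxel's time course fitted.  Returns a structured array with
    fields r, ph, amplitude.
    """
    if not runs:
        raise InputError("no runs")
    stack = np.mean([r.data for r in runs], axis=0)
    out = np.zeros(stack.shape[0], dtype=[("r", float), ("ph", float),
                                          ("amplitude", float)])
    for v in range(stack.shape[0]):
        fit = cosine_fit(stack[v], period)
        out[v] = (fit.r, fit.ph, fit.amplitude)
    return out


def trial_average(tm: TrialMatrix) -> np.ndarray:
    """Pointwise mean across trials."""
    if tm.n_trials < 1:
        raise InputError("need at least one trial")
    return tm.values.mean(axis=0)


def amplitude_std(mean_trial: np.ndarray, ddof: int = 0) -> float:
    """Response amplitude: population sd of the mean-trial vector."""
    x = np.asarray(mean_trial, dtype=float)
    if len(x) < 2:
        raise InputError("mean trial must have at least 2 points")
    return float(x.std(ddof=ddof))


def fourier_trial_metrics(mean_trial: np.ndarray) -> tuple[float, float]:
    """Amplitude and lag-phase of the one-cycle-per-trial Fourier component.

    Uses the DFT coefficient at index 1 (index 0 is DC).  Amplitude is scaled
    as ``2|X1|/N`` so a pure cosine of amplitude A returns A; phase follows
    the lag convention (``cos(2*pi*k/N - ph)`` -> ph), mapped to [0, 2*pi).
    """
    x = np.asarray(mean_trial, dtype=float)
    if len(x) < 4:
        raise InputError("mean trial must have at least 4 points")
    coef = np.fft.rfft(x)[1]
    amplitude = float(2.0 * np.abs(coef) / len(x))
    phase = _wrap_phase(-np.angle(coef))
    return amplitude, phase


@dataclass(frozen=True)
class EccBins:
    """Exponentially spaced eccentricity bin edges."""

    edges: np.ndarray

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    def assign(self, eccentricity: np.ndarray) -> np.ndarray:
        """Bin index per voxel; -1 for eccentricities outside the range.

        Bins are half-open [e_i, e_{i+1}) with the last bin closed.
        """
        ecc = np.asarray(eccentricity, dtype=float)
        finite = np.isfinite(ecc)
        idx = np.full(ecc.shape, -1, dtype=int)
        idx[finite] = np.searchsorted(self.edges, ecc[finite], side="right") - 1
        idx[ecc == self.edges[-1]] = self.n_bins - 1
        outside = finite & ((ecc < self.edges[0]) | (ecc > self.edges[-1]))
        if outside.any():
            warnings.warn(
                f"{int(outside.sum())} voxels outside the eccentricity range",
                stacklevel=2,
            )
        idx[outside] = -1
        return idx


def evc_indices(voxel_meta) -> np.ndarray:
    """Indices of analysis (EVC) voxels; all voxels if no ``in_evc`` column."""
    if "in_evc" in voxel_meta:
        return np.flatnonzero(voxel_meta["in_evc"].to_numpy().astype(bool))
    return np.arange(len(voxel_meta))


def make_eccentricity_bins(
    min_deg: float, max_deg: float, n_bins: int
) -> EccBins:
    """Edges ``e_i = min * (max/min) ** (i / n_bins)``: constant edge ratio."""
    if not 0 < min_deg < max_deg:
        raise ParameterError("need 0 < min_deg < max_deg")
    if n_bins < 1:
        raise ParameterError("n_bins must be >= 1")
    i = np.arange(n_bins + 1)
    edges = min_deg * (max_deg / min_deg) ** (i / n_bins)
    edges[0], edges[-1] = min_deg, max_deg  # exact endpoints
    return EccBins(edges=edges)


def bin_and_average(
    runs: list[RunTimeSeries],
    voxel_meta,
    bins: EccBins,
    condition: str,
    trial_volumes: int,
    response_flags: np.ndarray | None = None,
) -> dict[int, TrialMatrix]:
    """Per-bin trial matrices for one condition.

    Voxel series are averaged within each eccentricity bin, concatenated
    across that condition's runs, and segmented into trials.  Empty bins are
    omitted with a warning.
    """
    cond_runs = [r for r in runs if r.condition == condition]
    if not cond_runs:
        raise InputError(f"no runs with condition {condition!r}")
    assignment = bins.assign(voxel_meta["eccentricity_deg"].to_numpy())
    if "in_evc" in voxel_meta:
        assignment[~voxel_meta["in_evc"].to_numpy().astype(bool)] = -1
    out: dict[int, TrialMatrix] = {}
    for b in range(bins.n_bins):
        vox = np.flatnonzero(assignment == b)
        if len(vox) == 0:
            warnings.warn(f"eccentricity bin {b} is empty; omitted",
                          stacklevel=2)
            continue
        trials = concatenate_and_segment(
            cond_runs, trial_volumes, voxel_indices=vox,
            response_flags=response_flags,
        )
        out[b] = TrialMatrix(values=trials, tr=cond_runs[0].tr,
                             condition=condition)
    return out
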