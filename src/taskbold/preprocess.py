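"""fMRI time-series preprocessing: trial discard, normalization, z-scoring,
global-signal regression, concatenation and trial segmentation."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from taskbold.config import ParameterError
from taskbold.synth import SessionData

__all__ = [
    "RunTimeSeries",
    "concatenate_and_segment",
    "discard_first_trial",
    "normalize_run",
    "preprocess_session",
    "regress_global",
]


class InputError(ValueError):
    """Raised when input data violate an operation's precondition."""


@dataclass
class RunTimeSeries:
    """A voxel-by-volume matrix at one stage of the preprocessing chain."""

    data: np.ndarray
    tr: float
    condition: str | None = None
    volumes_discarded: int = 0
    excluded_voxels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim != 2:
            raise InputError("data must be a 2-D voxel-by-volume matrix")
        self.data = arr

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[1]


def discard_first_trial(run: RunTimeSeries, trial_volumes: int) -> RunTimeSeries:
    """Drop the first ``trial_volumes`` columns (magnet-saturation trial)."""
    if trial_volumes < 0:
        raise InputError("trial_volumes must be >= 0")
    if trial_volumes == 0:
        return replace(run)
    if run.n_volumes <= trial_volumes:
        raise InputError(
            f"run has {run.n_volumes} volumes, cannot discard {trial_volumes}"
        )
    return replace(
        run,
        data=run.data[:, trial_volumes:].copy(),
        volumes_discarded=run.volumes_discarded + trial_volumes,
    )


def normalize_run(run: RunTimeSeries, zscore_mode: str = "center-scale") -> RunTimeSeries:
    """Divide each voxel by its temporal mean, then z-score.

    ``zscore_mode``: "center-scale" (subtract mean, divide by sd),
    "divide-only" (divide by sd without centering), or "none" (mean-division
    only).  Voxels with nonpositive mean or zero variance are excluded and
    their indices recorded.
    """
    if zscore_mode not in ("center-scale", "divide-only", "none"):
        raise ParameterError(f"unknown zscore_mode {zscore_mode!r}")
    data = run.data
    means = data.mean(axis=1)
    sds = data.std(axis=1)
    bad = (means <= 0) | (sds == 0) | ~np.isfinite(means) | ~np.isfinite(sds)
    if bad.any():
        warnings.warn(
            f"excluding {int(bad.sum())} voxels with nonpositive mean or "
            "zero variance",
            stacklevel=2,
        )
    keep = ~bad
    out = data[keep] / means[keep][:, None]
    if zscore_mode != "none":
        mu = out.mean(axis=1, keepdims=True)
        sd = out.std(axis=1, keepdims=True)
        if zscore_mode == "center-scale":
            out = (out - mu) / sd
        else:
            out = out / sd
    excluded = list(run.excluded_voxels) + list(np.flatnonzero(bad))
    return replace(run, data=out, excluded_voxels=excluded)


def regress_global(run: RunTimeSeries) -> RunTimeSeries:
    """Remove the whole-volume mean series from every voxel by OLS.

    Residuals are orthogonal to both the intercept and the global mean
    series.  A constant global signal degrades to intercept-only regression
    with a warning.
    """
    if run.n_voxels < 2:
        raise InputError("global-signal regression needs at least 2 voxels")
    g = run.data.mean(axis=0)
    if g.std() == 0:
        warnings.warn("global signal is constant; removing intercept only",
                      stacklevel=2)
        design = np.ones((run.n_volumes, 1))
    else:
        design = np.column_stack([np.ones(run.n_volumes), g])
    beta, *_ = np.linalg.lstsq(design, run.data.T, rcond=None)
    resid = run.data - (design @ beta).T
    return replace(run, data=resid)


def concatenate_and_segment(
    runs: list[RunTimeSeries],
    trial_volumes: int,
    voxel_indices: np.ndarray | None = None,
    response_flags: np.ndarray | None = None,
) -> np.ndarray:
    """Voxel-average, concatenate across runs, and cut into trials.

    Returns a trials-by-timepoints array.  ``voxel_indices`` restricts the
    average to a subset (e.g. an eccentricity bin).  ``response_flags`` is a
    boolean keep-mask over the concatenated trials (no-response trials are
    excluded); absent means keep all.
    """
    if not runs:
        raise InputError("no runs to concatenate")
    if trial_volumes < 1:
        raise InputError("trial_volumes must be >= 1")
    shapes = {r.data.shape for r in runs}
    if len({s[0] for s in shapes}) > 1:
        raise InputError("runs have different voxel counts")
    series = []
    for r in runs:
        if r.n_volumes % trial_volumes != 0:
            raise InputError(
                f"run length {r.n_volumes} is not a multiple of "
                f"trial_volumes {trial_volumes}"
            )
        d = r.data if voxel_indices is None else r.data[voxel_indices]
        if d.shape[0] == 0:
            raise InputError("voxel_indices selects no voxels")
        series.append(d.mean(axis=0))
    cat = np.concatenate(series)
    trials = cat.reshape(-1, trial_volumes)
    if response_flags is not None:
        flags = np.asarray(response_flags, dtype=bool)
        if len(flags) != trials.shape[0]:
            raise InputError(
                f"{len(flags)} response flags for {trials.shape[0]} trials"
            )
        trials = trials[flags]
    return trials


def preprocess_session(
    session: SessionData,
    gsr: bool = True,
    zscore_mode: str = "center-scale",
    discard_volumes: int | None = None,
) -> list[RunTimeSeries]:
    """Apply the full preprocessing chain to every run of a session.

    Order follows the analysis pipeline: discard the first trial, divide by
    the voxel mean, z-score, then regress out the global signal (computed on
    the z-scored data).
    """
    trial_volumes = session.protocol.trial_volumes
    if discard_volumes is None:
        discard_volumes = trial_volumes
    out = []
    for run in session.runs:
        rts = RunTimeSeries(
            data=run.data, tr=session.protocol.tr, condition=run.condition
        )
        rts = discard_first_trial(rts, discard_volumes)
        rts = normalize_run(rts, zscore_mode=zscore_mode)
        if gsr:
            rts = regress_global(rts)
        out.append(rts)
    return out
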