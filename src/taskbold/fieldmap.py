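"""Visual-field projection of per-voxel responses via gaussian pRF weights."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from taskbold.config import ParameterError
from taskbold.preprocess import InputError

__all__ = [
    "FieldMap",
    "complex_response",
    "prf_sigma",
    "project_field",
]

#: floor for near-zero-eccentricity pRFs to avoid degenerate point weights
SIGMA_FLOOR_DEG = 0.05


def prf_sigma(r, roi):
    """pRF size in degrees: ``0.2 * r * roi ** 0.7``, floored at 0.05 deg.

    ``roi`` is 1, 2 or 3 for V1, V2, V3.  Accepts scalars or arrays.
    """
    r_arr = np.asarray(r, dtype=float)
    roi_arr = np.asarray(roi)
    if np.any(r_arr < 0):
        raise ParameterError("eccentricity must be >= 0")
    if not np.all(np.isin(roi_arr, (1, 2, 3))):
        raise ParameterError("roi must be 1 (V1), 2 (V2) or 3 (V3)")
    sigma = np.maximum(0.2 * r_arr * roi_arr.astype(float) ** 0.7,
                       SIGMA_FLOOR_DEG)
    return float(sigma) if np.isscalar(r) and np.isscalar(roi) else sigma


def complex_response(co, ph):
    """``c = co * (cos ph + i sin ph)``: modulus co, argument ph."""
    co_arr = np.asarray(co, dtype=float)
    if np.any(co_arr < 0):
        raise ParameterError("coherence must be >= 0")
    c = co_arr * np.exp(1j * np.asarray(ph, dtype=float))
    return complex(c) if np.isscalar(co) and np.isscalar(ph) else c


@dataclass
class FieldMap:
    """Per-pixel phase and coherence over a square visual-field grid."""

    x: np.ndarray
    y: np.ndarray
    phase: np.ndarray
    coherence: np.ndarray
    empty: np.ndarray


def project_field(
    responses: np.ndarray,
    voxel_meta: pd.DataFrame,
    grid_n: int = 121,
    extent_deg: float = 12.0,
    mode: str = "mean",
) -> FieldMap:
    """Project complex voxel responses into the visual field.

    Per pixel p the voxel responses are combined with gaussian pRF weights
    ``w_v(p) = exp(-|p - center_v|^2 / (2 sigma_v^2))``.  ``mode="mean"``
    (default) normalizes the weights per pixel before combining, so the
    plotted quantity is the phase/modulus of the weighted mean response;
    ``mode="sum"`` uses the raw weighted sum.  Pixels where all weights
    underflow are flagged empty.
    """
    if mode not in ("mean", "sum"):
        raise ParameterError("mode must be 'mean' or 'sum'")
    c = np.asarray(responses, dtype=complex)
    if c.size == 0:
        raise InputError("need at least one voxel")
    if grid_n < 1 or extent_deg <= 0:
        raise ParameterError("grid must be nonempty with positive extent")
    ecc = voxel_meta["eccentricity_deg"].to_numpy()
    roi = voxel_meta["roi"].to_numpy()
    px = voxel_meta["prf_x_deg"].to_numpy()
    py = voxel_meta["prf_y_deg"].to_numpy()
    sigma = prf_sigma(ecc, roi)

    axis = np.linspace(-extent_deg, extent_deg, grid_n)
    gx, gy = np.meshgrid(axis, axis)
    num = np.zeros(gx.shape, dtype=complex)
    wsum = np.zeros(gx.shape)
    for cv, x0, y0, s in zip(c, px, py, sigma):
        w = np.exp(-((gx - x0) ** 2 + (gy - y0) ** 2) / (2.0 * s * s))
        num += w * cv
        wsum += w
    empty = wsum <= 1e-300
    combined = np.zeros_like(num)
    if mode == "mean":
        combined[~empty] = num[~empty] / wsum[~empty]
    else:
        combined[~empty] = num[~empty]
    return FieldMap(
        x=gx,
        y=gy,
        phase=np.mod(np.angle(combined), 2 * np.pi),
        coherence=np.abs(combined),
        empty=empty,
    )
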