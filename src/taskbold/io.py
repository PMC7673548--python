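"""On-disk session bundle: one directory per session.

Run matrices are stored as flat little-endian binary arrays with a JSON text
sidecar header (shape, dtype, TR, condition).  Voxel metadata and per-trial
ground truth are tab-separated tables; physio and pupil traces are
tab-separated ``(time_s, value)`` / ``(time_s, pupil, blink_flag)`` files
following the BIDS physio convention.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from taskbold.config import ConditionParams, NoiseSpec, ProtocolConfig
from taskbold.preprocess import InputError
from taskbold.synth import PhysioTrace, PupilTrace, RunData, SessionData

__all__ = [
    "read_blink_events",
    "read_session",
    "write_session",
]


def _write_run(path_stem: Path, data: np.ndarray, tr: float,
               condition: str) -> None:
    arr = np.ascontiguousarray(data, dtype="<f8")
    arr.tofile(path_stem.with_suffix(".dat"))
    header = {
        "shape": list(arr.shape),
        "dtype": "<f8",
        "tr_s": tr,
        "condition": condition,
        "order": "C",
    }
    path_stem.with_suffix(".hdr").write_text(json.dumps(header, indent=1))


def _read_run(path_stem: Path) -> tuple[np.ndarray, float, str]:
    header = json.loads(path_stem.with_suffix(".hdr").read_text())
    arr = np.fromfile(path_stem.with_suffix(".dat"), dtype=header["dtype"])
    arr = arr.reshape(header["shape"])
    return arr, header["tr_s"], header["condition"]


def _physio_table(trace: PhysioTrace, duration: float) -> pd.DataFrame:
    """50 Hz peak-flag trace: value 1 at the sample containing each peak."""
    fs = trace.hr_fs
    n = int(round(duration * fs))
    flags = np.zeros(n, dtype=int)
    idx = np.rint(trace.peak_times * fs).astype(int)
    idx = idx[(idx >= 0) & (idx < n)]
    flags[idx] = 1
    return pd.DataFrame({"time_s": np.arange(n) / fs, "value": flags})


def write_session(session: SessionData, outdir: str | Path) -> Path:
    """Serialize a session bundle; returns the bundle directory."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    p = session.protocol
    for i, run in enumerate(session.runs):
        _write_run(out / f"run-{i:02d}_bold", run.data, p.tr, run.condition)
    session.voxel_meta.to_csv(out / "voxels.tsv", sep="\t", index=False)
    if session.ground_truth is not None:
        session.ground_truth.to_csv(out / "ground_truth.tsv", sep="\t",
                                    index=False)
    for i, trace in enumerate(session.physio):
        _physio_table(trace, p.run_duration).to_csv(
            out / f"run-{i:02d}_physio.tsv", sep="\t", index=False
        )
    if session.pupil is not None:
        for i, trace in enumerate(session.pupil):
            pd.DataFrame(
                {
                    "time_s": trace.times,
                    "pupil": trace.samples,
                    "blink_flag": trace.blink_mask.astype(int),
                }
            ).to_csv(out / f"run-{i:02d}_pupil.tsv", sep="\t", index=False)

    meta: dict = {
        "protocol": {
            "tr": p.tr,
            "trial_len": p.trial_len,
            "trials_per_run": p.trials_per_run,
            "runs_per_condition": p.runs_per_condition,
            "n_participants": p.n_participants,
            "fine_dt": p.fine_dt,
            "seed": p.seed,
        },
        "baseline": session.baseline,
        "pupil_conditions": (
            [t.condition for t in session.pupil]
            if session.pupil is not None else None
        ),
        "pupil_fs": (session.pupil[0].fs if session.pupil else None),
    }
    if session.condition_params is not None:
        meta["condition_params"] = {
            cond: {
                "amplitude": cp.amplitude,
                "hr_offset_bpm": cp.hr_offset_bpm,
                "noise": {
                    "independent_sd": cp.noise.independent_sd,
                    "amp_jitter_sd": cp.noise.amp_jitter_sd,
                    "temporal_jitter_sd": cp.noise.temporal_jitter_sd,
                    "measurement_sd": cp.noise.measurement_sd,
                },
            }
            for cond, cp in session.condition_params.items()
        }
    if session.physio and session.physio[0].injected_kernel is not None:
        meta["injected_kernel"] = list(session.physio[0].injected_kernel)
    (out / "session.json").write_text(json.dumps(meta, indent=1))
    return out


def read_session(indir: str | Path) -> SessionData:
    """Load a session bundle written by :func:`write_session`."""
    src = Path(indir)
    if not (src / "session.json").exists():
        raise InputError(f"{src} is not a session bundle (no session.json)")
    meta = json.loads((src / "session.json").read_text())
    protocol = ProtocolConfig(**meta["protocol"])

    runs = []
    for stem in sorted(src.glob("run-*_bold.hdr")):
        data, _tr, condition = _read_run(stem.with_suffix(""))
        runs.append(RunData(data=data, condition=condition))
    if not runs:
        raise InputError(f"no run matrices found in {src}")

    voxel_meta = pd.read_csv(src / "voxels.tsv", sep="\t")
    gt_path = src / "ground_truth.tsv"
    ground_truth = pd.read_csv(gt_path, sep="\t") if gt_path.exists() else None

    kernel = (np.asarray(meta["injected_kernel"])
              if "injected_kernel" in meta else None)
    physio = []
    for i, path in enumerate(sorted(src.glob("run-*_physio.tsv"))):
        table = pd.read_csv(path, sep="\t")
        peaks = table.loc[table["value"] > 0, "time_s"].to_numpy()
        physio.append(
            PhysioTrace(
                peak_times=peaks,
                injected_kernel=kernel,
                condition=runs[i].condition if i < len(runs) else None,
            )
        )

    pupil = None
    pupil_paths = sorted(src.glob("run-*_pupil.tsv"))
    if pupil_paths:
        conds = meta.get("pupil_conditions") or [None] * len(pupil_paths)
        fs = meta.get("pupil_fs") or 500.0
        pupil = []
        onsets = np.arange(protocol.trials_per_run) * protocol.trial_len
        for path, cond in zip(pupil_paths, conds):
            table = pd.read_csv(path, sep="\t")
            pupil.append(
                PupilTrace(
                    samples=table["pupil"].to_numpy(),
                    blink_mask=table["blink_flag"].to_numpy().astype(bool),
                    trial_onsets=onsets,
                    fs=fs,
                    condition=cond,
                )
            )

    condition_params = None
    if "condition_params" in meta:
        condition_params = {
            cond: ConditionParams(
                amplitude=cp["amplitude"],
                hr_offset_bpm=cp["hr_offset_bpm"],
                noise=NoiseSpec(**cp["noise"]),
            )
            for cond, cp in meta["condition_params"].items()
        }

    return SessionData(
        runs=runs,
        voxel_meta=voxel_meta,
        protocol=protocol,
        physio=physio,
        pupil=pupil,
        ground_truth=ground_truth,
        condition_params=condition_params,
        baseline=meta.get("baseline", 100.0),
    )


def read_blink_events(path: str | Path, fs: float,
                      n_samples: int) -> np.ndarray:
    """Blink mask from an event-list file with ``start_s``/``end_s`` columns."""
    events = pd.read_csv(path, sep="\t")
    mask = np.zeros(n_samples, dtype=bool)
    for _, row in events.iterrows():
        i0 = max(0, int(round(row["start_s"] * fs)))
        i1 = min(n_samples, int(round(row["end_s"] * fs)))
        mask[i0:i1] = True
    return mask
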