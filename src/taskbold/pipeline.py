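"""End-to-end orchestration: simulate, preprocess, measure, test.

A pipeline run generates one synthetic session per participant, applies the
preprocessing chain, computes response and variability statistics on the
ROI-averaged trial matrices, and runs group label-permutation tests on the
condition contrasts.  A single global seed fans out to independent
per-participant and per-stage substreams so that toggling one stage does not
perturb another's randomness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from taskbold.config import (
    CONDITIONS,
    ConditionParams,
    NoiseSpec,
    ProtocolConfig,
    default_condition_params,
)
from taskbold.metrics import (
    amplitude_std,
    evc_indices,
    fourier_trial_metrics,
    make_eccentricity_bins,
    bin_and_average,
    TrialMatrix,
    trial_average,
)
from taskbold.permutation import group_permutation_test
from taskbold.preprocess import concatenate_and_segment, preprocess_session
from taskbold.pupil import per_trial_phasic, per_trial_tonic, remove_blinks, segment_pupil_trials
from taskbold.synth import SessionData, generate_session, make_voxel_meta
from taskbold.variability import circular_std

__all__ = ["PipelineConfig", "run_pipeline", "STATISTICS", "analyze_session"]


# ---------------------------------------------------------------------------
# trial-set statistics usable in permutation tests

def _stat_amp_std(trials: np.ndarray) -> float:
    return amplitude_std(trials.mean(axis=0))


def _stat_fourier_amp(trials: np.ndarray) -> float:
    return fourier_trial_metrics(trials.mean(axis=0))[0]


def _stat_fourier_phase(trials: np.ndarray) -> float:
    return fourier_trial_metrics(trials.mean(axis=0))[1]


def _stat_tp_var(trials: np.ndarray) -> float:
    return float(trials.std(axis=0).mean())


def _stat_amp_var(trials: np.ndarray) -> float:
    return float(trials.std(axis=1).std())


def _stat_temp_var(trials: np.ndarray) -> float:
    coefs = np.fft.rfft(trials, axis=1)[:, 1]
    phases = np.mod(-np.angle(coefs), 2 * np.pi)
    return circular_std(phases)


STATISTICS = {
    "amp_std": _stat_amp_std,
    "fourier_amp": _stat_fourier_amp,
    "fourier_phase": _stat_fourier_phase,
    "tp_var": _stat_tp_var,
    "amp_var": _stat_amp_var,
    "temp_var": _stat_temp_var,
}


@dataclass
class PipelineConfig:
    """All pipeline parameters; round-trips through ``to_dict``/``from_dict``."""

    seed: int = 0
    n_participants: int = 4
    n_voxels: int = 24
    runs_per_condition: int = 2
    gsr: bool = True
    zscore_mode: str = "center-scale"
    n_perm: int = 1000
    sidedness: str = "one"
    n_bins: int = 12
    ecc_range: tuple = (0.2, 70.0)
    include_physio: bool = False
    include_pupil: bool = False
    condition_params: dict = field(default_factory=default_condition_params)
    out_dir: str | None = None

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items()
             if k != "condition_params"}
        d["ecc_range"] = list(self.ecc_range)
        d["condition_params"] = {
            c: {
                "amplitude": cp.amplitude,
                "hr_offset_bpm": cp.hr_offset_bpm,
                "noise": cp.noise.__dict__.copy(),
            }
            for c, cp in self.condition_params.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "condition_params" in d:
            d["condition_params"] = {
                c: ConditionParams(
                    amplitude=cp.get("amplitude", 1.0),
                    hr_offset_bpm=cp.get("hr_offset_bpm", 0.0),
                    noise=NoiseSpec(**cp.get("noise", {})),
                )
                for c, cp in d["condition_params"].items()
            }
        if "ecc_range" in d:
            d["ecc_range"] = tuple(d["ecc_range"])
        return cls(**d)


def analyze_session(
    session: SessionData,
    gsr: bool = True,
    zscore_mode: str = "center-scale",
) -> dict:
    """Preprocess one session and return per-condition trial matrices and
    scalar statistics for the whole-ROI average."""
    runs = preprocess_session(session, gsr=gsr, zscore_mode=zscore_mode)
    tv = session.protocol.trial_volumes
    roi = evc_indices(session.voxel_meta)
    out: dict = {"conditions": {}}
    all_trials, labels = [], []
    for cond in CONDITIONS:
        cond_runs = [r for r in runs if r.condition == cond]
        trials = concatenate_and_segment(cond_runs, tv, voxel_indices=roi)
        stats = {name: fn(trials) for name, fn in STATISTICS.items()}
        out["conditions"][cond] = {"trials": trials, "stats": stats}
        all_trials.append(trials)
        labels.append(np.full(trials.shape[0], cond == "high"))
    out["trials"] = np.concatenate(all_trials, axis=0)
    out["labels"] = np.concatenate(labels)
    out["preprocessed_runs"] = runs
    return out


def _bin_table(session, runs, n_bins, ecc_range) -> pd.DataFrame:
    bins = make_eccentricity_bins(ecc_range[0], ecc_range[1], n_bins)
    tv = session.protocol.trial_volumes
    rows = []
    for cond in CONDITIONS:
        per_bin = bin_and_average(runs, session.voxel_meta, bins, cond, tv)
        for b, tm in per_bin.items():
            mt = trial_average(tm)
            famp, fph = fourier_trial_metrics(mt)
            rows.append(
                {
                    "bin": b,
                    "ecc_lo_deg": bins.edges[b],
                    "ecc_hi_deg": bins.edges[b + 1],
                    "condition": cond,
                    "n_trials": tm.n_trials,
                    "amplitude_std": amplitude_std(mt),
                    "fourier_amp": famp,
                    "fourier_phase": fph,
                    "tp_var": _stat_tp_var(tm.values),
                    "amp_var": _stat_amp_var(tm.values),
                    "temp_var": _stat_temp_var(tm.values),
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full demo pipeline and return (and optionally write) a report."""
    root = np.random.SeedSequence(cfg.seed)
    participant_seeds, perm_seed, pupil_perm_seed = root.spawn(3)
    p_seeds = participant_seeds.spawn(cfg.n_participants)

    protocol = ProtocolConfig(
        runs_per_condition=cfg.runs_per_condition,
        n_participants=cfg.n_participants,
        seed=cfg.seed,
    )

    per_participant = []
    sessions = []
    bin_tables = []
    pupil_tonic, pupil_phasic = [], []
    hr_values = []
    for i in range(cfg.n_participants):
        rng = np.random.default_rng(p_seeds[i])
        meta = make_voxel_meta(cfg.n_voxels, rng)
        session = generate_session(
            protocol, cfg.condition_params, meta, rng,
            include_physio=cfg.include_physio,
            include_pupil=cfg.include_pupil,
        )
        sessions.append(session)
        res = analyze_session(session, gsr=cfg.gsr,
                              zscore_mode=cfg.zscore_mode)
        per_participant.append((res["trials"], res["labels"]))
        table = _bin_table(session, res["preprocessed_runs"], cfg.n_bins,
                           cfg.ecc_range)
        table.insert(0, "participant", i)
        bin_tables.append(table)

        if cfg.include_pupil and session.pupil is not None:
            t_vals, t_lab, p_vals, p_lab = [], [], [], []
            for trace in session.pupil:
                clean = remove_blinks(trace)
                samples, valid = segment_pupil_trials(clean)
                tonic = per_trial_tonic(samples, valid, fs=trace.fs)
                phasic = per_trial_phasic(samples, valid)
                is_high = trace.condition == "high"
                keep_t = np.isfinite(tonic)
                keep_p = np.isfinite(phasic)
                t_vals.append(tonic[keep_t])
                t_lab.append(np.full(keep_t.sum(), is_high))
                p_vals.append(phasic[keep_p])
                p_lab.append(np.full(keep_p.sum(), is_high))
            pupil_tonic.append(
                (np.concatenate(t_vals), np.concatenate(t_lab)))
            pupil_phasic.append(
                (np.concatenate(p_vals), np.concatenate(p_lab)))

        if cfg.include_physio and session.physio:
            from taskbold.physio import hr_trial_response, instantaneous_hr

            means, labs = [], []
            for trace, run in zip(session.physio, session.runs):
                hr = instantaneous_hr(trace.peak_times)
                _, mean_rate = hr_trial_response(hr, protocol)
                means.append(mean_rate)
                labs.append(run.condition == "high")
            hr_values.append((np.asarray(means), np.asarray(labs)))

    cfg_dict = cfg.to_dict()
    cfg_dict.pop("out_dir", None)  # keep the report path-independent
    report: dict = {
        "config": cfg_dict,
        "n_participants": cfg.n_participants,
        "statistics": {},
    }
    perm_rng = np.random.default_rng(perm_seed)
    for name, fn in STATISTICS.items():
        res = group_permutation_test(
            per_participant, fn, n_perm=cfg.n_perm,
            sidedness=cfg.sidedness, rng=perm_rng,
        )
        report["statistics"][name] = {
            "observed_diff": res.observed_diff,
            "p": res.p,
        }

    pupil_rng = np.random.default_rng(pupil_perm_seed)
    if pupil_tonic:
        for name, data in (("tonic", pupil_tonic), ("phasic", pupil_phasic)):
            res = group_permutation_test(
                data, lambda v: float(np.mean(v)), n_perm=cfg.n_perm,
                sidedness=cfg.sidedness, rng=pupil_rng,
            )
            report["statistics"][name] = {
                "observed_diff": res.observed_diff,
                "p": res.p,
            }
    if hr_values:
        res = group_permutation_test(
            hr_values, lambda v: float(np.mean(v)), n_perm=cfg.n_perm,
            sidedness=cfg.sidedness, rng=pupil_rng,
        )
        report["statistics"]["heart_rate"] = {
            "observed_diff": res.observed_diff,
            "p": res.p,
        }

    bin_table = pd.concat(bin_tables, ignore_index=True)
    report["sign_pattern"] = _sign_pattern(report["statistics"])

    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        bin_table.to_csv(out / "bin_metrics.tsv", sep="\t", index=False)
        (out / "report.json").write_text(
            json.dumps(report, indent=1, sort_keys=True)
        )
    report["bin_table"] = bin_table
    return report


def _sign_pattern(stats: dict) -> dict:
    """Direction of each condition contrast (high minus low)."""
    return {
        name: ("higher_for_high" if v["observed_diff"] > 0
               else "lower_for_high" if v["observed_diff"] < 0
               else "zero")
        for name, v in stats.items()
    }
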