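"""Group-level label-permutation inference for condition differences.

The observed statistic is the across-participant mean of (high - low) for an
arbitrary trial-set statistic.  The null distribution is built by shuffling
condition labels within each participant, recomputing the per-participant
difference, and averaging across participants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats as sps

from taskbold.config import ParameterError
from taskbold.preprocess import InputError

__all__ = ["PermResult", "group_permutation_test", "paired_t_test"]


@dataclass(frozen=True)
class PermResult:
    """Observed group difference, its permutation null, and the p-value."""

    observed_diff: float
    null_diffs: np.ndarray
    p: float
    sidedness: str
    n_perm: int


def _participant_diff(
    values: np.ndarray,
    labels: np.ndarray,
    statistic: Callable[[np.ndarray], float],
    name: str,
) -> float:
    hi = statistic(values[labels])
    lo = statistic(values[~labels])
    diff = hi - lo
    if not np.isfinite(diff):
        raise InputError(f"statistic returned a non-finite value for {name}")
    return diff


def group_permutation_test(
    per_participant_trials: Sequence[tuple[np.ndarray, np.ndarray]],
    statistic: Callable[[np.ndarray], float],
    n_perm: int = 10_000,
    sidedness: str = "two",
    rng: np.random.Generator | None = None,
    add_one: bool = False,
) -> PermResult:
    """Permutation test of a condition difference in a trial-set statistic.

    Parameters
    ----------
    per_participant_trials
        One ``(values, labels)`` pair per participant; ``values`` holds
        trial-level data (first axis = trials; rows may be vectors, e.g. a
        trial's time course) and ``labels`` is boolean with True = high.
    statistic
        Maps one condition's trial subset (array with trials on axis 0) to a
        scalar.
    sidedness
        "one" tests high > low (fraction of null >= observed); "two" doubles
        the smaller tail fraction, capped at 1.
    add_one
        Apply the (b+1)/(n+1) correction instead of the plain fraction.
    """
    if sidedness not in ("one", "two"):
        raise ParameterError("sidedness must be 'one' or 'two'")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is small; p-values will be coarse",
                      stacklevel=2)
    if rng is None:
        rng = np.random.default_rng()
    prepared = []
    for i, (values, labels) in enumerate(per_participant_trials):
        values = np.asarray(values)
        labels = np.asarray(labels, dtype=bool)
        if labels.all() or not labels.any():
            raise InputError(f"participant {i} lacks one of the conditions")
        if len(labels) != values.shape[0]:
            raise InputError(f"participant {i}: label/value length mismatch")
        prepared.append((values, labels))

    observed = float(
        np.mean([
            _participant_diff(v, l, statistic, f"participant {i}")
            for i, (v, l) in enumerate(prepared)
        ])
    )

    null = np.empty(n_perm)
    for p_idx in range(n_perm):
        diffs = []
        for i, (values, labels) in enumerate(prepared):
            perm = rng.permutation(labels)
            diffs.append(
                _participant_diff(values, perm, statistic,
                                  f"participant {i} (perm {p_idx})")
            )
        null[p_idx] = np.mean(diffs)

    ge = int(np.sum(null >= observed))
    le = int(np.sum(null <= observed))
    if add_one:
        frac_ge = (ge + 1) / (n_perm + 1)
        frac_le = (le + 1) / (n_perm + 1)
    else:
        # the fraction of permutations with equal-or-higher differences;
        # floor at 1/n_perm so p is never reported as 0
        frac_ge = max(ge, 1) / n_perm
        frac_le = max(le, 1) / n_perm
    if sidedness == "one":
        p = frac_ge
    else:
        p = min(1.0, 2.0 * min(frac_ge, frac_le))
    return PermResult(observed_diff=observed, null_diffs=null, p=float(p),
                      sidedness=sidedness, n_perm=n_perm)


def paired_t_test(high: np.ndarray, low: np.ndarray) -> tuple[float, float]:
    """Convenience wrapper: paired t test, returns (t, p)."""
    res = sps.ttest_rel(np.asarray(high), np.asarray(low))
    return float(res.statistic), float(res.pvalue)
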