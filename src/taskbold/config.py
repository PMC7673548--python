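"""Configuration types shared across the simulation and analysis modules."""

from __future__ import annotations

from dataclasses import dataclass, field, replace


class ParameterError(ValueError):
    """Raised when a configuration value violates its contract."""


@dataclass(frozen=True)
class ProtocolConfig:
    """Timing parameters of one scanning protocol.

    A run consists of ``trials_per_run`` trials of ``trial_len`` seconds,
    sampled every ``tr`` seconds.  ``fine_dt`` is the grid step used for
    impulse placement and IRF convolution before downsampling to the TR grid;
    sub-TR onset jitter is only representable on this finer grid.
    """

    tr: float = 1.5
    trial_len: float = 15.0
    trials_per_run: int = 16
    runs_per_condition: int = 5
    n_participants: int = 1
    fine_dt: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tr <= 0 or self.trial_len <= 0 or self.fine_dt <= 0:
            raise ParameterError("tr, trial_len and fine_dt must be positive")
        if self.trials_per_run < 1 or self.runs_per_condition < 1:
            raise ParameterError("trial and run counts must be >= 1")
        ratio = self.trial_len / self.tr
        if abs(ratio - round(ratio)) > 1e-9:
            raise ParameterError(
                f"trial_len ({self.trial_len}) must be an integer multiple "
                f"of tr ({self.tr})"
            )
        sub = self.tr / self.fine_dt
        if abs(sub - round(sub)) > 1e-9:
            raise ParameterError(
                f"tr ({self.tr}) must be an integer multiple of fine_dt "
                f"({self.fine_dt})"
            )

    @property
    def trial_volumes(self) -> int:
        """Volumes per trial (10 at defaults)."""
        return round(self.trial_len / self.tr)

    @property
    def run_volumes(self) -> int:
        """Volumes per run (160 at defaults)."""
        return self.trials_per_run * self.trial_volumes

    @property
    def run_duration(self) -> float:
        """Run duration in seconds (240 at defaults)."""
        return self.run_volumes * self.tr

    @property
    def fine_per_tr(self) -> int:
        return round(self.tr / self.fine_dt)

    @property
    def fine_samples(self) -> int:
        return self.run_volumes * self.fine_per_tr


#: Two canonical double-gamma shapes used as the default IRF pair.
_IRF_VARIANTS = {
    "A": dict(peak_delay=5.0, undershoot_delay=15.0, peak_disp=1.0,
              undershoot_disp=1.0, undershoot_ratio=1.0 / 6.0),
    "B": dict(peak_delay=6.0, undershoot_delay=12.0, peak_disp=1.0,
              undershoot_disp=1.0, undershoot_ratio=1.0 / 3.0),
}


@dataclass(frozen=True)
class IRFSpec:
    """Double-gamma impulse response: positive peak minus scaled undershoot."""

    peak_delay: float = 5.0
    undershoot_delay: float = 15.0
    peak_disp: float = 1.0
    undershoot_disp: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    variant: str = "A"

    def __post_init__(self) -> None:
        if self.peak_disp <= 0 or self.undershoot_disp <= 0:
            raise ParameterError("dispersions must be positive")
        if self.peak_delay <= 0 or self.undershoot_delay <= 0:
            raise ParameterError("delays must be positive")
        if self.undershoot_ratio < 0:
            raise ParameterError("undershoot_ratio must be >= 0")

    @classmethod
    def from_variant(cls, variant: str) -> "IRFSpec":
        try:
            params = _IRF_VARIANTS[variant]
        except KeyError:
            raise ParameterError(
                f"unknown IRF variant {variant!r}; choose from "
                f"{sorted(_IRF_VARIANTS)}"
            ) from None
        return cls(variant=variant, **params)


@dataclass(frozen=True)
class NoiseSpec:
    """Scales of the three dissociable noise sources plus sensor noise.

    ``independent_sd`` scales 1/f noise added per voxel, ``amp_jitter_sd`` is
    the pre-sigmoid gaussian sd of per-trial amplitude jitter,
    ``temporal_jitter_sd`` the gaussian sd (seconds) of per-trial onset
    jitter, and ``measurement_sd`` white sensor noise.  All zeros reproduce
    the noiseless template.
    """

    independent_sd: float = 0.0
    amp_jitter_sd: float = 0.0
    temporal_jitter_sd: float = 0.0
    measurement_sd: float = 0.0

    def __post_init__(self) -> None:
        for name in ("independent_sd", "amp_jitter_sd",
                     "temporal_jitter_sd", "measurement_sd"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")

    def with_(self, **kwargs) -> "NoiseSpec":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class ConditionParams:
    """Per-condition generative parameters: response amplitude and noise."""

    amplitude: float = 1.0
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    hr_offset_bpm: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ParameterError("amplitude must be >= 0")


CONDITIONS = ("high", "low")


def default_condition_params() -> dict[str, ConditionParams]:
    """Default reward-condition pair: high reward has a larger response,
    less onset jitter and less amplitude jitter than low reward (the
    generative ground-truth effect; effect sizes are free parameters)."""
    return {
        "high": ConditionParams(
            amplitude=1.2,
            noise=NoiseSpec(independent_sd=0.3, amp_jitter_sd=0.2,
                            temporal_jitter_sd=0.3),
            hr_offset_bpm=3.0,
        ),
        "low": ConditionParams(
            amplitude=1.0,
            noise=NoiseSpec(independent_sd=0.3, amp_jitter_sd=0.4,
                            temporal_jitter_sd=1.5),
            hr_offset_bpm=0.0,
        ),
    }
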