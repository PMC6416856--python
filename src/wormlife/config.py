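"""Run configuration shared across analysis stages."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

#: Days of pre-adult development subtracted from total lifespan to obtain
#: adult lifespan, per species. C. inopinata develops at roughly half the
#: rate of C. elegans, hence the doubled offset.
DEFAULT_ADULT_OFFSETS: dict[str, int] = {
    "C_elegans": 2,
    "C_elegans_fog2": 2,
    "C_inopinata": 4,
}

VALID_SCALINGS = ("all_offspring", "daughters_half")


@dataclass(frozen=True)
class Config:
    """Configuration for a full analysis run.

    Parameters
    ----------
    random_seed : int
        Seed for every stochastic stage (bootstrap resampling, simulation).
    bootstrap_reps : int
        Number of bootstrap resamples for rate-of-increase confidence
        intervals. Must be >= 1.
    adult_offset_days : mapping of species -> int
        Development time (days from egg lay to adulthood) subtracted from
        total lifespan when computing adult lifespan.
    offspring_scaling : {"all_offspring", "daughters_half"}
        Whether age-specific fecundity m_x counts all offspring or is halved
        to count daughters only (relevant for gonochoristic cohorts with a
        1:1 sex ratio).
    ci_level : float
        Confidence level for intervals, in (0, 1).
    """

    random_seed: int = 0
    bootstrap_reps: int = 1000
    adult_offset_days: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_ADULT_OFFSETS)
    )
    offspring_scaling: str = "all_offspring"
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if self.bootstrap_reps < 1:
            raise ValueError("bootstrap_reps must be >= 1")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must lie in (0, 1)")
        if self.offspring_scaling not in VALID_SCALINGS:
            raise ValueError(
                f"offspring_scaling must be one of {VALID_SCALINGS}, "
                f"got {self.offspring_scaling!r}"
            )
        for species, offset in self.adult_offset_days.items():
            if offset < 0:
                raise ValueError(
                    f"adult offset for {species!r} must be nonnegative"
                )

    def with_overrides(self, **kwargs) -> "Config":
        return replace(self, **kwargs)


def load_config(path: str | Path, **overrides) -> Config:
    """Load a Config from a flat ``key = value`` file (TOML-compatible).

    Unknown keys raise. ``adult_offset_days`` entries are given as
    ``adult_offset.<species> = <int>`` lines. CLI overrides win.
    """
    import tomllib

    raw = Path(path).read_bytes()
    data = tomllib.loads(raw.decode())
    offsets = dict(DEFAULT_ADULT_OFFSETS)
    offsets.update({k: int(v) for k, v in data.pop("adult_offset", {}).items()})
    known = {"random_seed", "bootstrap_reps", "offspring_scaling", "ci_level"}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    data["adult_offset_days"] = offsets
    data.update(overrides)
    return Config(**data)
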