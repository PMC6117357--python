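"""Experimental design for the duration discrimination and reproduction tasks.

The design mirrors a two-task psychophysics protocol: a two-interval duration
discrimination task against a fixed standard, and a duration reproduction
task, both run for visual (V), auditory (A) and audiovisual (AV) stimuli
under externally added sensory noise.  Noise enters only as a condition
label (``high`` / ``low`` / ``no``); its physical calibration is outside the
scope of this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

MODALITIES = ("V", "A", "AV")
NOISE_LEVELS = ("high", "low", "no")
#: placeholder for a noise slot that does not apply to a unisensory condition
NOISE_NA = "-"

STANDARD_MS = 640.0
DURATION_RANGE_MS = (450.0, 900.0)


@dataclass(frozen=True)
class Condition:
    """A stimulus condition: modality plus the per-modality noise levels."""

    modality: str
    vis_noise: str = NOISE_NA
    aud_noise: str = NOISE_NA

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}, got {self.modality!r}")
        if self.modality in ("V", "AV") and self.vis_noise not in NOISE_LEVELS:
            raise ValueError(f"vis_noise must be one of {NOISE_LEVELS} for modality {self.modality}")
        if self.modality in ("A", "AV") and self.aud_noise not in NOISE_LEVELS:
            raise ValueError(f"aud_noise must be one of {NOISE_LEVELS} for modality {self.modality}")
        if self.modality == "V" and self.aud_noise != NOISE_NA:
            raise ValueError("aud_noise does not apply to a visual-only condition")
        if self.modality == "A" and self.vis_noise != NOISE_NA:
            raise ValueError("vis_noise does not apply to an auditory-only condition")

    @property
    def key(self) -> str:
        if self.modality == "V":
            return f"V:{self.vis_noise}"
        if self.modality == "A":
            return f"A:{self.aud_noise}"
        return f"AV:{self.vis_noise}:{self.aud_noise}"

    @classmethod
    def from_key(cls, key: str) -> "Condition":
        parts = key.split(":")
        if parts[0] == "V" and len(parts) == 2:
            return cls("V", vis_noise=parts[1])
        if parts[0] == "A" and len(parts) == 2:
            return cls("A", aud_noise=parts[1])
        if parts[0] == "AV" and len(parts) == 3:
            return cls("AV", vis_noise=parts[1], aud_noise=parts[2])
        raise ValueError(f"unparseable condition key {key!r}")

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.key


#: the three audiovisual noise combinations used in the protocol:
#: equivalently noisy, vision-noisier, audition-noisier
AV_COMBINATIONS = (("high", "high"), ("high", "low"), ("low", "high"))


def default_conditions() -> tuple[Condition, ...]:
    """All 6 unisensory conditions plus the 3 audiovisual combinations."""
    conds = [Condition("V", vis_noise=n) for n in ("no", "low", "high")]
    conds += [Condition("A", aud_noise=n) for n in ("no", "low", "high")]
    conds += [Condition("AV", vis_noise=v, aud_noise=a) for v, a in AV_COMBINATIONS]
    return tuple(conds)


@dataclass(frozen=True)
class DesignSpec:
    """Full design: duration levels, repetitions and condition list.

    ``mean_duration_ms`` is the mean of the presented reproduction levels,
    i.e. the center of the stimulus distribution that a prior-forming
    observer would learn.
    """

    standard_ms: float
    comparison_levels_ms: tuple[float, ...]
    reproduction_levels_ms: tuple[float, ...]
    reps_discrimination: int
    reps_reproduction: int
    conditions: tuple[Condition, ...]
    mean_kind: str = "arithmetic"

    def __post_init__(self) -> None:
        if self.standard_ms <= 0:
            raise ValueError("standard_ms must be positive")
        for name, levels in (
            ("comparison_levels_ms", self.comparison_levels_ms),
            ("reproduction_levels_ms", self.reproduction_levels_ms),
        ):
            arr = np.asarray(levels, dtype=float)
            if arr.size < 2:
                raise ValueError(f"{name} needs at least 2 levels")
            if not np.all(np.diff(arr) > 0):
                raise ValueError(f"{name} must be strictly increasing")
            lo, hi = DURATION_RANGE_MS
            if arr[0] < lo or arr[-1] > hi:
                raise ValueError(f"{name} must lie within [{lo:g}, {hi:g}] ms")
        if self.reps_discrimination <= 0:
            raise ValueError("reps_discrimination must be positive")
        if self.reps_reproduction <= 0:
            raise ValueError("reps_reproduction must be positive")
        if self.mean_kind not in ("arithmetic", "geometric"):
            raise ValueError("mean_kind must be 'arithmetic' or 'geometric'")
        if not self.conditions:
            raise ValueError("conditions must be non-empty")

    @property
    def mean_duration_ms(self) -> float:
        levels = np.asarray(self.reproduction_levels_ms, dtype=float)
        if self.mean_kind == "geometric":
            return float(np.exp(np.mean(np.log(levels))))
        return float(np.mean(levels))

    def condition(self, cond: "Condition | str") -> Condition:
        """Resolve a condition or key to the design's condition instance."""
        if isinstance(cond, str):
            cond = Condition.from_key(cond)
        if cond not in self.conditions:
            known = ", ".join(c.key for c in self.conditions)
            raise ValueError(f"unknown condition {cond.key!r}; known conditions: {known}")
        return cond

    def condition_index(self, cond: "Condition | str") -> int:
        return self.conditions.index(self.condition(cond))


def make_design(
    n_levels: int = 7,
    duration_range_ms: Sequence[float] = DURATION_RANGE_MS,
    standard_ms: float = STANDARD_MS,
    reps_discrimination: int = 24,
    reps_reproduction: int = 60,
    conditions: Iterable[Condition] | None = None,
    mean_kind: str = "arithmetic",
) -> DesignSpec:
    """Build a :class:`DesignSpec` with log-spaced duration levels.

    Defaults reproduce the protocol: a 640 ms standard, comparison and
    reproduction durations log-spaced over 450-900 ms, 24 repetitions per
    comparison level and 60 per reproduction level, and all 6 unisensory
    plus 3 audiovisual noise conditions.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be at least 2")
    lo, hi = float(duration_range_ms[0]), float(duration_range_ms[1])
    if not (DURATION_RANGE_MS[0] <= lo < hi <= DURATION_RANGE_MS[1]):
        raise ValueError(
            f"duration_range_ms must satisfy {DURATION_RANGE_MS[0]:g} <= lo < hi <= {DURATION_RANGE_MS[1]:g}"
        )
    levels = tuple(float(x) for x in np.geomspace(lo, hi, n_levels))
    conds = tuple(conditions) if conditions is not None else default_conditions()
    return DesignSpec(
        standard_ms=float(standard_ms),
        comparison_levels_ms=levels,
        reproduction_levels_ms=levels,
        reps_discrimination=int(reps_discrimination),
        reps_reproduction=int(reps_reproduction),
        conditions=conds,
        mean_kind=mean_kind,
    )
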