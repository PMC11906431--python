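"""Two-phase potentiation gain model and genotype/drug condition presets.

The response gain of a potentiated component is

    g = 1 + s * [ (C - 1) * (1 - exp(-(day - 1) / tau_d))
                + (R - 1) * (1 - exp(-i_eff / tau_i)) ]

where ``C`` is the cumulative ceiling (contra- or ipsilateral), ``tau_d``
the day constant of the cumulative phase (plateau by about day 4 with the
defaults), ``R`` the rapid ceiling, ``tau_i`` the rapid trial constant and
``s`` the condition's plasticity scale.  ``i_eff`` is the effective trial
index the rapid phase runs on: the whole-experiment presentation count
when rapid potentiation persists across sessions (the default), else the
within-session index.  N1 reflects feed-forward geniculate input and never
potentiates; its gain is exactly 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from ..errors import InvalidParameterError

POTENTIATED_DEFAULT = ("P1", "N2", "P2", "N3")


@dataclass
class GainModel:
    cumulative_max_contra: float = 1.5
    cumulative_max_ipsi: float = 1.25
    cumulative_tau_days: float = 1.5
    rapid_max: float = 2.5
    rapid_tau_trials: float = 20.0
    rapid_persist: bool = True
    plasticity_scale: float = 1.0
    potentiated_components: tuple[str, ...] = POTENTIATED_DEFAULT

    def __post_init__(self) -> None:
        if "N1" in self.potentiated_components:
            raise InvalidParameterError("N1 never potentiates")
        if self.cumulative_max_contra < 1 or self.cumulative_max_ipsi < 1 or self.rapid_max < 1:
            raise InvalidParameterError("gain ceilings must be >= 1")
        if not 0.0 <= self.plasticity_scale <= 1.0:
            raise InvalidParameterError("plasticity_scale must lie in [0, 1]")
        if self.cumulative_tau_days <= 0 or self.rapid_tau_trials <= 0:
            raise InvalidParameterError("time constants must be positive")


@dataclass(frozen=True)
class ConditionPreset:
    """Genotype or pharmacology condition, as a plasticity scale."""

    name: str
    plasticity_scale: float


CONDITIONS: dict[str, ConditionPreset] = {
    "WT": ConditionPreset("WT", 1.0),
    "NR2A_het": ConditionPreset("NR2A_het", 0.5),
    "NR2A_KO": ConditionPreset("NR2A_KO", 0.0),
    "MK801": ConditionPreset("MK801", 0.0),
}


def get_condition(name: str) -> ConditionPreset:
    if name not in CONDITIONS:
        raise InvalidParameterError(f"unknown condition {name!r}; expected one of {list(CONDITIONS)}")
    return CONDITIONS[name]


def apply_condition(model: GainModel, condition: str | ConditionPreset) -> GainModel:
    """Return a copy of ``model`` with the condition's plasticity scale
    applied multiplicatively (so a model with scale 0 stays off under WT)."""
    preset = get_condition(condition) if isinstance(condition, str) else condition
    from dataclasses import replace

    return replace(model, plasticity_scale=model.plasticity_scale * preset.plasticity_scale)


def compute_gain(
    model: GainModel, component: str, day: int, trial_index: int, pathway: str
) -> float:
    """Closed-form two-phase gain for one component at one stimulation.

    ``trial_index`` is the effective rapid index ``i_eff`` (the caller's
    schedule bookkeeping supplies the cumulative count under persistence).
    """
    if day < 1 or trial_index < 0:
        raise InvalidParameterError("day must be >= 1 and trial_index >= 0")
    if pathway not in ("contra", "ipsi"):
        raise InvalidParameterError(f"pathway must be contra or ipsi, got {pathway!r}")
    if component == "N1" or component not in model.potentiated_components:
        return 1.0
    c_max = model.cumulative_max_contra if pathway == "contra" else model.cumulative_max_ipsi
    cumulative = (c_max - 1.0) * (1.0 - math.exp(-(day - 1) / model.cumulative_tau_days))
    rapid = (model.rapid_max - 1.0) * (1.0 - math.exp(-trial_index / model.rapid_tau_trials))
    return 1.0 + model.plasticity_scale * (cumulative + rapid)
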