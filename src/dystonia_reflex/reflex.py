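"""Proprioceptive reflex pathways and aberrant-reflex scenarios.

Three pathways excite each muscle's contractile element, each read at its own
neural latency: muscle-spindle position feedback (type II afferents, responds
to lengthening only), muscle-spindle velocity feedback (type Ia, lengthening
only) and Golgi-tendon-organ force feedback (type Ib, bidirectional because
active force is).  All pathways are modelled as (over-)excitatory, reflecting
the reduced central inhibition ("disinhibition") reported in CRPS: in
particular the Ib force pathway, physiologically autogenic-inhibitory, enters
here with positive sign.

A normal (reference) configuration is transformed into an aberrant one by one
of three scenarios, applied to one pathway at a time:

* ``increased_sensitivity`` — gain multiplied in BOTH muscles (hyperreflexia);
* ``imbalanced_sensitivity`` — gain multiplied in the agonist only;
* ``imbalanced_offset`` — a tonic offset added to the agonist's pathway only.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, asdict
from typing import Mapping

__all__ = [
    "SCENARIOS",
    "PATHWAYS",
    "MUSCLES",
    "MuscleReflex",
    "ReflexConfig",
    "ScenarioSpec",
    "spindle_position_signal",
    "spindle_velocity_signal",
    "gto_force_signal",
    "reflex_excitation",
    "apply_scenario",
]

SCENARIOS = ("reference", "increased_sensitivity", "imbalanced_sensitivity",
             "imbalanced_offset")
PATHWAYS = ("position", "velocity", "force")
MUSCLES = ("flexor", "extensor")

# pathway name -> (gain field, offset field, delay field)
_PATHWAY_FIELDS = {
    "position": ("k_p", "e_p", "tau_p"),
    "velocity": ("k_v", "e_v", "tau_v"),
    "force": ("k_f", "e_f", "tau_f"),
}


@dataclass(frozen=True)
class MuscleReflex:
    """Feedback gains, tonic offsets and latencies for one muscle.

    Gains are excitation per normalised signal (stretch in optimal CE
    lengths, stretch rate in optimal lengths per second, force as a fraction
    of f_max); offsets are tonic excitation added downstream of the gain.
    """

    k_p: float = 0.0
    k_v: float = 0.0
    k_f: float = 0.0
    e_p: float = 0.0
    e_v: float = 0.0
    e_f: float = 0.0
    tau_p: float = 0.03
    tau_v: float = 0.03
    tau_f: float = 0.03

    def __post_init__(self) -> None:
        for name in ("k_p", "k_v", "k_f", "e_p", "e_v", "e_f"):
            if getattr(self, name) < 0:
                raise ValueError(f"MuscleReflex.{name} must be >= 0 "
                                 "(all pathways are excitatory)")
        for name in ("tau_p", "tau_v", "tau_f"):
            if not getattr(self, name) > 0:
                raise ValueError(f"MuscleReflex.{name} must be > 0")


@dataclass(frozen=True)
class ReflexConfig:
    """Reflex configuration of the antagonistic pair."""

    flexor: MuscleReflex
    extensor: MuscleReflex

    def entry(self, muscle: str) -> MuscleReflex:
        if muscle not in MUSCLES:
            raise ValueError(f"unknown muscle {muscle!r}")
        return getattr(self, muscle)

    def min_delay(self) -> float:
        return min(getattr(m, f) for m in (self.flexor, self.extensor)
                   for f in ("tau_p", "tau_v", "tau_f"))

    def to_dict(self) -> dict:
        return {"flexor": asdict(self.flexor), "extensor": asdict(self.extensor)}

    @classmethod
    def from_dict(cls, d: Mapping) -> "ReflexConfig":
        return cls(flexor=MuscleReflex(**d["flexor"]),
                   extensor=MuscleReflex(**d["extensor"]))


@dataclass(frozen=True)
class ScenarioSpec:
    """Which aberration is applied to which pathway, and how strongly.

    ``magnitude`` is a gain multiplier (> 1) for the sensitivity scenarios and
    an offset level (> 0, excitation units) for the offset scenario; the
    reference scenario ignores pathway and magnitude.
    """

    scenario: str = "reference"
    pathway: str | None = None
    magnitude: float | None = None
    agonist: str = "flexor"

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(
                f"unknown scenario {self.scenario!r}; choose from {SCENARIOS}")
        if self.agonist not in MUSCLES:
            raise ValueError(f"unknown agonist {self.agonist!r}")
        if self.scenario == "reference":
            return
        if self.pathway not in PATHWAYS:
            raise ValueError(
                f"unknown pathway {self.pathway!r}; choose from {PATHWAYS}")
        if self.magnitude is None:
            raise ValueError("aberrant scenarios require a magnitude")
        if "sensitivity" in self.scenario and not self.magnitude >= 1:
            raise ValueError("sensitivity magnitude must be >= 1 "
                             "(1 is the identity)")
        if self.scenario == "imbalanced_offset" and not self.magnitude > 0:
            raise ValueError("offset magnitude must be > 0")

    @property
    def label(self) -> str:
        if self.scenario == "reference":
            return "reference"
        return f"{self.scenario}:{self.pathway}"

    def to_dict(self) -> dict:
        return asdict(self)


def spindle_position_signal(stretch: float) -> float:
    """Type II spindle output: normalised stretch, lengthening only."""
    return stretch if stretch > 0.0 else 0.0


def spindle_velocity_signal(stretch_rate: float) -> float:
    """Type Ia spindle output: normalised stretch rate, lengthening only."""
    return stretch_rate if stretch_rate > 0.0 else 0.0


def gto_force_signal(force: float, f_max: float) -> float:
    """Type Ib (GTO) output: force normalised by f_max, bidirectional.

    The GTO signals active force whatever the direction of length change, so
    no rectification is applied (force itself is non-negative).
    """
    if force < 0:
        raise ValueError("muscle force must be >= 0")
    return force / f_max


def reflex_excitation(delayed_stretch: float, delayed_rate: float,
                      delayed_force: float, cfg: MuscleReflex) -> float:
    """Total reflexive excitation of one muscle from its delayed afferents.

    Each pathway contributes gain * rectified signal + tonic offset; the
    caller adds voluntary drive and clips total excitation to [0, 1].
    """
    return (cfg.k_p * spindle_position_signal(delayed_stretch) + cfg.e_p
            + cfg.k_v * spindle_velocity_signal(delayed_rate) + cfg.e_v
            + cfg.k_f * delayed_force + cfg.e_f)


def apply_scenario(base: ReflexConfig, spec: ScenarioSpec) -> ReflexConfig:
    """Return the aberrant configuration for ``spec``; ``base`` is untouched."""
    if spec.scenario == "reference":
        return base
    k_field, e_field, _ = _PATHWAY_FIELDS[spec.pathway]

    def scale(entry: MuscleReflex) -> MuscleReflex:
        return replace(entry, **{k_field: getattr(entry, k_field) * spec.magnitude})

    if spec.scenario == "increased_sensitivity":
        return ReflexConfig(flexor=scale(base.flexor),
                            extensor=scale(base.extensor))
    if spec.scenario == "imbalanced_sensitivity":
        return replace(base, **{spec.agonist: scale(base.entry(spec.agonist))})
    # imbalanced_offset: tonic offset in the agonist's pathway only
    aberrant = replace(base.entry(spec.agonist), **{e_field: spec.magnitude})
    return replace(base, **{spec.agonist: aberrant})
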