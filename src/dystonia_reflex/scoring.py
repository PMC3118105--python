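"""Quantitative scoring of the five clinical dystonia characteristics.

Each simulated condition is scored 0-5 against the reference run on:
(i) abnormal posture, (ii) sustained contraction, (iii) increased stiffness,
(iv) worsening with activity and (v) loss of voluntary control.  The clinical
rubric is qualitative, so each characteristic is operationalised as an
explicit numeric criterion on the settled part of each protocol phase; all
thresholds are configurable and reported with the scores.

Measures are taken over the final second of each phase (the settled window),
so the transient by which an aberrant condition first attains its abnormal
posture is not mistaken for a response to the stimulus.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .engine import SimulationResult
from .reflex import MUSCLES

__all__ = [
    "ScoreThresholds",
    "DystoniaScore",
    "ConditionMeasures",
    "condition_measures",
    "count_zero_crossings",
    "max_zero_crossings_in_window",
    "score",
    "score_battery",
]

# sign changes of omega below this magnitude are treated as numerical rest
OMEGA_EPS = 0.02  # rad/s


@dataclass(frozen=True)
class ScoreThresholds:
    """Numeric criteria behind the five characteristics.

    ``theta_posture``: settled final-rest angle beyond which the posture is
    abnormal.  ``act_rest``: required excess (over reference) of the weaker
    muscle's resting activation for sustained (co-)contraction.
    ``stiffness_ratio``: a condition is stiffer if its settled deflection
    under external torque is below this fraction of the reference deflection.
    ``worsen_margin``: how far the settled voluntary-phase deviation must
    exceed the reference's for the dystonia to worsen with activity.
    ``voluntary_ratio``: voluntary control is lost when the voluntary
    excursion falls below this fraction of the reference excursion.
    """

    theta_posture: float = 0.05   # rad
    act_rest: float = 0.05        # activation units
    stiffness_ratio: float = 0.5
    worsen_margin: float = 0.02   # rad
    voluntary_ratio: float = 0.5

    def __post_init__(self) -> None:
        for name in ("theta_posture", "act_rest", "worsen_margin"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("stiffness_ratio", "voluntary_ratio"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must lie in (0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class DystoniaScore:
    """Five boolean characteristics and their count."""

    abnormal_posture: bool
    sustained_contraction: bool
    increased_stiffness: bool
    worsening_with_activity: bool
    loss_of_voluntary_control: bool

    @property
    def total(self) -> int:
        return sum((self.abnormal_posture, self.sustained_contraction,
                    self.increased_stiffness, self.worsening_with_activity,
                    self.loss_of_voluntary_control))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["total"] = self.total
        return d


@dataclass(frozen=True)
class ConditionMeasures:
    """Settled-window summary statistics of one simulated condition."""

    first_rest_posture: float    # mean theta, settled window of first rest [rad]
    final_rest_posture: float    # mean theta, settled window of final rest [rad]
    force_deflection: float      # settled |theta shift| caused by the torque [rad]
    force_peak_deviation: float  # peak |theta - rest posture|, settled force phase
    voluntary_posture: float     # mean theta, settled window of voluntary phase
    voluntary_excursion: float   # settled |theta shift| caused by voluntary drive
    rest_min_activation: float   # weaker muscle's mean activation, final rest
    rest_torque: dict            # per-muscle mean |torque| over final rest [N m]


def _phase_windows(result: SimulationResult):
    phases = result.protocol.phases
    if len(phases) != 4:
        raise ValueError("scoring expects the standard four-phase protocol")
    return phases


def _settled_mask(t_rel: np.ndarray, t_start: float, t_end: float,
                  settle: float = 1.0) -> np.ndarray:
    lo = max(t_start, t_end - settle)
    return (t_rel >= lo - 1e-12) & (t_rel <= t_end + 1e-12)


def condition_measures(result: SimulationResult,
                       settle: float = 1.0) -> ConditionMeasures:
    """Summary statistics used by the score and by the regime checks.

    All windows are located relative to the first time sample, so shifting
    the whole time grid by a constant does not change any measure.
    """
    force_ph, rest1, vol, rest2 = _phase_windows(result)
    t_rel = result.t - result.t[0]
    theta = result.theta

    def settled_mean(ph) -> float:
        return float(theta[_settled_mask(t_rel, ph.t_start, ph.t_end, settle)]
                     .mean())

    rest1_posture = settled_mean(rest1)
    rest2_posture = settled_mean(rest2)
    force_posture = settled_mean(force_ph)
    vol_posture = settled_mean(vol)

    # peak deviation from the condition's own resting posture over the second
    # half of the force phase (the settled response to the external torque)
    mid = 0.5 * (force_ph.t_start + force_ph.t_end)
    m = (t_rel >= mid) & (t_rel <= force_ph.t_end + 1e-12)
    force_peak = float(np.max(np.abs(theta[m] - rest1_posture)))

    m_rest2 = _settled_mask(t_rel, rest2.t_start, rest2.t_end, settle)
    rest_min_act = min(float(result.activation[mus][m_rest2].mean())
                       for mus in MUSCLES)
    rest_torque = {mus: float(np.abs(result.torque[mus][m_rest2]).mean())
                   for mus in MUSCLES}
    return ConditionMeasures(
        first_rest_posture=rest1_posture,
        final_rest_posture=rest2_posture,
        force_deflection=abs(force_posture - rest1_posture),
        force_peak_deviation=force_peak,
        voluntary_posture=vol_posture,
        voluntary_excursion=abs(vol_posture - rest1_posture),
        rest_min_activation=rest_min_act,
        rest_torque=rest_torque)


def count_zero_crossings(omega: np.ndarray, eps: float = OMEGA_EPS) -> int:
    """Sign changes of omega, ignoring samples within +-eps of rest."""
    sig = omega[np.abs(omega) > eps]
    if sig.size < 2:
        return 0
    return int(np.sum(np.diff(np.sign(sig)) != 0))


def max_zero_crossings_in_window(result: SimulationResult,
                                 window: float = 2.0,
                                 eps: float = OMEGA_EPS) -> int:
    """Largest zero-crossing count of omega over any sliding window."""
    t_rel = result.t - result.t[0]
    best = 0
    step = max(window / 4.0, 1e-6)
    t0 = 0.0
    while t0 + window <= t_rel[-1] + 1e-9:
        m = (t_rel >= t0) & (t_rel < t0 + window)
        best = max(best, count_zero_crossings(result.omega[m], eps))
        t0 += step
    return best


def _check_same_grid(result: SimulationResult,
                     reference: SimulationResult) -> None:
    if len(result.t) != len(reference.t):
        raise ValueError("result and reference must share one time grid")
    if not np.allclose(result.t - result.t[0],
                       reference.t - reference.t[0], atol=1e-9):
        raise ValueError("result and reference time grids differ")
    if result.protocol.to_dict() != reference.protocol.to_dict():
        raise ValueError("result and reference must share the protocol")


def score(result: SimulationResult, reference: SimulationResult,
          th: ScoreThresholds | None = None) -> DystoniaScore:
    """Score one condition against the reference run.

    The five criteria compare settled-window statistics of the condition with
    those of the reference; the reference scored against itself is 0.
    """
    th = th or ScoreThresholds()
    _check_same_grid(result, reference)
    m = condition_measures(result)
    ref = condition_measures(reference)

    abnormal = abs(m.final_rest_posture) > th.theta_posture
    sustained = (m.rest_min_activation
                 - ref.rest_min_activation) > th.act_rest
    stiff = m.force_peak_deviation < th.stiffness_ratio * ref.force_peak_deviation
    # worsening with activity: during voluntary use the limb deviates beyond
    # the range normal voluntary activity (the reference) produces
    worse = (abs(m.voluntary_posture)
             - abs(ref.voluntary_posture)) > th.worsen_margin
    loss = m.voluntary_excursion < th.voluntary_ratio * ref.voluntary_excursion
    return DystoniaScore(
        abnormal_posture=bool(abnormal),
        sustained_contraction=bool(sustained),
        increased_stiffness=bool(stiff),
        worsening_with_activity=bool(worse),
        loss_of_voluntary_control=bool(loss))


def score_battery(results: dict[str, SimulationResult],
                  th: ScoreThresholds | None = None,
                  reference_label: str = "reference") -> pd.DataFrame:
    """Score every condition of a battery; one row per condition."""
    th = th or ScoreThresholds()
    reference = results[reference_label]
    rows = []
    for label, res in results.items():
        s = score(res, reference, th)
        row = {"condition": label, **s.to_dict(),
               "unstable": res.unstable}
        rows.append(row)
    df = pd.DataFrame(rows)
    for name, value in th.to_dict().items():
        df[f"th_{name}"] = value
    return df
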