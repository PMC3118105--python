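"""Hill-type muscle mechanics and single-joint dynamics.

One muscle is a contractile element (CE) in series with an exponential elastic
element (SE); two such muscles act antagonistically across a one-degree-of-
freedom joint carrying the hand (or arm) inertia.  Activation follows
first-order excitation dynamics; the CE velocity is obtained by inverting the
force-velocity relation at the instantaneous series-elastic force, so each
muscle contributes exactly two continuous states: activation ``a`` and CE
length ``l_ce``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "MuscleParams",
    "MuscleState",
    "JointParams",
    "JointState",
    "EquilibriumError",
    "activation_rate",
    "force_length",
    "force_velocity",
    "invert_force_velocity",
    "series_force",
    "muscle_force",
    "joint_acceleration",
    "SE_STRAIN_REF",
    "ECCENTRIC_PLATEAU",
]

# Tendon strain at maximal isometric force; anchors the SE exponential.
SE_STRAIN_REF = 0.04
# Eccentric force-velocity plateau, as a multiple of isometric force.
ECCENTRIC_PLATEAU = 1.3


class EquilibriumError(RuntimeError):
    """No admissible CE velocity solves the Hill equilibrium (non-finite input)."""


@dataclass(frozen=True)
class MuscleParams:
    """Musculotendon parameters for one muscle.

    Units are SI throughout; ``v_max`` is expressed in optimal CE lengths per
    second.  ``sign`` is +1 for the flexor and -1 for the extensor, fixing the
    convention that flexion (positive joint angle) shortens the flexor.
    """

    f_max: float          # maximal isometric force [N]
    l_ce_opt: float       # optimal CE length [m]
    l_se_slack: float     # series-elastic slack length [m]
    k_se_shape: float     # SE exponential shape (dimensionless)
    w_fl: float           # force-length width (dimensionless)
    v_max: float          # maximal shortening velocity [l_ce_opt / s]
    a_hill: float         # Hill force-velocity curvature (dimensionless)
    tau_act: float        # activation time constant [s]
    tau_deact: float      # deactivation time constant [s]
    r: float              # moment arm [m], constant
    sign: int             # +1 flexor / -1 extensor

    def __post_init__(self) -> None:
        for name in ("f_max", "l_ce_opt", "l_se_slack", "k_se_shape", "w_fl",
                     "v_max", "a_hill", "tau_act", "tau_deact", "r"):
            if not getattr(self, name) > 0:
                raise ValueError(f"MuscleParams.{name} must be > 0")
        if self.sign not in (+1, -1):
            raise ValueError("MuscleParams.sign must be +1 or -1")
        if self.tau_act > self.tau_deact:
            raise ValueError("tau_act must not exceed tau_deact")

    @property
    def l_mt_neutral(self) -> float:
        """Musculotendon length at the neutral joint angle."""
        return self.l_ce_opt + self.l_se_slack


@dataclass
class MuscleState:
    """Continuous state of one muscle: activation and CE length."""

    a: float
    l_ce: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.a <= 1.0:
            raise ValueError("activation must lie in [0, 1]")
        if not self.l_ce > 0:
            raise ValueError("l_ce must be > 0")


@dataclass(frozen=True)
class JointParams:
    """Rotational inertia and passive damping of the joint segment."""

    inertia: float        # [kg m^2]
    b_passive: float      # [N m s / rad]
    theta_neutral: float = 0.0

    def __post_init__(self) -> None:
        if not self.inertia > 0:
            raise ValueError("inertia must be > 0")
        if self.b_passive < 0:
            raise ValueError("b_passive must be >= 0")


@dataclass
class JointState:
    """Joint angle (flexion positive, 0 = neutral) and angular velocity."""

    theta: float
    omega: float


def activation_rate(u: float, a: float, params: MuscleParams) -> float:
    """First-order activation dynamics da/dt = (u - a) / tau.

    The time constant is ``tau_act`` while excitation exceeds activation
    (calcium release) and ``tau_deact`` otherwise (re-uptake).
    """
    if not 0.0 <= u <= 1.0:
        raise ValueError(f"neural excitation u={u} outside [0, 1]")
    tau = params.tau_act if u > a else params.tau_deact
    return (u - a) / tau


def force_length(l_ce: float, params: MuscleParams) -> float:
    """Active force-length factor: Gaussian peaked at the optimal CE length."""
    if not l_ce > 0:
        raise ValueError("l_ce must be > 0")
    x = (l_ce / params.l_ce_opt - 1.0) / params.w_fl
    return math.exp(-x * x)

def force_velocity(v_ce: float, params: MuscleParams) -> float:
    """Hill force-velocity factor (shortening negative).

    Concentric branch is the classic hyperbola, zero at -v_max and 1 at rest;
    the eccentric branch rises with a slope continuous at v=0 and saturates at
    ``ECCENTRIC_PLATEAU`` times isometric force.
    """
    if not math.isfinite(v_ce):
        raise EquilibriumError("non-finite CE velocity")
    a = params.a_hill
    vn = v_ce / (params.v_max * params.l_ce_opt)
    if vn <= -1.0:
        return 0.0
    if vn < 0.0:
        return (1.0 + vn) / (1.0 - vn / a)
    g = (ECCENTRIC_PLATEAU - 1.0) / (1.0 + 1.0 / a)
    return 1.0 + (ECCENTRIC_PLATEAU - 1.0) * vn / (vn + g)


def invert_force_velocity(fv: float, params: MuscleParams) -> float:
    """Normalised CE velocity producing the given force-velocity factor.

    The inverse of :func:`force_velocity` on [0, plateau); demand at or above
    the eccentric plateau yields the lengthening cap vn = +1 (the muscle
    yields at v_max).  Demand <= 0 yields maximal shortening vn = -1.
    """
    a = params.a_hill
    if fv <= 0.0:
        return -1.0
    if fv < 1.0:
        return a * (fv - 1.0) / (a + fv)
    if fv >= ECCENTRIC_PLATEAU:
        return 1.0
    g = (ECCENTRIC_PLATEAU - 1.0) / (1.0 + 1.0 / a)
    return min(1.0, g * (fv - 1.0) / (ECCENTRIC_PLATEAU - fv))


def series_force(l_se: float, params: MuscleParams) -> float:
    """Series-elastic force: exponential in tendon strain, 0 below slack.

    Reaches exactly ``f_max`` at strain ``SE_STRAIN_REF``.
    """
    strain = (l_se - params.l_se_slack) / params.l_se_slack
    if strain <= 0.0:
        return 0.0
    k = params.k_se_shape
    return params.f_max * math.expm1(k * strain / SE_STRAIN_REF) / math.expm1(k)


def _force_and_velocity(a: float, l_ce: float, params: MuscleParams,
                        l_mt: float) -> tuple[float, float]:
    # plain-float core of muscle_force, shared with the simulation inner loop
    if not l_mt > 0:
        raise ValueError("l_mt must be > 0")
    if not (math.isfinite(l_mt) and math.isfinite(l_ce)):
        raise EquilibriumError(f"non-finite lengths: l_mt={l_mt}, l_ce={l_ce}")
    f_se = series_force(l_mt - l_ce, params)
    f_l = force_length(l_ce, params)
    capacity = max(a * f_l, 1e-9) * params.f_max
    vn = invert_force_velocity(f_se / capacity, params)
    return f_se, vn * params.v_max * params.l_ce_opt


def muscle_force(state: MuscleState, params: MuscleParams,
                 l_mt: float) -> tuple[float, float]:
    """Instantaneous musculotendon force [N] and CE velocity [m/s].

    The series-elastic force at ``l_se = l_mt - l_ce`` must equal the CE force
    ``a * f_max * f_l * f_v``; the Hill relation is inverted for the CE
    velocity that balances it.  With activation near zero and a taut tendon
    the demand exceeds the eccentric plateau and the CE lengthens at its cap.
    """
    return _force_and_velocity(state.a, state.l_ce, params, l_mt)


def joint_acceleration(js: JointState, f_flex: float, f_ext: float,
                       t_external: float, jp: JointParams,
                       r_flex: float, r_ext: float) -> float:
    """Angular acceleration of the joint under both muscle forces.

    inertia * alpha = r_flex*f_flex - r_ext*f_ext - b_passive*omega + t_external
    """
    if f_flex < 0 or f_ext < 0:
        raise ValueError("muscle forces must be >= 0")
    torque = (r_flex * f_flex - r_ext * f_ext
              - jp.b_passive * js.omega + t_external)
    return torque / jp.inertia
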