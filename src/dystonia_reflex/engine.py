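"""Delay-aware fixed-step integration of the joint-muscle-reflex system.

The coupled system is a delay differential equation: six continuous states
(joint angle and velocity, plus activation and CE length per muscle) driven by
reflex excitation read from the recent past of each afferent signal.  A fixed
integration step keeps the delays exact multiples of the step, so delayed
signals come from a per-step history with linear interpolation for the
Runge-Kutta mid-stages.  The whole run is deterministic: identical inputs give
bit-identical outputs.

The standard stimulus protocol is four contiguous 5-second phases: external
torque on, rest, voluntary contraction of the agonist, rest.
"""

from __future__ import annotations

import json
import math
from array import array
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .muscle import (JointParams, MuscleParams, _force_and_velocity,
                     force_length, series_force)
from .presets import Preset, get_preset
from .reflex import (MUSCLES, ReflexConfig, ScenarioSpec, apply_scenario,
                     reflex_excitation)

__all__ = [
    "Phase",
    "InputProtocol",
    "SimulationSettings",
    "SimulationResult",
    "build_protocol",
    "initial_ce_length",
    "simulate",
    "run_battery",
    "severity_sweep",
    "battery_labels",
    "THETA_CAP",
]

# hard physical bound on joint excursion; beyond this the run is flagged unstable
THETA_CAP = 3.0  # rad


def _read_history(h, x: float) -> float:
    """Linearly interpolated read of a per-step sample history at index x.

    ``x`` is a (fractional) step index; reads before index 0 return the
    neutral-rest sample at index 0 (constant pre-history).
    """
    if x <= 0.0:
        return h[0]
    i = int(x)
    if i >= len(h) - 1:
        return h[-1]
    frac = x - i
    return h[i] + frac * (h[i + 1] - h[i])


@dataclass(frozen=True)
class Phase:
    t_start: float
    t_end: float
    t_external: float   # external joint torque [N m], flexion-assisting positive
    u_voluntary: float  # voluntary drive to the agonist, in [0, 1]


@dataclass(frozen=True)
class InputProtocol:
    """Contiguous, non-overlapping phases covering [0, duration]."""

    phases: tuple[Phase, ...]
    duration: float

    def __post_init__(self) -> None:
        if not self.phases:
            raise ValueError("protocol needs at least one phase")
        t = 0.0
        for ph in self.phases:
            if not math.isclose(ph.t_start, t, abs_tol=1e-12):
                raise ValueError("phases must be contiguous from t = 0")
            if not ph.t_end > ph.t_start:
                raise ValueError("phase must have positive length")
            if not 0.0 <= ph.u_voluntary <= 1.0:
                raise ValueError("u_voluntary must lie in [0, 1]")
            t = ph.t_end
        if not math.isclose(t, self.duration, abs_tol=1e-12):
            raise ValueError("phases must cover [0, duration]")

    def inputs_at(self, t: float) -> tuple[float, float]:
        """(external torque, voluntary drive) at time t; [t_start, t_end)."""
        for ph in self.phases:
            if t < ph.t_end:
                return ph.t_external, ph.u_voluntary
        last = self.phases[-1]
        return last.t_external, last.u_voluntary

    def to_dict(self) -> dict:
        return {"duration": self.duration,
                "phases": [[p.t_start, p.t_end, p.t_external, p.u_voluntary]
                           for p in self.phases]}

    @classmethod
    def from_dict(cls, d: Mapping) -> "InputProtocol":
        return cls(phases=tuple(Phase(*row) for row in d["phases"]),
                   duration=float(d["duration"]))


def build_protocol(t_force: float, u_vol: float,
                   phase_duration: float = 5.0) -> InputProtocol:
    """The standard four-phase stimulus.

    ``phase_duration`` seconds of continuous external torque, the same of
    rest, the same of continuous voluntary contraction, and rest again.
    """
    if not math.isfinite(t_force):
        raise ValueError("t_force must be finite")
    if not 0.0 <= u_vol <= 1.0:
        raise ValueError("u_vol must lie in [0, 1]")
    p = phase_duration
    return InputProtocol(
        phases=(Phase(0.0, p, t_force, 0.0),
                Phase(p, 2 * p, 0.0, 0.0),
                Phase(2 * p, 3 * p, 0.0, u_vol),
                Phase(3 * p, 4 * p, 0.0, 0.0)),
        duration=4 * p)


@dataclass(frozen=True)
class SimulationSettings:
    """Integrator configuration.

    ``record_stride`` thins the stored output to every n-th step (the state
    itself always advances at ``dt``); it must divide the total step count.
    """

    dt: float = 1e-3
    method: str = "rk4"     # "rk4" or "euler"
    history_init: str = "neutral"
    record_stride: int = 1

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError("dt must be > 0")
        if self.method not in ("rk4", "euler"):
            raise ValueError("method must be 'rk4' or 'euler'")
        if self.history_init != "neutral":
            raise ValueError("only 'neutral' history initialization is supported")
        if self.record_stride < 1:
            raise ValueError("record_stride must be >= 1")

    def validate_against(self, cfg: ReflexConfig) -> None:
        if not self.dt < cfg.min_delay() / 4:
            raise ValueError(
                f"dt={self.dt} must be < min reflex delay / 4 "
                f"({cfg.min_delay() / 4})")

    def to_dict(self) -> dict:
        return {"dt": self.dt, "method": self.method,
                "history_init": self.history_init,
                "record_stride": self.record_stride}


@dataclass
class SimulationResult:
    """Time series of one simulated condition.

    Per-muscle dictionaries are keyed ``"flexor"`` / ``"extensor"``; torques
    carry the joint sign convention (flexor positive, extensor negative).
    """

    t: np.ndarray
    theta: np.ndarray
    omega: np.ndarray
    activation: dict[str, np.ndarray]
    force: dict[str, np.ndarray]
    torque: dict[str, np.ndarray]
    excitation: dict[str, np.ndarray]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.t)
        arrays = [self.theta, self.omega]
        for d in (self.activation, self.force, self.torque, self.excitation):
            arrays.extend(d[m] for m in MUSCLES)
        if any(len(a) != n for a in arrays):
            raise ValueError("all result arrays must share one time grid")

    @property
    def unstable(self) -> bool:
        return bool(self.metadata.get("unstable", False))

    @property
    def protocol(self) -> InputProtocol:
        return InputProtocol.from_dict(self.metadata["protocol"])

    def to_frame(self) -> pd.DataFrame:
        cols = {"t": self.t, "theta": self.theta, "omega": self.omega}
        for key, d in (("activation", self.activation), ("force", self.force),
                       ("torque", self.torque), ("excitation", self.excitation)):
            for m in MUSCLES:
                cols[f"{key}_{m}"] = d[m]
        return pd.DataFrame(cols)

    def save(self, path_base: str | Path) -> None:
        """Write `<base>.csv` (one row per stored step) and `<base>.json`."""
        base = Path(path_base)
        base.parent.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(base.with_suffix(".csv"), index=False)
        base.with_suffix(".json").write_text(
            json.dumps(self.metadata, indent=2, sort_keys=True),
            encoding="utf-8")

    @classmethod
    def load(cls, path_base: str | Path) -> "SimulationResult":
        base = Path(path_base)
        df = pd.read_csv(base.with_suffix(".csv"))
        meta = json.loads(base.with_suffix(".json").read_text(encoding="utf-8"))
        pick = lambda key: {m: df[f"{key}_{m}"].to_numpy() for m in MUSCLES}
        return cls(t=df["t"].to_numpy(), theta=df["theta"].to_numpy(),
                   omega=df["omega"].to_numpy(), activation=pick("activation"),
                   force=pick("force"), torque=pick("torque"),
                   excitation=pick("excitation"), metadata=meta)


def initial_ce_length(params: MuscleParams, u_baseline: float,
                      l_mt: float | None = None) -> float:
    """CE length at static equilibrium under tonic drive at neutral angle.

    Solves series-elastic force == a * f_max * f_l(l_ce) (isometric, v = 0)
    for ``l_ce`` at the neutral musculotendon length.
    """
    if l_mt is None:
        l_mt = params.l_mt_neutral
    if u_baseline <= 0.0:
        return min(params.l_ce_opt, l_mt - params.l_se_slack)

    def gap(l_ce: float) -> float:
        return (series_force(l_mt - l_ce, params)
                - u_baseline * params.f_max * force_length(l_ce, params))

    lo, hi = 0.5 * params.l_ce_opt, l_mt - params.l_se_slack
    return brentq(gap, lo, hi, xtol=1e-12)


def _resolve_preset(preset: str | Preset) -> Preset:
    return get_preset(preset) if isinstance(preset, str) else preset


def simulate(preset: str | Preset,
             reflex_cfg: ReflexConfig | None = None,
             protocol: InputProtocol | None = None,
             settings: SimulationSettings | None = None,
             scenario: ScenarioSpec | None = None) -> SimulationResult:
    """Integrate one condition over the full protocol.

    ``reflex_cfg`` defaults to the preset's reference configuration with
    ``scenario`` applied; pass an explicit config to override.  The run is
    deterministic.  If the joint angle leaves the physical bound or a state
    becomes non-finite, the run is flagged ``unstable`` in the metadata (the
    remaining samples hold the last stable values) instead of raising.
    """
    pr = _resolve_preset(preset)
    scenario = scenario or ScenarioSpec()
    if reflex_cfg is None:
        reflex_cfg = apply_scenario(pr.reflex, scenario)
    protocol = protocol or build_protocol(
        pr.defaults.get("t_force", 0.0), pr.defaults.get("u_vol", 0.0))
    settings = settings or SimulationSettings()
    settings.validate_against(reflex_cfg)

    dt = settings.dt
    n_steps = round(protocol.duration / dt)
    if not math.isclose(n_steps * dt, protocol.duration, rel_tol=1e-9):
        raise ValueError("protocol duration must be a multiple of dt")
    stride = settings.record_stride
    if n_steps % stride:
        raise ValueError("record_stride must divide the number of steps")

    mp_f, mp_e, jp = pr.flexor, pr.extensor, pr.joint
    cfg_f, cfg_e = reflex_cfg.flexor, reflex_cfg.extensor
    u_base = pr.u_baseline
    agonist_is_flexor = scenario.agonist == "flexor"

    # local bindings for the inner loop
    r_f, r_e = mp_f.r, mp_e.r
    L0_f, L0_e = mp_f.l_mt_neutral, mp_e.l_mt_neutral
    fmax_f, fmax_e = mp_f.f_max, mp_e.f_max
    inv_I, b = 1.0 / jp.inertia, jp.b_passive
    tau_a_f, tau_d_f = mp_f.tau_act, mp_f.tau_deact
    tau_a_e, tau_d_e = mp_e.tau_act, mp_e.tau_deact
    lopt_f, lopt_e = mp_f.l_ce_opt, mp_e.l_ce_opt

    # delays in step units (>= 4 by the settings invariant)
    d_p_f, d_v_f, d_f_f = cfg_f.tau_p / dt, cfg_f.tau_v / dt, cfg_f.tau_f / dt
    d_p_e, d_v_e, d_f_e = cfg_e.tau_p / dt, cfg_e.tau_v / dt, cfg_e.tau_f / dt

    # initial condition: neutral rest under tonic drive
    lce0_f = initial_ce_length(mp_f, u_base)
    lce0_e = initial_ce_length(mp_e, u_base)
    a0 = u_base
    state = (0.0, 0.0, a0, lce0_f, a0, lce0_e)

    # afferent-signal histories, one sample per step (pre-t=0 history is the
    # neutral-rest value, i.e. the sample at index 0)
    F0_f, _ = _force_and_velocity(a0, lce0_f, mp_f, L0_f)
    F0_e, _ = _force_and_velocity(a0, lce0_e, mp_e, L0_e)
    h_st_f = array("d", [0.0]); h_rt_f = array("d", [0.0])
    h_fn_f = array("d", [F0_f / fmax_f])
    h_st_e = array("d", [0.0]); h_rt_e = array("d", [0.0])
    h_fn_e = array("d", [F0_e / fmax_e])

    read = _read_history
    inputs_at = protocol.inputs_at

    def deriv(idx: float, s: tuple) -> tuple:
        theta, omega, a_f, l_f, a_e, l_e = s
        t_ext, u_vol = inputs_at(idx * dt)
        exc_f = reflex_excitation(read(h_st_f, idx - d_p_f),
                                  read(h_rt_f, idx - d_v_f),
                                  read(h_fn_f, idx - d_f_f), cfg_f)
        exc_e = reflex_excitation(read(h_st_e, idx - d_p_e),
                                  read(h_rt_e, idx - d_v_e),
                                  read(h_fn_e, idx - d_f_e), cfg_e)
        u_f = u_base + exc_f + (u_vol if agonist_is_flexor else 0.0)
        u_e = u_base + exc_e + (0.0 if agonist_is_flexor else u_vol)
        u_f = 0.0 if u_f < 0.0 else (1.0 if u_f > 1.0 else u_f)
        u_e = 0.0 if u_e < 0.0 else (1.0 if u_e > 1.0 else u_e)
        F_f, v_f = _force_and_velocity(a_f, l_f, mp_f, L0_f - r_f * theta)
        F_e, v_e = _force_and_velocity(a_e, l_e, mp_e, L0_e + r_e * theta)
        alpha = (r_f * F_f - r_e * F_e - b * omega + t_ext) * inv_I
        da_f = (u_f - a_f) / (tau_a_f if u_f > a_f else tau_d_f)
        da_e = (u_e - a_e) / (tau_a_e if u_e > a_e else tau_d_e)
        return (omega, alpha, da_f, v_f, da_e, v_e)

    # output buffers
    n_rec = n_steps // stride + 1
    out = {name: array("d", bytes(8 * n_rec)) for name in
           ("theta", "omega", "a_f", "a_e", "F_f", "F_e", "exc_f", "exc_e")}

    def record(j: int, s: tuple) -> None:
        theta, omega, a_f, l_f, a_e, l_e = s
        F_f, _ = _force_and_velocity(a_f, l_f, mp_f, L0_f - r_f * theta)
        F_e, _ = _force_and_velocity(a_e, l_e, mp_e, L0_e + r_e * theta)
        out["theta"][j] = theta; out["omega"][j] = omega
        out["a_f"][j] = a_f; out["a_e"][j] = a_e
        out["F_f"][j] = F_f; out["F_e"][j] = F_e
        idx = float(j * stride)
        out["exc_f"][j] = reflex_excitation(read(h_st_f, idx - d_p_f),
                                            read(h_rt_f, idx - d_v_f),
                                            read(h_fn_f, idx - d_f_f), cfg_f)
        out["exc_e"][j] = reflex_excitation(read(h_st_e, idx - d_p_e),
                                            read(h_rt_e, idx - d_v_e),
                                            read(h_fn_e, idx - d_f_e), cfg_e)

    record(0, state)
    unstable = False
    t_unstable = None
    use_rk4 = settings.method == "rk4"
    half = 0.5 * dt
    sixth = dt / 6.0

    for k in range(n_steps):
        fk = float(k)
        if use_rk4:
            k1 = deriv(fk, state)
            s2 = tuple(state[i] + half * k1[i] for i in range(6))
            k2 = deriv(fk + 0.5, s2)
            s3 = tuple(state[i] + half * k2[i] for i in range(6))
            k3 = deriv(fk + 0.5, s3)
            s4 = tuple(state[i] + dt * k3[i] for i in range(6))
            k4 = deriv(fk + 1.0, s4)
            state = tuple(
                state[i] + sixth * (k1[i] + 2.0 * (k2[i] + k3[i]) + k4[i])
                for i in range(6))
        else:
            k1 = deriv(fk, state)
            state = tuple(state[i] + dt * k1[i] for i in range(6))
        # clamp activations against accumulation of integration round-off
        theta, omega, a_f, l_f, a_e, l_e = state
        a_f = 0.0 if a_f < 0.0 else (1.0 if a_f > 1.0 else a_f)
        a_e = 0.0 if a_e < 0.0 else (1.0 if a_e > 1.0 else a_e)
        state = (theta, omega, a_f, l_f, a_e, l_e)

        if not (math.isfinite(theta) and math.isfinite(omega)
                and math.isfinite(l_f) and math.isfinite(l_e)
                and abs(theta) <= THETA_CAP):
            unstable = True
            t_unstable = (k + 1) * dt
            # hold the last stable sample for the remainder of the grid
            j_last = k // stride
            for name, buf in out.items():
                for j in range(j_last + 1, n_rec):
                    buf[j] = buf[j_last]
            break

        # append the new afferent samples for step k+1
        F_f, v_f = _force_and_velocity(a_f, l_f, mp_f, L0_f - r_f * theta)
        F_e, v_e = _force_and_velocity(a_e, l_e, mp_e, L0_e + r_e * theta)
        h_st_f.append((l_f - lce0_f) / lopt_f)
        h_rt_f.append(v_f / lopt_f)
        h_fn_f.append(F_f / fmax_f)
        h_st_e.append((l_e - lce0_e) / lopt_e)
        h_rt_e.append(v_e / lopt_e)
        h_fn_e.append(F_e / fmax_e)
        if (k + 1) % stride == 0:
            record((k + 1) // stride, state)

    t_grid = np.arange(n_rec) * (dt * stride)
    as_np = {k: np.frombuffer(v, dtype=float).copy() for k, v in out.items()}
    metadata = {
        "scenario": scenario.to_dict(),
        "condition": scenario.label,
        "preset": pr.name,
        "settings": settings.to_dict(),
        "protocol": protocol.to_dict(),
        "reflex_config": reflex_cfg.to_dict(),
        "u_baseline": u_base,
        "unstable": unstable,
        "t_unstable": t_unstable,
        "deterministic": True,
    }
    return SimulationResult(
        t=t_grid, theta=as_np["theta"], omega=as_np["omega"],
        activation={"flexor": as_np["a_f"], "extensor": as_np["a_e"]},
        force={"flexor": as_np["F_f"], "extensor": as_np["F_e"]},
        torque={"flexor": r_f * as_np["F_f"], "extensor": -r_e * as_np["F_e"]},
        excitation={"flexor": as_np["exc_f"], "extensor": as_np["exc_e"]},
        metadata=metadata)


def battery_labels() -> list[str]:
    """The ten condition labels: reference plus scenario x pathway."""
    labels = ["reference"]
    for scen in ("increased_sensitivity", "imbalanced_sensitivity",
                 "imbalanced_offset"):
        for pw in ("position", "velocity", "force"):
            labels.append(f"{scen}:{pw}")
    return labels


def run_battery(preset: str | Preset,
                base_cfg: ReflexConfig | None = None,
                magnitudes: Mapping[str, float] | None = None,
                protocol: InputProtocol | None = None,
                settings: SimulationSettings | None = None,
                agonist: str = "flexor") -> dict[str, SimulationResult]:
    """Run the reference condition plus all nine aberrant conditions.

    ``magnitudes`` maps ``"sensitivity"`` and ``"offset"`` to the gain
    multiplier and offset level (preset defaults if omitted).
    """
    pr = _resolve_preset(preset)
    base_cfg = base_cfg or pr.reflex
    mags = dict(magnitudes or {})
    sens = mags.get("sensitivity", pr.defaults.get("sensitivity_magnitude", 4.0))
    offs = mags.get("offset", pr.defaults.get("offset_magnitude", 0.2))
    results: dict[str, SimulationResult] = {}
    for label in battery_labels():
        if label == "reference":
            spec = ScenarioSpec(agonist=agonist)
        else:
            scen, pw = label.split(":")
            mag = offs if scen == "imbalanced_offset" else sens
            spec = ScenarioSpec(scenario=scen, pathway=pw, magnitude=mag,
                                agonist=agonist)
        results[label] = simulate(pr, reflex_cfg=apply_scenario(base_cfg, spec),
                                  protocol=protocol, settings=settings,
                                  scenario=spec)
    return results


def severity_sweep(preset: str | Preset,
                   magnitudes: Iterable[float] | None = None,
                   protocol: InputProtocol | None = None,
                   settings: SimulationSettings | None = None
                   ) -> dict[float, SimulationResult]:
    """Imbalanced force-feedback sensitivity at several degrees of imbalance."""
    pr = _resolve_preset(preset)
    if magnitudes is None:
        magnitudes = pr.defaults.get("severity_magnitudes", (2.0, 4.0, 8.0))
    out = {}
    for mag in magnitudes:
        spec = ScenarioSpec(scenario="imbalanced_sensitivity", pathway="force",
                            magnitude=float(mag))
        out[float(mag)] = simulate(pr, protocol=protocol, settings=settings,
                                   scenario=spec)
    return out
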