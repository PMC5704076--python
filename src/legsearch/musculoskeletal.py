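"""Muscles, joints and planar leg kinematics.

The leg moves in a vertical plane.  Two angles are integrated: ``beta``, the
elevation of the femur at the coxa-trochanter (CTr) joint (positive above the
horizontal), and ``gamma``, the interior femur-tibia (FTi) angle (180 deg =
fully stretched, the tibia flexes below the femur).  The tarsus angle
``alpha`` -- the direction of the line from the CTr pivot to the leg tip --
is purely kinematic and always recomputed from ``beta``, ``gamma`` and the
segment lengths, never integrated.

Muscles are antagonistic rotational springs in an overdamped joint: the
angular velocity is the sum over muscles of ``(passive + activation * gain) *
(rest_angle - angle)``.  There is no inertia and no gravity; the residual
passive stiffness is what holds posture when all motoneurons fall silent.
Activation follows motoneuron output with a first-order lag, capped by the
recruited fraction of the pool.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal, Union

import numpy as np

from .config import MuscleConfig
from .errors import ConfigurationError, LegsearchError

Role = Literal["levator", "depressor", "extensor", "flexor"]
Speed = Literal["fast", "slow"]

_CTR_ROLES = frozenset({"levator", "depressor"})
_FTI_ROLES = frozenset({"extensor", "flexor"})


@dataclass(frozen=True)
class LegGeometry:
    """Segment lengths in mm."""

    femur_mm: float = 13.0
    tibia_mm: float = 12.0

    def __post_init__(self):
        if self.femur_mm <= 0 or self.tibia_mm <= 0:
            raise ConfigurationError("segment lengths must be positive")


@dataclass(frozen=True)
class MusclePool:
    """A fast or slow muscle group with its recruitment state."""

    role: Role
    speed: Speed
    rest_angle_deg: float
    max_force: float            # active stiffness at full activation, deg/ms/deg
    passive_stiffness: float    # residual stiffness, deg/ms/deg
    tau_act_ms: float
    n_units: int = 1
    active_fraction: float = 1.0
    activation: float = 0.0

    def __post_init__(self):
        if self.role not in _CTR_ROLES | _FTI_ROLES:
            raise ConfigurationError(f"unknown muscle role {self.role!r}")
        if not 0.0 <= self.active_fraction <= 1.0:
            raise ConfigurationError("active_fraction must lie in [0, 1]")
        if not 0.0 <= self.activation <= 1.0:
            raise ConfigurationError("activation must lie in [0, 1]")
        if self.role in _FTI_ROLES and self.n_units != 1:
            # single slow and single fast extensor/flexor MN: no recruitment
            raise ConfigurationError(f"{self.role} pools must have n_units = 1")

    @property
    def joint(self) -> str:
        return "CTr" if self.role in _CTR_ROLES else "FTi"

    @classmethod
    def from_config(cls, name: str, cfg: MuscleConfig) -> "MusclePool":
        role, speed = name.rsplit("_", 1)
        return cls(role=role, speed=speed, rest_angle_deg=cfg.rest_angle_deg,
                   max_force=cfg.gain_per_ms, passive_stiffness=cfg.passive_per_ms,
                   tau_act_ms=cfg.tau_act_ms, n_units=cfg.n_units)


@dataclass(frozen=True)
class LegState:
    """Joint angles (deg) with the derived tarsus angle and angle rates."""

    beta: float
    gamma: float
    alpha: float
    beta_rate: float = 0.0   # deg/ms
    gamma_rate: float = 0.0

    @classmethod
    def from_angles(cls, beta: float, gamma: float, geom: LegGeometry,
                    beta_rate: float = 0.0, gamma_rate: float = 0.0) -> "LegState":
        return cls(beta=beta, gamma=gamma,
                   alpha=float(compute_alpha(beta, gamma, geom)),
                   beta_rate=beta_rate, gamma_rate=gamma_rate)


def compute_alpha(beta, gamma, geom: LegGeometry):
    """Tarsus angle relative to horizontal, from ``beta`` and ``gamma``.

    The femur leaves the CTr pivot at elevation ``beta``; the tibia deviates
    from the femur line by ``180 - gamma`` degrees downward.  For a fully
    stretched leg (``gamma`` = 180) alpha equals beta exactly.  Accepts
    scalars or arrays (broadcast).
    """
    beta = np.asarray(beta, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    if np.any(gamma <= 0.0) or np.any(gamma > 180.0):
        raise LegsearchError("gamma must lie in (0, 180] degrees")
    b = np.deg2rad(beta)
    t = np.deg2rad(beta - (180.0 - gamma))
    x = geom.femur_mm * np.cos(b) + geom.tibia_mm * np.cos(t)
    y = geom.femur_mm * np.sin(b) + geom.tibia_mm * np.sin(t)
    alpha = np.rad2deg(np.arctan2(y, x))
    return alpha if alpha.ndim else float(alpha)


def muscle_step(pool: MusclePool, mn_output: float, dt: float) -> MusclePool:
    """Relax activation toward ``mn_output * active_fraction`` (exact update).

    The recruited fraction caps the steady-state activation, so a partially
    recruited pool can never reach full force however strongly its MNs fire.
    """
    if not 0.0 <= mn_output <= 1.0:
        raise ConfigurationError("mn_output must lie in [0, 1]")
    target = mn_output * pool.active_fraction
    decay = math.exp(-dt / pool.tau_act_ms)
    act = target + (pool.activation - target) * decay
    return replace(pool, activation=min(1.0, max(0.0, act)))


def joint_torque(agonist: MusclePool, antagonist: MusclePool, angle: float) -> float:
    """Net overdamped drive (deg/ms) of an antagonistic pair at ``angle``.

    Each muscle pulls toward its own rest angle with stiffness
    ``passive + activation * max_force``; the passive terms alone define the
    joint's passive equilibrium.
    """
    if agonist.joint != antagonist.joint:
        raise ConfigurationError(
            f"pools act on different joints: {agonist.joint} vs {antagonist.joint}")
    torque = 0.0
    for m in (agonist, antagonist):
        k = m.passive_stiffness + m.activation * m.max_force
        torque += k * (m.rest_angle_deg - angle)
    return torque


def joint_step(state: LegState, torque_ctr: float, torque_fti: float,
               dt: float, geom: Union[LegGeometry, None] = None) -> LegState:
    """Advance both joint angles one step of the overdamped dynamics.

    Angle rates are the torques themselves (unit damping).  ``gamma`` is
    clamped to (0, 180]; at the stretched stop the rate is zeroed rather
    than integrated through.
    """
    if not 0.0 < dt <= 1.0:
        raise ConfigurationError("dt must lie in (0, 1] ms")
    geom = geom or LegGeometry()
    beta = state.beta + torque_ctr * dt
    gamma = state.gamma + torque_fti * dt
    gamma_rate = torque_fti
    if gamma >= 180.0:
        gamma, gamma_rate = 180.0, 0.0
    elif gamma < 1.0:
        gamma, gamma_rate = 1.0, 0.0
    return LegState.from_angles(beta, gamma, geom,
                                beta_rate=torque_ctr, gamma_rate=gamma_rate)
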