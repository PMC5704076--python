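"""The neuronal half of the model: two local control networks.

Each local network -- levator-depressor (LD, femur elevation) and
extensor-flexor (EF, tibia) -- contains a central pattern generator (CPG) of
two reciprocally inhibitory cells, four inhibitory premotor interneurons
(INs) that relay the CPG rhythm to the motoneurons by phasic inhibition,
four motoneurons (a fast and a slow MN per muscle), and two further INs per
network through which the sensory coupling conductances act on the CPG:

* LD: CPG cells C3 (levator phase) and C4 (depressor phase); IN7-IN10;
  MN(LF), MN(LS), MN(DF), MN(DS).  IN11 (central, inhibitory) and IN12
  (excitatory, driven by the gamma gate ``g_gamma``) project onto C3 and C4.
* EF: CPG cells C5 (flexor phase) and C6 (extensor phase); IN13-IN16;
  MN(EF), MN(ES), MN(FF), MN(FS).  IN17 (central, inhibitory) projects onto
  C5 and C6; IN18 (excitatory, driven by the beta gate ``g_beta``) projects
  onto the extensor-side cell C6, so a high femur gate biases the tibia
  network toward extension.

CPG cells are two-variable relaxation oscillators (persistent inward current
with instantaneous activation and slow inactivation ``h``); all INs and MNs
are first-order units with sigmoidal input-output whose activity lies in
[0, 1].  MNs receive a uniform central drive ``g_MN``; the premotor INs can
be silenced individually by the central conductances ``g_d7``-``g_d10`` and
``g_d13``-``g_d16``.  The whole network is deterministic: initial states sit
at the resting point with a fixed small voltage offset on C3 so the
half-centers leave the symmetric state reproducibly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .config import NetworkConfig, RunConfig
from .errors import ConfigurationError, NumericalError

# ---------------------------------------------------------------------------
# labels and canonical ordering

CPG_LABELS = ("C3", "C4", "C5", "C6")
IN_LABELS = tuple(f"IN{i}" for i in range(7, 19))
MN_LABELS = ("MN(LF)", "MN(LS)", "MN(DF)", "MN(DS)",
             "MN(EF)", "MN(ES)", "MN(FF)", "MN(FS)")
UNIT_LABELS = CPG_LABELS + IN_LABELS + MN_LABELS
UNIT_INDEX = {lbl: i for i, lbl in enumerate(UNIT_LABELS)}
N_UNITS = len(UNIT_LABELS)

#: MN label -> (speed, role) class
MN_CLASS = {
    "MN(LF)": ("fast", "levator"), "MN(LS)": ("slow", "levator"),
    "MN(DF)": ("fast", "depressor"), "MN(DS)": ("slow", "depressor"),
    "MN(EF)": ("fast", "extensor"), "MN(ES)": ("slow", "extensor"),
    "MN(FF)": ("fast", "flexor"), "MN(FS)": ("slow", "flexor"),
}
MN_CLASS_KEYS = tuple(f"{speed}_{role}" for speed, role in MN_CLASS.values())


@dataclass(frozen=True)
class SynapseSpec:
    source: str
    target: str
    sign: str                  # "excitatory" | "inhibitory"
    conductance: float

    def __post_init__(self):
        for lbl in (self.source, self.target):
            if lbl not in UNIT_INDEX:
                raise ConfigurationError(f"unknown unit label {lbl!r}")
        if self.sign not in ("excitatory", "inhibitory"):
            raise ConfigurationError(f"unknown synapse sign {self.sign!r}")
        if self.conductance < 0:
            raise ConfigurationError("synaptic conductance must be >= 0")


@dataclass
class NeuronUnit:
    """One unit: CPG cells carry state (V, h); INs/MNs carry activity (u)."""

    id: str
    state: np.ndarray
    output: float = 0.0


@dataclass(frozen=True)
class CentralDrives:
    g_mn: float
    g_app: tuple            # (g_app3, g_app4, g_app5, g_app6)
    g_d: dict               # IN label -> central inhibition

    @classmethod
    def from_config(cls, cfg: NetworkConfig) -> "CentralDrives":
        d = cfg.drives
        g_d = {f"IN{i}": getattr(d, f"g_d{i}") for i in (7, 8, 9, 10, 13, 14, 15, 16)}
        return cls(d.g_mn, (d.g_app3, d.g_app4, d.g_app5, d.g_app6), g_d)


def canonical_synapses(cfg: NetworkConfig) -> list[SynapseSpec]:
    """The fixed wiring of the two local networks.

    Signs: CPG mutual inhibition; CPG -> premotor IN excitation; premotor
    IN -> MN inhibition (so MNs fire in the phase opposite to the CPG cell
    that drives their IN, on top of the tonic g_MN drive); the sensory-relay
    IN12/IN18 excite CPG cells, the central IN11/IN17 inhibit them.
    """
    w = cfg.weights
    E, I = "excitatory", "inhibitory"
    syn = [
        SynapseSpec("C3", "C4", I, w.cpg_mutual_ld),
        SynapseSpec("C4", "C3", I, w.cpg_mutual_ld),
        SynapseSpec("C5", "C6", I, w.cpg_mutual_ef),
        SynapseSpec("C6", "C5", I, w.cpg_mutual_ef),
        # depressor-phase cell gates the levator MNs off and vice versa
        SynapseSpec("C4", "IN7", E, w.cpg_to_in),
        SynapseSpec("C4", "IN8", E, w.cpg_to_in),
        SynapseSpec("C3", "IN9", E, w.cpg_to_in),
        SynapseSpec("C3", "IN10", E, w.cpg_to_in),
        SynapseSpec("IN7", "MN(LF)", I, w.in_to_mn),
        SynapseSpec("IN8", "MN(LS)", I, w.in_to_mn),
        SynapseSpec("IN9", "MN(DF)", I, w.in_to_mn),
        SynapseSpec("IN10", "MN(DS)", I, w.in_to_mn),
        # flexor-phase cell gates the extensor MNs off and vice versa
        SynapseSpec("C5", "IN13", E, w.cpg_to_in),
        SynapseSpec("C5", "IN14", E, w.cpg_to_in),
        SynapseSpec("C6", "IN15", E, w.cpg_to_in),
        SynapseSpec("C6", "IN16", E, w.cpg_to_in),
        SynapseSpec("IN13", "MN(EF)", I, w.in_to_mn),
        SynapseSpec("IN14", "MN(ES)", I, w.in_to_mn),
        SynapseSpec("IN15", "MN(FF)", I, w.in_to_mn),
        SynapseSpec("IN16", "MN(FS)", I, w.in_to_mn),
        SynapseSpec("IN11", "C3", I, w.in11_to_cpg),
        SynapseSpec("IN11", "C4", I, w.in11_to_cpg),
        SynapseSpec("IN12", "C3", E, w.in12_to_cpg),
        SynapseSpec("IN12", "C4", E, w.in12_to_cpg),
        SynapseSpec("IN17", "C5", I, w.in17_to_cpg),
        SynapseSpec("IN17", "C6", I, w.in17_to_cpg),
        SynapseSpec("IN18", "C6", E, w.in18_to_c6),
    ]
    return syn


@dataclass
class NetworkModel:
    """Wired network with its parameter set and mutable unit states."""

    config: NetworkConfig
    units: dict[str, NeuronUnit]
    synapses: list[SynapseSpec]
    drives: CentralDrives
    w_exc: np.ndarray = field(repr=False, default=None)   # (N, N) target-major
    w_inh: np.ndarray = field(repr=False, default=None)
    mn_multipliers: np.ndarray = field(default=None)       # per-MN drive scale

    def __post_init__(self):
        if self.w_exc is None:
            self.w_exc = np.zeros((N_UNITS, N_UNITS))
            self.w_inh = np.zeros((N_UNITS, N_UNITS))
            for s in self.synapses:
                mat = self.w_exc if s.sign == "excitatory" else self.w_inh
                mat[UNIT_INDEX[s.target], UNIT_INDEX[s.source]] += s.conductance
        if self.mn_multipliers is None:
            self.mn_multipliers = np.ones(len(MN_LABELS))

    # -- state vector helpers -------------------------------------------------
    def state_vector(self) -> np.ndarray:
        """(V3,V4,V5,V6, h3..h6, u_IN7..u_IN18, u_MNs) as one flat vector."""
        v = [self.units[l].state[0] for l in CPG_LABELS]
        h = [self.units[l].state[1] for l in CPG_LABELS]
        u = [self.units[l].state[0] for l in IN_LABELS + MN_LABELS]
        return np.array(v + h + u)

    def set_state_vector(self, y: np.ndarray) -> None:
        for i, l in enumerate(CPG_LABELS):
            self.units[l].state[0] = y[i]
            self.units[l].state[1] = y[4 + i]
        for j, l in enumerate(IN_LABELS + MN_LABELS):
            self.units[l].state[0] = y[8 + j]
        out = unit_outputs(y, self.config)
        for l, o in zip(UNIT_LABELS, out):
            self.units[l].output = float(o)


def _sigmoid(x):
    from scipy.special import expit
    return expit(x)


def unit_outputs(y: np.ndarray, cfg: NetworkConfig) -> np.ndarray:
    """Map the flat state vector to the 24 unit activities in [0, 1]."""
    c = cfg.cell
    out = np.empty(N_UNITS)
    out[:4] = _sigmoid((y[:4] - c.out_half) / c.out_slope)
    out[4:] = y[8:]
    return out


def initial_state(cfg: NetworkConfig) -> np.ndarray:
    c = cfg.cell
    v = np.full(4, cfg.v_init_mv)
    v[0] += cfg.c3_init_offset_mv
    h = _sigmoid(-(v - c.h_half) / c.h_slope)
    u = np.zeros(len(IN_LABELS) + len(MN_LABELS))
    return np.concatenate([v, h, u])


def build_network(config: RunConfig | NetworkConfig) -> NetworkModel:
    """Wire the canonical network (plus any configured extra synapses)."""
    cfg = config.network if isinstance(config, RunConfig) else config
    synapses = canonical_synapses(cfg)
    for s in cfg.extra_synapses:
        synapses.append(SynapseSpec(s.source, s.target, s.sign, s.conductance))
    y0 = initial_state(cfg)
    units: dict[str, NeuronUnit] = {}
    for i, l in enumerate(CPG_LABELS):
        units[l] = NeuronUnit(l, np.array([y0[i], y0[4 + i]]))
    for j, l in enumerate(IN_LABELS + MN_LABELS):
        units[l] = NeuronUnit(l, np.array([y0[8 + j]]))
    model = NetworkModel(cfg, units, synapses, CentralDrives.from_config(cfg))
    model.set_state_vector(y0)
    return model


# ---------------------------------------------------------------------------
# reference dynamics (plain numpy; the fast path lives in legsearch.engine)

def network_derivs(y: np.ndarray, model: NetworkModel,
                   g_beta: float, g_gamma: float) -> np.ndarray:
    """Time derivative of the flat network state for fixed gate conductances."""
    cfg = model.config
    c, u = cfg.cell, cfg.unit
    out = unit_outputs(y, cfg)
    dy = np.empty_like(y)

    g_exc = model.w_exc[:4] @ out + np.asarray(model.drives.g_app)
    g_inh = model.w_inh[:4] @ out
    V, h = y[:4], y[4:8]
    m = _sigmoid((V - c.m_half) / c.m_slope)
    i_nap = c.g_nap * m * h * (V - c.e_na)
    i_leak = c.g_leak * (V - c.e_leak)
    i_syn = g_inh * (V - c.e_inh) + g_exc * (V - c.e_exc)
    dy[:4] = -(i_nap + i_leak + i_syn) / c.c_m
    h_inf = _sigmoid(-(V - c.h_half) / c.h_slope)
    tau_c5 = c.tau_h_max_ms if c.tau_h_max_ef_ms is None else c.tau_h_max_ef_ms
    tau_c6 = tau_c5 if c.tau_h_max_c6_ms is None else c.tau_h_max_c6_ms
    tau_h_max = np.array([c.tau_h_max_ms, c.tau_h_max_ms, tau_c5, tau_c6])
    tau_h = tau_h_max / np.cosh((V - c.h_half) / (2.0 * c.h_slope))
    if h_inf[2] > h[2]:
        tau_h[2] *= c.c5_h_recovery_scale
    dy[4:8] = (h_inf - h) / tau_h

    inputs = model.w_exc[4:] @ out - model.w_inh[4:] @ out
    # sensory gates drive the relay interneurons; central g_d inhibit INs
    inputs[UNIT_INDEX["IN12"] - 4] += g_gamma
    inputs[UNIT_INDEX["IN18"] - 4] += g_beta
    for lbl, gd in model.drives.g_d.items():
        inputs[UNIT_INDEX[lbl] - 4] -= gd
    n_in = len(IN_LABELS)
    inputs[n_in:] += model.drives.g_mn
    inputs[n_in:] *= model.mn_multipliers
    act = _sigmoid((inputs - u.act_half) / u.act_slope)
    taus = np.concatenate([np.full(n_in, u.tau_in_ms),
                           np.full(len(MN_LABELS), u.tau_mn_ms)])
    dy[8:] = (act - y[8:]) / taus
    return dy


def step_units(model: NetworkModel, external: Mapping[str, float],
               dt: float, n_steps: int = 1) -> NetworkModel:
    """Advance all unit states by ``n_steps`` fixed RK4 steps of ``dt`` ms.

    ``external`` supplies the gate conductances ``g_beta`` and ``g_gamma``
    (held constant over the call).  Deterministic for fixed inputs; a
    non-finite state aborts with a diagnostic naming the offending unit.
    """
    if not 0.0 < dt <= 1.0:
        raise ConfigurationError("dt must lie in (0, 1] ms")
    g_beta = float(external.get("g_beta", 0.0))
    g_gamma = float(external.get("g_gamma", 0.0))
    y = model.state_vector()
    for _ in range(n_steps):
        k1 = network_derivs(y, model, g_beta, g_gamma)
        k2 = network_derivs(y + 0.5 * dt * k1, model, g_beta, g_gamma)
        k3 = network_derivs(y + 0.5 * dt * k2, model, g_beta, g_gamma)
        k4 = network_derivs(y + dt * k3, model, g_beta, g_gamma)
        y = y + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    if not np.all(np.isfinite(y)):
        bad = int(np.argmax(~np.isfinite(y)))
        lbl = (CPG_LABELS + CPG_LABELS + IN_LABELS + MN_LABELS)[bad]
        raise NumericalError(f"non-finite state in unit {lbl} after {n_steps} steps")
    model.set_state_vector(y)
    return model


def motoneuron_drive(model: NetworkModel,
                     overrides: Mapping[str, float] | None = None) -> dict[str, float]:
    """Apply per-class drive multipliers and return the effective MN inputs.

    ``overrides`` maps class keys (``fast_levator`` ... ``slow_flexor``) to
    multipliers in [0, 1]; the effective input of each MN is its nominal
    input (central drive minus premotor inhibition) times its class
    multiplier.  Multiplier 1 reproduces nominal behavior; 0 silences the
    class.  The multipliers persist on the model for subsequent integration.
    """
    overrides = dict(overrides or {})
    for key, val in overrides.items():
        if key not in MN_CLASS_KEYS:
            raise ConfigurationError(f"unknown MN class {key!r}")
        if not 0.0 <= val <= 1.0:
            raise ConfigurationError(f"multiplier for {key} outside [0, 1]")
    for i, lbl in enumerate(MN_LABELS):
        speed, role = MN_CLASS[lbl]
        model.mn_multipliers[i] = overrides.get(f"{speed}_{role}",
                                                model.mn_multipliers[i])
    y = model.state_vector()
    out = unit_outputs(y, model.config)
    inputs = model.w_exc[4:] @ out - model.w_inh[4:] @ out
    for lbl, gd in model.drives.g_d.items():
        inputs[UNIT_INDEX[lbl] - 4] -= gd
    n_in = len(IN_LABELS)
    mn_in = (inputs[n_in:] + model.drives.g_mn) * model.mn_multipliers
    return {lbl: float(v) for lbl, v in zip(MN_LABELS, mn_in)}


def audit_wiring(model: NetworkModel,
                 table: Iterable[tuple[str, str, str]]) -> list[str]:
    """Compare the model's synapse list sign-for-sign against a reference
    ``(source, target, sign)`` table; returns a list of discrepancies."""
    have = {(s.source, s.target): s.sign for s in model.synapses}
    want = {(s, t): sign for s, t, sign in table}
    problems = []
    for key, sign in want.items():
        if key not in have:
            problems.append(f"missing synapse {key[0]} -> {key[1]}")
        elif have[key] != sign:
            problems.append(f"wrong sign on {key[0]} -> {key[1]}: "
                            f"{have[key]} (expected {sign})")
    for key in have:
        if key not in want:
            problems.append(f"unexpected synapse {key[0]} -> {key[1]}")
    return problems
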