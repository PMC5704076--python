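"""Fixed-step integrator for the full coupled neuromechanical model.

This module is the performance core: a single flat state vector (4 CPG cell
voltages, 4 inactivation variables, 12 interneuron and 8 motoneuron
activities, 8 muscle activations, the two joint angles and two sensed-angle
filter states) advanced with an explicit 4th-order Runge-Kutta scheme at a
fixed step (default 0.1 ms).  Gate conductances and protocol drive
multipliers are evaluated once per step and held constant across the four
stages.  The inner loop is compiled with numba; the physics is the same as
the plain-numpy reference implementations in :mod:`legsearch.network` and
:mod:`legsearch.musculoskeletal`, which the test suite cross-checks against
this kernel.

Everything here is deterministic: identical configuration and step size give
bit-identical trajectories.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np

from .config import MUSCLE_ORDER, RunConfig
from .errors import NoContactError, NumericalError
from .network import MN_LABELS, N_UNITS, UNIT_INDEX, build_network
from .trace import MN_COLUMNS, SimTrace

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f

_IN12 = UNIT_INDEX["IN12"]
_IN18 = UNIT_INDEX["IN18"]

# state layout offsets
_NV, _NH, _NU, _NMN, _NMU = 4, 4, 12, 8, 8
_OFF_U = 8
_OFF_MN = 20
_OFF_MU = 28
_OFF_BETA = 36
_OFF_GAMMA = 37
_OFF_SB = 38
_OFF_SG = 39
_NSTATE = 40


@njit(cache=True)
def _sig(x):
    # overflow-safe logistic
    if x >= 0.0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


@njit(cache=True)
def _alpha_deg(beta, gamma, lf, lt):
    b = beta * math.pi / 180.0
    t = (beta - (180.0 - gamma)) * math.pi / 180.0
    x = lf * math.cos(b) + lt * math.cos(t)
    y = lf * math.sin(b) + lt * math.sin(t)
    return math.atan2(y, x) * 180.0 / math.pi


@njit(cache=True)
def _derivs(y, dy, pn, w_exc, w_inh, drv_app, drv_in, mult, af,
            gate_b, gate_g, m_rest, m_gain, m_pass, m_tau, tau_sense, freeze):
    o = np.empty(N_UNITS)
    for i in range(4):
        o[i] = _sig((y[i] - pn[12]) / pn[13])
    for j in range(20):
        o[4 + j] = y[_OFF_U + j]
    # half-center cells: persistent inward current + slow inactivation
    for i in range(4):
        ge = drv_app[i]
        gi = 0.0
        for j in range(N_UNITS):
            ge += w_exc[i, j] * o[j]
            gi += w_inh[i, j] * o[j]
        V = y[i]
        h = y[4 + i]
        m = _sig((V - pn[7]) / pn[8])
        i_total = (pn[3] * m * h * (V - pn[4]) + pn[1] * (V - pn[2])
                   + gi * (V - pn[5]) + ge * (V - pn[6]))
        dy[i] = -i_total / pn[0]
        h_inf = _sig(-(V - pn[9]) / pn[10])
        tau_h_max = pn[11] if i < 2 else (pn[18] if i == 2 else pn[19])
        vv = (V - pn[9]) / (2.0 * pn[10])
        if vv > 300.0:
            vv = 300.0
        elif vv < -300.0:
            vv = -300.0
        tau_h = tau_h_max / math.cosh(vv)
        if i == 2 and h_inf > h:
            tau_h *= pn[20]
        dy[4 + i] = (h_inf - h) / tau_h
    # first-order interneurons and motoneurons
    for j in range(20):
        tgt = 4 + j
        x = drv_in[tgt]
        for k in range(N_UNITS):
            x += w_exc[tgt, k] * o[k] - w_inh[tgt, k] * o[k]
        if tgt == _IN12:
            x += gate_g
        elif tgt == _IN18:
            x += gate_b
        if j >= _NU:
            x *= mult[j - _NU]
        a = _sig((x - pn[16]) / pn[17])
        tau = pn[14] if j < _NU else pn[15]
        dy[_OFF_U + j] = (a - y[_OFF_U + j]) / tau
    # muscle activations track MN output, capped by the recruited fraction
    for i in range(8):
        tgt_a = y[_OFF_MN + i] * af[i]
        dy[_OFF_MU + i] = (tgt_a - y[_OFF_MU + i]) / m_tau[i]
    # overdamped joints
    if freeze:
        dy[_OFF_BETA] = 0.0
        dy[_OFF_GAMMA] = 0.0
    else:
        beta = y[_OFF_BETA]
        gamma = y[_OFF_GAMMA]
        db = 0.0
        for i in range(4):
            db += (m_pass[i] + m_gain[i] * y[_OFF_MU + i]) * (m_rest[i] - beta)
        dg = 0.0
        for i in range(4, 8):
            dg += (m_pass[i] + m_gain[i] * y[_OFF_MU + i]) * (m_rest[i] - gamma)
        dy[_OFF_BETA] = db
        dy[_OFF_GAMMA] = dg
    # optional first-order sensory filter on the gated angles
    if tau_sense > 0.0:
        dy[_OFF_SB] = (y[_OFF_BETA] - y[_OFF_SB]) / tau_sense
        dy[_OFF_SG] = (y[_OFF_GAMMA] - y[_OFF_SG]) / tau_sense
    else:
        dy[_OFF_SB] = 0.0
        dy[_OFF_SG] = 0.0


@njit(cache=True)
def _gate(angle, thr, hi, lo, high_above):
    above = angle >= thr
    if not high_above:
        above = not above
    return hi if above else lo


@njit(cache=True)
def _run(y0, n_steps, dt, rec_every,
         pn, w_exc, w_inh, drv_app, drv_in, smult,
         gp, m_rest, m_gain, m_pass, m_tau, lf, lt, tau_sense,
         protocol_on, po, t_arm, contact_dur, slow_ramp, fast_ef_delay,
         dur_lev, dur_dep, quantized, n_lev, n_dep):
    n_rec = n_steps // rec_every + (0 if n_steps % rec_every == 0 else 1) + 1
    rec_t = np.empty(n_rec)
    rec_ang = np.empty((n_rec, 3))          # beta, gamma, alpha
    rec_mn = np.empty((n_rec, 8))
    rec_gate = np.empty((n_rec, 2))
    rec_sched = np.empty((n_rec, 3))        # mult_slow, af_lev, af_dep
    rec_v = np.empty((n_rec, 4))            # CPG cell voltages

    y = y0.copy()
    dy = np.empty(_NSTATE)
    k1 = np.empty(_NSTATE)
    k2 = np.empty(_NSTATE)
    k3 = np.empty(_NSTATE)
    k4 = np.empty(_NSTATE)
    yt = np.empty(_NSTATE)
    mult = np.empty(8)
    af = np.empty(8)

    contacted = False
    removed = False
    t_contact = np.nan
    t_removal = np.nan
    alpha_min = 1e30
    alpha_max = -1e30
    ir = 0

    for step in range(n_steps + 1):
        t = step * dt
        # --- protocol phase and schedule ---------------------------------
        if contacted and not removed and t >= t_contact + contact_dur:
            removed = True
            t_removal = t
        freeze = False
        mult_slow = 1.0
        af_lev = 1.0
        af_dep = 1.0
        if contacted and not removed:
            freeze = True
            mult_slow = 0.0
            af_lev = 0.0
            af_dep = 0.0
            for i in range(8):
                mult[i] = 0.0
                af[i] = 1.0
        elif removed:
            tp = t - t_removal
            mult_slow = tp / slow_ramp
            if mult_slow > 1.0:
                mult_slow = 1.0
            m_ef = 1.0 if tp >= fast_ef_delay else 0.0
            af_lev = tp / dur_lev
            if af_lev > 1.0:
                af_lev = 1.0
            af_dep = tp / dur_dep
            if af_dep > 1.0:
                af_dep = 1.0
            if quantized:
                af_lev = math.floor(af_lev * n_lev) / n_lev
                af_dep = math.floor(af_dep * n_dep) / n_dep
            for i in range(8):
                af[i] = 1.0
                if i % 2 == 1:                      # slow MNs
                    mult[i] = smult[i] * mult_slow
                elif i >= 4:                        # fast extensor/flexor
                    mult[i] = smult[i] * m_ef
                else:                               # fast levator/depressor
                    mult[i] = smult[i]
            af[0] = af_lev
            af[2] = af_dep
        else:
            for i in range(8):
                mult[i] = smult[i]
                af[i] = 1.0

        # --- gates from (possibly filtered) angles ------------------------
        sb = y[_OFF_SB] if tau_sense > 0.0 else y[_OFF_BETA]
        sg = y[_OFF_SG] if tau_sense > 0.0 else y[_OFF_GAMMA]
        gate_b = _gate(sb, gp[0], gp[2], gp[3], gp[6] > 0.5)
        gate_g = _gate(sg, gp[1], gp[4], gp[5], gp[7] > 0.5)

        # --- record --------------------------------------------------------
        if step % rec_every == 0 or step == n_steps:
            rec_t[ir] = t
            rec_ang[ir, 0] = y[_OFF_BETA]
            rec_ang[ir, 1] = y[_OFF_GAMMA]
            rec_ang[ir, 2] = _alpha_deg(y[_OFF_BETA], y[_OFF_GAMMA], lf, lt)
            for i in range(8):
                rec_mn[ir, i] = y[_OFF_MN + i]
            rec_gate[ir, 0] = gate_b
            rec_gate[ir, 1] = gate_g
            rec_sched[ir, 0] = mult_slow
            rec_sched[ir, 1] = af_lev
            rec_sched[ir, 2] = af_dep
            for i in range(4):
                rec_v[ir, i] = y[i]
            ir += 1
        if step == n_steps:
            break

        # --- one RK4 step --------------------------------------------------
        a_prev = _alpha_deg(y[_OFF_BETA], y[_OFF_GAMMA], lf, lt)
        _derivs(y, k1, pn, w_exc, w_inh, drv_app, drv_in, mult, af,
                gate_b, gate_g, m_rest, m_gain, m_pass, m_tau, tau_sense, freeze)
        for i in range(_NSTATE):
            yt[i] = y[i] + 0.5 * dt * k1[i]
        _derivs(yt, k2, pn, w_exc, w_inh, drv_app, drv_in, mult, af,
                gate_b, gate_g, m_rest, m_gain, m_pass, m_tau, tau_sense, freeze)
        for i in range(_NSTATE):
            yt[i] = y[i] + 0.5 * dt * k2[i]
        _derivs(yt, k3, pn, w_exc, w_inh, drv_app, drv_in, mult, af,
                gate_b, gate_g, m_rest, m_gain, m_pass, m_tau, tau_sense, freeze)
        for i in range(_NSTATE):
            yt[i] = y[i] + dt * k3[i]
        _derivs(yt, k4, pn, w_exc, w_inh, drv_app, drv_in, mult, af,
                gate_b, gate_g, m_rest, m_gain, m_pass, m_tau, tau_sense, freeze)
        for i in range(_NSTATE):
            y[i] += (dt / 6.0) * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])

        # clamps: activities in [0,1], gamma at its mechanical stop
        for j in range(_OFF_U, _OFF_MU + 8):
            if y[j] < 0.0:
                y[j] = 0.0
            elif y[j] > 1.0:
                y[j] = 1.0
        if y[_OFF_GAMMA] > 180.0:
            y[_OFF_GAMMA] = 180.0
        elif y[_OFF_GAMMA] < 1.0:
            y[_OFF_GAMMA] = 1.0
        if tau_sense <= 0.0:
            y[_OFF_SB] = y[_OFF_BETA]
            y[_OFF_SG] = y[_OFF_GAMMA]

        # --- contact detection (downward alpha crossing of PO) ------------
        if protocol_on and not contacted and t + dt >= t_arm:
            a_new = _alpha_deg(y[_OFF_BETA], y[_OFF_GAMMA], lf, lt)
            if a_new < alpha_min:
                alpha_min = a_new
            if a_new > alpha_max:
                alpha_max = a_new
            if a_prev > po and a_new <= po and a_new < a_prev:
                contacted = True
                t_contact = t + dt
        if not np.isfinite(y[0]):
            break

    return (rec_t[:ir], rec_ang[:ir], rec_mn[:ir], rec_gate[:ir],
            rec_sched[:ir], rec_v[:ir], t_contact, t_removal,
            alpha_min, alpha_max, y)


# ---------------------------------------------------------------------------
# parameter packing and the python-facing entry point

def _pack(config: RunConfig):
    net = config.network
    c, u = net.cell, net.unit
    pn = np.array([c.c_m, c.g_leak, c.e_leak, c.g_nap, c.e_na, c.e_inh,
                   c.e_exc, c.m_half, c.m_slope, c.h_half, c.h_slope,
                   c.tau_h_max_ms, c.out_half, c.out_slope,
                   u.tau_in_ms, u.tau_mn_ms, u.act_half, u.act_slope,
                   0.0, 0.0, c.c5_h_recovery_scale])
    pn[18] = c.tau_h_max_ms if c.tau_h_max_ef_ms is None else c.tau_h_max_ef_ms
    pn[19] = pn[18] if c.tau_h_max_c6_ms is None else c.tau_h_max_c6_ms
    model = build_network(config)
    drv_app = np.array(model.drives.g_app)
    drv_in = np.zeros(N_UNITS)
    for lbl, gd in model.drives.g_d.items():
        drv_in[UNIT_INDEX[lbl]] -= gd
    for lbl in MN_LABELS:
        drv_in[UNIT_INDEX[lbl]] += model.drives.g_mn
    g = config.gating
    gp = np.array([g.beta_thr_deg, g.gamma_thr_deg,
                   g.g_beta_high, g.g_beta_low, g.g_gamma_high, g.g_gamma_low,
                   1.0 if g.beta_high_above else 0.0,
                   1.0 if g.gamma_high_above else 0.0])
    msk = config.musculoskeletal
    muscles = [msk.muscle(name) for name in MUSCLE_ORDER]
    m_rest = np.array([m.rest_angle_deg for m in muscles])
    m_gain = np.array([m.gain_per_ms for m in muscles])
    m_pass = np.array([m.passive_per_ms for m in muscles])
    m_tau = np.array([m.tau_act_ms for m in muscles])
    return model, pn, drv_app, drv_in, gp, m_rest, m_gain, m_pass, m_tau


def initial_full_state(config: RunConfig) -> np.ndarray:
    from .network import initial_state
    y = np.zeros(_NSTATE)
    y[:28] = initial_state(config.network)
    msk = config.musculoskeletal
    y[_OFF_BETA] = msk.beta_init_deg
    y[_OFF_GAMMA] = msk.gamma_init_deg
    y[_OFF_SB] = y[_OFF_BETA]
    y[_OFF_SG] = y[_OFF_GAMMA]
    return y


def simulate(config: RunConfig, duration_ms: float,
             po: Optional[float] = None,
             static_multipliers: Optional[np.ndarray] = None,
             y0: Optional[np.ndarray] = None,
             dt_ms: Optional[float] = None,
             record_every_ms: Optional[float] = None) -> SimTrace:
    """Integrate the full model and return a recorded trace.

    With ``po`` set, the obstacle protocol is active: after the arming time
    the first downward crossing of the tarsus angle through ``po`` freezes
    the leg and silences all motoneurons for the contact duration, and the
    staged reactivation schedule runs from the removal instant.  Without
    ``po`` the model runs freely.  ``static_multipliers`` (length 8, one per
    MN in canonical order) scale the MN inputs throughout the run.
    """
    model, pn, drv_app, drv_in, gp, m_rest, m_gain, m_pass, m_tau = _pack(config)
    dt = float(dt_ms if dt_ms is not None else config.integration.dt_ms)
    rec_ms = float(record_every_ms if record_every_ms is not None
                   else config.integration.record_every_ms)
    rec_every = max(1, int(round(rec_ms / dt)))
    n_steps = int(round(duration_ms / dt))
    smult = (np.ones(8) if static_multipliers is None
             else np.asarray(static_multipliers, dtype=float))

    prot = config.protocol
    from .protocol import recruitment_factor, select_interpolation_set
    if po is not None:
        iset = select_interpolation_set(config)
        rf_lev = recruitment_factor(po, iset.levator)
        rf_dep = recruitment_factor(po, iset.depressor)
    else:
        rf_lev = rf_dep = 1.0
    dur_lev = prot.base_duration_ms * rf_lev
    dur_dep = prot.base_duration_ms * rf_dep
    msk = config.musculoskeletal

    if y0 is None:
        y0 = initial_full_state(config)
    out = _run(np.asarray(y0, dtype=float), n_steps, dt, rec_every,
               pn, model.w_exc, model.w_inh, drv_app, drv_in, smult,
               gp, m_rest, m_gain, m_pass, m_tau,
               msk.femur_mm, msk.tibia_mm, config.gating.sensory_tau_ms,
               po is not None, po if po is not None else 0.0,
               prot.t_arm_ms, prot.contact_duration_ms, prot.slow_ramp_ms,
               prot.fast_ef_delay_ms, dur_lev, dur_dep,
               msk.quantized_recruitment,
               msk.levator_fast.n_units, msk.depressor_fast.n_units)
    (rec_t, rec_ang, rec_mn, rec_gate, rec_sched, rec_v,
     t_contact, t_removal, a_min, a_max, y_final) = out

    if not np.all(np.isfinite(rec_ang)):
        raise NumericalError("integration diverged (non-finite angles)")
    if po is not None and not np.isfinite(t_contact):
        raise NoContactError(po, a_min, a_max)

    events: dict[str, float] = {}
    meta = {"config_hash": config.config_hash(), "preset": config.preset,
            "dt_ms": dt}
    if po is not None:
        events["contact"] = float(t_contact)
        events["removal"] = float(t_removal)
        events["slow_full"] = float(t_removal + prot.slow_ramp_ms)
        events["fast_ld_full_levator"] = float(t_removal + dur_lev)
        events["fast_ld_full_depressor"] = float(t_removal + dur_dep)
        meta.update(po=float(po), rf_levator=rf_lev, rf_depressor=rf_dep)
    mn = {name: rec_mn[:, i] for i, name in enumerate(MN_COLUMNS)}
    gates = {"gate_beta": rec_gate[:, 0], "gate_gamma": rec_gate[:, 1]}
    extras = {"mult_slow": rec_sched[:, 0], "af_lev": rec_sched[:, 1],
              "af_dep": rec_sched[:, 2],
              "v_c3": rec_v[:, 0], "v_c4": rec_v[:, 1],
              "v_c5": rec_v[:, 2], "v_c6": rec_v[:, 3]}
    trace = SimTrace(rec_t, rec_ang[:, 0], rec_ang[:, 1], rec_ang[:, 2],
                     mn, gates, extras, events, meta)
    # full integrator state at the end of the run (not serialized with the
    # trace); lets callers continue a simulation from where it stopped
    trace.final_state = y_final.copy()
    return trace
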