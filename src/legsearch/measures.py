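"""Derived scalar measurements on simulated runs.

These helpers wrap full simulations into the headline quantities of the
model: recovery-schedule latencies, the passive-rigidity hold time, and the
calibrated search-rhythm angle extrema.  They are used by the test suite and
the reproduction script alike.
"""

from __future__ import annotations

import numpy as np

from .config import RunConfig, default_config
from .errors import ProtocolError

__all__ = [
    "slow_reactivation_latency_ms", "fast_ld_recruitment_time_ms",
    "posture_hold_time_ms", "search_angle_extrema", "rf_maximizing_po",
]


def slow_reactivation_latency_ms(config: RunConfig, po_deg: float = 0.0) -> float:
    """Time from obstacle removal until every slow-MN drive multiplier is 1.

    Measured from the recorded schedule column of an obstacle-experiment
    trace, not from the schedule formula.
    """
    from .protocol import run_obstacle_experiment
    trace = run_obstacle_experiment(config, po_deg)
    t_rem = trace.events["removal"]
    after = trace.t_ms >= t_rem
    full = after & (trace.extras["mult_slow"] >= 1.0)
    if not np.any(full):
        raise ProtocolError("slow-MN drive never reached full within the run")
    return float(trace.t_ms[full][0] - t_rem)


def rf_maximizing_po(config: RunConfig, po_lo: float = -40.0,
                     po_hi: float = 25.0) -> float:
    """Obstacle position (on a 1-degree grid) maximizing the recruitment
    slow-down factor of the slower fast levator/depressor pool."""
    from .protocol import recruitment_factor, select_interpolation_set
    iset = select_interpolation_set(config)
    grid = np.arange(po_lo, po_hi + 0.5, 1.0)
    rf = [max(recruitment_factor(po, iset.levator),
              recruitment_factor(po, iset.depressor)) for po in grid]
    return float(grid[int(np.argmax(rf))])


def fast_ld_recruitment_time_ms(config: RunConfig, po_deg: float) -> float:
    """Time from removal until both fast levator and depressor pools are
    fully recruited (recorded recruited-fraction columns reach 1)."""
    from .protocol import run_obstacle_experiment
    trace = run_obstacle_experiment(config, po_deg)
    t_rem = trace.events["removal"]
    after = trace.t_ms >= t_rem
    full = after & (trace.extras["af_lev"] >= 1.0) & (trace.extras["af_dep"] >= 1.0)
    if not np.any(full):
        raise ProtocolError("fast levator/depressor pools never fully "
                            "recruited within the run")
    return float(trace.t_ms[full][0] - t_rem)


def posture_hold_time_ms(config: RunConfig, drift_deg: float = 2.0,
                         settle_ms: float = 8000.0,
                         probe_ms: float = 4000.0) -> float:
    """How long the silenced leg holds its posture by passive rigidity alone.

    The unperturbed rhythm is integrated until a femur turning point (the
    posture the leg naturally pauses in); from that state every motoneuron
    drive multiplier is set to zero and the integration continues.  Returns
    the time until either joint angle first drifts more than ``drift_deg``
    from its value at silencing.
    """
    from . import engine
    from .analysis import extract_cycles
    free = engine.simulate(config, settle_ms)
    seg = free.segment(t0=settle_ms / 2)
    cycles = extract_cycles(seg.t_ms, seg.beta)
    if not cycles:
        raise ProtocolError("no rhythm to probe posture holding from")
    c = cycles[-1]
    i_peak = c.start + int(np.argmax(seg.beta[c]))
    t_peak = float(seg.t_ms[i_peak])
    primed = engine.simulate(config, t_peak)
    held = engine.simulate(config, probe_ms, y0=primed.final_state,
                           static_multipliers=np.zeros(8))
    db = np.abs(held.beta - held.beta[0])
    dg = np.abs(held.gamma - held.gamma[0])
    out = np.nonzero((db > drift_deg) | (dg > drift_deg))[0]
    if out.size == 0:
        return float(held.t_ms[-1] - held.t_ms[0])
    return float(held.t_ms[out[0]] - held.t_ms[0])


def search_angle_extrema(config: RunConfig | None = None,
                         duration_ms: float = 10_000.0,
                         transient_ms: float = 2000.0) -> dict[str, tuple[float, float]]:
    """Post-transient min/max of alpha, beta, gamma for the calibrated
    default search rhythm (threshold preset gamma_thr=145, beta_thr=16)."""
    from . import engine
    from .analysis import oscillation_stats
    if config is None:
        config = default_config("switch_b16")
    trace = engine.simulate(config, duration_ms)
    return oscillation_stats(trace, transient_ms=transient_ms).ranges
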