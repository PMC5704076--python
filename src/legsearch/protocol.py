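"""The obstacle-perturbation experiment and its recovery schedule.

Protocol, in the model's terms: the leg performs established rhythmic search
movements; an obstacle at angular position PO (on the tarsus angle alpha) is
hit on a downward swing, which silences every motoneuron while the passive
muscle rigidity holds the posture; after a very short contact (< 100 ms) the
obstacle is removed and the motor output is restored in stages --

1. all slow MNs ramp back to full drive within 200 ms,
2. the single fast extensor and flexor MNs are reactivated immediately,
3. the fast levator and depressor MN pools are *gradually* recruited, over
   ``base_duration * rf(PO)``, where the recruitment slow-down factor rf is
   linearly interpolated in PO between known endpoints (rf = 1 means the
   normal rate, rf = 2 half the rate).  Two interpolation-function sets
   exist: set A for low femur thresholds (beta_thr <= ~6 deg) and set B for
   high ones (> 10 deg), each with separate levator and depressor lines.

Contact is modeled as a kinematic freeze plus MN silencing, not as a contact
force, and only a downward-moving tarsus can hit the obstacle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .analysis import (detect_alternating_amplitude, detect_cessation,
                       extract_cycles, oscillation_stats, state_diagram)
from .config import PRESETS, InterpolationSetConfig, RampConfig, RunConfig
from .errors import ConfigurationError, NoContactError, ProtocolError
from .trace import SimTrace

__all__ = [
    "ObstacleEvent", "ReactivationSchedule", "recruitment_factor",
    "select_interpolation_set", "detect_contact", "staged_reactivation",
    "run_free", "run_obstacle_experiment", "run_po_sweep",
]


@dataclass(frozen=True)
class ObstacleEvent:
    """A recorded obstacle contact."""

    po_deg: float
    t_contact_ms: float
    contact_duration_ms: float = 100.0

    def __post_init__(self):
        if not 0.0 < self.contact_duration_ms <= 100.0:
            raise ConfigurationError("contact duration must be in (0, 100] ms")

    @property
    def t_removal_ms(self) -> float:
        return self.t_contact_ms + self.contact_duration_ms


@dataclass(frozen=True)
class ReactivationSchedule:
    """Timing of the staged motor recovery after obstacle removal."""

    slow_ramp_ms: float = 200.0
    fast_ef_delay_ms: float = 0.0
    fast_ld_duration_lev_ms: float = 500.0
    fast_ld_duration_dep_ms: float = 500.0
    interpolation_set: str = "A"

    def __post_init__(self):
        if self.slow_ramp_ms > 200.0 or self.slow_ramp_ms <= 0:
            raise ConfigurationError("slow ramp must be in (0, 200] ms")
        if self.fast_ef_delay_ms < 0:
            raise ConfigurationError("fast extensor/flexor delay must be >= 0")


def recruitment_factor(po_deg: float, ramp) -> float:
    """Linear interpolation of the recruitment slow-down factor at ``po``.

    ``ramp`` carries endpoints (rf0 at po0, rf1 at po1).  Extrapolation
    outside [po0, po1] is linear, floored at 1 (rf < 1 has no meaning: the
    normal rate is the fastest possible).
    """
    po0, po1 = float(ramp.po0_deg), float(ramp.po1_deg)
    if po0 == po1:
        raise ConfigurationError("ramp endpoints must differ in PO")
    rf = (ramp.rf1 - ramp.rf0) / (po1 - po0) * (po_deg - po0) + ramp.rf0
    return max(rf, 1.0)


def select_interpolation_set(config: RunConfig) -> InterpolationSetConfig:
    """Set A for low femur thresholds, set B for high ones."""
    prot = config.protocol
    if config.gating.beta_thr_deg <= prot.set_a_max_beta_thr_deg:
        return prot.set_a
    return prot.set_b


def schedule_for(config: RunConfig, po_deg: float) -> ReactivationSchedule:
    iset = select_interpolation_set(config)
    base = config.protocol.base_duration_ms
    return ReactivationSchedule(
        slow_ramp_ms=config.protocol.slow_ramp_ms,
        fast_ef_delay_ms=config.protocol.fast_ef_delay_ms,
        fast_ld_duration_lev_ms=base * recruitment_factor(po_deg, iset.levator),
        fast_ld_duration_dep_ms=base * recruitment_factor(po_deg, iset.depressor),
        interpolation_set="A" if iset is config.protocol.set_a else "B",
    )


def staged_reactivation(t_since_removal_ms: float,
                        schedule: ReactivationSchedule) -> dict[str, float]:
    """Per-class drive multipliers / recruited fractions at a recovery time.

    Returns ``slow`` (all slow MNs), ``fast_extensor_flexor``,
    ``fast_levator_fraction`` and ``fast_depressor_fraction``.  All are 0
    during contact (negative times are rejected: the contact epoch is not
    part of the recovery clock).
    """
    t = t_since_removal_ms
    if t < 0:
        raise ConfigurationError("t_since_removal must be >= 0")
    return {
        "slow": min(1.0, t / schedule.slow_ramp_ms),
        "fast_extensor_flexor": 1.0 if t >= schedule.fast_ef_delay_ms else 0.0,
        "fast_levator_fraction": min(1.0, t / schedule.fast_ld_duration_lev_ms),
        "fast_depressor_fraction": min(1.0, t / schedule.fast_ld_duration_dep_ms),
    }


def detect_contact(trace, po_deg: float) -> float:
    """First time the tarsus angle crosses ``po`` moving downward (offline).

    ``trace`` is a :class:`SimTrace` (or anything with ``t_ms`` and
    ``alpha``).  The crossing time is linearly interpolated between samples.
    Raises :class:`NoContactError` with the achieved alpha range if the
    obstacle is never reached on a downward swing.
    """
    t = np.asarray(trace.t_ms, dtype=float)
    a = np.asarray(trace.alpha, dtype=float)
    down = (a[:-1] > po_deg) & (a[1:] <= po_deg)
    idx = np.nonzero(down)[0]
    if idx.size == 0:
        raise NoContactError(po_deg, float(a.min()), float(a.max()))
    i = int(idx[0])
    frac = (a[i] - po_deg) / (a[i] - a[i + 1])
    return float(t[i] + frac * (t[i + 1] - t[i]))


# ---------------------------------------------------------------------------
# simulation drivers

def run_free(config: RunConfig, duration_ms: float = 10_000.0,
             **kwargs) -> SimTrace:
    """Unperturbed search rhythm (no obstacle)."""
    from . import engine
    return engine.simulate(config, duration_ms, po=None, **kwargs)


def _rhythm_diagnostic(config: RunConfig) -> str:
    from .gating import gating_regime
    try:
        trace = run_free(config, 8000.0)
        n_beta = len(extract_cycles(trace.t_ms, trace.beta))
        n_gamma = len(extract_cycles(trace.t_ms, trace.gamma))
        try:
            regime = gating_regime(trace.t_ms, trace.gamma,
                                   config.gating.gamma_thr_deg)
        except Exception:
            regime = "undetermined"
        return (f"beta cycles={n_beta}, gamma cycles={n_gamma}, "
                f"gamma gating regime={regime}")
    except Exception as exc:  # pragma: no cover - diagnostic of last resort
        return f"diagnostic run failed: {exc}"


def run_obstacle_experiment(config: RunConfig, po_deg: float) -> SimTrace:
    """Full perturbation-recovery run at one obstacle position.

    The returned trace contains the established pre-contact rhythm (at least
    three whole cycles), the contact epoch with held angles, and the
    post-removal recovery, with the contact/removal/full-recruitment event
    timestamps and the rf values embedded in the trace metadata.
    """
    from . import engine
    prot = config.protocol
    duration = (prot.t_arm_ms + prot.contact_wait_ms
                + prot.contact_duration_ms + prot.post_removal_ms)
    try:
        trace = engine.simulate(config, duration, po=po_deg)
    except NoContactError:
        raise ProtocolError(
            f"no contact at PO={po_deg:.1f} deg "
            f"(gamma_thr={config.gating.gamma_thr_deg:.0f}, "
            f"beta_thr={config.gating.beta_thr_deg:.0f}); "
            + _rhythm_diagnostic(config)) from None
    pre = trace.segment(t1=trace.events["contact"])
    if len(extract_cycles(pre.t_ms, pre.beta)) < 3 \
            and len(extract_cycles(pre.t_ms, pre.gamma)) < 3:
        raise ProtocolError(
            "no established pre-contact rhythm: " + _rhythm_diagnostic(config))
    return trace


def _row_descriptors(config: RunConfig, trace: SimTrace) -> dict:
    ana = config.analysis
    t_rem = trace.events["removal"]
    post = trace.segment(t0=t_rem)
    diagram = state_diagram(trace, tol_frac=ana.rdp_tol_frac,
                            floor_deg=ana.cessation_floor_deg)
    row: dict = {
        "rf_levator": trace.meta.get("rf_levator"),
        "rf_depressor": trace.meta.get("rf_depressor"),
        "t_contact_ms": trace.events["contact"],
        "pre_class": diagram.pre_class.label if diagram.pre_class else None,
        "pre_vertices": diagram.pre_class.vertex_count if diagram.pre_class else 0,
        "post_class": diagram.post_class.label if diagram.post_class else None,
    }
    for name in ("beta", "gamma"):
        x = getattr(post, name)
        ces = detect_cessation(post.t_ms, x, ana.cessation_floor_deg,
                               ana.cessation_min_ms, ana.cessation_window_ms)
        row[f"{name}_cessation"] = bool(ces)
        row[f"{name}_cessation_ms"] = max((b - a for a, b in ces), default=0.0)
        alt = detect_alternating_amplitude(post.t_ms, x,
                                           ana.alternation_rel_diff,
                                           ana.alternation_min_pairs,
                                           ana.smooth_frac)
        row[f"{name}_alternating"] = alt.flag
        row[f"{name}_alternation_depth"] = alt.depth
    stats = oscillation_stats(post)
    for name in ("beta", "gamma"):
        lo, hi = stats.ranges[name]
        row[f"{name}_min"] = lo
        row[f"{name}_max"] = hi
    row["period_ms"] = stats.period_ms
    return row


def run_po_sweep(config: RunConfig, po_values: Sequence[float],
                 presets: Optional[Iterable[str]] = None) -> pd.DataFrame:
    """Obstacle-position sweep over threshold presets.

    One row per (preset, PO) with the analysis descriptors: state-diagram
    class before/after, cessation flags and durations, alternating-amplitude
    flags, post-recovery angle ranges and period.  Individual run failures
    are recorded in the ``error`` column and the sweep continues.  The sweep
    is deterministic: re-running it reproduces every row bit-exactly.
    """
    if presets is None:
        presets = list(PRESETS)
    presets = list(presets)
    if not po_values or not presets:
        raise ConfigurationError("need at least one PO value and one preset")
    rows = []
    for preset in presets:
        cfg = config.model_copy(deep=True)
        cfg.preset = preset  # revalidates thresholds via the preset table
        cfg = RunConfig.model_validate(cfg.model_dump())
        for po in po_values:
            row = {"preset": preset,
                   "gamma_thr_deg": cfg.gating.gamma_thr_deg,
                   "beta_thr_deg": cfg.gating.beta_thr_deg,
                   "po_deg": float(po), "error": ""}
            try:
                trace = run_obstacle_experiment(cfg, float(po))
                row.update(_row_descriptors(cfg, trace))
            except Exception as exc:
                row["error"] = f"{type(exc).__name__}: {exc}"
            rows.append(row)
    return pd.DataFrame(rows)
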