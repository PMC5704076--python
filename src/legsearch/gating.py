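"""Threshold-gated sensory coupling between the two local networks.

Joint-angle signals are converted into two-valued synaptic conductances:
``g_beta`` (femur elevation, onto IN18 of the extensor-flexor network) and
``g_gamma`` (femur-tibia angle, onto IN12 of the levator-depressor network).
The conductance is ``g_high`` when the angle is at or above its threshold and
``g_low`` below it -- a hard switch with no intermediate values, no
hysteresis, evaluated on the instantaneous angle.

Two qualitatively different driving regimes follow.  With the threshold
below the angle's oscillation floor the gate never switches after the first
cycle (*tonic* regime: the receiving network is steadily excited); with the
threshold inside the oscillation band the gate flips every cycle
(*switching* regime: the excitation is itself periodic).
"""

from __future__ import annotations

from typing import Literal

import numpy as np

from .errors import AnalysisError

Regime = Literal["tonic", "switching"]


def gate_conductance(angle, thr: float, g_high: float, g_low: float,
                     high_above: bool = True):
    """Two-valued gate: ``g_high`` iff angle >= thr (ties go high).

    ``high_above=False`` flips the polarity (high below threshold).
    Accepts scalars or arrays.
    """
    if not g_high >= g_low >= 0.0:
        raise ValueError("need g_high >= g_low >= 0")
    angle = np.asarray(angle, dtype=float)
    above = angle >= thr
    cond = above if high_above else ~above
    out = np.where(cond, g_high, g_low)
    return out if out.ndim else float(out)


def gating_regime(t_ms, angle, thr: float, high_above: bool = True) -> Regime:
    """Classify the gate driven by an angle trace as tonic or switching.

    The trace must span at least three oscillation cycles (or be constant).
    ``tonic``: the gate value never changes after the first cycle;
    ``switching``: it changes at least once per cycle on average.  Sporadic
    switches rarer than one per cycle are treated as tonic.
    """
    from .analysis import extract_cycles  # deferred: avoids import cycle

    t_ms = np.asarray(t_ms, dtype=float)
    angle = np.asarray(angle, dtype=float)
    if t_ms.shape != angle.shape or t_ms.size < 4:
        raise AnalysisError("need matching, non-trivial time and angle arrays")
    cycles = extract_cycles(t_ms, angle)
    if np.ptp(angle) < 1e-9:
        return "tonic"
    if len(cycles) < 3:
        raise AnalysisError(
            f"trace spans only {len(cycles)} full cycles; need >= 3")
    gate = gate_conductance(angle, thr, 1.0, 0.0, high_above)
    first_cycle_end = cycles[0].stop
    changes = int(np.count_nonzero(np.diff(gate[first_cycle_end:])))
    if changes == 0:
        return "tonic"
    return "switching" if changes >= len(cycles) - 1 else "tonic"
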