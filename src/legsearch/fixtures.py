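"""Synthetic angle-trace generators for testing the analysis layer.

Each fixture constructs a trace that exhibits one named phenomenon *by
construction* -- a triangular or rectangular beta-gamma loop, an
alternating-amplitude oscillation, an oscillation that ceases mid-trace, or
up-down bobbing of a stretched leg -- so the analysis operations can be
validated without running the simulator.  Construction labels are embedded
in the trace metadata for the tests to assert against.  Fixtures are
deterministic for a given seed; the seed only feeds the optional noise.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .errors import ConfigurationError
from .musculoskeletal import LegGeometry, compute_alpha
from .trace import SimTrace

KINDS = ("triangle-loop", "rectangle-loop", "alternating", "cessation",
         "stretched-bobbing")

_TRIANGLE = np.array([(30.0, 170.0), (-5.0, 170.0), (-4.0, 85.0)])
_RECTANGLE = np.array([(-5.0, 85.0), (30.0, 85.0), (30.0, 170.0), (-5.0, 170.0)])


def _polygon_loop(vertices: np.ndarray, t_ms: np.ndarray, period_ms: float):
    """Traverse a closed polygon at constant speed, once per period."""
    closed = np.vstack([vertices, vertices[:1]])
    seg = np.hypot(*np.diff(closed, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    phase = (t_ms % period_ms) / period_ms * s[-1]
    beta = np.interp(phase, s, closed[:, 0])
    gamma = np.interp(phase, s, closed[:, 1])
    return beta, gamma


def make_fixture(kind: str, params: Optional[dict] = None,
                 seed: int = 0) -> SimTrace:
    """Build one synthetic trace of the requested kind.

    Common params: ``duration_ms`` (default 8000), ``period_ms`` (1000),
    ``dt_ms`` (2), ``noise_deg`` (0; gaussian, seeded).  Kind-specific
    params: loop fixtures accept ``vertices`` ((n, 2) beta/gamma arrays);
    ``alternating`` accepts ``amp_high``/``amp_low`` (25/15 deg);
    ``cessation`` accepts ``t_stop_ms`` (half the duration) and
    ``hold_deg`` (165); ``stretched-bobbing`` accepts ``gamma_hold``
    (160) and ``beta_amp`` (17).
    """
    if kind not in KINDS:
        raise ConfigurationError(f"unknown fixture kind {kind!r}; known: {KINDS}")
    p = dict(params or {})
    duration = float(p.pop("duration_ms", 8000.0))
    period = float(p.pop("period_ms", 1000.0))
    dt = float(p.pop("dt_ms", 2.0))
    noise = float(p.pop("noise_deg", 0.0))
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration, dt)
    meta: dict = {"fixture": kind, "seed": seed, "period_ms": period}

    if kind in ("triangle-loop", "rectangle-loop"):
        default = _TRIANGLE if kind == "triangle-loop" else _RECTANGLE
        vertices = np.asarray(p.pop("vertices", default), dtype=float)
        beta, gamma = _polygon_loop(vertices, t, period)
        meta["label"] = "triangular" if kind == "triangle-loop" else "quadrilateral"
        meta["n_vertices"] = int(vertices.shape[0])
    elif kind == "alternating":
        amp_high = float(p.pop("amp_high", 25.0))
        amp_low = float(p.pop("amp_low", 15.0))
        cyc = np.floor(t / period).astype(int)
        amp = np.where(cyc % 2 == 0, amp_high, amp_low)
        gamma = 130.0 + amp * np.sin(2 * np.pi * t / period)
        beta = 12.0 + 15.0 * np.sin(2 * np.pi * t / period - 0.5 * np.pi)
        meta["label"] = "alternating"
        meta["amplitudes"] = [amp_high, amp_low]
    elif kind == "cessation":
        t_stop = float(p.pop("t_stop_ms", duration / 2))
        hold = float(p.pop("hold_deg", 165.0))
        gamma = 130.0 + 40.0 * np.sin(2 * np.pi * t / period)
        # freeze at the hold angle from the stop time onward
        gamma = np.where(t < t_stop, gamma, hold)
        beta = 12.0 + 17.0 * np.sin(2 * np.pi * t / period - 0.5 * np.pi)
        meta["label"] = "cessation"
        meta["t_stop_ms"] = t_stop
    else:  # stretched-bobbing
        gamma_hold = float(p.pop("gamma_hold", 160.0))
        beta_amp = float(p.pop("beta_amp", 17.0))
        gamma = np.full_like(t, gamma_hold)
        beta = 12.0 + beta_amp * np.sin(2 * np.pi * t / period)
        meta["label"] = "stretched-bobbing"
    if p:
        raise ConfigurationError(f"unknown fixture params: {sorted(p)}")

    if noise > 0:
        beta = beta + rng.normal(0.0, noise, beta.size)
        gamma = np.clip(gamma + rng.normal(0.0, noise, gamma.size), 1.0, 180.0)
    gamma = np.clip(gamma, 1.0, 180.0)
    alpha = compute_alpha(beta, gamma, LegGeometry())
    return SimTrace(t, beta, gamma, np.asarray(alpha), meta=meta)
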