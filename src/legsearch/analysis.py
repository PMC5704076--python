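"""Quantitative descriptors of simulated (or experimental) angle traces.

The layer is simulator-agnostic: it consumes time-indexed ``beta``/``gamma``/
``alpha`` series in degrees, from whatever source.  It provides

* cycle segmentation (mean-crossing with a small hysteresis band),
* beta-gamma state diagrams with cycle-averaged loops,
* loop-shape classification (triangular vs quadrilateral vs degenerate) by
  iterative vertex pruning of the cycle-averaged loop,
* oscillation-cessation detection (sliding-window peak-to-peak amplitude),
* alternating-amplitude detection (period-2-like peak envelopes), and
* basic oscillation statistics (ranges, period, per-cycle amplitudes).

The triangular/quadrilateral distinction is operationalized as the dominant
vertex count of the simplified cycle-averaged loop; the original description
is by eye, so the pruning tolerance (a fraction of the loop's bounding-box
diagonal) is an explicit knob.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal
from scipy.ndimage import maximum_filter1d, minimum_filter1d

from .errors import AnalysisError

__all__ = [
    "LoopClass", "StateDiagram", "AlternationResult", "OscStats",
    "extract_cycles", "cycle_average_loop", "classify_loop",
    "detect_cessation", "detect_alternating_amplitude", "oscillation_stats",
    "state_diagram",
]


# ---------------------------------------------------------------------------
# cycle segmentation

def extract_cycles(t_ms, x, min_range: float = 1.0) -> list[slice]:
    """Split an oscillating trace into whole cycles.

    Cycles are delimited at successive *upward* crossings of the trace mean;
    a hysteresis band of 5% of the range suppresses jitter crossings.
    Partial cycles at either end are discarded.  A trace with no detectable
    oscillation (range below ``min_range`` degrees, or fewer than two
    crossings) yields an empty list -- that is a result, not an error.
    """
    t_ms = np.asarray(t_ms, dtype=float)
    x = np.asarray(x, dtype=float)
    if x.size < 4 or np.ptp(x) < min_range:
        return []
    mean = float(np.mean(x))
    band = 0.05 * np.ptp(x)
    starts: list[int] = []
    armed = x[0] < mean - band
    for i in range(1, x.size):
        if armed and x[i] >= mean:
            starts.append(i)
            armed = False
        elif not armed and x[i] < mean - band:
            armed = True
    return [slice(a, b) for a, b in zip(starts[:-1], starts[1:])]


def _cycle_periods(t_ms, cycles: list[slice]) -> np.ndarray:
    t_ms = np.asarray(t_ms, dtype=float)
    return np.array([t_ms[c.stop] - t_ms[c.start] for c in cycles])


# ---------------------------------------------------------------------------
# state diagrams and loop classification

@dataclass
class LoopClass:
    """Shape class of a closed beta-gamma loop."""

    label: str                 # triangular | quadrilateral | degenerate-line | quiescent
    vertex_count: int
    confidence: float          # in [0, 1]


@dataclass
class StateDiagram:
    """Cycle-averaged beta-gamma loops before contact and after removal."""

    pre_loop: Optional[np.ndarray]       # (n, 2) columns beta, gamma
    post_loop: Optional[np.ndarray]
    pre_cycles: int = 0
    post_cycles: int = 0
    pre_class: Optional[LoopClass] = None
    post_class: Optional[LoopClass] = None


def cycle_average_loop(beta, gamma, cycles: list[slice],
                       n_points: int = 200) -> np.ndarray:
    """Average the (beta, gamma) loop over whole cycles on a common phase grid.

    Each cycle is resampled to ``n_points`` equally spaced phases (by sample
    index, i.e. by time within the cycle) and the loops are averaged
    point-wise, preserving the traversal direction of the trace.
    """
    if not cycles:
        raise AnalysisError("no whole cycles to average")
    beta = np.asarray(beta, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    phases = np.linspace(0.0, 1.0, n_points, endpoint=False)
    acc = np.zeros((n_points, 2))
    for c in cycles:
        idx = np.arange(c.start, c.stop)
        ph = (idx - c.start) / (c.stop - c.start)
        acc[:, 0] += np.interp(phases, ph, beta[idx])
        acc[:, 1] += np.interp(phases, ph, gamma[idx])
    return acc / len(cycles)


def _point_segment_dist(p, a, b):
    ab = b - a
    denom = float(ab @ ab)
    if denom < 1e-30:
        return float(np.hypot(*(p - a)))
    u = np.clip(float((p - a) @ ab) / denom, 0.0, 1.0)
    return float(np.hypot(*(p - a - u * ab)))


def _prune_closed(points: np.ndarray, tol: float) -> np.ndarray:
    """Iteratively drop the vertex whose removal deviates least, while < tol."""
    pts = points.copy()
    while pts.shape[0] > 3:
        n = pts.shape[0]
        dists = np.array([
            _point_segment_dist(pts[i], pts[(i - 1) % n], pts[(i + 1) % n])
            for i in range(n)
        ])
        i = int(np.argmin(dists))
        if dists[i] >= tol:
            break
        pts = np.delete(pts, i, axis=0)
    return pts


def _resample_closed(points: np.ndarray, n: int) -> np.ndarray:
    closed = np.vstack([points, points[:1]])
    seg = np.hypot(*np.diff(closed, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        raise AnalysisError("loop has zero perimeter")
    grid = np.linspace(0.0, total, n, endpoint=False)
    return np.column_stack([np.interp(grid, s, closed[:, k]) for k in (0, 1)])


def _turn_angles_deg(polygon: np.ndarray) -> np.ndarray:
    """Absolute exterior (turning) angle at each vertex of a closed polygon."""
    n = polygon.shape[0]
    out = np.empty(n)
    for i in range(n):
        a, b, c = polygon[(i - 1) % n], polygon[i], polygon[(i + 1) % n]
        v1, v2 = b - a, c - b
        cross = v1[0] * v2[1] - v1[1] * v2[0]
        out[i] = np.degrees(abs(np.arctan2(cross, v1 @ v2)))
    return out


def classify_loop(points, tol_frac: float = 0.05, floor_deg: float = 2.0,
                  corner_min_deg: float = 45.0) -> LoopClass:
    """Classify a closed (beta, gamma) loop by its dominant vertex count.

    The loop is translated/scaled to a unit bounding-box diagonal (the label
    is invariant to translation and uniform scaling), resampled uniformly by
    arc length, and simplified by iterative vertex pruning with perpendicular
    distance tolerance ``tol_frac`` of the diagonal.  The *dominant* vertices
    of the simplified polygon are those turning the path by at least
    ``corner_min_deg``; gentler bends are treated as rounding, not corners.
    Three or fewer dominant vertices give ``triangular``, four or more
    ``quadrilateral``.  If one angle's range is below ``floor_deg`` the loop
    is a ``degenerate-line``; if both are, it is ``quiescent``.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise AnalysisError("loop must be an (n, 2) point array")
    pts = pts[np.concatenate([[True], np.any(np.diff(pts, axis=0) != 0, axis=1)])]
    if np.unique(pts, axis=0).shape[0] < 3:
        raise AnalysisError("need at least 3 distinct loop points")
    rng = np.ptp(pts, axis=0)
    small = rng < floor_deg
    if small.all():
        return LoopClass("quiescent", 0, 1.0)
    if small.any():
        return LoopClass("degenerate-line", 2, 1.0)

    diag = float(np.hypot(*rng))
    norm = (pts - np.mean(pts, axis=0)) / diag
    res = _resample_closed(norm, 256)
    simple = _prune_closed(res, tol_frac)
    turns = _turn_angles_deg(simple)
    n_vertices = int(np.count_nonzero(turns >= corner_min_deg))

    # residual of the simplified polygon against the resampled loop
    m = simple.shape[0]
    devs = np.empty(res.shape[0])
    for j, p in enumerate(res):
        devs[j] = min(
            _point_segment_dist(p, simple[i], simple[(i + 1) % m])
            for i in range(m)
        )
    confidence = float(np.clip(1.0 - devs.max() / (2.0 * tol_frac), 0.0, 1.0))
    label = "triangular" if n_vertices <= 3 else "quadrilateral"
    if simple.shape[0] > 6:
        confidence = min(confidence, 0.5)   # rounded, not really polygonal
    return LoopClass(label, n_vertices, confidence)


# ---------------------------------------------------------------------------
# cessation and alternation

def detect_cessation(t_ms, x, amplitude_floor: float = 2.0,
                     min_duration_ms: float = 500.0,
                     window_ms: float = 800.0) -> list[tuple[float, float]]:
    """Find quiescent intervals: sliding-window peak-to-peak below a floor.

    A sample is quiescent when the peak-to-peak amplitude over a centered
    window of ``window_ms`` stays below ``amplitude_floor`` degrees; maximal
    quiescent runs at least ``min_duration_ms`` long are returned as
    ``(t_start, t_end)`` pairs.  The window should be of the order of the
    oscillation period so dwell phases of a slow oscillation do not read as
    quiescence.
    """
    t_ms = np.asarray(t_ms, dtype=float)
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        return []
    dt = float(np.median(np.diff(t_ms)))
    w = max(3, int(round(window_ms / dt)) | 1)
    ptp = maximum_filter1d(x, w, mode="nearest") - minimum_filter1d(x, w, mode="nearest")
    quiet = ptp < amplitude_floor
    out: list[tuple[float, float]] = []
    i = 0
    while i < quiet.size:
        if quiet[i]:
            j = i
            while j + 1 < quiet.size and quiet[j + 1]:
                j += 1
            if t_ms[j] - t_ms[i] >= min_duration_ms:
                out.append((float(t_ms[i]), float(t_ms[j])))
            i = j + 1
        else:
            i += 1
    return out


@dataclass
class AlternationResult:
    """Outcome of the alternating-amplitude test on one angle trace."""

    flag: Optional[bool]        # None: too few peaks to decide
    depth: float                # mean relative amplitude difference
    n_peaks: int
    amplitudes: np.ndarray = field(default_factory=lambda: np.empty(0))


def detect_alternating_amplitude(t_ms, x, rel_diff: float = 0.10,
                                 min_pairs: int = 4,
                                 smooth_frac: float = 0.05) -> AlternationResult:
    """Flag oscillations whose successive peak amplitudes alternate.

    Peak amplitudes are measured as peak height above the trace mean on a
    lightly smoothed copy (centered moving average, ``smooth_frac`` of the
    mean cycle period).  The flag is true iff the sign of the successive
    amplitude difference alternates over at least ``min_pairs`` consecutive
    pairs with relative difference above ``rel_diff``; fewer than six peaks
    leave the flag undetermined (None).
    """
    t_ms = np.asarray(t_ms, dtype=float)
    x = np.asarray(x, dtype=float)
    if x.size < 8 or np.ptp(x) < 1e-9:
        return AlternationResult(None, 0.0, 0)
    dt = float(np.median(np.diff(t_ms)))
    cycles = extract_cycles(t_ms, x)
    if cycles:
        period = float(np.mean(_cycle_periods(t_ms, cycles)))
        w = max(1, int(round(smooth_frac * period / dt)))
        kernel = np.ones(w) / w
        xs = np.convolve(x, kernel, mode="same") if w > 1 else x
    else:
        xs = x
    prom = max(0.5, 0.02 * float(np.ptp(xs)))
    peaks, _ = signal.find_peaks(xs, prominence=prom)
    mean = float(np.mean(xs))
    amps = xs[peaks] - mean
    keep = amps > 0
    amps = amps[keep]
    if amps.size < 6:
        return AlternationResult(None, 0.0, int(amps.size), amps)
    d = np.diff(amps)
    rel = np.abs(d) / np.maximum(amps[:-1], amps[1:])
    good = rel > rel_diff
    run = best = 0
    for i in range(d.size):
        continues = i > 0 and good[i - 1] and d[i] * d[i - 1] < 0
        run = (run + 1 if continues else 1) if good[i] else 0
        best = max(best, run)
    flag = best >= min_pairs
    depth = float(np.mean(rel)) if rel.size else 0.0
    return AlternationResult(flag, depth, int(amps.size), amps)


# ---------------------------------------------------------------------------
# summary statistics

@dataclass
class OscStats:
    """Ranges, mean period and per-cycle amplitudes of the three angles."""

    ranges: dict[str, tuple[float, float]]
    periods_ms: dict[str, Optional[float]]
    amplitudes: dict[str, np.ndarray]
    n_cycles: dict[str, int]

    @property
    def period_ms(self) -> Optional[float]:
        for key in ("beta", "gamma", "alpha"):
            if self.periods_ms.get(key) is not None:
                return self.periods_ms[key]
        return None


def oscillation_stats(trace, transient_ms: float = 0.0) -> OscStats:
    """Per-angle min/max, mean cycle period and per-cycle amplitudes.

    ``trace`` is anything with ``t_ms``, ``beta``, ``gamma`` and ``alpha``
    array attributes (a ``SimTrace``).  The first ``transient_ms`` are
    discarded.  A constant angle reports a zero-width range and an absent
    (None) period.
    """
    t = np.asarray(trace.t_ms, dtype=float)
    sel = t >= t[0] + transient_ms
    ranges, periods, amplitudes, ncyc = {}, {}, {}, {}
    for name in ("alpha", "beta", "gamma"):
        x = np.asarray(getattr(trace, name), dtype=float)[sel]
        ranges[name] = (float(np.min(x)), float(np.max(x)))
        cycles = extract_cycles(t[sel], x)
        ncyc[name] = len(cycles)
        if len(cycles) >= 2:
            periods[name] = float(np.mean(_cycle_periods(t[sel], cycles)))
            amplitudes[name] = np.array([float(np.ptp(x[c])) for c in cycles])
        else:
            periods[name] = None
            amplitudes[name] = np.empty(0)
    return OscStats(ranges, periods, amplitudes, ncyc)


def state_diagram(trace, tol_frac: float = 0.05, floor_deg: float = 2.0,
                  post_last_cycles: int = 3, post_settle_ms: float = 0.0) -> StateDiagram:
    """Build and classify the beta-gamma state diagram of a protocol trace.

    The pre-contact segment (everything before the ``contact`` event, or the
    whole trace if there is none) and the post-removal segment are segmented
    into whole cycles on the beta trace (falling back to gamma when beta does
    not oscillate); loops are cycle-averaged before classification.  The post
    loop uses the last ``post_last_cycles`` whole cycles, i.e. the recovered
    regime rather than the transient.
    """
    t = np.asarray(trace.t_ms, dtype=float)
    beta = np.asarray(trace.beta, dtype=float)
    gamma = np.asarray(trace.gamma, dtype=float)
    events = getattr(trace, "events", {}) or {}
    t_contact = events.get("contact")
    t_removal = events.get("removal")

    def build(mask, last_k=None):
        tb, bb, gg = t[mask], beta[mask], gamma[mask]
        if tb.size < 8:
            return None, 0
        cycles = extract_cycles(tb, bb) or extract_cycles(tb, gg)
        if not cycles:
            return None, 0
        if last_k is not None:
            cycles = cycles[-last_k:]
        return cycle_average_loop(bb, gg, cycles), len(cycles)

    pre_mask = t < (t_contact if t_contact is not None else np.inf)
    pre_loop, pre_n = build(pre_mask)
    diagram = StateDiagram(pre_loop, None, pre_n, 0)
    if pre_loop is not None:
        diagram.pre_class = classify_loop(pre_loop, tol_frac, floor_deg)
    if t_removal is not None:
        post_mask = t >= t_removal + post_settle_ms
        post_loop, post_n = build(post_mask, last_k=post_last_cycles)
        diagram.post_loop, diagram.post_cycles = post_loop, post_n
        if post_loop is not None:
            diagram.post_class = classify_loop(post_loop, tol_frac, floor_deg)
    return diagram
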