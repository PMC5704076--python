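"""Time-indexed simulation traces and their plain-text (CSV) round-trip.

A trace records the three leg angles, the eight motoneuron outputs, the two
gate conductances, the recruitment/drive schedule columns and a set of
labeled event timestamps (contact, removal, full-recruitment marks).  The
file format is a CSV body preceded by ``#``-prefixed header lines carrying a
format tag, the config hash/preset and the events as JSON, so a trace file
is self-describing and survives a read/write cycle bit-faithfully to within
the printed precision.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import TraceParseError

_FORMAT_TAG = "legsearch-trace v1"
#: column order; the first four are mandatory, the rest optional
MN_COLUMNS = ("mn_lf", "mn_ls", "mn_df", "mn_ds", "mn_ef", "mn_es", "mn_ff", "mn_fs")
_REQUIRED = ("time_ms", "beta_deg", "gamma_deg", "alpha_deg")


@dataclass
class SimTrace:
    """In-memory trace: strictly increasing time grid plus per-sample signals."""

    t_ms: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray
    alpha: np.ndarray
    mn: dict[str, np.ndarray] = field(default_factory=dict)      # keys MN_COLUMNS
    gates: dict[str, np.ndarray] = field(default_factory=dict)   # gate_beta, gate_gamma
    extras: dict[str, np.ndarray] = field(default_factory=dict)  # schedule columns etc.
    events: dict[str, float] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        for name in ("beta", "gamma", "alpha"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(np.diff(self.t_ms) <= 0):
            raise TraceParseError("time grid must be strictly increasing")
        n = self.t_ms.size
        for arr in (self.beta, self.gamma, self.alpha):
            if arr.size != n:
                raise TraceParseError("angle column length mismatch")

    @property
    def duration_ms(self) -> float:
        return float(self.t_ms[-1] - self.t_ms[0])

    def segment(self, t0: float = -np.inf, t1: float = np.inf) -> "SimTrace":
        """Sub-trace with t0 <= t < t1 (events and meta carried over)."""
        m = (self.t_ms >= t0) & (self.t_ms < t1)
        pick = lambda d: {k: v[m] for k, v in d.items()}
        return SimTrace(self.t_ms[m], self.beta[m], self.gamma[m], self.alpha[m],
                        pick(self.mn), pick(self.gates), pick(self.extras),
                        dict(self.events), dict(self.meta))

    def to_frame(self) -> pd.DataFrame:
        cols = {"time_ms": self.t_ms, "beta_deg": self.beta,
                "gamma_deg": self.gamma, "alpha_deg": self.alpha}
        cols.update(self.mn)
        cols.update(self.gates)
        cols.update(self.extras)
        return pd.DataFrame(cols)


def write_trace(trace: SimTrace, path) -> None:
    """Write a trace as commented-header CSV (12 significant digits)."""
    with open(path, "w") as fh:
        fh.write(f"# {_FORMAT_TAG}\n")
        fh.write(f"# meta: {json.dumps(trace.meta, sort_keys=True)}\n")
        fh.write(f"# events: {json.dumps(trace.events, sort_keys=True)}\n")
        trace.to_frame().to_csv(fh, index=False, float_format="%.12g")


def read_trace(path) -> SimTrace:
    """Read a trace written by :func:`write_trace`.

    Malformed headers or missing mandatory columns raise
    :class:`~legsearch.errors.TraceParseError` with the offending line.
    """
    meta: dict = {}
    events: dict = {}
    header_lines = 0
    body = io.StringIO()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#"):
                header_lines += 1
                payload = line[1:].strip()
                try:
                    if payload.startswith("meta:"):
                        meta = json.loads(payload[5:])
                    elif payload.startswith("events:"):
                        events = json.loads(payload[7:])
                except json.JSONDecodeError as exc:
                    raise TraceParseError(f"line {lineno}: bad header JSON: {exc}")
            else:
                body.write(line)
    body.seek(0)
    try:
        df = pd.read_csv(body)
    except Exception as exc:
        raise TraceParseError(f"after line {header_lines}: {exc}") from exc
    for col in _REQUIRED:
        if col not in df.columns:
            raise TraceParseError(
                f"line {header_lines + 1}: missing required column {col!r}")
    mn = {c: df[c].to_numpy() for c in MN_COLUMNS if c in df.columns}
    gates = {c: df[c].to_numpy() for c in ("gate_beta", "gate_gamma")
             if c in df.columns}
    known = set(_REQUIRED) | set(mn) | set(gates)
    extras = {c: df[c].to_numpy() for c in df.columns if c not in known}
    return SimTrace(df["time_ms"].to_numpy(), df["beta_deg"].to_numpy(),
                    df["gamma_deg"].to_numpy(), df["alpha_deg"].to_numpy(),
                    mn, gates, extras, events, meta)
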