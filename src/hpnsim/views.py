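"""Result views and trace export.

A view selects flat node names by a regular expression — e.g. ``Ca__.*``
matches every grid cell of an unfolded spatial model — and optionally
aggregates the matches (sum or mean) into one output column.  Traces are
exported as plain CSV with full double precision (``repr`` shortest
round-trip form), so a re-read trace compares bit-exactly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .hybrid import Trace
from .model import HybridPetriNet

__all__ = ["View", "register_view", "apply_view", "export_csv", "read_csv"]


@dataclass(frozen=True)
class View:
    name: str
    pattern: str               # regular expression over flat node names
    aggregate: str | None = None  # None | "sum" | "mean"

    def __post_init__(self):
        if self.aggregate not in (None, "sum", "mean"):
            raise ValueError("aggregate must be None, 'sum' or 'mean'")
        re.compile(self.pattern)

    def matches(self, names) -> list:
        rx = re.compile(self.pattern)
        return [n for n in names if rx.fullmatch(n)]


def register_view(net: HybridPetriNet, view: View) -> View:
    """Attach a view to a model; it must match at least one node."""
    names = list(net.places) + list(net.transitions)
    if not view.matches(names):
        raise ValueError(
            f"view {view.name!r}: pattern {view.pattern!r} matches no node")
    net.views[view.name] = view
    return view


def apply_view(trace: Trace, view: View) -> Trace:
    """Project a trace onto a view's columns (aggregated if requested)."""
    cols = view.matches(trace.columns)
    if not cols:
        raise ValueError(
            f"view {view.name!r}: pattern {view.pattern!r} matches no "
            "recorded column")
    idx = [trace.columns.index(c) for c in cols]
    sub = trace.values[:, idx]
    meta = dict(trace.meta, view=view.name)
    if view.aggregate == "sum":
        return Trace(trace.times, (view.name,), sub.sum(axis=1, keepdims=True),
                     meta)
    if view.aggregate == "mean":
        return Trace(trace.times, (view.name,), sub.mean(axis=1, keepdims=True),
                     meta)
    return Trace(trace.times, tuple(cols), sub, meta)


def export_csv(trace: Trace, path: str) -> None:
    """Write ``time,<node...>`` rows at full double precision.

    Decimal point ``.``, no thousands separators, ``\\n`` line endings;
    byte-identical for identical traces.
    """
    if len(trace.times) == 0:
        raise ValueError("refusing to export an empty trace")
    with open(path, "w", newline="\n") as fh:
        fh.write("time," + ",".join(trace.columns) + "\n")
        for i, t in enumerate(trace.times):
            row = ",".join(repr(float(v)) for v in trace.values[i])
            fh.write(f"{float(t)!r},{row}\n")


def read_csv(path: str) -> Trace:
    """Read back an exported trace (bit-exact round trip)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(",")
        if header[0] != "time":
            raise ValueError(f"{path}: not a trace CSV (first column "
                             f"{header[0]!r}, expected 'time')")
        times, rows = [], []
        for line in fh:
            cells = line.rstrip("\n").split(",")
            times.append(float(cells[0]))
            rows.append([float(c) for c in cells[1:]])
    return Trace(np.array(times), tuple(header[1:]), np.array(rows),
                 {"source": path})
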