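"""Text formats: condensed networks (.inet), reaction lists (.crn),
trajectory CSV, and JSON reports.

Both network formats are line based, ``#`` starts a comment, and reading
back a written file reproduces the original object exactly.
"""

from __future__ import annotations

import csv
import json
import re
from pathlib import Path

import numpy as np

from .crn import Reaction, ReactionNetwork, Species
from .dynamics import Trajectory
from .influence import InfluenceEdge, InfluenceNetwork, InfluenceNode

__all__ = [
    "read_inet",
    "write_inet",
    "parse_inet",
    "format_inet",
    "read_crn",
    "write_crn",
    "parse_crn",
    "format_crn",
    "write_trajectory_csv",
    "read_trajectory_csv",
    "write_report",
]


class ParseError(ValueError):
    def __init__(self, lineno: int, message: str):
        super().__init__(f"line {lineno}: {message}")
        self.lineno = lineno


def _lines(text: str):
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if line:
            yield lineno, line


# ---------------------------------------------------------------------------
# .inet — condensed influence networks
# ---------------------------------------------------------------------------

_EDGE_RE = re.compile(
    r"^edge\s+(?P<src>\w+?)(?::(?P<pole>[02]))?\s+(?P<eff>act|inh)\s+"
    r"(?P<dst>\w+)(?:\s*@\s*(?P<rate>\S+))?$"
)
_NODE_RE = re.compile(
    r"^node\s+(?P<name>\w+)"
    r"(?:\s+total=(?P<total>\S+))?"
    r"(?:\s+init=(?P<i0>[^,\s]+),(?P<i1>[^,\s]+),(?P<i2>[^,\s]+))?$"
)


def parse_inet(text: str) -> InfluenceNetwork:
    """Parse the condensed-network format.

    ``node <name> [total=<f>] [init=<f>,<f>,<f>]`` declares a triplet node;
    ``const <name> <value>`` a clamped input; ``edge <src>[:0|:2] <act|inh>
    <dst> [@ <rate>]`` an influence (pole defaults to 2; ignored for clamped
    sources).
    """
    nodes: list[InfluenceNode] = []
    clamped: list[tuple[str, float]] = []
    edges: list[InfluenceEdge] = []
    for lineno, line in _lines(text):
        kind = line.split()[0]
        try:
            if kind == "node":
                m = _NODE_RE.match(line)
                if not m:
                    raise ValueError(f"malformed node line: {line!r}")
                total = float(m.group("total")) if m.group("total") else 1.0
                init = None
                if m.group("i0"):
                    init = tuple(float(m.group(k)) for k in ("i0", "i1", "i2"))
                nodes.append(InfluenceNode(m.group("name"), total=total, init=init))
            elif kind == "const":
                parts = line.split()
                if len(parts) != 3:
                    raise ValueError(f"malformed const line: {line!r}")
                clamped.append((parts[1], float(parts[2])))
            elif kind == "edge":
                m = _EDGE_RE.match(line)
                if not m:
                    raise ValueError(f"malformed edge line: {line!r}")
                edges.append(
                    InfluenceEdge(
                        source=m.group("src"),
                        pole=int(m.group("pole") or 2),
                        effect=m.group("eff"),
                        target=m.group("dst"),
                        rate=float(m.group("rate")) if m.group("rate") else 1.0,
                    )
                )
            else:
                raise ValueError(f"unknown directive {kind!r}")
        except ValueError as exc:
            raise ParseError(lineno, str(exc)) from None
    try:
        return InfluenceNetwork(nodes=tuple(nodes), edges=tuple(edges),
                                clamped=tuple(clamped))
    except ValueError as exc:
        raise ParseError(0, str(exc)) from None


def format_inet(inet: InfluenceNetwork) -> str:
    out = []
    for n in inet.nodes:
        line = f"node {n.name}"
        if n.total != 1.0:
            line += f" total={n.total:g}"
        if n.init is not None:
            line += " init=" + ",".join(f"{v:g}" for v in n.init)
        out.append(line)
    for c, v in inet.clamped:
        out.append(f"const {c} {v:g}")
    for e in inet.edges:
        src = e.source if e.source in inet.clamped_names else f"{e.source}:{e.pole}"
        line = f"edge {src} {e.effect} {e.target}"
        if e.rate != 1.0:
            line += f" @ {e.rate:g}"
        out.append(line)
    return "\n".join(out) + "\n"


def read_inet(path) -> InfluenceNetwork:
    return parse_inet(Path(path).read_text())


def write_inet(inet: InfluenceNetwork, path) -> None:
    Path(path).write_text(format_inet(inet))


# ---------------------------------------------------------------------------
# .crn — reaction lists
# ---------------------------------------------------------------------------

_RXN_RE = re.compile(r"^(?P<lhs>[^->@]+)->(?P<rhs>[^@]*)(?:@(?P<rate>.+))?$")


def _side(text: str, lineno: int) -> tuple[str, ...]:
    text = text.strip()
    if text in ("0", "∅", ""):
        return ()
    parts = [p.strip() for p in text.split("+")]
    if any(not p for p in parts):
        raise ParseError(lineno, f"malformed species list {text!r}")
    if len(parts) > 2:
        raise ParseError(lineno, f"at most 2 species per side, got {len(parts)}")
    return tuple(parts)


def parse_crn(text: str) -> ReactionNetwork:
    """Parse the reaction-list format: ``A + B -> A + C @ 1.0`` per line,
    plus ``clamp <name> <value>`` directives; species are implicit."""
    clamped: dict[str, float] = {}
    reactions: list[Reaction] = []
    order: list[str] = []
    seen: set[str] = set()

    def note(name: str):
        if name not in seen:
            seen.add(name)
            order.append(name)

    for lineno, line in _lines(text):
        if line.startswith("clamp"):
            parts = line.split()
            if len(parts) != 3:
                raise ParseError(lineno, f"malformed clamp line: {line!r}")
            clamped[parts[1]] = float(parts[2])
            note(parts[1])
            continue
        m = _RXN_RE.match(line)
        if not m:
            raise ParseError(lineno, f"cannot parse reaction: {line!r}")
        lhs = _side(m.group("lhs"), lineno)
        rhs = _side(m.group("rhs"), lineno)
        try:
            rate = float(m.group("rate")) if m.group("rate") else 1.0
            rxn = Reaction(lhs, rhs, rate)
        except ValueError as exc:
            raise ParseError(lineno, str(exc)) from None
        for q in lhs + rhs:
            note(q)
        reactions.append(rxn)
    species = [Species(n, clamped=n in clamped) for n in order]
    net = ReactionNetwork(species, reactions)
    net.clamp_values = dict(clamped)  # carried for simulation defaults
    return net


def format_crn(net: ReactionNetwork) -> str:
    out = []
    clamp_values = getattr(net, "clamp_values", {})
    for s in net.species:
        if s.clamped:
            out.append(f"clamp {s.name} {clamp_values.get(s.name, 0.0):g}")
    for r in net.reactions:
        lhs = " + ".join(r.reactants) if r.reactants else "0"
        rhs = " + ".join(r.products) if r.products else "0"
        out.append(f"{lhs} -> {rhs} @ {r.rate:g}")
    return "\n".join(out) + "\n"


def read_crn(path) -> ReactionNetwork:
    return parse_crn(Path(path).read_text())


def write_crn(net: ReactionNetwork, path) -> None:
    Path(path).write_text(format_crn(net))


# ---------------------------------------------------------------------------
# Trajectories and reports
# ---------------------------------------------------------------------------


def write_trajectory_csv(traj: Trajectory, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time"] + list(traj.species))
        for t, row in zip(traj.times, traj.values):
            w.writerow([f"{t:.10g}"] + [f"{v:.10g}" for v in row])


def read_trajectory_csv(path) -> Trajectory:
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    species = rows[0][1:]
    data = np.array([[float(v) for v in row] for row in rows[1:]])
    return Trajectory(times=data[:, 0], values=data[:, 1:], species=species)


def write_report(payload: dict, path, config: dict | None = None) -> None:
    """JSON report with stable key order and the resolved run config echoed,
    so a rerun with the same config reproduces it byte for byte."""
    from . import __version__

    doc = {"tool": "switchnet", "version": __version__}
    if config is not None:
        doc["config"] = config
    doc["results"] = payload
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
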