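"""Condensed influence networks, triplet expansion, and the model library.

A condensed node stands for three interconvertible forms of one molecule —
inactive (``_0``), intermediate (``_1``) and active (``_2``) — e.g. the
phosphorylation states of a multi-site substrate.  A directed influence edge
acts catalytically through one extremal form of its source (its *pole*):
an *activate* edge drives the target up the chain (0→1→2), an *inhibit* edge
drives it down (2→1→0), two catalytic bimolecular reactions per edge.
Clamped constant species (external inputs) may also act as catalysts.

The library bundles the networks studied in this package: the approximate-
majority protocol (AM), minimal mutual-antagonism and polarity models
(MI/PAR), septation-initiation asymmetry (SI), the epigenetic nucleosome
switch (EPI), the classical G2/M cell-cycle switch (CC), its Greatwall-
phosphatase extension (GW), and the two Cdc20 oscillator variants
(GWO_A/GWO_B).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .crn import Reaction, ReactionNetwork, SignedInfluenceGraph, Species

__all__ = [
    "InfluenceNode",
    "InfluenceEdge",
    "InfluenceNetwork",
    "MODEL_IDS",
    "node_species",
    "expand",
    "initial_state",
    "am_protocol",
    "library",
    "generate_random_inet",
    "signed_influence_graph",
    "extremal_influence_graph",
]

#: Default split of a node's total over (inactive, intermediate, active).
#: Equal thirds is an unstable fixed point of every bundled switch; the small
#: active-form surplus makes simulations started "undecided" actually decide.
DEFAULT_INIT_FRACTIONS = (0.33, 0.33, 0.34)


@dataclass(frozen=True)
class InfluenceNode:
    """A condensed node: three forms sharing a conserved total amount."""

    name: str
    total: float = 1.0
    init: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.total < 0:
            raise ValueError(f"node {self.name}: total must be nonnegative")
        if self.init is not None:
            init = tuple(float(v) for v in self.init)
            if len(init) != 3 or any(v < 0 for v in init):
                raise ValueError(f"node {self.name}: init must be 3 nonnegative values")
            if abs(sum(init) - self.total) > 1e-12 * max(1.0, self.total):
                raise ValueError(
                    f"node {self.name}: init {init} does not sum to total {self.total}"
                )
            object.__setattr__(self, "init", init)

    def init_or_default(self) -> tuple[float, float, float]:
        if self.init is not None:
            return self.init
        return tuple(f * self.total for f in DEFAULT_INIT_FRACTIONS)


@dataclass(frozen=True)
class InfluenceEdge:
    """Catalytic influence from one node's pole (or a clamped input) on a node.

    ``pole`` selects which extremal form of the source acts: 2 (active) or
    0 (inactive).  It is ignored when the source is a clamped species.
    """

    source: str
    effect: str  # "act" | "inh"
    target: str
    pole: int = 2
    rate: float = 1.0

    def __post_init__(self) -> None:
        if self.effect not in ("act", "inh"):
            raise ValueError(f"effect must be 'act' or 'inh', got {self.effect!r}")
        if self.pole not in (0, 2):
            raise ValueError(f"pole must be 0 or 2, got {self.pole!r}")
        if self.rate < 0:
            raise ValueError("edge rate must be nonnegative")


@dataclass(frozen=True)
class InfluenceNetwork:
    nodes: tuple[InfluenceNode, ...]
    edges: tuple[InfluenceEdge, ...]
    clamped: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", tuple(self.nodes))
        object.__setattr__(self, "edges", tuple(self.edges))
        object.__setattr__(self, "clamped", tuple((n, float(v)) for n, v in self.clamped))
        names = [n.name for n in self.nodes]
        cnames = [c for c, _ in self.clamped]
        if len(set(names + cnames)) != len(names) + len(cnames):
            raise ValueError("node / clamped-species names must be unique")
        declared = set(names) | set(cnames)
        for e in self.edges:
            if e.target not in set(names):
                raise ValueError(f"edge target {e.target!r} is not a declared node")
            if e.source not in declared:
                raise ValueError(f"edge source {e.source!r} is undeclared")

    @property
    def node_names(self) -> list[str]:
        return [n.name for n in self.nodes]

    @property
    def clamped_names(self) -> list[str]:
        return [c for c, _ in self.clamped]

    def node(self, name: str) -> InfluenceNode:
        for n in self.nodes:
            if n.name == name:
                return n
        raise KeyError(name)

    def with_rates(self, rates: dict | float) -> "InfluenceNetwork":
        """Copy with edge rates replaced (uniformly or per edge index)."""
        if isinstance(rates, (int, float)):
            new = [replace(e, rate=float(rates)) for e in self.edges]
        else:
            new = [replace(e, rate=float(rates.get(i, e.rate)))
                   for i, e in enumerate(self.edges)]
        return replace(self, edges=tuple(new))


def node_species(name: str) -> tuple[str, str, str]:
    """Species names for a node's inactive/intermediate/active forms."""
    return (f"{name}_0", f"{name}_1", f"{name}_2")


def _catalyst(inet: InfluenceNetwork, edge: InfluenceEdge) -> str:
    if edge.source in inet.clamped_names:
        return edge.source
    return f"{edge.source}_{edge.pole}"


def expand(inet: InfluenceNetwork) -> ReactionNetwork:
    """Expand a condensed network into its mass-action reaction network.

    Each node contributes its three forms; each edge contributes two catalytic
    conversions of the target — up the activation chain for *act* edges
    (t_0→t_1, t_1→t_2), down for *inh* edges (t_2→t_1, t_1→t_0) — catalysed by
    the source's pole form (or the clamped input), which appears unchanged on
    both sides.  Every reaction is bimolecular; each node's three forms are
    conserved by construction.
    """
    species = [Species(s) for n in inet.nodes for s in node_species(n.name)]
    species += [Species(c, clamped=True) for c in inet.clamped_names]
    reactions = []
    for e in inet.edges:
        cat = _catalyst(inet, e)
        t0, t1, t2 = node_species(e.target)
        if e.effect == "act":
            steps = [(t0, t1), (t1, t2)]
        else:
            steps = [(t2, t1), (t1, t0)]
        for lhs, rhs in steps:
            reactions.append(
                Reaction(reactants=(cat, lhs), products=(cat, rhs), rate=e.rate)
            )
    return ReactionNetwork(species, reactions)


def initial_state(inet: InfluenceNetwork, overrides: dict | None = None) -> dict[str, float]:
    """Initial concentrations: node init triples plus clamped values."""
    state: dict[str, float] = {}
    for n in inet.nodes:
        for s, v in zip(node_species(n.name), n.init_or_default()):
            state[s] = v
    for c, v in inet.clamped:
        state[c] = v
    if overrides:
        unknown = set(overrides) - set(state)
        if unknown:
            raise ValueError(f"unknown species in overrides: {sorted(unknown)}")
        state.update(overrides)
    return state


# ---------------------------------------------------------------------------
# Signed influence graphs
# ---------------------------------------------------------------------------


def signed_influence_graph(inet: InfluenceNetwork) -> SignedInfluenceGraph:
    """Signed graph at condensed-node granularity: + per act edge, − per inh."""
    nodes = tuple(inet.node_names + inet.clamped_names)
    edges = tuple(
        (e.source, e.target, "+" if e.effect == "act" else "-")
        for e in inet.edges
    )
    return SignedInfluenceGraph(nodes=nodes, edges=edges)


def extremal_influence_graph(inet: InfluenceNetwork) -> SignedInfluenceGraph:
    """Signed graph between extremal forms (the wiring-diagram view).

    Each node is represented by its two extremal forms.  An activate edge
    catalysed by form c promotes the target's active form (c → t_2 with +) at
    the expense of its inactive form (c → t_0 with −); an inhibit edge does
    the reverse.  For AM this recovers the decided-state antagonism picture:
    two autocatalytic extremal forms that mutually suppress each other —
    three positive feedback loops, none negative.
    """
    nodes: list[str] = []
    for n in inet.nodes:
        s0, _, s2 = node_species(n.name)
        nodes += [s0, s2]
    nodes += inet.clamped_names
    edges = []
    for e in inet.edges:
        cat = _catalyst(inet, e)
        t0, _, t2 = node_species(e.target)
        if e.effect == "act":
            edges += [(cat, t2, "+"), (cat, t0, "-")]
        else:
            edges += [(cat, t0, "+"), (cat, t2, "-")]
    return SignedInfluenceGraph(nodes=tuple(nodes), edges=tuple(edges))


# ---------------------------------------------------------------------------
# The approximate-majority protocol and the model library
# ---------------------------------------------------------------------------


def am_protocol() -> ReactionNetwork:
    """The approximate-majority protocol as a reaction network.

    Two decided states X and Y and an undecided state B, unit rates:
    opposite decided agents un-decide each other (X+Y→X+B, X+Y→B+Y) and
    decided agents convert undecided ones (X+B→X+X, B+Y→Y+Y).
    """
    sp = [Species("X"), Species("B"), Species("Y")]
    rx = [
        Reaction(("X", "Y"), ("X", "B")),
        Reaction(("X", "Y"), ("B", "Y")),
        Reaction(("X", "B"), ("X", "X")),
        Reaction(("B", "Y"), ("Y", "Y")),
    ]
    return ReactionNetwork(sp, rx)


def _n(name: str, total: float = 1.0, init=None) -> InfluenceNode:
    return InfluenceNode(name=name, total=total, init=init)


def _e(src: str, effect: str, dst: str, pole: int = 2, rate: float = 1.0) -> InfluenceEdge:
    return InfluenceEdge(source=src, effect=effect, target=dst, pole=pole, rate=rate)


def _am() -> InfluenceNetwork:
    # One node: the active form is autocatalytic, the inactive form (the
    # opposing decided state) drives the node back down.
    return InfluenceNetwork(
        nodes=(_n("x"),),
        edges=(_e("x", "act", "x", pole=2), _e("x", "inh", "x", pole=0)),
    )


def _mutual_antagonism(a: str, b: str) -> InfluenceNetwork:
    # Two autocatalytic species whose active forms inhibit each other.
    return InfluenceNetwork(
        nodes=(_n(a), _n(b)),
        edges=(
            _e(a, "act", a, pole=2),
            _e(b, "act", b, pole=2),
            _e(a, "inh", b, pole=2),
            _e(b, "inh", a, pole=2),
        ),
    )


def _si() -> InfluenceNetwork:
    # Septation-initiation asymmetry: a double-positive loop (mutual
    # activation by the active forms) and a double-negative loop (mutual
    # inhibition by the inactive forms) between the old and new spindle
    # pole bodies.
    return InfluenceNetwork(
        nodes=(_n("spbO"), _n("spbN")),
        edges=(
            _e("spbO", "act", "spbN", pole=2),
            _e("spbN", "act", "spbO", pole=2),
            _e("spbO", "inh", "spbN", pole=0),
            _e("spbN", "inh", "spbO", pole=0),
        ),
    )


def _epi() -> InfluenceNetwork:
    # Nucleosome modification switch: methylated (active form) recruits
    # methylating enzymes, acetylated (inactive form) recruits acetylating
    # ones; same condensed topology as AM.
    return InfluenceNetwork(
        nodes=(_n("nuc"),),
        edges=(_e("nuc", "act", "nuc", pole=2), _e("nuc", "inh", "nuc", pole=0)),
    )


def _cc() -> InfluenceNetwork:
    # Classical G2/M switch: Cdk activates its activator Cdc25 and inhibits
    # its inhibitor Wee1; constant inputs oppose Cdk (i deactivates Cdc25,
    # a activates Wee1), standing in for an unregulated phosphatase.  Input
    # level 0.25 puts the default undecided state in the upward basin while
    # keeping the upper steady state visibly below the maximum.
    return InfluenceNetwork(
        nodes=(_n("cdk"), _n("cdc25"), _n("wee1")),
        edges=(
            _e("cdc25", "act", "cdk", pole=2),
            _e("wee1", "inh", "cdk", pole=2),
            _e("cdk", "act", "cdc25", pole=2),
            _e("cdk", "inh", "wee1", pole=2),
            _e("i", "inh", "cdc25"),
            _e("a", "act", "wee1"),
        ),
        clamped=(("a", 0.25), ("i", 0.25)),
    )


def _gw() -> InfluenceNetwork:
    # Greatwall extension: the constant inputs are replaced by the PP1/PP2A
    # phosphatase node, mutually antagonistic with Cdk (via Wee1/Cdc25 and a
    # direct Greatwall-mediated Cdk ⊣ PP edge) and autocatalytic.
    return InfluenceNetwork(
        nodes=(_n("cdk"), _n("cdc25"), _n("wee1"), _n("pp")),
        edges=(
            _e("cdc25", "act", "cdk", pole=2),
            _e("wee1", "inh", "cdk", pole=2),
            _e("cdk", "act", "cdc25", pole=2),
            _e("cdk", "inh", "wee1", pole=2),
            _e("pp", "act", "wee1", pole=2),
            _e("pp", "inh", "cdc25", pole=2),
            _e("cdk", "inh", "pp", pole=2),
            _e("pp", "act", "pp", pole=2),
        ),
    )


#: Rate of the Cdc20 turnover edges in the oscillator models.  Cdc20/APC
#: activation and reset are slower than the phosphorylation events of the
#: switch; making the negative loop the slow variable is what turns the
#: bistable switch into a relaxation oscillator.
GWO_CDC20_RATE = 0.3
#: Constant Cdc20-inactivation input (APC reset).
GWO_RESET_LEVEL = 0.4
#: Constant Cdk-activation input (cyclin synthesis closing the degradation
#: loop; without it the low-Cdk state is absorbing and no new cycle starts).
GWO_SYNTHESIS_LEVEL = 0.2


def _gwo(variant: str) -> InfluenceNetwork:
    # The GW switch embedded in the Cdc20/APC negative feedback: Cdk
    # activates Cdc20, Cdc20 inhibits Cdk (cyclin degradation), a constant
    # input e resets Cdc20, and a constant input s re-activates Cdk (cyclin
    # synthesis).  Variant A keeps the PP autocatalysis; variant B replaces
    # it with activation of PP by Cdc20.
    gw = _gw()
    edges = list(gw.edges)
    if variant == "B":
        edges = [e for e in edges
                 if not (e.source == "pp" and e.target == "pp")]
        edges.append(_e("cdc20", "act", "pp", pole=2))
    edges += [
        _e("cdk", "act", "cdc20", pole=2, rate=GWO_CDC20_RATE),
        _e("cdc20", "inh", "cdk", pole=2),
        _e("e", "inh", "cdc20", rate=GWO_CDC20_RATE),
        _e("s", "act", "cdk"),
    ]
    return InfluenceNetwork(
        nodes=gw.nodes + (_n("cdc20"),),
        edges=tuple(edges),
        clamped=(("e", GWO_RESET_LEVEL), ("s", GWO_SYNTHESIS_LEVEL)),
    )


_BUILDERS = {
    "AM": _am,
    "MI": lambda: _mutual_antagonism("y", "z"),
    "PAR": lambda: _mutual_antagonism("parA", "parP"),
    "SI": _si,
    "EPI": _epi,
    "CC": _cc,
    "GW": _gw,
    "GWO_A": lambda: _gwo("A"),
    "GWO_B": lambda: _gwo("B"),
}

MODEL_IDS = tuple(_BUILDERS)


def library(model_id: str) -> InfluenceNetwork:
    """Canonical condensed encoding of a bundled model, all rates 1."""
    key = model_id.upper()
    if key not in _BUILDERS:
        raise KeyError(
            f"unknown model {model_id!r}; available: {', '.join(MODEL_IDS)}"
        )
    return _BUILDERS[key]()


# ---------------------------------------------------------------------------
# Random fixtures
# ---------------------------------------------------------------------------

_LETTERS = "abcdefghijklmnopqrstuvwxyz"


def _node_name(i: int) -> str:
    # letter-only names keep node identity recoverable from species prefixes
    name = ""
    i += 1
    while i:
        i, r = divmod(i - 1, 26)
        name = _LETTERS[r] + name
    return "v" + name


def generate_random_inet(
    n_nodes: int, edge_density: float = 0.5, seed: int = 0
) -> InfluenceNetwork:
    """Reproducible random condensed network for property tests.

    Every node receives exactly one mandatory activate and one mandatory
    inhibit edge so the full triplet motif is exercised; a mandatory
    self-edge follows the autocatalysis convention (activation through the
    active form, inhibition through the inactive form), so a single node
    always reproduces the AM topology.  Extra edges between distinct nodes
    are added independently with probability *edge_density* per
    (source, pole, effect, target) slot.
    """
    if n_nodes < 1:
        raise ValueError("n_nodes must be >= 1")
    if not 0 < edge_density <= 1:
        raise ValueError("edge_density must be in (0, 1]")
    rng = np.random.default_rng(seed)
    names = [_node_name(i) for i in range(n_nodes)]
    edges: set[tuple[str, int, str, str]] = set()
    for t in names:
        for effect in ("act", "inh"):
            src = names[rng.integers(n_nodes)]
            if src == t:
                pole = 2 if effect == "act" else 0
            else:
                pole = int(rng.choice([0, 2]))
            edges.add((src, pole, effect, t))
    for src in names:
        for pole in (0, 2):
            for effect in ("act", "inh"):
                for t in names:
                    if t != src and rng.random() < edge_density * 0.25:
                        edges.add((src, pole, effect, t))
    return InfluenceNetwork(
        nodes=tuple(_n(nm) for nm in names),
        edges=tuple(
            _e(src, effect, t, pole=pole)
            for src, pole, effect, t in sorted(edges)
        ),
    )
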