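"""Reaction-network data model and structural analysis.

A :class:`ReactionNetwork` is a list of species and mass-action reactions
(reactant/product multisets with a rate constant).  Networks produced by
expanding condensed influence networks are purely bimolecular and catalytic:
every reaction has two reactants, one of which (the catalyst) reappears
unchanged among the products, so each condensed node's three forms are
conserved.  On top of the data model this module provides the mass-action
vector field, stoichiometry queries, signed influence graphs at two
granularities, simple-cycle (feedback-loop) enumeration with signs, and
detection of conserved species totals.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "Species",
    "Reaction",
    "ReactionNetwork",
    "SignedInfluenceGraph",
    "FeedbackLoop",
    "net_stoichiometry",
    "vector_field",
    "enumerate_feedback_loops",
    "conservation_laws",
]


@dataclass(frozen=True)
class Species:
    """A chemical species; ``clamped`` species are held constant (pure inputs)."""

    name: str
    clamped: bool = False

    def __post_init__(self) -> None:
        if not re.fullmatch(r"[A-Za-z_][A-Za-z0-9_]*", self.name):
            raise ValueError(f"invalid species name: {self.name!r}")


@dataclass(frozen=True)
class Reaction:
    """Mass-action reaction with reactant and product multisets.

    Multisets are stored as sorted name tuples so that two reactions with the
    same chemistry compare equal regardless of how they were written.  At most
    two reactants are supported (binary collisions); an empty reactant tuple
    denotes a zeroth-order synthesis.
    """

    reactants: tuple[str, ...]
    products: tuple[str, ...]
    rate: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "reactants", tuple(sorted(self.reactants)))
        object.__setattr__(self, "products", tuple(sorted(self.products)))
        if len(self.reactants) > 2 or len(self.products) > 2:
            raise ValueError(
                f"at most 2 reactants/products supported, got {self}"
            )
        if not np.isfinite(self.rate) or self.rate < 0:
            raise ValueError(f"rate must be finite and nonnegative: {self.rate}")

    def net_stoichiometry(self, name: str) -> int:
        """Multiplicity of *name* in products minus multiplicity in reactants."""
        return self.products.count(name) - self.reactants.count(name)

    @property
    def species(self) -> set[str]:
        return set(self.reactants) | set(self.products)

    def __str__(self) -> str:
        lhs = " + ".join(self.reactants) if self.reactants else "0"
        rhs = " + ".join(self.products) if self.products else "0"
        return f"{lhs} -> {rhs} @ {self.rate:g}"


def net_stoichiometry(reaction: Reaction, name: str) -> int:
    """Net stoichiometric coefficient of species *name* in *reaction*."""
    return reaction.net_stoichiometry(name)


class ReactionNetwork:
    """Species plus mass-action reactions, with cached numerics.

    Species order is the declared order; it fixes the layout of state vectors,
    the stoichiometric matrix and trajectory columns.
    """

    def __init__(self, species: Sequence[Species], reactions: Sequence[Reaction]):
        names = [s.name for s in species]
        if len(set(names)) != len(names):
            raise ValueError("duplicate species names")
        declared = set(names)
        for r in reactions:
            missing = r.species - declared
            if missing:
                raise ValueError(f"reaction {r} references undeclared species {sorted(missing)}")
        self.species: tuple[Species, ...] = tuple(species)
        self.reactions: tuple[Reaction, ...] = tuple(reactions)
        self.index: dict[str, int] = {n: i for i, n in enumerate(names)}
        self._cache: dict[str, np.ndarray] | None = None

    # -- basic views -------------------------------------------------------

    @property
    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    @property
    def clamped_names(self) -> list[str]:
        return [s.name for s in self.species if s.clamped]

    def species_by_name(self, name: str) -> Species:
        return self.species[self.index[name]]

    def stoichiometric_matrix(self) -> np.ndarray:
        """Net stoichiometry, shape (n_species, n_reactions)."""
        S = np.zeros((len(self.species), len(self.reactions)), dtype=int)
        for j, r in enumerate(self.reactions):
            for name in r.species:
                S[self.index[name], j] = r.net_stoichiometry(name)
        return S

    # -- mass-action kinetics ---------------------------------------------

    def _numerics(self) -> dict[str, np.ndarray]:
        if self._cache is None:
            n_r = len(self.reactions)
            ra = np.full(n_r, -1, dtype=int)  # first reactant index (-1: none)
            rb = np.full(n_r, -1, dtype=int)  # second reactant index
            for j, r in enumerate(self.reactions):
                idx = [self.index[q] for q in r.reactants]
                if len(idx) >= 1:
                    ra[j] = idx[0]
                if len(idx) == 2:
                    rb[j] = idx[1]
            S = self.stoichiometric_matrix().astype(float)
            clamped = np.array([s.clamped for s in self.species], dtype=bool)
            S[clamped, :] = 0.0
            self._cache = {
                "ra": ra,
                "rb": rb,
                "rates": np.array([r.rate for r in self.reactions]),
                "S_eff": S,
            }
        return self._cache

    def propensities(self, state: np.ndarray) -> np.ndarray:
        """Mass-action fluxes rate·Πreactants at the given state."""
        nm = self._numerics()
        flux = nm["rates"].copy()
        has_a = nm["ra"] >= 0
        flux[has_a] *= state[nm["ra"][has_a]]
        has_b = nm["rb"] >= 0
        flux[has_b] *= state[nm["rb"][has_b]]
        return flux

    def vector_field(self, state: np.ndarray | Mapping[str, float]) -> np.ndarray:
        """Time derivative of concentrations; clamped entries are zero.

        d[s]/dt = Σ_r rate(r)·netstoich(s,r)·Π_{q∈reactants(r)} [q]
        """
        x = self.state_vector(state)
        if np.any(x < 0):
            raise ValueError("state must be nonnegative")
        nm = self._numerics()
        return nm["S_eff"] @ self.propensities(x)

    def state_vector(self, state: np.ndarray | Mapping[str, float]) -> np.ndarray:
        """Coerce a dict or array state to the network's species order."""
        if isinstance(state, Mapping):
            unknown = set(state) - set(self.index)
            if unknown:
                raise ValueError(f"unknown species in state: {sorted(unknown)}")
            return np.array([float(state.get(n, 0.0)) for n in self.species_names])
        x = np.asarray(state, dtype=float)
        if x.shape != (len(self.species),):
            raise ValueError(
                f"state has shape {x.shape}, expected ({len(self.species)},)"
            )
        return x.copy()

    # -- comparison --------------------------------------------------------

    def reaction_multiset(self) -> dict[tuple[tuple[str, ...], tuple[str, ...], float], int]:
        out: dict[tuple[tuple[str, ...], tuple[str, ...], float], int] = {}
        for r in self.reactions:
            key = (r.reactants, r.products, r.rate)
            out[key] = out.get(key, 0) + 1
        return out

    def __repr__(self) -> str:
        return (
            f"<ReactionNetwork {len(self.species)} species, "
            f"{len(self.reactions)} reactions>"
        )


def vector_field(net: ReactionNetwork, state) -> np.ndarray:
    """Functional form of :meth:`ReactionNetwork.vector_field`."""
    return net.vector_field(state)


# ---------------------------------------------------------------------------
# Signed influence graphs and feedback loops
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SignedInfluenceGraph:
    """Directed graph with +/− edges; parallel opposite-sign edges allowed."""

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str, str], ...]  # (source, target, "+" | "-")

    def __post_init__(self) -> None:
        for u, v, s in self.edges:
            if s not in ("+", "-"):
                raise ValueError(f"edge sign must be '+' or '-', got {s!r}")
            if u not in self.nodes or v not in self.nodes:
                raise ValueError(f"edge ({u},{v}) references undeclared node")


@dataclass(frozen=True)
class FeedbackLoop:
    """A simple directed cycle; sign is + iff it has an even number of − edges."""

    cycle: tuple[str, ...]
    edge_signs: tuple[str, ...]

    @property
    def sign(self) -> str:
        return "+" if self.edge_signs.count("-") % 2 == 0 else "-"

    @property
    def length(self) -> int:
        return len(self.cycle)


def _canonical_rotation(nodes: tuple[str, ...], signs: tuple[str, ...]):
    """Rotate a cycle so it starts at its lexicographically smallest node."""
    k = min(range(len(nodes)), key=lambda i: nodes[i])
    return nodes[k:] + nodes[:k], signs[k:] + signs[:k]


def enumerate_feedback_loops(g: SignedInfluenceGraph) -> list[FeedbackLoop]:
    """All simple directed cycles of *g*, annotated with their sign.

    Node cycles come from :func:`networkx.simple_cycles`; each is expanded over
    every combination of parallel signed edges along it, so a pair of nodes
    joined by both a + and a − edge yields distinct loops.  Output is sorted
    lexicographically by (node sequence, edge signs).
    """
    dg = nx.DiGraph()
    dg.add_nodes_from(g.nodes)
    signs: dict[tuple[str, str], set[str]] = {}
    for u, v, s in g.edges:
        dg.add_edge(u, v)
        signs.setdefault((u, v), set()).add(s)

    loops: set[tuple[tuple[str, ...], tuple[str, ...]]] = set()
    for cyc in nx.simple_cycles(dg):
        nodes = tuple(cyc)
        pairs = [(nodes[i], nodes[(i + 1) % len(nodes)]) for i in range(len(nodes))]
        choices: list[tuple[str, ...]] = [()]
        for uv in pairs:
            choices = [c + (s,) for c in choices for s in sorted(signs[uv])]
        for sgn in choices:
            loops.add(_canonical_rotation(nodes, sgn))
    return [
        FeedbackLoop(cycle=nodes, edge_signs=sgn)
        for nodes, sgn in sorted(loops)
    ]


# ---------------------------------------------------------------------------
# Conservation laws
# ---------------------------------------------------------------------------


def _is_conserved(net: ReactionNetwork, subset: frozenset[str]) -> bool:
    return all(
        sum(r.net_stoichiometry(n) for n in subset) == 0 for r in net.reactions
    )


def conservation_laws(net: ReactionNetwork) -> list[frozenset[str]]:
    """Species subsets whose summed amount is invariant under every reaction.

    Candidates are generated two ways and then verified against the
    stoichiometric matrix: (a) grouping species by node prefix (name with a
    trailing digit stripped), which recovers the per-node triples of expanded
    triplet networks; (b) sign-uniform vectors of the left null space of the
    stoichiometric matrix.  Only exactly conserved subsets are returned,
    sorted for reproducibility.
    """
    candidates: set[frozenset[str]] = set()

    groups: dict[str, set[str]] = {}
    for s in net.species:
        prefix = re.sub(r"[0-9]+$", "", s.name) or s.name
        groups.setdefault(prefix, set()).add(s.name)
    candidates.update(frozenset(v) for v in groups.values())

    S = net.stoichiometric_matrix()
    if S.size:
        # Left null space: vectors y with yᵀS = 0.
        _, sv, vt = np.linalg.svd(S.T.astype(float))
        tol = max(S.shape) * np.finfo(float).eps * (sv[0] if sv.size else 1.0)
        null = vt[np.sum(sv > tol):]
        names = net.species_names
        for y in null:
            y = np.where(np.abs(y) < 1e-10, 0.0, y)
            if np.all(y >= 0) or np.all(y <= 0):
                support = frozenset(n for n, c in zip(names, y) if c != 0)
                if support:
                    candidates.add(support)

    laws = [c for c in candidates if c and _is_conserved(net, c)]
    return sorted(laws, key=lambda c: sorted(c))
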