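"""Reaction-network morphisms: homomorphism, stoichiomorphism, emulation.

A morphism between reaction networks maps species to species and reactions
to reactions.  It is a *homomorphism* when every reaction's reactant and
product multisets are preserved under the species map, and a
*stoichiomorphism* when, for every source species s and every target
reaction r′, the rate-weighted net stoichiometries of the source reactions
mapping onto r′ sum to the target's::

    Σ_{r ↦ r′} rate(r)·netstoich(s, r)  =  rate(r′)·netstoich(m(s), r′)

A morphism with both properties is an *emulation*: for every target initial
condition, giving each source species its image's value makes every source
trajectory coincide exactly with its image's trajectory.  This module
provides the structural checkers, an independent vector-field oracle, a
numerical trajectory-level verifier, re-solving of source rates after the
target's rates change, and exhaustive search for triplet-respecting
emulations.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .crn import Reaction, ReactionNetwork
from .dynamics import simulate_ode
from .influence import InfluenceNetwork, expand, node_species

__all__ = [
    "Morphism",
    "MorphismReport",
    "EmulationReport",
    "parse_node_map",
    "induce_reaction_map",
    "check_homomorphism",
    "check_stoichiomorphism",
    "check_morphism",
    "vector_field_equivalence",
    "verify_emulation",
    "solve_source_rates",
    "find_emulations",
    "compose",
]

STOICH_TOL = 1e-12


@dataclass
class Morphism:
    """Species map plus reaction map (source reaction index → target index).

    ``species_map`` may be partial (e.g. clamped inputs without an image);
    reactions touching unmapped species cannot have an image and are listed
    in ``unmapped_reactions``.
    """

    species_map: dict[str, str]
    reaction_map: dict[int, int]
    unmapped_reactions: list[tuple[int, str]] = field(default_factory=list)

    def is_total_on(self, src: ReactionNetwork) -> bool:
        return all(s.name in self.species_map for s in src.species) and all(
            j in self.reaction_map for j in range(len(src.reactions))
        )


@dataclass
class MorphismReport:
    is_homomorphism: bool
    is_stoichiomorphism: bool
    violations: list[tuple] = field(default_factory=list)

    @property
    def certified(self) -> bool:
        """Both structural properties hold, hence emulation by the theorem."""
        return self.is_homomorphism and self.is_stoichiomorphism


@dataclass
class EmulationReport:
    structural: MorphismReport
    max_deviation: float
    initial_conditions: list[dict[str, float]]
    tol: float
    verdict: bool


# ---------------------------------------------------------------------------
# Species maps
# ---------------------------------------------------------------------------

_MAP_LINE = re.compile(
    r"^(?:map\s+)?(?:(?P<sp>species)\s+)?(?P<rev>~)?(?P<src>\w+)\s*->\s*(?P<dst>\w+)$"
)


def parse_node_map(
    text: str, src: InfluenceNetwork, dst: InfluenceNetwork
) -> dict[str, str]:
    """Expand node-level map shorthand into a species-level map.

    One entry per line: ``y -> x`` maps y_0,y_1,y_2 to x_0,x_1,x_2 in order;
    ``~y -> x`` reverses the orientation (y_0↦x_2, y_1↦x_1, y_2↦x_0);
    ``species y_1 -> x_1`` maps a single species (used for clamped inputs).
    Lines may carry a leading ``map`` keyword; ``#`` starts a comment.
    """
    species_map: dict[str, str] = {}
    src_nodes = set(src.node_names)
    dst_nodes = set(dst.node_names)
    dst_species = {s for n in dst.node_names for s in node_species(n)} | set(
        dst.clamped_names
    )
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        m = _MAP_LINE.match(line)
        if not m:
            raise ValueError(f"line {lineno}: cannot parse map entry {raw!r}")
        if m.group("sp"):
            s, d = m.group("src"), m.group("dst")
            if d not in dst_species:
                raise ValueError(f"line {lineno}: unknown target species {d!r}")
            species_map[s] = d
            continue
        s, d = m.group("src"), m.group("dst")
        if s not in src_nodes:
            raise ValueError(f"line {lineno}: unknown source node {s!r}")
        if d not in dst_nodes:
            raise ValueError(f"line {lineno}: unknown target node {d!r}")
        src_sp = node_species(s)
        dst_sp = node_species(d)
        if m.group("rev"):
            dst_sp = dst_sp[::-1]
        species_map.update(zip(src_sp, dst_sp))
    return species_map


def node_map(
    src: InfluenceNetwork,
    dst: InfluenceNetwork,
    assignment: dict[str, tuple[str, bool]],
) -> dict[str, str]:
    """Species map from {src node: (dst node, reversed?)} assignments."""
    text = "\n".join(
        f"{'~' if rev else ''}{s} -> {d}" for s, (d, rev) in assignment.items()
    )
    return parse_node_map(text, src, dst)


# ---------------------------------------------------------------------------
# Structural checks
# ---------------------------------------------------------------------------


def _image_multiset(names: tuple[str, ...], smap: dict[str, str]):
    return tuple(sorted(smap[n] for n in names))


def induce_reaction_map(
    species_map: dict[str, str], src: ReactionNetwork, dst: ReactionNetwork
) -> Morphism:
    """Homomorphic projection: each source reaction maps to the target
    reaction with the image reactant and product multisets.

    Reactions whose species are not all mapped, or whose image multisets
    match no target reaction, are recorded as unmapped (homomorphism
    violations) rather than raising.
    """
    by_multisets: dict[tuple, int] = {}
    for j, r in enumerate(dst.reactions):
        by_multisets.setdefault((r.reactants, r.products), j)
    reaction_map: dict[int, int] = {}
    unmapped: list[tuple[int, str]] = []
    for j, r in enumerate(src.reactions):
        missing = [q for q in r.species if q not in species_map]
        if missing:
            unmapped.append((j, f"unmapped species {missing}"))
            continue
        key = (
            _image_multiset(r.reactants, species_map),
            _image_multiset(r.products, species_map),
        )
        if key in by_multisets:
            reaction_map[j] = by_multisets[key]
        else:
            unmapped.append((j, f"no target reaction with image {key}"))
    return Morphism(species_map=dict(species_map), reaction_map=reaction_map,
                    unmapped_reactions=unmapped)


def check_homomorphism(
    m: Morphism, src: ReactionNetwork, dst: ReactionNetwork
) -> MorphismReport:
    """Verify reactant/product multiset preservation reaction by reaction."""
    violations: list[tuple] = [(j, why) for j, why in m.unmapped_reactions]
    for j, r in enumerate(src.reactions):
        if j not in m.reaction_map:
            if not any(v[0] == j for v in violations):
                violations.append((j, "reaction has no image"))
            continue
        if any(q not in m.species_map for q in r.species):
            violations.append((j, "reaction involves unmapped species"))
            continue
        rp = dst.reactions[m.reaction_map[j]]
        img_r = _image_multiset(r.reactants, m.species_map)
        img_p = _image_multiset(r.products, m.species_map)
        if img_r != rp.reactants or img_p != rp.products:
            violations.append(
                (j, f"image multisets {img_r}->{img_p} differ from {rp}")
            )
    return MorphismReport(
        is_homomorphism=not violations,
        is_stoichiomorphism=False,
        violations=violations,
    )


def check_stoichiomorphism(
    m: Morphism, src: ReactionNetwork, dst: ReactionNetwork
) -> MorphismReport:
    """Full structural check: homomorphism plus the rate-weighted
    stoichiometry balance for every (source species, target reaction) pair."""
    hom = check_homomorphism(m, src, dst)
    violations: list[tuple] = []
    if not all(s.name in m.species_map for s in src.species):
        missing = [s.name for s in src.species if s.name not in m.species_map]
        violations.append(("species_map", f"not total: {missing} unmapped"))
    for s in src.species:
        if s.name not in m.species_map:
            continue
        img = m.species_map[s.name]
        for jp, rp in enumerate(dst.reactions):
            lhs = sum(
                r.rate * r.net_stoichiometry(s.name)
                for j, r in enumerate(src.reactions)
                if m.reaction_map.get(j) == jp
            )
            rhs = rp.rate * rp.net_stoichiometry(img)
            if abs(lhs - rhs) > STOICH_TOL:
                violations.append(
                    ((s.name, jp), f"aggregate {lhs:g} != target {rhs:g}")
                )
    return MorphismReport(
        is_homomorphism=hom.is_homomorphism,
        is_stoichiomorphism=hom.is_homomorphism and not violations,
        violations=hom.violations + violations,
    )


def check_morphism(
    species_map: dict[str, str], src: ReactionNetwork, dst: ReactionNetwork
) -> tuple[Morphism, MorphismReport]:
    """Induce the reaction map and run both structural checks."""
    m = induce_reaction_map(species_map, src, dst)
    return m, check_stoichiomorphism(m, src, dst)


def compose(
    m1: Morphism, m2: Morphism
) -> Morphism:
    """Composite morphism A→C of m1: A→B and m2: B→C."""
    smap = {s: m2.species_map[d] for s, d in m1.species_map.items()
            if d in m2.species_map}
    rmap = {j: m2.reaction_map[k] for j, k in m1.reaction_map.items()
            if k in m2.reaction_map}
    return Morphism(species_map=smap, reaction_map=rmap)


# ---------------------------------------------------------------------------
# Numerical verification
# ---------------------------------------------------------------------------


def pullback_state(
    m: Morphism, src: ReactionNetwork, dst_state: dict[str, float] | np.ndarray,
    dst: ReactionNetwork,
) -> np.ndarray:
    """Source state in which each species takes its image's value."""
    xd = dst.state_vector(dst_state)
    xs = np.zeros(len(src.species))
    for i, s in enumerate(src.species):
        img = m.species_map.get(s.name)
        if img is None:
            raise ValueError(f"species {s.name!r} has no image; pullback undefined")
        xs[i] = xd[dst.index[img]]
    return xs


def vector_field_equivalence(
    m: Morphism,
    src: ReactionNetwork,
    dst: ReactionNetwork,
    n_points: int = 100,
    seed: int = 0,
) -> float:
    """Independent oracle for emulation: max |ds/dt − d m(s)/dt| over random
    target states with source states set by pullback.

    Zero (to rounding) iff the two differential systems coincide under the
    mapping — the analytical content of the emulation theorem.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_points):
        xd = rng.uniform(0.0, 1.0, size=len(dst.species))
        xs = pullback_state(m, src, xd, dst)
        fs = src.vector_field(xs)
        fd = dst.vector_field(xd)
        for i, s in enumerate(src.species):
            dev = abs(fs[i] - fd[dst.index[m.species_map[s.name]]])
            worst = max(worst, float(dev))
    return worst


def verify_emulation(
    m: Morphism,
    src: ReactionNetwork,
    dst: ReactionNetwork,
    target_init: dict[str, float] | None = None,
    t_end: float = 30.0,
    tol: float = 1e-6,
    n_random: int = 5,
    seed: int = 0,
    rel_tol: float = 1e-9,
    n_out: int = 300,
) -> EmulationReport:
    """Trajectory-level emulation check.

    For each target initial condition (given, or *n_random* random draws),
    the source starts from the pullback state; both networks are integrated
    and the sup-norm deviation between every source trace and its image's
    trace is taken.  The verdict is ``max_deviation < tol``; the structural
    report is attached so theorem-certified cases can be recognized.
    """
    structural = check_stoichiomorphism(m, src, dst)
    rng = np.random.default_rng(seed)
    if target_init is not None:
        inits = [dict(zip(dst.species_names, map(float, dst.state_vector(target_init))))]
    else:
        inits = [
            dict(zip(dst.species_names, rng.uniform(0.0, 1.0, len(dst.species))))
            for _ in range(n_random)
        ]
    max_dev = 0.0
    for init in inits:
        try:
            xs0 = pullback_state(m, src, init, dst)
        except ValueError:
            max_dev = np.inf
            break
        ts = simulate_ode(src, xs0, t_end=t_end, rel_tol=rel_tol, n_out=n_out)
        td = simulate_ode(dst, init, t_end=t_end, rel_tol=rel_tol, n_out=n_out)
        for i, s in enumerate(src.species):
            img = m.species_map[s.name]
            dev = float(np.max(np.abs(ts.values[:, i] - td[img])))
            max_dev = max(max_dev, dev)
    return EmulationReport(
        structural=structural,
        max_deviation=max_dev,
        initial_conditions=inits,
        tol=tol,
        verdict=bool(max_dev < tol),
    )


# ---------------------------------------------------------------------------
# Change of rates
# ---------------------------------------------------------------------------


def solve_source_rates(
    m: Morphism,
    src: ReactionNetwork,
    dst: ReactionNetwork,
    residual_tol: float = 1e-9,
) -> dict[int, float]:
    """Re-solve source rates so the morphism remains a stoichiomorphism of a
    re-rated target network (change of rates).

    The stoichiomorphism balance is linear in the source rates once the
    reaction map is fixed; it is solved as a nonnegative least-squares
    problem and accepted only when the residual vanishes.  Raises
    ``ValueError`` with the violated (species, target reaction) constraints
    when no nonnegative solution exists.
    """
    if not m.is_total_on(src):
        raise ValueError("morphism must be total on the source network")
    n = len(src.reactions)
    rows = []
    rhs = []
    labels = []
    for s in src.species:
        img = m.species_map[s.name]
        for jp, rp in enumerate(dst.reactions):
            row = np.zeros(n)
            for j, r in enumerate(src.reactions):
                if m.reaction_map.get(j) == jp:
                    row[j] = r.net_stoichiometry(s.name)
            b = rp.rate * rp.net_stoichiometry(img)
            if np.any(row != 0) or b != 0:
                rows.append(row)
                rhs.append(b)
                labels.append((s.name, jp))
    A = np.array(rows)
    b = np.array(rhs)
    x, _ = nnls(A, b)
    resid = A @ x - b
    bad = [
        (labels[i], float(resid[i]))
        for i in np.flatnonzero(np.abs(resid) > residual_tol)
    ]
    if bad:
        raise ValueError(f"no nonnegative source rates satisfy the balance: {bad}")
    return {j: float(x[j]) for j in range(n)}


def rerate(net: ReactionNetwork, rates: dict[int, float]) -> ReactionNetwork:
    """Copy of *net* with reaction rates replaced by index."""
    new = [
        Reaction(r.reactants, r.products, rates.get(j, r.rate))
        for j, r in enumerate(net.reactions)
    ]
    return ReactionNetwork(net.species, new)


# ---------------------------------------------------------------------------
# Exhaustive emulation search
# ---------------------------------------------------------------------------


@dataclass
class FoundEmulation:
    assignment: dict[str, tuple[str, bool]]  # src node -> (dst node, reversed?)
    clamped_assignment: dict[str, str]
    morphism: Morphism
    report: MorphismReport


def find_emulations(
    src: InfluenceNetwork,
    dst: InfluenceNetwork,
    max_species: int = 12,
) -> list[FoundEmulation]:
    """Exhaustively search triplet-respecting emulations from src to dst.

    Candidate species maps send each source node to a target node either
    orientation-preserving or reversed, and each clamped source input to a
    clamped target input; candidates passing both structural checks (hence
    certified emulations) are returned in deterministic order.  Raises on
    search spaces past ``max_species`` source species.
    """
    src_net, dst_net = expand(src), expand(dst)
    if len(src_net.species) > max_species:
        raise ValueError(
            f"source has {len(src_net.species)} species > max_species={max_species}"
        )
    node_choices = [
        (d, rev) for d in dst.node_names for rev in (False, True)
    ]
    found: list[FoundEmulation] = []
    src_clamped = src.clamped_names
    dst_clamped = dst.clamped_names
    if src_clamped and not dst_clamped:
        clamp_options: list[tuple[str, ...]] = []  # no admissible clamp image
    else:
        clamp_options = list(itertools.product(dst_clamped, repeat=len(src_clamped)))
        clamp_options = clamp_options or [()]
    for combo in itertools.product(node_choices, repeat=len(src.nodes)):
        assignment = dict(zip(src.node_names, combo))
        for clamp_combo in clamp_options:
            smap = node_map(src, dst, assignment)
            smap.update(dict(zip(src_clamped, clamp_combo)))
            morph, report = check_morphism(smap, src_net, dst_net)
            if report.certified:
                found.append(
                    FoundEmulation(
                        assignment=assignment,
                        clamped_assignment=dict(zip(src_clamped, clamp_combo)),
                        morphism=morph,
                        report=report,
                    )
                )
    return found
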