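"""Morphism parsing, structural checks, oracle, emulation, rate solving."""

import numpy as np
import pytest

from switchnet import (
    expand,
    generate_random_inet,
    library,
)
from switchnet.crn import Reaction, ReactionNetwork
from switchnet.morphism import (
    check_homomorphism,
    check_morphism,
    check_stoichiomorphism,
    compose,
    find_emulations,
    induce_reaction_map,
    node_map,
    parse_node_map,
    rerate,
    solve_source_rates,
    vector_field_equivalence,
    verify_emulation,
)

from conftest import BUNDLED_MAPS, CC_MAP


class TestParseNodeMap:
    def test_reversed_shorthand(self, am_inet):
        mi = library("MI")
        smap = parse_node_map("~z -> x", mi, am_inet)
        assert smap == {"z_0": "x_2", "z_1": "x_1", "z_2": "x_0"}

    def test_preserving_shorthand(self, am_inet):
        mi = library("MI")
        smap = parse_node_map("y -> x", mi, am_inet)
        assert smap == {"y_0": "x_0", "y_1": "x_1", "y_2": "x_2"}

    def test_identity_shorthand(self, am_inet):
        smap = parse_node_map("x -> x", am_inet, am_inet)
        assert smap == {s: s for s in ("x_0", "x_1", "x_2")}

    def test_species_level_entry_and_comments(self, am_inet):
        mi = library("MI")
        smap = parse_node_map("# comment\nmap species y_1 -> x_1\n", mi, am_inet)
        assert smap == {"y_1": "x_1"}

    def test_unknown_nodes_rejected(self, am_inet):
        with pytest.raises(ValueError, match="unknown source node"):
            parse_node_map("ghost -> x", library("MI"), am_inet)
        with pytest.raises(ValueError, match="unknown target node"):
            parse_node_map("y -> ghost", library("MI"), am_inet)


class TestInduceReactionMap:
    def test_mi_reaction_images(self, am_inet, am_net):
        mi = library("MI")
        mi_net = expand(mi)
        smap = parse_node_map(BUNDLED_MAPS["MI"], mi, am_inet)
        m = induce_reaction_map(smap, mi_net, am_net)
        assert not m.unmapped_reactions
        # z_2 catalyses y_1 -> y_0, whose image is x_0 catalysing x_1 -> x_0
        j = mi_net.reactions.index(Reaction(("z_2", "y_1"), ("z_2", "y_0")))
        jp = am_net.reactions.index(Reaction(("x_0", "x_1"), ("x_0", "x_0")))
        assert m.reaction_map[j] == jp

    def test_identity_is_identity(self, am_net):
        smap = {s: s for s in am_net.species_names}
        m = induce_reaction_map(smap, am_net, am_net)
        assert m.reaction_map == {j: j for j in range(4)}

    def test_scrambled_map_reports_every_unmappable_reaction(self, am_net):
        smap = {"x_0": "x_1", "x_1": "x_1", "x_2": "x_1"}  # collapse to x_1
        m = induce_reaction_map(smap, am_net, am_net)
        assert not m.reaction_map
        assert len(m.unmapped_reactions) == 4


class TestStructuralChecks:
    def test_bundled_maps_are_certified(self, bundled_morphism_inputs, am_net):
        for mid, _src, src_net, smap in bundled_morphism_inputs:
            _, report = check_morphism(smap, src_net, am_net)
            assert report.is_homomorphism, mid
            assert report.is_stoichiomorphism, mid
            assert report.violations == []

    def test_unreversed_z_breaks_homomorphism(self, am_inet, am_net):
        mi = library("MI")
        smap = parse_node_map("y -> x\nz -> x", mi, am_inet)
        m = induce_reaction_map(smap, expand(mi), am_net)
        report = check_homomorphism(m, expand(mi), am_net)
        assert not report.is_homomorphism

    def test_rate_mismatch_breaks_stoichiomorphism_only(self, am_net):
        doubled = rerate(am_net, {j: 2.0 for j in range(4)})
        smap = {s: s for s in am_net.species_names}
        m = induce_reaction_map(smap, doubled, am_net)
        report = check_stoichiomorphism(m, doubled, am_net)
        assert report.is_homomorphism
        assert not report.is_stoichiomorphism

    def test_single_perturbed_rate_breaks_the_balance(self, am_inet, am_net):
        mi = library("MI")
        mi_net = expand(mi)
        smap = parse_node_map(BUNDLED_MAPS["MI"], mi, am_inet)
        for j in range(len(mi_net.reactions)):
            perturbed = rerate(mi_net, {j: 1.1})
            m = induce_reaction_map(smap, perturbed, am_net)
            report = check_stoichiomorphism(m, perturbed, am_net)
            assert not report.is_stoichiomorphism

    def test_cc_to_am_fails_structurally(self, am_inet, am_net):
        cc = library("CC")
        smap = parse_node_map(CC_MAP, cc, am_inet)
        _, report = check_morphism(smap, expand(cc), am_net)
        assert not report.is_homomorphism
        assert any("unmapped species" in str(v) for v in report.violations)

    def test_composition_of_certified_morphisms_is_certified(self, am_inet, am_net):
        # EPI → AM → AM(identity): composite must pass both checks
        epi = library("EPI")
        epi_net = expand(epi)
        m1, r1 = check_morphism(
            parse_node_map(BUNDLED_MAPS["EPI"], epi, am_inet), epi_net, am_net
        )
        m2, r2 = check_morphism(
            {s: s for s in am_net.species_names}, am_net, am_net
        )
        assert r1.certified and r2.certified
        comp = compose(m1, m2)
        report = check_stoichiomorphism(comp, epi_net, am_net)
        assert report.certified


class TestVectorFieldOracle:
    def test_zero_residual_for_bundled_maps(self, bundled_morphism_inputs, am_net):
        for mid, _src, src_net, smap in bundled_morphism_inputs:
            m = induce_reaction_map(smap, src_net, am_net)
            assert vector_field_equivalence(m, src_net, am_net,
                                            n_points=50, seed=2) < 1e-12, mid

    def test_identity_residual_is_exactly_zero(self, am_net):
        m = induce_reaction_map(
            {s: s for s in am_net.species_names}, am_net, am_net
        )
        assert vector_field_equivalence(m, am_net, am_net, n_points=20, seed=0) == 0.0

    def test_perturbed_rate_gives_positive_residual(self, am_inet, am_net):
        mi = library("MI")
        perturbed = rerate(expand(mi), {0: 1.1})
        smap = parse_node_map(BUNDLED_MAPS["MI"], mi, am_inet)
        m = induce_reaction_map(smap, perturbed, am_net)
        assert vector_field_equivalence(m, perturbed, am_net,
                                        n_points=50, seed=2) > 1e-3

    def test_checker_agrees_with_oracle_on_random_morphisms(self, am_inet, am_net):
        # random triplet maps onto AM: the structural verdict and the
        # vector-field residual must always agree
        rng = np.random.default_rng(123)
        agree = 0
        for k in range(30):
            inet = generate_random_inet(int(rng.integers(1, 4)), 0.5,
                                        seed=int(rng.integers(1e6)))
            assignment = {
                n: ("x", bool(rng.integers(2))) for n in inet.node_names
            }
            smap = node_map(inet, am_inet, assignment)
            net = expand(inet)
            m, report = check_morphism(smap, net, am_net)
            if m.unmapped_reactions:
                continue  # oracle needs a total reaction map
            resid = vector_field_equivalence(m, net, am_net, n_points=40,
                                             seed=k)
            assert report.is_stoichiomorphism == (resid < 1e-10)
            agree += 1
        assert agree >= 5  # the comparison must actually exercise both sides


class TestVerifyEmulation:
    def test_gw_emulates_am_exactly(self, am_inet, am_net):
        gw = library("GW")
        gw_net = expand(gw)
        smap = parse_node_map(BUNDLED_MAPS["GW"], gw, am_inet)
        m = induce_reaction_map(smap, gw_net, am_net)
        report = verify_emulation(m, gw_net, am_net, n_random=5, seed=4)
        assert report.structural.certified
        assert report.verdict
        assert report.max_deviation < 1e-6

    def test_supplied_initial_condition(self, am_inet, am_net):
        mi = library("MI")
        mi_net = expand(mi)
        smap = parse_node_map(BUNDLED_MAPS["MI"], mi, am_inet)
        m = induce_reaction_map(smap, mi_net, am_net)
        report = verify_emulation(
            m, mi_net, am_net,
            target_init={"x_0": 0.2, "x_1": 0.5, "x_2": 0.3},
        )
        assert report.verdict and len(report.initial_conditions) == 1

    def test_perturbed_rate_produces_visible_deviation(self, am_inet, am_net):
        mi = library("MI")
        perturbed = rerate(expand(mi), {0: 1.1})
        smap = parse_node_map(BUNDLED_MAPS["MI"], mi, am_inet)
        m = induce_reaction_map(smap, perturbed, am_net)
        report = verify_emulation(m, perturbed, am_net, n_random=5, seed=4)
        assert not report.structural.certified
        assert report.max_deviation > 1e-3
        assert not report.verdict


class TestSolveSourceRates:
    def test_identity_with_doubled_target(self, am_net):
        doubled = rerate(am_net, {j: 2.0 for j in range(4)})
        m = induce_reaction_map(
            {s: s for s in am_net.species_names}, am_net, doubled
        )
        rates = solve_source_rates(m, am_net, doubled)
        assert rates == {j: pytest.approx(2.0) for j in range(4)}

    def test_mi_rates_for_rerated_am(self, am_inet, am_net):
        mi = library("MI")
        mi_net = expand(mi)
        target = rerate(am_net, {0: 2.0, 1: 3.0, 2: 2.0, 3: 3.0})
        smap = parse_node_map(BUNDLED_MAPS["MI"], mi, am_inet)
        m = induce_reaction_map(smap, mi_net, am_net)
        rates = solve_source_rates(m, mi_net, target)
        assert all(v >= 0 for v in rates.values())
        rerated = rerate(mi_net, rates)
        assert vector_field_equivalence(m, rerated, target,
                                        n_points=50, seed=1) < 1e-9

    def test_infeasible_target_reported(self, am_net):
        # target with an extra reaction no source reaction maps onto: the
        # aggregate balance for its consumed species demands 0 = −rate
        extra = Reaction(("x_1", "x_2"), ("x_1", "x_1"), 1.0)
        target = ReactionNetwork(am_net.species,
                                 list(am_net.reactions) + [extra])
        m = induce_reaction_map(
            {s.name: s.name for s in am_net.species}, am_net, target
        )
        assert not m.unmapped_reactions
        with pytest.raises(ValueError, match="no nonnegative source rates"):
            solve_source_rates(m, am_net, target)


class TestFindEmulations:
    def test_mi_to_am_finds_both_mirror_maps(self, am_inet):
        found = find_emulations(library("MI"), am_inet)
        assignments = [f.assignment for f in found]
        assert {"y": ("x", False), "z": ("x", True)} in assignments
        assert {"y": ("x", True), "z": ("x", False)} in assignments

    def test_am_to_am_contains_identity(self, am_inet):
        found = find_emulations(am_inet, am_inet)
        assert {"x": ("x", False)} in [f.assignment for f in found]

    def test_cc_to_am_finds_none(self, am_inet):
        assert find_emulations(library("CC"), am_inet) == []

    def test_search_space_guard(self, am_inet):
        with pytest.raises(ValueError, match="max_species"):
            find_emulations(library("GW"), am_inet, max_species=6)
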