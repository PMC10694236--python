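"""Sulfur-oxidation core network, pathway enumeration and energetics."""

import pytest

from sulfurgem.core import Reaction, check_balance
from sulfurgem.curation import detect_energy_cycles
from sulfurgem.fba import fba
from sulfurgem.sulfur import (
    SULFUR_SUBSYSTEM,
    build_sulfur_core,
    compare_cbb_variants,
    core_medium,
    enumerate_pathways,
    fixed_co2_substrate_demand,
    insertion_test,
    optimal_pathway,
    pathway_energetics,
    sor_reaction,
    substrate_equivalence,
)

PATH_I_TOPOLOGY = {"OMP", "SQR", "CONDS", "HDR", "APSSAT"}


class TestCoreBuild:
    def test_every_non_boundary_reaction_balanced(self, sulfur_core):
        for rxn in sulfur_core.reactions.values():
            report = check_balance(rxn, sulfur_core.metabolites)
            assert report in ("exempt", {}), f"{rxn.id}: {report}"

    def test_core_is_energy_cycle_free(self, sulfur_core):
        assert detect_energy_cycles(sulfur_core) == []

    def test_grows_on_sulfur_not_without_it(self, sulfur_core):
        growing = fba(sulfur_core, "BIOMASS", core_medium(1.5))
        assert growing.objective_value > 1e-3
        starved = fba(sulfur_core, "BIOMASS", core_medium(0.0))
        assert starved.objective_value == pytest.approx(0.0, abs=1e-8)

    def test_variants_differ_by_exactly_the_sebp_switch(self):
        incomplete = build_sulfur_core("incomplete")
        classical = build_sulfur_core("classical")
        only_inc = set(incomplete.reactions) - set(classical.reactions)
        only_cls = set(classical.reactions) - set(incomplete.reactions)
        assert only_inc == {"TALA"}
        assert only_cls == {"SBPA", "SBPASE"}

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            build_sulfur_core("heterotrophic")


class TestOptimalPathway:
    def test_path_i_topology_at_default_uptake(self, sulfur_core):
        pw = optimal_pathway(sulfur_core, 1.5)
        assert pw is not None
        assert set(pw.active_reactions) == PATH_I_TOPOLOGY
        assert pw.energetics.atp_rate > 0
        assert pw.energetics.growth_rate > 0

    def test_zero_uptake_means_zero_energetics(self, sulfur_core):
        assert optimal_pathway(sulfur_core, 0.0) is None

    def test_sulfur_mass_balance_at_optimum(self, sulfur_core):
        """S atoms in equal S atoms out (as sulfate) at the ATP optimum."""
        from sulfurgem.fba import pfba

        state = pfba(sulfur_core, "ATPM", core_medium(1.5))
        s_in = -state.fluxes["EX_s_e"]
        s_out = state.fluxes["EX_so4_e"] + state.fluxes.get("EX_h2s_e", 0.0)
        assert s_in == pytest.approx(1.5, abs=1e-6)
        assert s_out == pytest.approx(s_in, abs=1e-6)


class TestEnumeration:
    def test_at_least_two_pathways_with_strictly_decreasing_atp(self, sulfur_core):
        pathways = enumerate_pathways(sulfur_core, 1.5)
        assert len(pathways) >= 2
        rates = [p.energetics.atp_rate for p in pathways]
        assert all(a > b + 1e-6 for a, b in zip(rates, rates[1:]))
        assert set(pathways[0].active_reactions) == PATH_I_TOPOLOGY

    def test_path_i_dominates_componentwise(self, sulfur_core):
        pathways = enumerate_pathways(sulfur_core, 1.5)
        first = pathways[0].energetics
        for other in pathways[1:]:
            e = other.energetics
            assert first.atp_rate >= e.atp_rate
            assert first.nadh_nadph_rate >= e.nadh_nadph_rate - 1e-9
            assert first.co2_uptake >= e.co2_uptake - 1e-9
            assert first.growth_rate >= e.growth_rate - 1e-9

    def test_active_sets_are_distinct_and_deterministic(self, sulfur_core):
        first = enumerate_pathways(sulfur_core, 1.5)
        again = enumerate_pathways(sulfur_core, 1.5)
        sets = [p.active_set for p in first]
        assert len(sets) == len(set(sets))
        assert [p.active_reactions for p in first] == [p.active_reactions for p in again]

    def test_single_route_model_yields_one_pathway(self):
        """A stripped core with only the Path-I route cannot reroute."""
        model = build_sulfur_core()
        for rid in ("SOX", "TQO", "TETH", "SDO"):
            model.remove_reaction(rid)
        # also block partially oxidized RISC secretion, which would otherwise
        # allow a truncated-oxidation pathway
        for ex in ("EX_s2o3_e", "EX_h2s_e", "EX_s4o6_e"):
            model.reactions[ex].upper_bound = 0.0
        pathways = enumerate_pathways(model, 1.5)
        assert len(pathways) == 1
        assert set(pathways[0].active_reactions) == PATH_I_TOPOLOGY


class TestEnergetics:
    def test_doubling_uptake_doubles_every_rate(self, sulfur_core):
        pw = optimal_pathway(sulfur_core, 1.5)
        double = pathway_energetics(sulfur_core, pw.active_reactions, 3.0)
        single = pw.energetics
        assert double.atp_rate == pytest.approx(2 * single.atp_rate, rel=1e-6)
        assert double.nadh_nadph_rate == pytest.approx(2 * single.nadh_nadph_rate, rel=1e-6)
        assert double.co2_uptake == pytest.approx(2 * single.co2_uptake, rel=1e-6)
        assert double.growth_rate == pytest.approx(2 * single.growth_rate, rel=1e-6)

    def test_zero_rate_all_zero(self, sulfur_core):
        pw = optimal_pathway(sulfur_core, 1.5)
        zero = pathway_energetics(sulfur_core, pw.active_reactions, 0.0)
        assert zero.as_tuple() == pytest.approx((0.0, 0.0, 0.0, 0.0), abs=1e-8)


class TestComparative:
    def test_cbb_comparison_self_consistent_with_direct_lp(self):
        """The reported growth per variant equals a direct biomass FBA."""
        rows = {r["variant"]: r for r in compare_cbb_variants(1.5)}
        for variant in ("classical", "incomplete"):
            model = build_sulfur_core(variant)
            direct = fba(model, "BIOMASS", core_medium(1.5)).objective_value
            assert rows[variant]["growth"] == pytest.approx(direct, rel=1e-9)
            assert rows[variant]["co2_fixation"] > 0

    def test_substrate_equivalence_products(self):
        assert substrate_equivalence(0.76, 4) == pytest.approx(3.04)
        assert substrate_equivalence(0.0, 4) == 0.0
        assert substrate_equivalence(1.5, 1) == pytest.approx(1.5)
        with pytest.raises(ValueError):
            substrate_equivalence(-1, 4)

    def test_fixed_co2_demand_decreases_with_substrate_energy_content(self, sulfur_core):
        """Per molecule, tetrathionate (14 e-) needs fewer moles than S (6 e-)."""
        co2 = 0.2
        demand_s = fixed_co2_substrate_demand(sulfur_core, "EX_s_e", co2)
        demand_tts = fixed_co2_substrate_demand(sulfur_core, "EX_s4o6_e", co2)
        assert 0 < demand_tts < demand_s

    def test_fixed_co2_zero_rate_zero_demand(self, sulfur_core):
        assert fixed_co2_substrate_demand(sulfur_core, "EX_s_e", 0.0) == pytest.approx(
            0.0, abs=1e-8
        )


class TestInsertion:
    def test_sor_reaction_is_balanced_and_growth_neutral(self, sulfur_core):
        model = sulfur_core.copy()
        sor = sor_reaction(model)
        assert check_balance(sor, model.metabolites) == {}
        before, after = insertion_test(model, sor, 1.5)
        assert after == pytest.approx(before, rel=1e-9)

    def test_duplicate_reaction_changes_nothing(self, sulfur_core):
        dup = sulfur_core.reactions["SDO"].copy()
        dup.id = "SDO_copy"
        before, after = insertion_test(sulfur_core, dup, 1.5)
        assert after == pytest.approx(before, rel=1e-9)

    def test_gratuitous_atp_source_raises_growth(self, sulfur_core):
        cheat = Reaction(
            "FREEATP", {"adp_c": -1, "pi_c": -1, "h_c": -1, "atp_c": 1, "h2o_c": 1},
            lower_bound=0, upper_bound=1000, subsystem=SULFUR_SUBSYSTEM,
        )
        before, after = insertion_test(sulfur_core, cheat, 1.5)
        assert after > before + 1e-3
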