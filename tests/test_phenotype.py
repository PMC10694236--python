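"""Phenotype calling, growth simulation, concordance and model extension."""

import numpy as np
import pytest

from sulfurgem.curation import UniversalReactionDB
from sulfurgem.fba import Medium
from sulfurgem.phenotype import (
    ConfusionTable,
    PhenotypeEntry,
    PhenotypePanel,
    call_phenotypes,
    concordance,
    extend_for_phenotypes,
    simulate_substrate_growth,
    tabulate,
)
from sulfurgem.synth import SyntheticSpec, generate_phenotype_panel, generate_toy_model, seed_gaps


def panel_of(ous):
    return PhenotypePanel([PhenotypeEntry(f"s{i}", ou=ou) for i, ou in enumerate(ous)])


class TestCalling:
    def test_threshold_is_a_strict_inequality(self):
        called = call_phenotypes(panel_of([115, 114, 0]))
        assert [e.call for e in called] == ["positive", "negative", "negative"]

    def test_zero_threshold_makes_everything_positive(self):
        called = call_phenotypes(panel_of([1, 50, 300]), threshold=0)
        assert all(e.call == "positive" for e in called)

    def test_boundary_wells_stay_flagged_and_score_negative(self):
        panel = PhenotypePanel([PhenotypeEntry("w", ou=110, call="boundary")])
        called = call_phenotypes(panel)
        assert called.entries[0].call == "boundary"
        assert not called.entries[0].experimental_positive


class TestConfusionTable:
    def test_headline_arithmetic(self):
        table = ConfusionTable(tp=11, tn=52, fp=3, fn=5)
        assert table.n == 71
        assert table.agreement == pytest.approx(100 * 63 / 71)
        assert round(table.agreement, 1) == 88.7

    def test_agreement_bounds_and_reorder_invariance(self):
        entries = [
            PhenotypeEntry(f"s{i}", ou=200 if i % 3 else 50,
                           call="positive" if i % 3 else "negative",
                           model_call="positive" if i % 2 else "negative")
            for i in range(12)
        ]
        table = tabulate(PhenotypePanel(entries))
        assert 0 <= table.agreement <= 100
        reordered = tabulate(PhenotypePanel(list(reversed(entries))))
        assert reordered == table


class TestSimulation:
    def test_unmapped_substrate_negative_with_reason(self, toy_model, toy_base_medium):
        call, reason = simulate_substrate_growth(toy_model, "unmapped", toy_base_medium)
        assert (call, reason) == ("negative", "no exchange")

    def test_substrate_without_exchange_negative(self, toy_model, toy_base_medium):
        call, reason = simulate_substrate_growth(toy_model, "atp_c", toy_base_medium)
        assert (call, reason) == ("negative", "no exchange")

    def test_growth_substrate_positive(self, toy_model, toy_base_medium):
        call, reason = simulate_substrate_growth(toy_model, "sub_e", toy_base_medium)
        assert call == "positive"

    def test_broken_pathway_negative_with_reason(self, toy_model, toy_base_medium):
        gapped, _ = seed_gaps(toy_model, 1, seed=5)
        call, reason = simulate_substrate_growth(gapped, "sub_e", toy_base_medium)
        assert (call, reason) == ("negative", "no utilization route")


class TestConcordance:
    def test_noiseless_panel_agrees_perfectly(self, toy_model, toy_base_medium):
        panel, _ = generate_phenotype_panel(toy_model, 12, 0.0, seed=3)
        table, _ = concordance(toy_model, call_phenotypes(panel), toy_base_medium)
        assert table.agreement == 100.0
        assert table.fp == table.fn == 0

    def test_full_noise_inverts_every_call(self, toy_model, toy_base_medium):
        panel, _ = generate_phenotype_panel(toy_model, 12, 1.0, seed=3)
        table, _ = concordance(toy_model, call_phenotypes(panel), toy_base_medium)
        assert table.agreement == 0.0

    def test_determinism(self, toy_model, toy_base_medium):
        panel, _ = generate_phenotype_panel(toy_model, 10, 0.3, seed=8)
        t1, _ = concordance(toy_model, call_phenotypes(panel), toy_base_medium)
        t2, _ = concordance(toy_model, call_phenotypes(panel), toy_base_medium)
        assert t1 == t2

    def test_label_noise_gives_binomial_agreement(self):
        """With labels flipped at rate 0.2 and truth-faithful predictions, the
        mean agreement over 100 seeds is within 3 sigma of 80%."""
        rho, n_sub, n_seeds = 0.2, 10, 100
        agreements = []
        for seed in range(n_seeds):
            model = generate_toy_model(SyntheticSpec(10, 14, seed=1))
            panel, _ = generate_phenotype_panel(model, n_sub, rho, seed=seed)
            table, _ = concordance(model, call_phenotypes(panel), Medium(closed={"EX_sub_e"}))
            agreements.append(table.agreement)
        mean = float(np.mean(agreements))
        sigma = 100 * np.sqrt(rho * (1 - rho) / (n_sub * n_seeds))
        assert abs(mean - 80.0) <= 3 * sigma


class TestExtension:
    def test_no_false_negatives_leaves_model_unchanged(self, toy_model, toy_base_medium):
        panel, _ = generate_phenotype_panel(toy_model, 8, 0.0, seed=2)
        db = UniversalReactionDB({})
        extended, report = extend_for_phenotypes(toy_model, call_phenotypes(panel), db,
                                                 toy_base_medium)
        assert set(extended.reactions) == set(toy_model.reactions)
        assert report.added_reactions == []

    def test_seeded_false_negatives_all_recovered(self, toy_base_medium):
        """Gap-created false negatives flip back to true positives and the
        extension never decreases TP nor increases FN."""
        model = generate_toy_model(SyntheticSpec(10, 14, seed=1))
        panel, _ = generate_phenotype_panel(model, 10, 0.0, seed=4)
        gapped, removed = seed_gaps(model, 1, seed=4, protect={"SUBt", "HDRAIN"})
        before, _ = concordance(gapped, call_phenotypes(panel), toy_base_medium)
        assert before.fn == 5  # every growth-supporting well turned false negative
        db = UniversalReactionDB({r: model.reactions[r].copy() for r in removed})
        extended, _ = extend_for_phenotypes(gapped, call_phenotypes(panel), db,
                                            toy_base_medium)
        after, _ = concordance(extended, call_phenotypes(panel), toy_base_medium)
        assert after.tp >= before.tp
        assert after.fn <= before.fn
        assert after.agreement == 100.0


def test_bundled_panel_reproduces_published_marginals():
    from sulfurgem.sulfur import _data_path

    panel = PhenotypePanel.from_tsv(_data_path("biolog_gen3_panel.tsv"))
    assert len(panel) == 71
    table = tabulate(panel)
    assert (table.tp, table.tn, table.fp, table.fn) == (11, 52, 3, 5)
    assert round(table.agreement, 1) == 88.7
    # calls are consistent with the strict OU > 114 rule
    recalled = call_phenotypes(panel)
    assert [e.call for e in recalled] == [e.call for e in panel]
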