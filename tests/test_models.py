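"""Expectation models: nucleotide formulas, positional strategies, codon/AA roll-up."""

import itertools
import math

import numpy as np
import pytest

from codoncomp.composition import GlobalContent, PositionalContent
from codoncomp.genetic_code import BASES, STOP_CODONS, sense_codons, translate
from codoncomp.io import CodonCountTable
from codoncomp.models import (
    EmpiricalRelation,
    EmpiricalRelationSet,
    deviation_report,
    expected_amino_acid_distribution,
    expected_codon_distribution,
    expected_nucleotides,
    expected_positional_nucleotides,
    fit_empirical_relations,
    model1_positional_content,
    model2_positional_content,
    observe,
    predict,
)
from codoncomp.simulate import (
    SimulationSpec,
    example_relations,
    expected_count_table,
    simulate_codon_table,
    simulate_collection,
)

from conftest import random_positional_freqs


def brute_force_codon_distribution(pos_freqs):
    """Oracle: enumerate all 64 products and subtract the stop products."""
    products = {
        "".join(c): pos_freqs[0][c[0]] * pos_freqs[1][c[1]] * pos_freqs[2][c[2]]
        for c in itertools.product(BASES, repeat=3)
    }
    sense_sum = sum(v for c, v in products.items() if c not in STOP_CODONS)
    return {c: v / sense_sum for c, v in products.items() if c not in STOP_CODONS}


class TestExpectedNucleotides:
    def test_gc_only_purine_balanced_sequence(self):
        freqs = expected_nucleotides(GlobalContent(S=1.0, R=0.5))
        assert freqs == {"A": 0.0, "T": 0.0, "G": 0.5, "C": 0.5}

    def test_uniform_contents(self):
        freqs = expected_nucleotides(GlobalContent(S=0.5, R=0.5))
        assert all(v == 0.25 for v in freqs.values())

    def test_purine_balance_implies_chargaff_parity(self, rng):
        # R = 0.5 forces A = T = (1-S)/2 and G = C = S/2 for any S
        for s in rng.random(200):
            freqs = expected_nucleotides(GlobalContent(S=float(s), R=0.5))
            assert freqs["A"] == pytest.approx((1 - s) / 2, abs=1e-12)
            assert freqs["T"] == pytest.approx((1 - s) / 2, abs=1e-12)
            assert freqs["G"] == pytest.approx(s / 2, abs=1e-12)
            assert freqs["C"] == pytest.approx(s / 2, abs=1e-12)

    def test_conservation_and_content_reconstruction(self, rng):
        for s, r in rng.random((500, 2)):
            freqs = expected_nucleotides(GlobalContent(S=float(s), R=float(r)))
            assert sum(freqs.values()) == pytest.approx(1.0, abs=1e-12)
            assert freqs["G"] + freqs["C"] == pytest.approx(s, abs=1e-12)
            assert freqs["A"] + freqs["G"] == pytest.approx(r, abs=1e-12)

    def test_expected_g_nondecreasing_in_s_at_fixed_r(self):
        values = [expected_nucleotides(GlobalContent(S=s, R=0.4))["G"] for s in np.linspace(0, 1, 21)]
        assert all(b >= a for a, b in zip(values, values[1:]))

    def test_complement_parametrisations_are_equivalent(self, rng):
        # The same four frequencies expressed through AT content (S^c) and/or
        # pyrimidine content (R^c): every variant reduces to the same values.
        for s, r in rng.random((50, 2)):
            sc, rc = 1 - s, 1 - r
            base = expected_nucleotides(GlobalContent(S=float(s), R=float(r)))
            assert base["A"] == pytest.approx(sc * r, abs=1e-12)          # {S^c, R}
            assert base["T"] == pytest.approx(sc * rc, abs=1e-12)         # {S^c, R^c}
            assert base["C"] == pytest.approx((1 - sc) * rc, abs=1e-12)   # {S, R^c}


class TestExpectedPositionalNucleotides:
    def test_gc_only_contents_at_every_position(self):
        freqs = expected_positional_nucleotides(
            PositionalContent(S=(1, 1, 1), R=(0.5, 0.5, 0.5))
        )
        for scope in freqs:
            assert scope == {"A": 0.0, "T": 0.0, "G": 0.5, "C": 0.5}

    def test_pure_adenine_contents(self):
        freqs = expected_positional_nucleotides(PositionalContent(S=(0, 0, 0), R=(1, 1, 1)))
        assert all(scope["A"] == 1.0 for scope in freqs)

    def test_each_position_sums_to_one(self, rng):
        pc = PositionalContent(S=tuple(rng.random(3)), R=tuple(rng.random(3)))
        for scope in expected_positional_nucleotides(pc):
            assert sum(scope.values()) == pytest.approx(1.0, abs=1e-12)


class TestPositionalStrategies:
    def test_model2_delegates_to_observed_content(self, cgcgcg_table):
        pc = model2_positional_content(cgcgcg_table)
        assert pc.S == (1.0, 1.0, 1.0)
        assert pc.R == (0.5, 0.5, 0.5)

    def test_model1_identity_relations_reduce_to_global(self):
        content = GlobalContent(S=0.37, R=0.53)
        pc = model1_positional_content(content, EmpiricalRelationSet.identity())
        assert pc.S == (0.37, 0.37, 0.37)
        assert pc.R == (0.53, 0.53, 0.53)

    def test_model1_zero_slope_returns_intercepts(self):
        rel = {
            (p, i): EmpiricalRelation(predictor=p, position=i, slope=0.0, intercept=0.3)
            for p in "SR"
            for i in (1, 2, 3)
        }
        pc = model1_positional_content(
            GlobalContent(S=0.9, R=0.1), EmpiricalRelationSet(relations=rel)
        )
        assert pc.S == (0.3, 0.3, 0.3) and pc.R == (0.3, 0.3, 0.3)

    def test_model1_out_of_range_predictions_are_clamped(self):
        rel = {
            (p, i): EmpiricalRelation(predictor=p, position=i, slope=3.0, intercept=-1.0)
            for p in "SR"
            for i in (1, 2, 3)
        }
        pc = model1_positional_content(
            GlobalContent(S=0.9, R=0.1), EmpiricalRelationSet(relations=rel)
        )
        assert pc.S == (1.0, 1.0, 1.0)  # 3*0.9 - 1 = 1.7 -> 1
        assert pc.R == (0.0, 0.0, 0.0)  # 3*0.1 - 1 = -0.7 -> 0

    def test_incomplete_relation_set_rejected(self):
        rel = {
            ("S", i): EmpiricalRelation(predictor="S", position=i, slope=1.0, intercept=0.0)
            for i in (1, 2, 3)
        }
        with pytest.raises(ValueError, match="missing"):
            EmpiricalRelationSet(relations=rel)


class TestFitEmpiricalRelations:
    def test_noise_free_collection_recovers_generating_lines(self):
        generating = example_relations()
        tables = simulate_collection(
            SimulationSpec(n_species=10, seed=3, relations=generating, n_codons=1000),
            s_range=(0.2, 0.8),
        )
        fitted = fit_empirical_relations(tables)
        for key, rel in generating.relations.items():
            assert fitted.relations[key].slope == pytest.approx(rel.slope, abs=1e-9)
            assert fitted.relations[key].intercept == pytest.approx(rel.intercept, abs=1e-9)
            assert fitted.relations[key].r_squared == pytest.approx(1.0, abs=1e-9)

    def test_two_point_exact_interpolation_when_guard_relaxed(self):
        generating = example_relations()
        tables = simulate_collection(
            SimulationSpec(n_species=2, seed=3, relations=generating, n_codons=1000),
            s_range=(0.3, 0.7),
        )
        fitted = fit_empirical_relations(tables, min_tables=2)
        for key, rel in generating.relations.items():
            assert fitted.relations[key].slope == pytest.approx(rel.slope, abs=1e-9)

    def test_too_few_tables_rejected(self):
        tables = simulate_collection(SimulationSpec(n_species=2, seed=0, n_codons=100))
        with pytest.raises(ValueError, match="at least 3"):
            fit_empirical_relations(tables)

    def test_zero_predictor_variance_rejected(self):
        t = expected_count_table(
            PositionalContent(S=(0.5, 0.5, 0.5), R=(0.5, 0.5, 0.5)), 100, label="same"
        )
        with pytest.raises(ValueError, match="identical"):
            fit_empirical_relations([t, t, t])

    def test_relations_file_round_trip_is_bit_exact(self, tmp_path):
        generating = example_relations()
        tables = simulate_collection(
            SimulationSpec(n_species=10, seed=3, relations=generating, n_codons=1000)
        )
        fitted = fit_empirical_relations(tables, label="demo")
        path = tmp_path / "relations.tsv"
        fitted.to_file(path)
        back = EmpiricalRelationSet.from_file(path)
        assert back.provenance == "demo"
        assert back.n_species == 10
        for key, rel in fitted.relations.items():
            assert back.relations[key] == rel


class TestExpectedCodonDistribution:
    def test_uniform_positional_frequencies(self):
        uniform = [{b: 0.25 for b in BASES}] * 3
        dist = expected_codon_distribution(uniform)
        assert all(v == pytest.approx(1 / 61, abs=1e-15) for v in dist.values())

    def test_gc_only_support(self):
        freqs = expected_positional_nucleotides(
            PositionalContent(S=(1, 1, 1), R=(0.5, 0.5, 0.5))
        )
        dist = expected_codon_distribution(freqs)
        gc_codons = {c for c in dist if set(c) <= {"G", "C"}}
        assert len(gc_codons) == 8
        for c, v in dist.items():
            assert v == pytest.approx(0.125 if c in gc_codons else 0.0, abs=1e-15)

    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(25):
            pos = random_positional_freqs(rng)
            dist = expected_codon_distribution(pos)
            oracle = brute_force_codon_distribution(pos)
            for c in oracle:
                assert dist[c] == pytest.approx(oracle[c], abs=1e-12)
            assert sum(dist.values()) == pytest.approx(1.0, abs=1e-12)

    def test_all_mass_on_stops_is_an_error(self):
        pos = [
            {"A": 0, "C": 0, "G": 0, "T": 1},
            {"A": 1, "C": 0, "G": 0, "T": 0},
            {"A": 1, "C": 0, "G": 0, "T": 0},
        ]
        with pytest.raises(ValueError, match="stop"):
            expected_codon_distribution(pos)


class TestExpectedAminoAcids:
    def test_uniform_distribution_reflects_degeneracy(self):
        aa = expected_amino_acid_distribution({c: 1 / 61 for c in sense_codons()})
        for symbol in "LSR":
            assert aa[symbol] == pytest.approx(6 / 61, abs=1e-12)
        for symbol in "MW":
            assert aa[symbol] == pytest.approx(1 / 61, abs=1e-12)
        assert sum(aa.values()) == pytest.approx(1.0, abs=1e-12)

    def test_alanine_under_gc_only_contents(self):
        freqs = expected_positional_nucleotides(
            PositionalContent(S=(1, 1, 1), R=(0.5, 0.5, 0.5))
        )
        aa = expected_amino_acid_distribution(expected_codon_distribution(freqs))
        # GCN intersected with {G,C}^3 leaves GCG and GCC, 0.125 each
        assert aa["A"] == pytest.approx(0.25, abs=1e-12)


class TestPredict:
    def test_model2_reproduces_worked_global_guanine(self, cgcgcg_table):
        bundle = predict(cgcgcg_table, model=2)
        assert bundle.nucleotide.total["G"] == pytest.approx(0.5, abs=1e-15)
        assert bundle.model_tag == 2

    def test_model1_requires_relations_and_model2_forbids_them(self, cgcgcg_table):
        with pytest.raises(ValueError):
            predict(cgcgcg_table, model=1)
        with pytest.raises(ValueError):
            predict(cgcgcg_table, model=2, relations=EmpiricalRelationSet.identity())
        with pytest.raises(ValueError):
            predict(cgcgcg_table, model=3)

    def test_model1_identity_equals_model2_when_positions_match_global(self):
        # every base equally frequent at every position: positional == global
        t = CodonCountTable(label="flat", counts={"AAA": 1, "CCC": 1, "GGG": 1, "TTT": 1})
        m1 = predict(t, model=1, relations=EmpiricalRelationSet.identity())
        m2 = predict(t, model=2)
        assert m1.codon == pytest.approx(m2.codon, abs=1e-12)
        assert m1.amino_acid == pytest.approx(m2.amino_acid, abs=1e-12)

    def test_positional_nucleotides_reconstruct_driving_contents(self, rng):
        spec = SimulationSpec(n_codons=5000, seed=17)
        table = simulate_codon_table(spec)
        bundle = predict(table, model=2)
        for i in range(3):
            scope = bundle.nucleotide.by_position[i]
            assert scope["G"] + scope["C"] == pytest.approx(bundle.positional_content.S[i], abs=1e-12)
            assert scope["A"] + scope["G"] == pytest.approx(bundle.positional_content.R[i], abs=1e-12)


class TestDeviationReport:
    def test_zero_deviation_when_observed_equals_expected(self):
        # On the {G,C}^3 support the sense-restricted product has no stop mass,
        # so an exact expected-count table realises the model distribution itself.
        t = expected_count_table(
            PositionalContent(S=(1, 1, 1), R=(0.5, 0.5, 0.5)), 800, label="gc"
        )
        report = deviation_report(observe(t), predict(t, model=2))
        assert report["difference"].abs().max() < 1e-12

    def test_differences_sum_to_zero_per_category(self):
        table = simulate_codon_table(SimulationSpec(n_codons=2000, seed=5))
        report = deviation_report(observe(table), predict(table, model=2))
        sums = report.groupby("category")["difference"].sum()
        assert sums.abs().max() < 1e-12

    def test_mean_absolute_deviation_shrinks_with_sample_size(self):
        reports = {}
        for n in (10_000, 1_000_000):
            table = simulate_codon_table(SimulationSpec(n_codons=n, seed=9))
            rep = deviation_report(observe(table), predict(table, model=2))
            reports[n] = rep[rep.category == "codon"]["difference"].abs().mean()
        assert reports[1_000_000] < reports[10_000]

    def test_label_mismatch_rejected(self, cgcgcg_table):
        other = CodonCountTable(label="other", counts={"ATG": 1})
        with pytest.raises(ValueError, match="label"):
            deviation_report(observe(cgcgcg_table), predict(other, model=2))
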