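from fractions import Fraction

import numpy as np
import pytest

from herbminer.apriori import derive_rules, frequent_itemsets, rule_metrics
from herbminer.corpus import to_binary_matrix
from herbminer.errors import EmptyInputError, VocabularyError

from conftest import make_corpus
from oracles import brute_force_itemsets, brute_force_rules, random_corpus


class TestFrequentItemsets:
    def test_hand_enumerated_example(self, tiny_corpus):
        m = to_binary_matrix(tiny_corpus)
        found = {fi.items: (fi.count, fi.support) for fi in frequent_itemsets(m, 0.6)}
        expected = {
            frozenset("A"): (2, 2 / 3),
            frozenset("B"): (3, 1.0),
            frozenset("C"): (2, 2 / 3),
            frozenset("AB"): (2, 2 / 3),
            frozenset("BC"): (2, 2 / 3),
        }
        assert found == expected

    def test_all_common_case(self):
        corpus = make_corpus({"P1": {"A", "B"}, "P2": {"A", "B"}})
        m = to_binary_matrix(corpus)
        found = {fi.items for fi in frequent_itemsets(m, 1.0)}
        assert found == {frozenset("A"), frozenset("B"), frozenset("AB")}

    def test_threshold_boundary_is_inclusive_but_strict_above_excludes(self):
        corpus = make_corpus({"P1": {"A", "U"}, "P2": {"A"}, "P3": {"A"}, "P4": {"A"}})
        m = to_binary_matrix(corpus)
        at = {fi.items for fi in frequent_itemsets(m, 0.25)}
        assert frozenset("U") in at  # support exactly 1/4 kept
        above = {fi.items for fi in frequent_itemsets(m, 0.2500001)}
        assert frozenset("U") not in above

    def test_output_order_by_size_then_lexicographic(self, tiny_corpus):
        m = to_binary_matrix(tiny_corpus)
        keys = [tuple(sorted(fi.items)) for fi in frequent_itemsets(m, 0.5)]
        assert keys == sorted(keys, key=lambda t: (len(t), t))

    def test_empty_matrix_rejected(self, tiny_corpus):
        m = to_binary_matrix(tiny_corpus)
        with pytest.raises(EmptyInputError):
            frequent_itemsets(m.iloc[0:0], 0.5)

    def test_max_size_cap(self, tiny_corpus):
        m = to_binary_matrix(tiny_corpus)
        assert all(len(fi.items) <= 1 for fi in frequent_itemsets(m, 0.5, max_size=1))

    @pytest.mark.parametrize("seed", range(10))
    def test_oracle_equivalence_on_random_corpora(self, seed):
        rng = np.random.default_rng(seed)
        corpus = random_corpus(rng, max_herbs=8, max_prescriptions=12)
        min_support = float(rng.choice([0.1, 0.25, 0.5]))
        m = to_binary_matrix(corpus)
        found = {fi.items: fi.count for fi in frequent_itemsets(m, min_support)}
        assert found == brute_force_itemsets(corpus, min_support)

    def test_downward_closure(self, reference_synthetic):
        corpus, _ = reference_synthetic
        m = to_binary_matrix(corpus.subset("anti_recurrence"))
        found = {fi.items for fi in frequent_itemsets(m, 0.15)}
        for items in found:
            for x in items:
                assert items - {x} in found or len(items) == 1

    def test_anti_monotone_in_min_support(self, tiny_corpus):
        m = to_binary_matrix(tiny_corpus)
        low = {fi.items for fi in frequent_itemsets(m, 0.3)}
        high = {fi.items for fi in frequent_itemsets(m, 0.7)}
        assert high <= low


class TestDeriveRules:
    def test_hand_enumerated_rules(self, tiny_corpus):
        m = to_binary_matrix(tiny_corpus)
        rules = derive_rules(frequent_itemsets(m, 0.6), m, 0.8)
        found = {(r.lhs, r.rhs): (r.confidence, r.lift) for r in rules}
        assert found == {
            (frozenset("A"), frozenset("B")): (1.0, 1.0),
            (frozenset("C"), frozenset("B")): (1.0, 1.0),
        }

    def test_vacuous_confidence_threshold_yields_nothing(self):
        # no deterministic implication anywhere
        corpus = make_corpus({"P1": {"A", "B"}, "P2": {"A"}, "P3": {"B"}})
        m = to_binary_matrix(corpus)
        assert derive_rules(frequent_itemsets(m, 0.3), m, 1.0) == []

    def test_sorted_by_lift_then_confidence(self, reference_synthetic):
        corpus, _ = reference_synthetic
        m = to_binary_matrix(corpus.subset("anti_recurrence"))
        rules = derive_rules(frequent_itemsets(m, 0.08), m, 0.8)
        keys = [(-r.lift, -r.confidence, -r.support) for r in rules]
        assert keys == sorted(keys)

    def test_anti_monotone_in_min_confidence(self, tiny_corpus):
        m = to_binary_matrix(tiny_corpus)
        its = frequent_itemsets(m, 0.3)
        low = {(r.lhs, r.rhs) for r in derive_rules(its, m, 0.5)}
        high = {(r.lhs, r.rhs) for r in derive_rules(its, m, 0.9)}
        assert high <= low

    def test_multi_consequent_rules(self, tiny_corpus):
        m = to_binary_matrix(tiny_corpus)
        rules = derive_rules(frequent_itemsets(m, 0.3), m, 0.5, rhs_size=2)
        assert rules and all(len(r.rhs) == 2 for r in rules)

    @pytest.mark.parametrize("seed", range(10))
    def test_rule_oracle_equivalence_on_random_corpora(self, seed):
        rng = np.random.default_rng(100 + seed)
        corpus = random_corpus(rng, max_herbs=8, max_prescriptions=12)
        m = to_binary_matrix(corpus)
        rules = derive_rules(frequent_itemsets(m, 0.2), m, 0.6)
        found = {(r.lhs, r.rhs): (Fraction(r.count, len(corpus)),) for r in rules}
        oracle = brute_force_rules(corpus, 0.2, 0.6)
        assert set(found) == set(oracle)
        for key, (supp, conf, lift) in oracle.items():
            r = next(x for x in rules if (x.lhs, x.rhs) == key)
            assert r.support == pytest.approx(float(supp), abs=1e-12)
            assert r.confidence == pytest.approx(float(conf), abs=1e-12)
            assert r.lift == pytest.approx(float(lift), abs=1e-12)


class TestRuleMetrics:
    def test_hand_enumeration(self, tiny_corpus):
        m = to_binary_matrix(tiny_corpus)
        supp, conf, lift = rule_metrics(m, {"A"}, {"C"})
        assert (supp, conf, lift) == (pytest.approx(1 / 3), pytest.approx(0.5),
                                      pytest.approx(0.75))

    def test_ubiquitous_consequent_forces_unit_confidence_and_lift(self, tiny_corpus):
        m = to_binary_matrix(tiny_corpus)  # B is in every prescription
        _, conf, lift = rule_metrics(m, {"A"}, {"B"})
        assert conf == 1.0 and lift == 1.0

    def test_lift_is_one_under_empirical_independence(self):
        # P(A)=1/2, P(B)=1/2, P(A,B)=1/4 over 4 prescriptions
        corpus = make_corpus({"P1": {"A", "B"}, "P2": {"A", "x"},
                              "P3": {"B", "y"}, "P4": {"x", "y"}})
        m = to_binary_matrix(corpus)
        _, conf, lift = rule_metrics(m, {"A"}, {"B"})
        assert lift == pytest.approx(1.0)
        assert conf == pytest.approx(0.5)

    def test_unsupported_antecedent_reports_no_number(self):
        corpus = make_corpus({"P1": {"A", "B"}, "P2": {"C", "B"}})
        m = to_binary_matrix(corpus)
        supp, conf, lift = rule_metrics(m, {"A", "C"}, {"B"})
        assert supp == 0.0 and conf is None and lift is None

    def test_argument_errors(self, tiny_corpus):
        m = to_binary_matrix(tiny_corpus)
        with pytest.raises(VocabularyError):
            rule_metrics(m, {"A"}, {"Z"})
        with pytest.raises(ValueError):
            rule_metrics(m, {"A", "B"}, {"B"})
        with pytest.raises(ValueError):
            rule_metrics(m, set(), {"B"})
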