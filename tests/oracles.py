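"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately share no code with the implementation: itemsets are
enumerated exhaustively over the power set and all measures come from raw
prescription scans with exact rational arithmetic.
"""

from fractions import Fraction
from itertools import chain, combinations

from herbminer.corpus import PrescriptionCorpus


def powerset_nonempty(items):
    items = sorted(items)
    return chain.from_iterable(combinations(items, r) for r in range(1, len(items) + 1))


def count_containing(corpus: PrescriptionCorpus, items) -> int:
    items = set(items)
    return sum(1 for p in corpus if items <= p.herbs)


def brute_force_itemsets(corpus: PrescriptionCorpus, min_support: float):
    """{itemset: count} for every itemset with support >= min_support."""
    n = len(corpus)
    out = {}
    for cand in powerset_nonempty(corpus.vocabulary):
        c = count_containing(corpus, cand)
        if Fraction(c, n) >= Fraction(str(min_support)):
            out[frozenset(cand)] = c
    return out


def brute_force_rules(corpus: PrescriptionCorpus, min_support: float,
                      min_confidence: float, rhs_size: int = 1):
    """{(lhs, rhs): (support, confidence, lift)} over all qualifying partitions."""
    n = len(corpus)
    frequent = brute_force_itemsets(corpus, min_support)
    rules = {}
    for items, c in frequent.items():
        if len(items) < 2 or len(items) <= rhs_size:
            continue
        for rhs in combinations(sorted(items), rhs_size):
            rhs = frozenset(rhs)
            lhs = items - rhs
            conf = Fraction(c, count_containing(corpus, lhs))
            if conf >= Fraction(str(min_confidence)):
                rhs_supp = Fraction(count_containing(corpus, rhs), n)
                rules[(lhs, rhs)] = (Fraction(c, n), conf, conf / rhs_supp)
    return rules


def random_corpus(rng, max_herbs: int = 12, max_prescriptions: int = 20) -> PrescriptionCorpus:
    """A random small corpus for oracle-equivalence checks."""
    from herbminer.corpus import Prescription
    n_herbs = rng.integers(2, max_herbs + 1)
    n_rx = rng.integers(2, max_prescriptions + 1)
    herbs = [f"h{i}" for i in range(n_herbs)]
    prescriptions = []
    for i in range(n_rx):
        size = rng.integers(1, n_herbs + 1)
        chosen = rng.choice(herbs, size=size, replace=False)
        prescriptions.append(Prescription(f"P{i}", "anti_recurrence", frozenset(chosen)))
    return PrescriptionCorpus(prescriptions)
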