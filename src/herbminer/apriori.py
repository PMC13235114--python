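"""Level-wise Apriori frequent-itemset mining and association rules.

The miner operates on the presence/absence matrix produced by
:func:`herbminer.corpus.to_binary_matrix`.  Support is the fraction of
prescriptions containing an itemset; confidence is the conditional
frequency of the consequent given the antecedent; lift is confidence over
the consequent's marginal support (1 = empirical independence).

Support and confidence thresholds are inclusive and compared as exact
rationals (``Fraction(count, N) >= Fraction(str(threshold))``, i.e. the
decimal the caller wrote) so floating-point round-off can never flip a
boundary case.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations

import numpy as np
import pandas as pd

from .errors import EmptyInputError, VocabularyError


@dataclass(frozen=True)
class FrequentItemset:
    items: frozenset[str]
    count: int
    support: float


@dataclass(frozen=True)
class AssociationRule:
    lhs: frozenset[str]
    rhs: frozenset[str]
    support: float      # support of lhs ∪ rhs
    confidence: float
    lift: float
    count: int          # co-occurrence count of lhs ∪ rhs

    def __str__(self) -> str:
        return (f"{{{', '.join(sorted(self.lhs))}}} -> {{{', '.join(sorted(self.rhs))}}} "
                f"(supp={self.support:.4f}, conf={self.confidence:.4f}, lift={self.lift:.2f})")


def _sort_key(items: frozenset[str]) -> tuple:
    return (len(items), tuple(sorted(items)))


def frequent_itemsets(matrix: pd.DataFrame, min_support: float,
                      max_size: int | None = None) -> list[FrequentItemset]:
    """All itemsets with support >= ``min_support`` (inclusive).

    Level-wise candidate generation with downward-closure pruning: a
    candidate of size k is generated only from two frequent (k-1)-sets
    sharing a (k-2)-prefix and kept only if all of its (k-1)-subsets are
    frequent.  Output ordered by size, then lexicographically.

    ``max_size`` optionally caps the itemset size (safety valve for
    adversarial corpora; unbounded by default).
    """
    if matrix.shape[0] == 0 or matrix.shape[1] == 0:
        raise EmptyInputError("empty binary matrix")
    if not 0 < min_support <= 1:
        raise ValueError("min_support must lie in (0, 1]")
    n = matrix.shape[0]
    threshold = Fraction(str(min_support))
    cols = {h: matrix[h].to_numpy(dtype=bool) for h in matrix.columns}

    counts: dict[frozenset[str], int] = {}
    masks: dict[frozenset[str], np.ndarray] = {}
    # level 1
    level = []
    for h in matrix.columns:
        c = int(cols[h].sum())
        if Fraction(c, n) >= threshold:
            s = frozenset([h])
            counts[s] = c
            masks[s] = cols[h]
            level.append(s)
    level.sort(key=_sort_key)

    k = 2
    while level and (max_size is None or k <= max_size):
        frequent_prev = set(level)
        # join step: (k-1)-sets sharing all but their last sorted element
        prefixes: dict[tuple, list[str]] = {}
        for s in level:
            ordered = tuple(sorted(s))
            prefixes.setdefault(ordered[:-1], []).append(ordered[-1])
        candidates = []
        for prefix, lasts in prefixes.items():
            lasts.sort()
            for a, b in combinations(lasts, 2):
                cand = frozenset(prefix + (a, b))
                # prune: every (k-1)-subset must be frequent
                if all(cand - {x} in frequent_prev for x in cand):
                    candidates.append(cand)
        next_level = []
        for cand in candidates:
            ordered = sorted(cand)
            base = frozenset(ordered[:-1])
            mask = masks[base] & cols[ordered[-1]]
            c = int(mask.sum())
            if Fraction(c, n) >= threshold:
                counts[cand] = c
                masks[cand] = mask
                next_level.append(cand)
        next_level.sort(key=_sort_key)
        level = next_level
        k += 1

    return [FrequentItemset(s, counts[s], counts[s] / n)
            for s in sorted(counts, key=_sort_key)]


def derive_rules(itemsets: list[FrequentItemset], matrix: pd.DataFrame,
                 min_confidence: float, rhs_size: int = 1) -> list[AssociationRule]:
    """Association rules from frequent itemsets.

    For every frequent itemset of size >= 2, every partition into a
    non-empty antecedent and a consequent of exactly ``rhs_size`` herbs is
    evaluated; rules at or above ``min_confidence`` are returned sorted by
    lift descending, ties broken by confidence, then support, then
    lexicographic antecedent.  ``rhs_size=1`` (the default) yields the
    standard single-consequent rules.
    """
    if rhs_size < 1:
        raise ValueError("rhs_size must be >= 1")
    n = matrix.shape[0]
    conf_threshold = Fraction(str(min_confidence))
    counts = {fi.items: fi.count for fi in itemsets}
    rules = []
    for fi in itemsets:
        if len(fi.items) < 2 or len(fi.items) <= rhs_size:
            continue
        for rhs_tuple in combinations(sorted(fi.items), rhs_size):
            rhs = frozenset(rhs_tuple)
            lhs = fi.items - rhs
            # downward closure guarantees lhs and rhs are frequent
            lhs_count = counts[lhs]
            rhs_count = counts[rhs]
            confidence = fi.count / lhs_count
            if Fraction(fi.count, lhs_count) >= conf_threshold:
                lift = confidence / (rhs_count / n)
                rules.append(AssociationRule(lhs, rhs, fi.support, confidence, lift, fi.count))
    rules.sort(key=lambda r: (-r.lift, -r.confidence, -r.support,
                              tuple(sorted(r.lhs)), tuple(sorted(r.rhs))))
    return rules


def rule_metrics(matrix: pd.DataFrame, lhs: frozenset[str] | set[str],
                 rhs: frozenset[str] | set[str]) -> tuple[float, float | None, float | None]:
    """(support, confidence, lift) of an arbitrary rule, from raw counts.

    Returns ``(support, None, None)`` when the antecedent never occurs
    (confidence undefined) — an explicit no-support result, not a number.
    """
    lhs, rhs = frozenset(lhs), frozenset(rhs)
    if not lhs or not rhs:
        raise ValueError("lhs and rhs must be non-empty")
    if lhs & rhs:
        raise ValueError("lhs and rhs must be disjoint")
    unknown = (lhs | rhs) - set(matrix.columns)
    if unknown:
        raise VocabularyError(f"herbs not in vocabulary: {sorted(unknown)}")
    n = matrix.shape[0]
    arr = matrix.to_numpy(dtype=bool)
    idx = {h: i for i, h in enumerate(matrix.columns)}
    lhs_mask = arr[:, [idx[h] for h in lhs]].all(axis=1)
    rhs_mask = arr[:, [idx[h] for h in rhs]].all(axis=1)
    both = int((lhs_mask & rhs_mask).sum())
    support = both / n
    n_lhs = int(lhs_mask.sum())
    if n_lhs == 0:
        return support, None, None
    confidence = both / n_lhs
    rhs_support = int(rhs_mask.sum()) / n
    lift = confidence / rhs_support if rhs_support > 0 else None
    return support, confidence, lift


def rules_to_frame(rules: list[AssociationRule]) -> pd.DataFrame:
    """Tabular export: lhs/rhs '|'-joined plus the three measures and count."""
    return pd.DataFrame([{
        "lhs": "|".join(sorted(r.lhs)),
        "rhs": "|".join(sorted(r.rhs)),
        "support": r.support,
        "confidence": r.confidence,
        "lift": r.lift,
        "count": r.count,
    } for r in rules], columns=["lhs", "rhs", "support", "confidence", "lift", "count"])


def itemsets_to_frame(itemsets: list[FrequentItemset]) -> pd.DataFrame:
    return pd.DataFrame([{
        "items": "|".join(sorted(fi.items)),
        "size": len(fi.items),
        "count": fi.count,
        "support": fi.support,
    } for fi in itemsets], columns=["items", "size", "count", "support"])
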