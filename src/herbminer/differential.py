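"""Two-group validation: frequency banding and a random-forest classifier.

*Frequency variance* is interpreted as the signed difference of per-group
herb frequencies in percentage points; the band labels only make sense on
a bounded difference scale.  Band edges partition the positive axis as
(20, inf) = high, (10, 20] = moderate, (0, 10] = slight (strict ">" at 20,
matching the stated "> 20%" cut).

The forest contract is behavioral: bootstrap-resampled trees, ~sqrt(p)
feature subsampling per split, Gini splits, unlimited depth, OOB error,
and the two classical importance measures — mean decrease Gini (total
impurity decrease) and mean decrease accuracy (per-tree out-of-bag
permutation importance, averaged over trees).  scikit-learn provides the
forest and the Gini importances; the OOB permutation importance is
computed here per tree from the bootstrap membership, since no installed
estimator exposes it directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .corpus import PrescriptionCorpus, to_binary_matrix
from .errors import EmptyInputError, InsufficientDataError


@dataclass(frozen=True)
class DifferentialRecord:
    herb: str
    freq_anti: float
    freq_general: float
    diff_points: float   # signed, percentage points
    band: str            # high | moderate | slight
    direction: str       # anti_enriched | general_enriched | balanced


def band_for(diff_points: float) -> str:
    """Band from |diff| in points: >20 high, (10,20] moderate, else slight."""
    mag = abs(diff_points)
    if mag > 20:
        return "high"
    if mag > 10:
        return "moderate"
    return "slight"


def frequency_differential(corpus_anti: PrescriptionCorpus,
                           corpus_general: PrescriptionCorpus) -> list[DifferentialRecord]:
    """One record per herb of the union vocabulary, sorted by |diff| desc.

    A herb absent from a group has frequency 0 there.  ``diff_points`` is
    ``100 * (freq_anti - freq_general)``.
    """
    if len(corpus_anti) == 0 or len(corpus_general) == 0:
        raise EmptyInputError("both corpora must be non-empty")
    n_a, n_g = len(corpus_anti), len(corpus_general)
    counts_a: dict[str, int] = {}
    counts_g: dict[str, int] = {}
    for p in corpus_anti:
        for h in p.herbs:
            counts_a[h] = counts_a.get(h, 0) + 1
    for p in corpus_general:
        for h in p.herbs:
            counts_g[h] = counts_g.get(h, 0) + 1
    records = []
    for herb in sorted(set(counts_a) | set(counts_g)):
        fa = counts_a.get(herb, 0) / n_a
        fg = counts_g.get(herb, 0) / n_g
        diff = 100.0 * (fa - fg)
        if diff > 0:
            direction = "anti_enriched"
        elif diff < 0:
            direction = "general_enriched"
        else:
            direction = "balanced"
        records.append(DifferentialRecord(herb, fa, fg, diff, band_for(diff), direction))
    records.sort(key=lambda r: (-abs(r.diff_points), r.herb))
    return records


def differential_to_frame(records: list[DifferentialRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records],
                        columns=["herb", "freq_anti", "freq_general",
                                 "diff_points", "band", "direction"])


@dataclass
class ForestReport:
    oob_error: float
    importance: pd.DataFrame   # index herb; mean_decrease_accuracy, mean_decrease_gini
    ranking: list[str]         # herbs by mean_decrease_accuracy descending
    n_trees: int
    seed: int


def _stacked_matrix(corpus_anti: PrescriptionCorpus, corpus_general: PrescriptionCorpus
                    ) -> tuple[np.ndarray, np.ndarray, list[str]]:
    vocab = sorted(set(corpus_anti.vocabulary) | set(corpus_general.vocabulary))
    rows, labels = [], []
    for corpus, label in ((corpus_anti, 1), (corpus_general, 0)):
        m = to_binary_matrix(corpus).reindex(columns=vocab, fill_value=0)
        rows.append(m.to_numpy(dtype=np.float32))
        labels.append(np.full(len(corpus), label))
    return np.vstack(rows), np.concatenate(labels), vocab


def rf_differential(corpus_anti: PrescriptionCorpus, corpus_general: PrescriptionCorpus,
                    n_trees: int = 1000, seed: int = 123,
                    min_count: int = 0) -> ForestReport:
    """Random forest separating the two groups from herb presence features.

    ``min_count`` optionally drops herbs below a document-count floor in
    the stacked corpus (0 keeps the full union vocabulary).  The OOB error
    is the misclassification rate of each prescription under the trees
    whose bootstrap sample excluded it; mean decrease accuracy is the drop
    in per-tree OOB accuracy when the feature's column is permuted,
    averaged over trees (the classical permutation importance).
    """
    if len(corpus_anti) < 2 or len(corpus_general) < 2:
        raise InsufficientDataError("each group needs at least 2 prescriptions")
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    x, y, vocab = _stacked_matrix(corpus_anti, corpus_general)
    if min_count > 0:
        keep = x.sum(axis=0) >= min_count
        x, vocab = x[:, keep], [h for h, k in zip(vocab, keep) if k]
    n, p = x.shape

    rf = RandomForestClassifier(
        n_estimators=n_trees, criterion="gini", max_features="sqrt",
        max_depth=None, bootstrap=True, oob_score=True, random_state=seed,
        n_jobs=1,
    )
    rf.fit(x, y)
    oob_error = 1.0 - float(rf.oob_score_)

    # per-tree OOB permutation importance
    rng = np.random.default_rng(seed)
    mda = np.zeros(p)
    n_samples = x.shape[0]
    for tree, sample_idx in zip(rf.estimators_, rf.estimators_samples_):
        oob_mask = np.ones(n_samples, dtype=bool)
        oob_mask[sample_idx] = False
        if not oob_mask.any():
            continue
        x_oob, y_oob = x[oob_mask], y[oob_mask]
        base_acc = float(np.mean(tree.predict(x_oob, check_input=False) == y_oob))
        # only features the tree actually split on can change its output
        used = np.unique(tree.tree_.feature[tree.tree_.feature >= 0])
        for j in used:
            x_perm = x_oob.copy()
            x_perm[:, j] = rng.permutation(x_perm[:, j])
            perm_acc = float(np.mean(tree.predict(x_perm, check_input=False) == y_oob))
            mda[j] += base_acc - perm_acc
    mda /= n_trees

    importance = pd.DataFrame({
        "mean_decrease_accuracy": mda,
        "mean_decrease_gini": rf.feature_importances_,
    }, index=pd.Index(vocab, name="herb"))
    ranking = list(importance.sort_values("mean_decrease_accuracy", ascending=False,
                                          kind="stable").index)
    return ForestReport(oob_error, importance, ranking, n_trees, seed)
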