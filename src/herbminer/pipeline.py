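"""Consensus core-herb extraction and pipeline orchestration.

The two mining arms nominate herb sets independently — the union of the
herbs in the top-lift association rules, and the members of the
top-composite embedding clusters — and the *core herb spectrum* is their
intersection, annotated per herb with the evidence supporting it
(``apriori``, ``gcn``, ``frequency_high`` for a >20-point anti-enriched
frequency differential, ``rf_top`` for a top-rank permutation importance).

Orchestration follows the estimator/results idiom: :class:`CoreHerbModel`
is built from the two corpora plus a :class:`PipelineConfig`; ``fit()``
runs corpus → rules → graph/GCN/clusters → differential → consensus and
returns a :class:`CoreHerbResults` carrying every stage artifact, a
``summary()`` table and a deterministic JSON-able report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import apriori, differential as diff_mod, gcn as gcn_mod
from .apriori import AssociationRule, FrequentItemset
from .corpus import (HerbLexicon, PrescriptionCorpus, read_corpus,
                     standardize_herbs, to_binary_matrix, write_corpus)
from .differential import DifferentialRecord, ForestReport
from .errors import EmptyInputError, PipelineStageError
from .gcn import ClusterAssignment, ClusterScore, EmbeddingMatrix, GcnHyperparams
from .synthetic import SyntheticConfig, generate_two_group_corpus


def select_rule_herbs(rules: Sequence[AssociationRule], top_n: int = 1) -> frozenset[str]:
    """Union of lhs ∪ rhs over the ``top_n`` highest-lift rules."""
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    if not rules:
        import warnings
        warnings.warn("empty rule list: rule arm selects no herbs", stacklevel=2)
        return frozenset()
    out: set[str] = set()
    for r in rules[:top_n]:
        out |= r.lhs | r.rhs
    return frozenset(out)


def select_cluster_herbs(scores: Sequence[ClusterScore], n_clusters: int = 1) -> frozenset[str]:
    """Union of members of the ``n_clusters`` top-composite clusters."""
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    out: set[str] = set()
    for s in scores[:n_clusters]:
        out |= s.members
    return frozenset(out)


@dataclass
class ConsensusResult:
    rule_herbs: frozenset[str]
    cluster_herbs: frozenset[str]
    intersection: frozenset[str]
    union: frozenset[str]
    venn_counts: tuple[int, int, int]   # (only_rules, only_cluster, both)
    provenance: dict[str, frozenset[str]]  # herb -> evidence tags


def consensus_core(rule_herbs: frozenset[str], cluster_herbs: frozenset[str],
                   differential: Sequence[DifferentialRecord] | None = None,
                   forest: ForestReport | None = None,
                   rf_top_window: int = 14) -> ConsensusResult:
    """Intersect the two arms and attach per-herb evidence tags.

    ``frequency_high`` marks herbs in the high band and anti-enriched;
    ``rf_top`` marks herbs within the top ``rf_top_window`` of the
    mean-decrease-accuracy ranking.
    """
    rule_herbs, cluster_herbs = frozenset(rule_herbs), frozenset(cluster_herbs)
    inter = rule_herbs & cluster_herbs
    union = rule_herbs | cluster_herbs
    venn = (len(rule_herbs - cluster_herbs), len(cluster_herbs - rule_herbs), len(inter))

    high = {r.herb for r in differential or []
            if r.band == "high" and r.direction == "anti_enriched"}
    rf_top = set(forest.ranking[:rf_top_window]) if forest is not None else set()
    provenance = {}
    for herb in sorted(union):
        tags = set()
        if herb in rule_herbs:
            tags.add("apriori")
        if herb in cluster_herbs:
            tags.add("gcn")
        if herb in high:
            tags.add("frequency_high")
        if herb in rf_top:
            tags.add("rf_top")
        provenance[herb] = frozenset(tags)
    return ConsensusResult(rule_herbs, cluster_herbs, inter, union, venn, provenance)


@dataclass
class PipelineConfig:
    """Thresholds, hyperparameters and seeds for the full pipeline.

    Defaults mirror the canonical analysis: support 0.08, confidence 0.80,
    rules ranked by lift; GCN 32/16 dims, 200 epochs, Adam at 0.01;
    K-means with silhouette-selected K; forest of 1000 trees at seed 123.
    """

    min_support: float = 0.08
    min_confidence: float = 0.80
    rhs_size: int = 1
    gcn: GcnHyperparams = field(default_factory=GcnHyperparams)
    k: int | str = "auto"
    k_range: tuple[int, int] = (2, 10)
    n_trees: int = 1000
    rf_seed: int = 123
    rule_top_n: int = 1
    cluster_top_n: int = 1
    rf_top_window: int = 14
    seed: int = 0


@dataclass
class CoreHerbResults:
    """Fitted artifacts of the full prescription-mining pipeline."""

    config: PipelineConfig
    corpus_anti: PrescriptionCorpus
    corpus_general: PrescriptionCorpus
    itemsets: list[FrequentItemset]
    rules: list[AssociationRule]
    graph: "gcn_mod.nx.Graph"
    embeddings: EmbeddingMatrix
    assignment: ClusterAssignment
    cluster_scores: list[ClusterScore]
    differential: list[DifferentialRecord]
    forest: ForestReport
    consensus: ConsensusResult

    def core_herbs(self, top_herbs: int | None = None) -> list[str]:
        """The consensus herbs, optionally trimmed to ``top_herbs``.

        Trimming sorts by number of evidence tags (descending), ties by
        the frequency differential, then name.
        """
        diff = {r.herb: r.diff_points for r in self.differential}
        ordered = sorted(self.consensus.intersection,
                         key=lambda h: (-len(self.consensus.provenance[h]),
                                        -diff.get(h, 0.0), h))
        return ordered[:top_herbs] if top_herbs else ordered

    def to_report(self) -> dict:
        """Deterministic JSON-able report of every stage (no timestamps)."""
        c = self.consensus
        return {
            "config": {
                "min_support": self.config.min_support,
                "min_confidence": self.config.min_confidence,
                "rhs_size": self.config.rhs_size,
                "gcn": asdict(self.config.gcn),
                "k": self.config.k,
                "k_range": list(self.config.k_range),
                "n_trees": self.config.n_trees,
                "rf_seed": self.config.rf_seed,
                "rule_top_n": self.config.rule_top_n,
                "cluster_top_n": self.config.cluster_top_n,
                "rf_top_window": self.config.rf_top_window,
                "seed": self.config.seed,
            },
            "corpus": {
                "n_anti": len(self.corpus_anti),
                "n_general": len(self.corpus_general),
                "vocab_anti": len(self.corpus_anti.vocabulary),
                "vocab_general": len(self.corpus_general.vocabulary),
            },
            "rules": {
                "n_itemsets": len(self.itemsets),
                "n_rules": len(self.rules),
                "top_rule": None if not self.rules else {
                    "lhs": sorted(self.rules[0].lhs),
                    "rhs": sorted(self.rules[0].rhs),
                    "support": self.rules[0].support,
                    "confidence": self.rules[0].confidence,
                    "lift": self.rules[0].lift,
                },
            },
            "gcn": {
                "n_nodes": len(self.embeddings.nodes),
                "n_edges": self.graph.number_of_edges(),
                "final_loss": self.embeddings.training_loss_trace[-1],
                "k_selected": self.assignment.k,
                "silhouette": self.assignment.silhouette,
                "cluster_scores": [{
                    "cluster_id": s.cluster_id,
                    "size": len(s.members),
                    "avg_degree": s.avg_degree,
                    "subgraph_density": s.subgraph_density,
                    "coverage": s.coverage,
                    "composite": s.composite,
                    "members": sorted(s.members),
                } for s in self.cluster_scores],
            },
            "differential": {
                "n_high": sum(r.band == "high" for r in self.differential),
                "n_moderate": sum(r.band == "moderate" for r in self.differential),
                "oob_error": self.forest.oob_error,
                "rf_top": self.forest.ranking[:self.config.rf_top_window],
            },
            "consensus": {
                "rule_herbs": sorted(c.rule_herbs),
                "cluster_herbs": sorted(c.cluster_herbs),
                "intersection": sorted(c.intersection),
                "venn_counts": list(c.venn_counts),
                "provenance": {h: sorted(t) for h, t in c.provenance.items()},
            },
        }

    def summary(self) -> str:
        """Human-readable multi-stage summary table."""
        r = self.to_report()
        lines = [
            "Core-herb prescription mining",
            "=" * 64,
            f"Corpora: {r['corpus']['n_anti']} anti-recurrence / "
            f"{r['corpus']['n_general']} general prescriptions; "
            f"vocabularies {r['corpus']['vocab_anti']} / {r['corpus']['vocab_general']} herbs",
            "-" * 64,
            f"Association rules  (support >= {self.config.min_support}, "
            f"confidence >= {self.config.min_confidence})",
            f"  frequent itemsets: {r['rules']['n_itemsets']}   rules: {r['rules']['n_rules']}",
        ]
        if self.rules:
            lines.append(f"  top rule by lift: {self.rules[0]}")
        lines += [
            "-" * 64,
            f"GCN embedding ({self.config.gcn.hidden_dim}/{self.config.gcn.out_dim} dims, "
            f"{self.config.gcn.epochs} epochs)  K={self.assignment.k} "
            f"(silhouette {self.assignment.silhouette:.3f})",
            f"  top cluster ({len(self.cluster_scores[0].members)} herbs, "
            f"composite {self.cluster_scores[0].composite:.3f}): "
            f"{', '.join(sorted(self.cluster_scores[0].members)[:8])}"
            f"{'...' if len(self.cluster_scores[0].members) > 8 else ''}",
            "-" * 64,
            f"Differential: {r['differential']['n_high']} high-band herbs; "
            f"forest OOB error {self.forest.oob_error:.2%} ({self.forest.n_trees} trees)",
            "-" * 64,
            f"Consensus core ({len(self.consensus.intersection)} herbs):",
        ]
        for h in self.core_herbs():
            lines.append(f"  {h}  [{', '.join(sorted(self.consensus.provenance[h]))}]")
        return "\n".join(lines)

    def save_artifacts(self, out_dir: str | Path) -> None:
        """Write per-stage artifacts plus the master JSON report."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        apriori.rules_to_frame(self.rules).to_csv(out / "rules.csv", index=False)
        apriori.itemsets_to_frame(self.itemsets).to_csv(out / "itemsets.csv", index=False)
        nx = gcn_mod.nx
        nx.write_weighted_edgelist(self.graph, out / "cooccurrence_edges.tsv", delimiter="\t")
        emb = pd.DataFrame(self.embeddings.vectors, index=self.embeddings.nodes)
        emb.to_csv(out / "embeddings.tsv", sep="\t", header=False)
        pd.DataFrame({
            "herb": list(self.assignment.labels),
            "cluster": list(self.assignment.labels.values()),
        }).to_csv(out / "clusters.csv", index=False)
        diff_mod.differential_to_frame(self.differential).to_csv(
            out / "differential.csv", index=False)
        self.forest.importance.to_csv(out / "importance.csv")
        (out / "report.json").write_text(
            json.dumps(self.to_report(), indent=2, sort_keys=True) + "\n")


class CoreHerbModel:
    """Prescription-mining model over a two-group herb corpus.

    Parameters
    ----------
    corpus_anti, corpus_general
        The anti-recurrence and general-treatment prescription corpora.
        Rule mining and graph embedding run on the anti-recurrence corpus;
        the differential stages contrast the two.
    config
        Thresholds/hyperparameters; defaults are the canonical analysis.
    """

    def __init__(self, corpus_anti: PrescriptionCorpus,
                 corpus_general: PrescriptionCorpus,
                 config: PipelineConfig | None = None):
        if len(corpus_anti) == 0 or len(corpus_general) == 0:
            raise EmptyInputError("both corpora must be non-empty")
        self.corpus_anti = corpus_anti
        self.corpus_general = corpus_general
        self.config = config or PipelineConfig()

    @classmethod
    def from_files(cls, anti_path, general_path, config: PipelineConfig | None = None,
                   format: str = "long", lexicon: HerbLexicon | None = None) -> "CoreHerbModel":
        """Build the model from two prescription tables on disk."""
        def load(path, stage):
            try:
                corpus = read_corpus(path, format=format)
            except Exception as e:
                raise PipelineStageError(stage, e) from e
            return standardize_herbs(corpus, lexicon) if lexicon else corpus
        return cls(load(anti_path, "corpus:anti"), load(general_path, "corpus:general"), config)

    @classmethod
    def from_synthetic(cls, synth: SyntheticConfig, config: PipelineConfig | None = None
                       ) -> tuple["CoreHerbModel", "SyntheticConfig"]:
        """Build the model from a generated two-group corpus.

        Returns the model and the generator's ground truth.
        """
        corpus, truth = generate_two_group_corpus(synth)
        model = cls(corpus.subset("anti_recurrence"), corpus.subset("general"), config)
        return model, truth

    def fit(self) -> CoreHerbResults:
        """Run every stage and return the results object.

        Identical corpora + config (all seeds included) produce an
        identical report; any stage failure aborts with the stage name.
        """
        cfg = self.config

        def stage(name, fn):
            try:
                return fn()
            except Exception as e:
                raise PipelineStageError(name, e) from e

        matrix = stage("encode", lambda: to_binary_matrix(self.corpus_anti))
        itemsets = stage("itemsets", lambda: apriori.frequent_itemsets(matrix, cfg.min_support))
        rules = stage("rules", lambda: apriori.derive_rules(
            itemsets, matrix, cfg.min_confidence, cfg.rhs_size))
        graph = stage("graph", lambda: gcn_mod.build_cooccurrence_graph(self.corpus_anti))
        embeddings = stage("embed", lambda: gcn_mod.gcn_embed(graph, cfg.gcn))
        assignment = stage("cluster", lambda: gcn_mod.cluster_embeddings(
            embeddings, cfg.k, cfg.k_range, seed=cfg.seed))
        scores = stage("score_clusters", lambda: gcn_mod.score_clusters(
            graph, self.corpus_anti, assignment))
        differential = stage("differential", lambda: diff_mod.frequency_differential(
            self.corpus_anti, self.corpus_general))
        forest = stage("forest", lambda: diff_mod.rf_differential(
            self.corpus_anti, self.corpus_general, cfg.n_trees, cfg.rf_seed))
        consensus = stage("consensus", lambda: consensus_core(
            select_rule_herbs(rules, cfg.rule_top_n) if rules else frozenset(),
            select_cluster_herbs(scores, cfg.cluster_top_n),
            differential, forest, cfg.rf_top_window))
        return CoreHerbResults(cfg, self.corpus_anti, self.corpus_general, itemsets,
                               rules, graph, embeddings, assignment, scores,
                               differential, forest, consensus)


def run_pipeline(anti_path=None, general_path=None, synthetic: SyntheticConfig | None = None,
                 config: PipelineConfig | None = None, out_dir=None) -> CoreHerbResults:
    """Functional wrapper: load (or generate) corpora, fit, save artifacts."""
    if synthetic is not None:
        model, _ = CoreHerbModel.from_synthetic(synthetic, config)
    elif anti_path is not None and general_path is not None:
        model = CoreHerbModel.from_files(anti_path, general_path, config)
    else:
        raise PipelineStageError("corpus", ValueError(
            "provide either both corpus paths or a synthetic config"))
    results = model.fit()
    if out_dir is not None:
        results.save_artifacts(out_dir)
        write_corpus(results.corpus_anti, Path(out_dir) / "corpus_anti.csv")
        write_corpus(results.corpus_general, Path(out_dir) / "corpus_general.csv")
    return results
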