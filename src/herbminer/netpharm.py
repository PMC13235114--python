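"""Compound/target screening and bipartite degree ranking.

The screening arm consumes user-supplied (or synthetic) tables of herb
compounds with oral bioavailability (OB, percent) and drug-likeness (DL)
scores, and compound→target links with SVM and random-forest interaction
scores.  Canonical thresholds — OB >= 30, DL >= 0.18, SVM_score >= 0.8,
RF_score >= 0.7, all inclusive — retain pharmacologically plausible
compounds and confident target links.  The surviving links form a simple
compound–target bipartite network on which node degree ranks key active
compounds and central targets.

Database retrieval is out of scope: the module never queries a pharmacology
platform, it only filters tables exported from one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .errors import FormatError

OB_MIN_DEFAULT = 30.0
DL_MIN_DEFAULT = 0.18
SVM_MIN_DEFAULT = 0.8
RF_MIN_DEFAULT = 0.7

_COMPOUND_COLS = ["compound_id", "ob", "dl"]
_TARGET_COLS = ["compound_id", "gene_symbol", "svm_score", "rf_score"]


def _require(df: pd.DataFrame, cols: list[str], what: str) -> None:
    missing = set(cols) - set(df.columns)
    if missing:
        raise FormatError(f"{what} table missing columns: {sorted(missing)}")


def filter_compounds(records: pd.DataFrame, ob_min: float = OB_MIN_DEFAULT,
                     dl_min: float = DL_MIN_DEFAULT) -> pd.DataFrame:
    """Rows with ob >= ob_min AND dl >= dl_min, input order preserved."""
    _require(records, _COMPOUND_COLS, "compound")
    if ob_min < 0 or dl_min < 0:
        raise ValueError("thresholds must be non-negative")
    return records[(records["ob"] >= ob_min) & (records["dl"] >= dl_min)].copy()


def filter_targets(links: pd.DataFrame, svm_min: float = SVM_MIN_DEFAULT,
                   rf_min: float = RF_MIN_DEFAULT) -> pd.DataFrame:
    """Rows with svm_score >= svm_min AND rf_score >= rf_min."""
    _require(links, _TARGET_COLS, "target-link")
    if not (0 <= svm_min <= 1 and 0 <= rf_min <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    return links[(links["svm_score"] >= svm_min) & (links["rf_score"] >= rf_min)].copy()


@dataclass
class BipartiteRanking:
    """Compound–target network plus degree rankings.

    ``dropped_links`` counts links naming compounds that did not survive
    filtering (or were never supplied).
    """

    network: nx.Graph
    compound_degrees: pd.Series
    target_degrees: pd.Series
    top_compounds: list[str] = field(default_factory=list)
    top_targets: list[str] = field(default_factory=list)
    dropped_links: int = 0


def build_bipartite_rank(compounds: pd.DataFrame, links: pd.DataFrame,
                         top_n: int = 10) -> BipartiteRanking:
    """Simple bipartite network restricted to surviving compounds.

    Duplicate (compound, target) pairs collapse to one edge; degree is the
    resulting edge count per node.  Rankings are degree descending, ties
    broken lexicographically.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    _require(compounds, ["compound_id"], "compound")
    _require(links, ["compound_id", "gene_symbol"], "target-link")
    known = set(compounds["compound_id"])
    kept = links[links["compound_id"].isin(known)]
    dropped = len(links) - len(kept)

    g = nx.Graph()
    g.add_nodes_from(sorted(known), bipartite="compound")
    edges = {(str(c), str(t)) for c, t in zip(kept["compound_id"], kept["gene_symbol"])}
    for c, t in sorted(edges):
        g.add_node(t, bipartite="target")
        g.add_edge(c, t)

    comp_nodes = sorted(known)
    targ_nodes = sorted(n for n, d in g.nodes(data=True) if d["bipartite"] == "target")
    cdeg = pd.Series({c: g.degree(c) for c in comp_nodes}, dtype=int).sort_index()
    tdeg = pd.Series({t: g.degree(t) for t in targ_nodes}, dtype=int).sort_index()

    def top(series: pd.Series) -> list[str]:
        ordered = sorted(series.items(), key=lambda kv: (-kv[1], kv[0]))
        return [name for name, d in ordered[:top_n] if d > 0]

    return BipartiteRanking(g, cdeg, tdeg, top(cdeg), top(tdeg), dropped)


def screen_and_rank(compounds: pd.DataFrame, links: pd.DataFrame,
                    ob_min: float = OB_MIN_DEFAULT, dl_min: float = DL_MIN_DEFAULT,
                    svm_min: float = SVM_MIN_DEFAULT, rf_min: float = RF_MIN_DEFAULT,
                    top_n: int = 10) -> tuple[pd.DataFrame, pd.DataFrame, BipartiteRanking]:
    """Full screening arm: both filters, then the degree ranking."""
    kept_c = filter_compounds(compounds, ob_min, dl_min)
    kept_t = filter_targets(links, svm_min, rf_min)
    return kept_c, kept_t, build_bipartite_rank(kept_c, kept_t, top_n)
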