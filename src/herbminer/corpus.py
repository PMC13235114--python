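"""Prescription corpora: data model, I/O, name standardization and summaries.

A *prescription* (formula) is a set of herb names co-prescribed for one
indication; it is the transaction unit of every downstream mining step.
Corpora carry a group label per prescription — ``anti_recurrence`` or
``general`` — because the differential stage contrasts the two collections.

Dosages are deliberately not modelled: all downstream statistics
(support, co-occurrence, frequency bands, forest features) are
presence-based, so prescriptions are plain sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import EmptyInputError, FormatError, RecordError

GROUPS = ("anti_recurrence", "general")

NATURES = ("cold", "cool", "neutral", "warm", "hot", "unknown")
FLAVORS = ("sour", "bitter", "sweet", "pungent", "salty", "astringent", "bland", "unknown")


@dataclass(frozen=True)
class Prescription:
    """One formula: an id, a group label and a non-empty set of herb names."""

    id: str
    group: str
    herbs: frozenset[str]

    def __post_init__(self):
        if self.group not in GROUPS:
            raise RecordError(f"prescription {self.id!r}: unknown group {self.group!r}")
        if not self.herbs:
            raise RecordError(f"prescription {self.id!r} has an empty herb set")


@dataclass(frozen=True)
class LexiconEntry:
    standard_name: str
    nature: str = "unknown"
    flavors: frozenset[str] = frozenset({"unknown"})


class HerbLexicon:
    """Mapping raw herb name -> (standard name, nature, flavors).

    Stands in for an external name-standardization service: the pipeline
    consumes a user-supplied table rather than querying a database.
    """

    def __init__(self, entries: Mapping[str, LexiconEntry] | None = None):
        self.entries: dict[str, LexiconEntry] = dict(entries or {})
        for raw, e in self.entries.items():
            if not e.standard_name:
                raise FormatError(f"lexicon entry {raw!r} has an empty standard name")
            if e.nature not in NATURES:
                raise FormatError(f"lexicon entry {raw!r}: unknown nature {e.nature!r}")
            bad = set(e.flavors) - set(FLAVORS)
            if bad:
                raise FormatError(f"lexicon entry {raw!r}: unknown flavors {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, raw: str) -> bool:
        return raw in self.entries

    def standard(self, raw: str) -> str:
        """Standard name for ``raw``; unmapped names pass through unchanged."""
        e = self.entries.get(raw)
        return e.standard_name if e is not None else raw

    @classmethod
    def from_csv(cls, path, sep: str = ",", flavor_sep: str = "|") -> "HerbLexicon":
        df = pd.read_csv(path, sep=sep, dtype=str).fillna("")
        required = {"raw_name", "standard_name"}
        missing = required - set(df.columns)
        if missing:
            raise FormatError(f"lexicon file missing columns: {sorted(missing)}")
        entries = {}
        for row in df.itertuples(index=False):
            nature = getattr(row, "nature", "") or "unknown"
            flav_raw = getattr(row, "flavor", "") or "unknown"
            flavors = frozenset(f.strip() for f in flav_raw.split(flavor_sep) if f.strip())
            entries[row.raw_name] = LexiconEntry(row.standard_name, nature, flavors or frozenset({"unknown"}))
        return cls(entries)


class PrescriptionCorpus:
    """An ordered collection of prescriptions plus its herb vocabulary.

    The vocabulary is the lexicographically sorted union of all herb sets;
    sorting makes binary-matrix columns and graph node indices deterministic.
    """

    def __init__(self, prescriptions: Sequence[Prescription]):
        ids = [p.id for p in prescriptions]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise RecordError(f"duplicate prescription ids: {dup}")
        self.prescriptions: list[Prescription] = list(prescriptions)
        self.vocabulary: list[str] = sorted(set().union(*[p.herbs for p in prescriptions]) if prescriptions else set())

    def __len__(self) -> int:
        return len(self.prescriptions)

    def __iter__(self):
        return iter(self.prescriptions)

    def subset(self, group: str) -> "PrescriptionCorpus":
        """Corpus restricted to one group label."""
        return PrescriptionCorpus([p for p in self.prescriptions if p.group == group])

    @property
    def groups(self) -> set[str]:
        return {p.group for p in self.prescriptions}


def _dedupe(prescriptions: Iterable[Prescription]) -> list[Prescription]:
    # Duplicate formulas with identical compositions are counted once,
    # scoped per group (identical compositions in different groups are kept
    # because they inform the differential analysis); earliest id wins.
    seen: dict[tuple[str, frozenset[str]], Prescription] = {}
    for p in prescriptions:
        key = (p.group, p.herbs)
        if key not in seen:
            seen[key] = p
    return list(seen.values())


def read_corpus(path, format: str = "long", sep: str = ",", herb_sep: str = ";") -> PrescriptionCorpus:
    """Read a prescription table.

    ``long`` format: one row per (prescription, herb) with columns
    ``prescription_id, group, herb``.  ``wide`` format: one row per
    prescription with columns ``prescription_id, group, herbs`` where
    ``herbs`` is a ``herb_sep``-joined list.
    """
    df = pd.read_csv(path, sep=sep, dtype=str)
    if format == "long":
        required = ["prescription_id", "group", "herb"]
    elif format == "wide":
        required = ["prescription_id", "group", "herbs"]
    else:
        raise ValueError(f"unknown format {format!r}")
    missing = set(required) - set(df.columns)
    if missing:
        raise FormatError(f"corpus file missing columns: {sorted(missing)}")

    prescriptions: list[Prescription] = []
    if format == "long":
        df = df.dropna(subset=["herb"])
        # preserve first-appearance order of prescription ids
        for (pid, group), sub in df.groupby(["prescription_id", "group"], sort=False):
            herbs = frozenset(h.strip() for h in sub["herb"] if h and h.strip())
            if not herbs:
                raise RecordError(f"prescription {pid!r} has an empty herb set")
            prescriptions.append(Prescription(str(pid), str(group), herbs))
    else:
        for row in df.itertuples(index=False):
            raw = row.herbs if isinstance(row.herbs, str) else ""
            herbs = frozenset(h.strip() for h in raw.split(herb_sep) if h.strip())
            if not herbs:
                raise RecordError(f"prescription {row.prescription_id!r} has an empty herb set")
            prescriptions.append(Prescription(str(row.prescription_id), str(row.group), herbs))
    return PrescriptionCorpus(_dedupe(prescriptions))


def write_corpus(corpus: PrescriptionCorpus, path, sep: str = ",") -> None:
    """Write a corpus in the long dialect (herbs sorted within prescription)."""
    rows = [
        {"prescription_id": p.id, "group": p.group, "herb": h}
        for p in corpus
        for h in sorted(p.herbs)
    ]
    pd.DataFrame(rows, columns=["prescription_id", "group", "herb"]).to_csv(path, sep=sep, index=False)


def standardize_herbs(corpus: PrescriptionCorpus, lexicon: HerbLexicon) -> PrescriptionCorpus:
    """Map raw herb names through the lexicon; unmapped names pass through.

    Unmapped names are reported with a warning rather than failing — the
    authoritative standardization lives outside the package.  Prescriptions
    are re-deduplicated after mapping (two raw names may collapse to one
    standard name, making previously distinct compositions identical).
    """
    unmapped: set[str] = set()
    mapped = []
    for p in corpus:
        herbs = set()
        for h in p.herbs:
            if h not in lexicon:
                unmapped.add(h)
            herbs.add(lexicon.standard(h))
        mapped.append(Prescription(p.id, p.group, frozenset(herbs)))
    if unmapped:
        warnings.warn(f"{len(unmapped)} herb names not in lexicon passed through unchanged: "
                      f"{sorted(unmapped)[:10]}{'...' if len(unmapped) > 10 else ''}",
                      stacklevel=2)
    return PrescriptionCorpus(_dedupe(mapped))


def to_binary_matrix(corpus: PrescriptionCorpus) -> pd.DataFrame:
    """Presence/absence matrix: rows = prescription ids, columns = vocabulary.

    Row sums equal prescription sizes; column sums equal herb document
    frequencies.
    """
    if len(corpus) == 0:
        raise EmptyInputError("cannot encode an empty corpus")
    data = [[1 if h in p.herbs else 0 for h in corpus.vocabulary] for p in corpus]
    return pd.DataFrame(data, index=[p.id for p in corpus], columns=corpus.vocabulary, dtype="int8")


def herb_frequency_table(corpus: PrescriptionCorpus) -> pd.DataFrame:
    """Per-herb document counts and frequencies (fraction of prescriptions).

    Returns a DataFrame indexed by herb with ``count`` and ``frequency``
    columns, sorted by count descending then herb name.
    """
    if len(corpus) == 0:
        raise EmptyInputError("cannot summarize an empty corpus")
    n = len(corpus)
    counts = {h: 0 for h in corpus.vocabulary}
    for p in corpus:
        for h in p.herbs:
            counts[h] += 1
    df = pd.DataFrame({"count": pd.Series(counts)})
    df["frequency"] = df["count"] / n
    return df.sort_index().sort_values("count", ascending=False, kind="stable")


@dataclass
class PropertySummary:
    """Tally of herb natures and flavors over a herb set."""

    nature_counts: dict[str, int] = field(default_factory=dict)
    flavor_counts: dict[str, int] = field(default_factory=dict)
    herbs_covered: int = 0
    herbs_unknown: int = 0


def property_distribution(herbs: Iterable[str], lexicon: HerbLexicon) -> PropertySummary:
    """Distribution of natures and flavors over ``herbs``.

    Herbs missing from the lexicon count as unknown; a multi-flavor herb
    increments each of its flavor bins.
    """
    summary = PropertySummary()
    for h in sorted(set(herbs)):
        entry = None
        # the lexicon is keyed by raw name; accept standard names too
        if h in lexicon:
            entry = lexicon.entries[h]
        else:
            for e in lexicon.entries.values():
                if e.standard_name == h:
                    entry = e
                    break
        if entry is None:
            summary.herbs_unknown += 1
            summary.nature_counts["unknown"] = summary.nature_counts.get("unknown", 0) + 1
            summary.flavor_counts["unknown"] = summary.flavor_counts.get("unknown", 0) + 1
            continue
        summary.herbs_covered += 1
        summary.nature_counts[entry.nature] = summary.nature_counts.get(entry.nature, 0) + 1
        for f in sorted(entry.flavors):
            summary.flavor_counts[f] = summary.flavor_counts.get(f, 0) + 1
    return summary
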