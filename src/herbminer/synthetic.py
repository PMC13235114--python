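"""Two-group synthetic prescription corpora with planted structure.

The generator emulates the statistical structure the mining stages assume:
a vocabulary of a couple of hundred herbs, prescriptions of roughly 5–20
herbs, one or more *modules* of frequently co-prescribed herbs (the signal
the rule miner and the graph clustering should recover), a set of
*differential* herbs whose inclusion frequency differs between the
anti-recurrence and general groups (the signal for the frequency bands and
the random forest), and low-probability background herbs.

Each prescription is assembled by union over three independent mechanisms:

1. module activation — each module activates with ``activation_prob``
   (multiplied by ``group_bias`` in the general group); when active, each
   member herb is included independently with ``inclusion_prob``;
2. differential herbs — included with their group-specific frequency;
3. background — every remaining vocabulary herb included with
   ``background_prob``.

A prescription whose size falls outside ``size_range`` is resampled
(rejection, not truncation) so the within-prescription dependence structure
is preserved.  All randomness flows from one seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .corpus import Prescription, PrescriptionCorpus
from .errors import ConfigurationError

_MAX_REJECTIONS = 1000


@dataclass(frozen=True)
class Module:
    """A planted co-prescription module."""

    herbs: frozenset[str]
    activation_prob: float = 0.6
    inclusion_prob: float = 0.9
    group_bias: float = 0.5  # multiplier on activation_prob in the general group


@dataclass(frozen=True)
class DifferentialHerb:
    herb: str
    freq_anti: float
    freq_general: float


@dataclass
class SyntheticConfig:
    """Study-condition parameters for the two-group generator.

    Defaults are the reference conditions used throughout the test suite:
    one planted 8-herb module (activation 0.6, inclusion 0.9, biased to the
    anti-recurrence group), a 216-herb vocabulary, background inclusion
    0.03, 150 + 120 prescriptions, and three module herbs carrying a
    40-point frequency differential (0.6 vs 0.2).
    """

    n_anti: int = 150
    n_general: int = 120
    vocab_size: int = 216
    modules: list[Module] = field(default_factory=list)
    background_prob: float = 0.03
    differential_herbs: list[DifferentialHerb] = field(default_factory=list)
    size_range: tuple[int, int] = (2, 25)
    seed: int = 0

    def validate(self) -> None:
        probs = [self.background_prob]
        for m in self.modules:
            probs += [m.activation_prob, m.inclusion_prob]
            if not 0 <= m.group_bias * m.activation_prob <= 1:
                raise ConfigurationError("group-biased activation probability outside [0, 1]")
        for d in self.differential_herbs:
            probs += [d.freq_anti, d.freq_general]
        if any(not 0 <= p <= 1 for p in probs):
            raise ConfigurationError("all probabilities must lie in [0, 1]")
        named = set().union(*[m.herbs for m in self.modules], {d.herb for d in self.differential_herbs}) \
            if (self.modules or self.differential_herbs) else set()
        if self.vocab_size < len(named):
            raise ConfigurationError("vocab_size smaller than the number of named herbs")
        lo, hi = self.size_range
        if lo > hi or lo < 1:
            raise ConfigurationError(f"infeasible size_range {self.size_range}")


@dataclass
class GroundTruth:
    """What was planted, for scoring recovery downstream."""

    planted_modules: list[frozenset[str]]
    planted_differentials: dict[str, tuple[float, float]]


def default_config(seed: int = 0) -> SyntheticConfig:
    """The reference two-group configuration (see class docstring)."""
    module_herbs = [f"herb_{i:03d}" for i in range(8)]
    diff = [DifferentialHerb(h, 0.6, 0.2) for h in module_herbs[:3]]
    return SyntheticConfig(
        modules=[Module(frozenset(module_herbs))],
        differential_herbs=diff,
        seed=seed,
    )


def _vocabulary(config: SyntheticConfig) -> list[str]:
    named = sorted(set().union(*[m.herbs for m in config.modules], {d.herb for d in config.differential_herbs})
                   if (config.modules or config.differential_herbs) else set())
    filler = [f"herb_{i:03d}" for i in range(config.vocab_size * 2)]
    vocab = list(named)
    for h in filler:
        if len(vocab) >= config.vocab_size:
            break
        if h not in named:
            vocab.append(h)
    return sorted(vocab)


def _sample_prescription(rng: np.random.Generator, config: SyntheticConfig,
                         vocab: list[str], group: str) -> frozenset[str]:
    lo, hi = config.size_range
    named = set().union(*[m.herbs for m in config.modules], {d.herb for d in config.differential_herbs}) \
        if (config.modules or config.differential_herbs) else set()
    background = [h for h in vocab if h not in named]
    for _ in range(_MAX_REJECTIONS):
        herbs: set[str] = set()
        for m in config.modules:
            act = m.activation_prob * (m.group_bias if group == "general" else 1.0)
            if rng.random() < act:
                herbs.update(h for h in sorted(m.herbs) if rng.random() < m.inclusion_prob)
        for d in config.differential_herbs:
            p = d.freq_anti if group == "anti_recurrence" else d.freq_general
            if rng.random() < p:
                herbs.add(d.herb)
        mask = rng.random(len(background)) < config.background_prob
        herbs.update(h for h, keep in zip(background, mask) if keep)
        if lo <= len(herbs) <= hi:
            return frozenset(herbs)
    raise ConfigurationError(
        f"size_range {config.size_range} rejected {_MAX_REJECTIONS} consecutive draws; "
        "expected prescription size is incompatible with the clamp")


def generate_two_group_corpus(config: SyntheticConfig) -> tuple[PrescriptionCorpus, GroundTruth]:
    """Generate the two-group corpus and its ground truth.

    Deterministic given ``config.seed``.  Prescription ids are ``A0001``…
    for the anti-recurrence group and ``G0001``… for the general group.
    Generated compositions are not deduplicated: ids are distinct by
    construction and duplicate compositions are legitimate draws.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    vocab = _vocabulary(config)
    prescriptions = []
    for i in range(config.n_anti):
        herbs = _sample_prescription(rng, config, vocab, "anti_recurrence")
        prescriptions.append(Prescription(f"A{i + 1:04d}", "anti_recurrence", herbs))
    for i in range(config.n_general):
        herbs = _sample_prescription(rng, config, vocab, "general")
        prescriptions.append(Prescription(f"G{i + 1:04d}", "general", herbs))
    truth = GroundTruth(
        planted_modules=[m.herbs for m in config.modules],
        planted_differentials={d.herb: (d.freq_anti, d.freq_general) for d in config.differential_herbs},
    )
    return PrescriptionCorpus(prescriptions), truth


def generate_netpharm_tables(n_compounds: int, n_targets: int, pass_fraction: float,
                             seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic compound and compound→target tables for the screening arm.

    Each compound passes the canonical screen (OB >= 30, DL >= 0.18) with
    probability ``pass_fraction``: with that probability its scores are
    drawn uniformly from the passing region, otherwise rejection-sampled
    from the complement.  Target links behave the same way for
    (SVM_score >= 0.8, RF_score >= 0.7).  OB is in percent on (0, 60);
    DL on (0, 0.5); both target scores on (0, 1).
    """
    if n_compounds <= 0 or n_targets <= 0:
        raise ConfigurationError("n_compounds and n_targets must be positive")
    if not 0 <= pass_fraction <= 1:
        raise ConfigurationError("pass_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)

    def draw(region_pass: bool, lo_a, hi_a, thr_a, lo_b, hi_b, thr_b):
        if region_pass:
            return rng.uniform(thr_a, hi_a), rng.uniform(thr_b, hi_b)
        while True:
            a, b = rng.uniform(lo_a, hi_a), rng.uniform(lo_b, hi_b)
            if not (a >= thr_a and b >= thr_b):
                return a, b

    herbs = ["Astragalus Membranacei Radix", "Atractylodes Macrocephalae Rhizoma",
             "Poria Cocos", "Hedyotis Diffusa Herba"]
    compounds = []
    for i in range(n_compounds):
        ob, dl = draw(rng.random() < pass_fraction, 0, 60, 30, 0, 0.5, 0.18)
        compounds.append({
            "herb": herbs[i % len(herbs)],
            "compound_id": f"C{i + 1:04d}",
            "compound_name": f"compound_{i + 1}",
            "ob": ob,
            "dl": dl,
        })
    targets = []
    gene_pool = [f"GENE{j + 1:03d}" for j in range(max(10, n_targets // 3))]
    for j in range(n_targets):
        svm, rf = draw(rng.random() < pass_fraction, 0, 1, 0.8, 0, 1, 0.7)
        targets.append({
            "compound_id": f"C{rng.integers(1, n_compounds + 1):04d}",
            "gene_symbol": gene_pool[rng.integers(0, len(gene_pool))],
            "svm_score": svm,
            "rf_score": rf,
        })
    return pd.DataFrame(compounds), pd.DataFrame(targets)
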