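import pytest

from herbminer.corpus import Prescription, PrescriptionCorpus


def make_corpus(sets: dict[str, set[str]], group: str = "anti_recurrence") -> PrescriptionCorpus:
    return PrescriptionCorpus([
        Prescription(pid, group, frozenset(herbs)) for pid, herbs in sets.items()
    ])


@pytest.fixture
def tiny_corpus():
    """Three prescriptions over herbs {A, B, C}; hand-enumerable everywhere."""
    return make_corpus({"P1": {"A", "B"}, "P2": {"A", "B", "C"}, "P3": {"B", "C"}})


@pytest.fixture(scope="session")
def reference_synthetic():
    """The reference two-group synthetic corpus at seed 1 (shared: read-only)."""
    from herbminer.synthetic import default_config, generate_two_group_corpus
    corpus, truth = generate_two_group_corpus(default_config(seed=1))
    return corpus, truth
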