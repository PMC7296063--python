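import pytest

from domainca import Architecture, Corpus, build_transition_model


def _make_corpus(seqs, prefix="p"):
    return Corpus(
        architectures=tuple(
            Architecture(protein_id=f"{prefix}{i + 1}", domains=tuple(seq))
            for i, seq in enumerate(seqs)
        )
    )


@pytest.fixture
def make_corpus():
    """Factory: list of domain-name lists -> Corpus."""
    return _make_corpus


@pytest.fixture
def toy_corpus():
    """The three-protein hand corpus used for worked examples."""
    return _make_corpus([["PH", "RhoGEF"], ["RhoGEF"], ["PH", "RhoGEF", "SH3"]])


@pytest.fixture
def toy_model(toy_corpus):
    return build_transition_model(toy_corpus)


@pytest.fixture
def chain_corpus():
    """Single architecture [A, B]: its pair graph is the deterministic
    chain X-start -> A -> B -> X-end."""
    return _make_corpus([["A", "B"]])


@pytest.fixture
def chain_model(chain_corpus):
    return build_transition_model(chain_corpus)
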