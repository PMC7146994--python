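import pytest

from smilesgen import corpus as cp
from smilesgen import fixtures as fx


@pytest.fixture(scope="session")
def fixture_smiles() -> list[str]:
    """1,000 valid-by-construction SMILES shared across the suite."""
    spec = fx.FixtureSpec(n_molecules=1000, hac_range=(5, 25), seed=11)
    return fx.generate_fixture_corpus(spec)


@pytest.fixture(scope="session")
def small_corpus(fixture_smiles):
    """Prepared molecules + substituted texts + vocabulary for 200 of
    the session fixtures."""
    molecules, _ = cp.prepare_corpus(fixture_smiles[:200])
    texts = [cp.substitute_tokens(m.canonical_smiles) for m in molecules]
    vocab = cp.build_vocabulary(texts)
    return molecules, texts, vocab
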