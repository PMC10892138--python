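import numpy as np
import pytest

from moltree import MockModel, TokenVocabulary
from moltree.chem import BOS, EOS, PAD
from moltree.dataset import template_smiles
from importlib import resources


@pytest.fixture(scope="session")
def mpro_smiles() -> list[str]:
    """Ten reference Mpro inhibitor candidates packaged with the library."""
    ref = resources.files("moltree.data") / "mpro_candidates.smi"
    with resources.as_file(ref) as path:
        from moltree.chem import read_smi
        return read_smi(path)


@pytest.fixture(scope="session")
def template_lib() -> list[str]:
    return template_smiles()


def make_vocab(chem_tokens) -> TokenVocabulary:
    return TokenVocabulary(tokens=(PAD, BOS, EOS, *chem_tokens))


def random_mock_model(chem_tokens, max_len: int, rng: np.random.Generator) -> MockModel:
    """A MockModel with a complete transition table over every prefix of
    chemical tokens shorter than *max_len* (EOS shares the support)."""
    vocab = make_vocab(chem_tokens)
    table: dict[tuple, dict] = {}

    def visit(prefix: list[str]) -> None:
        if len(prefix) - 1 >= max_len:
            return
        probs = rng.dirichlet(rng.uniform(0.3, 2.0, size=len(chem_tokens) + 1))
        table[tuple(prefix)] = {
            vocab.eos: probs[0],
            **{t: p for t, p in zip(chem_tokens, probs[1:])},
        }
        for t in chem_tokens:
            visit(prefix + [t])

    visit([vocab.bos])
    return MockModel(vocab, table)


def enumerate_completions(model: MockModel, max_len: int):
    """All complete sequences (EOS-terminated or cut at max_len) with their
    log-probability sums; the brute-force oracle for beam search."""
    vocab = model.vocab
    out = []

    def visit(prefix: list[str], logsum: float) -> None:
        dist = model.next_token_distribution(None, prefix)
        for idx, p in enumerate(dist):
            tok = vocab.token(idx)
            if tok in (vocab.bos, vocab.pad):
                continue
            lp = logsum + (np.log(p) if p > 0 else -np.inf)
            seq = prefix[1:] + [tok]  # strip BOS
            if tok == vocab.eos:
                out.append((seq, lp))
            elif len(seq) >= max_len:
                out.append((seq, lp))
            else:
                visit(prefix + [tok], lp)

    visit([vocab.bos], 0.0)
    return out
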