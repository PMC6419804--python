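import numpy as np
import pytest

from crfvoter.corpus_io import Corpus, Document, LabeledSentence, Token, spans_to_iob
from crfvoter.corpus_io import EntityMention

TYPES = ("ABBREVIATION", "FULLNAME", "FAMILY")


def random_sentence(rng: np.random.Generator, types=TYPES) -> LabeledSentence:
    n = int(rng.integers(3, 12))
    tokens = [
        Token("".join(rng.choice(list("abcdefgh"), size=int(rng.integers(2, 6)))))
        for _ in range(n)
    ]
    mentions = []
    pos = 0
    while pos < n:
        if rng.random() < 0.3:
            k = min(int(rng.integers(1, 4)), n - pos)
            mentions.append(
                EntityMention("", 0, pos, pos + k, str(rng.choice(types)))
            )
            pos += k + 1
        else:
            pos += 1
    return LabeledSentence(tokens, spans_to_iob(n, mentions))


def random_corpus(seed: int, n_docs: int = 5, types=TYPES) -> Corpus:
    rng = np.random.default_rng(seed)
    docs = []
    for d in range(n_docs):
        n_sent = int(rng.integers(1, 4))
        docs.append(
            Document(f"doc{d}", [random_sentence(rng, types) for _ in range(n_sent)])
        )
    return Corpus(docs)


@pytest.fixture
def tiny_corpus() -> Corpus:
    sent1 = LabeledSentence(
        [Token("EGFR"), Token("binds"), Token("stuff")],
        ["B-ABBREVIATION", "O", "O"],
    )
    sent2 = LabeledSentence(
        [Token("Epidermal"), Token("Growth"), Token("Factor")],
        ["B-FULLNAME", "I-FULLNAME", "I-FULLNAME"],
    )
    return Corpus([Document("d0", [sent1]), Document("d1", [sent2])])
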