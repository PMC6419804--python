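"""IOB2 corpus handling: CoNLL-style TSV I/O, span/tag conversion, splits.

Conventions
-----------
* TSV dialect: UTF-8; one token per line; tab-separated columns with the
  IOB2 label in the last column; a blank line ends a sentence; a comment
  line ``#doc <id>`` opens a new document.
* All token indices are 0-based half-open; character offsets likewise.
* Document raw text is reconstructed by joining tokens with single spaces
  (sentences are also joined with a single space).  Character-offset
  annotations are interpreted against this layout.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

logger = logging.getLogger(__name__)

_IOB_RE = re.compile(r"^(O|[BI]-\S+)$")

__all__ = [
    "Token",
    "LabeledSentence",
    "Document",
    "Corpus",
    "EntityMention",
    "CharMention",
    "CorpusFormatError",
    "OverlapError",
    "read_tsv",
    "write_tsv",
    "spans_to_iob",
    "iob_to_spans",
    "repair_iob",
    "filter_subtoken_mentions",
    "split_corpus",
    "retokenize_on_nonalnum",
]


class CorpusFormatError(ValueError):
    """Raised for malformed TSV input (ragged rows, bad labels)."""


class OverlapError(ValueError):
    """Raised when two entity mentions overlap on the same sentence."""


@dataclass(frozen=True)
class Token:
    """A surface form plus optional linguistic feature columns (lemma, POS, ...)."""

    surface: str
    columns: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.surface:
            raise ValueError("token surface must be non-empty")
        if "\t" in self.surface or "\n" in self.surface:
            raise ValueError("token surface may not contain tab or newline")


@dataclass(frozen=True)
class EntityMention:
    """A typed, token-indexed entity span (start inclusive, end exclusive)."""

    doc_id: str
    sentence_index: int
    start_token: int
    end_token: int
    entity_type: str

    def __post_init__(self) -> None:
        if not (0 <= self.start_token < self.end_token):
            raise ValueError(
                f"invalid span [{self.start_token}, {self.end_token})"
            )

    @property
    def length(self) -> int:
        return self.end_token - self.start_token


@dataclass(frozen=True)
class CharMention:
    """A gold mention located by character offsets into the raw document text."""

    doc_id: str
    start_char: int
    end_char: int
    entity_type: str


@dataclass
class LabeledSentence:
    tokens: list[Token]
    labels: list[str]

    def __post_init__(self) -> None:
        if len(self.tokens) != len(self.labels):
            raise ValueError(
                f"{len(self.tokens)} tokens but {len(self.labels)} labels"
            )
        for lab in self.labels:
            if not _IOB_RE.match(lab):
                raise CorpusFormatError(f"not an IOB2 tag: {lab!r}")

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def surfaces(self) -> list[str]:
        return [t.surface for t in self.tokens]


@dataclass
class Document:
    doc_id: str
    sentences: list[LabeledSentence]

    def text(self) -> str:
        """Raw text under the space-joined layout convention."""
        return " ".join(" ".join(s.surfaces) for s in self.sentences)


@dataclass
class Corpus:
    documents: list[Document] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for doc in self.documents:
            if doc.doc_id in seen:
                raise ValueError(f"duplicate doc_id {doc.doc_id!r}")
            seen.add(doc.doc_id)

    def __len__(self) -> int:
        return len(self.documents)

    def sentences(self) -> Iterator[tuple[str, int, LabeledSentence]]:
        """Yield (doc_id, sentence_index, sentence) in corpus order."""
        for doc in self.documents:
            for i, sent in enumerate(doc.sentences):
                yield doc.doc_id, i, sent

    def n_sentences(self) -> int:
        return sum(len(d.sentences) for d in self.documents)

    def n_tokens(self) -> int:
        return sum(len(s) for _, _, s in self.sentences())

    def mentions(self) -> set[EntityMention]:
        """Decode all gold IOB2 labels into entity mentions."""
        out: set[EntityMention] = set()
        for doc_id, i, sent in self.sentences():
            out |= iob_to_spans(sent.labels, doc_id=doc_id, sentence_index=i)
        return out


def repair_iob(labels: Sequence[str], warn: bool = True) -> list[str]:
    """Rewrite invalid I- continuations to B- (standard IOB repair).

    An ``I-<T>`` that follows ``O``, the sentence start, or a tag of a
    different type becomes ``B-<T>``.  Decoding is therefore total.
    """
    repaired: list[str] = []
    n_fixed = 0
    prev_type: str | None = None
    for lab in labels:
        if lab == "O":
            repaired.append(lab)
            prev_type = None
            continue
        marker, etype = lab.split("-", 1)
        if marker == "I" and etype != prev_type:
            repaired.append(f"B-{etype}")
            n_fixed += 1
        else:
            repaired.append(lab)
        prev_type = etype
    if n_fixed and warn:
        logger.warning("repaired %d invalid IOB2 continuation tag(s)", n_fixed)
    return repaired


def spans_to_iob(sentence_length: int, mentions: Iterable[EntityMention]) -> list[str]:
    """Encode non-overlapping mentions of one sentence as an IOB2 tag sequence."""
    labels = ["O"] * sentence_length
    ordered = sorted(mentions, key=lambda m: (m.start_token, m.end_token))
    prev: EntityMention | None = None
    for m in ordered:
        if m.end_token > sentence_length:
            raise ValueError(f"mention {m} exceeds sentence length {sentence_length}")
        if prev is not None and m.start_token < prev.end_token:
            raise OverlapError(f"overlapping mentions: {prev} and {m}")
        labels[m.start_token] = f"B-{m.entity_type}"
        for j in range(m.start_token + 1, m.end_token):
            labels[j] = f"I-{m.entity_type}"
        prev = m
    return labels


def iob_to_spans(
    labels: Sequence[str], doc_id: str = "", sentence_index: int = 0
) -> set[EntityMention]:
    """Decode an IOB2 tag sequence into mentions (input repaired first)."""
    labels = repair_iob(labels, warn=False)
    spans: set[EntityMention] = set()
    start: int | None = None
    cur_type: str | None = None
    for j, lab in enumerate(labels):
        if lab == "O" or lab.startswith("B-"):
            if start is not None:
                spans.add(
                    EntityMention(doc_id, sentence_index, start, j, cur_type)
                )
                start, cur_type = None, None
        if lab.startswith("B-"):
            start, cur_type = j, lab[2:]
    if start is not None:
        spans.add(
            EntityMention(doc_id, sentence_index, start, len(labels), cur_type)
        )
    return spans


def read_tsv(path: str | Path) -> Corpus:
    """Read a CoNLL-style TSV corpus (see module docstring for the dialect)."""
    path = Path(path)
    documents: list[Document] = []
    cur_doc_id: str | None = None
    cur_sents: list[LabeledSentence] = []
    rows: list[tuple[str, tuple[str, ...], str]] = []
    ncols: int | None = None
    auto_id = 0

    def flush_sentence(lineno: int) -> None:
        nonlocal rows, ncols, cur_doc_id
        if not rows:
            return
        if cur_doc_id is None:
            cur_doc_id = f"doc{auto_id}"
        tokens = [Token(surface, cols) for surface, cols, _ in rows]
        labels = [lab for _, _, lab in rows]
        if any(not _IOB_RE.match(lab) for lab in labels):
            bad = next(lab for lab in labels if not _IOB_RE.match(lab))
            raise CorpusFormatError(
                f"{path}: invalid IOB2 label {bad!r} in sentence ending at line {lineno}"
            )
        labels = repair_iob(labels)
        cur_sents.append(LabeledSentence(tokens, labels))
        rows, ncols = [], None

    def flush_document() -> None:
        nonlocal cur_sents, cur_doc_id, auto_id
        if cur_doc_id is not None and cur_sents:
            documents.append(Document(cur_doc_id, cur_sents))
        cur_sents, cur_doc_id = [], None
        auto_id += 1

    lineno = 0
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if line.startswith("#doc"):
                flush_sentence(lineno)
                flush_document()
                cur_doc_id = line[len("#doc"):].strip() or f"doc{auto_id}"
                continue
            if not line.strip():
                flush_sentence(lineno)
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise CorpusFormatError(
                    f"{path}:{lineno}: expected at least 2 tab-separated columns"
                )
            if ncols is None:
                ncols = len(parts)
            elif len(parts) != ncols:
                raise CorpusFormatError(
                    f"{path}:{lineno}: ragged row ({len(parts)} columns, expected {ncols})"
                )
            rows.append((parts[0], tuple(parts[1:-1]), parts[-1]))
    flush_sentence(lineno)
    flush_document()
    return Corpus(documents)


def write_tsv(corpus: Corpus, path: str | Path) -> Path:
    """Write a corpus in the TSV dialect; returns the path written."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for doc in corpus.documents:
            fh.write(f"#doc {doc.doc_id}\n")
            for sent in doc.sentences:
                for tok, lab in zip(sent.tokens, sent.labels):
                    fh.write("\t".join((tok.surface, *tok.columns, lab)) + "\n")
                fh.write("\n")
    return path


def _token_char_spans(doc: Document) -> dict[tuple[int, int], tuple[int, int]]:
    """Map (sentence_index, token_index) -> (start_char, end_char) under the layout."""
    spans: dict[tuple[int, int], tuple[int, int]] = {}
    pos = 0
    for i, sent in enumerate(doc.sentences):
        for j, tok in enumerate(sent.tokens):
            spans[(i, j)] = (pos, pos + len(tok.surface))
            pos += len(tok.surface) + 1
    return spans


def filter_subtoken_mentions(
    corpus: Corpus, gold_char_spans: Iterable[CharMention]
) -> tuple[list[EntityMention], list[CharMention]]:
    """Partition character-offset gold mentions by token-boundary alignment.

    Mentions whose character span coincides with whole-token boundaries are
    returned as trainable token-indexed mentions; the rest (sub-token cases
    such as an annotation covering only part of a fused token) are returned
    unchanged as untrainable.  Untrainable mentions are excluded from
    training labels but must still be counted as gold during evaluation.
    """
    layouts = {doc.doc_id: _token_char_spans(doc) for doc in corpus.documents}
    texts = {doc.doc_id: doc.text() for doc in corpus.documents}
    trainable: list[EntityMention] = []
    untrainable: list[CharMention] = []
    for cm in gold_char_spans:
        if cm.doc_id not in layouts:
            raise KeyError(f"unknown doc_id {cm.doc_id!r}")
        text = texts[cm.doc_id]
        if not (0 <= cm.start_char < cm.end_char <= len(text)):
            raise IndexError(
                f"offset [{cm.start_char}, {cm.end_char}) outside document "
                f"{cm.doc_id!r} of length {len(text)}"
            )
        layout = layouts[cm.doc_id]
        start_key = next(
            (k for k, (s, _) in layout.items() if s == cm.start_char), None
        )
        end_key = next(
            (k for k, (_, e) in layout.items() if e == cm.end_char), None
        )
        if start_key is None or end_key is None or start_key[0] != end_key[0]:
            untrainable.append(cm)
            continue
        trainable.append(
            EntityMention(
                cm.doc_id, start_key[0], start_key[1], end_key[1] + 1, cm.entity_type
            )
        )
    return trainable, untrainable


def split_corpus(
    corpus: Corpus, ratios: tuple[float, float, float], seed: int
) -> tuple[Corpus, Corpus, Corpus]:
    """Randomly partition documents into train/dev/test by the given ratios.

    Sizes are floor-based for dev and test; the remainder goes to train.
    Deterministic given the seed; document order within each split follows
    the original corpus order.
    """
    if any(r <= 0 for r in ratios):
        raise ValueError("ratios must be positive")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios must sum to 1, got {sum(ratios)}")
    n = len(corpus.documents)
    if n < 3:
        raise ValueError(f"cannot split {n} document(s) three ways")
    n_dev = math.floor(ratios[1] * n)
    n_test = math.floor(ratios[2] * n)
    n_train = n - n_dev - n_test
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    idx_train = sorted(order[:n_train].tolist())
    idx_dev = sorted(order[n_train : n_train + n_dev].tolist())
    idx_test = sorted(order[n_train + n_dev :].tolist())
    docs = corpus.documents
    return (
        Corpus([docs[i] for i in idx_train]),
        Corpus([docs[i] for i in idx_dev]),
        Corpus([docs[i] for i in idx_test]),
    )


def retokenize_on_nonalnum(surface: str) -> list[str]:
    """Split a token on non-alphanumeric characters, keeping separators.

    Helper for pre-tokenized input; e.g. ``"B-RafV600E"`` ->
    ``["B", "-", "RafV600E"]``.
    """
    parts = re.findall(r"[0-9A-Za-z]+|[^0-9A-Za-z]", surface)
    return [p for p in parts if p]
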