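"""Seeded generator of GPRO-like corpora and simulated tagger outputs.

Documents contain sentences of pseudo-word background tokens into which
typed multi-token entity mentions are planted.  Surface-form patterns per
entity class are an invention of this package (uppercase acronyms for
ABBREVIATION, capitalized multiword phrases for FULLNAME, suffix-patterned
words for FAMILY, ...), chosen only so that classes are learnable and
visually distinct; they are configurable via the lexicon generators.

A configurable fraction of mentions is rendered as *sub-token* cases: the
mention's last token is fused with a trailing suffix so the gold character
span ends mid-token.  Such mentions carry no IOB labels (they cannot be
trained) but stay in the character-offset sidecar, mirroring how corpus
filtering treats them.

Simulated learner outputs corrupt gold annotations with per-type deletion,
one-token boundary jitter and type confusion, deterministically per
(seed, document, sentence), so complementary error structure across
learners can be constructed exactly.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .corpus_io import (
    CharMention,
    Corpus,
    Document,
    EntityMention,
    LabeledSentence,
    Token,
    iob_to_spans,
    spans_to_iob,
    split_corpus,
)

__all__ = [
    "GeneratorConfig",
    "ErrorProfile",
    "SimulatedLearner",
    "generate_corpus",
    "simulate_learner_output",
    "make_complementary_benchmark",
    "GPRO_TYPE1_COUNTS",
    "GPRO_TYPE2_COUNTS",
    "default_type_weights",
]

# Published per-class annotation counts of the GPRO task (type 1 = mentions
# normalizable to database entries, type 2 = the rest).  Used for default
# class weighting and for report arithmetic.
GPRO_TYPE1_COUNTS: dict[str, int] = {
    "ABBREVIATION": 7516,
    "FAMILY": 1,
    "FULLNAME": 4815,
    "IDENTIFIER": 1,
    "NESTED": 89,
}
GPRO_TYPE2_COUNTS: dict[str, int] = {
    "ABBREVIATION": 27,
    "FAMILY": 5029,
    "FULLNAME": 27,
    "MULTIPLE": 178,
    "NOCLASS": 45,
    "SEQUENCE": 23,
}


def default_type_weights() -> dict[str, float]:
    """Class weights proportional to the published type-1 counts."""
    total = sum(GPRO_TYPE1_COUNTS.values())
    return {t: c / total for t, c in GPRO_TYPE1_COUNTS.items()}


class GeneratorConfigError(ValueError):
    pass


@dataclass(frozen=True)
class GeneratorConfig:
    n_documents: int = 50
    sentences_per_doc: tuple[int, int] = (2, 4)
    tokens_per_sentence: tuple[int, int] = (6, 14)
    entity_type_weights: Mapping[str, float] = field(
        default_factory=default_type_weights
    )
    mention_rate: float = 1.0
    mention_length_distribution: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.6, 2: 0.3, 3: 0.1}
    )
    entity_lexicon_size: int = 80
    background_lexicon_size: int = 300
    subtoken_case_rate: float = 0.0085
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.entity_type_weights.values()) - 1.0) > 1e-9:
            raise GeneratorConfigError("entity_type_weights must sum to 1")
        if abs(sum(self.mention_length_distribution.values()) - 1.0) > 1e-9:
            raise GeneratorConfigError("mention_length_distribution must sum to 1")
        if self.mention_rate < 0:
            raise GeneratorConfigError("mention_rate must be >= 0")
        if not (0.0 <= self.subtoken_case_rate <= 1.0):
            raise GeneratorConfigError("subtoken_case_rate must lie in [0, 1]")
        lo, hi = self.sentences_per_doc
        if lo < 1 or lo > hi:
            raise GeneratorConfigError("bad sentences_per_doc range")
        lo, hi = self.tokens_per_sentence
        if lo < 1 or lo > hi:
            raise GeneratorConfigError("bad tokens_per_sentence range")
        if max(self.mention_length_distribution) > self.tokens_per_sentence[0]:
            raise GeneratorConfigError(
                "mention length can exceed the shortest sentence"
            )


@dataclass(frozen=True)
class ErrorProfile:
    """Controllable corruption of gold annotations for one simulated learner."""

    learner_id: str
    per_type_miss_rate: Mapping[str, float] = field(default_factory=dict)
    boundary_jitter_rate: float = 0.0
    type_confusion: Mapping[str, tuple[str, float]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        probs = list(self.per_type_miss_rate.values()) + [self.boundary_jitter_rate]
        probs += [p for _, p in self.type_confusion.values()]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")


_LOWER = np.array(list("abcdefghijklmnopqrstuvwxyz"))
_UPPER = np.array(list("ABCDEFGHIJKLMNOPQRSTUVWXYZ"))
_DIGIT = np.array(list("0123456789"))


def _rand_word(rng, chars, lo, hi) -> str:
    k = int(rng.integers(lo, hi + 1))
    return "".join(rng.choice(chars, size=k))


def _entity_token(rng: np.random.Generator, etype: str) -> str:
    if etype == "ABBREVIATION":
        w = _rand_word(rng, _UPPER, 3, 5)
        if rng.random() < 0.3:
            w += _rand_word(rng, _DIGIT, 1, 2)
        return w
    if etype == "FULLNAME":
        return _rand_word(rng, _UPPER, 1, 1) + _rand_word(rng, _LOWER, 4, 8)
    if etype == "FAMILY":
        return _rand_word(rng, _LOWER, 3, 6) + rng.choice(["ase", "in", "or"])
    if etype == "IDENTIFIER":
        return (
            _rand_word(rng, _UPPER, 1, 2)
            + _rand_word(rng, _DIGIT, 2, 4)
            + _rand_word(rng, _UPPER, 0, 1)
        )
    if etype == "NESTED":
        return _rand_word(rng, _UPPER, 2, 3) + _rand_word(rng, _LOWER, 2, 4)
    if etype == "SEQUENCE":
        return "".join(rng.choice(np.array(list("ACGT")), size=int(rng.integers(6, 12))))
    # MULTIPLE, NOCLASS, anything else: mixed-case pseudo-word
    return _rand_word(rng, _LOWER, 2, 4) + _rand_word(rng, _UPPER, 1, 2)


def _build_lexica(rng: np.random.Generator, cfg: GeneratorConfig):
    background = sorted(
        {_rand_word(rng, _LOWER, 3, 8) for _ in range(cfg.background_lexicon_size)}
    )
    entity: dict[str, list[str]] = {}
    for etype in cfg.entity_type_weights:
        entity[etype] = sorted(
            {_entity_token(rng, etype) for _ in range(cfg.entity_lexicon_size)}
        )
    return background, entity


def generate_corpus(config: GeneratorConfig) -> tuple[Corpus, list[CharMention]]:
    """Generate a labeled corpus plus its character-offset gold sidecar.

    Deterministic given ``config.seed``.  Sub-token mentions appear in the
    sidecar but carry ``O`` labels in the corpus.
    """
    rng = np.random.default_rng(config.seed)
    background, entity_lex = _build_lexica(rng, config)
    types = list(config.entity_type_weights)
    type_p = np.array([config.entity_type_weights[t] for t in types])
    lengths = sorted(config.mention_length_distribution)
    length_p = np.array([config.mention_length_distribution[k] for k in lengths])

    documents: list[Document] = []
    char_mentions: list[CharMention] = []
    for di in range(config.n_documents):
        doc_id = f"d{di:05d}"
        sentences: list[LabeledSentence] = []
        # (sentence_index, mention, subtoken_suffix or None)
        doc_mentions: list[tuple[int, EntityMention, str | None]] = []
        n_sents = int(rng.integers(config.sentences_per_doc[0],
                                   config.sentences_per_doc[1] + 1))
        for si in range(n_sents):
            n_tok = int(rng.integers(config.tokens_per_sentence[0],
                                     config.tokens_per_sentence[1] + 1))
            surfaces = [str(rng.choice(background)) for _ in range(n_tok)]
            n_ment = int(rng.poisson(config.mention_rate))
            placed: list[EntityMention] = []
            for _ in range(n_ment):
                etype = types[int(rng.choice(len(types), p=type_p))]
                k = int(lengths[int(rng.choice(len(lengths), p=length_p))])
                if k > n_tok:
                    continue
                for _attempt in range(10):
                    start = int(rng.integers(0, n_tok - k + 1))
                    span = EntityMention(doc_id, si, start, start + k, etype)
                    if all(
                        span.end_token <= m.start_token or span.start_token >= m.end_token
                        for m in placed
                    ):
                        placed.append(span)
                        break
            for m in placed:
                for j in range(m.start_token, m.end_token):
                    surfaces[j] = str(rng.choice(entity_lex[m.entity_type]))
            labeled: list[EntityMention] = []
            for m in sorted(placed, key=lambda m: m.start_token):
                suffix = None
                if rng.random() < config.subtoken_case_rate:
                    suffix = _rand_word(rng, _UPPER, 1, 1) + _rand_word(rng, _DIGIT, 2, 3)
                    surfaces[m.end_token - 1] += suffix
                else:
                    labeled.append(m)
                doc_mentions.append((si, m, suffix))
            labels = spans_to_iob(n_tok, labeled)
            sentences.append(
                LabeledSentence([Token(s) for s in surfaces], labels)
            )
        doc = Document(doc_id, sentences)
        # character offsets under the space-joined layout
        pos = 0
        starts: dict[tuple[int, int], int] = {}
        ends: dict[tuple[int, int], int] = {}
        for si, sent in enumerate(doc.sentences):
            for ti, tok in enumerate(sent.tokens):
                starts[(si, ti)] = pos
                ends[(si, ti)] = pos + len(tok.surface)
                pos += len(tok.surface) + 1
        for si, m, suffix in doc_mentions:
            end = ends[(si, m.end_token - 1)]
            if suffix is not None:
                end -= len(suffix)
            char_mentions.append(
                CharMention(doc_id, starts[(si, m.start_token)], end, m.entity_type)
            )
        documents.append(doc)
    return Corpus(documents), char_mentions


def _sentence_rng(profile: ErrorProfile, doc_id: str, sent_idx: int):
    return np.random.default_rng(
        [profile.seed, zlib.crc32(doc_id.encode("utf-8")), sent_idx]
    )


def simulate_learner_output(
    gold: Corpus, profile: ErrorProfile
) -> list[list[str]]:
    """Corrupt gold labels per the profile; aligned with ``gold.sentences()``."""
    outputs: list[list[str]] = []
    for doc_id, si, sent in gold.sentences():
        rng = _sentence_rng(profile, doc_id, si)
        n = len(sent)
        mentions = sorted(
            iob_to_spans(sent.labels, doc_id=doc_id, sentence_index=si),
            key=lambda m: m.start_token,
        )
        kept: list[EntityMention] = []
        for m in mentions:
            if rng.random() < profile.per_type_miss_rate.get(m.entity_type, 0.0):
                continue
            etype = m.entity_type
            conf = profile.type_confusion.get(etype)
            if conf is not None and rng.random() < conf[1]:
                etype = conf[0]
            start, end = m.start_token, m.end_token
            if rng.random() < profile.boundary_jitter_rate:
                move = int(rng.integers(4))
                s, e = start, end
                if move == 0:
                    s -= 1
                elif move == 1:
                    s += 1
                elif move == 2:
                    e -= 1
                else:
                    e += 1
                if 0 <= s < e <= n:
                    start, end = s, e
            cand = EntityMention(doc_id, si, start, end, etype)
            if all(
                cand.end_token <= k.start_token or cand.start_token >= k.end_token
                for k in kept
            ):
                kept.append(cand)
        outputs.append(spans_to_iob(n, kept))
    return outputs


@dataclass(frozen=True)
class SimulatedLearner:
    """A corpus-level tagger backed by an :class:`ErrorProfile`."""

    profile: ErrorProfile

    @property
    def learner_id(self) -> str:
        return self.profile.learner_id

    def tag_corpus(self, corpus: Corpus) -> list[list[str]]:
        return simulate_learner_output(corpus, self.profile)


def make_complementary_benchmark(
    config: GeneratorConfig, l: int, seed: int
) -> tuple[Corpus, Corpus, Corpus, list[ErrorProfile]]:
    """Corpus split 60/20/20 plus ``l`` profiles with disjoint high-miss types.

    Learner m is nearly blind to type m (misses it at 0.9) and noisy on all
    other types (miss 0.45, boundary jitter 0.25), so every learner's
    specialty holes differ and no single learner dominates.
    """
    if l < 2:
        raise GeneratorConfigError("need at least 2 simulated learners")
    types = [t for t, w in config.entity_type_weights.items() if w > 0]
    if len(types) < l:
        raise GeneratorConfigError(
            f"{l} learners need at least {l} entity types with positive weight"
        )
    corpus, _ = generate_corpus(replace(config, seed=seed))
    train, dev, test = split_corpus(corpus, (0.6, 0.2, 0.2), seed + 1)
    profiles = []
    for m in range(l):
        miss = {t: 0.45 for t in types}
        miss[types[m]] = 0.9
        profiles.append(
            ErrorProfile(
                learner_id=f"sim{m}",
                per_type_miss_rate=miss,
                boundary_jitter_rate=0.25,
                seed=seed + 101 + m,
            )
        )
    return train, dev, test, profiles
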