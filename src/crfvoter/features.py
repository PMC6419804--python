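"""Configurable sparse feature templates for token positions.

The switch set mirrors the tunable option inventory of a classic CRF-based
NER tagger (word identity, character n-grams, neighbor words, word pairs,
tag/shape sequences, disjunctive windows, gazetteer lookups, ...).  The
generator behind each switch is defined *here*; the names are an emulation
of the historical option names, not a re-implementation of any external
tool.  Each enabled switch contributes an independent set of feature
strings, so enabling a switch can only ever add features.

Column conventions: ``Token.columns[LEMMA_COL]`` holds the lemma and
``Token.columns[TAG_COL]`` the POS tag when present; switches that read a
missing column are silently skipped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields, asdict
from pathlib import Path
from typing import Iterable

from .corpus_io import LabeledSentence

LEMMA_COL = 0
TAG_COL = 1

_BOS = "<s>"
_EOS = "</s>"

__all__ = [
    "FeatureConfig",
    "FeatureVector",
    "Gazetteer",
    "extract_features",
    "word_shape",
    "char_ngrams",
    "SHAPE_MODES",
]


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class FeatureVector:
    """A sparse indicator feature set with deterministic serialization."""

    features: frozenset[str]

    def __iter__(self):
        return iter(self.features)

    def __len__(self) -> int:
        return len(self.features)

    def __contains__(self, item: str) -> bool:
        return item in self.features

    def sorted(self) -> list[str]:
        return sorted(self.features)


@dataclass(frozen=True)
class Gazetteer:
    """Lexicon of known (phrase, type) pairs; phrases are space-joined tokens."""

    entries: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        if any(not phrase for phrase, _ in self.entries):
            raise ValueError("gazetteer phrases must be non-empty")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "Gazetteer":
        return cls(frozenset(pairs))

    @classmethod
    def read_tsv(cls, path: str | Path) -> "Gazetteer":
        pairs = []
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            if not line.strip():
                continue
            phrase, etype = line.split("\t")
            pairs.append((phrase, etype))
        return cls.from_pairs(pairs)

    def unigrams(self) -> frozenset[str]:
        return frozenset(
            w for phrase, _ in self.entries for w in phrase.split(" ")
        )


_INT_RANGES = {"max_left": (1, 8), "max_right": (1, 8), "max_ngram_leng": (1, 6)}


@dataclass(frozen=True)
class FeatureConfig:
    use_word: bool = True
    use_class_feature: bool = False
    use_ngrams: bool = False
    no_mid_ngrams: bool = False
    normalize_terms: bool = False
    use_position: bool = False
    use_neighbor_ngrams: bool = False
    use_more_neighbor_ngrams: bool = False
    use_prev: bool = False
    use_next: bool = False
    use_tags: bool = False
    use_word_pairs: bool = False
    use_disjunctive: bool = False
    use_sequences: bool = False
    use_prev_sequences: bool = False
    use_next_sequences: bool = False
    use_long_sequences: bool = False
    use_taggy_sequences: bool = False
    use_sym_word_pairs: bool = False
    use_sym_tags: bool = False
    use_type_seqs: bool = False
    use_type_seqs2: bool = False
    use_typey_sequences: bool = False
    use_gaz_features: bool = False
    use_word_tag: bool = False
    use_wide_disjunctive: bool = False
    use_lemmas: bool = False
    use_prev_next_lemmas: bool = False
    sloppy_gazette: bool = False
    max_left: int = 4
    max_right: int = 4
    max_ngram_leng: int = 4
    word_shape: str = "none"

    def __post_init__(self) -> None:
        for name, (lo, hi) in _INT_RANGES.items():
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ConfigurationError(f"{name}={v} outside [{lo}, {hi}]")
        if self.word_shape not in SHAPE_MODES and self.word_shape != "none":
            raise ConfigurationError(f"unknown word_shape mode {self.word_shape!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown feature switches: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "FeatureConfig":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))

    def to_dict(self) -> dict:
        return asdict(self)


def _translit(surface: str) -> str:
    out = []
    for ch in surface:
        if ch.isupper():
            out.append("X")
        elif ch.islower():
            out.append("x")
        elif ch.isdigit():
            out.append("0")
        else:
            out.append(ch)
    return "".join(out)


def _compress_runs(shape: str, max_run: int = 4) -> str:
    out: list[str] = []
    run = 0
    for ch in shape:
        if out and ch == out[-1]:
            run += 1
            if run >= max_run:
                continue
        else:
            run = 0
        out.append(ch)
    return "".join(out)


SHAPE_MODES = {
    "plain": _translit,
    "chris2uselc": lambda s: _compress_runs(_translit(s)),
}


def word_shape(surface: str, mode: str = "plain") -> str:
    """Character-class transliteration: uppercase->X, lowercase->x, digit->0.

    ``chris2uselc`` additionally collapses runs of identical shape
    characters longer than 4 down to 4.
    """
    try:
        fn = SHAPE_MODES[mode]
    except KeyError:
        raise ConfigurationError(f"unknown word_shape mode {mode!r}") from None
    return fn(surface)


def char_ngrams(surface: str, max_len: int, no_mid: bool = False) -> frozenset[str]:
    """Character n-grams of length <= max_len, plus boundary-marked variants.

    With ``no_mid`` only prefixes and suffixes are emitted (boundary-marked).
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    grams: set[str] = set()
    L = len(surface)
    for k in range(1, min(max_len, L) + 1):
        for i in range(L - k + 1):
            g = surface[i : i + k]
            if i == 0:
                grams.add("<" + g)
            if i + k == L:
                grams.add(g + ">")
            if not no_mid:
                grams.add(g)
    return frozenset(grams)


def _surf(sentence: LabeledSentence, j: int, cfg: FeatureConfig) -> str:
    """Word at offset-resolved index j, with boundary sentinels and clipping."""
    if j < 0:
        return _BOS
    if j >= len(sentence):
        return _EOS
    return sentence.tokens[j].surface


def _col(sentence: LabeledSentence, j: int, col: int) -> str | None:
    if j < 0:
        return _BOS
    if j >= len(sentence):
        return _EOS
    cols = sentence.tokens[j].columns
    return cols[col] if col < len(cols) else None


def _in_window(cfg: FeatureConfig, offset: int) -> bool:
    return -cfg.max_left <= offset <= cfg.max_right


def _word_class(surface: str) -> str:
    has_upper = any(c.isupper() for c in surface)
    has_lower = any(c.islower() for c in surface)
    has_digit = any(c.isdigit() for c in surface)
    if has_digit and not has_upper and not has_lower:
        return "DIGITS"
    if has_upper and not has_lower:
        return "ALLCAPS" if not has_digit else "CAPSNUM"
    if has_upper and has_lower:
        return "MIXED" if not surface[0].isupper() else "CAPITALIZED"
    if has_lower:
        return "LOWER" if not has_digit else "LOWERNUM"
    return "OTHER"


def extract_features(
    sentence: LabeledSentence,
    position: int,
    config: FeatureConfig,
    gazetteer: Gazetteer | None = None,
) -> FeatureVector:
    """Emit the union of all enabled per-switch feature generators.

    A constant bias feature ``b`` is always present.  Context generators
    never look outside ``[position - max_left, position + max_right]``.
    """
    n = len(sentence)
    if not (0 <= position < n):
        raise IndexError(f"position {position} out of range [0, {n})")
    cfg = config
    j = position
    feats: set[str] = {"b"}

    def w(off: int) -> str:
        if not _in_window(cfg, off):
            return _BOS if off < 0 else _EOS
        return _surf(sentence, j + off, cfg)

    def tag(off: int) -> str | None:
        if not _in_window(cfg, off):
            return _BOS if off < 0 else _EOS
        return _col(sentence, j + off, TAG_COL)

    def lemma(off: int) -> str | None:
        if not _in_window(cfg, off):
            return _BOS if off < 0 else _EOS
        return _col(sentence, j + off, LEMMA_COL)

    w0 = w(0)
    if cfg.use_word:
        ident = w0.lower() if cfg.normalize_terms else w0
        feats.add(f"w0={ident}")
    if cfg.use_class_feature:
        feats.add(f"cls={_word_class(w0)}")
    if cfg.use_ngrams:
        for g in char_ngrams(w0, cfg.max_ngram_leng, cfg.no_mid_ngrams):
            feats.add(f"ng={g}")
    if cfg.use_position:
        if j == 0:
            bucket = "first"
        elif j == n - 1:
            bucket = "last"
        else:
            bucket = "mid"
        feats.add(f"pos={bucket}")
    if cfg.use_prev:
        feats.add(f"w-1={w(-1)}")
    if cfg.use_next:
        feats.add(f"w+1={w(+1)}")
    if cfg.use_neighbor_ngrams:
        for off in (-1, +1):
            wn = w(off)
            if wn in (_BOS, _EOS):
                feats.add(f"nng[{off:+d}]={wn}")
                continue
            for g in char_ngrams(wn, cfg.max_ngram_leng, cfg.no_mid_ngrams):
                feats.add(f"nng[{off:+d}]={g}")
    if cfg.use_more_neighbor_ngrams:
        for off in (-2, +2):
            wn = w(off)
            if wn in (_BOS, _EOS):
                feats.add(f"nng[{off:+d}]={wn}")
                continue
            for g in char_ngrams(wn, cfg.max_ngram_leng, cfg.no_mid_ngrams):
                feats.add(f"nng[{off:+d}]={g}")
    if cfg.use_word_pairs:
        feats.add(f"wp={w(-1)}|{w0}")
        feats.add(f"wp={w0}|{w(+1)}")
    if cfg.use_sym_word_pairs:
        feats.add(f"swp={w(-1)}|{w(+1)}")
    if cfg.use_disjunctive:
        for off in range(1, min(4, cfg.max_left) + 1):
            feats.add(f"dl={w(-off)}")
        for off in range(1, min(4, cfg.max_right) + 1):
            feats.add(f"dr={w(+off)}")
    if cfg.use_wide_disjunctive:
        for off in range(1, min(8, cfg.max_left) + 1):
            feats.add(f"wdl={w(-off)}")
        for off in range(1, min(8, cfg.max_right) + 1):
            feats.add(f"wdr={w(+off)}")
    if cfg.use_sequences:
        feats.add(f"seq={w(-1)}|{w0}|{w(+1)}")
    if cfg.use_prev_sequences:
        feats.add(f"pseq={w(-1)}|{w0}")
    if cfg.use_next_sequences:
        feats.add(f"nseq={w0}|{w(+1)}")
    if cfg.use_long_sequences:
        feats.add(f"lseq={w(-2)}|{w(-1)}|{w0}|{w(+1)}")
    if cfg.use_tags:
        t0 = tag(0)
        if t0 is not None:
            feats.add(f"t0={t0}")
    if cfg.use_sym_tags:
        tm, tp = tag(-1), tag(+1)
        if tm is not None and tp is not None:
            feats.add(f"st={tm}|{tp}")
    if cfg.use_taggy_sequences:
        ts = [tag(-1), tag(0), tag(+1)]
        if all(t is not None for t in ts):
            feats.add("tseq=" + "|".join(ts))
    if cfg.use_word_tag:
        t0 = tag(0)
        if t0 is not None:
            feats.add(f"wt={w0}|{t0}")
    if cfg.use_lemmas:
        l0 = lemma(0)
        if l0 is not None:
            feats.add(f"l0={l0}")
    if cfg.use_prev_next_lemmas:
        lm, lp = lemma(-1), lemma(+1)
        if lm is not None:
            feats.add(f"l-1={lm}")
        if lp is not None:
            feats.add(f"l+1={lp}")
    shape_mode = cfg.word_shape
    if shape_mode != "none":
        sh0 = word_shape(w0, shape_mode)
        feats.add(f"sh={sh0}")
        if cfg.use_type_seqs:
            feats.add(f"ts={sh0}")
        if cfg.use_type_seqs2:
            prev_sh = w(-1)
            if prev_sh not in (_BOS, _EOS):
                prev_sh = word_shape(prev_sh, shape_mode)
            feats.add(f"ts2={prev_sh}|{sh0}")
        if cfg.use_typey_sequences:
            parts = []
            for off in (-1, 0, +1):
                ws = w(off)
                parts.append(
                    ws if ws in (_BOS, _EOS) else word_shape(ws, shape_mode)
                )
            feats.add("tys=" + "|".join(parts))
    if gazetteer is not None and cfg.use_gaz_features:
        for (phrase, etype) in gazetteer.entries:
            words = phrase.split(" ")
            k = len(words)
            for start in range(j - k + 1, j + 1):
                if start < 0 or start + k > n:
                    continue
                if not (_in_window(cfg, start - j) and _in_window(cfg, start + k - 1 - j)):
                    continue
                if [t.surface for t in sentence.tokens[start : start + k]] == words:
                    feats.add(f"gaz={etype}")
    if gazetteer is not None and cfg.sloppy_gazette:
        if w0 in gazetteer.unigrams():
            feats.add("gazw")
    return FeatureVector(frozenset(feats))
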