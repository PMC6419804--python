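"""Combining base sequence labelers: majority voting and a two-stage voter.

The two-stage voter trains each base learner on the training split
(hyper-optimizing it against the development split), then tags the
development split with every base and trains a second-level linear-chain
CRF whose only input features are the base-learner output labels per
position (optionally a +-window of neighboring outputs).  At prediction
time every base tags the input and the level-2 CRF decodes the stacked
rows.

Level-2 training data must be disjoint (at document level) from the base
training data: stacking on the bases' own training output would leak
optimistically biased base accuracy into the combiner.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, Sequence, runtime_checkable

from . import crf as crf_mod
from .corpus_io import Corpus, LabeledSentence, repair_iob
from .crf import CRFModel, LabelSet, TrainingInstance, viterbi_decode
from .evaluation import evaluate_corpus
from .features import FeatureConfig, FeatureVector, Gazetteer, extract_features
from .hyperopt import Configuration, ParameterSpace, optimize

logger = logging.getLogger(__name__)

__all__ = [
    "BaseLearner",
    "BaseSpec",
    "StackedRow",
    "CRFVoterModel",
    "majority_vote",
    "majority_vote_corpus",
    "build_stacked_rows",
    "stacked_rows_from_outputs",
    "fit_level2",
    "train_crfvoter",
    "predict",
    "save_voter",
    "load_voter",
    "split_configuration",
]

RESERVED_DIMS = ("penalty", "c")

# Accepted in search-space definitions for compatibility with historical
# tagger option inventories, but inert in this engine (no higher-order
# lattice, no beam pruning, no chunked training).
INERT_DIMS = frozenset(
    {
        "num_iterations",
        "beam_size",
        "order",
        "effective_order",
        "num_chunks",
        "prob_threshold",
        "quadratic_penalty",
    }
)


@runtime_checkable
class CorpusTagger(Protocol):
    learner_id: str

    def tag_corpus(self, corpus: Corpus) -> list[list[str]]: ...


@dataclass(frozen=True)
class StackedRow:
    """Ordered learner_id -> predicted tag at one position."""

    base_outputs: tuple[tuple[str, str], ...]

    def as_dict(self) -> dict[str, str]:
        return dict(self.base_outputs)


@dataclass
class BaseLearner:
    """A trained CRF base labeler with its feature configuration."""

    learner_id: str
    feature_config: FeatureConfig
    model: CRFModel
    gazetteer: Gazetteer | None = None

    def tag(self, sentence: LabeledSentence) -> list[str]:
        if self.model is None:
            raise RuntimeError(f"base learner {self.learner_id} is untrained")
        rows = [
            extract_features(sentence, j, self.feature_config, self.gazetteer)
            for j in range(len(sentence))
        ]
        return repair_iob(viterbi_decode(self.model, rows), warn=False)

    def tag_corpus(self, corpus: Corpus) -> list[list[str]]:
        return [self.tag(sent) for _, _, sent in corpus.sentences()]


@dataclass(frozen=True)
class BaseSpec:
    """Recipe for one base learner: its search space, method and budget."""

    learner_id: str
    space: ParameterSpace
    method: str = "tpe"
    budget: int = 10
    gazetteer: Gazetteer | None = None


@dataclass
class CRFVoterModel:
    base_learners: list  # CorpusTagger instances, order fixed
    level2: CRFModel
    stacking_window: int = 0

    @property
    def learner_ids(self) -> list[str]:
        return [b.learner_id for b in self.base_learners]


def majority_vote(
    per_position_tags: Sequence[Sequence[str]], prefer_o: bool = False
) -> list[str]:
    """Positionwise modal tag over l aligned tag sequences.

    Ties go to the first-listed learner carrying a tied tag (or to ``O``
    with ``prefer_o`` when O is among the tied tags).  The result is
    repaired to valid IOB2.
    """
    if not per_position_tags:
        raise ValueError("need at least one tag sequence")
    n = len(per_position_tags[0])
    if any(len(seq) != n for seq in per_position_tags):
        raise ValueError("alignment error: unequal sequence lengths")
    voted: list[str] = []
    for j in range(n):
        column = [seq[j] for seq in per_position_tags]
        counts = Counter(column)
        top = max(counts.values())
        tied = {t for t, c in counts.items() if c == top}
        if prefer_o and "O" in tied:
            voted.append("O")
            continue
        voted.append(next(t for t in column if t in tied))
    return repair_iob(voted, warn=False)


def majority_vote_corpus(
    outputs_per_learner: Sequence[Sequence[Sequence[str]]], prefer_o: bool = False
) -> list[list[str]]:
    """Sentence-wise majority vote over per-learner corpus outputs."""
    n_sent = len(outputs_per_learner[0])
    if any(len(o) != n_sent for o in outputs_per_learner):
        raise ValueError("alignment error: unequal sentence counts")
    return [
        majority_vote([o[i] for o in outputs_per_learner], prefer_o=prefer_o)
        for i in range(n_sent)
    ]


def stacked_rows_from_outputs(
    learner_ids: Sequence[str],
    outputs: Sequence[Sequence[str]],
    window: int = 0,
) -> list[FeatureVector]:
    """Feature rows from aligned base outputs for one sentence.

    Position j carries ``<id>[+0]=<tag>`` for every learner, plus the
    outputs at offsets up to +-window; out-of-range offsets emit nothing,
    so the distinct-feature inventory stays within
    l * (2*window + 1) * |labels| strings.
    """
    n = len(outputs[0])
    if any(len(o) != n for o in outputs):
        raise ValueError("alignment error")
    rows: list[FeatureVector] = []
    for j in range(n):
        feats = set()
        for lid, out in zip(learner_ids, outputs):
            for off in range(-window, window + 1):
                k = j + off
                if 0 <= k < n:
                    feats.add(f"{lid}[{off:+d}]={out[k]}")
        rows.append(FeatureVector(frozenset(feats)))
    return rows


def build_stacked_rows(
    base_learners: Sequence[BaseLearner],
    sentence: LabeledSentence,
    window: int = 0,
) -> list[StackedRow]:
    """Per-position base-learner output rows for one sentence."""
    outputs = [b.tag(sentence) for b in base_learners]
    ids = [b.learner_id for b in base_learners]
    return [
        StackedRow(tuple((lid, out[j]) for lid, out in zip(ids, outputs)))
        for j in range(len(sentence))
    ]


def split_configuration(
    config: Configuration,
) -> tuple[FeatureConfig, str, float]:
    """Split a search-space point into (FeatureConfig, penalty kind, cost c).

    Dimensions named ``penalty`` and ``c`` are reserved for the trainer;
    all others must be FeatureConfig fields.
    """
    d = config.as_dict()
    penalty = str(d.pop("penalty", "L2")).removeprefix("CRF-")
    c = float(d.pop("c", 1.0))
    dropped = [k for k in d if k in INERT_DIMS]
    for k in dropped:
        d.pop(k)
    if dropped:
        logger.warning("ignoring inert hyperparameter(s): %s", sorted(dropped))
    return FeatureConfig.from_dict(d), penalty, c


def _corpus_instances(
    corpus: Corpus, fc: FeatureConfig, gazetteer: Gazetteer | None
) -> list[TrainingInstance]:
    out = []
    for _, _, sent in corpus.sentences():
        rows = tuple(
            extract_features(sent, j, fc, gazetteer) for j in range(len(sent))
        )
        out.append(TrainingInstance(rows, tuple(sent.labels)))
    return out


def _gold_label_set(*corpora: Corpus) -> LabelSet:
    seen: list[str] = ["O"]
    for corpus in corpora:
        for _, _, sent in corpus.sentences():
            for lab in sent.labels:
                if lab not in seen:
                    seen.append(lab)
    return LabelSet(tuple(seen))


def fit_level2(
    taggers: Sequence[CorpusTagger],
    dev: Corpus,
    penalty_kind: str = "L2",
    cost_c: float = 15.0,
    stacking_window: int = 0,
    label_set: LabelSet | None = None,
) -> CRFVoterModel:
    """Train the level-2 CRF on base outputs over the development corpus."""
    if dev.n_sentences() == 0:
        raise ValueError("insufficient data: empty development corpus")
    if label_set is None:
        label_set = _gold_label_set(dev)
    ids = [t.learner_id for t in taggers]
    if len(set(ids)) != len(ids):
        raise ValueError("learner_id values must be unique")
    outputs = [t.tag_corpus(dev) for t in taggers]
    instances = []
    for i, (_, _, sent) in enumerate(dev.sentences()):
        rows = stacked_rows_from_outputs(
            ids, [o[i] for o in outputs], stacking_window
        )
        instances.append(TrainingInstance(tuple(rows), tuple(sent.labels)))
    level2 = crf_mod.train(
        instances, penalty_kind=penalty_kind, cost_c=cost_c, label_set=label_set
    )
    return CRFVoterModel(list(taggers), level2, stacking_window)


def train_crfvoter(
    train: Corpus,
    dev: Corpus,
    base_specs: Sequence[BaseSpec],
    level2_penalty: str = "L2",
    level2_c: float = 15.0,
    stacking_window: int = 0,
    seed: int = 0,
) -> tuple[CRFVoterModel, dict]:
    """Full two-stage training: optimize + train bases, then stack on dev.

    Returns the voter model and a diagnostics dict with per-base
    optimization reports and dev F1 values.  Deterministic given seed.
    """
    if dev.n_sentences() == 0:
        raise ValueError("insufficient data: empty development corpus")
    train_ids = {d.doc_id for d in train.documents}
    dev_ids = {d.doc_id for d in dev.documents}
    if train_ids & dev_ids:
        raise ValueError("train and dev must be disjoint at document level")
    label_set = _gold_label_set(train, dev)
    learners: list[BaseLearner] = []
    diagnostics: dict = {"bases": {}}
    for i, spec in enumerate(base_specs):

        def objective(config: Configuration) -> float:
            fc, penalty, c = split_configuration(config)
            model = crf_mod.train(
                _corpus_instances(train, fc, spec.gazetteer),
                penalty_kind=penalty,
                cost_c=c,
                label_set=label_set,
            )
            learner = BaseLearner(spec.learner_id, fc, model, spec.gazetteer)
            return evaluate_corpus(dev, learner.tag_corpus(dev)).overall.f1

        report = optimize(
            spec.space,
            objective,
            method=spec.method,
            budget=spec.budget,
            seed=seed + 1000 * (i + 1),
        )
        fc, penalty, c = split_configuration(report.best.config)
        model = crf_mod.train(
            _corpus_instances(train, fc, spec.gazetteer),
            penalty_kind=penalty,
            cost_c=c,
            label_set=label_set,
        )
        learners.append(BaseLearner(spec.learner_id, fc, model, spec.gazetteer))
        diagnostics["bases"][spec.learner_id] = {
            "best_metric": report.best.metric,
            "best_config": report.best.config.as_dict(),
            "n_trials": len(report.trials),
        }
    voter = fit_level2(
        learners,
        dev,
        penalty_kind=level2_penalty,
        cost_c=level2_c,
        stacking_window=stacking_window,
        label_set=label_set,
    )
    return voter, diagnostics


def save_voter(model: CRFVoterModel, directory: str | Path) -> Path:
    """Persist a voter whose bases are CRF-backed :class:`BaseLearner` s."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {"stacking_window": model.stacking_window, "learners": []}
    for b in model.base_learners:
        if not isinstance(b, BaseLearner):
            raise TypeError(
                f"cannot persist non-CRF base learner {b.learner_id!r}"
            )
        bdir = directory / "bases" / b.learner_id
        bdir.mkdir(parents=True, exist_ok=True)
        (bdir / "feature_config.json").write_text(
            json.dumps(b.feature_config.to_dict(), indent=2), encoding="utf-8"
        )
        b.model.save(bdir / "crf")
        if b.gazetteer is not None:
            with (bdir / "gazetteer.tsv").open("w", encoding="utf-8") as fh:
                for phrase, etype in sorted(b.gazetteer.entries):
                    fh.write(f"{phrase}\t{etype}\n")
        meta["learners"].append(b.learner_id)
    model.level2.save(directory / "level2")
    (directory / "meta.json").write_text(json.dumps(meta, indent=2), encoding="utf-8")
    return directory


def load_voter(directory: str | Path) -> CRFVoterModel:
    directory = Path(directory)
    meta = json.loads((directory / "meta.json").read_text(encoding="utf-8"))
    learners = []
    for lid in meta["learners"]:
        bdir = directory / "bases" / lid
        fc = FeatureConfig.from_json(bdir / "feature_config.json")
        gaz_path = bdir / "gazetteer.tsv"
        gaz = Gazetteer.read_tsv(gaz_path) if gaz_path.exists() else None
        learners.append(BaseLearner(lid, fc, CRFModel.load(bdir / "crf"), gaz))
    level2 = CRFModel.load(directory / "level2")
    return CRFVoterModel(learners, level2, meta["stacking_window"])


def predict(model: CRFVoterModel, corpus: Corpus) -> list[list[str]]:
    """Tag a corpus: run every base, stack, Viterbi-decode the level-2 CRF."""
    sents = list(corpus.sentences())
    if not sents:
        return []
    ids = model.learner_ids
    outputs = [t.tag_corpus(corpus) for t in model.base_learners]
    predictions: list[list[str]] = []
    for i, (_, _, sent) in enumerate(sents):
        rows = stacked_rows_from_outputs(
            ids, [o[i] for o in outputs], model.stacking_window
        )
        predictions.append(
            repair_iob(viterbi_decode(model.level2, rows), warn=False)
        )
    return predictions
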