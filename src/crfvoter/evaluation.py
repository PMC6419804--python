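"""Entity-level scoring, pairwise output difference, and McNemar's test.

Matching is strict: a predicted mention is a true positive iff it matches a
gold mention exactly on (doc, sentence, start, end, type).  Zero
denominators give P = R = F1 = 0 so every metric is total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Sequence

from scipy.stats import chi2, binomtest

from .corpus_io import Corpus, EntityMention, iob_to_spans

__all__ = [
    "EvalCounts",
    "MetricsReport",
    "McNemarResult",
    "match_entities",
    "compute_metrics",
    "f1_score",
    "evaluate_corpus",
    "pairwise_difference",
    "mcnemar_test",
    "round_report",
]


@dataclass(frozen=True)
class EvalCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    def __add__(self, other: "EvalCounts") -> "EvalCounts":
        return EvalCounts(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)


@dataclass(frozen=True)
class Metrics:
    precision: float
    recall: float
    f1: float
    counts: EvalCounts


@dataclass
class MetricsReport:
    overall: Metrics
    per_type: dict[str, Metrics] = field(default_factory=dict)

    def to_dict(self) -> dict:
        def one(m: Metrics) -> dict:
            return {
                "precision": m.precision,
                "recall": m.recall,
                "f1": m.f1,
                "tp": m.counts.tp,
                "fp": m.counts.fp,
                "fn": m.counts.fn,
            }

        return {
            "overall": one(self.overall),
            "per_type": {t: one(m) for t, m in sorted(self.per_type.items())},
        }


@dataclass(frozen=True)
class McNemarResult:
    b: int
    c: int
    statistic: float
    significant_at_alpha: bool
    alpha: float
    undefined: bool = False
    p_value: float | None = None


def match_entities(
    gold: Iterable[EntityMention], predicted: Iterable[EntityMention]
) -> EvalCounts:
    """Exact-match TP/FP/FN over (doc, sentence, span, type)."""
    gold, predicted = set(gold), set(predicted)
    tp = len(gold & predicted)
    return EvalCounts(tp=tp, fp=len(predicted) - tp, fn=len(gold) - tp)


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def compute_metrics(counts: EvalCounts) -> Metrics:
    """P = TP/(TP+FP), R = TP/(TP+FN), F1 harmonic mean; 0 on empty denominators."""
    p = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else 0.0
    r = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else 0.0
    return Metrics(precision=p, recall=r, f1=f1_score(p, r), counts=counts)


def evaluate_corpus(
    gold: Corpus,
    predicted_labels: Sequence[Sequence[str]],
    extra_gold: Iterable[EntityMention] = (),
    collapse_types: bool = False,
) -> MetricsReport:
    """Score predicted tag sequences (aligned with ``gold.sentences()``).

    ``extra_gold`` adds gold mentions that carry no trainable labels (the
    sub-token cases); they count as false negatives unless matched.  With
    ``collapse_types`` all entity types are merged before matching.
    """
    gold_mentions = set(gold.mentions()) | set(extra_gold)
    pred_mentions: set[EntityMention] = set()
    sents = list(gold.sentences())
    if len(sents) != len(predicted_labels):
        raise ValueError(
            f"{len(predicted_labels)} predictions for {len(sents)} sentences"
        )
    for (doc_id, i, sent), labels in zip(sents, predicted_labels):
        if len(labels) != len(sent):
            raise ValueError("prediction length mismatch")
        pred_mentions |= iob_to_spans(labels, doc_id=doc_id, sentence_index=i)
    if collapse_types:
        def collapse(ms):
            return {
                EntityMention(m.doc_id, m.sentence_index, m.start_token, m.end_token, "ENT")
                for m in ms
            }
        gold_mentions, pred_mentions = collapse(gold_mentions), collapse(pred_mentions)
    overall = compute_metrics(match_entities(gold_mentions, pred_mentions))
    per_type: dict[str, Metrics] = {}
    for etype in sorted(
        {m.entity_type for m in gold_mentions} | {m.entity_type for m in pred_mentions}
    ):
        g = {m for m in gold_mentions if m.entity_type == etype}
        p = {m for m in pred_mentions if m.entity_type == etype}
        per_type[etype] = compute_metrics(match_entities(g, p))
    return MetricsReport(overall=overall, per_type=per_type)


def pairwise_difference(
    tags_a: Sequence[Sequence[str]] | Sequence[str],
    tags_b: Sequence[Sequence[str]] | Sequence[str],
) -> float:
    """Percentage of token positions at which two outputs disagree."""
    flat_a = _flatten(tags_a)
    flat_b = _flatten(tags_b)
    if len(flat_a) != len(flat_b):
        raise ValueError(f"alignment error: {len(flat_a)} vs {len(flat_b)} tokens")
    if not flat_a:
        return 0.0
    diff = sum(1 for a, b in zip(flat_a, flat_b) if a != b)
    return 100.0 * diff / len(flat_a)


def _flatten(tags) -> list[str]:
    if tags and isinstance(tags[0], str):
        return list(tags)
    return [t for seq in tags for t in seq]


def _span_correct(
    mention: EntityMention,
    labels_by_sentence: Mapping[tuple[str, int], Sequence[str]],
    gold_by_sentence: Mapping[tuple[str, int], Sequence[str]],
) -> bool:
    key = (mention.doc_id, mention.sentence_index)
    sys_tags = labels_by_sentence[key]
    gold_tags = gold_by_sentence[key]
    sl = slice(mention.start_token, mention.end_token)
    return list(sys_tags[sl]) == list(gold_tags[sl])


def mcnemar_test(
    gold: Corpus,
    sys1: Sequence[Sequence[str]],
    sys2: Sequence[Sequence[str]],
    alpha: float = 0.05,
    exact: bool = False,
) -> McNemarResult:
    """McNemar's test on span-level labeling disagreements.

    A system is "positive" on a gold mention iff its tags over the mention
    span exactly reproduce the gold tags.  b counts mentions correct in
    system 1 only, c in system 2 only.  The default statistic is the
    continuity-corrected chi-square  (|b-c|-1)^2/(b+c)  against the
    chi-square(1) critical value; ``exact`` switches to the binomial test.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    sents = list(gold.sentences())
    if len(sents) != len(sys1) or len(sents) != len(sys2):
        raise ValueError("alignment error: prediction count != sentence count")
    gold_by = {(d, i): s.labels for d, i, s in sents}
    sys1_by = {(d, i): labels for (d, i, _), labels in zip(sents, sys1)}
    sys2_by = {(d, i): labels for (d, i, _), labels in zip(sents, sys2)}
    b = c = 0
    for m in gold.mentions():
        ok1 = _span_correct(m, sys1_by, gold_by)
        ok2 = _span_correct(m, sys2_by, gold_by)
        if ok1 and not ok2:
            b += 1
        elif ok2 and not ok1:
            c += 1
    if b + c == 0:
        return McNemarResult(0, 0, 0.0, False, alpha, undefined=True)
    if exact:
        res = binomtest(b, b + c, 0.5)
        return McNemarResult(
            b, c, float("nan"), res.pvalue < alpha, alpha, p_value=float(res.pvalue)
        )
    stat = (abs(b - c) - 1) ** 2 / (b + c)
    crit = float(chi2.ppf(1.0 - alpha, df=1))
    p_value = float(chi2.sf(stat, df=1))
    return McNemarResult(b, c, stat, stat > crit, alpha, p_value=p_value)


def round_report(value: float, ndigits: int = 2) -> float:
    """Half-up rounding for printed reports (0.755 -> 0.76)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))
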