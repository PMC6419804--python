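# crfvoter

Stacked linear-chain CRF ensembles for gene/protein named-entity
recognition, built to be testable at desk scale without any external
corpus or third-party tagger:

* **corpus_io** — CoNLL-style TSV corpora with IOB2 labels, span/tag
  conversion with total IOB repair, sub-token gold-mention filtering,
  seeded document-level 60/20/20 splits.
* **features** — a configurable sparse feature-template engine (word
  identity, character n-grams, neighbor windows, word pairs, shape and
  tag sequences, disjunctive windows, gazetteers) whose switch set mirrors
  classic CRF-tagger option inventories so base learners can be
  diversified and hyper-optimized.
* **crf** — a from-scratch linear-chain CRF: log-space forward/backward
  partition function, Viterbi decoding with a fixed tie rule, and
  penalized maximum-likelihood training (L2 via L-BFGS, L1 via exact
  non-negative splitting under bounds).
* **hyperopt** — exhaustive grid search, random search, and a
  from-scratch Tree-structured Parzen Estimator that splits trial history
  into good/bad groups and proposes the candidate maximizing the l/g
  density ratio.
* **ensemble** — positionwise majority voting and the two-stage voter:
  base learners are optimized and trained on the training split, then a
  second-level CRF is trained on a disjoint development split using only
  the base-learner output labels as features.
* **evaluation** — strict entity-level TP/FP/FN with P/R/F1 and per-type
  breakdown, pairwise token-difference percentages, and McNemar's
  continuity-corrected chi-square test on span-level disagreements.
* **synthetic_data** — a seeded generator of GPRO-like corpora (typed
  multi-token mentions, configurable class mixture, sub-token special
  cases) and of simulated tagger outputs with controllable, complementary
  error structure.

## CLI

All commands are subcommands of `crfvoter` (JSON configs throughout):

```bash
# synthetic corpus: train/dev/test TSV plus character-offset gold sidecar
crfvoter generate --config gen.json --out corpus/

# hyper-optimize one CRF base learner against dev F1
crfvoter optimize --space space.json --method tpe --budget 200 --seed 1 \
    --train corpus/train.tsv --dev corpus/dev.tsv --out trials.jsonl

# two-stage voter: optimize + train bases, stack on dev, persist
crfvoter train --train corpus/train.tsv --dev corpus/dev.tsv \
    --bases bases.json --seed 1 --out model/
crfvoter predict --model model/ --in corpus/test.tsv --out pred.tsv

# combine existing prediction TSVs
crfvoter vote --inputs a.tsv --inputs b.tsv --inputs c.tsv --out voted.tsv
crfvoter stack --dev-gold corpus/dev.tsv --dev-preds a_dev.tsv \
    --test-preds a_test.tsv --out stacked.tsv

# scoring and system comparison
crfvoter evaluate --gold corpus/test.tsv --pred pred.tsv --per-type
crfvoter compare --gold corpus/test.tsv --a pred_a.tsv --b pred_b.tsv

# end-to-end demo on the complementary-error benchmark
crfvoter pipeline --config run.json --out rundir/
```

A search space is a JSON object like

```json
{
  "use_word": {"type": "cat", "values": [true]},
  "use_ngrams": {"type": "cat", "values": [true, false]},
  "c": {"type": "cat", "values": [0.6, 1, 1.6, 3, 5, 7, 15, 50, 100, 1000]},
  "penalty": {"type": "cat", "values": ["CRF-L1", "CRF-L2"]}
}
```

where `penalty` and `c` are reserved for the trainer and all other
dimensions name feature switches.

## TSV dialect

UTF-8, one token per line, tab-separated, IOB2 label in the last column;
blank line between sentences; `#doc <id>` lines mark document
boundaries. Optional middle columns carry lemma (column 1) and POS tag
(column 2) which feature switches such as `use_tags`/`use_lemmas` read
when present.
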