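import numpy as np
import pytest

from crfvoter import crf as crf_mod
from crfvoter.corpus_io import Corpus, Document, LabeledSentence, Token
from crfvoter.ensemble import (
    BaseLearner,
    BaseSpec,
    build_stacked_rows,
    fit_level2,
    load_voter,
    majority_vote,
    majority_vote_corpus,
    predict,
    save_voter,
    split_configuration,
    stacked_rows_from_outputs,
    train_crfvoter,
)
from crfvoter.evaluation import evaluate_corpus
from crfvoter.features import FeatureConfig
from crfvoter.hyperopt import Categorical, Configuration, ParameterSpace
from crfvoter.synthetic_data import (
    ErrorProfile,
    GeneratorConfig,
    SimulatedLearner,
    generate_corpus,
    make_complementary_benchmark,
)

UNIFORM3 = {"ABBREVIATION": 1 / 3, "FULLNAME": 1 / 3, "FAMILY": 1 / 3}


class TestMajorityVote:
    def test_modal_tag(self):
        assert majority_vote([["B-X"], ["B-X"], ["O"]]) == ["B-X"]

    def test_two_way_tie_first_listed_wins(self):
        assert majority_vote([["B-X"], ["O"]]) == ["B-X"]
        assert majority_vote([["O"], ["B-X"]]) == ["O"]

    def test_prefer_o_mode(self):
        assert majority_vote([["B-X"], ["O"]], prefer_o=True) == ["O"]

    def test_unanimous_gold(self):
        gold = ["B-X", "I-X", "O"]
        assert majority_vote([gold, gold, gold]) == gold

    def test_output_repaired_to_valid_iob2(self):
        # per-position votes can produce I- after O; repair must fix it
        voted = majority_vote(
            [["O", "I-X"], ["O", "I-X"], ["B-X", "O"]]
        )
        assert voted == ["O", "B-X"]

    def test_alignment_error(self):
        with pytest.raises(ValueError):
            majority_vote([["O"], ["O", "O"]])

    def test_empty_learner_list(self):
        with pytest.raises(ValueError):
            majority_vote([])


class TestStackedRows:
    def test_direct_construction(self):
        rows = stacked_rows_from_outputs(
            ["c1", "c2", "c3"], [["B-X"], ["O"], ["B-X"]], window=0
        )
        assert set(rows[0]) == {"c1[+0]=B-X", "c2[+0]=O", "c3[+0]=B-X"}

    def test_window_adds_positional_prefixes(self):
        rows = stacked_rows_from_outputs(
            ["c1"], [["B-X", "I-X", "O"]], window=1
        )
        assert set(rows[1]) == {"c1[-1]=B-X", "c1[+0]=I-X", "c1[+1]=O"}
        # boundary positions omit out-of-range offsets
        assert set(rows[0]) == {"c1[+0]=B-X", "c1[+1]=I-X"}

    def test_row_count_equals_length(self):
        outs = [["O"] * 7, ["O"] * 7]
        assert len(stacked_rows_from_outputs(["a", "b"], outs)) == 7

    def test_feature_inventory_bound(self):
        # l * (2w+1) * |labels| distinct strings at most
        rng = np.random.default_rng(0)
        labels = ["O", "B-X", "I-X"]
        l, w, n = 3, 1, 50
        outs = [[str(rng.choice(labels)) for _ in range(n)] for _ in range(l)]
        rows = stacked_rows_from_outputs([f"c{i}" for i in range(l)], outs, window=w)
        inventory = {f for row in rows for f in row}
        assert len(inventory) <= l * (2 * w + 1) * len(labels)

    def test_alignment_error(self):
        with pytest.raises(ValueError):
            stacked_rows_from_outputs(["a", "b"], [["O"], ["O", "O"]])


def _labeled(tokens, labels):
    return LabeledSentence([Token(t) for t in tokens], labels)


class TestSplitConfiguration:
    def test_reserved_dims(self):
        cfg = Configuration.from_dict(
            {"use_word": True, "penalty": "CRF-L1", "c": 15}
        )
        fc, penalty, c = split_configuration(cfg)
        assert fc.use_word is True
        assert penalty == "L1" and c == 15.0

    def test_inert_dims_dropped_with_warning(self, caplog):
        cfg = Configuration.from_dict({"use_word": True, "beam_size": 5, "order": 3})
        with caplog.at_level("WARNING"):
            fc, _, _ = split_configuration(cfg)
        assert fc.use_word is True
        assert any("inert" in r.message for r in caplog.records)

    def test_unknown_dim_rejected(self):
        with pytest.raises(Exception):
            split_configuration(Configuration.from_dict({"bogus": 1}))


@pytest.fixture(scope="module")
def sim_setup():
    cfg = GeneratorConfig(
        n_documents=120, entity_type_weights=UNIFORM3, subtoken_case_rate=0.0, seed=3
    )
    return make_complementary_benchmark(cfg, 3, seed=21)


class TestFitLevel2:
    def test_perfect_bases_learn_identity(self, sim_setup):
        train, dev, test, _ = sim_setup
        perfect = [
            SimulatedLearner(ErrorProfile(f"p{i}", seed=i)) for i in range(3)
        ]
        voter = fit_level2(perfect, dev)
        report = evaluate_corpus(test, predict(voter, test))
        assert report.overall.f1 == 1.0

    def test_single_base_close_to_that_base(self):
        # miss-only errors: the level-2 CRF should learn the identity map
        cfg = GeneratorConfig(
            n_documents=250, entity_type_weights=UNIFORM3,
            subtoken_case_rate=0.0, seed=17,
        )
        from crfvoter.corpus_io import split_corpus

        corpus, _ = generate_corpus(cfg)
        _, dev, test = split_corpus(corpus, (0.6, 0.2, 0.2), seed=2)
        learner = SimulatedLearner(
            ErrorProfile("solo", per_type_miss_rate={t: 0.3 for t in UNIFORM3}, seed=9)
        )
        voter = fit_level2([learner], dev)
        base_f1 = evaluate_corpus(test, learner.tag_corpus(test)).overall.f1
        ens_f1 = evaluate_corpus(test, predict(voter, test)).overall.f1
        assert abs(ens_f1 - base_f1) <= 0.02

    def test_complementary_bases_beat_each_base_and_vote(self, sim_setup):
        train, dev, test, profiles = sim_setup
        learners = [SimulatedLearner(p) for p in profiles]
        outputs = [l.tag_corpus(test) for l in learners]
        base_f1 = [evaluate_corpus(test, o).overall.f1 for o in outputs]
        mv_f1 = evaluate_corpus(test, majority_vote_corpus(outputs)).overall.f1
        voter = fit_level2(learners, dev)
        ens_f1 = evaluate_corpus(test, predict(voter, test)).overall.f1
        assert all(ens_f1 > b for b in base_f1)
        assert ens_f1 > mv_f1

    def test_determinism(self, sim_setup):
        train, dev, test, profiles = sim_setup
        learners = [SimulatedLearner(p) for p in profiles]
        v1 = fit_level2(learners, dev)
        v2 = fit_level2(learners, dev)
        assert np.array_equal(v1.level2.W, v2.level2.W)
        assert predict(v1, test) == predict(v2, test)

    def test_empty_dev_rejected(self, sim_setup):
        with pytest.raises(ValueError, match="nsufficient"):
            fit_level2([SimulatedLearner(ErrorProfile("x"))], Corpus([]))

    def test_duplicate_learner_ids_rejected(self, sim_setup):
        _, dev, _, _ = sim_setup
        dup = [SimulatedLearner(ErrorProfile("same")), SimulatedLearner(ErrorProfile("same"))]
        with pytest.raises(ValueError, match="unique"):
            fit_level2(dup, dev)

    def test_predict_empty_corpus(self, sim_setup):
        _, dev, _, _ = sim_setup
        voter = fit_level2([SimulatedLearner(ErrorProfile("x"))], dev)
        assert predict(voter, Corpus([])) == []

    def test_prediction_lengths_match(self, sim_setup):
        _, dev, test, profiles = sim_setup
        voter = fit_level2([SimulatedLearner(profiles[0])], dev)
        preds = predict(voter, test)
        for (_, _, sent), tags in zip(test.sentences(), preds):
            assert len(tags) == len(sent)


WORD_SPACE = ParameterSpace.from_dict(
    {
        "use_word": Categorical((True,)),
        "use_prev": Categorical((True, False)),
        "penalty": Categorical(("CRF-L2",)),
        "c": Categorical((15,)),
    }
)


@pytest.fixture(scope="module")
def small_crf_corpora():
    # small lexica so word-identity features generalize from little data
    cfg = GeneratorConfig(
        n_documents=40,
        sentences_per_doc=(2, 3),
        tokens_per_sentence=(5, 8),
        entity_type_weights=UNIFORM3,
        entity_lexicon_size=12,
        background_lexicon_size=40,
        subtoken_case_rate=0.0,
        seed=13,
    )
    from crfvoter.corpus_io import split_corpus

    corpus, _ = generate_corpus(cfg)
    return split_corpus(corpus, (0.6, 0.2, 0.2), seed=1)


class TestTrainCrfvoter:
    def test_end_to_end_with_crf_bases(self, small_crf_corpora):
        train_c, dev_c, test_c = small_crf_corpora
        specs = [
            BaseSpec("w", WORD_SPACE, method="random", budget=2),
            BaseSpec(
                "shape",
                ParameterSpace.from_dict(
                    {
                        "use_word": Categorical((False,)),
                        "use_ngrams": Categorical((True,)),
                        "word_shape": Categorical(("chris2uselc",)),
                        "penalty": Categorical(("CRF-L2",)),
                        "c": Categorical((15,)),
                    }
                ),
                method="grid",
            ),
        ]
        voter, diagnostics = train_crfvoter(train_c, dev_c, specs, seed=0)
        assert set(diagnostics["bases"]) == {"w", "shape"}
        preds = predict(voter, test_c)
        report = evaluate_corpus(test_c, preds)
        # entity lexica are (near-)disjoint from background: should be high
        assert report.overall.f1 > 0.5

    def test_train_dev_overlap_rejected(self, small_crf_corpora):
        train_c, dev_c, _ = small_crf_corpora
        with pytest.raises(ValueError, match="disjoint"):
            train_crfvoter(train_c, train_c, [BaseSpec("w", WORD_SPACE)], seed=0)

    def test_build_stacked_rows_from_base_learners(self, small_crf_corpora):
        train_c, dev_c, _ = small_crf_corpora
        fc = FeatureConfig(use_word=True)
        from crfvoter.ensemble import _corpus_instances

        model = crf_mod.train(
            _corpus_instances(train_c, fc, None), cost_c=15.0
        )
        learner = BaseLearner("b1", fc, model)
        sent = dev_c.documents[0].sentences[0]
        rows = build_stacked_rows([learner], sent)
        assert len(rows) == len(sent)
        tags = learner.tag(sent)
        assert rows[0].as_dict() == {"b1": tags[0]}


class TestVoterPersistence:
    def test_save_load_round_trip(self, small_crf_corpora, tmp_path):
        train_c, dev_c, test_c = small_crf_corpora
        specs = [BaseSpec("w", WORD_SPACE, method="random", budget=1)]
        voter, _ = train_crfvoter(train_c, dev_c, specs, seed=5)
        save_voter(voter, tmp_path / "model")
        again = load_voter(tmp_path / "model")
        assert predict(again, test_c) == predict(voter, test_c)

    def test_simulated_bases_not_persistable(self, sim_setup, tmp_path):
        _, dev, _, profiles = sim_setup
        voter = fit_level2([SimulatedLearner(profiles[0])], dev)
        with pytest.raises(TypeError):
            save_voter(voter, tmp_path / "m")
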