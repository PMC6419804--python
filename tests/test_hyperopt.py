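import math

import numpy as np
import pytest
from scipy.stats import kstwobign

from crfvoter.hyperopt import (
    Categorical,
    Configuration,
    FloatRange,
    InsufficientHistoryError,
    IntRange,
    OptimizationReport,
    ParameterSpace,
    TPESettings,
    Trial,
    UnsupportedSpaceError,
    grid_search,
    optimize,
    random_search,
    tpe_split,
    tpe_suggest,
)

CRFPP_SPACE = ParameterSpace.from_dict(
    {
        "c": Categorical((0.6, 1, 1.6, 3, 5, 7, 15, 50, 100, 1000)),
        "penalty": Categorical(("CRF-L1", "CRF-L2")),
    }
)


class TestGridSearch:
    def test_crfpp_space_has_20_trials(self):
        best, trials = grid_search(CRFPP_SPACE, lambda cfg: 0.5)
        assert len(trials) == 20

    def test_single_config_space(self):
        space = ParameterSpace.from_dict({"x": Categorical((1,))})
        best, trials = grid_search(space, lambda cfg: 0.7)
        assert len(trials) == 1 and best is trials[0]

    def test_best_equals_max(self):
        best, trials = grid_search(CRFPP_SPACE, lambda cfg: cfg["c"] / 1000.0)
        assert best.metric == max(t.metric for t in trials)
        assert best.config["c"] == 1000

    def test_continuous_dimension_rejected(self):
        space = ParameterSpace.from_dict({"x": FloatRange(0.0, 1.0)})
        with pytest.raises(UnsupportedSpaceError):
            grid_search(space, lambda cfg: 0.0)

    def test_trial_count_is_cardinality_product(self):
        space = ParameterSpace.from_dict(
            {"a": Categorical((1, 2, 3)), "b": IntRange(0, 4), "c": Categorical(("x", "y"))}
        )
        _, trials = grid_search(space, lambda cfg: 0.0)
        assert len(trials) == 3 * 5 * 2

    def test_tie_breaks_to_lowest_index(self):
        best, trials = grid_search(CRFPP_SPACE, lambda cfg: 1.0)
        assert best.trial_index == 0

    def test_lexicographic_order(self):
        space = ParameterSpace.from_dict(
            {"a": Categorical((1, 2)), "b": Categorical(("x", "y"))}
        )
        _, trials = grid_search(space, lambda cfg: 0.0)
        combos = [(t.config["a"], t.config["b"]) for t in trials]
        assert combos == [(1, "x"), (1, "y"), (2, "x"), (2, "y")]


class TestRandomSearch:
    SPACE = ParameterSpace.from_dict(
        {"x": FloatRange(0.0, 1.0), "k": IntRange(1, 5), "c": Categorical(("a", "b"))}
    )

    def test_budget_one(self):
        _, trials = random_search(self.SPACE, lambda cfg: 0.0, budget=1, seed=0)
        assert len(trials) == 1

    def test_determinism(self):
        _, t1 = random_search(self.SPACE, lambda cfg: 0.0, budget=20, seed=5)
        _, t2 = random_search(self.SPACE, lambda cfg: 0.0, budget=20, seed=5)
        assert [t.config.as_dict() for t in t1] == [t.config.as_dict() for t in t2]

    def test_values_in_domain(self):
        _, trials = random_search(self.SPACE, lambda cfg: 0.0, budget=200, seed=1)
        for t in trials:
            assert 0.0 <= t.config["x"] <= 1.0
            assert 1 <= t.config["k"] <= 5
            assert t.config["c"] in ("a", "b")

    def test_continuous_dimension_uniform_ks(self):
        space = ParameterSpace.from_dict({"x": FloatRange(0.0, 1.0)})
        _, trials = random_search(space, lambda cfg: 0.0, budget=10_000, seed=42)
        xs = np.sort([t.config["x"] for t in trials])
        n = len(xs)
        ecdf = np.arange(1, n + 1) / n
        ks = max(np.max(np.abs(ecdf - xs)), np.max(np.abs(xs - (ecdf - 1 / n))))
        crit = kstwobign.ppf(0.99) / math.sqrt(n)  # 1% critical value
        assert ks < crit


def make_trials(metrics):
    return [
        Trial(Configuration.from_dict({"x": float(i)}), m, i)
        for i, m in enumerate(metrics)
    ]


class TestTpeSplit:
    def test_top_quantile(self):
        trials = make_trials([0.1, 0.9, 0.3, 0.8, 0.2, 0.5, 0.4, 0.7, 0.6, 0.0])
        good, bad = tpe_split(trials, gamma=0.2)
        assert {t.metric for t in good} == {0.9, 0.8}

    def test_all_equal_tie_by_index(self):
        trials = make_trials([0.5] * 6)
        good, bad = tpe_split(trials, gamma=0.25)
        assert good and bad
        assert [t.trial_index for t in good] == [0, 1]

    def test_conservation(self):
        trials = make_trials([0.3, 0.1, 0.9, 0.6, 0.2])
        good, bad = tpe_split(trials, gamma=0.4)
        assert sorted(t.trial_index for t in good + bad) == list(range(5))
        assert not ({t.trial_index for t in good} & {t.trial_index for t in bad})

    def test_insufficient_history(self):
        with pytest.raises(InsufficientHistoryError):
            tpe_split(make_trials([0.1]), gamma=0.25)


class TestTpeSuggest:
    def test_identical_groups_returns_first_candidate(self):
        space = ParameterSpace.from_dict({"x": Categorical(("a", "b"))})
        # duplicated history -> l and g fit identical densities
        trials = make_trials([0.5] * 4)
        trials = [
            Trial(Configuration.from_dict({"x": "a" if i % 2 else "b"}), 0.5, i)
            for i in range(4)
        ]
        settings = TPESettings(gamma=0.5, n_startup=2, n_candidates=8, seed=3)
        rng = np.random.default_rng(3)
        got = tpe_suggest(trials, space, settings, rng=rng)
        # EI == 1 everywhere, so the proposal is the first candidate drawn
        # from l with an identically-seeded rng
        rng2 = np.random.default_rng(3)
        from crfvoter.hyperopt import _CategoricalDensity

        dens = _CategoricalDensity(("a", "b"), ["b", "a"])
        assert got["x"] == dens.sample(rng2)

    def test_good_only_categorical_value_wins(self):
        space = ParameterSpace.from_dict({"x": Categorical(("A", "B", "C"))})
        history = [
            Trial(Configuration.from_dict({"x": "A"}), 0.9, 0),
            Trial(Configuration.from_dict({"x": "B"}), 0.2, 1),
            Trial(Configuration.from_dict({"x": "B"}), 0.1, 2),
            Trial(Configuration.from_dict({"x": "C"}), 0.15, 3),
            Trial(Configuration.from_dict({"x": "C"}), 0.05, 4),
        ]
        settings = TPESettings(gamma=0.2, n_startup=2, n_candidates=64, seed=0)
        from crfvoter.hyperopt import _CategoricalDensity

        l_dens = _CategoricalDensity(("A", "B", "C"), ["A"])
        g_dens = _CategoricalDensity(("A", "B", "C"), ["B", "B", "C", "C"])
        # "A" has higher l-probability than its smoothed bad-group frequency
        assert l_dens.probs[0] > g_dens.probs[0]
        got = tpe_suggest(history, space, settings)
        assert got["x"] == "A"

    def test_startup_falls_back_to_random(self):
        space = ParameterSpace.from_dict({"x": FloatRange(0.0, 1.0)})
        settings = TPESettings(n_startup=10, seed=7)
        rng = np.random.default_rng(7)
        got = tpe_suggest(make_trials([0.5] * 3), space, settings, rng=rng)
        rng2 = np.random.default_rng(7)
        from crfvoter.hyperopt import _sample_config

        assert got.as_dict() == _sample_config(space, rng2).as_dict()


def quadratic_objective(cfg):
    return -((cfg["x"] - 0.3) ** 2)


class TestOptimize:
    def test_trajectory_non_decreasing(self):
        space = ParameterSpace.from_dict({"x": FloatRange(0.0, 1.0)})
        report = optimize(space, quadratic_objective, method="random", budget=50, seed=0)
        traj = report.trajectory
        assert all(a <= b for a, b in zip(traj, traj[1:]))

    def test_grid_history_length_20(self):
        report = optimize(CRFPP_SPACE, lambda cfg: 0.0, method="grid")
        assert len(report.trials) == 20

    def test_best_is_max_over_history(self):
        space = ParameterSpace.from_dict({"x": FloatRange(0.0, 1.0)})
        for method in ("random", "tpe"):
            report = optimize(space, quadratic_objective, method=method, budget=30, seed=2)
            assert report.best.metric == max(t.metric for t in report.trials)

    def test_failed_trial_scores_zero(self, caplog):
        space = ParameterSpace.from_dict({"x": Categorical((1, 2))})

        def bad(cfg):
            if cfg["x"] == 2:
                raise RuntimeError("boom")
            return 0.5

        with caplog.at_level("WARNING"):
            report = optimize(space, bad, method="grid")
        failed = [t for t in report.trials if t.failed]
        assert len(failed) == 1 and failed[0].metric == 0.0

    def test_tpe_with_large_startup_identical_to_random(self):
        space = ParameterSpace.from_dict(
            {"x": FloatRange(0.0, 1.0), "k": IntRange(1, 4)}
        )
        seed, budget = 9, 25
        rnd = optimize(space, quadratic_objective, method="random", budget=budget, seed=seed)
        tpe = optimize(
            space,
            quadratic_objective,
            method="tpe",
            budget=budget,
            seed=seed,
            tpe_settings=TPESettings(n_startup=budget, seed=seed),
        )
        assert [t.config.as_dict() for t in rnd.trials] == [
            t.config.as_dict() for t in tpe.trials
        ]

    def test_tpe_beats_random_on_quadratic(self):
        space = ParameterSpace.from_dict({"x": FloatRange(0.0, 1.0)})
        budget, reps = 60, 20
        best_tpe, best_rnd = [], []
        for rep in range(reps):
            r = optimize(space, quadratic_objective, method="random", budget=budget, seed=rep)
            t = optimize(space, quadratic_objective, method="tpe", budget=budget, seed=rep)
            best_rnd.append(r.best.metric)
            best_tpe.append(t.best.metric)
        assert np.median(best_tpe) >= np.median(best_rnd)

    def test_jsonl_report(self, tmp_path):
        space = ParameterSpace.from_dict({"x": Categorical((1, 2, 3))})
        report = optimize(space, lambda cfg: cfg["x"] / 3.0, method="grid")
        p = report.to_jsonl(tmp_path / "trials.jsonl")
        import json

        lines = [json.loads(l) for l in p.read_text().splitlines()]
        assert len(lines) == 3
        assert lines[2]["metric"] == pytest.approx(1.0)


class TestSpaceSerialization:
    def test_json_round_trip(self, tmp_path):
        import json

        p = tmp_path / "space.json"
        p.write_text(
            json.dumps(
                {
                    "c": {"type": "cat", "values": [0.6, 1]},
                    "k": {"type": "int", "low": 1, "high": 5},
                    "x": {"type": "float", "low": 0.0, "high": 2.0},
                }
            )
        )
        space = ParameterSpace.from_json(p)
        assert space.to_json_dict() == json.loads(p.read_text())

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError):
            ParameterSpace((("a", Categorical((1,))), ("a", Categorical((2,)))))

    def test_infinite_bounds_rejected(self):
        with pytest.raises(ValueError):
            FloatRange(0.0, math.inf)
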