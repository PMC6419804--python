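"""Hyperparameter search: grid, random, and a Tree-structured Parzen Estimator.

The driver maximizes a validation metric (F1).  TPE splits the trial
history into a good group (top gamma quantile) and a bad group, fits a
density l from the good group and g from the bad group per dimension,
draws candidates from l, and proposes the candidate maximizing the
expected-improvement ratio l(x)/g(x).  For the first ``n_startup`` trials
TPE falls back to pure random sampling, consuming the same random stream
as random search (so TPE with n_startup >= budget is bit-identical to
random search at equal seed).

Spaces are flat; conditional (tree-structured) dimensions are not
implemented.  Failed objective evaluations are recorded with metric 0.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Categorical",
    "IntRange",
    "FloatRange",
    "ParameterSpace",
    "Configuration",
    "Trial",
    "TPESettings",
    "OptimizationReport",
    "grid_search",
    "random_search",
    "tpe_split",
    "tpe_suggest",
    "optimize",
    "UnsupportedSpaceError",
]


class UnsupportedSpaceError(ValueError):
    pass


class InsufficientHistoryError(ValueError):
    pass


@dataclass(frozen=True)
class Categorical:
    values: tuple

    def __post_init__(self) -> None:
        if not self.values:
            raise ValueError("empty categorical domain")

    def contains(self, v) -> bool:
        return v in self.values


@dataclass(frozen=True)
class IntRange:
    low: int
    high: int  # inclusive

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise ValueError("empty integer range")

    def contains(self, v) -> bool:
        return isinstance(v, (int, np.integer)) and self.low <= v <= self.high


@dataclass(frozen=True)
class FloatRange:
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.low) and math.isfinite(self.high)):
            raise ValueError("continuous bounds must be finite")
        if self.low >= self.high:
            raise ValueError("empty interval")

    def contains(self, v) -> bool:
        return self.low <= float(v) <= self.high


Dimension = Categorical | IntRange | FloatRange


@dataclass(frozen=True)
class ParameterSpace:
    """Ordered name -> domain mapping (insertion order is search order)."""

    dimensions: tuple[tuple[str, Dimension], ...]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.dimensions]
        if len(set(names)) != len(names):
            raise ValueError("duplicate dimension names")
        if not names:
            raise ValueError("empty parameter space")

    @classmethod
    def from_dict(cls, d: Mapping[str, Dimension]) -> "ParameterSpace":
        return cls(tuple(d.items()))

    @classmethod
    def from_json(cls, source: str | Path | Mapping) -> "ParameterSpace":
        if isinstance(source, (str, Path)):
            spec = json.loads(Path(source).read_text(encoding="utf-8"))
        else:
            spec = source
        dims: dict[str, Dimension] = {}
        for name, d in spec.items():
            kind = d["type"]
            if kind == "cat":
                dims[name] = Categorical(tuple(d["values"]))
            elif kind == "int":
                dims[name] = IntRange(int(d["low"]), int(d["high"]))
            elif kind == "float":
                dims[name] = FloatRange(float(d["low"]), float(d["high"]))
            else:
                raise ValueError(f"unknown dimension type {kind!r}")
        return cls.from_dict(dims)

    def to_json_dict(self) -> dict:
        out = {}
        for name, dim in self.dimensions:
            if isinstance(dim, Categorical):
                out[name] = {"type": "cat", "values": list(dim.values)}
            elif isinstance(dim, IntRange):
                out[name] = {"type": "int", "low": dim.low, "high": dim.high}
            else:
                out[name] = {"type": "float", "low": dim.low, "high": dim.high}
        return out

    def validate(self, config: "Configuration") -> None:
        for name, dim in self.dimensions:
            if name not in config.assignment:
                raise ValueError(f"missing dimension {name!r}")
            if not dim.contains(config.assignment[name]):
                raise ValueError(
                    f"value {config.assignment[name]!r} outside domain of {name!r}"
                )


@dataclass(frozen=True)
class Configuration:
    assignment: tuple[tuple[str, object], ...]

    @classmethod
    def from_dict(cls, d: Mapping) -> "Configuration":
        return cls(tuple(d.items()))

    def __getitem__(self, name: str):
        return dict(self.assignment)[name]

    def as_dict(self) -> dict:
        return dict(self.assignment)


@dataclass(frozen=True)
class Trial:
    config: Configuration
    metric: float
    trial_index: int
    failed: bool = False


@dataclass(frozen=True)
class TPESettings:
    gamma: float = 0.25
    n_startup: int = 20
    n_candidates: int = 24
    bandwidth_rule: str = "silverman"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.gamma < 1.0):
            raise ValueError("gamma must lie in (0, 1)")
        if self.n_startup < 1 or self.n_candidates < 1:
            raise ValueError("n_startup and n_candidates must be >= 1")
        if self.bandwidth_rule != "silverman":
            raise ValueError(f"unknown bandwidth rule {self.bandwidth_rule!r}")


@dataclass
class OptimizationReport:
    method: str
    best: Trial
    trials: list[Trial]

    @property
    def trajectory(self) -> list[float]:
        """Best-so-far metric after each trial (non-decreasing)."""
        out, best = [], -math.inf
        for t in self.trials:
            best = max(best, t.metric)
            out.append(best)
        return out

    def to_jsonl(self, path: str | Path) -> Path:
        path = Path(path)
        with path.open("w", encoding="utf-8") as fh:
            for t in self.trials:
                fh.write(
                    json.dumps(
                        {
                            "trial_index": t.trial_index,
                            "metric": t.metric,
                            "failed": t.failed,
                            "config": t.config.as_dict(),
                        }
                    )
                    + "\n"
                )
        return path


# ---------------------------------------------------------------------------


def _sample_config(space: ParameterSpace, rng: np.random.Generator) -> Configuration:
    assignment = {}
    for name, dim in space.dimensions:
        if isinstance(dim, Categorical):
            assignment[name] = dim.values[int(rng.integers(len(dim.values)))]
        elif isinstance(dim, IntRange):
            assignment[name] = int(rng.integers(dim.low, dim.high + 1))
        else:
            assignment[name] = float(rng.uniform(dim.low, dim.high))
    return Configuration.from_dict(assignment)


def _evaluate(objective, config: Configuration, index: int) -> Trial:
    try:
        metric = float(objective(config))
    except Exception as exc:  # failed trials score 0, run continues
        logger.warning("trial %d failed: %s", index, exc)
        return Trial(config, 0.0, index, failed=True)
    return Trial(config, metric, index)


def _best(trials: Sequence[Trial]) -> Trial:
    return max(trials, key=lambda t: (t.metric, -t.trial_index))


def grid_search(
    space: ParameterSpace, objective: Callable[[Configuration], float]
) -> tuple[Trial, list[Trial]]:
    """Evaluate every configuration once, in lexicographic dimension order."""
    for name, dim in space.dimensions:
        if isinstance(dim, FloatRange):
            raise UnsupportedSpaceError(
                f"continuous dimension {name!r}: discretize it for grid search"
            )
    values: list[list] = []
    for _, dim in space.dimensions:
        if isinstance(dim, Categorical):
            values.append(list(dim.values))
        else:
            values.append(list(range(dim.low, dim.high + 1)))
    names = [n for n, _ in space.dimensions]
    trials: list[Trial] = []
    import itertools

    for i, combo in enumerate(itertools.product(*values)):
        config = Configuration.from_dict(dict(zip(names, combo)))
        trials.append(_evaluate(objective, config, i))
    return _best(trials), trials


def random_search(
    space: ParameterSpace,
    objective: Callable[[Configuration], float],
    budget: int,
    seed: int,
) -> tuple[Trial, list[Trial]]:
    """Independent uniform sampling of each dimension; deterministic per seed."""
    if budget < 1:
        raise ValueError("budget must be >= 1")
    rng = np.random.default_rng(seed)
    trials = [
        _evaluate(objective, _sample_config(space, rng), i) for i in range(budget)
    ]
    return _best(trials), trials


def tpe_split(
    trials: Sequence[Trial], gamma: float
) -> tuple[list[Trial], list[Trial]]:
    """Top-gamma quantile by metric -> good group; rest -> bad group."""
    if len(trials) < 2:
        raise InsufficientHistoryError("need at least 2 trials to split")
    n_good = max(1, math.ceil(gamma * len(trials)))
    n_good = min(n_good, len(trials) - 1)
    ranked = sorted(trials, key=lambda t: (-t.metric, t.trial_index))
    return list(ranked[:n_good]), list(ranked[n_good:])


class _CategoricalDensity:
    """Additive-smoothed empirical frequencies over a finite value list."""

    def __init__(self, values: tuple, observed: list) -> None:
        self.values = values
        counts = np.array([sum(1 for o in observed if o == v) for v in values], float)
        self.probs = (counts + 1.0) / (counts.sum() + len(values))

    def logpdf(self, v) -> float:
        return float(np.log(self.probs[self.values.index(v)]))

    def sample(self, rng: np.random.Generator):
        return self.values[int(rng.choice(len(self.values), p=self.probs))]


class _ParzenDensity:
    """Truncated Gaussian mixture over observed values (Silverman bandwidth)."""

    def __init__(self, low: float, high: float, observed: list, integer: bool) -> None:
        self.low, self.high, self.integer = low, high, integer
        self.centers = np.asarray([float(o) for o in observed])
        n = len(self.centers)
        span = high - low
        if n >= 2:
            sd = float(np.std(self.centers, ddof=1))
            q75, q25 = np.percentile(self.centers, [75, 25])
            iqr = q75 - q25
            scale = min(sd, iqr / 1.34) if iqr > 0 else sd
            bw = 0.9 * scale * n ** (-0.2) if scale > 0 else 0.0
        else:
            bw = 0.0
        self.bw = max(bw, 0.05 * span / max(n, 1), 1e-3 * span)

    def logpdf(self, v) -> float:
        x = float(v)
        z = (x - self.centers) / self.bw
        comps = -0.5 * z**2 - math.log(self.bw * math.sqrt(2 * math.pi))
        from scipy.special import logsumexp

        return float(logsumexp(comps) - math.log(len(self.centers)))

    def sample(self, rng: np.random.Generator):
        c = self.centers[int(rng.integers(len(self.centers)))]
        x = float(np.clip(rng.normal(c, self.bw), self.low, self.high))
        if self.integer:
            return int(np.clip(round(x), self.low, self.high))
        return x


def _fit_density(dim: Dimension, observed: list):
    if isinstance(dim, Categorical):
        return _CategoricalDensity(dim.values, observed)
    if isinstance(dim, IntRange):
        return _ParzenDensity(dim.low, dim.high, observed, integer=True)
    return _ParzenDensity(dim.low, dim.high, observed, integer=False)


def tpe_suggest(
    trials: Sequence[Trial],
    space: ParameterSpace,
    settings: TPESettings,
    rng: np.random.Generator | None = None,
) -> Configuration:
    """Propose the candidate maximizing the l/g expected-improvement ratio.

    With fewer than ``n_startup`` trials this is a single random draw.
    Ties in the ratio keep the earliest-drawn candidate.
    """
    if rng is None:
        rng = np.random.default_rng(settings.seed)
    if len(trials) < settings.n_startup:
        return _sample_config(space, rng)
    good, bad = tpe_split(trials, settings.gamma)
    densities = []
    for name, dim in space.dimensions:
        l_obs = [t.config[name] for t in good]
        g_obs = [t.config[name] for t in bad]
        densities.append((name, _fit_density(dim, l_obs), _fit_density(dim, g_obs)))
    best_cfg, best_ei = None, -math.inf
    for _ in range(settings.n_candidates):
        assignment = {}
        log_ei = 0.0
        for name, l_dens, g_dens in densities:
            v = l_dens.sample(rng)
            assignment[name] = v
            log_ei += l_dens.logpdf(v) - g_dens.logpdf(v)
        if log_ei > best_ei:
            best_ei = log_ei
            best_cfg = Configuration.from_dict(assignment)
    return best_cfg


def optimize(
    space: ParameterSpace,
    objective: Callable[[Configuration], float],
    method: str = "tpe",
    budget: int = 1,
    seed: int = 0,
    tpe_settings: TPESettings | None = None,
) -> OptimizationReport:
    """Run one search method; history length == number of evaluations."""
    if method == "grid":
        best, trials = grid_search(space, objective)
        return OptimizationReport("grid", best, trials)
    if budget < 1:
        raise ValueError("budget must be >= 1")
    if method == "random":
        best, trials = random_search(space, objective, budget, seed)
        return OptimizationReport("random", best, trials)
    if method != "tpe":
        raise ValueError(f"unknown method {method!r}")
    settings = tpe_settings or TPESettings(seed=seed)
    rng = np.random.default_rng(seed)
    trials: list[Trial] = []
    for i in range(budget):
        config = tpe_suggest(trials, space, settings, rng=rng)
        trials.append(_evaluate(objective, config, i))
    return OptimizationReport("tpe", _best(trials), trials)
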