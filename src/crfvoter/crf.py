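"""Linear-chain CRF: scoring, exact inference, penalized ML training.

The model scores a labeling y of a sentence x as

    score(x, y) = sum_j emission(features_j, y_j) + transition(y_{j-1}, y_j)

with a virtual START state supplying the j = 0 transition, and defines
P(y | x) = exp(score) / Z_x with Z_x computed by the forward recursion in
log space.  Training maximizes  sum_i log P(y_i | x_i) - penalty  where the
penalty is (1/c) * ||w||_1  or  (1/(2c)) * ||w||_2^2, i.e. larger cost c
means weaker regularization (the CRF++ convention of c multiplying the
likelihood, divided through).

Transitions are first-order label-pair indicators only; emission features
are arbitrary strings.  Unseen test-time features score 0.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .features import FeatureVector

logger = logging.getLogger(__name__)

__all__ = [
    "LabelSet",
    "CRFModel",
    "TrainingInstance",
    "sequence_score",
    "log_partition",
    "viterbi_decode",
    "train",
    "TrainingDivergenceError",
]


class TrainingDivergenceError(RuntimeError):
    pass


class LabelError(KeyError):
    pass


@dataclass(frozen=True)
class LabelSet:
    """Ordered label alphabet with an index <-> tag bijection."""

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if "O" not in self.labels:
            raise ValueError('label set must contain "O"')
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate labels")

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise LabelError(label) from None


@dataclass(frozen=True)
class TrainingInstance:
    feature_rows: tuple[FeatureVector, ...]
    gold_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.feature_rows) != len(self.gold_labels):
            raise ValueError("feature/label length mismatch")
        if len(self.feature_rows) == 0:
            raise ValueError("empty instance")


class CRFModel:
    """Weights over (feature, label) emissions and (label, label) transitions.

    ``start`` holds the virtual-START transition weights.  Lookups of
    unseen features return 0.
    """

    def __init__(
        self,
        label_set: LabelSet,
        penalty_kind: str = "L2",
        cost_c: float = 1.0,
    ) -> None:
        if penalty_kind not in ("L1", "L2"):
            raise ValueError(f"penalty_kind must be L1 or L2, got {penalty_kind}")
        if cost_c <= 0:
            raise ValueError("cost_c must be positive")
        self.label_set = label_set
        self.penalty_kind = penalty_kind
        self.cost_c = float(cost_c)
        self.feature_index: dict[str, int] = {}
        L = len(label_set)
        self.W = np.zeros((0, L))  # emissions, row per feature
        self.T = np.zeros((L, L))  # transitions prev -> cur
        self.start = np.zeros(L)  # virtual START -> cur
        self.n_iter: int = 0
        self.final_objective: float = float("nan")
        self.converged: bool = False

    # -- weight access -------------------------------------------------
    def emission_weight(self, feature: str, label: str) -> float:
        i = self.feature_index.get(feature)
        if i is None:
            return 0.0
        return float(self.W[i, self.label_set.index(label)])

    def transition_weight(self, prev: str | None, label: str) -> float:
        li = self.label_set.index(label)
        if prev is None:
            return float(self.start[li])
        return float(self.T[self.label_set.index(prev), li])

    def set_emission_weight(self, feature: str, label: str, w: float) -> None:
        i = self.feature_index.get(feature)
        if i is None:
            i = len(self.feature_index)
            self.feature_index[feature] = i
            self.W = np.vstack([self.W, np.zeros((1, len(self.label_set)))])
        self.W[i, self.label_set.index(label)] = w

    def set_transition_weight(self, prev: str | None, label: str, w: float) -> None:
        li = self.label_set.index(label)
        if prev is None:
            self.start[li] = w
        else:
            self.T[self.label_set.index(prev), li] = w

    # -- scoring -------------------------------------------------------
    def emission_matrix(self, feature_rows: Sequence[FeatureVector]) -> np.ndarray:
        """(n, L) matrix of emission scores; unseen features contribute 0."""
        n = len(feature_rows)
        E = np.zeros((n, len(self.label_set)))
        for j, fv in enumerate(feature_rows):
            for f in fv:
                i = self.feature_index.get(f)
                if i is not None:
                    E[j] += self.W[i]
        return E

    # -- persistence ---------------------------------------------------
    def save(self, directory: str | Path) -> Path:
        """Write JSON header + TSV weight table; reload is bit-exact."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        header = {
            "labels": list(self.label_set.labels),
            "penalty_kind": self.penalty_kind,
            "cost_c": self.cost_c,
        }
        (directory / "model.json").write_text(
            json.dumps(header, indent=2), encoding="utf-8"
        )
        labels = self.label_set.labels
        with (directory / "weights.tsv").open("w", encoding="utf-8") as fh:
            for li, lab in enumerate(labels):
                if self.start[li] != 0.0:
                    fh.write(f"S\t{lab}\t{self.start[li].hex()}\n")
            for pi, prev in enumerate(labels):
                for li, lab in enumerate(labels):
                    if self.T[pi, li] != 0.0:
                        fh.write(f"T\t{prev}\t{lab}\t{self.T[pi, li].hex()}\n")
            for f, i in sorted(self.feature_index.items()):
                for li, lab in enumerate(labels):
                    if self.W[i, li] != 0.0:
                        fh.write(f"E\t{f}\t{lab}\t{self.W[i, li].hex()}\n")
        return directory

    @classmethod
    def load(cls, directory: str | Path) -> "CRFModel":
        directory = Path(directory)
        header = json.loads((directory / "model.json").read_text(encoding="utf-8"))
        model = cls(
            LabelSet(tuple(header["labels"])),
            penalty_kind=header["penalty_kind"],
            cost_c=header["cost_c"],
        )
        for line in (directory / "weights.tsv").read_text(encoding="utf-8").splitlines():
            parts = line.split("\t")
            if parts[0] == "S":
                model.set_transition_weight(None, parts[1], float.fromhex(parts[2]))
            elif parts[0] == "T":
                model.set_transition_weight(parts[1], parts[2], float.fromhex(parts[3]))
            elif parts[0] == "E":
                model.set_emission_weight(parts[1], parts[2], float.fromhex(parts[3]))
        return model


def sequence_score(
    model: CRFModel,
    feature_rows: Sequence[FeatureVector],
    labels: Sequence[str],
) -> float:
    """Unnormalized log-score of a labeling (the exponent of P(y|x))."""
    if len(feature_rows) != len(labels):
        raise ValueError("length mismatch")
    idx = [model.label_set.index(lab) for lab in labels]
    E = model.emission_matrix(feature_rows)
    score = model.start[idx[0]] + E[0, idx[0]]
    for j in range(1, len(idx)):
        score += model.T[idx[j - 1], idx[j]] + E[j, idx[j]]
    return float(score)


def log_partition(
    model: CRFModel, feature_rows: Sequence[FeatureVector]
) -> float:
    """log Z_x via the forward recursion in log space (log-sum-exp stable)."""
    if len(feature_rows) == 0:
        raise ValueError("empty sequence")
    E = model.emission_matrix(feature_rows)
    alpha = model.start + E[0]
    for j in range(1, len(feature_rows)):
        alpha = logsumexp(alpha[:, None] + model.T, axis=0) + E[j]
    return float(logsumexp(alpha))


def viterbi_decode(
    model: CRFModel, feature_rows: Sequence[FeatureVector]
) -> list[str]:
    """Max-score labeling; ties broken toward the lowest label index."""
    if len(feature_rows) == 0:
        raise ValueError("empty sequence")
    E = model.emission_matrix(feature_rows)
    n, L = E.shape
    delta = model.start + E[0]
    back = np.zeros((n, L), dtype=int)
    for j in range(1, n):
        scores = delta[:, None] + model.T  # prev x cur
        back[j] = np.argmax(scores, axis=0)  # first max -> lowest index
        delta = scores[back[j], np.arange(L)] + E[j]
    path = [int(np.argmax(delta))]
    for j in range(n - 1, 0, -1):
        path.append(int(back[j, path[-1]]))
    path.reverse()
    return [model.label_set.labels[i] for i in path]


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def _index_instances(
    instances: Sequence[TrainingInstance], feature_index: dict[str, int]
) -> list[tuple[list[np.ndarray], np.ndarray]]:
    """Per instance: list of active-feature index arrays per position + gold indices."""
    indexed = []
    for inst in instances:
        rows = []
        for fv in inst.feature_rows:
            ids = []
            for f in fv:
                if f not in feature_index:
                    feature_index[f] = len(feature_index)
                ids.append(feature_index[f])
            rows.append(np.asarray(sorted(ids), dtype=int))
        indexed.append((rows, inst.gold_labels))
    return indexed


def _neg_log_likelihood_and_grad(
    params: np.ndarray,
    indexed,
    gold_idx,
    F: int,
    L: int,
):
    """Unpenalized negative log-likelihood and its gradient."""
    W = params[: F * L].reshape(F, L)
    start = params[F * L : F * L + L]
    T = params[F * L + L :].reshape(L, L)
    gW = np.zeros_like(W)
    gstart = np.zeros_like(start)
    gT = np.zeros_like(T)
    nll = 0.0
    for (rows, _), yidx in zip(indexed, gold_idx):
        n = len(rows)
        E = np.zeros((n, L))
        for j, ids in enumerate(rows):
            if ids.size:
                E[j] = W[ids].sum(axis=0)
        # forward
        log_alpha = np.zeros((n, L))
        log_alpha[0] = start + E[0]
        for j in range(1, n):
            log_alpha[j] = logsumexp(log_alpha[j - 1][:, None] + T, axis=0) + E[j]
        logZ = logsumexp(log_alpha[n - 1])
        # backward
        log_beta = np.zeros((n, L))
        for j in range(n - 2, -1, -1):
            log_beta[j] = logsumexp(T + (E[j + 1] + log_beta[j + 1])[None, :], axis=1)
        # gold score
        score = start[yidx[0]] + E[0, yidx[0]]
        for j in range(1, n):
            score += T[yidx[j - 1], yidx[j]] + E[j, yidx[j]]
        nll += logZ - score
        # expected - empirical counts
        node_marg = np.exp(log_alpha + log_beta - logZ)  # (n, L)
        for j, ids in enumerate(rows):
            if ids.size:
                gW[ids] += node_marg[j]
                gW[ids, yidx[j]] -= 1.0
        gstart += node_marg[0]
        gstart[yidx[0]] -= 1.0
        for j in range(1, n):
            edge = (
                log_alpha[j - 1][:, None]
                + T
                + (E[j] + log_beta[j])[None, :]
                - logZ
            )
            gT += np.exp(edge)
            gT[yidx[j - 1], yidx[j]] -= 1.0
    grad = np.concatenate([gW.ravel(), gstart, gT.ravel()])
    return nll, grad


def penalized_objective(
    params: np.ndarray,
    indexed,
    gold_idx,
    F: int,
    L: int,
    penalty_kind: str,
    cost_c: float,
):
    """Negative penalized log-likelihood and gradient (L2 case; L1 handled
    by non-negative splitting in :func:`train`)."""
    nll, grad = _neg_log_likelihood_and_grad(params, indexed, gold_idx, F, L)
    if penalty_kind == "L2":
        nll += params @ params / (2.0 * cost_c)
        grad = grad + params / cost_c
    else:
        nll += np.abs(params).sum() / cost_c
        grad = grad + np.sign(params) / cost_c
    return nll, grad


def train(
    instances: Sequence[TrainingInstance],
    penalty_kind: str = "L2",
    cost_c: float = 1.0,
    max_iter: int = 300,
    tol: float = 1e-6,
    label_set: LabelSet | None = None,
) -> CRFModel:
    """Penalized maximum-likelihood training with L-BFGS-B.

    L1 uses the exact non-negative splitting w = w+ - w- under bound
    constraints; convergence at relative objective change < ``tol`` or
    ``max_iter`` iterations.
    """
    if not instances:
        raise ValueError("empty training set")
    if cost_c <= 0:
        raise ValueError("cost_c must be positive")
    if label_set is None:
        seen: list[str] = []
        for inst in instances:
            for lab in inst.gold_labels:
                if lab not in seen:
                    seen.append(lab)
        if "O" not in seen:
            seen.insert(0, "O")
        label_set = LabelSet(tuple(seen))
    model = CRFModel(label_set, penalty_kind=penalty_kind, cost_c=cost_c)
    feature_index: dict[str, int] = {}
    indexed = _index_instances(instances, feature_index)
    gold_idx = [
        np.asarray([label_set.index(lab) for lab in inst.gold_labels], dtype=int)
        for inst in instances
    ]
    F, L = len(feature_index), len(label_set)
    n_params = F * L + L + L * L

    if penalty_kind == "L2":

        def fun(p):
            return penalized_objective(p, indexed, gold_idx, F, L, "L2", cost_c)

        res = minimize(
            fun,
            np.zeros(n_params),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-8},
        )
        params = res.x
    else:
        # w = p - q with p, q >= 0; |w| = p + q at the optimum
        def fun(pq):
            p, q = pq[:n_params], pq[n_params:]
            nll, grad = _neg_log_likelihood_and_grad(p - q, indexed, gold_idx, F, L)
            nll += (p.sum() + q.sum()) / cost_c
            gp = grad + 1.0 / cost_c
            gq = -grad + 1.0 / cost_c
            return nll, np.concatenate([gp, gq])

        res = minimize(
            fun,
            np.zeros(2 * n_params),
            jac=True,
            method="L-BFGS-B",
            bounds=[(0.0, None)] * (2 * n_params),
            options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-8},
        )
        params = res.x[:n_params] - res.x[n_params:]

    if not np.isfinite(res.fun):
        raise TrainingDivergenceError(f"non-finite objective: {res.fun}")
    model.feature_index = feature_index
    model.W = params[: F * L].reshape(F, L).copy()
    model.start = params[F * L : F * L + L].copy()
    model.T = params[F * L + L :].reshape(L, L).copy()
    model.n_iter = int(res.nit)
    model.final_objective = float(res.fun)
    model.converged = bool(res.success)
    return model
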