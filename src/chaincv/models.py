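"""Predictive models: logistic baseline, gradient-boosted classifier
chains, and a sequential model-based hyperparameter tuner.

A classifier chain orders the targets, training the i-th member on the
features concatenated with the *true* labels of the targets preceding it
(teacher forcing); at inference the member receives hard 0/1 predictions
from the earlier members.  A chain ensemble (CCE) averages the per-target
scores of several chains with independently sampled random orderings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import HistGradientBoostingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

LEARNER_KINDS = ("logistic", "gbm")

#: Bounded hyperparameter search space for the GBM base learner.
GBM_SEARCH_SPACE = {
    "learning_rate": (0.01, 0.3, "log"),
    "max_iter": (50, 500, "int"),
    "max_leaf_nodes": (7, 63, "int"),
    "l2_regularization": (0.0, 10.0, "linear"),
}

LOGISTIC_SEARCH_SPACE = {"C": (1e-3, 1e3, "log")}

#: Deliberately small GBM defaults so desk-scale runs stay tractable.
GBM_DESK_PARAMS = {
    "learning_rate": 0.1,
    "max_iter": 60,
    "max_leaf_nodes": 15,
    "l2_regularization": 1.0,
}


class ModelError(ValueError):
    pass


@dataclass(frozen=True)
class BaseLearnerSpec:
    """A base learner kind plus hyperparameters and a seed."""

    kind: str = "gbm"
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.kind not in LEARNER_KINDS:
            raise ModelError(f"unknown learner kind {self.kind!r}; use one of {LEARNER_KINDS}")
        space = GBM_SEARCH_SPACE if self.kind == "gbm" else LOGISTIC_SEARCH_SPACE
        for k, v in self.params.items():
            if k in space:
                lo, hi, _ = space[k]
                if not lo <= v <= hi:
                    raise ModelError(f"hyperparameter {k}={v} outside bounds [{lo}, {hi}]")


class FittedBase:
    """A fitted base learner exposing ``score(X) -> P(y=1) in [0, 1]``."""

    def __init__(self, estimator, n_inputs: int):
        self._est = estimator
        self.n_inputs = n_inputs

    def score(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, float)
        if X.shape[1] != self.n_inputs:
            raise ModelError(f"expected {self.n_inputs} input columns, got {X.shape[1]}")
        return self._est.predict_proba(X)[:, 1]


def fit_base(spec: BaseLearnerSpec, X, y) -> FittedBase:
    """Fit one binary base learner.  Deterministic given ``spec.seed``."""
    X = np.asarray(X, float)
    y = np.asarray(y).astype(int)
    if not np.all(np.isfinite(X)):
        raise ModelError("X contains non-finite values")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ModelError(f"y has a single class ({classes.tolist()}); cannot fit")
    if spec.kind == "logistic":
        est = make_pipeline(
            StandardScaler(),
            LogisticRegression(C=spec.params.get("C", 1.0), max_iter=1000),
        )
    else:
        p = {**GBM_DESK_PARAMS, **spec.params}
        est = HistGradientBoostingClassifier(
            learning_rate=p["learning_rate"],
            max_iter=int(p["max_iter"]),
            max_leaf_nodes=int(p["max_leaf_nodes"]),
            l2_regularization=p["l2_regularization"],
            early_stopping=False,
            random_state=spec.seed,
        )
    est.fit(X, y)
    return FittedBase(est, X.shape[1])


@dataclass
class ChainModel:
    """One classifier chain over ``n_targets`` binary labels."""

    ordering: np.ndarray  # permutation of target indices
    members: list  # FittedBase, one per position in the ordering
    n_features: int
    hard_labels: bool = True  # pass thresholded predictions downstream

    @property
    def n_targets(self) -> int:
        return len(self.ordering)


def _check_ordering(ordering, n_targets: int) -> np.ndarray:
    ordering = np.asarray(ordering, int)
    if sorted(ordering.tolist()) != list(range(n_targets)):
        raise ModelError(f"ordering {ordering.tolist()} is not a permutation of 0..{n_targets - 1}")
    return ordering


def fit_chain(spec: BaseLearnerSpec, X, Y, ordering, seed: int, hard_labels: bool = True) -> ChainModel:
    """Train one chain; member i sees X plus the TRUE preceding labels."""
    X = np.asarray(X, float)
    Y = np.asarray(Y, int)
    ordering = _check_ordering(ordering, Y.shape[1])
    seeds = np.random.SeedSequence(seed).spawn(len(ordering))
    members = []
    for i, target in enumerate(ordering):
        extra = Y[:, ordering[:i]]
        Xi = np.hstack([X, extra]) if i else X
        member_seed = int(np.random.default_rng(seeds[i]).integers(0, 2**31 - 1))
        members.append(fit_base(replace(spec, seed=member_seed), Xi, Y[:, target]))
    return ChainModel(ordering=ordering, members=members, n_features=X.shape[1], hard_labels=hard_labels)


def predict_chain(chain: ChainModel, X) -> np.ndarray:
    """Sequential chain inference.

    Member i receives the predictions of the earlier members — hard 0/1
    labels at threshold 0.5 by default, raw probabilities when the chain
    was built with ``hard_labels=False``.  Scores are returned re-indexed
    to canonical target order.
    """
    X = np.asarray(X, float)
    if X.shape[1] != chain.n_features:
        raise ModelError(f"X has {X.shape[1]} columns; chain expects {chain.n_features}")
    n = X.shape[0]
    scores = np.empty((n, chain.n_targets))
    passed = np.empty((n, chain.n_targets))
    for i, target in enumerate(chain.ordering):
        Xi = np.hstack([X, passed[:, :i]]) if i else X
        s = chain.members[i].score(Xi)
        scores[:, target] = s
        passed[:, i] = (s >= 0.5).astype(float) if chain.hard_labels else s
    return scores


@dataclass
class CCEModel:
    """Ensemble of chains with independently sampled orderings."""

    chains: list

    @property
    def n_targets(self) -> int:
        return self.chains[0].n_targets


def fit_cce(
    spec: BaseLearnerSpec, X, Y, n_chains: int = 10, seed: int = 0, hard_labels: bool = True
) -> CCEModel:
    """Fit ``n_chains`` chains with uniform random orderings (seeded)."""
    if n_chains < 1:
        raise ModelError("n_chains must be >= 1")
    Y = np.asarray(Y, int)
    rng = np.random.default_rng(seed)
    chains = []
    for _ in range(n_chains):
        ordering = rng.permutation(Y.shape[1])
        chain_seed = int(rng.integers(0, 2**31 - 1))
        chains.append(fit_chain(spec, X, Y, ordering, chain_seed, hard_labels=hard_labels))
    return CCEModel(chains=chains)


def predict_cce(model: CCEModel, X) -> np.ndarray:
    """Arithmetic mean of the chains' score matrices."""
    return np.mean([predict_chain(c, X) for c in model.chains], axis=0)


def fit_independent(spec: BaseLearnerSpec, X, Y, seed: int = 0):
    """One base learner per target, ignoring the other labels."""
    Y = np.asarray(Y, int)
    seeds = np.random.SeedSequence(seed).spawn(Y.shape[1])
    return [
        fit_base(
            replace(spec, seed=int(np.random.default_rng(s).integers(0, 2**31 - 1))), X, Y[:, j]
        )
        for j, s in enumerate(seeds)
    ]


def predict_independent(models, X) -> np.ndarray:
    return np.column_stack([m.score(X) for m in models])


# ---------------------------------------------------------------------------
# multi-label model front-end used by the evaluation stage
# ---------------------------------------------------------------------------

MODEL_KINDS = ("lrc", "gbm_cce", "gbm_independent")


@dataclass(frozen=True)
class ModelSpec:
    """A multi-label model configuration.

    ``lrc``: independent logistic regressions (the linear baseline);
    ``gbm_cce``: ensemble of ``n_chains`` gradient-boosted classifier
    chains; ``gbm_independent``: per-target GBMs with no chaining.
    """

    kind: str = "gbm_cce"
    base_params: dict = field(default_factory=dict)
    n_chains: int = 10
    hard_labels: bool = True

    def __post_init__(self):
        if self.kind not in MODEL_KINDS:
            raise ModelError(f"unknown model kind {self.kind!r}; use one of {MODEL_KINDS}")

    def base_spec(self, seed: int = 0) -> BaseLearnerSpec:
        learner = "logistic" if self.kind == "lrc" else "gbm"
        return BaseLearnerSpec(kind=learner, params=dict(self.base_params), seed=seed)


class FittedMultiLabel:
    def __init__(self, spec: ModelSpec, inner):
        self.spec = spec
        self._inner = inner

    def score_matrix(self, X) -> np.ndarray:
        if self.spec.kind == "gbm_cce":
            return predict_cce(self._inner, X)
        return predict_independent(self._inner, X)


def fit_multilabel(spec: ModelSpec, X, Y, seed: int = 0) -> FittedMultiLabel:
    base = spec.base_spec()
    if spec.kind == "gbm_cce":
        inner = fit_cce(base, X, Y, n_chains=spec.n_chains, seed=seed, hard_labels=spec.hard_labels)
    else:
        inner = fit_independent(base, X, Y, seed=seed)
    return FittedMultiLabel(spec, inner)


# ---------------------------------------------------------------------------
# sequential model-based optimization (Gaussian-process surrogate)
# ---------------------------------------------------------------------------


def _space_to_unit(space: dict, values: dict) -> np.ndarray:
    u = []
    for name, (lo, hi, kind) in space.items():
        v = values[name]
        if kind == "log":
            u.append((np.log(v) - np.log(lo)) / (np.log(hi) - np.log(lo)))
        else:
            u.append((v - lo) / (hi - lo))
    return np.array(u)


def _unit_to_space(space: dict, u: np.ndarray) -> dict:
    out = {}
    for (name, (lo, hi, kind)), x in zip(space.items(), u):
        if kind == "log":
            v = float(np.exp(np.log(lo) + x * (np.log(hi) - np.log(lo))))
        elif kind == "int":
            v = int(round(lo + x * (hi - lo)))
        else:
            v = float(lo + x * (hi - lo))
        out[name] = v
    return out


def smbo_maximize(objective, space: dict, budget: int, seed: int = 0, n_candidates: int = 256):
    """Sequential model-based maximization over a bounded space.

    A Gaussian-process surrogate (Matern 5/2 + white noise) is fitted to
    past evaluations in the unit cube; each iteration evaluates the
    candidate with the highest expected improvement among ``n_candidates``
    uniform draws.  Returns ``(best_params, best_value, trajectory)``
    where ``trajectory`` is the list of (params, value) pairs in
    evaluation order.  Deterministic given ``seed``.
    """
    from scipy.stats import norm
    from sklearn.gaussian_process import GaussianProcessRegressor
    from sklearn.gaussian_process.kernels import Matern, WhiteKernel

    if budget < 1:
        raise ModelError("budget must be >= 1")
    if not space:
        raise ModelError("empty search space")
    rng = np.random.default_rng(seed)
    dim = len(space)
    n_init = min(budget, max(3, budget // 4))
    U = list(rng.random((n_init, dim)))
    evaluated, values = [], []
    trajectory = []
    for it in range(budget):
        if it < len(U):
            u = U[it]
        else:
            gp = GaussianProcessRegressor(
                kernel=Matern(nu=2.5, length_scale=np.full(dim, 0.3), length_scale_bounds="fixed")
                + WhiteKernel(noise_level=1e-4, noise_level_bounds="fixed"),
                normalize_y=True,
                random_state=0,
            )
            gp.fit(np.array(evaluated), np.array(values))
            cand = rng.random((n_candidates, dim))
            mu, sd = gp.predict(cand, return_std=True)
            best = max(values)
            sd = np.maximum(sd, 1e-12)
            z = (mu - best) / sd
            ei = (mu - best) * norm.cdf(z) + sd * norm.pdf(z)
            u = cand[int(np.argmax(ei))]
        params = _unit_to_space(space, u)
        val = float(objective(params))
        evaluated.append(_space_to_unit(space, params))
        values.append(val)
        trajectory.append((params, val))
    ibest = int(np.argmax(values))
    return trajectory[ibest][0], values[ibest], trajectory


def tune_hyperparameters(
    spec: BaseLearnerSpec, X, y, budget: int = 25, seed: int = 0, space: dict | None = None,
    val_fraction: float = 0.2,
) -> BaseLearnerSpec:
    """Tune a base learner by maximizing AUROC on an inner validation split.

    An 80/20 stratified split is carved from ``(X, y)``; the surrogate
    optimizer proposes hyperparameters, each evaluated by fitting on the
    inner-train portion and scoring the held-out portion.  Returns the
    best evaluated configuration as a new spec.
    """
    from sklearn.model_selection import train_test_split

    from chaincv.evaluation import auroc

    if space is None:
        space = GBM_SEARCH_SPACE if spec.kind == "gbm" else LOGISTIC_SEARCH_SPACE
    X = np.asarray(X, float)
    y = np.asarray(y, int)
    idx_tr, idx_va = train_test_split(
        np.arange(len(y)), test_size=val_fraction, stratify=y, random_state=seed
    )

    def objective(params: dict) -> float:
        fitted = fit_base(replace(spec, params={**spec.params, **params}), X[idx_tr], y[idx_tr])
        return auroc(fitted.score(X[idx_va]), y[idx_va])

    best_params, _, _ = smbo_maximize(objective, space, budget=budget, seed=seed)
    return replace(spec, params={**spec.params, **best_params})
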