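import numpy as np
import pytest

from chaincv.evaluation import auroc
from chaincv.models import (
    BaseLearnerSpec,
    ChainModel,
    ModelError,
    ModelSpec,
    fit_base,
    fit_cce,
    fit_chain,
    fit_independent,
    fit_multilabel,
    predict_cce,
    predict_chain,
    predict_independent,
    smbo_maximize,
    tune_hyperparameters,
)


def _toy_xy(rng, n=200, p=4):
    X = rng.normal(size=(n, p))
    y = (X[:, 0] + 0.5 * rng.normal(size=n) > 0).astype(int)
    return X, y


class TestFitBase:
    def test_separable_logistic_training_auroc_one(self, rng):
        X = np.vstack([rng.normal(-3, 0.3, (50, 2)), rng.normal(3, 0.3, (50, 2))])
        y = np.repeat([0, 1], 50)
        m = fit_base(BaseLearnerSpec("logistic"), X, y)
        assert auroc(m.score(X), y) == 1.0

    def test_independent_labels_auroc_near_half(self):
        rng = np.random.default_rng(4)
        n = 2000
        X = rng.normal(size=(n, 5))
        y = rng.integers(0, 2, n)
        m = fit_base(BaseLearnerSpec("logistic"), X[: n // 2], y[: n // 2])
        a = auroc(m.score(X[n // 2 :]), y[n // 2 :])
        assert abs(a - 0.5) < 0.05

    def test_xor_gbm_succeeds_logistic_fails(self, rng):
        n = 2000
        A = rng.integers(0, 2, n)
        B = rng.integers(0, 2, n)
        X = np.column_stack([A, B]) + rng.normal(0, 0.1, (n, 2))
        y = A ^ B
        half = n // 2
        gbm = fit_base(BaseLearnerSpec("gbm"), X[:half], y[:half])
        lrc = fit_base(BaseLearnerSpec("logistic"), X[:half], y[:half])
        assert auroc(gbm.score(X[half:]), y[half:]) > 0.95
        assert abs(auroc(lrc.score(X[half:]), y[half:]) - 0.5) < 0.08

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(20, 3))
        with pytest.raises(ModelError, match="single class"):
            fit_base(BaseLearnerSpec("gbm"), X, np.zeros(20))

    def test_nonfinite_rejected(self, rng):
        X = rng.normal(size=(20, 3))
        X[0, 0] = np.nan
        with pytest.raises(ModelError, match="non-finite"):
            fit_base(BaseLearnerSpec("logistic"), X, np.tile([0, 1], 10))

    def test_scores_in_unit_interval(self, rng):
        X, y = _toy_xy(rng)
        for kind in ("logistic", "gbm"):
            s = fit_base(BaseLearnerSpec(kind), X, y).score(X)
            assert np.all((s >= 0) & (s <= 1))

    def test_unknown_kind_rejected(self):
        with pytest.raises(ModelError):
            BaseLearnerSpec("forest")

    def test_params_out_of_bounds_rejected(self):
        with pytest.raises(ModelError, match="learning_rate"):
            BaseLearnerSpec("gbm", params={"learning_rate": 5.0})

    def test_gbm_deterministic_given_seed(self, rng):
        X, y = _toy_xy(rng)
        a = fit_base(BaseLearnerSpec("gbm", seed=7), X, y).score(X)
        b = fit_base(BaseLearnerSpec("gbm", seed=7), X, y).score(X)
        np.testing.assert_array_equal(a, b)


class _StubLearner:
    """Deterministic stand-in base learner for chain plumbing tests."""

    def __init__(self, fn, n_inputs):
        self._fn = fn
        self.n_inputs = n_inputs
        self.seen = []

    def score(self, X):
        X = np.asarray(X, float)
        if X.shape[1] != self.n_inputs:
            raise ModelError(f"expected {self.n_inputs} inputs, got {X.shape[1]}")
        self.seen.append(X.copy())
        return self._fn(X)


class TestChain:
    def test_single_disorder_chain_equals_base(self, rng):
        X, y = _toy_xy(rng)
        Y = y[:, None]
        chain = fit_chain(BaseLearnerSpec("logistic"), X, Y, [0], seed=0)
        base_scores = chain.members[0].score(X)
        np.testing.assert_allclose(predict_chain(chain, X)[:, 0], base_scores)

    def test_member_input_widths_follow_ordering(self, rng):
        X = rng.normal(size=(300, 4))
        Y = (rng.random((300, 3)) < 0.4).astype(int)
        chain = fit_chain(BaseLearnerSpec("logistic"), X, Y, [2, 0, 1], seed=0)
        # member for disorder 0 is second in the chain -> sees n_features + 1
        assert [m.n_inputs for m in chain.members] == [4, 5, 6]
        assert chain.ordering.tolist() == [2, 0, 1]

    def test_training_uses_true_preceding_labels(self, rng):
        # disorder 1 is an exact copy of disorder 0; with teacher forcing the
        # second member sees the true label column and becomes near-perfect
        n = 600
        X = rng.normal(size=(n, 3))
        y0 = (X[:, 0] + rng.normal(0, 1.5, n) > 0).astype(int)
        Y = np.column_stack([y0, y0])
        chain = fit_chain(BaseLearnerSpec("gbm"), X, Y, [0, 1], seed=0)
        lab_col = chain.members[1].score(np.hstack([X, Y[:, :1]]))
        assert auroc(lab_col, Y[:, 1]) > 0.99

    def test_invalid_ordering_rejected(self, rng):
        X, y = _toy_xy(rng)
        Y = np.column_stack([y, 1 - y])
        with pytest.raises(ModelError, match="permutation"):
            fit_chain(BaseLearnerSpec("logistic"), X, Y, [0, 0], seed=0)

    def test_width_mismatch_rejected(self, rng):
        X, y = _toy_xy(rng)
        chain = fit_chain(BaseLearnerSpec("logistic"), X, y[:, None], [0], seed=0)
        with pytest.raises(ModelError):
            predict_chain(chain, X[:, :2])

    def test_members_ignoring_labels_equal_independent(self, rng):
        X = rng.normal(size=(10, 3))
        fns = [lambda Z: 1 / (1 + np.exp(-Z[:, 0])), lambda Z: 1 / (1 + np.exp(-Z[:, 1]))]
        chain = ChainModel(
            ordering=np.array([0, 1]),
            members=[_StubLearner(fns[0], 3), _StubLearner(fns[1], 4)],
            n_features=3,
        )
        out = predict_chain(chain, X)
        np.testing.assert_allclose(out[:, 0], fns[0](X))
        np.testing.assert_allclose(out[:, 1], fns[1](X))

    def test_constant_first_member_feeds_all_ones(self, rng):
        X = rng.normal(size=(8, 2))
        first = _StubLearner(lambda Z: np.ones(len(Z)), 2)
        second = _StubLearner(lambda Z: Z[:, -1], 3)
        chain = ChainModel(ordering=np.array([0, 1]), members=[first, second], n_features=2)
        predict_chain(chain, X)
        np.testing.assert_array_equal(second.seen[0][:, -1], 1.0)

    def test_sequential_inference_matches_bruteforce_oracle(self, rng):
        # oracle: naive per-row sequential re-implementation on a 5-row fixture
        n, p, D = 5, 3, 3
        X = rng.normal(size=(n, p))
        Y = (rng.random((n, D)) < 0.5).astype(int)
        Y[:2] = [[0, 1, 0], [1, 0, 1]]  # ensure both classes per column
        Y[2:] = [[1, 1, 1], [0, 0, 0], [1, 0, 0]]
        ordering = [1, 2, 0]
        chain = fit_chain(BaseLearnerSpec("logistic"), X, Y, ordering, seed=3)
        expected = np.empty((n, D))
        for i in range(n):
            hist = []
            for pos, target in enumerate(ordering):
                xi = np.concatenate([X[i], hist])[None, :]
                s = chain.members[pos].score(xi)[0]
                expected[i, target] = s
                hist.append(1.0 if s >= 0.5 else 0.0)
        np.testing.assert_allclose(predict_chain(chain, X), expected, atol=1e-12)

    def test_soft_label_passing_option(self, rng):
        n, D = 5, 2
        X = rng.normal(size=(200, 3))
        Y = (rng.random((200, D)) < 0.5).astype(int)
        chain = fit_chain(BaseLearnerSpec("logistic"), X, Y, [0, 1], seed=0, hard_labels=False)
        Xq = X[:n]
        s0 = chain.members[0].score(Xq)
        s1 = chain.members[1].score(np.hstack([Xq, s0[:, None]]))
        np.testing.assert_allclose(predict_chain(chain, Xq)[:, 1], s1, atol=1e-12)


class TestCCE:
    def test_single_chain_ensemble_equals_chain(self, rng):
        X = rng.normal(size=(300, 3))
        Y = (rng.random((300, 2)) < 0.4).astype(int)
        cce = fit_cce(BaseLearnerSpec("logistic"), X, Y, n_chains=1, seed=5)
        np.testing.assert_allclose(predict_cce(cce, X), predict_chain(cce.chains[0], X))

    def test_zero_chains_rejected(self, rng):
        X = rng.normal(size=(30, 2))
        Y = (rng.random((30, 2)) < 0.5).astype(int)
        with pytest.raises(ModelError, match="n_chains"):
            fit_cce(BaseLearnerSpec("logistic"), X, Y, n_chains=0)

    def test_paper_config_ten_chains_of_ten_members(self, rng):
        X = rng.normal(size=(400, 5))
        Y = (rng.random((400, 10)) < 0.3).astype(int)
        cce = fit_cce(BaseLearnerSpec("logistic"), X, Y, n_chains=10, seed=1)
        assert len(cce.chains) == 10
        for c in cce.chains:
            assert len(c.members) == 10
            assert sorted(c.ordering.tolist()) == list(range(10))

    def test_orderings_vary_across_chains(self, rng):
        X = rng.normal(size=(200, 3))
        Y = (rng.random((200, 5)) < 0.4).astype(int)
        cce = fit_cce(BaseLearnerSpec("logistic"), X, Y, n_chains=8, seed=2)
        assert len({tuple(c.ordering) for c in cce.chains}) > 1

    def test_prediction_row_order_equivariant(self, rng):
        X = rng.normal(size=(100, 3))
        Y = (rng.random((100, 3)) < 0.4).astype(int)
        cce = fit_cce(BaseLearnerSpec("logistic"), X, Y, n_chains=3, seed=0)
        perm = rng.permutation(100)
        np.testing.assert_allclose(predict_cce(cce, X[perm]), predict_cce(cce, X)[perm])

    def test_ensemble_reduces_score_variance_across_seeds(self, rng):
        X = rng.normal(size=(400, 4))
        y0 = (X[:, 0] + rng.normal(0, 1, 400) > 0).astype(int)
        y1 = (X[:, 1] + rng.normal(0, 1, 400) > 0).astype(int)
        Y = np.column_stack([y0, y1])
        Xq = rng.normal(size=(50, 4))
        singles, ensembles = [], []
        for seed in range(8):
            spec = BaseLearnerSpec("gbm", params={"max_iter": 50})
            singles.append(predict_chain(fit_cce(spec, X, Y, 1, seed).chains[0], Xq))
            ensembles.append(predict_cce(fit_cce(spec, X, Y, 6, seed + 100), Xq))
        v_single = np.var(np.stack(singles), axis=0).mean()
        v_ens = np.var(np.stack(ensembles), axis=0).mean()
        assert v_ens <= v_single

    def test_multilabel_frontend_kinds(self, rng):
        X = rng.normal(size=(200, 3))
        Y = (rng.random((200, 2)) < 0.4).astype(int)
        for kind in ("lrc", "gbm_cce", "gbm_independent"):
            m = fit_multilabel(ModelSpec(kind=kind, n_chains=2), X, Y, seed=0)
            S = m.score_matrix(X)
            assert S.shape == (200, 2)
            assert np.all((S >= 0) & (S <= 1))
        with pytest.raises(ModelError):
            ModelSpec(kind="svm")

    def test_independent_frontend_matches_fit_independent(self, rng):
        X = rng.normal(size=(150, 3))
        Y = (rng.random((150, 2)) < 0.4).astype(int)
        ms = fit_independent(BaseLearnerSpec("logistic"), X, Y, seed=0)
        S = predict_independent(ms, X)
        assert S.shape == (150, 2)


class TestSMBO:
    SPACE = {"x": (0.0, 1.0, "linear")}

    def test_budget_one_returns_single_point(self):
        calls = []

        def f(p):
            calls.append(p["x"])
            return -((p["x"] - 0.3) ** 2)

        best, val, traj = smbo_maximize(f, self.SPACE, budget=1, seed=0)
        assert len(traj) == 1
        assert best["x"] == calls[0]

    def test_quadratic_within_5pct_of_grid_optimum(self):
        # oracle: dense grid over the 1-D objective
        def f(p):
            return -((p["x"] - 0.62) ** 2)

        grid = np.linspace(0, 1, 2001)
        grid_best = grid[np.argmax(-((grid - 0.62) ** 2))]
        best, val, _ = smbo_maximize(f, self.SPACE, budget=25, seed=1)
        assert abs(best["x"] - grid_best) < 0.05

    def test_identical_seeds_identical_trajectories(self):
        def f(p):
            return np.sin(5 * p["x"]) * p["x"]

        _, _, t1 = smbo_maximize(f, self.SPACE, budget=12, seed=9)
        _, _, t2 = smbo_maximize(f, self.SPACE, budget=12, seed=9)
        assert [v for _, v in t1] == [v for _, v in t2]
        assert [p for p, _ in t1] == [p for p, _ in t2]

    def test_empty_space_rejected(self):
        with pytest.raises(ModelError, match="empty"):
            smbo_maximize(lambda p: 0.0, {}, budget=3)

    def test_zero_budget_rejected(self):
        with pytest.raises(ModelError, match="budget"):
            smbo_maximize(lambda p: 0.0, self.SPACE, budget=0)

    def test_int_and_log_dimensions_respected(self):
        space = {"trees": (50, 500, "int"), "lr": (0.01, 0.3, "log")}
        seen = []

        def f(p):
            seen.append(p)
            return 0.0

        smbo_maximize(f, space, budget=6, seed=3)
        for p in seen:
            assert isinstance(p["trees"], int) and 50 <= p["trees"] <= 500
            assert 0.01 <= p["lr"] <= 0.3


class TestTuneHyperparameters:
    def test_returns_spec_within_bounds_and_deterministic(self, rng):
        X, y = _toy_xy(rng, n=300)
        spec = BaseLearnerSpec("gbm")
        t1 = tune_hyperparameters(spec, X, y, budget=4, seed=2)
        t2 = tune_hyperparameters(spec, X, y, budget=4, seed=2)
        assert t1.params == t2.params
        from chaincv.models import GBM_SEARCH_SPACE

        for k, (lo, hi, _) in GBM_SEARCH_SPACE.items():
            assert lo <= t1.params[k] <= hi
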