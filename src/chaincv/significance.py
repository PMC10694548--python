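"""Permutation-based significance of cross-validated mean AUROC.

The null hypothesis is that the model discovered no relationship between
features and labels.  Each replicate applies one uniform permutation of
the label matrix's ROW ORDER against a fixed feature order — preserving
column marginals and the co-occurrence pattern multiset while severing all
feature-label association — and re-runs the complete cross-validated
evaluation with a fresh split plan and fresh model seeds.  The whole label
matrix is permuted jointly because chain models consume the other
disorders' labels.

The p-value convention is ``(count of null >= observed + 1) / B`` clamped
to 1, which makes the minimum attainable value 1/B (0.002 at B=500) and
never returns 0; ties count against significance.  The alternative
``(count + 1) / (B + 1)`` convention is available via config.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from chaincv.evaluation import evaluate_model


class SignificanceError(ValueError):
    pass


def bonferroni_adjust(alpha: float, m: int) -> float:
    """Family-wise error control: the adjusted per-test level alpha / m."""
    if not 0.0 < alpha < 1.0:
        raise SignificanceError(f"alpha must lie in (0, 1), got {alpha}")
    if m < 1:
        raise SignificanceError(f"number of tests must be >= 1, got {m}")
    return alpha / m


def permute_labels(Y, seed: int):
    """Uniform random permutation of the label matrix's rows."""
    if len(Y) == 0:
        raise SignificanceError("label matrix is empty")
    perm = np.random.default_rng(seed).permutation(len(Y))
    if isinstance(Y, pd.DataFrame):
        out = Y.iloc[perm].reset_index(drop=True)
        out.index = Y.index
        return out
    return np.asarray(Y)[perm]


@dataclass(frozen=True)
class PermutationConfig:
    n_permutations: int = 500
    alpha: float = 0.05
    n_tests: int = 20
    seed: int = 0
    p_convention: str = "count_plus_one_over_B"  # or "count_plus_one_over_B_plus_one"

    def __post_init__(self):
        if self.n_permutations < 1:
            raise SignificanceError("n_permutations must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise SignificanceError("alpha must lie in (0, 1)")
        if self.n_tests < 1:
            raise SignificanceError("n_tests must be >= 1")

    @property
    def adjusted_alpha(self) -> float:
        return bonferroni_adjust(self.alpha, self.n_tests)


def _p_value(count: int, B: int, convention: str) -> float:
    if convention == "count_plus_one_over_B":
        return min(1.0, (count + 1) / B)
    if convention == "count_plus_one_over_B_plus_one":
        return (count + 1) / (B + 1)
    raise SignificanceError(f"unknown p-value convention {convention!r}")


@dataclass
class PermutationResult:
    """Observed mean AUROCs, their permutation nulls, and p-values."""

    observed: pd.Series  # per disorder
    null: pd.DataFrame  # (B, disorders)
    config: PermutationConfig
    model_kind: str = ""
    observed_result: object = None

    @property
    def exceedance(self) -> pd.Series:
        # ties count against significance (>=)
        return (self.null.ge(self.observed, axis=1)).sum(axis=0)

    @property
    def p_values(self) -> pd.Series:
        B = self.config.n_permutations
        return self.exceedance.map(lambda c: _p_value(int(c), B, self.config.p_convention))

    @property
    def significant(self) -> pd.Series:
        return self.p_values <= self.config.adjusted_alpha

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "model": self.model_kind,
                "disorder": self.observed.index,
                "observed_mean_auroc": self.observed.values,
                "exceedance_count": self.exceedance.values,
                "p_value": self.p_values.values,
                "adjusted_alpha": self.config.adjusted_alpha,
                "significant": self.significant.values,
            }
        )

    def null_frame(self) -> pd.DataFrame:
        long = self.null.copy()
        long.insert(0, "replicate", np.arange(1, len(long) + 1))
        long = long.melt(id_vars="replicate", var_name="disorder", value_name="mean_auroc")
        long.insert(0, "model", self.model_kind)
        return long


def permutation_test(
    features,
    Y,
    model_spec,
    split_plan_factory,
    config: PermutationConfig,
    residualization: str = "none",
    confounders=None,
) -> PermutationResult:
    """Full permutation test of one model's cross-validated mean AUROC.

    ``split_plan_factory(Y, seed)`` must return a fresh split plan; it is
    invoked once for the observed labels and once per permutation, each
    with its own derived seed, so every replicate is a complete, freshly
    seeded pipeline run.
    """
    ss = np.random.SeedSequence(config.seed)
    seeds = ss.spawn(1 + config.n_permutations)

    def _run(labels, seed_seq, tag):
        child = seed_seq.spawn(3)
        split_seed = int(np.random.default_rng(child[0]).integers(0, 2**31 - 1))
        eval_seed = int(np.random.default_rng(child[1]).integers(0, 2**31 - 1))
        perm_seed = int(np.random.default_rng(child[2]).integers(0, 2**31 - 1))
        try:
            plan = split_plan_factory(labels, split_seed)
            res = evaluate_model(
                features,
                labels,
                model_spec,
                plan,
                residualization=residualization,
                confounders=confounders,
                seed=eval_seed,
            )
        except Exception as exc:
            raise SignificanceError(f"permutation run {tag} failed: {exc}") from exc
        return res, perm_seed

    observed_res, _ = _run(Y, seeds[0], "observed")
    observed = observed_res.mean_auroc()

    null_rows = []
    for b in range(config.n_permutations):
        child = seeds[b + 1].spawn(1)[0]
        perm_seed = int(np.random.default_rng(child).integers(0, 2**31 - 1))
        Yp = permute_labels(Y, perm_seed)
        res, _ = _run(Yp, seeds[b + 1], f"replicate {b + 1}")
        null_rows.append(res.mean_auroc())
    null = pd.DataFrame(null_rows).reset_index(drop=True)

    return PermutationResult(
        observed=observed,
        null=null,
        config=config,
        model_kind=getattr(model_spec, "kind", str(model_spec)),
        observed_result=observed_res,
    )
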