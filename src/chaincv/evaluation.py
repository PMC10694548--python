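"""Repeated multi-label stratified cross-validation and metrics.

Splitting uses iterative stratification: within each repeat, rows are
assigned label-by-label (rarest remaining label first) to the fold whose
desired count for that label is largest, so each fold's per-disorder
prevalence approximates the overall prevalence.  Every one of the
``n_repeats * n_folds`` splits is an independent experiment — a freshly
seeded model is fitted on the training rows only, and metrics are computed
per split and then averaged (never pooled).

AUROC is the rank-based (Mann-Whitney) statistic with ties counted 1/2.
The operating point for balanced accuracy / sensitivity / specificity is
the threshold maximizing Youden's J over all achievable cuts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from chaincv.confound_adjust import fit_residualizer, apply_residualizer
from chaincv.models import ModelSpec, fit_multilabel


class EvaluationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------


def iterative_stratification(Y: np.ndarray, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    """Assign each row to one of ``n_folds`` folds, stratifying all labels.

    Implementation of the iterative-stratification heuristic for
    multi-label data: process labels from rarest to most frequent,
    assigning each still-unassigned row carrying the current label to the
    fold with the greatest remaining demand for that label (ties broken by
    overall remaining capacity, then at random).  Rows with no positive
    label are distributed by remaining capacity.
    """
    Y = np.asarray(Y, int)
    n, L = Y.shape
    assignment = np.full(n, -1, dtype=int)
    capacity = np.full(n_folds, n / n_folds)
    desired = np.tile(Y.sum(axis=0) / n_folds, (n_folds, 1)).astype(float)  # (folds, labels)

    remaining_per_label = Y.sum(axis=0).astype(float)
    active = remaining_per_label > 0
    while True:
        unassigned = assignment < 0
        counts = Y[unassigned].sum(axis=0)
        counts = np.where(active & (counts > 0), counts, np.inf)
        if np.all(np.isinf(counts)):
            break
        lab = int(np.argmin(counts))
        rows = np.flatnonzero(unassigned & (Y[:, lab] == 1))
        rng.shuffle(rows)
        for r in rows:
            best = desired[:, lab]
            cand = np.flatnonzero(best == best.max())
            if len(cand) > 1:
                caps = capacity[cand]
                cand = cand[caps == caps.max()]
            f = int(rng.choice(cand)) if len(cand) > 1 else int(cand[0])
            assignment[r] = f
            capacity[f] -= 1
            desired[f, Y[r] == 1] -= 1
        active[lab] = False

    for r in np.flatnonzero(assignment < 0):
        cand = np.flatnonzero(capacity == capacity.max())
        f = int(rng.choice(cand)) if len(cand) > 1 else int(cand[0])
        assignment[r] = f
        capacity[f] -= 1
    return assignment


@dataclass(frozen=True)
class Split:
    repeat: int  # 1-based
    fold: int  # 1-based
    train_idx: np.ndarray
    test_idx: np.ndarray


@dataclass
class SplitPlan:
    """The full repeated-CV partition; the unit of all averaging."""

    splits: list
    n_rows: int
    n_repeats: int
    n_folds: int
    stratification_report: pd.DataFrame | None = None

    def __len__(self) -> int:
        return len(self.splits)

    def __iter__(self):
        return iter(self.splits)

    def to_frame(self, row_ids=None) -> pd.DataFrame:
        ids = np.asarray(row_ids) if row_ids is not None else np.arange(self.n_rows)
        rows = []
        for s in self.splits:
            for role, idx in (("train", s.train_idx), ("test", s.test_idx)):
                rows.append(
                    pd.DataFrame(
                        {
                            "repeat": s.repeat,
                            "fold": s.fold,
                            "role": role,
                            "row_id": ids[idx],
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)


def make_splits(Y, n_repeats: int = 30, n_folds: int = 5, seed: int = 0) -> SplitPlan:
    """Build the repeated multi-label stratified split plan.

    Produces ``n_repeats * n_folds`` (train, test) splits — 150 at the
    default configuration.  Within each repeat, the test folds partition
    all rows.  Deterministic given ``seed``.
    """
    if isinstance(Y, pd.DataFrame):
        names = list(Y.columns)
        Ym = Y.to_numpy(int)
    else:
        Ym = np.asarray(Y, int)
        names = [f"D{i}" for i in range(Ym.shape[1])]
    n = Ym.shape[0]
    if n < n_folds:
        raise EvaluationError(f"need at least n_folds={n_folds} rows, got {n}")
    counts = Ym.sum(axis=0)
    for j, c in enumerate(counts):
        if c < n_folds:
            raise EvaluationError(
                f"disorder {names[j]!r} has {int(c)} cases, fewer than n_folds={n_folds}"
            )
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    splits = []
    for rep in range(1, n_repeats + 1):
        assignment = iterative_stratification(Ym, n_folds, rng)
        for fold in range(1, n_folds + 1):
            test = np.flatnonzero(assignment == fold - 1)
            train = np.flatnonzero(assignment != fold - 1)
            splits.append(Split(repeat=rep, fold=fold, train_idx=train, test_idx=test))

    overall = counts / n
    rows = []
    for s in splits:
        prev = Ym[s.test_idx].mean(axis=0)
        rows.append(prev)
    prevs = np.array(rows)
    report = pd.DataFrame(
        {
            "disorder": names,
            "overall_prevalence": overall,
            "min_fold_prevalence": prevs.min(axis=0),
            "max_fold_prevalence": prevs.max(axis=0),
        }
    )
    return SplitPlan(
        splits=splits,
        n_rows=n,
        n_repeats=n_repeats,
        n_folds=n_folds,
        stratification_report=report,
    )


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def auroc(scores, labels) -> float:
    """Rank-based AUROC; ties contribute 1/2.  Requires both classes."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    n1 = int(labels.sum())
    n2 = len(labels) - n1
    if n1 == 0 or n2 == 0:
        raise EvaluationError("AUROC undefined: labels contain a single class")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n2))


def youden_threshold(scores, labels):
    """Operating point maximizing Youden's J = sensitivity + specificity - 1.

    Candidate thresholds are the midpoints between consecutive sorted
    unique scores plus the two infinities; classification is
    ``score >= threshold``.  Ties in J are broken toward the lower
    threshold.  Returns ``(threshold, J, sensitivity, specificity,
    balanced_accuracy)``; warns when the best J is not positive
    (anti-predictive or uninformative scores).
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    n1 = int(labels.sum())
    n2 = len(labels) - n1
    if n1 == 0 or n2 == 0:
        raise EvaluationError("Youden threshold undefined: labels contain a single class")
    uniq = np.unique(scores)
    cuts = np.concatenate(([-np.inf], (uniq[:-1] + uniq[1:]) / 2, [np.inf]))
    # sensitivity/specificity at every cut, vectorized over thresholds
    pred = scores[None, :] >= cuts[:, None]  # (cuts, n)
    tp = (pred & (labels == 1)[None, :]).sum(axis=1)
    tn = (~pred & (labels == 0)[None, :]).sum(axis=1)
    sens = tp / n1
    spec = tn / n2
    J = sens + spec - 1.0
    # exact integer maximization of J (= (tp*n2 + tn*n1)/(n1*n2) - 1) so
    # mathematically tied thresholds are not split by float rounding;
    # argmax returns the first (lowest) maximizer
    i = int(np.argmax(tp * n2 + tn * n1))
    if J[i] <= 0:
        warnings.warn("best Youden J is not positive; scores may be anti-predictive")
    return float(cuts[i]), float(J[i]), float(sens[i]), float(spec[i]), float((sens[i] + spec[i]) / 2)


# ---------------------------------------------------------------------------
# evaluation loop
# ---------------------------------------------------------------------------

METRIC_COLUMNS = (
    "auroc",
    "threshold",
    "youden_j",
    "balanced_accuracy",
    "sensitivity",
    "specificity",
    "n_cases",
    "n_controls",
)

RESIDUALIZATION_MODES = ("none", "per_split", "global")


@dataclass
class EvaluationResult:
    """Per-(split, disorder) metrics plus per-disorder aggregates."""

    per_split: pd.DataFrame
    disorder_names: tuple
    model_kind: str
    residualization: str

    def summary(self) -> pd.DataFrame:
        agg = self.per_split.groupby("disorder", sort=False).agg(
            mean_auroc=("auroc", "mean"),
            min_auroc=("auroc", "min"),
            max_auroc=("auroc", "max"),
            mean_balanced_accuracy=("balanced_accuracy", "mean"),
            min_balanced_accuracy=("balanced_accuracy", "min"),
            max_balanced_accuracy=("balanced_accuracy", "max"),
            mean_sensitivity=("sensitivity", "mean"),
            min_sensitivity=("sensitivity", "min"),
            max_sensitivity=("sensitivity", "max"),
            mean_specificity=("specificity", "mean"),
            min_specificity=("specificity", "min"),
            max_specificity=("specificity", "max"),
            n_splits=("auroc", "size"),
        )
        return agg.reset_index()

    def mean_auroc(self) -> pd.Series:
        return self.per_split.groupby("disorder", sort=False)["auroc"].mean()


def evaluate_model(
    features,
    Y,
    model_spec: ModelSpec,
    plan: SplitPlan,
    residualization: str = "none",
    confounders: pd.DataFrame | None = None,
    seed: int = 0,
    tuned_params: dict | None = None,
) -> EvaluationResult:
    """Run the full repeated-CV evaluation of one model.

    Every split fits a newly initialized model on the training rows only;
    with ``residualization="per_split"`` the confounder regression is also
    fitted on the training rows and applied to the test rows, with
    ``"global"`` it is fitted once on all rows up front (the leakier
    variant kept for comparability).  ``tuned_params`` optionally
    overrides the base-learner hyperparameters.
    """
    from chaincv.confound_adjust import encode_confounders, transform_confounders

    if residualization not in RESIDUALIZATION_MODES:
        raise EvaluationError(
            f"unknown residualization mode {residualization!r}; use one of {RESIDUALIZATION_MODES}"
        )
    if isinstance(Y, pd.DataFrame):
        names = tuple(Y.columns)
        Ym = Y.to_numpy(int)
    else:
        Ym = np.asarray(Y, int)
        names = tuple(f"D{i}" for i in range(Ym.shape[1]))
    X = features.to_numpy(float) if isinstance(features, pd.DataFrame) else np.asarray(features, float)
    if X.shape[0] != Ym.shape[0] or X.shape[0] != plan.n_rows:
        raise EvaluationError("features, labels and split plan are not row-aligned")

    design = None
    if residualization != "none":
        if confounders is None:
            raise EvaluationError(f"residualization={residualization!r} requires confounders")
        design = encode_confounders(confounders)
        if residualization == "global":
            r = fit_residualizer(X, design)
            X = np.asarray(apply_residualizer(r, X, design.matrix))

    if tuned_params:
        model_spec = ModelSpec(
            kind=model_spec.kind,
            base_params={**model_spec.base_params, **tuned_params},
            n_chains=model_spec.n_chains,
            hard_labels=model_spec.hard_labels,
        )

    split_seeds = np.random.SeedSequence(seed).spawn(len(plan))
    records = []
    for s, ss in zip(plan, split_seeds):
        try:
            Xtr, Xte = X[s.train_idx], X[s.test_idx]
            if residualization == "per_split":
                from chaincv.confound_adjust import ConfounderDesign

                Mtr = design.matrix[s.train_idx]
                Mte = design.matrix[s.test_idx]
                sub = ConfounderDesign(
                    columns=design.columns,
                    matrix=Mtr,
                    continuous=design.continuous,
                    categorical=design.categorical,
                    source_columns=design.source_columns,
                )
                r = fit_residualizer(Xtr, sub)
                Xtr = np.asarray(apply_residualizer(r, Xtr, Mtr))
                Xte = np.asarray(apply_residualizer(r, Xte, Mte))
            model_seed = int(np.random.default_rng(ss).integers(0, 2**31 - 1))
            fitted = fit_multilabel(model_spec, Xtr, Ym[s.train_idx], seed=model_seed)
            S = fitted.score_matrix(Xte)
            Yte = Ym[s.test_idx]
            for j, name in enumerate(names):
                a = auroc(S[:, j], Yte[:, j])
                thr, J, sens, spec, bacc = youden_threshold(S[:, j], Yte[:, j])
                records.append(
                    {
                        "repeat": s.repeat,
                        "fold": s.fold,
                        "disorder": name,
                        "auroc": a,
                        "threshold": thr,
                        "youden_j": J,
                        "balanced_accuracy": bacc,
                        "sensitivity": sens,
                        "specificity": spec,
                        "n_cases": int(Yte[:, j].sum()),
                        "n_controls": int(len(Yte) - Yte[:, j].sum()),
                    }
                )
        except Exception as exc:
            raise EvaluationError(
                f"evaluation failed at repeat={s.repeat} fold={s.fold}: {exc}"
            ) from exc
    per_split = pd.DataFrame.from_records(records)
    return EvaluationResult(
        per_split=per_split,
        disorder_names=names,
        model_kind=model_spec.kind,
        residualization=residualization,
    )
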