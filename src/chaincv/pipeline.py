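"""Config-driven orchestration: simulate -> assemble -> residualize ->
evaluate -> permutation-test -> report.

Every stage reads and writes plain CSV under a single run directory; the
master seed fans out to per-stage seeds through ``numpy.random
.SeedSequence(master_seed).spawn(...)`` in the fixed order (simulate,
assemble, evaluate, permtest), so re-running an identical config
reproduces every output byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from chaincv.cohort_assembly import apply_selection, build_label_matrix
from chaincv.evaluation import evaluate_model, make_splits
from chaincv.models import ModelSpec, tune_hyperparameters
from chaincv.significance import PermutationConfig, permutation_test
from chaincv.synthetic_cohort import Cohort, SyntheticScenario, scenario_preset

log = logging.getLogger("chaincv")


class PipelineError(RuntimeError):
    pass


SCALE_PROFILES = {
    # paper profile mirrors the published evaluation constants
    "paper": dict(n_repeats=30, n_folds=5, n_permutations=500),
    "desk": dict(n_repeats=2, n_folds=5, n_permutations=99),
}


@dataclass
class RunConfig:
    scenario: str = "null"  # preset name or path to a scenario file
    residualization: str = "none"  # none | per_split | global
    models: tuple = ("lrc", "gbm_cce")
    n_repeats: int = 2
    n_folds: int = 5
    n_permutations: int = 99
    alpha: float = 0.05
    n_tests: int | None = None  # default: len(models) * n_disorders
    tuning_budget: int = 0  # 0 disables tuning
    tune_mode: str = "once_per_disorder"
    n_chains: int = 10
    master_seed: int = 0
    out_dir: str = "runs/run0"
    scale_profile: str = "desk"

    def __post_init__(self):
        if self.scale_profile not in SCALE_PROFILES:
            raise PipelineError(
                f"unknown scale profile {self.scale_profile!r}; "
                f"use one of {tuple(SCALE_PROFILES)}"
            )
        self.models = tuple(self.models)

    @classmethod
    def from_profile(cls, profile: str, **overrides) -> "RunConfig":
        kw = dict(SCALE_PROFILES[profile], scale_profile=profile)
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        profile = d.pop("scale_profile", "desk")
        return cls.from_profile(profile, **d)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["models"] = list(self.models)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        d["models"] = list(self.models)
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


def load_scenario(ref: str) -> SyntheticScenario:
    from chaincv.synthetic_cohort import PRESET_NAMES

    if ref in PRESET_NAMES:
        return scenario_preset(ref)
    path = Path(ref)
    if path.exists():
        return SyntheticScenario.load(path)
    raise PipelineError(f"scenario {ref!r} is neither a preset ({PRESET_NAMES}) nor a file")


def stage_seeds(master_seed: int) -> dict:
    ss = np.random.SeedSequence(master_seed).spawn(4)
    names = ("simulate", "assemble", "evaluate", "permtest")
    return {
        name: int(np.random.default_rng(s).integers(0, 2**31 - 1))
        for name, s in zip(names, ss)
    }


def plan_jobs(config: RunConfig, n_disorders: int | None = None) -> dict:
    """Dry-run cost accounting for a config, computed without executing.

    Reports the experiment-grid sizes: permutation tests (models x
    disorders), CV splits per evaluation, and total evaluations / model
    fits implied by the permutation design.
    """
    if n_disorders is None:
        n_disorders = load_scenario(config.scenario).n_disorders
    n_models = len(config.models)
    splits_per_eval = config.n_repeats * config.n_folds
    evals_per_model = 1 + config.n_permutations
    return {
        "n_models": n_models,
        "n_disorders": n_disorders,
        "n_permutation_tests": n_models * n_disorders,
        "n_splits_per_evaluation": splits_per_eval,
        "n_evaluations_per_model": evals_per_model,
        "n_model_fits": n_models * evals_per_model * splits_per_eval,
        "n_test_evaluations_grid": n_models * n_disorders * evals_per_model * splits_per_eval,
    }


def model_spec_for(kind: str, config: RunConfig) -> ModelSpec:
    return ModelSpec(kind=kind, n_chains=config.n_chains)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def stage_simulate(config: RunConfig, out: Path) -> Cohort:
    scenario = load_scenario(config.scenario)
    seed = stage_seeds(config.master_seed)["simulate"]
    log.info("simulate: scenario=%s seed=%d", config.scenario, seed)
    from chaincv.synthetic_cohort import generate_cohort

    cohort = generate_cohort(scenario, seed)
    cohort.to_dir(out)
    scenario.save(out / "scenario.yaml")
    return cohort


def stage_assemble(config: RunConfig, out: Path, cohort: Cohort):
    seed = stage_seeds(config.master_seed)["assemble"]
    log.info("assemble: seed=%d", seed)
    selected, ledger = apply_selection(cohort, seed)
    labels, prevalence, patterns = build_label_matrix(selected)
    ledger.to_frame().to_csv(out / "selection_ledger.csv", index=False)
    labels.to_csv(out / "labels.csv")
    prevalence.rename("prevalence").to_csv(out / "prevalence.csv")
    patterns.to_csv(out / "cooccurrence_patterns.csv", index=False)
    return selected, labels


def stage_residualize(config: RunConfig, out: Path, selected: Cohort):
    """Write globally residualized features when mode is 'global'.

    In 'per_split' mode the regression happens inside the evaluation loop
    (fit on train, apply to test), so only the mode is logged here.
    """
    from chaincv.confound_adjust import (
        apply_residualizer,
        encode_confounders,
        fit_residualizer,
    )

    log.info("residualize: mode=%s", config.residualization)
    if config.residualization == "global":
        design = encode_confounders(selected.confounder_table())
        r = fit_residualizer(selected.features, design)
        resid = apply_residualizer(r, selected.features, design)
        resid.to_csv(out / "features_residualized.csv")
        return resid
    return selected.features


def stage_evaluate(config: RunConfig, out: Path, selected: Cohort, labels: pd.DataFrame):
    seed = stage_seeds(config.master_seed)["evaluate"]
    confounders = selected.confounder_table()
    per_split_frames, summary_frames = [], []
    tuned: dict = {}
    results = {}
    for i, kind in enumerate(config.models):
        plan = make_splits(labels, config.n_repeats, config.n_folds, seed=seed + i)
        plan.to_frame(labels.index.to_numpy()).assign(model=kind).to_csv(
            out / f"splits_{kind}.csv", index=False
        )
        spec = model_spec_for(kind, config)
        tuned_params = None
        if config.tuning_budget > 0 and kind != "lrc":
            tuned_params = _tune_once(config, selected, labels, spec, seed + 1000 + i)
            tuned[kind] = tuned_params
        res = evaluate_model(
            selected.features if config.residualization != "global" else pd.read_csv(
                out / "features_residualized.csv", index_col=0
            ),
            labels,
            spec,
            plan,
            residualization="per_split" if config.residualization == "per_split" else "none",
            confounders=confounders if config.residualization == "per_split" else None,
            seed=seed + 10_000 + i,
        )
        results[kind] = res
        per_split_frames.append(res.per_split.assign(model=kind))
        summary_frames.append(res.summary().assign(model=kind))
    pd.concat(per_split_frames, ignore_index=True).to_csv(
        out / "metrics_per_split.csv", index=False
    )
    pd.concat(summary_frames, ignore_index=True).to_csv(out / "metrics_summary.csv", index=False)
    if tuned:
        (out / "tuned_params.json").write_text(json.dumps(tuned, indent=2))
    return results


def _tune_once(config: RunConfig, selected: Cohort, labels: pd.DataFrame, spec: ModelSpec, seed: int):
    """Fast tune-once-per-disorder mode: tune on the most prevalent
    disorder and reuse the hyperparameters across members (logged)."""
    log.info("tuning: budget=%d mode=%s (fast desk-scale mode)", config.tuning_budget, config.tune_mode)
    target = labels.sum().idxmax()
    base = spec.base_spec(seed=seed)
    X = selected.features.to_numpy(float)
    tuned = tune_hyperparameters(base, X, labels[target].to_numpy(), budget=config.tuning_budget, seed=seed)
    return tuned.params


def stage_permtest(config: RunConfig, out: Path, selected: Cohort, labels: pd.DataFrame):
    seed = stage_seeds(config.master_seed)["permtest"]
    n_tests = config.n_tests or len(config.models) * labels.shape[1]
    confounders = selected.confounder_table()
    pval_frames, null_frames = [], []
    for i, kind in enumerate(config.models):
        pc = PermutationConfig(
            n_permutations=config.n_permutations,
            alpha=config.alpha,
            n_tests=n_tests,
            seed=seed + i,
        )
        res = permutation_test(
            selected.features,
            labels,
            model_spec_for(kind, config),
            lambda Y, s: make_splits(Y, config.n_repeats, config.n_folds, seed=s),
            pc,
            residualization="per_split" if config.residualization == "per_split" else "none",
            confounders=confounders if config.residualization == "per_split" else None,
        )
        pval_frames.append(res.to_frame())
        null_frames.append(res.null_frame())
    pd.concat(pval_frames, ignore_index=True).to_csv(out / "pvalues.csv", index=False)
    pd.concat(null_frames, ignore_index=True).to_csv(out / "null_distribution.csv", index=False)


REPORT_INPUTS = ("metrics_per_split.csv", "metrics_summary.csv", "pvalues.csv", "null_distribution.csv")


def make_report(run_dir) -> dict:
    """Build the summary tables from a completed run directory.

    Returns ``{"summary": <best-model table>, "figure_export": <observed
    vs null rows>}`` and writes ``report_summary.csv`` and
    ``report_figure_export.csv``.
    """
    run_dir = Path(run_dir)
    missing = [f for f in REPORT_INPUTS if not (run_dir / f).exists()]
    if missing:
        raise PipelineError(f"incomplete run; missing stage outputs: {missing}")
    summary = pd.read_csv(run_dir / "metrics_summary.csv")
    pvalues = pd.read_csv(run_dir / "pvalues.csv")

    best = (
        summary.sort_values("mean_auroc", ascending=False)
        .groupby("disorder", sort=False)
        .first()
        .reset_index()
        .rename(columns={"model": "best_model"})
    )
    best = best.merge(
        pvalues.rename(columns={"model": "best_model"})[
            ["best_model", "disorder", "p_value", "significant"]
        ],
        on=["best_model", "disorder"],
        how="left",
    )
    fig = pvalues[["model", "disorder", "observed_mean_auroc"]].copy()
    best.to_csv(run_dir / "report_summary.csv", index=False)
    fig.to_csv(run_dir / "report_figure_export.csv", index=False)
    return {"summary": best, "figure_export": fig}


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        config.to_yaml(out / "config.yaml")
        plan = plan_jobs(config)
        log.info("plan: %s", plan)
        if config.scale_profile == "paper":
            log.warning(
                "paper profile: %d model fits planned — cluster-scale at full n",
                plan["n_model_fits"],
            )
        cohort = stage_simulate(config, out)
        selected, labels = stage_assemble(config, out, cohort)
        stage_residualize(config, out, selected)
        stage_evaluate(config, out, selected, labels)
        stage_permtest(config, out, selected, labels)
        make_report(out)
        manifest = {
            "config_hash": config.config_hash(),
            "master_seed": config.master_seed,
            "stage_seeds": stage_seeds(config.master_seed),
            "plan": plan,
            "version": "0.1.0",
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    except Exception as exc:
        log.error("pipeline failed: %s", exc)
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
    return out
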