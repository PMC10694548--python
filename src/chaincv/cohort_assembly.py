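"""Participant selection and OR-rule label derivation.

Diagnostic reports arrive in long format: one row per (participant,
component code, informant) carrying three boolean time-state flags
(current / past / in-remission) and a missing indicator.  A disorder is
considered present for a child when *any* in-scope informant reports *any*
time state for *any* of the disorder's component codes.  A disorder label
is missing only when every in-scope report for some component is missing
and no positive report exists.

Selection removes, in this fixed order: participants with missing feature
vectors, participants with any missing disorder label, and all but one
randomly chosen child per family.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

TIME_STATES = ("current", "past", "remission")

INFORMANTS = ("parent", "self")


class AssemblyError(ValueError):
    """Raised on invalid selection or labelling inputs."""


class MissingLabelError(AssemblyError):
    """All in-scope reports for a label are missing."""


@dataclass(frozen=True)
class DiagnosisReport:
    """One informant's report for one component diagnosis code."""

    disorder_code: str
    informant: str  # "parent" | "self"
    current: bool = False
    past: bool = False
    remission: bool = False
    missing: bool = False

    def __post_init__(self) -> None:
        if self.informant not in INFORMANTS:
            raise AssemblyError(f"unknown informant {self.informant!r}")

    @property
    def positive(self) -> bool:
        return (not self.missing) and (self.current or self.past or self.remission)


@dataclass(frozen=True)
class DisorderDefinition:
    """A target disorder as an OR over component diagnosis codes.

    ``scope`` restricts which informants are consulted: ``"both"`` uses
    parent and self reports, ``"parent"`` uses parent reports only.
    """

    code: str
    components: tuple[str, ...]
    scope: str = "both"

    def __post_init__(self) -> None:
        if len(self.components) < 1:
            raise AssemblyError(f"definition {self.code!r} needs >=1 component")
        if self.scope not in ("both", "parent"):
            raise AssemblyError(f"definition {self.code!r}: scope must be 'both' or 'parent'")

    @property
    def informants(self) -> tuple[str, ...]:
        return INFORMANTS if self.scope == "both" else ("parent",)


#: Canonical target order used for every label matrix.
PAPER_DISORDER_ORDER = ("MDD", "BD", "PSY", "ADHD", "ODD", "CD", "PTSD", "OCD", "GAD", "SAD")


def paper_definitions() -> tuple[DisorderDefinition, ...]:
    """The ten target disorders, including the two composite categories.

    Bipolar disorder aggregates the type I and II diagnoses; psychotic
    symptoms aggregate hallucinations, delusions, associated psychotic
    symptoms and the unspecified schizophrenia-spectrum diagnosis, and are
    assessed from the parent interview only.
    """
    defs = []
    for code in PAPER_DISORDER_ORDER:
        if code == "BD":
            defs.append(DisorderDefinition("BD", ("BD1", "BD2")))
        elif code == "PSY":
            defs.append(DisorderDefinition("PSY", ("HALL", "DELU", "APSY", "USS"), scope="parent"))
        else:
            defs.append(DisorderDefinition(code, (code,)))
    return tuple(defs)


def simple_definitions(n_disorders: int) -> tuple[DisorderDefinition, ...]:
    """One single-component, both-informant definition per disorder (D0, D1, ...)."""
    return tuple(DisorderDefinition(f"D{i}", (f"D{i}",)) for i in range(n_disorders))


def or_rule_label(reports, scope: str = "both"):
    """Aggregate reports for one child and ONE component code.

    Returns 1 if any in-scope, non-missing report has any time-state flag
    set; 0 if at least one in-scope report is present and none is
    positive.  Raises :class:`MissingLabelError` when every in-scope
    report is missing (the signal that drives participant exclusion).
    """
    informants = INFORMANTS if scope == "both" else ("parent",)
    in_scope = [r for r in reports if r.informant in informants]
    if not in_scope:
        raise MissingLabelError("no in-scope reports")
    if any(r.positive for r in in_scope):
        return 1
    if all(r.missing for r in in_scope):
        raise MissingLabelError("all in-scope reports missing")
    return 0


def composite_label(reports, definition: DisorderDefinition):
    """OR over the definition's component codes of :func:`or_rule_label`.

    Positive components win over missing ones (the OR rule needs only one
    positive report); the label is missing only when some component is
    entirely missing and no component is positive.
    """
    any_missing = False
    for comp in definition.components:
        comp_reports = [r for r in reports if r.disorder_code == comp]
        try:
            if or_rule_label(comp_reports, definition.scope) == 1:
                return 1
        except MissingLabelError:
            any_missing = True
    if any_missing:
        raise MissingLabelError(f"{definition.code}: component reports all missing")
    return 0


def _labels_from_reports(reports: pd.DataFrame, definitions) -> pd.DataFrame:
    """Vectorized label derivation for a long-format report table.

    Returns a participant x disorder frame of {0.0, 1.0, NaN}; NaN marks a
    missing label.
    """
    req = {"participant_id", "disorder_code", "informant", "current", "past", "remission", "missing"}
    missing_cols = req - set(reports.columns)
    if missing_cols:
        raise AssemblyError(f"reports table lacks columns: {sorted(missing_cols)}")
    r = reports.copy()
    flags = r[["current", "past", "remission"]].astype(bool)
    r["positive"] = flags.any(axis=1) & ~r["missing"].astype(bool)

    pids = reports["participant_id"].unique()
    out = pd.DataFrame(index=pd.Index(pids, name="participant_id"))
    for d in definitions:
        scope = r["informant"].isin(d.informants)
        comp_missing = []
        comp_positive = []
        for comp in d.components:
            sel = r[(r["disorder_code"] == comp) & scope]
            if sel.empty:
                raise AssemblyError(f"no reports found for component code {comp!r}")
            g = sel.groupby("participant_id")
            comp_positive.append(g["positive"].any())
            comp_missing.append(g["missing"].all())
        positive = pd.concat(comp_positive, axis=1).any(axis=1)
        missing = pd.concat(comp_missing, axis=1).any(axis=1) & ~positive
        lab = positive.astype(float).where(~missing, np.nan)
        out[d.code] = lab.reindex(out.index)
    return out


@dataclass(frozen=True)
class SelectionLedger:
    """Participants removed at each selection step, in application order."""

    n_input: int
    removed_missing_features: int
    removed_missing_diagnosis: int
    removed_siblings: int

    @property
    def n_retained(self) -> int:
        return (
            self.n_input
            - self.removed_missing_features
            - self.removed_missing_diagnosis
            - self.removed_siblings
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": [
                    "input",
                    "missing_features",
                    "missing_diagnosis",
                    "sibling_exclusion",
                    "retained",
                ],
                "removed": [
                    0,
                    self.removed_missing_features,
                    self.removed_missing_diagnosis,
                    self.removed_siblings,
                    0,
                ],
                "remaining": [
                    self.n_input,
                    self.n_input - self.removed_missing_features,
                    self.n_input - self.removed_missing_features - self.removed_missing_diagnosis,
                    self.n_retained,
                    self.n_retained,
                ],
            }
        )


def apply_selection(cohort, seed: int):
    """Run the three-step selection flow on a cohort.

    Steps, in fixed order: (1) drop participants whose feature vector is
    missing; (2) drop participants with any missing derived disorder
    label; (3) retain exactly one uniformly-random child per family.
    Returns ``(selected_cohort, ledger)``.
    """
    if cohort.n == 0:
        raise AssemblyError("cohort is empty")
    parts = cohort.participants
    n_input = len(parts)

    feat_missing = cohort.features.isna().any(axis=1)
    # enforce the all-or-none invariant on feature missingness
    partially = feat_missing & ~cohort.features.isna().all(axis=1)
    if partially.any():
        raise AssemblyError("feature vectors must be fully present or fully missing")
    keep1 = parts["participant_id"][~feat_missing.loc[parts["participant_id"]].to_numpy()]
    removed1 = n_input - len(keep1)
    if len(keep1) == 0:
        raise AssemblyError("selection emptied the cohort at step: missing_features")

    labels = _labels_from_reports(
        cohort.reports[cohort.reports["participant_id"].isin(keep1)], cohort.definitions
    )
    labels = labels.reindex(keep1)
    any_missing = labels.isna().any(axis=1)
    keep2 = keep1[~any_missing.to_numpy()]
    removed2 = len(keep1) - len(keep2)
    if len(keep2) == 0:
        raise AssemblyError("selection emptied the cohort at step: missing_diagnosis")

    sub = parts.set_index("participant_id").loc[keep2].reset_index()
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(sub))
    shuffled = sub.iloc[order]
    chosen = shuffled.drop_duplicates(subset="family_id", keep="first")["participant_id"]
    keep3 = keep2[keep2.isin(set(chosen))]
    removed3 = len(keep2) - len(keep3)

    ledger = SelectionLedger(n_input, removed1, removed2, removed3)
    selected = dataclasses.replace(
        cohort,
        participants=parts[parts["participant_id"].isin(set(keep3))].reset_index(drop=True),
        features=cohort.features.loc[keep3],
        reports=cohort.reports[cohort.reports["participant_id"].isin(set(keep3))].reset_index(
            drop=True
        ),
        labels_truth=(
            cohort.labels_truth.loc[keep3] if cohort.labels_truth is not None else None
        ),
    )
    return selected, ledger


def build_label_matrix(cohort, definitions=None):
    """Derive the binary label matrix for an already-selected cohort.

    Returns ``(labels, prevalence, patterns)`` where ``labels`` is a
    participant x disorder 0/1 frame in the documented disorder order,
    ``prevalence`` the per-disorder mean, and ``patterns`` the relative
    frequency of each observed co-occurrence pattern (most frequent
    first) — the co-morbidity pattern table.
    """
    if definitions is None:
        definitions = cohort.definitions
    labels = _labels_from_reports(cohort.reports, definitions)
    labels = labels.reindex(cohort.participants["participant_id"])
    if labels.isna().any().any():
        bad = labels.columns[labels.isna().any()].tolist()
        raise AssemblyError(
            f"missing labels remain for {bad}; run apply_selection first"
        )
    labels = labels.astype(np.int8)
    prevalence = labels.mean()
    patterns = (
        labels.groupby(list(labels.columns))
        .size()
        .sort_values(ascending=False)
        .rename("frequency")
        / len(labels)
    )
    return labels, prevalence, patterns.reset_index()
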