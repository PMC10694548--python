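import numpy as np
import pandas as pd
import pytest

from chaincv.cohort_assembly import simple_definitions
from chaincv.synthetic_cohort import Cohort


def manual_cohort(participants, reports, features=None, n_features=3, definitions=None):
    """Construct a Cohort by hand for selection/labelling fixtures.

    ``participants``: list of (participant_id, family_id) or dicts with
    optional confounder overrides.  ``reports``: list of dicts with keys
    participant_id, disorder_code, informant and optional flag overrides.
    ``features``: mapping participant_id -> vector or None (missing).
    """
    rows = []
    for p in participants:
        if not isinstance(p, dict):
            p = {"participant_id": p[0], "family_id": p[1]}
        rows.append(
            {
                "participant_id": p["participant_id"],
                "family_id": p["family_id"],
                "age": p.get("age", 9.9),
                "sex": p.get("sex", "F"),
                "marriage": p.get("marriage", "married"),
                "site": p.get("site", "site0"),
                "education": p.get("education", "bachelor"),
                "ethnicity": p.get("ethnicity", "white"),
                "stv": p.get("stv", 1.05e6),
            }
        )
    parts = pd.DataFrame(rows)
    pids = parts["participant_id"].tolist()

    feat_cols = [f"f{i:03d}" for i in range(n_features)]
    fm = {}
    features = features or {}
    for pid in pids:
        v = features.get(pid, np.zeros(n_features))
        fm[pid] = np.full(n_features, np.nan) if v is None else np.asarray(v, float)
    feats = pd.DataFrame.from_dict(fm, orient="index", columns=feat_cols)
    feats.index.name = "participant_id"
    feats = feats.loc[pids]

    rep_rows = []
    for r in reports:
        rep_rows.append(
            {
                "participant_id": r["participant_id"],
                "disorder_code": r["disorder_code"],
                "informant": r.get("informant", "parent"),
                "current": bool(r.get("current", False)),
                "past": bool(r.get("past", False)),
                "remission": bool(r.get("remission", False)),
                "missing": bool(r.get("missing", False)),
            }
        )
    reps = pd.DataFrame(rep_rows)
    if definitions is None:
        codes = sorted(reps["disorder_code"].unique()) if len(reps) else ["D0"]
        definitions = tuple(
            d for d in simple_definitions(len(codes))
        )
        # align simple definitions to the observed codes
        from chaincv.cohort_assembly import DisorderDefinition

        definitions = tuple(DisorderDefinition(c, (c,)) for c in codes)
    names = tuple(d.code for d in definitions)
    return Cohort(
        participants=parts,
        features=feats,
        reports=reps,
        labels_truth=None,
        definitions=tuple(definitions),
        disorder_names=names,
    )


def full_reports(pids, codes, positives=(), missing=(), informants=("parent", "self")):
    """All-negative report grid with selected (pid, code, informant) positives."""
    out = []
    positives = set(positives)
    missing = set(missing)
    for pid in pids:
        for code in codes:
            for inf in informants:
                out.append(
                    {
                        "participant_id": pid,
                        "disorder_code": code,
                        "informant": inf,
                        "current": (pid, code, inf) in positives,
                        "missing": (pid, code, inf) in missing,
                    }
                )
    return out


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
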