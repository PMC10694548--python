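"""Linear residualization of features on a sociodemographic design.

Continuous confounders are standardized, categoricals one-hot encoded with
the first level dropped, and an intercept appended.  Per-feature ordinary
least squares fits yield a :class:`Residualizer` that can be applied to
held-out rows without re-fitting (the leakage-safe per-split mode) or to
the full sample (the global mode).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class ConfounderError(ValueError):
    pass


@dataclass
class ConfounderDesign:
    """Encoded confounder design with the fitted encoding map.

    ``matrix`` is (n, p) with the intercept as the first column.
    ``continuous`` maps column name -> (mean, sd); ``categorical`` maps
    column name -> ordered level tuple (first level dropped on encoding).
    """

    columns: tuple
    matrix: np.ndarray
    continuous: dict = field(default_factory=dict)
    categorical: dict = field(default_factory=dict)
    source_columns: tuple = ()

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def p(self) -> int:
        return self.matrix.shape[1]


def _is_categorical(s: pd.Series) -> bool:
    return s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == bool


def encode_confounders(table: pd.DataFrame, categorical=None) -> ConfounderDesign:
    """Encode a confounder table into a full-rank design matrix.

    Columns listed in ``categorical`` (default: inferred from dtype) are
    one-hot encoded with the first (sorted) level dropped; the rest are
    standardized to zero mean / unit variance.  Raises on missing values,
    constant non-intercept columns, and rank deficiency.
    """
    if table.isna().any().any():
        bad = table.columns[table.isna().any()].tolist()
        raise ConfounderError(f"missing confounder values in columns {bad}")
    if categorical is None:
        categorical = [c for c in table.columns if _is_categorical(table[c])]
    categorical = set(categorical)

    names = ["intercept"]
    cols = [np.ones(len(table))]
    cont_map: dict = {}
    cat_map: dict = {}
    for c in table.columns:
        if c in categorical:
            levels = tuple(sorted(map(str, table[c].unique())))
            if len(levels) < 2:
                raise ConfounderError(f"categorical column {c!r} is constant")
            cat_map[c] = levels
            vals = table[c].astype(str)
            for lev in levels[1:]:
                names.append(f"{c}={lev}")
                cols.append((vals == lev).to_numpy(float))
        else:
            x = table[c].to_numpy(float)
            sd = x.std()
            if sd == 0:
                raise ConfounderError(f"continuous column {c!r} is constant")
            cont_map[c] = (float(x.mean()), float(sd))
            names.append(c)
            cols.append((x - x.mean()) / sd)
    M = np.column_stack(cols)
    if np.linalg.matrix_rank(M) < M.shape[1]:
        raise ConfounderError("encoded design is rank-deficient")
    return ConfounderDesign(
        columns=tuple(names),
        matrix=M,
        continuous=cont_map,
        categorical=cat_map,
        source_columns=tuple(table.columns),
    )


def transform_confounders(design: ConfounderDesign, table: pd.DataFrame) -> np.ndarray:
    """Encode new rows with a previously fitted encoding map.

    Unseen categorical levels raise, naming the level and column.
    """
    if tuple(table.columns) != design.source_columns:
        raise ConfounderError(
            f"confounder columns {tuple(table.columns)} do not match "
            f"fitted columns {design.source_columns}"
        )
    names = ["intercept"]
    cols = [np.ones(len(table))]
    for c in table.columns:
        if c in design.categorical:
            levels = design.categorical[c]
            vals = table[c].astype(str)
            unseen = set(vals.unique()) - set(levels)
            if unseen:
                raise ConfounderError(
                    f"unseen level(s) {sorted(unseen)} in categorical column {c!r}"
                )
            for lev in levels[1:]:
                names.append(f"{c}={lev}")
                cols.append((vals == lev).to_numpy(float))
        else:
            mean, sd = design.continuous[c]
            names.append(c)
            cols.append((table[c].to_numpy(float) - mean) / sd)
    return np.column_stack(cols)


@dataclass
class Residualizer:
    """Per-feature OLS coefficients mapping the design onto the features."""

    coef: np.ndarray  # (p, n_features)
    design_columns: tuple
    fitted_n: int
    feature_names: tuple = ()

    def predict(self, design_matrix: np.ndarray) -> np.ndarray:
        return design_matrix @ self.coef


def _as_matrix(features):
    if isinstance(features, pd.DataFrame):
        return features.to_numpy(float), tuple(features.columns), features.index
    return np.asarray(features, float), (), None


def fit_residualizer(features, design: ConfounderDesign) -> Residualizer:
    """Least-squares fit of every feature on the encoded design."""
    X, feat_names, _ = _as_matrix(features)
    M = design.matrix
    if X.shape[0] != M.shape[0]:
        raise ConfounderError(
            f"features have {X.shape[0]} rows but design has {M.shape[0]}"
        )
    if M.shape[0] < M.shape[1]:
        raise ConfounderError("fewer rows than design columns")
    if np.linalg.matrix_rank(M) < M.shape[1]:
        raise ConfounderError("design is rank-deficient; refusing to pseudo-invert")
    coef, *_ = np.linalg.lstsq(M, X, rcond=None)
    return Residualizer(
        coef=coef, design_columns=design.columns, fitted_n=M.shape[0], feature_names=feat_names
    )


def apply_residualizer(resid: Residualizer, features, design_matrix):
    """Subtract the fitted confounder contribution; never re-fits.

    ``design_matrix`` may be a :class:`ConfounderDesign` (its columns are
    checked against the fitting description) or a raw encoded matrix.
    """
    if isinstance(design_matrix, ConfounderDesign):
        if design_matrix.columns != resid.design_columns:
            raise ConfounderError(
                f"design columns {design_matrix.columns} do not match fitted "
                f"columns {resid.design_columns}"
            )
        M = design_matrix.matrix
    else:
        M = np.asarray(design_matrix, float)
        if M.shape[1] != resid.coef.shape[0]:
            raise ConfounderError(
                f"design has {M.shape[1]} columns, residualizer expects "
                f"{resid.coef.shape[0]}"
            )
    X, feat_names, index = _as_matrix(features)
    R = X - resid.predict(M)
    if index is not None:
        return pd.DataFrame(R, index=index, columns=list(feat_names))
    return R
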