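"""Tabular preparation for subject-by-attribute data.

Clinical tables such as the OASIS-2 visit table mix demographics
(age, gender, education), clinical scores (SES, MMSE) and MRI-derived
volumetrics (eTIV, nWBV, ASF) on wildly different scales, with missing
entries in some columns and near-collinear feature pairs. Before a
distance-based clustering stage can be meaningful every attribute must be
brought to a comparable scale; this module provides the standard pipeline:

* binary categorical encoding (e.g. gender M/F -> 0/1),
* mean imputation of missing values (on the raw scale),
* min-max normalization to [0, 1],
* pairwise Pearson correlation screening for redundant features.

All operations are pure: they return a new :class:`FeatureTable` and never
mutate their input. Fit/transform are split so that statistics can be
learned on a training fold and applied to held-out rows without leakage.
"""

from __future__ import annotations

import copy
import json
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FeatureTable",
    "encode_categorical",
    "drop_columns",
    "fit_minmax",
    "transform_minmax",
    "inverse_minmax",
    "fit_mean_impute",
    "transform_impute",
    "pearson_matrix",
    "high_correlation_pairs",
]

_DEFAULT_NA = ("", "NA", "NaN", "nan")


class FeatureTable:
    """A subject-by-attribute table with optional binary labels.

    Parameters
    ----------
    data : pandas.DataFrame
        M rows by n attribute columns. Numeric columns may contain NaN for
        missing entries; object columns are allowed only until they are
        encoded with :func:`encode_categorical`.
    labels : array-like of {0, 1}, optional
        Binary class per row (1 = positive / demented). NaN not allowed.
    fitted : dict, optional
        Per-column preprocessing statistics (see :func:`fit_minmax`,
        :func:`fit_mean_impute`). Treated as immutable once present.
    """

    def __init__(self, data: pd.DataFrame, labels=None, fitted: dict | None = None):
        if not isinstance(data, pd.DataFrame):
            data = pd.DataFrame(data)
        if data.shape[0] < 1 or data.shape[1] < 1:
            raise ValueError("FeatureTable requires at least one row and one column")
        self.data = data.reset_index(drop=True)
        if labels is not None:
            labels = np.asarray(labels)
            if labels.shape != (len(self.data),):
                raise ValueError(
                    f"labels length {labels.shape} does not match {len(self.data)} rows"
                )
            uniq = set(np.unique(labels[~pd.isna(labels)]).tolist())
            if not uniq <= {0, 1, 0.0, 1.0}:
                raise ValueError(f"labels must be binary 0/1, got values {sorted(uniq)}")
            labels = labels.astype(int)
        self.labels = labels
        self.fitted = fitted if fitted is not None else {}

    # -- basic introspection -------------------------------------------------
    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_rows(self) -> int:
        return len(self.data)

    @property
    def values(self) -> np.ndarray:
        """Float matrix of the features; raises if categoricals remain."""
        non_numeric = [
            c for c in self.data.columns
            if not pd.api.types.is_numeric_dtype(self.data[c])
        ]
        if non_numeric:
            raise ValueError(
                f"columns {non_numeric} are not numeric; encode them first"
            )
        return self.data.to_numpy(dtype=float)

    # -- construction helpers ------------------------------------------------
    @classmethod
    def read_csv(cls, path, label_column: str | None = None,
                 na_values: Sequence[str] = _DEFAULT_NA) -> "FeatureTable":
        df = pd.read_csv(path, na_values=list(na_values), keep_default_na=False)
        labels = None
        if label_column is not None:
            if label_column not in df.columns:
                raise KeyError(f"label column {label_column!r} not in CSV header")
            labels = df.pop(label_column).to_numpy()
        return cls(df, labels=labels)

    def to_csv(self, path, label_column: str | None = None) -> None:
        df = self.data.copy()
        if label_column is not None and self.labels is not None:
            df[label_column] = self.labels
        df.to_csv(path, index=False)

    def select_rows(self, rows) -> "FeatureTable":
        """Row subset (e.g. a CV fold); fitted state is NOT carried over."""
        rows = np.asarray(rows)
        labels = self.labels[rows] if self.labels is not None else None
        return FeatureTable(self.data.iloc[rows], labels=labels)

    def _replace(self, data=None, fitted=None) -> "FeatureTable":
        return FeatureTable(
            self.data if data is None else data,
            labels=self.labels,
            fitted=self.fitted if fitted is None else fitted,
        )

    # -- fitted-state serialization -------------------------------------------
    def fitted_to_json(self) -> str:
        return json.dumps(self.fitted, sort_keys=True)

    @staticmethod
    def fitted_from_json(text: str) -> dict:
        return json.loads(text)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        lab = "labelled" if self.labels is not None else "unlabelled"
        return f"<FeatureTable {self.n_rows}x{len(self.columns)} {lab}>"


def _check_columns(table: FeatureTable, columns: Iterable[str]) -> list[str]:
    cols = list(columns)
    missing = [c for c in cols if c not in table.data.columns]
    if missing:
        raise KeyError(f"columns not present: {missing}")
    return cols


def encode_categorical(table: FeatureTable, column: str,
                       mapping: Mapping) -> FeatureTable:
    """Replace a categorical column by numeric 0/1 codes.

    Every non-missing value must appear in ``mapping``; an unknown category
    raises a ``ValueError`` naming the offending value.
    """
    _check_columns(table, [column])
    series = table.data[column]
    codes = set(mapping.values())
    if not codes <= {0, 1}:
        raise ValueError(f"mapping codes must be 0/1, got {sorted(codes)}")
    out = []
    for v in series:
        if pd.isna(v):
            out.append(np.nan)
        elif v in mapping:
            out.append(float(mapping[v]))
        else:
            raise ValueError(
                f"value {v!r} in column {column!r} not covered by mapping {dict(mapping)}"
            )
    data = table.data.copy()
    data[column] = out
    return table._replace(data=data)


def drop_columns(table: FeatureTable, columns: Iterable[str]) -> FeatureTable:
    cols = _check_columns(table, columns)
    return table._replace(data=table.data.drop(columns=cols))


def fit_minmax(table: FeatureTable, columns: Iterable[str] | None = None) -> FeatureTable:
    """Learn per-column (min, max) from this table's non-missing entries.

    Constant columns are stored with a ``degenerate`` flag; their transform
    maps every value to 0.0 so small folds never error out.
    """
    if "minmax" in table.fitted:
        raise ValueError("min-max state already fitted; fitted state is immutable")
    cols = _check_columns(table, table.columns if columns is None else columns)
    stats: dict[str, dict] = {}
    for c in cols:
        x = pd.to_numeric(table.data[c], errors="coerce")
        obs = x.dropna()
        if obs.empty:
            raise ValueError(f"column {c!r} is entirely missing; cannot fit min/max")
        lo, hi = float(obs.min()), float(obs.max())
        stats[c] = {"min": lo, "max": hi, "degenerate": bool(lo == hi)}
    fitted = copy.deepcopy(table.fitted)
    fitted["minmax"] = stats
    return table._replace(fitted=fitted)


def transform_minmax(table: FeatureTable,
                     fitted: dict | None = None) -> FeatureTable:
    """Apply ``(x - min) / (max - min)`` per fitted column.

    Values outside the fitted range transform linearly without clamping, so
    held-out rows may fall outside [0, 1]; missing entries stay missing.
    """
    state = (fitted or table.fitted).get("minmax")
    if state is None:
        raise ValueError("no fitted min-max state; call fit_minmax first")
    data = table.data.copy()
    for c, st in state.items():
        if c not in data.columns:
            continue
        x = pd.to_numeric(data[c], errors="coerce")
        if st["degenerate"]:
            data[c] = np.where(x.isna(), np.nan, 0.0)
        else:
            data[c] = (x - st["min"]) / (st["max"] - st["min"])
    fitted_out = copy.deepcopy(table.fitted)
    fitted_out.setdefault("minmax", copy.deepcopy(state))
    return table._replace(data=data, fitted=fitted_out)


def inverse_minmax(table: FeatureTable, fitted: dict | None = None) -> FeatureTable:
    """Map normalized values back to the raw scale (non-degenerate columns)."""
    state = (fitted or table.fitted).get("minmax")
    if state is None:
        raise ValueError("no fitted min-max state")
    data = table.data.copy()
    for c, st in state.items():
        if c in data.columns and not st["degenerate"]:
            data[c] = data[c] * (st["max"] - st["min"]) + st["min"]
    return table._replace(data=data)


def fit_mean_impute(table: FeatureTable, columns: Iterable[str]) -> FeatureTable:
    """Store per-column means of the non-missing entries (raw scale)."""
    if "mean" in table.fitted:
        raise ValueError("imputation state already fitted; fitted state is immutable")
    cols = _check_columns(table, columns)
    means: dict[str, float] = {}
    for c in cols:
        x = pd.to_numeric(table.data[c], errors="coerce").dropna()
        if x.empty:
            raise ValueError(f"column {c!r} is entirely missing; cannot fit mean")
        means[c] = float(x.mean())
    fitted = copy.deepcopy(table.fitted)
    fitted["mean"] = means
    return table._replace(fitted=fitted)


def transform_impute(table: FeatureTable, fitted: dict | None = None) -> FeatureTable:
    """Fill missing entries with the fitted means; observed values untouched."""
    state = (fitted or table.fitted).get("mean")
    if state is None:
        raise ValueError("no fitted imputation state; call fit_mean_impute first")
    data = table.data.copy()
    for c, mean in state.items():
        if c in data.columns:
            x = pd.to_numeric(data[c], errors="coerce")
            data[c] = x.fillna(mean)
    fitted_out = copy.deepcopy(table.fitted)
    fitted_out.setdefault("mean", copy.deepcopy(state))
    return table._replace(data=data, fitted=fitted_out)


def pearson_matrix(table: FeatureTable) -> pd.DataFrame:
    """Pairwise Pearson correlation of all feature columns.

    Requires at least two rows and no missing values (impute first).
    Correlations involving a zero-variance column are reported as NaN
    (undefined marker) rather than raising.
    """
    X = table.values
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows for correlation")
    if np.isnan(X).any():
        raise ValueError("missing values present; impute before correlation")
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = (Xc.T @ Xc) / X.shape[0]
        corr = cov / np.outer(sd, sd)
    corr[~np.isfinite(corr)] = np.nan
    np.fill_diagonal(corr, np.where(sd > 0, 1.0, np.nan))
    return pd.DataFrame(corr, index=table.columns, columns=table.columns)


def high_correlation_pairs(corr: pd.DataFrame,
                           threshold: float = 0.95) -> list[tuple[str, str, float]]:
    """Report feature pairs with |r| >= threshold, sorted by |r| descending.

    Feature dropping itself is a deliberate user decision (e.g. dropping eTIV
    once its near-collinearity with ASF is confirmed); this only reports.
    """
    pairs = []
    cols = list(corr.columns)
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            r = corr.iloc[i, j]
            if np.isfinite(r) and abs(r) >= threshold:
                pairs.append((cols[i], cols[j], float(r)))
    return sorted(pairs, key=lambda p: -abs(p[2]))
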