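"""Registry cleaning, temporal splitting and train-window standardization.

Cleaning follows the registry's deterministic preprocessing rules: a missing
categorical/ordinal risk factor is assumed to be at baseline level (code 0,
risk factor absent), missing age is imputed as the median patient age of the
same calendar year, records with missing mortality status are removed and
counted, and out-of-declared-range values are clipped with a report.

Standardization (subtract mean, divide by SD) is fitted on the training
window only and applied unchanged to the holdout window.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import FeatureSpec

__all__ = [
    "CleaningReport",
    "clean_records",
    "temporal_split",
    "Standardizer",
    "fit_standardizer",
    "apply_standardizer",
]


@dataclass
class CleaningReport:
    """Bookkeeping of what cleaning changed."""

    rows_in: int = 0
    rows_out: int = 0
    missing_outcome_removed: int = 0
    imputed: dict[str, int] = field(default_factory=dict)
    clipped: dict[str, int] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


def clean_records(table: pd.DataFrame,
                  feature_specs: tuple[FeatureSpec, ...],
                  age_column: str = "age",
                  month_column: str = "month",
                  outcome_column: str = "mortality",
                  ) -> tuple[pd.DataFrame, CleaningReport]:
    """Apply the deterministic registry cleaning rules.

    Non-missing values are never altered except by declared-range clipping;
    the record count changes only through missing-outcome removal.
    """
    report = CleaningReport(rows_in=len(table))
    df = table.copy()

    missing_outcome = df[outcome_column].isna()
    report.missing_outcome_removed = int(missing_outcome.sum())
    df = df.loc[~missing_outcome].copy()
    df[outcome_column] = df[outcome_column].astype(int)

    years = pd.PeriodIndex(df[month_column], freq="M").year

    for spec in feature_specs:
        col = spec.name
        if col not in df.columns:
            continue
        miss = df[col].isna()
        n_miss = int(miss.sum())
        if n_miss:
            if spec.kind == "continuous":
                if col != age_column:
                    raise ValueError(
                        f"continuous feature {col!r} has no declared baseline; "
                        "only age carries a median-by-year imputation rule"
                    )
                year_arr = np.asarray(years)
                miss_arr = miss.to_numpy()
                for year in np.unique(year_arr[miss_arr]):
                    sel = (year_arr == year) & miss_arr
                    donors = df.loc[(year_arr == year) & ~miss_arr, col]
                    if donors.empty:
                        raise ValueError(f"no non-missing ages in year {year}")
                    df.loc[sel, col] = float(donors.median())
            else:
                df.loc[miss, col] = 0.0  # baseline level: risk factor absent
            report.imputed[col] = n_miss
        # declared-range clipping of erroneously inputted values
        if spec.kind == "continuous":
            lo = -np.inf if spec.lower is None else spec.lower
            hi = np.inf if spec.upper is None else spec.upper
        else:
            lo, hi = 0, spec.n_levels - 1
        vals = df[col].astype(float)
        out_of_range = (vals < lo) | (vals > hi)
        if out_of_range.any():
            df[col] = vals.clip(lo, hi)
            report.clipped[col] = int(out_of_range.sum())

    report.rows_out = len(df)
    return df, report


def temporal_split(table: pd.DataFrame, boundary: str,
                   month_column: str = "month") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition records at a calendar boundary.

    Records with month strictly before ``boundary`` (ISO date or "YYYY-MM")
    form the training window; records at/after it the holdout window.  Row
    order within each part is preserved.
    """
    cut = pd.Period(pd.Timestamp(boundary), freq="M") if "-" in str(boundary) and len(
        str(boundary)) > 7 else pd.Period(boundary, freq="M")
    months = pd.PeriodIndex(table[month_column], freq="M")
    before = months < cut
    train = table.loc[before].copy()
    holdout = table.loc[~before].copy()
    if train.empty or holdout.empty:
        warnings.warn(f"temporal boundary {boundary} leaves one side empty", stacklevel=2)
    return train, holdout


class Standardizer:
    """Column-wise (x - mean) / SD transform fitted on the training window.

    Sample (n-1) SD is used.  By default continuous and ordinal features are
    standardized while binary flags pass through unchanged
    (``include_binary=True`` switches that).  Columns with zero SD are
    passed through unscaled and listed in ``constant_columns_``.
    """

    def __init__(self, feature_specs: tuple[FeatureSpec, ...],
                 include_binary: bool = False):
        self.feature_specs = tuple(feature_specs)
        self.include_binary = include_binary

    @property
    def _candidate_columns(self) -> list[str]:
        kinds = ("continuous", "ordinal") if not self.include_binary else (
            "continuous", "ordinal", "binary")
        return [f.name for f in self.feature_specs if f.kind in kinds]

    def fit(self, table: pd.DataFrame) -> "Standardizer":
        self.mean_: dict[str, float] = {}
        self.scale_: dict[str, float] = {}
        self.constant_columns_: list[str] = []
        for col in self._candidate_columns:
            if col not in table.columns:
                continue
            x = table[col].to_numpy(dtype=float)
            sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
            if sd <= 0.0:
                self.constant_columns_.append(col)
                continue
            self.mean_[col] = float(np.mean(x))
            self.scale_[col] = sd
        return self

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "mean_"):
            raise RuntimeError("Standardizer is not fitted")
        df = table.copy()
        for col, mu in self.mean_.items():
            if col in df.columns:
                df[col] = (df[col].astype(float) - mu) / self.scale_[col]
        return df

    def fit_transform(self, table: pd.DataFrame) -> pd.DataFrame:
        return self.fit(table).transform(table)

    def to_dict(self) -> dict:
        return {"mean": dict(self.mean_), "scale": dict(self.scale_),
                "constant": list(self.constant_columns_),
                "include_binary": self.include_binary}


def fit_standardizer(train_table: pd.DataFrame,
                     feature_specs: tuple[FeatureSpec, ...],
                     include_binary: bool = False) -> Standardizer:
    return Standardizer(feature_specs, include_binary=include_binary).fit(train_table)


def apply_standardizer(stats: Standardizer, table: pd.DataFrame) -> pd.DataFrame:
    return stats.transform(table)
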