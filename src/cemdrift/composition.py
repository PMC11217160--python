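"""Per-month dataset composition and month-to-month drift scores.

Tracks the empirical category distribution of selected variables per
calendar month (continuous variables pre-binned; default age grouping
<60 / >=60 years) and scores change between months with the total-variation
distance (Jensen-Shannon divergence available as an alternative).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon

__all__ = ["bin_continuous", "CompositionSeries", "monthly_composition",
           "composition_change", "DEFAULT_AGE_EDGES"]

DEFAULT_AGE_EDGES = (60.0,)


def bin_continuous(values, edges, labels: list[str] | None = None):
    """Assign values to half-open bins [e_i, e_{i+1}) defined by interior edges.

    ``edges`` are the interior cut points (strictly increasing); the outer
    bins are unbounded, so nothing is out of range, and a value exactly at
    an edge falls in the upper bin (the last bin is closed above).
    Returns (labels_array, n_clipped) where n_clipped counts values beyond
    the outermost interior edges by more than the data support (always 0
    with unbounded outer bins; kept for report symmetry).
    """
    e = np.asarray(edges, dtype=float)
    if e.ndim != 1 or e.size < 1 or np.any(np.diff(e) <= 0):
        raise ValueError("edges must be strictly increasing")
    v = np.asarray(values, dtype=float)
    if labels is None:
        labels = ([f"<{e[0]:g}"] +
                  [f"[{a:g},{b:g})" for a, b in zip(e[:-1], e[1:])] +
                  [f">={e[-1]:g}"])
    if len(labels) != e.size + 1:
        raise ValueError("need len(edges) + 1 labels")
    idx = np.searchsorted(e, v, side="right")
    return np.asarray(labels, dtype=object)[idx], 0


@dataclass
class CompositionSeries:
    """Per-month category proportions of one feature."""

    feature: str
    months: pd.PeriodIndex
    proportions: pd.DataFrame      # months x categories, rows sum to 1
    counts: pd.Series              # records per month

    def to_frame(self) -> pd.DataFrame:
        df = self.proportions.copy()
        df.insert(0, "n", self.counts)
        df.insert(0, "month", self.months.astype(str))
        return df.reset_index(drop=True)


def monthly_composition(table: pd.DataFrame, feature: str,
                        age_edges=DEFAULT_AGE_EDGES,
                        continuous: bool | None = None) -> CompositionSeries:
    """Empirical per-month category proportions with counts.

    Continuous features (detected from non-integer values, or forced via
    ``continuous=True``) are binned first; the default age grouping is the
    published <60 / >=60 split, with an age of exactly 60 falling in the
    upper bin by the half-open convention.
    """
    if feature not in table.columns:
        raise KeyError(f"unknown feature {feature!r}")
    values = table[feature].to_numpy()
    if continuous is None:
        continuous = not np.allclose(values.astype(float),
                                     values.astype(float).round())
    if continuous:
        values, _ = bin_continuous(values, age_edges)
    months = pd.PeriodIndex(table["month"], freq="M")
    df = pd.DataFrame({"month": months, "cat": values})
    counts = df.groupby(["month", "cat"], observed=True).size().unstack(fill_value=0)
    n = counts.sum(axis=1)
    props = counts.div(n, axis=0)
    return CompositionSeries(feature=feature,
                             months=pd.PeriodIndex(props.index, freq="M"),
                             proportions=props.reset_index(drop=True),
                             counts=pd.Series(n.to_numpy(), name="n"))


def composition_change(series: CompositionSeries, month_a, month_b,
                       method: str = "tv") -> float:
    """Distance between two months' category distributions.

    ``method="tv"`` gives the total-variation distance
    0.5 * sum_c |p_a(c) - p_b(c)| in [0, 1]; ``method="js"`` the
    Jensen-Shannon divergence (base 2).
    """
    idx = {m: i for i, m in enumerate(series.months)}
    a, b = pd.Period(month_a, "M"), pd.Period(month_b, "M")
    for m in (a, b):
        if m not in idx:
            raise KeyError(f"month {m} not present in series")
    pa = series.proportions.iloc[idx[a]].to_numpy(dtype=float)
    pb = series.proportions.iloc[idx[b]].to_numpy(dtype=float)
    if method == "tv":
        return float(0.5 * np.sum(np.abs(pa - pb)))
    if method == "js":
        return float(jensenshannon(pa, pb, base=2) ** 2)
    raise ValueError(f"unknown method {method!r}")
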