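"""End-to-end drift-monitoring pipeline and reporting utilities.

``run_pipeline`` ties the stages together in the study's design order:
simulate (or load) -> clean -> temporal split -> standardize -> train the
requested model families with CV selection -> whole-holdout bootstrap
evaluation with the paired comparison battery -> per-month metric series
with trend fits -> variable-importance drift for the best model ->
composition drift for the top variables -> net-benefit projection.  The
output is a JSON-serialisable report in which every number is traceable to
a (stage, seed, settings) header; reruns with the same config are
byte-identical.

A single master seed fans out into named sub-seeds (generator, CV,
bootstrap, importance) so each component is independently reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import drift as _drift
from . import importance as _importance
from . import composition as _composition
from .euroscore2 import euroscore2_risk
from .metrics import bootstrap_evaluate, default_thresholds
from .models import ModelSpec, cross_validate_select, fit_final, predict_risk
from .preprocessing import clean_records, fit_standardizer, temporal_split
from .synthetic import GeneratorConfig, generate_cohort, nacsa_like_config

log = logging.getLogger("cemdrift")

__all__ = ["RunConfig", "run_pipeline", "percentage", "cohort_counts_report",
           "cohort_table_report", "subseed"]


def subseed(master: int, name: str) -> int:
    """Named deterministic sub-seed below 2**31."""
    h = np.random.SeedSequence([master, *name.encode()]).generate_state(1)[0]
    return int(h % (2 ** 31))


def percentage(numerator: float, denominator: float) -> float:
    """Plain percentage 100 * numerator / denominator."""
    if denominator == 0:
        raise ZeroDivisionError("empty denominator")
    return 100.0 * numerator / denominator


def cohort_counts_report(n_total: int, n_deaths: int, n_train: int,
                         n_holdout: int) -> dict[str, float]:
    """Headline cohort bookkeeping from raw counts."""
    if n_train + n_holdout != n_total:
        raise ValueError("split sizes must partition the cohort")
    return {
        "n_total": n_total,
        "n_deaths": n_deaths,
        "mortality_pct": percentage(n_deaths, n_total),
        "n_train": n_train,
        "n_holdout": n_holdout,
        "train_pct": percentage(n_train, n_total),
        "holdout_pct": percentage(n_holdout, n_total),
    }


def cohort_table_report(table: pd.DataFrame, boundary: str) -> dict[str, float]:
    """Same bookkeeping computed from a patient table and split boundary."""
    train, holdout = temporal_split(table, boundary)
    return cohort_counts_report(len(table), int(table["mortality"].sum()),
                                len(train), len(holdout))


@dataclass
class RunConfig:
    """Schema-checked pipeline configuration.

    Every stage seed is explicit after construction, filled from
    ``master_seed``.
    """

    master_seed: int = 0
    split_date: str = "2017-01-01"
    models: tuple[str, ...] = ("logistic_regression", "xgboost")
    control_model: str | None = None        # default: best CEM
    bootstrap_B: int = 200
    #: F1 binarisation threshold; None resolves to the training-window
    #: outcome prevalence at run time (recorded in the report) — at a 2.76%
    #: mortality prevalence a fixed 0.5 cutoff predicts no deaths at all and
    #: leaves F1 (hence CEM) degenerate.
    f1_threshold: float | None = None
    ece_bins: int = 10
    dca_step: float = 0.01
    alpha: float = 0.05
    projection_month: int = 156             # Jan 2017 -> Jan 2030
    include_euroscore2: bool = False
    run_importance: bool = True
    importance_model: str = "xgboost"
    top_variables: int = 3
    generator: dict | None = None           # GeneratorConfig dict; None -> default small
    model_overrides: dict = field(default_factory=dict)   # family -> fixed_params
    seeds: dict = field(default_factory=dict)

    def __post_init__(self):
        self.models = tuple(self.models)
        for name in ("generator", "cv", "bootstrap", "importance"):
            self.seeds.setdefault(name, subseed(self.master_seed, name))
        if self.f1_threshold is not None and not 0 < self.f1_threshold < 1:
            raise ValueError("f1_threshold must lie in (0,1)")
        if self.bootstrap_B < 1:
            raise ValueError("bootstrap_B must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def thresholds(self) -> np.ndarray:
        if self.dca_step == 0.01:
            return default_thresholds()
        return np.round(np.arange(self.dca_step, 1.0, self.dca_step), 10)


def _stage(name):
    log.info("stage: %s", name)


def run_pipeline(config: RunConfig, table: pd.DataFrame | None = None) -> dict:
    """Execute the full design and return the report bundle.

    ``table`` may supply a pre-loaded registry; otherwise the synthetic
    generator runs with ``config.generator`` (or a small default cohort).
    Any stage failure aborts with the stage name; partial results computed
    so far are attached to the raised exception's ``partial`` attribute.
    """
    report: dict = {"settings": config.to_dict(), "stages": {}}
    stage = "simulate"
    try:
        if table is None:
            _stage(stage)
            if config.generator:
                gen = GeneratorConfig.from_dict(config.generator)
            else:
                gen = nacsa_like_config(n_per_month=400, start_month="2015-01",
                                        end_month="2017-12",
                                        seed=config.seeds["generator"])
            table = generate_cohort(gen)
            report["stages"]["simulate"] = {"n": len(table),
                                            "months": int(table["month"].nunique()),
                                            "seed": gen.seed}
            specs = gen.features
        else:
            from .synthetic import NACSA_FEATURES
            specs = NACSA_FEATURES

        stage = "clean"
        _stage(stage)
        clean, cleaning = clean_records(table, specs)
        report["stages"]["clean"] = dataclasses.asdict(cleaning)

        stage = "split"
        _stage(stage)
        train, holdout = temporal_split(clean, config.split_date)
        report["stages"]["split"] = cohort_counts_report(
            len(clean), int(clean["mortality"].sum()), len(train), len(holdout))
        f1_thr = (config.f1_threshold if config.f1_threshold is not None
                  else float(train["mortality"].mean()))
        report["stages"]["split"]["f1_threshold"] = f1_thr

        stage = "standardize"
        _stage(stage)
        stats = fit_standardizer(train, specs)
        train_s = stats.transform(train)
        holdout_s = stats.transform(holdout)
        report["stages"]["standardize"] = stats.to_dict()

        stage = "train"
        _stage(stage)
        preds: dict[str, pd.DataFrame] = {}
        chosen: dict[str, dict] = {}
        for family in config.models:
            spec = ModelSpec(family, seed=config.seeds["cv"],
                             fixed_params=config.model_overrides.get(family))
            params, _cv = cross_validate_select(spec, train_s, f1_threshold=f1_thr,
                                                ece_bins=config.ece_bins)
            model = fit_final(spec, train_s, params)
            preds[family] = predict_risk(model, holdout_s)
            chosen[family] = params
        if config.include_euroscore2:
            preds["euroscore2"] = pd.DataFrame({
                "probability": euroscore2_risk(holdout),
                "outcome": holdout["mortality"].to_numpy(),
                "month": holdout["month"].to_numpy()})
        report["stages"]["train"] = {"chosen_hyperparameters": chosen}

        stage = "evaluate"
        _stage(stage)
        t_grid = config.thresholds()
        summaries = {
            name: bootstrap_evaluate(p["probability"].to_numpy(),
                                     p["outcome"].to_numpy().astype(int),
                                     B=config.bootstrap_B,
                                     f1_threshold=f1_thr,
                                     n_bins=config.ece_bins, thresholds=t_grid,
                                     seed=config.seeds["bootstrap"])
            for name, p in preds.items()}
        report["stages"]["evaluate"] = {k: v.as_dict() for k, v in summaries.items()}
        cem_matrix = pd.DataFrame({k: v.samples["cem"] for k, v in summaries.items()}
                                  ).dropna()
        control = config.control_model or max(summaries,
                                              key=lambda k: summaries[k].point["cem"])
        if len(preds) >= 2:
            comps = _drift.compare_models_nontemporal(cem_matrix, control,
                                                      seed=config.seeds["bootstrap"])
            report["stages"]["evaluate"]["comparisons"] = {
                k: v.as_dict() for k, v in comps.items()}
        report["stages"]["evaluate"]["control_model"] = control

        stage = "drift"
        _stage(stage)
        drift_out = {}
        series_by_model = {}
        for name, p in preds.items():
            series = _drift.monthly_series(p, metric="cem", B=config.bootstrap_B,
                                           seed=config.seeds["bootstrap"],
                                           f1_threshold=f1_thr,
                                           n_bins=config.ece_bins, thresholds=t_grid)
            series_by_model[name] = series
            fit = _drift.fit_drift(series, alpha=config.alpha)
            entry = {"series": series.to_frame().to_dict(orient="list"),
                     "fit": fit.as_dict(), "missing_months": series.missing_months}
            if fit.method == "linear_regression":
                entry["projection"] = {
                    "month_index": config.projection_month,
                    "value": _drift.project_metric(fit, config.projection_month)}
            drift_out[name] = entry
        report["stages"]["drift"] = drift_out

        if config.run_importance and config.importance_model in config.models:
            stage = "importance"
            _stage(stage)
            spec = ModelSpec(config.importance_model, seed=config.seeds["importance"],
                             fixed_params=config.model_overrides.get(
                                 config.importance_model))
            holdout_raw = holdout  # importance on cleaned, unstandardized slices
            imp = _importance.importance_series(holdout_raw, spec,
                                                seed=config.seeds["importance"])
            top = _importance.top_features(imp, m=max(config.top_variables, 6))
            report["stages"]["importance"] = {
                "top_features": top,
                "series": imp.drop_duplicates(["month_index", "feature"])[
                    ["month_index", "feature", "geomean"]].to_dict(orient="list"),
                "backend": imp["backend"].iloc[0],
                "missing_months": imp.attrs.get("missing_months", [])}

            stage = "dataset_drift"
            _stage(stage)
            comp_out = {}
            for feat in top[:config.top_variables]:
                series = _composition.monthly_composition(holdout, feat)
                tv = [float(_composition.composition_change(
                    series, series.months[i - 1], series.months[i]))
                    for i in range(1, len(series.months))]
                comp_out[feat] = {"months": [str(m) for m in series.months],
                                  "proportions": series.proportions.to_dict(orient="list"),
                                  "month_to_month_tv": tv}
            report["stages"]["dataset_drift"] = comp_out
    except Exception as exc:
        exc.partial = report  # retain partial outputs for debugging
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return report


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=_default)


def _default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
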