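"""Reading breath tables, analysis configuration and report bundles.

Input is delimited text (comma or tab, auto-detected) with a time column
in seconds from exercise onset and a VO2 column in either mL·kg⁻¹·min⁻¹
or mL·min⁻¹ (converted at load time given body mass).  Output is a JSON
report (canonical) plus flat CSV tables of the processed series and the
fitted/residual curves.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from . import preprocessing as pp
from .comparison import comparison_report, extra_ss_f_test
from .errors import InvalidInputError, Vo2FitError
from .fitting import FitResult, bootstrap_fit, fit_model
from .models import (
    asc_difference,
    asc_end,
    baseline_a0,
    end_vo2,
    get_model,
)
from .series import ABSOLUTE, PER_KG, BreathSeries


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_breath_table(
    path,
    time_col: str | int = 0,
    vo2_col: str | int = 1,
    unit: str = PER_KG,
    body_mass: float | None = None,
    delimiter: str | None = None,
    time_offset: float = 0.0,
    label: str | None = None,
) -> BreathSeries:
    """Parse a delimited breath-by-breath table into a BreathSeries.

    Columns may be named (header present) or positional (0-based).
    Duplicate timestamps are averaged; absolute VO2 is converted to
    mL·kg⁻¹·min⁻¹ using ``body_mass``.  ``time_offset`` is added to the
    time column to realign the exercise onset at t = 0.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=delimiter, engine="python",
                         header="infer" if isinstance(time_col, str) else None,
                         comment="#")
    except Exception as exc:
        raise InvalidInputError(f"{path}: cannot parse table: {exc}") from exc

    def column(col):
        if isinstance(col, str):
            if col not in df.columns:
                raise InvalidInputError(
                    f"{path}: missing column {col!r}; found {list(df.columns)}"
                )
            return df[col]
        if col >= df.shape[1]:
            raise InvalidInputError(
                f"{path}: table has only {df.shape[1]} columns, need index {col}"
            )
        return df.iloc[:, col]

    t_raw, v_raw = column(time_col), column(vo2_col)
    t = pd.to_numeric(t_raw, errors="coerce")
    v = pd.to_numeric(v_raw, errors="coerce")
    bad = t.isna() | v.isna()
    if bad.any():
        lines = (np.flatnonzero(bad.to_numpy()) + 2).tolist()[:10]
        raise InvalidInputError(
            f"{path}: non-numeric cells at line(s) {lines}"
        )
    if unit == ABSOLUTE and (body_mass is None or body_mass <= 0):
        raise InvalidInputError(
            f"{path}: VO2 in mL·min⁻¹ requires a positive body_mass (kg)"
        )
    series = BreathSeries.from_samples(
        t.to_numpy(float) + time_offset, v.to_numpy(float),
        unit=unit, body_mass=body_mass, label=label or path.name,
    )
    return series.to_per_kg() if unit == ABSOLUTE else series


# ---------------------------------------------------------------------------
# Analysis configuration
# ---------------------------------------------------------------------------

#: filter chain entry: (name, {param: value}); applied in order after trimming
FilterStep = tuple[str, dict[str, Any]]


@dataclass
class AnalysisConfig:
    """Everything needed to reproduce one analysis run."""

    input_paths: list[str]
    models: list[str] = field(default_factory=lambda: ["bi_td"])
    time_col: str | int = 0
    vo2_col: str | int = 1
    unit: str = PER_KG
    body_mass: float | None = None
    time_offset: float = 0.0
    rest_path: str | None = None
    trim_cutoff: float = 20.0
    baseline_window: float = 120.0
    end_window: float = 60.0
    filters: list[FilterStep] = field(default_factory=list)
    bounds: dict[str, list[float]] = field(default_factory=dict)
    bootstrap_B: int = 1000
    seed: int = 0
    alpha: float = 0.05
    compare: list[str] | None = None   # [simple, complex]
    out_dir: str = "."
    formats: list[str] = field(default_factory=lambda: ["json", "csv"])

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "AnalysisConfig":
        raw = json.loads(text)
        raw["filters"] = [tuple(f) for f in raw.get("filters", [])]
        return cls(**raw)


_FILTERS = {
    "rolling_sd": lambda s, p: pp.rolling_sd_exclude(s, **p)[0],
    "box": lambda s, p: pp.box_average(s, **p),
    "moving_average": lambda s, p: pp.moving_average(s, **p),
    "interpolate_1s": lambda s, p: pp.interpolate_1s(s),
    "delete": lambda s, p: pp.delete_points(s, **p),
}


def _apply_filters(series: BreathSeries, steps: Sequence[FilterStep]) -> BreathSeries:
    for name, params in steps:
        if name not in _FILTERS:
            raise InvalidInputError(
                f"unknown filter {name!r}; available: {sorted(_FILTERS)}"
            )
        series = _FILTERS[name](series, params)
    return series


def _fit_to_dict(fit: FitResult) -> dict:
    return {
        "model": fit.spec.name,
        "estimates": fit.estimates,
        "rss": fit.rss,
        "df_residual": fit.df_residual,
        "se_regression": fit.se_regression,
        "converged": fit.converged,
        "n_iterations": fit.n_iterations,
        "init_used": fit.init_used,
        "bounds_used": {p: list(b) for p, b in fit.bounds_used.items()},
    }


def run_analysis(cfg: AnalysisConfig) -> dict:
    """Execute the full pipeline described by ``cfg`` and write the bundle.

    read → (ensemble when several inputs) → trim → filters → fit(s) →
    bootstrap → derived measures → optional nested comparison.  The report
    (JSON), the processed series and per-model fitted/residual curves
    (CSV) land in ``cfg.out_dir``.
    """
    for m in cfg.models:
        get_model(m)
    if cfg.compare:
        get_model(cfg.compare[0]), get_model(cfg.compare[1])
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {"config": json.loads(cfg.to_json()), "stages": []}

    def stage(name):
        report["stages"].append(name)

    try:
        stage("read")
        inputs = [
            read_breath_table(p, cfg.time_col, cfg.vo2_col, cfg.unit,
                              cfg.body_mass, time_offset=cfg.time_offset)
            for p in cfg.input_paths
        ]
        series = inputs[0] if len(inputs) == 1 else pp.ensemble_average(inputs)

        a0_measured = None
        if cfg.rest_path:
            stage("baseline")
            rest = read_breath_table(cfg.rest_path, cfg.time_col, cfg.vo2_col,
                                     cfg.unit, cfg.body_mass)
            a0_measured = baseline_a0(rest, window=cfg.baseline_window)
            report["baseline_a0"] = a0_measured

        stage("trim")
        raw_end = end_vo2(series, window=cfg.end_window)
        trimmed = pp.trim_cardiodynamic(series, cfg.trim_cutoff) \
            if cfg.trim_cutoff > 0 else series
        stage("filter")
        processed = _apply_filters(trimmed, cfg.filters)

        stage("fit")
        bounds = {p: tuple(b) for p, b in cfg.bounds.items()}
        fits: dict[str, FitResult] = {}
        report["fits"] = {}
        for name in cfg.models:
            spec = get_model(name)
            fixed = {"A0": a0_measured} \
                if name == "mono_td_fixed_baseline" and a0_measured is not None \
                else None
            fit = fit_model(processed, spec, bounds=bounds or None,
                            fixed=fixed, seed=cfg.seed)
            fits[name] = fit
            report["fits"][name] = _fit_to_dict(fit)

        stage("bootstrap")
        report["bootstrap"] = {}
        for name, fit in fits.items():
            if not fit.converged:
                report["bootstrap"][name] = None
                continue
            bs = bootstrap_fit(processed, fit.spec, fit,
                               B=cfg.bootstrap_B, seed=cfg.seed)
            report["bootstrap"][name] = {
                "B": bs.B, "seed": bs.seed,
                "n_failed_refits": bs.n_failed_refits,
                "parameters": bs.stats,
            }

        stage("derived")
        report["derived"] = {}
        for name, fit in fits.items():
            est = fit.estimates
            d = {"vo2_end": raw_end, "t_end": series.t_end,
                 "A0": est.get("A0")}
            if "Ap" in est:
                d["Asc_diff"] = asc_difference(raw_end, est["A0"], est["Ap"])
            if "Asc" in est and series.t_end >= est["TDsc"]:
                d["A_sc_end"] = asc_end(est["Asc"], est["TDsc"],
                                        est["tau_sc"], series.t_end)
            report["derived"][name] = d

        if cfg.compare:
            stage("compare")
            simple, complex_ = cfg.compare
            cmp = extra_ss_f_test(fits[simple], fits[complex_], alpha=cfg.alpha)
            report["comparison"] = {
                "simple": simple, "complex": complex_,
                "f_value": cmp.f_value, "df_num": cmp.df_num,
                "df_den": cmp.df_den, "p_value": cmp.p_value,
                "alpha": cmp.alpha, "preferred": cmp.preferred,
                "shapiro_simple": list(cmp.shapiro_simple),
                "shapiro_complex": list(cmp.shapiro_complex),
            }
            comparison_report(cmp).to_csv(out / "comparison.csv", index=False)

        stage("write")
        pd.DataFrame({"time": processed.time, "vo2": processed.vo2}).to_csv(
            out / "processed.csv", index=False
        )
        for name, fit in fits.items():
            pd.DataFrame({
                "time": fit.time, "observed": fit.vo2,
                "fitted": fit.fitted, "residual": fit.residuals,
            }).to_csv(out / f"curve_{name}.csv", index=False)
        report["converged_all"] = all(f.converged for f in fits.values())
    except Vo2FitError as exc:
        report["error"] = {"stage": report["stages"][-1], "message": str(exc)}
        (out / "report.json").write_text(json.dumps(report, indent=2, default=_json_default))
        raise
    (out / "report.json").write_text(json.dumps(report, indent=2, default=_json_default))
    return report
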