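"""Bounded nonlinear least-squares fitting and residual-bootstrap precision.

Point estimates come from trust-region-reflective least squares
(scipy.optimize.least_squares) inside wide physiological box bounds; on a
failed solve the fit is retried from a fixed number of jittered starting
points.  Estimate precision is quantified by the residual bootstrap:
observed residuals are resampled with replacement, added back to the
fitted curve at the observed times, and the model is refit (warm-started
from the original estimates); per-parameter mean, SD, CV% and percentile
95% CIs summarize the B resampled refits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import (
    InsufficientDataError,
    InvalidParameterError,
    NumericError,
    UnstableFitError,
)
from .models import ModelSpec, Params
from .series import BreathSeries

#: jittered restarts attempted when the first solve fails to converge
MULTISTART_RESTARTS = 5
#: relative jitter applied to the starting point on each restart
MULTISTART_JITTER = 0.2


@dataclass
class FitResult:
    """Outcome of one bounded least-squares fit of one model on one series."""

    spec: ModelSpec
    estimates: Params                 # free + fixed parameters
    residuals: np.ndarray             # observed − fitted, per sample
    rss: float
    df_residual: int
    se_regression: float
    converged: bool
    n_iterations: int
    init_used: Params
    bounds_used: dict[str, tuple[float, float]]
    time: np.ndarray = field(repr=False, default=None)
    vo2: np.ndarray = field(repr=False, default=None)

    @property
    def free_estimates(self) -> Params:
        return {p: self.estimates[p] for p in self.spec.free_params}

    @property
    def fitted(self) -> np.ndarray:
        return self.vo2 - self.residuals

    @property
    def n_samples(self) -> int:
        return int(self.residuals.size)


def default_init(series: BreathSeries, spec: ModelSpec,
                 fixed: Mapping[str, float] | None = None) -> Params:
    """Heuristic starting values from the series itself.

    Baseline from the first 10 s; amplitudes split the observed rise
    (all of it for mono forms, 80/20 between fast and slow components for
    bi-exponential forms); delays and time constants at typical severe-
    intensity values (TDp 15 s, τp 25 s, TDsc 120 s, τsc 60 s).  Values
    are clipped into the default bounds.
    """
    if series.n < 2:
        raise InsufficientDataError("need at least 2 samples to initialize a fit")
    series = series.to_per_kg()
    v = series.vo2
    first10 = v[series.time <= series.t_start + 10.0]
    a0 = float(first10.mean()) if first10.size else float(v[0])
    rise = max(float(v.max()) - a0, 1.0)
    init: Params = {}
    for p in spec.free_params:
        if p == "A0":
            init[p] = a0
        elif p == "Ap":
            init[p] = rise if spec.name.startswith("mono") or spec.name == "logistic" \
                else (0.7 * rise if spec.name == "tri" else 0.8 * rise)
        elif p == "TDp":
            init[p] = 15.0
        elif p == "tau_p":
            init[p] = 25.0
        elif p == "Asc":
            init[p] = 0.2 * rise
        elif p == "TDsc":
            init[p] = 120.0
        elif p == "tau_sc":
            init[p] = 60.0
        elif p == "Ac":
            init[p] = 0.1 * rise
        elif p == "tau_c":
            init[p] = 10.0
        elif p == "k":
            init[p] = 0.05
        elif p == "t50":
            above = np.flatnonzero(v >= a0 + 0.5 * rise)
            init[p] = float(series.time[above[0]]) if above.size else 0.5 * series.t_end
    bounds = spec.default_bounds(series.t_end)
    for p, (lo, hi) in bounds.items():
        init[p] = float(np.clip(init[p], lo, hi))
    return init


def _prepare_fixed(series: BreathSeries, spec: ModelSpec,
                   fixed: Mapping[str, float] | None) -> Params:
    out = dict(spec.fixed_params)
    if fixed:
        out.update(fixed)
    if spec.name == "mono_td_fixed_baseline" and (fixed is None or "A0" not in fixed):
        # default the fixed baseline to the first-10-s mean of the series
        first10 = series.vo2[series.time <= series.t_start + 10.0]
        out["A0"] = float(first10.mean()) if first10.size else float(series.vo2[0])
    return out


def fit_model(
    series: BreathSeries,
    spec: ModelSpec,
    init: Params | None = None,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    fixed: Mapping[str, float] | None = None,
    multistart: int = MULTISTART_RESTARTS,
    seed: int = 0,
    max_nfev: int | None = None,
    ftol: float = 1e-14,
) -> FitResult:
    """Fit ``spec`` to ``series`` by bounded nonlinear least squares.

    ``fixed`` overrides the spec's structurally fixed parameter values
    (e.g. the measured resting baseline for ``mono_td_fixed_baseline``).
    On a failed first solve, up to ``multistart`` jittered restarts are
    attempted (deterministic given ``seed``); the best candidate is kept
    and ``converged`` reflects whether any solve succeeded.
    """
    series = series.to_per_kg()
    if series.n <= spec.n_free:
        raise InsufficientDataError(
            f"{series.n} samples cannot identify {spec.n_free} free parameters"
        )
    fixed_full = _prepare_fixed(series, spec, fixed)
    if init is None:
        init = default_init(series, spec, fixed_full)
    init = {p: float(init[p]) for p in spec.free_params}
    bmap = spec.default_bounds(series.t_end)
    if bounds:
        bmap.update({p: (float(lo), float(hi)) for p, (lo, hi) in bounds.items()})
    for p, (lo, hi) in bmap.items():
        if not lo < hi:
            raise InvalidParameterError(f"bounds for {p} must satisfy lower < upper")
        if not lo <= init[p] <= hi:
            raise InvalidParameterError(
                f"initial value for {p} ({init[p]}) outside bounds [{lo}, {hi}]"
            )
    names = spec.free_params
    lo = np.array([bmap[p][0] for p in names])
    hi = np.array([bmap[p][1] for p in names])
    t, y = series.time, series.vo2

    def resid(x: np.ndarray) -> np.ndarray:
        params = dict(zip(names, x))
        params.update(fixed_full)
        return y - spec.curve(params, t)

    x0 = np.array([init[p] for p in names])
    r0 = resid(x0)
    if not np.all(np.isfinite(r0)):
        raise NumericError(
            f"non-finite objective at the initial point for model {spec.name!r}"
        )

    def solve(x_start):
        return least_squares(
            resid, x_start, bounds=(lo, hi), method="trf", x_scale="jac",
            ftol=ftol, xtol=ftol, gtol=ftol, max_nfev=max_nfev,
        )

    res = solve(x0)
    n_iter = int(res.nfev)
    converged = bool(res.success and np.isfinite(res.cost))
    if not converged and multistart > 0:
        rng = np.random.default_rng(seed)
        best = res if np.isfinite(res.cost) else None
        for _ in range(multistart):
            jitter = 1.0 + rng.uniform(-MULTISTART_JITTER, MULTISTART_JITTER, x0.size)
            xj = np.clip(x0 * jitter, lo, hi)
            try:
                cand = solve(xj)
            except Exception:
                continue
            n_iter += int(cand.nfev)
            if not np.isfinite(cand.cost):
                continue
            if best is None or cand.cost < best.cost or (cand.success and not converged):
                best = cand
            if cand.success:
                converged = True
                break
        if best is not None:
            res = best
    if not np.isfinite(res.cost):
        raise NumericError(f"fit of {spec.name!r} produced a non-finite objective")

    estimates = dict(zip(names, (float(v) for v in res.x)))
    estimates.update(fixed_full)
    residuals = resid(res.x)
    rss = float(residuals @ residuals)
    df = series.n - spec.n_free
    return FitResult(
        spec=spec,
        estimates=estimates,
        residuals=residuals,
        rss=rss,
        df_residual=df,
        se_regression=float(np.sqrt(rss / df)),
        converged=converged,
        n_iterations=n_iter,
        init_used=dict(init),
        bounds_used=bmap,
        time=t,
        vo2=y,
    )


# ---------------------------------------------------------------------------
# Residual bootstrap
# ---------------------------------------------------------------------------

@dataclass
class BootstrapSummary:
    """Per-parameter precision summary over B residual-bootstrap refits."""

    stats: dict[str, dict[str, float]]   # param -> mean/sd/cv_percent/ci_low/ci_high
    B: int
    seed: int | None
    n_failed_refits: int
    samples: pd.DataFrame = field(repr=False, default=None)

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(self.stats).T[
            ["mean", "sd", "cv_percent", "ci_low", "ci_high"]
        ]

    @property
    def max_sd(self) -> float:
        return max(s["sd"] for s in self.stats.values())


def _summarize(samples: pd.DataFrame, B: int, seed, n_failed) -> BootstrapSummary:
    stats: dict[str, dict[str, float]] = {}
    for p in samples.columns:
        s = samples[p].to_numpy()
        mean = float(s.mean())
        sd = float(s.std(ddof=1)) if s.size > 1 else 0.0
        cv = 100.0 * sd / abs(mean) if mean != 0.0 else float("nan")
        stats[p] = {
            "mean": mean,
            "sd": sd,
            "cv_percent": cv,
            "ci_low": float(np.quantile(s, 0.025, method="lower")),
            "ci_high": float(np.quantile(s, 0.975, method="higher")),
        }
    return BootstrapSummary(stats, B, seed, n_failed, samples)


def bootstrap_fit(
    series: BreathSeries,
    spec: ModelSpec,
    fit: FitResult,
    B: int = 1000,
    seed: int | None = None,
    max_nfev: int | None = 100,
    max_failed_fraction: float = 0.2,
) -> BootstrapSummary:
    """Residual bootstrap around an existing fit.

    For each of B resamples, residuals are drawn with replacement, added
    to the fitted curve at the observed times, and the model is refit
    warm-started from the original estimates.  Fully reproducible given
    ``seed``.  Raises :class:`UnstableFitError` (carrying the partial
    summary) when more than ``max_failed_fraction`` of refits fail.
    """
    if B < 2:
        raise InvalidParameterError(f"B must be >= 2, got {B}")
    if not fit.converged:
        raise InvalidParameterError("bootstrap requires a converged fit")
    series = series.to_per_kg()
    rng = np.random.default_rng(seed)
    fitted = fit.fitted
    resid = fit.residuals
    n = resid.size
    names = spec.free_params
    warm = {p: fit.estimates[p] for p in names}
    fixed = {p: fit.estimates[p] for p in spec.fixed_params}
    rows = []
    n_failed = 0
    for _ in range(B):
        idx = rng.integers(0, n, n)
        y_b = fitted + resid[idx]
        boot_series = BreathSeries(series.time, np.maximum(y_b, 0.0),
                                   unit=series.unit, body_mass=series.body_mass)
        try:
            refit = fit_model(
                boot_series, spec, init=warm, bounds=fit.bounds_used,
                fixed=fixed, multistart=0, max_nfev=max_nfev, ftol=1e-10,
            )
        except Exception:
            n_failed += 1
            continue
        if not refit.converged:
            n_failed += 1
            continue
        rows.append([refit.estimates[p] for p in names])
    samples = pd.DataFrame(rows, columns=list(names))
    if samples.empty:
        raise UnstableFitError("every bootstrap refit failed", None)
    summary = _summarize(samples, B, seed, n_failed)
    if n_failed > max_failed_fraction * B:
        raise UnstableFitError(
            f"{n_failed}/{B} bootstrap refits failed", summary
        )
    return summary
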