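"""Goodness of fit and nested-model selection.

Two fitted models on the same series are compared by the extra-sum-of-
squares F-test:

    F = ((RSS_simple − RSS_complex) / (df_simple − df_complex))
        / (RSS_complex / df_complex)

with p from the upper tail of F(df_num, df_den).  At α the complex model
is preferred when p < α; otherwise the outcome is "no difference" — the
simpler model is never declared superior, only not-worse.  Shapiro–Wilk
on each model's residuals is reported as a normality diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidComparisonError, InvalidInputError, NumericError
from .fitting import FitResult
from .models import is_nested

PREFER_COMPLEX = "complex"
NO_DIFFERENCE = "no_difference"


def shapiro_wilk(residuals) -> tuple[float, float]:
    """Shapiro–Wilk normality test (W statistic, p-value); 3 ≤ n ≤ 5000."""
    r = np.asarray(residuals, dtype=float)
    if r.ndim != 1 or not (3 <= r.size <= 5000):
        raise InvalidInputError(
            f"Shapiro-Wilk requires 3 <= n <= 5000 samples, got {r.size}"
        )
    if not np.all(np.isfinite(r)):
        raise InvalidInputError("residuals must be finite")
    w, p = stats.shapiro(r)
    return float(w), float(p)


@dataclass(frozen=True)
class ModelComparison:
    simple: FitResult
    complex: FitResult
    f_value: float
    df_num: int
    df_den: int
    p_value: float
    shapiro_simple: tuple[float, float]
    shapiro_complex: tuple[float, float]
    alpha: float
    preferred: str  # PREFER_COMPLEX or NO_DIFFERENCE


def extra_ss_f_test(
    simple: FitResult, complex: FitResult, alpha: float = 0.05
) -> ModelComparison:
    """Extra-sum-of-squares F-test between two nested fits on one series."""
    if not is_nested(simple.spec.name, complex.spec.name):
        raise InvalidComparisonError(
            f"{simple.spec.name!r} is not a declared restriction of "
            f"{complex.spec.name!r}"
        )
    if simple.n_samples != complex.n_samples or not np.array_equal(
        simple.time, complex.time
    ):
        raise InvalidComparisonError("fits must come from the same series")
    df_num = simple.df_residual - complex.df_residual
    df_den = complex.df_residual
    if df_num <= 0:
        raise InvalidComparisonError(
            "the simple fit must have more residual degrees of freedom"
        )
    d_rss = simple.rss - complex.rss
    if complex.rss == 0.0:
        if simple.rss > 0.0:
            f_value, p_value = float("inf"), 0.0
        else:
            f_value, p_value = 0.0, 1.0
    else:
        f_value = (d_rss / df_num) / (complex.rss / df_den)
        f_value = max(f_value, 0.0) if d_rss <= 0 else f_value
        p_value = float(stats.f.sf(f_value, df_num, df_den)) if f_value > 0 else 1.0
    preferred = PREFER_COMPLEX if p_value < alpha else NO_DIFFERENCE
    return ModelComparison(
        simple=simple,
        complex=complex,
        f_value=float(f_value),
        df_num=df_num,
        df_den=df_den,
        p_value=float(p_value),
        shapiro_simple=shapiro_wilk(simple.residuals),
        shapiro_complex=shapiro_wilk(complex.residuals),
        alpha=alpha,
        preferred=preferred,
    )


def comparison_report(cmp: ModelComparison) -> pd.DataFrame:
    """ANOVA-style comparison table, one row per model.

    Columns: Res.Df, Res.Sum Sq, Df, Sum Sq, F value, Pr(>F) and the SE of
    regression of each model.  The stored RSS values are audited against a
    recomputation from the residual vectors before reporting.
    """
    for fit in (cmp.simple, cmp.complex):
        recomputed = float(fit.residuals @ fit.residuals)
        if not np.isclose(recomputed, fit.rss, rtol=1e-12, atol=1e-12):
            raise NumericError(
                f"stored RSS for {fit.spec.name!r} ({fit.rss}) does not match "
                f"its residuals ({recomputed})"
            )
    return pd.DataFrame(
        {
            "model": [cmp.simple.spec.name, cmp.complex.spec.name],
            "Res.Df": [cmp.simple.df_residual, cmp.complex.df_residual],
            "Res.Sum Sq": [cmp.simple.rss, cmp.complex.rss],
            "Df": [np.nan, cmp.df_num],
            "Sum Sq": [np.nan, cmp.simple.rss - cmp.complex.rss],
            "F value": [np.nan, cmp.f_value],
            "Pr(>F)": [np.nan, cmp.p_value],
            "SE of reg": [cmp.simple.se_regression, cmp.complex.se_regression],
        }
    )
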