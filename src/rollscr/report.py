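"""Correlations, regressions and precision summaries over a session series.

Associations between the rolling-window estimates (density, g0, sigma) and
the demographic covariates (individuals, detections, spatial recaptures per
sex) are summarised with Pearson correlations and linear/quadratic
("curvilinear") least-squares fits.  Per-session "precision" is the width of
the 95% confidence interval for density on the per-100 km^2 scale.

Note that consecutive rolling sessions share all but two days of data, so
p-values computed as if the sessions were independent are anticonservative;
they are reported as descriptive statistics of the series, not as tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.polynomial import polynomial as npoly
from scipy import stats

from .errors import ParameterError
from .sessions import SessionSeries

__all__ = [
    "AssociationResult",
    "PrecisionSummary",
    "SERIES_VARIABLES",
    "pearson",
    "fit_polynomial_r2",
    "precision_summary",
    "association_table",
]

# variable name -> results-frame column
SERIES_VARIABLES = {
    "D": "D",
    "g0": "g0",
    "sigma": "sigma",
    "n_male": "n_male",
    "n_female": "n_female",
    "det_male": "det_male",
    "det_female": "det_female",
    "spatial_recaptures": "n_spatial_recaptures",
    "mean_spatial_recaptures_per_male": "mean_spatial_recaptures_per_male",
}


@dataclass
class AssociationResult:
    x_name: str
    y_name: str
    n: int
    pearson_r: float
    p_value: float
    linear_r2: float
    quadratic_r2: float
    subset: tuple[int, int] | None = None


@dataclass
class PrecisionSummary:
    """95% CI widths for density, per 100 km^2, across sessions."""

    widths: np.ndarray
    mean: float
    min: float
    max: float
    n: int


def _pairwise_complete(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ParameterError("x and y must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    return x[ok], y[ok]


def pearson(x, y) -> tuple[float, float, int]:
    """Product-moment correlation with its two-sided p-value and n used.

    Missing pairs are dropped (pairwise-complete); needs n >= 3 and
    non-degenerate variance in both series.
    """
    x, y = _pairwise_complete(x, y)
    n = len(x)
    if n < 3:
        raise ParameterError(f"need >= 3 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ParameterError("correlation undefined for a constant series")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), n


def fit_polynomial_r2(x, y, degree: int) -> tuple[float, np.ndarray]:
    """Least-squares polynomial fit; returns (R^2, coefficients low->high).

    Degree 1 is the linear model, degree 2 the curvilinear (quadratic) one.
    """
    if degree not in (1, 2):
        raise ParameterError("degree must be 1 or 2")
    x, y = _pairwise_complete(x, y)
    if len(x) <= degree + 1:
        raise ParameterError(f"need > {degree + 1} points for degree {degree}")
    if np.ptp(x) == 0:
        raise ParameterError("degenerate design: x is constant")
    coeffs = npoly.polyfit(x, y, degree)
    resid = y - npoly.polyval(x, coeffs)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        return 1.0, coeffs
    r2 = 1.0 - float((resid**2).sum()) / ss_tot
    return r2, coeffs


def _series_frame(series) -> pd.DataFrame:
    if isinstance(series, pd.DataFrame):
        return series
    if isinstance(series, SessionSeries):
        return series.to_frame()
    raise ParameterError(f"expected SessionSeries or DataFrame, got {type(series)}")


def precision_summary(series) -> PrecisionSummary:
    """Mean/min/max 95% CI width for density over non-missing sessions."""
    df = _series_frame(series)
    widths = (df["D_hi"] - df["D_lo"]).to_numpy(dtype=float) * 100.0
    widths = widths[np.isfinite(widths)]
    if len(widths) == 0:
        raise ParameterError("no sessions with confidence intervals")
    return PrecisionSummary(
        widths=widths,
        mean=float(widths.mean()),
        min=float(widths.min()),
        max=float(widths.max()),
        n=len(widths),
    )


def association_table(
    series,
    pairs: list[tuple[str, str]],
    subset: tuple[int, int] | None = None,
) -> list[AssociationResult]:
    """Pearson r and linear/quadratic R^2 for each named variable pair.

    ``subset`` is an inclusive 1-based session index range (e.g. (1, 160)
    restricts to the first 160 sessions).
    """
    df = _series_frame(series)
    if subset is not None:
        lo, hi = int(subset[0]), int(subset[1])
        if not (1 <= lo <= hi <= len(df)):
            raise ParameterError(f"subset {subset} outside [1, {len(df)}]")
        df = df.iloc[lo - 1 : hi]
    out = []
    for x_name, y_name in pairs:
        for name in (x_name, y_name):
            if name not in SERIES_VARIABLES:
                raise ParameterError(
                    f"unknown variable {name!r}; choose from "
                    f"{sorted(SERIES_VARIABLES)}"
                )
        x = df[SERIES_VARIABLES[x_name]].to_numpy(dtype=float)
        y = df[SERIES_VARIABLES[y_name]].to_numpy(dtype=float)
        r, p, n = pearson(x, y)
        lin_r2, _ = fit_polynomial_r2(x, y, 1)
        quad_r2, _ = fit_polynomial_r2(x, y, 2)
        out.append(
            AssociationResult(
                x_name=x_name, y_name=y_name, n=n,
                pearson_r=r, p_value=p,
                linear_r2=lin_r2, quadratic_r2=quad_r2,
                subset=subset,
            )
        )
    return out
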