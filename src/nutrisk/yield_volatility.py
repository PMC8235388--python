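"""Regional wheat-productivity volatility estimation.

Pipeline: standardize the annual productivity series to its
reference-year level, difference ``d`` times (default 1), fit ARMA(p, q)
candidates over a small order grid by exact maximum likelihood, select
by AIC (ties broken toward the smaller p+q, then smaller p), and report
the sample standard deviation of the selected model's residuals as the
region's volatility sigma_r.

Moving-average coefficients at the invertibility boundary (|theta| close
to 1) are accepted but flagged; they arise naturally when a stationary
series is over-differenced.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.tsa.arima.model import ARIMA

from .synthetic_world import YieldSeries

__all__ = [
    "ARIMAFit",
    "standardize",
    "fit_arima",
    "residual_sd",
    "null_fit",
    "fit_table",
    "read_yield_csv",
]

log = logging.getLogger(__name__)

BOUNDARY_TOL = 0.999


@dataclass(frozen=True)
class ARIMAFit:
    """A fitted (or null) ARIMA model for one region's yield series."""

    region: str
    p: int
    q: int
    d: int
    ar_coefs: tuple[float, ...]
    ma_coefs: tuple[float, ...]
    residuals: np.ndarray = field(repr=False)
    sigma: float
    aic: float
    converged: bool = True
    method: str = "mle"
    boundary: bool = False  # any |MA coefficient| at the invertibility boundary
    is_null: bool = False  # non-producing region: sigma pinned to 0

    def __post_init__(self):
        if self.p < 0 or self.q < 0 or self.d < 0:
            raise ValueError("model orders must be nonnegative")
        if self.sigma < 0:
            raise ValueError("residual SD must be nonnegative")


def null_fit(region: str) -> ARIMAFit:
    """Null fit for a region that does not produce wheat: sigma_r = 0."""
    return ARIMAFit(
        region=region,
        p=0,
        q=0,
        d=0,
        ar_coefs=(),
        ma_coefs=(),
        residuals=np.zeros(0),
        sigma=0.0,
        aic=float("nan"),
        is_null=True,
    )


def standardize(series: YieldSeries) -> YieldSeries:
    """Divide the whole series by its reference-year value (idempotent)."""
    ref = series.reference_value
    if ref <= 0:
        raise ValueError("reference-year productivity must be positive")
    return YieldSeries(
        region=series.region,
        years=series.years.copy(),
        values=series.values / ref,
        reference_year=series.reference_year,
    )


def _sample_sd(values: np.ndarray) -> float:
    v = np.asarray(values, dtype=float)
    if v.size <= 1:
        return 0.0
    return float(np.std(v, ddof=1))


def residual_sd(fit: ARIMAFit) -> float:
    """Sample (n-1 denominator) SD of the stored residual vector."""
    if not fit.converged:
        raise ValueError("cannot take residual SD of a non-converged fit")
    if fit.residuals.size == 0:
        return 0.0
    return _sample_sd(fit.residuals)


def _fit_one(diffed: np.ndarray, p: int, q: int):
    """Fit ARMA(p, q) with no constant; exact MLE, CSS-style fallback."""
    if p == 0 and q == 0:
        resid = diffed.copy()
        n = resid.size
        sigma2 = float(resid @ resid) / n
        if sigma2 <= 0:
            aic = -float("inf")
        else:
            aic = n * (np.log(2 * np.pi * sigma2) + 1.0) + 2.0
        return (), (), resid, aic, "closed-form"
    last_err = None
    for method in ("statespace", "hannan_rissanen"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = ARIMA(diffed, order=(p, 0, q), trend="n")
                res = model.fit(method=method)
            ar = tuple(float(v) for v in res.arparams) if p else ()
            ma = tuple(float(v) for v in res.maparams) if q else ()
            if not np.all(np.isfinite(res.resid)) or not np.isfinite(res.aic):
                raise ValueError("non-finite fit result")
            if method != "statespace":
                log.info("ARMA(%d,%d): fell back to %s estimation", p, q, method)
            return ar, ma, np.asarray(res.resid), float(res.aic), method
        except Exception as err:  # noqa: BLE001 - collect and report
            last_err = err
    raise RuntimeError(f"ARMA({p},{q}) failed: {last_err}")


def fit_arima(
    series: YieldSeries, max_p: int = 3, max_q: int = 3, d: int = 1
) -> ARIMAFit:
    """AIC-selected ARIMA fit of the standardized series.

    Scans ``(p, q)`` over ``[0, max_p] x [0, max_q]`` on the d-times
    differenced standardized series; ties within 1e-9 of the minimum AIC
    go to the smaller ``p+q``, then the smaller ``p``.  Raises if every
    candidate order fails.
    """
    n = series.values.size
    if n <= max_p + max_q + d + 1:
        raise ValueError(
            f"series length {n} too short for max_p={max_p}, max_q={max_q}, d={d}"
        )
    std = standardize(series)
    diffed = np.diff(std.values, n=d) if d > 0 else std.values.copy()

    if np.ptp(diffed) == 0.0:
        # constant (after differencing): white noise of zero variance
        resid = diffed - diffed[0] if d == 0 else diffed.copy()
        return ARIMAFit(
            region=series.region,
            p=0,
            q=0,
            d=d,
            ar_coefs=(),
            ma_coefs=(),
            residuals=np.zeros_like(diffed),
            sigma=0.0,
            aic=-float("inf"),
            method="degenerate",
        )
    if d == 0:
        diffed = diffed - 1.0  # deviations around the standardized unit level

    candidates = []
    failures = []
    for p in range(max_p + 1):
        for q in range(max_q + 1):
            try:
                ar, ma, resid, aic, method = _fit_one(diffed, p, q)
            except RuntimeError as err:
                failures.append(((p, q), str(err)))
                continue
            candidates.append((aic, p + q, p, q, ar, ma, resid, method))
    if not candidates:
        raise RuntimeError(
            "all candidate ARIMA orders failed to converge: "
            + "; ".join(f"{pq}: {msg}" for pq, msg in failures)
        )
    best_aic = min(c[0] for c in candidates)
    viable = [c for c in candidates if c[0] <= best_aic + 1e-9]
    viable.sort(key=lambda c: (c[1], c[2]))
    aic, _, p, q, ar, ma, resid, method = viable[0]
    return ARIMAFit(
        region=series.region,
        p=p,
        q=q,
        d=d,
        ar_coefs=ar,
        ma_coefs=ma,
        residuals=resid,
        sigma=_sample_sd(resid),
        aic=aic,
        method=method,
        boundary=any(abs(t) >= BOUNDARY_TOL for t in ma),
    )


def fit_table(fits) -> pd.DataFrame:
    """Summarize fits as a region x (delta1..3, theta1..3, SD) table."""
    rows = []
    for f in fits:
        row = {"region": f.region}
        for i in range(3):
            row[f"delta{i + 1}"] = f.ar_coefs[i] if i < len(f.ar_coefs) else np.nan
            row[f"theta{i + 1}"] = f.ma_coefs[i] if i < len(f.ma_coefs) else np.nan
        row["SD"] = np.nan if f.is_null else f.sigma
        row["boundary"] = f.boundary
        rows.append(row)
    return pd.DataFrame(rows).set_index("region")


def read_yield_csv(path_or_buf, reference_year: int = 2014) -> dict[str, YieldSeries]:
    """Read per-region yield series from CSV.

    Accepts either ``(region, year, productivity)`` columns or
    ``(region, year, production, area_harvested)``, in which case
    productivity = production / area.
    """
    df = pd.read_csv(path_or_buf, comment="#")
    if "productivity" not in df.columns:
        if not {"production", "area_harvested"} <= set(df.columns):
            raise ValueError(
                "yield CSV needs either a 'productivity' column or both"
                " 'production' and 'area_harvested'"
            )
        df = df.assign(productivity=df["production"] / df["area_harvested"])
    out = {}
    for region, grp in df.groupby("region", sort=True):
        grp = grp.sort_values("year")
        out[str(region)] = YieldSeries(
            region=str(region),
            years=grp["year"].to_numpy(),
            values=grp["productivity"].to_numpy(),
            reference_year=reference_year,
        )
    return out
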