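"""Four-parameter logistic growth curves: fitting and rate kinetics.

Plate-reader OD600 time series are modelled as

    y(t) = A2 + (A1 - A2) / (1 + (t/x0)**p)

with A1 the early asymptote (inoculation density), A2 the late (stationary)
asymptote, x0 the half-transition time in hours and p a dimensionless shape
exponent.  Growth speed is the closed-form first derivative

    y'(t) = (A2 - A1) * p * (t/x0)**p / (t * (1 + (t/x0)**p)**2)

which for p > 1 has an interior maximum at  t* = x0 * ((p-1)/(p+1))**(1/p).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "GrowthCurve",
    "LogisticFit",
    "GrowthKinetics",
    "logistic",
    "fit_logistic",
    "fit_many",
    "logistic_rate",
    "time_of_max_rate",
    "growth_kinetics",
    "spotting_dilutions",
]

MIN_POINTS = 6


class FitError(RuntimeError):
    """Raised when a logistic fit cannot be obtained."""


@dataclass(frozen=True)
class GrowthCurve:
    """One well's OD600 trajectory."""

    times: np.ndarray
    od: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.od, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "od", y)
        if t.shape != y.shape or t.ndim != 1:
            raise ValueError("times and od must be 1-D arrays of equal length")
        if len(t) < MIN_POINTS:
            raise ValueError(f"need at least {MIN_POINTS} points to fit, got {len(t)}")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(y < 0):
            raise ValueError("OD readings must be non-negative")


@dataclass(frozen=True)
class LogisticFit:
    A1: float
    A2: float
    x0: float
    p: float
    r_squared: float = float("nan")
    converged: bool = True

    def __post_init__(self) -> None:
        if not (self.x0 > 0 and self.p > 0):
            raise ValueError("x0 and p must be positive")
        for v in (self.A1, self.A2, self.x0, self.p):
            if not np.isfinite(v):
                raise ValueError("fit parameters must be finite")

    @property
    def decreasing(self) -> bool:
        """True when A2 < A1 (a shrinking signal; flagged, not forbidden)."""
        return self.A2 < self.A1


@dataclass(frozen=True)
class GrowthKinetics:
    """Sampled rate curve plus location and value of the maximum rate."""

    times: np.ndarray
    rates: np.ndarray
    t_max_rate: float
    max_rate: float
    extrapolated: bool


def logistic(t, A1: float, A2: float, x0: float, p: float):
    """Model value(s) at time t (hours)."""
    t = np.asarray(t, dtype=float)
    with np.errstate(divide="ignore"):
        ratio = np.where(t > 0, (t / x0) ** p, 0.0 if p > 0 else np.inf)
    return A2 + (A1 - A2) / (1.0 + ratio)


def _initial_guess(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    a1, a2 = float(y.min()), float(y.max())
    half = 0.5 * (a1 + a2)
    above = np.nonzero(y >= half)[0]
    x0 = float(t[above[0]]) if len(above) else float(np.median(t))
    x0 = max(x0, float(t[t > 0][0]) if np.any(t > 0) else 1.0)
    return a1, a2, x0, 4.0


def fit_logistic(curve: GrowthCurve, n_restarts: int = 3, seed: int = 0) -> LogisticFit:
    """Least-squares logistic fit with jittered multi-start.

    Positivity of x0 and p is enforced by optimising their logarithms.
    Raises :class:`FitError` for flat curves or after all restarts fail.
    """
    t, y = curve.times, curve.od
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise FitError(f"curve {curve.label!r} is flat (zero variance); nothing to fit")

    def model(tt, a1, a2, log_x0, log_p):
        return logistic(tt, a1, a2, np.exp(log_x0), np.exp(log_p))

    a1, a2, x0g, pg = _initial_guess(t, y)
    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray] | None = None
    last_err: Exception | None = None
    for attempt in range(n_restarts + 1):
        p0 = np.array([a1, a2, np.log(x0g), np.log(pg)])
        if attempt > 0:
            p0 = p0 + rng.normal(0.0, 0.2, size=4) * np.maximum(np.abs(p0), 0.1)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(model, t, y, p0=p0, maxfev=20_000)
        except (RuntimeError, ValueError) as err:  # pragma: no cover - rare
            last_err = err
            continue
        resid = y - model(t, *popt)
        ss_res = float(np.sum(resid**2))
        if best is None or ss_res < best[0]:
            best = (ss_res, popt)
    if best is None:
        raise FitError(
            f"logistic fit failed for curve {curve.label!r} after "
            f"{n_restarts + 1} starts: {last_err}"
        )
    ss_res, popt = best
    return LogisticFit(
        A1=float(popt[0]),
        A2=float(popt[1]),
        x0=float(np.exp(popt[2])),
        p=float(np.exp(popt[3])),
        r_squared=1.0 - ss_res / ss_tot,
        converged=True,
    )


def logistic_rate(fit: LogisticFit, t) -> np.ndarray | float:
    """Closed-form first derivative of the model at t > 0 (OD/hour)."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr <= 0):
        raise ValueError("rate is defined for t > 0 only")
    ratio = (t_arr / fit.x0) ** fit.p
    rate = (fit.A2 - fit.A1) * fit.p * ratio / (t_arr * (1.0 + ratio) ** 2)
    return rate if t_arr.ndim else float(rate)


def time_of_max_rate(fit: LogisticFit) -> float:
    """Time of the rate maximum, x0*((p-1)/(p+1))**(1/p), for p > 1.

    For p <= 1 the rate is maximal as t -> 0+; 0.0 is returned with a
    warning rather than raising.
    """
    if fit.p <= 1.0:
        warnings.warn(
            "p <= 1: growth rate has no interior maximum (supremum at t -> 0+)",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0
    return fit.x0 * ((fit.p - 1.0) / (fit.p + 1.0)) ** (1.0 / fit.p)


def growth_kinetics(fit: LogisticFit, times: np.ndarray) -> GrowthKinetics:
    """Rate curve sampled on the observed grid plus the analytic maximum."""
    times = np.asarray(times, dtype=float)
    pos = times[times > 0]
    rates = logistic_rate(fit, pos)
    t_star = time_of_max_rate(fit) if fit.p > 1 else float(pos[0])
    extrapolated = not (pos[0] <= t_star <= pos[-1])
    return GrowthKinetics(
        times=pos,
        rates=np.asarray(rates),
        t_max_rate=t_star,
        max_rate=float(logistic_rate(fit, t_star)) if t_star > 0 else float(rates[0]),
        extrapolated=extrapolated,
    )


def fit_many(df: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Fit every well of a plate-reader table.

    Accepts wide format (first column time, one column per well) or long
    format (columns time, well, od).  Returns one row per well with the
    parameters, R^2 and rate kinetics.
    """
    if {"time", "well", "od"}.issubset(df.columns):
        long = df[["time", "well", "od"]]
    else:
        time_col = df.columns[0]
        long = df.melt(id_vars=time_col, var_name="well", value_name="od").rename(
            columns={time_col: "time"}
        )
    rows = []
    for well, grp in long.groupby("well", sort=True):
        grp = grp.sort_values("time")
        curve = GrowthCurve(grp["time"].to_numpy(), grp["od"].to_numpy(), label=str(well))
        fit = fit_logistic(curve, seed=seed)
        kin = growth_kinetics(fit, curve.times)
        rows.append(
            {
                "well": well,
                "A1": fit.A1,
                "A2": fit.A2,
                "x0": fit.x0,
                "p": fit.p,
                "r_squared": fit.r_squared,
                "t_max_rate": kin.t_max_rate,
                "max_rate": kin.max_rate,
                "decreasing": fit.decreasing,
            }
        )
    return pd.DataFrame(rows)


def spotting_dilutions(od_start: float, n_dilutions: int, factor: int = 10) -> list[float]:
    """Serial dilution ODs [od/factor, ..., od/factor**n]."""
    if factor <= 1:
        raise ValueError("dilution factor must exceed 1")
    if n_dilutions < 0:
        raise ValueError("n_dilutions must be >= 0")
    return [od_start * factor ** (-i) for i in range(1, n_dilutions + 1)]
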