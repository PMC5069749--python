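"""Growth-curve kinetics: exponential rate, lag phase, derived quantities.

The model is the classical batch-culture description: a lag phase at the
inoculation turbidity od0, then exponential growth OD(t) = od0·exp(μ(t−lag))
up to a plateau. μ is estimated by a sliding-window log-linear fit: the
steepest window (default 4 points) of ln OD against time whose fit reaches
r² ≥ 0.98 seeds the exponential phase, and the window is then extended one
point at a time while the candidate point stays within the fit's own
residual scale — on a noise-free curve the extension stops exactly where
the exponential law breaks, so clean data invert exactly, while on noisy
data the widened window averages the read noise down. The fit is weighted
by OD², the correct weighting when turbidity noise is additive (so the log
residuals are heteroscedastic). The lag is where the back-extrapolated
exponential line crosses the initial OD level (Monod's geometric
construction), clipped at zero; the line's intercept is anchored on the
first e-fold of the exponential phase to keep the extrapolation lever arm
short.

Derived quantities: doubling time ln2/μ, and an upper bound on a suppressor
subpopulation that could instead explain a lag — if the lag spans n
doubling times, a subpopulation growing from fraction 2^(−n) of the culture
would need n duplications to take over, so the fraction is 100·2^(−n) %.

Usage::

    model = GrowthCurveModel.from_dataframe(df)   # time_h + OD column(s)
    res = model.fit()                             # GrowthResults
    res.mu, res.lag, res.doubling_time, res.summary()
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["GrowthCurveModel", "GrowthResults", "NoExponentialPhase",
           "doubling_time", "suppressor_fraction_bound"]


class NoExponentialPhase(RuntimeError):
    """No window of the curve satisfied the exponential-fit criteria."""


def doubling_time(mu: float) -> float:
    """ln(2)/μ in hours; requires μ > 0."""
    if not mu > 0:
        raise ValueError("doubling time requires mu > 0")
    return math.log(2.0) / mu


def suppressor_fraction_bound(lag: float, td: float) -> tuple[int, float]:
    """(n duplications, percent) bound on a lag-explaining subpopulation.

    n = lag/td rounded to the nearest integer; the fraction that could have
    grown through n duplications during the lag is 100·2^(−n) percent.
    """
    if not (lag > 0 and td > 0):
        raise ValueError("lag and doubling time must be positive")
    n = int(round(lag / td))
    return n, 100.0 * 2.0 ** (-n)


@dataclass(frozen=True)
class GrowthResults:
    """Fitted kinetic parameters of one growth curve."""

    mu: float                      # h^-1
    lag: float                     # h
    r2_fit: float
    window: tuple[float, float]    # (start h, end h) of the fitted window
    intercept: float               # ln OD at t = 0 of the fitted line
    od_initial: float              # baseline OD level used for the lag
    n_points: int

    @property
    def doubling_time(self) -> float:
        return doubling_time(self.mu)

    def suppressor_bound(self) -> tuple[int, float]:
        return suppressor_fraction_bound(self.lag, self.doubling_time)

    def summary(self) -> str:
        lines = [
            "Growth-curve fit",
            "----------------",
            f"growth rate mu     {self.mu:10.4f} 1/h",
            f"doubling time      {self.doubling_time:10.4f} h",
            f"lag phase          {self.lag:10.4f} h",
            f"r2 (log-linear)    {self.r2_fit:10.4f}",
            f"fit window         {self.window[0]:.2f}-{self.window[1]:.2f} h",
            f"points in curve    {self.n_points:10d}",
        ]
        return "\n".join(lines)

    def as_dict(self) -> dict:
        return {"mu": self.mu, "lag": self.lag,
                "doubling_time": self.doubling_time, "r2_fit": self.r2_fit,
                "window_start": self.window[0], "window_end": self.window[1]}


class GrowthCurveModel:
    """Turbidity (OD600) time series to be fitted for μ and lag.

    Replicate OD series are averaged point-wise on construction; the fit
    always operates on the mean curve.
    """

    def __init__(self, times, od) -> None:
        times = np.asarray(times, dtype=float)
        od = np.asarray(od, dtype=float)
        if od.ndim == 2:              # replicates in columns
            od = od.mean(axis=1)
        if times.ndim != 1 or times.shape != od.shape:
            raise ValueError("times and od must be 1-D and equally long")
        if times.size < 4:
            raise ValueError("need at least 4 time points")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(od < 0):
            raise ValueError("od must be >= 0")
        self.times = times
        self.od = od

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame,
                       time_col: str = "time_h") -> "GrowthCurveModel":
        """Build from a table with a time column and >= 1 OD columns."""
        if time_col not in df.columns:
            raise ValueError(f"missing time column {time_col!r}")
        od_cols = [c for c in df.columns if c != time_col]
        if not od_cols:
            raise ValueError("no OD columns found")
        return cls(df[time_col].to_numpy(), df[od_cols].to_numpy())

    @staticmethod
    def _wls(ti: np.ndarray, yi: np.ndarray, wi: np.ndarray):
        """Weighted straight-line fit; returns (slope, intercept, r2).

        Zero weighted variance of y (a flat stretch) is an exact fit with
        slope 0 and r² = 1.
        """
        wsum = wi.sum()
        tm = (wi * ti).sum() / wsum
        ym = (wi * yi).sum() / wsum
        stt = (wi * (ti - tm) ** 2).sum()
        sty = (wi * (ti - tm) * (yi - ym)).sum()
        syy = (wi * (yi - ym) ** 2).sum()
        if syy < 1e-24:
            return 0.0, float(ym), 1.0
        slope = sty / stt
        return float(slope), float(ym - slope * tm), float(sty ** 2 / (stt * syy))

    def fit(self, window: int = 4, r2_min: float = 0.98,
            od_floor: float = 1e-6) -> GrowthResults:
        """Sliding-window log-linear fit with residual-gated extension.

        The steepest ``window``-point OD²-weighted fit of ln OD vs time
        with r² >= ``r2_min`` seeds the exponential phase; the window then
        grows one point at a time while the candidate point's linear-space
        residual stays within 3.5× the current fit's residual scale and the
        widened fit keeps r² >= ``r2_min``. Points with OD <= ``od_floor``
        (detection floor) are excluded. Raises :class:`NoExponentialPhase`
        when no window qualifies; a perfectly flat curve fits exactly with
        μ = 0 (the derived doubling time then raises, not the fit).
        """
        if window < 3:
            raise ValueError("window must span at least 3 points")
        mask = self.od > od_floor
        t, od = self.times[mask], self.od[mask]
        if t.size < window:
            raise NoExponentialPhase("too few points above the detection floor")
        y = np.log(od)
        w = od ** 2

        best = None
        for i in range(t.size - window + 1):
            sl = slice(i, i + window)
            slope, icept, r2 = self._wls(t[sl], y[sl], w[sl])
            if r2 >= r2_min and (best is None or slope > best[0]):
                best = (slope, icept, r2, i, i + window - 1)
        if best is None:
            raise NoExponentialPhase(
                f"no {window}-point window reached r2 >= {r2_min}")
        mu, icept, r2, lo, hi = best

        # extend while new points obey the fitted exponential law
        improved = True
        while improved:
            improved = False
            seg = slice(lo, hi + 1)
            resid = od[seg] - np.exp(icept + mu * t[seg])
            tol = 3.5 * math.sqrt(float(np.mean(resid ** 2))) + 1e-9 * od.max()
            for lo2, hi2, j in ((lo - 1, hi, lo - 1), (lo, hi + 1, hi + 1)):
                if lo2 < 0 or hi2 >= t.size:
                    continue
                if abs(od[j] - math.exp(icept + mu * t[j])) > tol:
                    continue
                sl = slice(lo2, hi2 + 1)
                mu2, icept2, r22 = self._wls(t[sl], y[sl], w[sl])
                if r22 >= r2_min and mu2 > 0:
                    lo, hi, mu, icept, r2 = lo2, hi2, mu2, icept2, r22
                    improved = True
                    break

        lag, od_init = self._lag(mu, icept, t, od, y, w)
        return GrowthResults(mu=float(mu), lag=lag, r2_fit=float(r2),
                             window=(float(t[lo]), float(t[hi])),
                             intercept=float(icept), od_initial=od_init,
                             n_points=int(self.times.size))

    def _lag(self, mu: float, intercept: float, t: np.ndarray,
             od: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[float, float]:
        """Back-extrapolate the exponential line to the initial OD level.

        The baseline is first taken as the inoculation point OD; the
        crossing time then identifies the pre-growth plateau, whose mean OD
        gives a noise-robust baseline. The line's intercept is re-anchored
        on the first e-fold of the exponential phase (short extrapolation
        lever arm); on a noise-free curve this reproduces the global line
        exactly. μ = 0 curves have no crossing; lag is reported as 0.
        """
        if mu <= 0:
            return 0.0, float(self.od[0])
        od_init = float(self.od[0])
        if od_init <= 0:
            positive = self.od[self.od > 0]
            if positive.size == 0:
                return 0.0, 0.0
            od_init = float(positive[0])
        lag0 = (math.log(od_init) - intercept) / mu
        plateau = self.od[self.times <= lag0]
        if plateau.size > 0 and np.all(plateau > 0):
            od_init = float(plateau.mean())
        lag = (math.log(od_init) - intercept) / mu

        for span in (1.0, 2.0, math.inf):          # e-folds past onset
            early = (t >= lag) & (t <= lag + span / mu)
            if early.sum() >= 3:
                break
        if early.sum() >= 2:
            we = w[early]
            icept = float(np.sum(we * (y[early] - mu * t[early])) / we.sum())
            lag = (math.log(od_init) - icept) / mu
        return max(lag, 0.0), od_init
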