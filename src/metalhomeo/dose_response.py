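"""IC50 estimation from endpoint-turbidity dose-response series.

The endpoint OD600 after a fixed incubation is modelled as a logistic
decline in inhibitor concentration c,

    OD(c) = od0 / (1 + exp(b (c − IC50))),

the minimal sigmoid with a well-defined half-maximal point: OD(IC50) is
exactly od0/2. The three parameters (uninhibited endpoint od0, shape b,
IC50) are fitted by least squares; the IC50 standard error comes from a
seeded residual bootstrap. Two strains differ significantly when their
IC50 ± error bars do not overlap — the same error-bar-separation rule
(D > 1) used for the array statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .simulate import logistic_decline

__all__ = ["DoseResponseModel", "DoseResponseResults", "compare_resistance"]


@dataclass(frozen=True)
class DoseResponseResults:
    """Fitted IC50 with uncertainty; ``converged`` is False when the data
    never bracket the half-maximal endpoint."""

    ic50: float                    # µM (NaN when not converged)
    ic50_err: float                # µM; NaN when bootstrap disabled
    slope: float
    od0_hat: float
    converged: bool
    n_points: int
    message: str = ""

    def summary(self) -> str:
        if not self.converged:
            return f"Dose-response fit: not converged ({self.message})"
        err = "   n/a" if math.isnan(self.ic50_err) else f"{self.ic50_err:6.2f}"
        return "\n".join([
            "Dose-response fit",
            "-----------------",
            f"IC50               {self.ic50:10.2f} µM  ± {err}",
            f"slope b            {self.slope:10.4f} per µM",
            f"uninhibited OD     {self.od0_hat:10.3f}",
            f"points fitted      {self.n_points:10d}",
        ])


class DoseResponseModel:
    """Pooled endpoint observations (concentration_uM, od600) to fit.

    Accepts one table or a list of replicate tables; replicates are pooled
    for the point estimate.
    """

    def __init__(self, series) -> None:
        if isinstance(series, pd.DataFrame):
            series = [series]
        frames = []
        for i, s in enumerate(series):
            missing = {"concentration_uM", "od600"} - set(s.columns)
            if missing:
                raise ValueError(f"series {i} missing columns {sorted(missing)}")
            if (s["concentration_uM"] < 0).any():
                raise ValueError("concentrations must be >= 0")
            if (s["od600"] < 0).any():
                raise ValueError("endpoints must be >= 0")
            frames.append(s[["concentration_uM", "od600"]])
        if not frames:
            raise ValueError("no series supplied")
        self.data = pd.concat(frames, ignore_index=True)
        if self.data["concentration_uM"].nunique() < 5:
            raise ValueError("need at least 5 distinct concentrations")

    # -- internals ---------------------------------------------------------

    def _initial_guess(self, c: np.ndarray, y: np.ndarray) -> list[float]:
        od0 = float(np.mean(y[c == c.min()]))
        half = od0 / 2.0
        order = np.argsort(c)
        cs, ys = c[order], y[order]
        below = np.nonzero(ys <= half)[0]
        ic50 = float(cs[below[0]]) if below.size else float(cs[-1])
        ic50 = max(ic50, 1e-6)
        return [od0, 4.0 / max(ic50, 1.0), ic50]

    def _fit_once(self, c: np.ndarray, y: np.ndarray) -> np.ndarray:
        p0 = self._initial_guess(c, y)
        popt, _ = curve_fit(
            logistic_decline, c, y, p0=p0,
            bounds=([0.0, 1e-6, 1e-6], [np.inf, np.inf, np.inf]),
            maxfev=10000)
        return popt

    # -- public API --------------------------------------------------------

    def fit(self, n_boot: int = 200, seed: int = 0) -> DoseResponseResults:
        """Least-squares fit; IC50 error by residual bootstrap.

        Requires endpoints on both sides of half the zero-concentration
        endpoint; otherwise the half-maximal point is unconstrained and the
        result is flagged unconverged. ``n_boot = 0`` skips the bootstrap
        (ic50_err NaN).
        """
        c = self.data["concentration_uM"].to_numpy(dtype=float)
        y = self.data["od600"].to_numpy(dtype=float)
        e0 = float(np.mean(y[c == c.min()]))
        if e0 <= 0 or not (y.min() < 0.5 * e0 < y.max()):
            return DoseResponseResults(
                math.nan, math.nan, math.nan, math.nan, False, len(y),
                message="endpoints do not bracket the half-maximal level")
        try:
            od0, b, ic50 = self._fit_once(c, y)
        except RuntimeError as exc:       # no convergence
            return DoseResponseResults(math.nan, math.nan, math.nan,
                                       math.nan, False, len(y),
                                       message=str(exc))

        err = math.nan
        if n_boot > 0:
            rng = np.random.default_rng(seed)
            fitted = logistic_decline(c, od0, b, ic50)
            resid = y - fitted
            draws = []
            for _ in range(n_boot):
                yb = fitted + rng.choice(resid, size=resid.size, replace=True)
                try:
                    draws.append(self._fit_once(c, np.clip(yb, 0.0, None))[2])
                except RuntimeError:
                    continue
            if len(draws) >= 2:
                err = float(np.std(draws, ddof=1))
        return DoseResponseResults(float(ic50), err, float(b), float(od0),
                                   True, len(y))


def compare_resistance(fit_a: DoseResponseResults,
                       fit_b: DoseResponseResults) -> bool | None:
    """Error-bar-overlap significance between two IC50 estimates.

    Significant iff |IC50_a − IC50_b| > err_a + err_b (non-touching bars,
    the D > 1 rule with D formed from the two estimates). Returns None when
    either fit is unconverged or lacks an error estimate — the comparison
    cannot be quantified.
    """
    if not (fit_a.converged and fit_b.converged):
        return None
    if math.isnan(fit_a.ic50_err) or math.isnan(fit_b.ic50_err):
        return None
    return abs(fit_a.ic50 - fit_b.ic50) > fit_a.ic50_err + fit_b.ic50_err
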