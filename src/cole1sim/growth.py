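"""Growth-rate estimation from OD600 time series.

The log-transformed growth curve ln(OD/OD0) is fitted with a degree-4
polynomial by least squares (coefficients in descending powers, as in
MATLAB ``polyfit``); fit quality is assessed with a reduced chi-square
statistic and the specific growth rate at a harvest time is the first
derivative of the fitted polynomial at that time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class FittingError(ValueError):
    pass


@dataclass(frozen=True)
class GrowthModel:
    """Degree-n polynomial of ln(OD/OD0) versus time (hours).

    ``coefficients`` are in descending powers.  Evaluation and
    differentiation are only defined inside the fitted time window
    ``time_domain``.
    """

    coefficients: tuple[float, ...]
    time_domain: tuple[float, float]

    @property
    def degree(self) -> int:
        return len(self.coefficients) - 1

    def _check_domain(self, t: float) -> None:
        lo, hi = self.time_domain
        if not (lo <= t <= hi):
            raise ValueError(
                f"t = {t} h outside the fitted time domain [{lo}, {hi}] h")

    def log_od(self, t: float) -> float:
        """ln(OD/OD0) predicted at time ``t`` (hours)."""
        self._check_domain(t)
        return float(np.polyval(self.coefficients, t))

    def growth_rate_at(self, t: float) -> float:
        """Specific growth rate mu(t) = d/dt ln(OD/OD0), in h^-1."""
        self._check_domain(t)
        deriv = np.polyder(np.poly1d(self.coefficients))
        return float(deriv(t))


def fit_growth(times_h: np.ndarray, od600: np.ndarray,
               degree: int = 4) -> GrowthModel:
    """Least-squares polynomial fit of ln(OD/OD0) against time.

    OD values are normalized to the first reading before the log
    transform.  Requires at least ``degree + 1`` points and strictly
    positive OD readings.
    """
    t = np.asarray(times_h, dtype=float)
    od = np.asarray(od600, dtype=float)
    if t.shape != od.shape or t.ndim != 1:
        raise FittingError("times and OD readings must be 1-D and equal length")
    if len(t) < degree + 1:
        raise FittingError(
            f"need at least {degree + 1} points for a degree-{degree} fit, "
            f"got {len(t)}")
    if np.any(od <= 0):
        raise FittingError("all OD readings must be positive")
    y = np.log(od / od[0])
    coeffs = np.polyfit(t, y, degree)
    return GrowthModel(tuple(coeffs), (float(t.min()), float(t.max())))


def growth_rate_at(model: GrowthModel, t: float) -> float:
    """Module-level convenience wrapper around ``GrowthModel.growth_rate_at``."""
    return model.growth_rate_at(t)


def chi2_reduced(model: GrowthModel, times_h: np.ndarray, od600: np.ndarray,
                 sigma: np.ndarray | float) -> float:
    """Reduced chi-square of the fitted log-OD curve.

    sum(((y - p(t)) / sigma)^2) / (n - (degree + 1)), with y = ln(OD/OD0)
    and per-point uncertainties ``sigma`` on the log scale.
    """
    t = np.asarray(times_h, dtype=float)
    od = np.asarray(od600, dtype=float)
    sig = np.broadcast_to(np.asarray(sigma, dtype=float), t.shape)
    if np.any(sig <= 0):
        raise ValueError("sigma must be positive")
    dof = len(t) - (model.degree + 1)
    if dof <= 0:
        raise ValueError("need more points than polynomial coefficients")
    y = np.log(od / od[0])
    pred = np.polyval(model.coefficients, t)
    return float(np.sum(((y - pred) / sig) ** 2) / dof)


def read_od_table(path) -> pd.DataFrame:
    """Read an OD table CSV with columns time_h, od600[, replicate]."""
    df = pd.read_csv(path)
    missing = {"time_h", "od600"} - set(df.columns)
    if missing:
        raise FittingError(f"OD table lacks columns: {sorted(missing)}")
    return df


def growth_rate_table(model: GrowthModel, harvest_times_h: dict[str, float]) -> pd.DataFrame:
    """Per-timepoint growth rates and generation times (minutes, rounded)."""
    from .simulate import generation_time
    rows = []
    for name, t in harvest_times_h.items():
        mu = model.growth_rate_at(t)
        rows.append({"time_point": name, "harvest_h": t,
                     "growth_rate_per_h": mu,
                     "generation_min": round(generation_time(mu))})
    return pd.DataFrame(rows)
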