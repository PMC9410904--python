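"""Time-course models for the noise-mean scaling constant Omega.

After a perturbation (cold shock, gyrase inhibition, ATP depletion) the
relative Omega of a reporter cohort — normalized to 1 at t = 0 — shifts over
tens of minutes.  This module fits:

* a fixed-steepness sigmoid L / (1 + exp(-a (t - x0))) with a = 0.1 min^-1
  held fixed (only L and x0 are free; a profile over x0 with the closed-form
  L makes the fit a 1-D optimization, run from a multi-start grid);
* nested polynomials of order 0 and 1 with an extra-sum-of-squares F-test on
  whether the slope improves the fit;
* temperature-sensitive models of the promoter unlocking rate k_plus(t),
  mapped to Omega through the telegraph-model factor
  c * (1 + k1 * k_minus / (k_plus(t) + k_minus)^2), where the proportionality
  scale c is co-fitted per series.  Four parametric families are shipped
  (exponential, constant, linear, power); models are compared by R^2, with
  AIC reported alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .analytic import omega_ratio_on_off

__all__ = [
    "OmegaSeries",
    "SigmoidFit",
    "PolynomialFit",
    "KPlusModel",
    "KPLUS_FAMILIES",
    "fit_sigmoid",
    "fit_polynomial",
    "nested_f_test",
    "fit_kplus_model",
    "select_kplus_model",
]

KPLUS_FAMILIES = ("exponential", "constant", "linear", "power")


@dataclass
class OmegaSeries:
    """Relative Omega over time (dimensionless, 1 at t = 0)."""

    times: np.ndarray  # minutes since the shift
    omega_rel: np.ndarray
    se: Optional[np.ndarray] = None
    condition: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.omega_rel = np.asarray(self.omega_rel, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.omega_rel.shape:
            raise ValueError("times and omega_rel must be 1-D and equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.se is not None:
            self.se = np.asarray(self.se, dtype=float)


@dataclass
class SigmoidFit:
    L: float
    x0: float
    a: float
    r2: float
    rss: float
    identifiable: bool = True

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.L / (1.0 + np.exp(-self.a * (t - self.x0)))


@dataclass
class PolynomialFit:
    order: int
    coeffs: np.ndarray  # highest order first (numpy convention)
    rss: float
    n: int

    def predict(self, t) -> np.ndarray:
        return np.polyval(self.coeffs, np.asarray(t, dtype=float))


@dataclass
class KPlusModel:
    family: str
    params: dict
    scale_c: float
    r2: float
    aic: float
    rss: float
    flag_degenerate: bool = False

    def kplus(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        p = self.params
        if self.family == "exponential":
            return p["k0"] * np.exp(-p["beta"] * t)
        if self.family == "constant":
            return np.full_like(t, p["k0"])
        if self.family == "linear":
            return p["k0"] - p["beta"] * t
        if self.family == "power":
            return p["k0"] * (1.0 + t) ** (-p["beta"])
        raise ValueError(f"unknown family {self.family}")


def _sigmoid_profile_rss(x0: float, t: np.ndarray, y: np.ndarray, a: float):
    """Closed-form L and RSS at fixed (x0, a)."""
    s = 1.0 / (1.0 + np.exp(-a * (t - x0)))
    denom = float(s @ s)
    L = float(y @ s) / denom if denom > 0 else 0.0
    resid = y - L * s
    return float(resid @ resid), L


def fit_sigmoid(series: OmegaSeries, a_fixed: float = 0.1,
                fit_steepness: bool = False) -> SigmoidFit:
    """Least-squares sigmoid with fixed steepness a (default 0.1 min^-1).

    The fit profiles over the midpoint x0 on a dense grid spanning beyond the
    observed time range (L is linear given x0, so it is solved exactly at each
    grid point), then polishes the best grid point with a bounded scalar
    minimization.  A flat series leaves x0 unidentifiable and is flagged.
    Set ``fit_steepness=True`` to also free a (bounded below at 1e-4).
    """
    t, y = series.times, series.omega_rel
    if t.size < 4:
        raise ValueError("need >= 4 time points")
    tss = float(((y - y.mean()) ** 2).sum())
    if tss < 1e-12 * max(1.0, float(np.abs(y).max()) ** 2):
        return SigmoidFit(L=float(y.mean()), x0=float("nan"), a=a_fixed,
                          r2=float("nan"), rss=0.0, identifiable=False)
    span = t[-1] - t[0]
    lo, hi = t[0] - span, t[-1] + span
    grid = np.linspace(lo, hi, 401)
    rss_grid = np.array([_sigmoid_profile_rss(x, t, y, a_fixed)[0] for x in grid])
    i = int(np.argmin(rss_grid))
    bl = grid[max(i - 1, 0)]
    bh = grid[min(i + 1, grid.size - 1)]
    res = optimize.minimize_scalar(
        lambda x: _sigmoid_profile_rss(x, t, y, a_fixed)[0],
        bounds=(bl, bh), method="bounded",
        options={"xatol": 1e-8})
    x0 = float(res.x)
    rss, L = _sigmoid_profile_rss(x0, t, y, a_fixed)
    a = a_fixed
    if fit_steepness:
        def resid(p):
            s = 1.0 / (1.0 + np.exp(-p[2] * (t - p[1])))
            return p[0] * s - y
        sol = optimize.least_squares(resid, x0=[L, x0, a_fixed],
                                     bounds=([0, lo, 1e-4], [np.inf, hi, np.inf]))
        L, x0, a = map(float, sol.x)
        rss = float(2 * sol.cost)
    r2 = 1.0 - rss / tss
    return SigmoidFit(L=L, x0=x0, a=a, r2=r2, rss=rss)


def fit_polynomial(series: OmegaSeries, order: int) -> PolynomialFit:
    """OLS polynomial fit of omega_rel on time (order 0 or 1)."""
    if order not in (0, 1):
        raise ValueError("order must be 0 or 1")
    t, y = series.times, series.omega_rel
    if t.size <= order + 1:
        raise ValueError("need more points than parameters")
    coeffs = np.polyfit(t, y, deg=order)
    resid = y - np.polyval(coeffs, t)
    return PolynomialFit(order=order, coeffs=coeffs, rss=float(resid @ resid),
                         n=t.size)


def nested_f_test(fit_low: PolynomialFit, fit_high: PolynomialFit):
    """Extra-sum-of-squares F-test between nested polynomial fits.

    For orders (0, 1) this is F = ((RSS0 - RSS1)/1) / (RSS1/(n-2)) with
    (1, n-2) degrees of freedom; the p-value is the upper tail.
    """
    if fit_high.order <= fit_low.order:
        raise ValueError("fit_high must have higher order than fit_low")
    if fit_low.n != fit_high.n:
        raise ValueError("fits must be on the same data")
    n = fit_high.n
    df_num = fit_high.order - fit_low.order
    df_den = n - (fit_high.order + 1)
    if fit_high.rss > fit_low.rss * (1 + 1e-10) + 1e-12:
        raise ValueError("higher-order RSS exceeds lower-order RSS; fits inconsistent")
    if fit_high.rss <= 0:
        return float("inf"), 0.0
    F = ((fit_low.rss - fit_high.rss) / df_num) / (fit_high.rss / df_den)
    p = float(stats.f.sf(F, df_num, df_den))
    return float(F), p


def _kplus_curve(family: str, theta: np.ndarray, t: np.ndarray) -> np.ndarray:
    if family == "exponential":
        return np.exp(theta[0]) * np.exp(-theta[1] * t)
    if family == "constant":
        return np.full_like(t, np.exp(theta[0]))
    if family == "linear":
        return np.exp(theta[0]) - theta[1] * t
    if family == "power":
        return np.exp(theta[0]) * (1.0 + t) ** (-theta[1])
    raise ValueError(f"unknown k_plus family {family!r}")


_N_PARAMS = {"exponential": 2, "constant": 1, "linear": 2, "power": 2}


def fit_kplus_model(series: OmegaSeries, family: str, k1: float,
                    k_minus: float) -> KPlusModel:
    """Fit a temperature-sensitive k_plus(t) model to a relative-Omega series.

    The predicted series is c * (1 + k1*k_minus/(k_plus(t)+k_minus)^2) with c
    solved in closed form (it enters linearly) at each candidate k_plus(t).
    k1 and k_minus are held fixed.  Fits with non-positive predicted k_plus on
    the observed range are rejected (infinite RSS).  With k_minus = 0 the
    mapping is constant in k_plus and the model is flagged degenerate.
    """
    if family not in KPLUS_FAMILIES:
        raise ValueError(f"family must be one of {KPLUS_FAMILIES}")
    if k1 <= 0 or k_minus < 0:
        raise ValueError("k1 must be > 0 and k_minus >= 0")
    t, y = series.times, series.omega_rel
    tss = float(((y - y.mean()) ** 2).sum())

    if k_minus == 0:
        c = float(y.mean())
        resid = y - c
        rss = float(resid @ resid)
        return KPlusModel(family=family, params={"k0": float("nan")},
                          scale_c=c, r2=(1 - rss / tss) if tss > 0 else float("nan"),
                          aic=float("nan"), rss=rss, flag_degenerate=True)

    def rss_and_c(theta):
        k = _kplus_curve(family, theta, t)
        if np.any(k <= 0) or not np.all(np.isfinite(k)):
            return 1e100, 0.0  # large finite penalty keeps the simplex stable
        u = np.asarray(omega_ratio_on_off(k1, k, k_minus))
        denom = float(u @ u)
        c = float(y @ u) / denom
        resid = y - c * u
        return float(resid @ resid), c

    n_par = _N_PARAMS[family]
    # multi-start over initial unlocking rates and decay constants
    k0_grid = np.geomspace(1e-3, 10.0, 7) * max(k_minus, 1e-3)
    beta_grid = [0.0, 0.01, 0.05, 0.2] if n_par == 2 else [None]
    best = (np.inf, None, 0.0)
    span = max(t[-1] - t[0], 1.0)
    for k0 in k0_grid:
        for beta in beta_grid:
            theta0 = np.array([math.log(k0)] if beta is None
                              else [math.log(k0), beta])
            try:
                sol = optimize.minimize(lambda th: rss_and_c(th)[0], theta0,
                                        method="Nelder-Mead",
                                        options={"xatol": 1e-10, "fatol": 1e-14,
                                                 "maxiter": 2000})
            except Exception:
                continue
            rss, c = rss_and_c(sol.x)
            if rss < best[0]:
                best = (rss, sol.x.copy(), c)
    rss, theta, c = best
    if theta is None or not np.isfinite(rss) or rss >= 1e99:
        raise RuntimeError(f"no admissible {family} k_plus fit found")
    params = {"k0": float(np.exp(theta[0]))}
    if n_par == 2:
        params["beta"] = float(theta[1])
    n = t.size
    n_fit = n_par + 1  # + scale c
    aic = n * math.log(max(rss, 1e-300) / n) + 2 * n_fit
    r2 = (1 - rss / tss) if tss > 0 else float("nan")
    return KPlusModel(family=family, params=params, scale_c=c, r2=r2,
                      aic=aic, rss=rss)


def select_kplus_model(series: OmegaSeries, k1: float, k_minus: float,
                       families: Sequence[str] = KPLUS_FAMILIES):
    """Fit every k_plus family and return (best_by_r2, all_fits)."""
    fits = {fam: fit_kplus_model(series, fam, k1, k_minus) for fam in families}
    best = max(fits.values(), key=lambda m: (not m.flag_degenerate, m.r2))
    return best, fits
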