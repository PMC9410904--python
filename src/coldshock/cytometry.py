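"""Background-corrected protein-number moments from single-cell fluorescence.

Raw flow-cytometry events mix the reporter signal with cell autofluorescence.
Treating the measured intensity as X = T + B with T (true signal) independent
of B (background, measured on unlabeled cells under the same condition), the
first three cumulants subtract:

    mean_T = mean_X - mean_B
    var_T  = var_X  - var_B
    k3_T   = k3_X   - k3_B        (third cumulant = third central moment)

Corrected intensity moments are converted to protein-number scale with a
multiplicative factor (default 0.1 molecules per a.u., calibrated against
absolute protein counts).  CV^2 and skewness are invariant under this scaling;
Omega scales linearly with it.

Cohort-level Omega is estimated by a no-intercept ordinary least squares fit
of CV^2 on 1/M across genes (CV^2 = Omega/M).  Genes whose corrected variance
falls below the autofluorescence noise floor are flagged and excluded from
fits, and reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "FlowSample",
    "CorrectedMoments",
    "OmegaEstimate",
    "EstimationError",
    "correct_moments",
    "to_protein_numbers",
    "moment_table",
    "estimate_omega",
    "skewness_comparison",
    "noise_floor",
]

DEFAULT_SCALE_FACTOR = 0.1  # molecules per arbitrary fluorescence unit
MIN_EVENTS = 30


class EstimationError(RuntimeError):
    """Raised when a cohort fit has no usable genes."""


@dataclass
class FlowSample:
    """Single-cell fluorescence events for one gene/condition/time point."""

    gene_id: str
    condition: str
    time_min: float
    events: np.ndarray
    background_events: np.ndarray

    def __post_init__(self) -> None:
        self.events = np.asarray(self.events, dtype=float).ravel()
        self.background_events = np.asarray(self.background_events, dtype=float).ravel()
        if self.events.size == 0:
            raise ValueError("events must be nonempty")
        if not (np.isfinite(self.events).all()
                and np.isfinite(self.background_events).all()):
            raise ValueError("intensities must be finite")


@dataclass
class CorrectedMoments:
    """Background-corrected moments on the protein-number scale."""

    gene_id: str
    mean: float
    variance: float
    third_central_moment: float
    n_events: int
    flag_below_floor: bool

    @property
    def cv2(self) -> float:
        return self.variance / self.mean**2 if self.mean > 0 else float("nan")

    @property
    def skewness(self) -> float:
        if self.variance <= 0:
            return float("nan")
        return self.third_central_moment / self.variance**1.5


@dataclass
class OmegaEstimate:
    omega: float
    se_omega: float
    r2: float
    n_genes: int


def _k_stats(x: np.ndarray) -> tuple[float, float, float]:
    """Unbiased cumulant estimates (mean, k2, k3)."""
    n = x.size
    mean = x.mean()
    k2 = x.var(ddof=1) if n > 1 else 0.0
    if n > 2:
        m3 = ((x - mean) ** 3).mean()
        k3 = m3 * n * n / ((n - 1) * (n - 2))
    else:
        k3 = 0.0
    return mean, k2, k3


def correct_moments(sample: FlowSample,
                    scale_factor: float = DEFAULT_SCALE_FACTOR,
                    min_events: int = MIN_EVENTS,
                    floor_multiplier: float = 1.0) -> CorrectedMoments:
    """Cumulant-subtract autofluorescence and rescale to protein numbers.

    The gene is flagged below the noise floor when its corrected variance is
    smaller than ``floor_multiplier`` times the background variance (or not
    positive at all); flagged genes carry their moments but are excluded from
    downstream fits.
    """
    if sample.events.size < min_events or sample.background_events.size < min_events:
        raise ValueError(f"need >= {min_events} events in both event sets")
    mu_s, v_s, k3_s = _k_stats(sample.events)
    mu_b, v_b, k3_b = _k_stats(sample.background_events)
    mean_c = mu_s - mu_b
    var_c = v_s - v_b
    m3_c = k3_s - k3_b
    flag = (var_c <= 0) or (var_c < floor_multiplier * v_b)
    mean_c, var_c, m3_c = to_protein_numbers(mean_c, var_c, m3_c, scale_factor)
    return CorrectedMoments(gene_id=sample.gene_id, mean=mean_c, variance=var_c,
                            third_central_moment=m3_c, n_events=sample.events.size,
                            flag_below_floor=bool(flag))


def to_protein_numbers(mean: float, variance: float, third_central_moment: float,
                       scale_factor: float = DEFAULT_SCALE_FACTOR):
    """Convert intensity-scale moments to molecule scale (mean*s, var*s^2, m3*s^3)."""
    if scale_factor <= 0:
        raise ValueError("scale_factor must be > 0")
    s = float(scale_factor)
    return mean * s, variance * s**2, third_central_moment * s**3


def moment_table(moments: Iterable[CorrectedMoments]) -> pd.DataFrame:
    """Tabulate corrected moments (one row per gene)."""
    rows = [{"gene_id": m.gene_id, "M": m.mean, "variance": m.variance,
             "m3": m.third_central_moment, "cv2": m.cv2, "skewness": m.skewness,
             "n_events": m.n_events, "flag_below_floor": m.flag_below_floor}
            for m in moments]
    return pd.DataFrame(rows)


def estimate_omega(cohort) -> OmegaEstimate:
    """Fit CV^2 = Omega / M across a gene cohort by no-intercept OLS.

    ``cohort`` is a sequence of (M, cv2) pairs, a DataFrame with columns
    ``M``/``cv2`` (rows with ``flag_below_floor`` true are dropped), or a list
    of :class:`CorrectedMoments`.
    """
    if isinstance(cohort, pd.DataFrame):
        df = cohort
    elif len(cohort) and isinstance(cohort[0], CorrectedMoments):
        df = moment_table(cohort)
    else:
        df = pd.DataFrame(cohort, columns=["M", "cv2"])
    if "flag_below_floor" in df:
        df = df[~df["flag_below_floor"]]
    df = df[(df["M"] > 0) & np.isfinite(df["cv2"])]
    if len(df) < 2:
        raise EstimationError("need >= 2 unflagged genes with M > 0")
    x = 1.0 / df["M"].to_numpy()
    y = df["cv2"].to_numpy()
    fit = sm.OLS(y, x[:, None]).fit()
    omega = float(fit.params[0])
    if omega <= 0:
        raise EstimationError("fitted Omega is non-positive")
    return OmegaEstimate(omega=omega, se_omega=float(fit.bse[0]),
                         r2=float(fit.rsquared), n_genes=len(df))


def skewness_comparison(moments: Sequence[CorrectedMoments], omega: float):
    """Pair empirical and predicted (Gamma) skewness for genes above the floor.

    Predicted skewness is 2*sqrt(Omega/M) with the cohort Omega.  Returns a
    DataFrame of paired values plus the OLS slope and Pearson r of empirical
    vs predicted; floor-excluded genes are listed separately.
    """
    if omega <= 0:
        raise ValueError("omega must be > 0")
    kept, excluded = [], []
    for m in moments:
        if m.flag_below_floor or m.mean <= 0 or m.variance <= 0:
            excluded.append(m.gene_id)
            continue
        kept.append({"gene_id": m.gene_id,
                     "empirical_skewness": m.skewness,
                     "predicted_skewness": 2.0 * np.sqrt(omega / m.mean)})
    if len(kept) < 3:
        raise EstimationError("need >= 3 genes above the noise floor")
    df = pd.DataFrame(kept)
    lr = stats.linregress(df["predicted_skewness"], df["empirical_skewness"])
    return {"pairs": df, "slope": float(lr.slope), "intercept": float(lr.intercept),
            "r": float(lr.rvalue), "excluded": excluded}


def noise_floor(background_events: np.ndarray, M_grid: np.ndarray,
                scale_factor: float = DEFAULT_SCALE_FACTOR) -> np.ndarray:
    """Minimal resolvable CV^2 as a function of mean protein number.

    floor(M) = var(background, molecule scale) / M^2 — the CV^2 a gene would
    show if its entire corrected variance came from background fluctuations.
    Strictly decreasing in M.
    """
    bg = np.asarray(background_events, dtype=float)
    if bg.size == 0:
        raise ValueError("background events must be nonempty")
    var_b = bg.var(ddof=1) * scale_factor**2 if bg.size > 1 else 0.0
    M = np.asarray(M_grid, dtype=float)
    if np.any(M <= 0):
        raise ValueError("M_grid must be strictly positive")
    return var_b / M**2
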