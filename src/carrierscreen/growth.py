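"""Growth-curve analysis: max specific growth rates, dose-response, IC90,
and competitive-substrate protection.

The maximum specific growth rate mu_max is the steepest least-squares slope
of ln(OD) against time over a sliding window (5 consecutive 10-minute
readings by default), after blank subtraction. Dose-response profiles are
per-concentration means with standard errors over replicates (n = 3 in the
validation experiments), and inhibitory concentrations come from a Hill fit

    mu(c) = mu0 / (1 + (c / IC50)^h)

with mu0 pinned to the zero-concentration arm. IC90 — the concentration
reducing the wild-type growth rate by 90% — is the closed-form inversion of
the fitted curve, never extrapolated beyond the measured range. Protection
by a competing native substrate is quantified as the fraction of the
untreated growth rate recovered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from ._exceptions import DomainError, EstimationError, InputError, RangeError

logger = logging.getLogger(__name__)

OD_FLOOR = 1e-4  # detection floor on blank-subtracted OD


@dataclass(frozen=True)
class RateEstimate:
    """Maximum specific growth rate of one culture."""

    mu_max: float                      # 1/h
    window: tuple[float, float] | None  # (start, end) time in min; None if no growth
    r_squared: float


@dataclass(frozen=True)
class ICEstimate:
    """An inhibitory-concentration estimate at a given level (0.9 = IC90)."""

    level: float
    concentration: float  # uM
    method: str           # "hill_fit" or "interpolation"
    mu0: float | None = None
    ic50: float | None = None
    h: float | None = None


def _rolling_slopes(t_h: np.ndarray, y: np.ndarray, w: int) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares slope and R^2 of every length-w window (vectorized)."""
    tw = np.lib.stride_tricks.sliding_window_view(t_h, w)
    yw = np.lib.stride_tricks.sliding_window_view(y, w)
    tm = tw.mean(axis=1, keepdims=True)
    ym = yw.mean(axis=1, keepdims=True)
    sxx = ((tw - tm) ** 2).sum(axis=1)
    sxy = ((tw - tm) * (yw - ym)).sum(axis=1)
    syy = ((yw - ym) ** 2).sum(axis=1)
    slope = sxy / sxx
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(syy > 0, sxy**2 / (sxx * syy), 1.0)
    return slope, r2


def mu_max(
    curve: pd.DataFrame,
    window_points: int = 5,
    blank: str | float = "first",
) -> RateEstimate:
    """Estimate the maximum specific growth rate from one OD600 time series.

    ``curve`` needs ``time_min`` and ``od600``. The blank is subtracted
    (``"first"``: the first reading, typically the instrument's media-only
    startup read; a float: that value; ``"none"``: no subtraction), the
    result floored at the detection limit, and the steepest sliding-window
    slope of ln(OD) returned in 1/h. Samples at or below the floor are
    below detection and excluded from window fitting; a curve with no
    usable window (no growth) gets mu_max = 0.
    """
    if not {"time_min", "od600"}.issubset(curve.columns):
        raise InputError("curve needs time_min and od600 columns")
    t_min = curve["time_min"].to_numpy(dtype=float)
    od = curve["od600"].to_numpy(dtype=float)
    if len(od) < window_points:
        raise EstimationError(
            f"need at least {window_points} samples, got {len(od)}"
        )
    if blank == "first":
        blank_value = od[0]
    elif blank == "none":
        blank_value = 0.0
    else:
        blank_value = float(blank)
    x = od - blank_value
    usable = x > OD_FLOOR

    best_slope, best_r2, best_window = None, np.nan, None
    # fit within each maximal run of consecutive above-floor samples
    idx = np.flatnonzero(usable)
    if idx.size >= window_points:
        splits = np.flatnonzero(np.diff(idx) > 1)
        for run in np.split(idx, splits + 1):
            if run.size < window_points:
                continue
            t_h = t_min[run] / 60.0
            y = np.log(x[run])
            slopes, r2s = _rolling_slopes(t_h, y, window_points)
            k = int(np.argmax(slopes))
            if best_slope is None or slopes[k] > best_slope:
                best_slope = float(slopes[k])
                best_r2 = float(r2s[k])
                best_window = (float(t_min[run[k]]), float(t_min[run[k + window_points - 1]]))
    if best_slope is None:
        return RateEstimate(0.0, None, float("nan"))
    return RateEstimate(max(best_slope, 0.0), best_window, best_r2)


def final_od(curve: pd.DataFrame, blank: str | float = "first") -> float:
    """Blank-subtracted OD of the last sample (biomass-yield criterion).

    Reported alongside mu_max because yield can reveal resistance that the
    growth rate misses (e.g. protection raising final OD while the rate
    stays inhibited).
    """
    if curve.empty:
        return 0.0
    od = curve.sort_values("time_min")["od600"].to_numpy(dtype=float)
    if blank == "first":
        blank_value = od[0]
    elif blank == "none":
        blank_value = 0.0
    else:
        blank_value = float(blank)
    return float(max(od[-1] - blank_value, 0.0))


def dose_response(rates: pd.DataFrame) -> pd.DataFrame:
    """Per-concentration mean mu_max and standard error over replicates.

    ``rates`` needs ``conc_uM`` and ``mu_max`` (one row per replicate) and
    must include the zero-concentration reference arm.
    """
    if not {"conc_uM", "mu_max"}.issubset(rates.columns):
        raise InputError("rates needs conc_uM and mu_max columns")
    concs = rates["conc_uM"].unique()
    if len(concs) < 2:
        raise InputError("need at least two concentrations")
    if 0.0 not in concs:
        raise InputError("missing zero-concentration reference arm")
    grouped = (
        rates.groupby("conc_uM")["mu_max"]
        .agg(mu_max="mean", sd=lambda v: v.std(ddof=1), n="count")
        .reset_index()
        .sort_values("conc_uM")
        .reset_index(drop=True)
    )
    grouped["se"] = (grouped["sd"] / np.sqrt(grouped["n"])).fillna(0.0)
    return grouped[["conc_uM", "mu_max", "se", "n"]]


def invert_hill(mu0: float, ic50: float, h: float, level: float) -> float:
    """Concentration where the Hill curve reaches (1 - level) x mu0.

    Closed form: c = IC50 x (level / (1 - level))^(1/h); level 0.9 gives
    the IC90 = IC50 x 9^(1/h).
    """
    if not (0.0 < level < 1.0):
        raise DomainError(f"level must be in (0, 1), got {level}")
    if ic50 <= 0 or h <= 0 or mu0 <= 0:
        raise DomainError("mu0, IC50 and h must be positive")
    return ic50 * (level / (1.0 - level)) ** (1.0 / h)


class HillDoseResponse:
    """Hill dose-response model mu(c) = mu0 / (1 + (c/IC50)^h).

    mu0 is pinned to the zero-concentration arm (mean over its replicates)
    rather than fitted, which stabilises the small concentration panels of
    a validation experiment; ``fit()`` estimates IC50 and h by least
    squares and returns a :class:`HillDoseResponseResults`.
    """

    def __init__(self, conc_uM: np.ndarray, mu: np.ndarray, mu0: float | None = None):
        self.conc = np.asarray(conc_uM, dtype=float)
        self.mu = np.asarray(mu, dtype=float)
        if self.conc.shape != self.mu.shape or self.conc.size == 0:
            raise InputError("conc and mu must be equal-length, non-empty arrays")
        if mu0 is None:
            at_zero = self.mu[self.conc == 0]
            if at_zero.size == 0:
                raise InputError("missing zero-concentration reference arm")
            mu0 = float(at_zero.mean())
        if mu0 <= 0:
            raise DomainError("mu0 must be positive")
        self.mu0 = mu0

    @classmethod
    def from_dataframe(cls, dr: pd.DataFrame, mu0: float | None = None) -> "HillDoseResponse":
        return cls(dr["conc_uM"].to_numpy(), dr["mu_max"].to_numpy(), mu0=mu0)

    def predict(self, conc: np.ndarray, ic50: float, h: float) -> np.ndarray:
        conc = np.asarray(conc, dtype=float)
        return self.mu0 / (1.0 + (conc / ic50) ** h)

    def fit(self) -> "HillDoseResponseResults":
        positive = self.conc[self.conc > 0]
        if positive.size == 0:
            raise InputError("need at least one positive concentration")
        p0 = (float(np.exp(np.mean(np.log(positive)))), 1.0)
        params, cov = curve_fit(
            lambda c, ic50, h: self.predict(c, ic50, h),
            self.conc,
            self.mu,
            p0=p0,
            bounds=([1e-12, 1e-3], [np.inf, 50.0]),
            maxfev=20000,
        )
        return HillDoseResponseResults(self, float(params[0]), float(params[1]), cov)


class HillDoseResponseResults:
    """Fitted Hill parameters with uncertainties and IC-level inversion."""

    def __init__(self, model: HillDoseResponse, ic50: float, h: float, cov: np.ndarray):
        self.model = model
        self.ic50 = ic50
        self.h = h
        self.cov = cov
        with np.errstate(invalid="ignore"):
            self.bse = np.sqrt(np.diag(cov))

    @property
    def mu0(self) -> float:
        return self.model.mu0

    def ic(self, level: float = 0.9) -> float:
        """Inhibitory concentration at ``level`` (no range check here)."""
        return invert_hill(self.mu0, self.ic50, self.h, level)

    def summary(self) -> str:
        lines = [
            "Hill dose-response fit",
            "=" * 40,
            f"  mu0 (fixed)   {self.mu0:12.6g}  1/h",
            f"  IC50          {self.ic50:12.6g}  uM   (se {self.bse[0]:.3g})",
            f"  hill h        {self.h:12.6g}       (se {self.bse[1]:.3g})",
            f"  IC90          {self.ic(0.9):12.6g}  uM",
            f"  n obs         {self.model.conc.size:12d}",
        ]
        return "\n".join(lines)


def ic_level(dr: pd.DataFrame, level: float = 0.9) -> ICEstimate:
    """Estimate the concentration inhibiting growth rate by ``level``.

    Fits the Hill model to the dose-response table (``conc_uM``,
    ``mu_max``); if the fit fails to converge, falls back to monotone
    interpolation of mu against log concentration. The requested level
    must be bracketed by the measured responses and the returned
    concentration must lie inside the measured concentration range —
    extrapolation raises a range error reporting the bracketing gap.
    """
    if not (0.0 < level < 1.0):
        raise DomainError(f"level must be in (0, 1), got {level}")
    model = HillDoseResponse.from_dataframe(dr)
    target = (1.0 - level) * model.mu0
    mu_lo, mu_hi = float(dr["mu_max"].min()), float(dr["mu_max"].max())
    if not (mu_lo <= target <= mu_hi):
        raise RangeError(
            f"level {level} (target mu {target:.4g}) not bracketed by measured "
            f"responses [{mu_lo:.4g}, {mu_hi:.4g}]"
        )
    try:
        res = model.fit()
        conc = res.ic(level)
        method, ic50, h = "hill_fit", res.ic50, res.h
    except (RuntimeError, ValueError):
        logger.warning("Hill fit failed to converge; using interpolation fallback")
        conc = _interp_ic(dr, target)
        method, ic50, h = "interpolation", None, None
    c_max = float(dr["conc_uM"].max())
    if conc > c_max:
        raise RangeError(
            f"estimated concentration {conc:.4g} uM exceeds the measured range "
            f"(max {c_max:.4g} uM); refusing to extrapolate"
        )
    return ICEstimate(level, float(conc), method, model.mu0, ic50, h)


def _interp_ic(dr: pd.DataFrame, target: float) -> float:
    """Monotone log-concentration interpolation fallback."""
    sub = dr[dr["conc_uM"] > 0].sort_values("conc_uM")
    logc = np.log(sub["conc_uM"].to_numpy(dtype=float))
    mu = sub["mu_max"].to_numpy(dtype=float)
    # np.interp needs increasing x: mu decreases with conc, so reverse
    return float(np.exp(np.interp(target, mu[::-1], logc[::-1])))


def recovery_fraction(mu_drug_plus_competitor: float, mu_untreated: float) -> float:
    """Fraction of the untreated growth rate recovered under protection."""
    if mu_untreated <= 0:
        raise DomainError(f"untreated growth rate must be positive, got {mu_untreated}")
    return max(mu_drug_plus_competitor / mu_untreated, 0.0)


def protection_profile(
    drug_conc: float,
    competitor_concs: np.ndarray,
    ic50: float,
    h: float,
    ks: float,
    mu0: float = 1.0,
) -> pd.DataFrame:
    """Closed-form protection sweep under the single-site competitive model.

    For each competitor concentration: the effective drug concentration
    c_eff = c_drug / (1 + c_comp / Ks), the resulting Hill growth rate, and
    the recovery fraction relative to the untreated rate. Recovery rises
    monotonically to 1 as the competitor saturates the carrier.
    """
    from .simulate import apply_protection, hill_rate

    rows = []
    for c_comp in np.asarray(competitor_concs, dtype=float):
        c_eff = apply_protection(drug_conc, float(c_comp), ks)
        mu = hill_rate(mu0, c_eff, ic50, h)
        rows.append(
            {
                "competitor_uM": float(c_comp),
                "effective_drug_uM": c_eff,
                "mu_max": mu,
                "recovery": recovery_fraction(mu, mu0),
            }
        )
    return pd.DataFrame(rows)
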