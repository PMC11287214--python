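"""Four-parameter logistic (4PL) dose-response fitting and corrinoid preference.

A dependent isolate's growth response to a corrinoid concentration series is
summarized by the 4PL model

    y(x) = bottom + (top - bottom) / (1 + (ec50 / x)^hill)

with bottom/top the asymptotic ODs, hill > 0 the slope, and ec50 the
concentration of half-maximal growth.  EC50s are fitted on the log10
concentration scale (tested ranges span ~6 decades, which makes linear-space
fitting ill-conditioned) with multistart initialization, and 95% Wald
confidence intervals are computed on log10 EC50 and back-transformed.  CI
bounds that fall outside the tested concentration range, or that cannot be
determined, are reported as one-sided "<" / ">" sentinels.  The corrinoid
with the lowest EC50 among successful fits is the isolate's preferred
corrinoid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "CORRINOID_CODES",
    "DoseResponseDataset",
    "FourPLFit",
    "PreferenceTable",
    "fourpl_predict",
    "fourpl_inverse",
    "fit_fourpl",
    "ec50_confidence_interval",
    "preference_ranking",
]

#: Corrinoid three-letter codes used throughout: cobalamin (B12), four other
#: complete cobamides with different lower ligands, and cobinamide.
CORRINOID_CODES = ("B12", "2MA", "5OH", "ADE", "CRE", "CBI")

_HILL_MAX = 10.0


def fourpl_predict(x, bottom: float, top: float, hill: float, ec50: float):
    """Evaluate the 4PL response at concentration ``x`` (molar, > 0)."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("concentrations must be positive")
    if ec50 <= 0:
        raise ValueError("ec50 must be positive")
    out = bottom + (top - bottom) / (1.0 + (ec50 / x) ** hill)
    return float(out) if out.ndim == 0 else out


def fourpl_inverse(y: float, bottom: float, top: float, hill: float, ec50: float) -> float:
    """Concentration producing response ``y``; requires bottom < y < top."""
    if not (min(bottom, top) < y < max(bottom, top)):
        raise ValueError("response must lie strictly between bottom and top")
    return ec50 * ((top - bottom) / (y - bottom) - 1.0) ** (-1.0 / hill)


@dataclass
class DoseResponseDataset:
    """Final ODs across a concentration series for one isolate x corrinoid."""

    isolate_id: str
    corrinoid: str
    concentrations: np.ndarray  # molar, replicates allowed
    od600: np.ndarray

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.od600 = np.asarray(self.od600, dtype=float)
        if self.concentrations.shape != self.od600.shape:
            raise ValueError("concentrations and od600 must have equal length")
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be positive")
        if np.any(self.od600 < 0):
            raise ValueError("od600 must be non-negative")

    @property
    def n_distinct(self) -> int:
        return int(np.unique(self.concentrations).size)


@dataclass
class FourPLFit:
    """Fitted 4PL parameters with EC50 confidence information.

    ``status`` is ``"fit"`` for a successful regression, ``"NG"`` (no growth)
    when every response sits below the growth floor, and ``"ND"`` (no data /
    no regression possible) for insufficient or degenerate input.  CI bounds
    carry sentinel markers mirroring the one-sided "<" / ">" reporting used
    when a bound cannot be determined within the tested range.
    """

    status: str
    bottom: float = math.nan
    top: float = math.nan
    hill: float = math.nan
    ec50: float = math.nan
    log10_ec50: float = math.nan
    se_log10_ec50: float = math.nan
    ec50_ci_low: float = math.nan
    ec50_ci_high: float = math.nan
    ci_low_sentinel: bool = False   # True -> report as "< lowest bound"
    ci_high_sentinel: bool = False  # True -> report as "> highest bound"
    converged: bool = False
    ssr: float = math.nan
    n_obs: int = 0

    def ci_text(self, sig: int = 2) -> str:
        from .dilution import format_concentration

        if self.status != "fit":
            return self.status
        lo = ("<" + format_concentration(self.ec50_ci_low, sig)
              if self.ci_low_sentinel else format_concentration(self.ec50_ci_low, sig))
        hi = (">" + format_concentration(self.ec50_ci_high, sig)
              if self.ci_high_sentinel else format_concentration(self.ec50_ci_high, sig))
        return f"({lo}, {hi})"


def _residuals(theta: np.ndarray, lx: np.ndarray, y: np.ndarray) -> np.ndarray:
    bottom, span, hill, l10 = theta
    return bottom + span / (1.0 + 10.0 ** (hill * (l10 - lx))) - y


def fit_fourpl(
    data: DoseResponseDataset,
    growth_floor: float = 0.1,
    flat_tol: float = 0.05,
    n_starts: int = 6,
) -> FourPLFit:
    """Least-squares 4PL fit with EC50 estimated on the log10 scale.

    Replicates enter the loss individually, unweighted.  Multistart
    initialization places the initial log10 EC50 on a grid spanning the
    tested concentration range; bottom/top start at the data extremes and the
    hill slope at 1, constrained to (0, 10] with bottom >= 0 and top >=
    bottom.  Returns status "NG" when no concentration elicits growth above
    ``growth_floor``, and "ND" when fewer than 4 distinct concentrations are
    available, the response range is below ``flat_tol``, or the optimizer
    fails.
    """
    y = data.od600
    if np.all(y < growth_floor):
        return FourPLFit(status="NG", n_obs=int(y.size))
    if data.n_distinct < 4:
        return FourPLFit(status="ND", n_obs=int(y.size))
    span_obs = float(y.max() - y.min())
    if span_obs < flat_tol:
        return FourPLFit(status="ND", n_obs=int(y.size))

    lx = np.log10(data.concentrations)
    l10_lo, l10_hi = float(lx.min()), float(lx.max())
    bounds_lo = np.array([0.0, 0.0, 1e-3, l10_lo - 3.0])
    bounds_hi = np.array([float(y.max()), 2.0 * max(span_obs, 1e-6) + float(y.max()),
                          _HILL_MAX, l10_hi + 3.0])

    best = None
    for l10_init in np.linspace(l10_lo, l10_hi, n_starts):
        theta0 = np.array([float(y.min()), span_obs, 1.0, l10_init])
        theta0 = np.clip(theta0, bounds_lo + 1e-12, bounds_hi - 1e-12)
        try:
            res = least_squares(_residuals, theta0, args=(lx, y),
                                bounds=(bounds_lo, bounds_hi), method="trf",
                                xtol=1e-12, ftol=1e-12, gtol=1e-12)
        except Exception:  # pragma: no cover - scipy failure path
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not best.success:
        return FourPLFit(status="ND", n_obs=int(y.size))

    bottom, span, hill, l10 = best.x
    if span <= 1e-9:  # collapsed to a flat line: no usable regression
        return FourPLFit(status="ND", n_obs=int(y.size))
    ssr = float(2.0 * best.cost)
    fit = FourPLFit(
        status="fit", bottom=float(bottom), top=float(bottom + span),
        hill=float(hill), ec50=float(10.0 ** l10), log10_ec50=float(l10),
        converged=bool(best.success), ssr=ssr, n_obs=int(y.size),
    )
    _wald_ci(fit, best.jac, ssr, y.size, (l10_lo, l10_hi))
    return fit


def _wald_ci(fit: FourPLFit, jac: np.ndarray, ssr: float, n: int,
             tested_range: tuple, z: float = 1.959963984540054) -> None:
    """95% Wald interval on log10 EC50 from the regression covariance.

    Non-finite bounds (singular covariance) and bounds outside the tested
    concentration range are replaced by one-sided sentinels, clipped to the
    tested range, reproducing "<" / ">" reporting.
    """
    dof = n - jac.shape[1]
    l10_lo, l10_hi = tested_range
    try:
        jtj = jac.T @ jac
        cov = np.linalg.inv(jtj) * (ssr / dof if dof > 0 else math.nan)
        var_l10 = float(cov[3, 3])
    except np.linalg.LinAlgError:
        var_l10 = math.nan
    if not math.isfinite(var_l10) or var_l10 < 0:
        fit.se_log10_ec50 = math.nan
        fit.ec50_ci_low, fit.ec50_ci_high = 10.0 ** l10_lo, 10.0 ** l10_hi
        fit.ci_low_sentinel = fit.ci_high_sentinel = True
        return
    se = math.sqrt(var_l10)
    fit.se_log10_ec50 = se
    lo, hi = fit.log10_ec50 - z * se, fit.log10_ec50 + z * se
    if lo < l10_lo:
        fit.ec50_ci_low, fit.ci_low_sentinel = 10.0 ** l10_lo, True
    else:
        fit.ec50_ci_low = 10.0 ** lo
    if hi > l10_hi:
        fit.ec50_ci_high, fit.ci_high_sentinel = 10.0 ** l10_hi, True
    else:
        fit.ec50_ci_high = 10.0 ** hi


def ec50_confidence_interval(fit: FourPLFit, data: DoseResponseDataset
                             ) -> tuple[float, float]:
    """Recompute the 95% EC50 interval for a fitted curve from its data.

    Returns the (low, high) bounds in molar; sentinel status is recorded on
    the fit (``ci_low_sentinel`` / ``ci_high_sentinel``).
    """
    if fit.status != "fit":
        raise ValueError("confidence interval requires a successful fit")
    lx = np.log10(data.concentrations)
    theta = np.array([fit.bottom, fit.top - fit.bottom, fit.hill, fit.log10_ec50])
    # numerical Jacobian of the residual vector at the solution
    eps = 1e-6
    cols = []
    for j in range(4):
        dt = np.zeros(4)
        dt[j] = eps * max(1.0, abs(theta[j]))
        cols.append((_residuals(theta + dt, lx, data.od600)
                     - _residuals(theta - dt, lx, data.od600)) / (2 * dt[j]))
    jac = np.column_stack(cols)
    ssr = float(np.sum(_residuals(theta, lx, data.od600) ** 2))
    _wald_ci(fit, jac, ssr, data.od600.size, (float(lx.min()), float(lx.max())))
    return fit.ec50_ci_low, fit.ec50_ci_high


@dataclass
class PreferenceTable:
    """Per-corrinoid fits for one isolate, ranked by EC50 (lower = preferred)."""

    isolate_id: str
    fits: Dict[str, FourPLFit]
    preferred: Optional[str] = field(init=False)
    ranking: list = field(init=False)
    tie_flag: bool = field(init=False)

    def __post_init__(self) -> None:
        fitted = [(c, f.ec50) for c, f in self.fits.items() if f.status == "fit"]
        fitted.sort(key=lambda t: (t[1], t[0]))
        self.ranking = [c for c, _ in fitted]
        self.preferred = fitted[0][0] if fitted else None
        self.tie_flag = (len(fitted) > 1 and
                         math.isclose(fitted[0][1], fitted[1][1],
                                      rel_tol=0.0, abs_tol=0.0))


def preference_ranking(isolate_id: str, fits: Dict[str, FourPLFit]) -> PreferenceTable:
    """Rank an isolate's corrinoids by fitted EC50, ascending.

    NG/ND entries are excluded from the ranking but retained in the table;
    with no successful fit the preferred corrinoid is undefined.  Exact EC50
    ties keep both entries and flag the tie (the strictly smallest point
    estimate, breaking ties by corrinoid code, is reported as preferred).
    """
    if not fits:
        raise ValueError("need at least one fit")
    return PreferenceTable(isolate_id=isolate_id, fits=dict(fits))
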