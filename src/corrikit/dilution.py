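"""Poisson occupancy mathematics for limiting-dilution isolation.

When a dilute cell suspension is dispensed into microplate wells, the number
of founder cells per well is modeled as Poisson with mean ``lambda_``
(founders per well).  A well is growth-positive when it received at least one
founder, and the resulting culture is clonal when it received exactly one.
These two observables tie the plate design to the expected purity of the
isolate collection: occupancy near 30% is the classic operating point at
which ~80% of positive wells are expected to be clonal.

This module provides the forward and inverse occupancy maps, the conditional
clonality probability, maximum-likelihood MPN (most probable number)
estimation from positive/negative well counts across dilution levels, and
geometric dilution-series construction for dose-response plates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "OccupancyModel",
    "DilutionSeries",
    "MpnEstimate",
    "positive_fraction_from_lambda",
    "lambda_from_positive_fraction",
    "clonal_fraction",
    "mpn_from_counts",
    "serial_dilution_series",
    "format_concentration",
]


def positive_fraction_from_lambda(lambda_: float) -> float:
    """Expected fraction of growth-positive wells, P(X >= 1) = 1 - exp(-lambda)."""
    if lambda_ < 0:
        raise ValueError(f"lambda_ must be >= 0, got {lambda_}")
    return -math.expm1(-lambda_)


def lambda_from_positive_fraction(p: float) -> float:
    """Mean founders per well from the observed positive-well fraction.

    Inverts ``positive_fraction_from_lambda``: returns ``-ln(1 - p)``.

    Parameters
    ----------
    p : float
        Fraction of wells showing growth, in [0, 1).

    Raises
    ------
    ValueError
        If ``p`` is outside [0, 1); at p = 1 the founder rate is unbounded.
    """
    if not 0 <= p < 1:
        raise ValueError(f"positive fraction must be in [0, 1), got {p}")
    return -math.log1p(-p)


def clonal_fraction(lambda_: float) -> float:
    """Probability a growth-positive well holds exactly one founder.

    P(X = 1 | X >= 1) = lambda * exp(-lambda) / (1 - exp(-lambda)) for
    X ~ Poisson(lambda).  The limit as lambda -> 0 is 1 (every positive well
    has a single founder); at lambda = -ln(0.7) (30% occupancy) the value is
    ~0.832, the ~80% clonality expected in limiting-dilution isolation.
    """
    if lambda_ < 0:
        raise ValueError(f"lambda_ must be >= 0, got {lambda_}")
    if lambda_ == 0:
        return 1.0
    return lambda_ * math.exp(-lambda_) / -math.expm1(-lambda_)


@dataclass
class OccupancyModel:
    """Poisson well-occupancy summary for a limiting-dilution plate design."""

    lambda_: float
    n_wells: int = 0
    positive_fraction: float = field(init=False)
    clonal_fraction: float = field(init=False)

    def __post_init__(self) -> None:
        if self.lambda_ < 0:
            raise ValueError("lambda_ must be >= 0")
        self.positive_fraction = positive_fraction_from_lambda(self.lambda_)
        self.clonal_fraction = clonal_fraction(self.lambda_)

    @classmethod
    def from_positive_fraction(cls, p: float, n_wells: int = 0) -> "OccupancyModel":
        return cls(lambda_=lambda_from_positive_fraction(p), n_wells=n_wells)

    def expected_clonal_wells(self) -> float:
        return self.n_wells * self.positive_fraction * self.clonal_fraction


@dataclass
class MpnEstimate:
    """Maximum-likelihood founder-rate estimate from well counts.

    ``status`` is ``"estimate"`` for an interior ML solution, ``"all_negative"``
    (lambda_hat = 0, one-sided upper bound only) when no well grew, and
    ``"all_positive"`` (lambda_hat = inf, no finite estimate) when every well
    grew.  ``concentration_hat`` is founders per ml when an inoculum volume is
    supplied, else None.
    """

    lambda_hat: float
    ci_low: float
    ci_high: float
    status: str = "estimate"
    concentration_hat: Optional[float] = None

    @property
    def is_finite(self) -> bool:
        return self.status == "estimate" or (
            self.status == "all_negative" and self.lambda_hat == 0.0
        )


def _mpn_score(lam: float, positives: np.ndarray, wells: np.ndarray,
               dilutions: np.ndarray) -> float:
    # d/dlambda of the binomial log-likelihood with q_i = 1 - exp(-lam * d_i)
    e = np.exp(-lam * dilutions)
    q = -np.expm1(-lam * dilutions)
    return float(np.sum(positives * dilutions * e / q)
                 - np.sum((wells - positives) * dilutions))


def mpn_from_counts(
    positives: Sequence[int],
    wells: Sequence[int],
    dilutions: Optional[Sequence[float]] = None,
    inoculum_volume_ml: Optional[float] = None,
    confidence: float = 0.95,
) -> MpnEstimate:
    """MPN (most probable number) estimate of founders per well at dilution 1.

    Solves the ML score equation

        sum_i [ p_i d_i e^(-lam d_i) / (1 - e^(-lam d_i)) - (w_i - p_i) d_i ] = 0

    by bracketed 1-D root finding, where ``d_i`` is the relative inoculum of
    dilution level ``i``.  With a single dilution level this reduces exactly to
    ``lambda_from_positive_fraction(p/w) / d``.

    The confidence interval is a log-normal Wald interval: the Fisher
    information I(lam) = sum_i w_i d_i^2 e^(-lam d_i) / (1 - e^(-lam d_i))
    gives se(lam) = I^(-1/2), and the interval is lam * exp(+/- z se/lam).

    All-negative plates return lambda_hat = 0 with an exact one-sided upper
    bound; all-positive plates return an ``"all_positive"`` sentinel (never an
    exception) so batch pipelines can proceed.
    """
    p = np.asarray(positives, dtype=float)
    w = np.asarray(wells, dtype=float)
    if dilutions is None:
        d = np.ones_like(p)
    else:
        d = np.asarray(dilutions, dtype=float)
    if not (p.shape == w.shape == d.shape):
        raise ValueError("positives, wells and dilutions must have equal length")
    if np.any(p < 0) or np.any(p > w):
        raise ValueError("need 0 <= positives[i] <= wells[i]")
    if np.any(d <= 0):
        raise ValueError("dilutions must be positive")
    alpha = 1.0 - confidence
    from scipy.stats import norm

    z = norm.ppf(1.0 - alpha / 2.0)

    total_wd = float(np.sum(w * d))
    if np.all(p == 0):
        # exact one-sided bound: P(all negative | lam) = exp(-lam * sum w_i d_i)
        upper = -math.log(alpha) / total_wd if total_wd > 0 else math.inf
        return MpnEstimate(0.0, 0.0, upper, status="all_negative",
                           concentration_hat=_conc(0.0, inoculum_volume_ml))
    if np.all(p == w):
        return MpnEstimate(math.inf, math.nan, math.inf, status="all_positive")

    # bracket the root: score is decreasing, -> +inf as lam -> 0+
    lo, hi = 1e-12, 1.0
    while _mpn_score(hi, p, w, d) > 0:
        hi *= 2.0
        if hi > 1e12:  # pragma: no cover - unreachable for valid counts
            raise RuntimeError("MPN root bracketing failed")
    lam = brentq(lambda x: _mpn_score(x, p, w, d), lo, hi, xtol=1e-12, rtol=1e-12)

    e = np.exp(-lam * d)
    q = -np.expm1(-lam * d)
    info = float(np.sum(w * d * d * e / q))
    se = 1.0 / math.sqrt(info) if info > 0 else math.inf
    half = z * se / lam if lam > 0 else math.inf
    ci_low = lam * math.exp(-half)
    ci_high = lam * math.exp(half)
    return MpnEstimate(lam, ci_low, ci_high,
                       concentration_hat=_conc(lam, inoculum_volume_ml))


def _conc(lam: float, volume_ml: Optional[float]) -> Optional[float]:
    if volume_ml is None:
        return None
    if volume_ml <= 0:
        raise ValueError("inoculum volume must be positive")
    return lam / volume_ml


@dataclass
class DilutionSeries:
    """Geometric concentration series for a dose-response plate."""

    top_concentration: float
    n_points: int
    fold: float
    concentrations: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.top_concentration <= 0:
            raise ValueError("top concentration must be positive")
        if self.n_points < 2:
            raise ValueError("need at least 2 points")
        if self.fold <= 1:
            raise ValueError("dilution fold must exceed 1")
        self.concentrations = self.top_concentration / self.fold ** np.arange(
            self.n_points, dtype=float
        )

    @property
    def lowest(self) -> float:
        return float(self.concentrations[-1])

    def labels(self, sig: int = 2) -> list:
        return [format_concentration(c, sig) for c in self.concentrations]


def serial_dilution_series(top: float, n_points: int, fold: float) -> DilutionSeries:
    """Build the geometric series top, top/fold, ..., top/fold^(n_points-1).

    The standard 12-point 4-fold series from 10 nM ends at 2.384 fM (2.4 fM at
    two significant figures).
    """
    return DilutionSeries(top_concentration=top, n_points=n_points, fold=fold)


_UNITS = [
    (1.0, "M"), (1e-3, "mM"), (1e-6, "μM"),
    (1e-9, "nM"), (1e-12, "pM"), (1e-15, "fM"), (1e-18, "aM"),
]


def format_concentration(molar: float, sig: int = 2) -> str:
    """Human-readable molar concentration, default 2 significant figures.

    Concentrations are carried in molar units everywhere; this is
    presentation only (e.g. 2.3842e-15 -> "2.4 fM").
    """
    if molar < 0:
        raise ValueError("concentration must be non-negative")
    if molar == 0:
        return "0 M"
    for scale, unit in _UNITS:
        if molar >= scale:
            break
    mantissa = molar / scale
    rounded = float(f"{mantissa:.{sig}g}")
    text = f"{rounded:g}"
    return f"{text} {unit}"
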