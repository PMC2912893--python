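"""Per-primer standard-curve regression and the slope-to-efficiency transform.

For each primer the model is ``CT = beta0 + beta1 * log2(dilution) + eps``.
With a base-2 log, a unit slope (beta1 = -1) corresponds to perfect
amplification efficiency E = 2 (exact doubling per cycle); in general

    E = 2 ** (-1 / beta1),        beta1 < 0,

which is strictly increasing on beta1 < 0, so a confidence interval
(beta_lower, beta_upper) for the slope maps directly onto a confidence
interval for E — provided beta_upper < 0, i.e. the whole interval stays on
the negative side of the singularity at zero.  The length of this
*transformed* confidence interval is the reliability measure used by the
outlier filter downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_tables import DilutionTable

__all__ = [
    "PrimerFit",
    "EfficiencyEstimate",
    "fit_primer",
    "fit_all",
    "min_valid_points",
    "slope_confidence_interval",
    "efficiency_from_slope",
    "transform_interval",
    "estimate_efficiency",
]

_TINY_P = float(np.finfo(float).tiny)  # p-value clamp for exactly collinear fits


class DegenerateDesignError(ValueError):
    """All regressor values identical — the slope is unidentifiable."""


@dataclass(frozen=True)
class PrimerFit:
    """OLS summary of one primer's dilution curve (CT on log2 dilution)."""

    primer_id: str
    n: int
    beta0: float              # intercept, cycles
    beta1: float              # slope, cycles per log2-dilution unit
    se_beta1: float
    t_stat: float
    p_value: float            # two-sided, t with n-2 df
    r_squared: float
    residuals: np.ndarray     # per valid point, cycles

    @property
    def rss(self) -> float:
        return float(np.sum(self.residuals**2))


@dataclass(frozen=True)
class EfficiencyEstimate:
    """Efficiency point estimate with its transformed confidence interval.

    ``e_lower``/``e_upper``/``ci_length`` are NaN when the slope interval is
    not entirely negative (the transform is then undefined).
    """

    primer_id: str
    efficiency: float
    beta_lower: float
    beta_upper: float
    e_lower: float
    e_upper: float
    ci_length: float
    level: float = 0.95

    @property
    def defined(self) -> bool:
        return not math.isnan(self.ci_length)


def min_valid_points(n_levels: int) -> int:
    """Fewest non-missing points that still allow a fit.

    A primer missing half or more of its dilution points is unusable (at four
    levels: two or more missing), and at least 3 points are always required
    so the slope t-test keeps n-2 >= 1 degree of freedom.
    """
    return max(3, n_levels // 2 + 1)


def fit_primer(table: DilutionTable, primer_id: str) -> PrimerFit | None:
    """OLS fit of one primer's curve, or None when too few points remain.

    Returns None (no fit) when fewer than :func:`min_valid_points` CT values
    are non-missing.  Raises :class:`DegenerateDesignError` if the valid
    points share a single dilution level.
    """
    y = table.row(primer_id)
    mask = ~np.isnan(y)
    n = int(mask.sum())
    if n < min_valid_points(table.n_levels):
        return None
    x = table.log2_dilution[mask]
    y = y[mask]
    if np.ptp(x) == 0:
        raise DegenerateDesignError(
            f"primer {primer_id!r}: all valid points at one dilution level"
        )
    xbar, ybar = x.mean(), y.mean()
    sxx = float(np.sum((x - xbar) ** 2))
    sxy = float(np.sum((x - xbar) * (y - ybar)))
    syy = float(np.sum((y - ybar) ** 2))
    beta1 = sxy / sxx
    beta0 = ybar - beta1 * xbar
    resid = y - (beta0 + beta1 * x)
    rss = float(np.sum(resid**2))
    df = n - 2
    sigma2 = rss / df
    se = math.sqrt(sigma2 / sxx)
    if syy == 0.0:
        # flat, noise-free response: zero slope explains everything
        r2, t, p = 1.0, 0.0, 1.0
    else:
        r2 = 1.0 - rss / syy
        if se == 0.0:
            t = math.inf if beta1 > 0 else -math.inf if beta1 < 0 else 0.0
            p = _TINY_P if beta1 != 0 else 1.0
        else:
            t = beta1 / se
            p = 2.0 * float(stats.t.sf(abs(t), df))
            p = max(p, _TINY_P)
    return PrimerFit(
        primer_id=primer_id,
        n=n,
        beta0=float(beta0),
        beta1=float(beta1),
        se_beta1=float(se),
        t_stat=float(t),
        p_value=float(p),
        r_squared=float(min(max(r2, 0.0), 1.0)),
        residuals=resid,
    )


def fit_all(table: DilutionTable) -> dict[str, PrimerFit | None]:
    """Fit every primer in the table; None marks curves with too few points."""
    return {p: fit_primer(table, p) for p in table.primer_ids}


def slope_confidence_interval(fit: PrimerFit, level: float = 0.95) -> tuple[float, float]:
    """Normality-based CI for the slope: beta1 ± t_{(1-level)/2, n-2} SE."""
    if not 0.0 < level < 1.0:
        raise ValueError(f"confidence level must be in (0, 1), got {level}")
    tq = float(stats.t.ppf(0.5 + level / 2.0, fit.n - 2))
    half = tq * fit.se_beta1
    return fit.beta1 - half, fit.beta1 + half


def efficiency_from_slope(beta1: float) -> float:
    """E = 2**(-1/beta1); strictly increasing on beta1 < 0; E(-1) = 2."""
    if not beta1 < 0:
        raise ValueError(f"slope must be negative to define an efficiency, got {beta1}")
    return 2.0 ** (-1.0 / beta1)


def transform_interval(beta_lower: float, beta_upper: float) -> tuple[float, float] | None:
    """Map a slope CI to an efficiency CI, or None when it crosses zero.

    Requires beta_upper < 0; since the transform is increasing the bound
    order is preserved: (2**(-1/beta_lower), 2**(-1/beta_upper)).
    """
    if beta_lower > beta_upper:
        raise ValueError("beta_lower must not exceed beta_upper")
    if beta_upper >= 0:
        return None
    return efficiency_from_slope(beta_lower), efficiency_from_slope(beta_upper)


def estimate_efficiency(fit: PrimerFit, level: float = 0.95) -> EfficiencyEstimate:
    """Point estimate and transformed CI for one fitted primer.

    The efficiency itself requires beta1 < 0; callers are expected to have
    excluded non-negative slopes (the reliability filter does).  For a
    non-negative slope the estimate and interval are all NaN.
    """
    lo, hi = slope_confidence_interval(fit, level)
    if fit.beta1 < 0:
        e = efficiency_from_slope(fit.beta1)
    else:
        e = math.nan
    interval = transform_interval(lo, hi)
    if interval is None:
        e_lo = e_hi = length = math.nan
    else:
        e_lo, e_hi = interval
        length = e_hi - e_lo
    return EfficiencyEstimate(
        primer_id=fit.primer_id,
        efficiency=e,
        beta_lower=lo,
        beta_upper=hi,
        e_lower=e_lo,
        e_upper=e_hi,
        ci_length=length,
        level=level,
    )
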