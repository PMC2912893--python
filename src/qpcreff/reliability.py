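"""Three-stage purge of unreliable primers.

Stage order (first applicable label wins, mirroring the workflow flow chart):

1. ``REMOVED_MISSING``    — too many undetected dilution points for a fit;
2. ``REMOVED_SLOPE``      — slope not both negative and significant at alpha;
3. ``REMOVED_CI_OUTLIER`` — transformed-CI length above the 1.5 x IQR fence
   (Q3 + multiplier x IQR over the survivors' CI lengths).

Keeping only negative-and-significant slopes at level alpha guarantees the
(1 - alpha) slope interval lies below zero, so every survivor has a defined
transformed CI; if the caller decouples the CI level from alpha, an undefined
interval is treated as infinitely long (always an outlier).
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass

import numpy as np

from .estimation import (
    EfficiencyEstimate,
    PrimerFit,
    estimate_efficiency,
    fit_all,
    min_valid_points,
)
from .io_tables import DilutionTable

__all__ = ["Status", "ReliabilityReport", "purge", "filter_missing", "filter_slope", "filter_ci_outliers"]

MIN_PRIMERS_FOR_FENCE = 4  # quantiles of fewer CI lengths are too unstable


class Status(str, enum.Enum):
    KEPT = "KEPT"
    REMOVED_MISSING = "REMOVED_MISSING"
    REMOVED_SLOPE = "REMOVED_SLOPE"
    REMOVED_CI_OUTLIER = "REMOVED_CI_OUTLIER"


@dataclass(frozen=True)
class ReliabilityReport:
    """Outcome of the purge: one exclusive status per primer plus thresholds."""

    statuses: dict[str, Status]
    alpha: float
    ci_level: float
    iqr_multiplier: float
    ci_upper_fence: float           # NaN when the fence stage was skipped
    fits: dict[str, PrimerFit | None]
    estimates: dict[str, EfficiencyEstimate]

    @property
    def kept(self) -> tuple[str, ...]:
        return tuple(p for p, s in self.statuses.items() if s is Status.KEPT)

    def counts(self) -> dict[str, int]:
        out = {s.value: 0 for s in Status}
        for s in self.statuses.values():
            out[s.value] += 1
        return out


def filter_missing(table: DilutionTable) -> dict[str, Status | None]:
    """Stage 1: None = passes, REMOVED_MISSING = too few valid points."""
    need = min_valid_points(table.n_levels)
    counts = table.valid_counts()
    return {
        p: (Status.REMOVED_MISSING if c < need else None)
        for p, c in zip(table.primer_ids, counts)
    }


def filter_slope(fits: dict[str, PrimerFit], alpha: float = 0.05) -> dict[str, Status | None]:
    """Stage 2: remove primers whose slope is non-negative or insignificant."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    return {
        p: (Status.REMOVED_SLOPE if (f.p_value > alpha or f.beta1 >= 0) else None)
        for p, f in fits.items()
    }


def filter_ci_outliers(
    ci_lengths: dict[str, float], multiplier: float = 1.5
) -> tuple[dict[str, Status | None], float]:
    """Stage 3: flag CI lengths above Q3 + multiplier x IQR.

    Quantiles use linear interpolation between order statistics (numpy's
    default, "type 7").  NaN lengths (undefined transformed intervals) count
    as infinite and are always flagged.  With fewer than 4 survivors the
    fence is not computed: a warning is emitted and nothing is removed.
    """
    if multiplier <= 0:
        raise ValueError(f"iqr multiplier must be positive, got {multiplier}")
    if len(ci_lengths) < MIN_PRIMERS_FOR_FENCE:
        warnings.warn(
            f"only {len(ci_lengths)} primers reach the CI-length filter; "
            "quantiles would be unstable, skipping outlier removal",
            stacklevel=2,
        )
        return {p: None for p in ci_lengths}, math.nan
    vals = np.array([math.inf if math.isnan(v) else v for v in ci_lengths.values()])
    finite = vals[np.isfinite(vals)]
    if finite.size == 0:
        return {p: Status.REMOVED_CI_OUTLIER for p in ci_lengths}, math.nan
    q1, q3 = np.percentile(finite, [25, 75])
    fence = q3 + multiplier * (q3 - q1)
    out = {
        p: (Status.REMOVED_CI_OUTLIER if v > fence else None)
        for (p, _), v in zip(ci_lengths.items(), vals)
    }
    return out, float(fence)


def purge(
    table: DilutionTable,
    alpha: float = 0.05,
    iqr_multiplier: float = 1.5,
    ci_level: float | None = None,
) -> ReliabilityReport:
    """Run all three stages and return one exclusive status per primer.

    ``ci_level`` defaults to ``1 - alpha`` so that surviving the slope test
    guarantees a defined transformed interval.
    """
    if ci_level is None:
        ci_level = 1.0 - alpha
    statuses: dict[str, Status] = {}

    stage1 = filter_missing(table)
    fits = fit_all(table)
    for p, s in stage1.items():
        if s is not None:
            statuses[p] = s

    fitted = {p: f for p, f in fits.items() if p not in statuses and f is not None}
    stage2 = filter_slope(fitted, alpha)
    for p, s in stage2.items():
        if s is not None:
            statuses[p] = s

    survivors = {p: f for p, f in fitted.items() if p not in statuses}
    estimates = {p: estimate_efficiency(f, ci_level) for p, f in survivors.items()}
    lengths = {p: est.ci_length for p, est in estimates.items()}
    stage3, fence = filter_ci_outliers(lengths, iqr_multiplier)
    for p, s in stage3.items():
        if s is not None:
            statuses[p] = s

    for p in table.primer_ids:
        statuses.setdefault(p, Status.KEPT)
    # preserve table order
    ordered = {p: statuses[p] for p in table.primer_ids}
    return ReliabilityReport(
        statuses=ordered,
        alpha=alpha,
        ci_level=ci_level,
        iqr_multiplier=iqr_multiplier,
        ci_upper_fence=fence,
        fits=fits,
        estimates=estimates,
    )
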