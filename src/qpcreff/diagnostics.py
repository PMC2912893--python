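"""Residual-based model checks that justify pooling primers.

Three checks back the clustering step: Bartlett's test for unequal residual
variance across primers (run before and after the purge in the full
workflow), Shapiro-Wilk normality of the pooled residuals, and a nested
F-test for slope heterogeneity (common slope vs per-primer slopes, both with
per-primer intercepts).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy import stats

from .estimation import PrimerFit
from .io_tables import DilutionTable

__all__ = [
    "DiagnosticsSummary",
    "bartlett_residuals",
    "shapiro_residuals",
    "slope_heterogeneity_test",
]


@dataclass(frozen=True)
class DiagnosticsSummary:
    bartlett_stat: float
    bartlett_p: float
    shapiro_stat: float
    shapiro_p: float
    interaction_F: float
    interaction_p: float


def _residual_groups(fits: Mapping[str, PrimerFit]) -> list[np.ndarray]:
    groups = []
    for p, f in fits.items():
        if f is None:
            continue
        if np.var(f.residuals) == 0.0:
            warnings.warn(
                f"primer {p!r} has zero residual variance; excluded from Bartlett",
                stacklevel=3,
            )
            continue
        groups.append(f.residuals)
    return groups


def bartlett_residuals(fits: Mapping[str, PrimerFit]) -> tuple[float, float]:
    """Bartlett's test of equal residual variance across primers.

    Primers with exactly zero residual variance (noise-free synthetic
    curves) are excluded with a warning — their log variance is undefined.
    """
    groups = _residual_groups(fits)
    if len(groups) < 2:
        raise ValueError("Bartlett needs at least 2 primers with residual variance")
    stat, p = stats.bartlett(*groups)
    if math.isnan(p):
        # scipy yields NaN when the statistic degenerates to exactly 0
        p = stats.chi2.sf(max(float(stat), 0.0), len(groups) - 1)
    return float(stat), float(p)


def shapiro_residuals(fits: Mapping[str, PrimerFit]) -> tuple[float, float]:
    """Shapiro-Wilk normality test on the pooled residuals of all fits.

    Returns (NaN, NaN) with a warning when fewer than 3 residuals exist.
    """
    pooled = np.concatenate(
        [f.residuals for f in fits.values() if f is not None] or [np.empty(0)]
    )
    if pooled.size < 3:
        warnings.warn("too few residuals for Shapiro-Wilk; test skipped", stacklevel=2)
        return math.nan, math.nan
    stat, p = stats.shapiro(pooled)
    return float(stat), float(p)


def slope_heterogeneity_test(
    table: DilutionTable, kept: Iterable[str]
) -> tuple[float, float]:
    """Nested F-test: per-primer slopes vs one common slope.

    Both models carry a separate intercept per primer.  With P primers and N
    valid points, F = ((RSS_r - RSS_f)/(P-1)) / (RSS_f/(N - 2P)); a
    significant F says slope differences exceed residual error, i.e. the
    efficiencies genuinely differ.
    """
    from .clustering import group_fit_rss, primer_suffstats  # local: avoid cycle

    kept = list(kept)
    if len(kept) < 2:
        raise ValueError("need at least 2 primers to compare slopes")
    ss = primer_suffstats(table, kept)
    P = len(kept)
    N = int(ss.n.sum())
    df_full = N - 2 * P
    if df_full <= 0:
        raise ValueError(f"insufficient residual df: N={N}, P={P}")
    # restricted model: common slope, per-primer intercepts
    _, rss_r = group_fit_rss(table, kept)
    # full model: per-primer slopes; RSS decomposes into per-primer fit RSS
    rss_f = float(np.sum(ss.syy - ss.sxy**2 / ss.sxx))
    F = ((rss_r - rss_f) / (P - 1)) / (rss_f / df_full)
    F = max(F, 0.0)
    p = float(stats.f.sf(F, P - 1, df_full))
    return float(F), p
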