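"""Efficiency clustering: grouped-slope models selected by nested F-tests.

The grouped model gives every primer its own intercept but only one dilution
slope per *group*; primers in a group therefore share one efficiency.  For a
fixed number of groups k the partition is chosen to minimise the residual
sum of squares (equivalently maximise R^2).  Because groups differ only
through a scalar slope, the optimal partition is contiguous when primers are
sorted by their individual slope estimates, which reduces the search to an
exact dynamic program over segment boundaries:

* segment cost — with x = log2(dilution) centred within each primer, the
  pooled slope of a member set is gamma = sum(Sxy_i)/sum(Sxx_i) and its RSS
  is sum(Syy_i) - (sum Sxy_i)^2 / sum(Sxx_i), so prefix sums of the
  per-primer sufficient statistics give every segment cost in O(1);
* model growth — starting from k = 1, k+1 groups are accepted whenever the
  nested F-test on the optimal partitions shows a significant RSS drop,
  F = (RSS_k - RSS_{k+1}) / (RSS_{k+1} / df),  df = N - (P + k + 1),
  stopping at the first insignificant improvement.

Ties between partitions (noise-free data) are broken toward the most
balanced group sizes, then the lexicographically smallest boundary set.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .estimation import DegenerateDesignError, efficiency_from_slope
from .io_tables import DilutionTable

__all__ = [
    "PrimerSuffStats",
    "ClusterModel",
    "ClusterStep",
    "ClusterTrace",
    "primer_suffstats",
    "group_fit_rss",
    "optimal_partition",
    "select_clusters",
    "cluster_efficiencies",
]

DEFAULT_K_MAX = 15
PERFECT_FIT_EPS_SCALE = 1e-12  # x total CT variance: stop when RSS is numerically zero


@dataclass(frozen=True)
class PrimerSuffStats:
    """Within-primer-centred sufficient statistics, aligned with ``primers``."""

    primers: tuple[str, ...]
    n: np.ndarray      # valid points per primer
    sxx: np.ndarray    # sum (x - xbar_i)^2
    sxy: np.ndarray    # sum (x - xbar_i)(y - ybar_i)
    syy: np.ndarray    # sum (y - ybar_i)^2

    @property
    def slopes(self) -> np.ndarray:
        """Individual OLS slope of each primer."""
        return self.sxy / self.sxx


@dataclass(frozen=True)
class ClusterModel:
    """A partition of primers into slope groups with the grouped-model fit."""

    k: int
    assignment: dict[str, int]          # primer -> group index (slope-ordered)
    group_slopes: tuple[float, ...]     # gamma_g, increasing with group index
    group_efficiencies: tuple[float, ...]
    sizes: tuple[int, ...]
    rss: float
    r_squared: float                    # 1 - RSS / total SS about the grand CT mean

    def members(self, g: int) -> tuple[str, ...]:
        return tuple(p for p, gi in self.assignment.items() if gi == g)


@dataclass(frozen=True)
class ClusterStep:
    """One attempted refinement k -> k+1 in the selection loop."""

    k_from: int
    k_to: int
    rss_from: float
    rss_to: float
    F: float
    p: float
    accepted: bool


ClusterTrace = tuple


def primer_suffstats(table: DilutionTable, primers: Iterable[str]) -> PrimerSuffStats:
    """Per-primer centred sums over the valid points (x = log2 dilution)."""
    primers = tuple(primers)
    x_all = table.log2_dilution
    n = np.empty(len(primers), dtype=int)
    sxx = np.empty(len(primers))
    sxy = np.empty(len(primers))
    syy = np.empty(len(primers))
    for i, p in enumerate(primers):
        y = table.row(p)
        m = ~np.isnan(y)
        x, yv = x_all[m], y[m]
        n[i] = m.sum()
        if n[i] < 2 or np.ptp(x) == 0:
            raise DegenerateDesignError(
                f"primer {p!r} has no dilution spread among its valid points"
            )
        dx = x - x.mean()
        dy = yv - yv.mean()
        sxx[i] = dx @ dx
        sxy[i] = dx @ dy
        syy[i] = dy @ dy
    return PrimerSuffStats(primers, n, sxx, sxy, syy)


def group_fit_rss(table: DilutionTable, members: Iterable[str]) -> tuple[float, float]:
    """Pooled slope and RSS of one group (per-primer intercepts, one slope).

    Closed form from the within-primer-centred sums:
    gamma = sum Sxy_i / sum Sxx_i;  RSS = sum Syy_i - (sum Sxy_i)^2 / sum Sxx_i.
    A single member reduces to that primer's individual fit.
    """
    ss = primer_suffstats(table, members)
    Sxx, Sxy, Syy = ss.sxx.sum(), ss.sxy.sum(), ss.syy.sum()
    gamma = Sxy / Sxx
    rss = max(Syy - Sxy**2 / Sxx, 0.0)
    return float(gamma), float(rss)


def _sorted_stats(table, kept):
    ss = primer_suffstats(table, kept)
    slopes = ss.slopes
    order = np.lexsort((np.array(ss.primers), slopes))
    return ss, order


def _segment_arrays(ss: PrimerSuffStats, order: np.ndarray):
    """Prefix sums over the slope-sorted primers for O(1) segment costs."""
    z = np.zeros(1)
    cxx = np.concatenate([z, np.cumsum(ss.sxx[order])])
    cxy = np.concatenate([z, np.cumsum(ss.sxy[order])])
    cyy = np.concatenate([z, np.cumsum(ss.syy[order])])

    def cost(i: int, j: int) -> float:
        """RSS of the grouped fit over sorted primers i..j-1 (half-open)."""
        sxx = cxx[j] - cxx[i]
        sxy = cxy[j] - cxy[i]
        syy = cyy[j] - cyy[i]
        return max(syy - sxy * sxy / sxx, 0.0)

    def gamma(i: int, j: int) -> float:
        return (cxy[j] - cxy[i]) / (cxx[j] - cxx[i])

    return cost, gamma


def _dp_partition(P: int, k: int, cost, tol: float):
    """Exact DP over contiguous partitions minimising total segment RSS.

    State value per (end, groups): (rss, sum of squared sizes, boundaries);
    rss compared with absolute tolerance ``tol``, ties broken by the more
    balanced partition (smaller sum of squared sizes) then the smaller
    boundary tuple.  Returns the boundary tuple (g+1 cut points incl. 0, P).
    """

    def better(a, b):
        if a is None:
            return False
        if b is None:
            return True
        if a[0] < b[0] - tol:
            return True
        if a[0] > b[0] + tol:
            return False
        return (a[1], a[2]) < (b[1], b[2])

    # best[g][j]: optimal split of sorted primers [0, j) into g groups
    best = [[None] * (P + 1) for _ in range(k + 1)]
    best[0][0] = (0.0, 0, ())
    for g in range(1, k + 1):
        for j in range(g, P + 1):
            cur = None
            for i in range(g - 1, j):
                prev = best[g - 1][i]
                if prev is None:
                    continue
                size = j - i
                cand = (prev[0] + cost(i, j), prev[1] + size * size, prev[2] + (i,))
                if better(cand, cur):
                    cur = cand
            best[g][j] = cur
    rss, _, cuts = best[k][P]
    return rss, cuts + (P,)


def optimal_partition(table: DilutionTable, kept: Iterable[str], k: int) -> ClusterModel:
    """RSS-minimising partition of the kept primers into k slope groups.

    The search is exact over partitions contiguous in the order of the
    individual slope estimates (slope ties broken by primer id); the result
    is invariant to the input order of ``kept``.
    """
    kept = list(kept)
    P = len(kept)
    if not 1 <= k <= P:
        raise ValueError(f"k must be in [1, {P}], got {k}")
    ss, order = _sorted_stats(table, kept)
    cost, gamma = _segment_arrays(ss, order)
    tol = 1e-9 * (1.0 + float(ss.syy.sum()))
    rss, bounds = _dp_partition(P, k, cost, tol)
    sorted_primers = [ss.primers[i] for i in order]
    assignment: dict[str, int] = {}
    slopes, sizes = [], []
    for g in range(k):
        i, j = bounds[g], bounds[g + 1]
        for p in sorted_primers[i:j]:
            assignment[p] = g
        slopes.append(gamma(i, j))
        sizes.append(j - i)
    effs = tuple(
        efficiency_from_slope(s) if s < 0 else math.nan for s in slopes
    )
    # R^2 against the grand-mean total SS over all valid CT of the kept set
    ys = np.concatenate([table.row(p)[~np.isnan(table.row(p))] for p in kept])
    tss = float(np.sum((ys - ys.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    return ClusterModel(
        k=k,
        assignment={p: assignment[p] for p in sorted_primers},
        group_slopes=tuple(float(s) for s in slopes),
        group_efficiencies=effs,
        sizes=tuple(sizes),
        rss=float(rss),
        r_squared=float(r2),
    )


def select_clusters(
    table: DilutionTable,
    kept: Iterable[str],
    alpha: float = 0.05,
    k_max: int = DEFAULT_K_MAX,
) -> tuple[ClusterModel, tuple[ClusterStep, ...]]:
    """Grow the number of slope groups until the F-test stops improving.

    Starting from one group, the optimal k- and (k+1)-group partitions are
    compared by F = (RSS_k - RSS_{k+1}) / (RSS_{k+1}/df) with
    df = N - (P + k + 1); the first insignificant step (p >= alpha) stops the
    loop and the k-group model is returned along with the step trace.

    Termination guards: a hard cap ``k_max``, a stop when the residual df
    would be exhausted, and a perfect-fit stop when RSS falls below
    1e-12 x the total CT variation (noise-free data).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    kept = list(kept)
    P = len(kept)
    if P < 2:
        raise ValueError("need at least 2 kept primers to cluster")
    ss = primer_suffstats(table, kept)
    N = int(ss.n.sum())
    ys = np.concatenate([table.row(p)[~np.isnan(table.row(p))] for p in kept])
    eps = PERFECT_FIT_EPS_SCALE * max(float(np.sum((ys - ys.mean()) ** 2)), 1.0)

    current = optimal_partition(table, kept, 1)
    trace: list[ClusterStep] = []
    k_cap = min(k_max, P)
    while current.k < k_cap:
        if current.rss < eps:
            break
        k1 = current.k + 1
        df = N - (P + k1)
        if df <= 0:
            warnings.warn(
                f"no residual df left at k={k1}; stopping at k={current.k}",
                stacklevel=2,
            )
            break
        nxt = optimal_partition(table, kept, k1)
        if nxt.rss < eps:
            # numerically perfect fit: accept and stop, the F-test is 0/0
            trace.append(
                ClusterStep(current.k, k1, current.rss, nxt.rss, math.inf, 0.0, True)
            )
            current = nxt
            break
        F = (current.rss - nxt.rss) / (nxt.rss / df)
        F = max(F, 0.0)
        p = float(stats.f.sf(F, 1, df))
        accepted = p < alpha
        trace.append(ClusterStep(current.k, k1, current.rss, nxt.rss, float(F), p, accepted))
        if not accepted:
            break
        current = nxt
    return current, tuple(trace)


def cluster_efficiencies(model: ClusterModel) -> dict[str, float]:
    """Map each primer to its group efficiency E_g = 2**(-1/gamma_g)."""
    return {p: model.group_efficiencies[g] for p, g in model.assignment.items()}
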