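"""Efficiency-adjusted CT values, expression ratios, and the AFC/CoV metric.

The adjusted threshold cycle CT* = CT x log2(E) is the cycle count the
reaction would have needed at perfect efficiency (E = 2): E**CT = 2**CT*.
Adjusted values drop into any downstream log2-scale expression analysis
unchanged.  The fold difference 2**CT / E**CT = 2**(CT - CT*) quantifies how
far the perfect-efficiency assumption misstates the fold quantity.

The adjusted fold change AFC = E**CT x d (estimated fold change rescaled by
the relative concentration d) is constant across a dilution series exactly
when E is the true efficiency, so the coefficient of variation of the AFC
values across dilutions scores the accuracy of an assumed efficiency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clustering import ClusterModel, cluster_efficiencies
from .io_tables import DilutionTable

__all__ = [
    "AdjustedResult",
    "AFCProfile",
    "adjust_ct",
    "expression_ratio",
    "afc_profile",
    "compare_schemes",
    "SCHEMES",
]

SCHEMES = ("perfect", "global", "cluster", "individual")


@dataclass(frozen=True)
class AdjustedResult:
    primer_id: str
    efficiency_used: float
    ct: float
    ct_star: float
    fold_difference: float


@dataclass(frozen=True)
class AFCProfile:
    primer_id: str
    dilutions: np.ndarray
    afc_per_dilution: np.ndarray
    cov: float


def adjust_ct(ct: float, efficiency: float, primer_id: str = "") -> AdjustedResult:
    """CT* = CT x log2(E) and the fold difference 2**(CT - CT*).

    E = 2 leaves CT unchanged (fold 1); E < 2 shrinks it (the reaction
    needed extra cycles to compensate sub-perfect amplification).
    """
    if not efficiency > 1.0:
        raise ValueError(f"efficiency must exceed 1, got {efficiency}")
    if not ct > 0:
        raise ValueError(f"CT must be positive, got {ct}")
    ct_star = ct * math.log2(efficiency)
    fold = 2.0 ** (ct - ct_star)
    return AdjustedResult(primer_id, efficiency, float(ct), float(ct_star), float(fold))


def expression_ratio(ct_a: float, e_a: float, ct_b: float, e_b: float) -> float:
    """Initial target amount of reaction A relative to reaction B.

    ratio = E_b**CT_b / E_a**CT_a (a higher CT means less starting template);
    with a shared efficiency E this is E**(CT_b - CT_a), and in general it
    equals 2**(CT*_b - CT*_a).  Computed in log space to avoid overflow.
    """
    a = adjust_ct(ct_a, e_a)
    b = adjust_ct(ct_b, e_b)
    return 2.0 ** (b.ct_star - a.ct_star)


def afc_profile(table: DilutionTable, primer_id: str, efficiency: float) -> AFCProfile:
    """Adjusted fold changes across a primer's dilution series and their CoV.

    AFC at relative concentration d is E**CT x d; the coefficient of
    variation uses the sample (n-1) standard deviation over the valid
    dilutions.  Requires at least two valid points.
    """
    if not efficiency > 1.0:
        raise ValueError(f"efficiency must exceed 1, got {efficiency}")
    y = table.row(primer_id)
    mask = ~np.isnan(y)
    if mask.sum() < 2:
        raise ValueError(f"primer {primer_id!r} has fewer than 2 valid points")
    d = table.dilution_levels[mask]
    ct = y[mask]
    # log-space for numerical safety, then exponentiate
    log2_afc = ct * math.log2(efficiency) + np.log2(d)
    afc = 2.0**log2_afc
    cov = float(np.std(afc, ddof=1) / np.mean(afc))
    return AFCProfile(primer_id, d, afc, cov)


def compare_schemes(
    table: DilutionTable,
    kept,
    cluster_model: ClusterModel,
    individual_e: dict[str, float],
) -> pd.DataFrame:
    """Per-primer AFC coefficient of variation under four efficiency schemes.

    Schemes: ``perfect`` (E = 2 for all), ``global`` (one array-wide mean of
    the individual efficiencies), ``cluster`` (the group efficiency), and
    ``individual``.  Returns a DataFrame indexed by primer with one CoV
    column per scheme; rows are sorted by primer id, so the result is
    invariant to the input order.  Descending-sorted CoV curves (the usual
    comparison plot) are ``np.sort(df[col])[::-1]``.
    """
    kept = sorted(kept)
    cluster_e = cluster_efficiencies(cluster_model)
    global_e = float(np.mean([individual_e[p] for p in kept]))
    scheme_e = {
        "perfect": {p: 2.0 for p in kept},
        "global": {p: global_e for p in kept},
        "cluster": cluster_e,
        "individual": individual_e,
    }
    data = {
        name: [afc_profile(table, p, emap[p]).cov for p in kept]
        for name, emap in scheme_e.items()
    }
    return pd.DataFrame(data, index=pd.Index(kept, name="primer"))
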