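"""Synthetic serial-dilution tables with known ground truth.

The generator emulates a 96-primer low-density qPCR array measured at four
ten-fold dilutions: each clean primer follows CT = beta0 + beta1 log2(d) +
Gaussian noise with beta1 = -1/log2(E_true) (from d x E**CT = threshold),
true efficiencies planted in a small number of groups, and three defect
classes mirroring what the reliability purge is built to catch —
all-censored curves, flat (zero-slope) curves, and high-noise curves whose
transformed confidence intervals blow up.

When defects are planted the generator *guarantees* that the default purge
(alpha 0.05, 1.5 x IQR) recovers the planted sets exactly: after sampling it
runs the purge and re-draws the noise of any primer whose status disagrees
with its planted role, iterating to a fixed point.  Without this step a
truly flat primer would slip past the slope test with probability alpha, and
a clean primer occasionally trips the IQR fence, so exact recovery could not
be promised.  Everything is driven by a single seed; the same seed always
yields the same table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_tables import DilutionTable

__all__ = ["SimulationSpec", "simulate_table", "default_array_spec"]

NOISE_INFLATION = 10.0      # residual-sd multiplier for planted high-noise primers
MAX_SEPARATION_ITER = 200

#: default efficiency groups: seven clusters spanning the realistic qPCR
#: range 1.72-2.14 (perfect doubling is E = 2)
DEFAULT_GROUP_EFFICIENCIES = tuple(np.round(np.linspace(1.72, 2.14, 7), 4))


@dataclass(frozen=True)
class SimulationSpec:
    """Study conditions for one synthetic array."""

    n_primers: int = 96
    dilution_levels: tuple[float, ...] = (1.0, 0.1, 0.01, 0.001)
    true_efficiencies: tuple[float, ...] = DEFAULT_GROUP_EFFICIENCIES
    intercept_range: tuple[float, float] = (18.0, 24.0)
    residual_sd: float = 0.08
    n_missing_primers: int = 3
    n_flat_primers: int = 8
    n_noisy_primers: int = 7
    ct_cutoff: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_primers < 1:
            raise ValueError("n_primers must be positive")
        if any(e <= 1.0 for e in self.true_efficiencies):
            raise ValueError("true efficiencies must exceed 1")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be non-negative")
        n_def = self.n_missing_primers + self.n_flat_primers + self.n_noisy_primers
        if min(self.n_missing_primers, self.n_flat_primers, self.n_noisy_primers) < 0:
            raise ValueError("defect counts must be non-negative")
        if n_def > self.n_primers:
            raise ValueError("defect counts exceed n_primers")
        if not self.intercept_range[0] <= self.intercept_range[1]:
            raise ValueError("intercept_range must be a non-decreasing pair")

    @property
    def n_clean(self) -> int:
        return self.n_primers - (
            self.n_missing_primers + self.n_flat_primers + self.n_noisy_primers
        )


def default_array_spec(seed: int = 0, **overrides) -> SimulationSpec:
    """The default 96-primer array: 7 efficiency groups, defects 3/8/7."""
    return replace(SimulationSpec(seed=seed), **overrides)


def _slope(e: float) -> float:
    return -1.0 / math.log2(e)


def _draw_row(rng, role, beta0, beta1, x, sd, cutoff):
    if role == "missing":
        return rng.uniform(cutoff + 1.0, cutoff + 5.0, size=x.size)
    if role == "flat":
        return beta0 + rng.normal(0.0, sd, size=x.size)
    scale = sd * NOISE_INFLATION if role == "noisy" else sd
    return beta0 + beta1 * x + rng.normal(0.0, scale, size=x.size)


def simulate_table(
    spec: SimulationSpec, ensure_separation: bool | None = None
) -> tuple[DilutionTable, pd.DataFrame]:
    """Generate one table plus its ground-truth record.

    Returns ``(table, truth)`` where ``truth`` has one row per primer with
    columns (primer, role, group, true_efficiency, beta0, beta1,
    residual_sd); role is one of clean/missing/flat/noisy, group is the
    planted efficiency-group index (-1 for defect primers).

    ``ensure_separation`` (default: on whenever defects are planted and the
    noise is non-zero) re-draws defect/clean primers until the default purge
    labels every primer by its planted role — see the module docstring.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_primers
    if ensure_separation is None:
        has_defects = n - spec.n_clean > 0
        ensure_separation = has_defects and spec.residual_sd > 0

    width = max(3, len(str(n)))
    primers = tuple(f"P{i + 1:0{width}d}" for i in range(n))
    levels = np.asarray(spec.dilution_levels, dtype=float)
    x = np.log2(levels)

    order = rng.permutation(n)
    roles = np.array(["clean"] * n, dtype=object)
    roles[order[: spec.n_missing_primers]] = "missing"
    roles[order[spec.n_missing_primers : spec.n_missing_primers + spec.n_flat_primers]] = "flat"
    roles[
        order[
            spec.n_missing_primers + spec.n_flat_primers : spec.n_missing_primers
            + spec.n_flat_primers
            + spec.n_noisy_primers
        ]
    ] = "noisy"

    effs = np.asarray(spec.true_efficiencies, dtype=float)
    groups = np.full(n, -1, dtype=int)
    clean_idx = np.flatnonzero(roles == "clean")
    groups[clean_idx] = np.arange(clean_idx.size) % effs.size

    true_e = np.full(n, np.nan)
    beta1 = np.full(n, np.nan)
    true_e[clean_idx] = effs[groups[clean_idx]]
    noisy_idx = np.flatnonzero(roles == "noisy")
    true_e[noisy_idx] = rng.choice(effs, size=noisy_idx.size)
    for i in np.flatnonzero(~np.isnan(true_e)):
        beta1[i] = _slope(true_e[i])
    beta1[roles == "flat"] = 0.0

    lo, hi = spec.intercept_range
    beta0 = rng.uniform(lo, hi, size=n)
    sd_per = np.where(roles == "noisy", spec.residual_sd * NOISE_INFLATION, spec.residual_sd)

    grid = np.empty((n, levels.size))
    for i in range(n):
        grid[i] = _draw_row(rng, roles[i], beta0[i], beta1[i], x, spec.residual_sd, spec.ct_cutoff)

    def build(g):
        return DilutionTable(primers, levels, g.copy()).censor(spec.ct_cutoff)

    table = build(grid)

    if ensure_separation:
        from .reliability import Status, purge  # deferred: avoid import cycle

        expected = {
            "clean": Status.KEPT,
            "missing": Status.REMOVED_MISSING,
            "flat": Status.REMOVED_SLOPE,
            "noisy": Status.REMOVED_CI_OUTLIER,
        }
        for _ in range(MAX_SEPARATION_ITER):
            report = purge(table)
            bad = [
                i
                for i, p in enumerate(primers)
                if report.statuses[p] is not expected[roles[i]]
            ]
            if not bad:
                break
            for i in bad:
                grid[i] = _draw_row(
                    rng, roles[i], beta0[i], beta1[i], x, spec.residual_sd, spec.ct_cutoff
                )
            table = build(grid)
        else:
            raise RuntimeError(
                "could not separate planted defects from clean primers; "
                "the spec's noise/defect configuration is too extreme"
            )

    truth = pd.DataFrame(
        {
            "primer": primers,
            "role": roles,
            "group": groups,
            "true_efficiency": true_e,
            "beta0": beta0,
            "beta1": beta1,
            "residual_sd": sd_per,
        }
    )
    return table, truth
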