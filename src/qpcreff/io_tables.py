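"""Serial-dilution CT tables: the container and its CSV/TSV readers and writers.

A dilution table is the sole experimental input of the workflow: one row per
primer pair, one column per relative initial concentration (dilution level),
and threshold-cycle (CT) values in the cells.  CT values above the detection
cutoff (40 cycles by default) mean "no detectable product" and are treated as
missing; missing cells are represented as NaN throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["DilutionTable", "read_dilution_table", "write_report", "DEFAULT_CT_CUTOFF"]

DEFAULT_CT_CUTOFF = 40.0

#: canonical long-layout column names
LONG_COLUMNS = ("primer", "dilution", "ct")


class FormatError(ValueError):
    """Malformed dilution-table file (duplicates, bad dilution values...)."""


@dataclass(frozen=True)
class DilutionTable:
    """Primer x dilution grid of CT values with missing cells marked as NaN.

    Parameters
    ----------
    primer_ids
        Unique, non-empty primer labels; order is preserved.
    dilution_levels
        Relative initial concentrations in (0, 1], strictly decreasing
        (undiluted = 1).  At least two levels are required.
    ct
        Array of shape ``(n_primers, n_levels)``; each cell is a finite
        positive CT in cycles or NaN for missing/undetected.
    """

    primer_ids: tuple[str, ...]
    dilution_levels: np.ndarray
    ct: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        pids = tuple(str(p) for p in self.primer_ids)
        object.__setattr__(self, "primer_ids", pids)
        if len(set(pids)) != len(pids):
            raise FormatError("primer ids must be unique")
        if any(p == "" for p in pids):
            raise FormatError("primer ids must be non-empty")
        levels = np.asarray(self.dilution_levels, dtype=float)
        if levels.ndim != 1 or levels.size < 2:
            raise ValueError("need at least 2 dilution levels")
        if not np.all(np.isfinite(levels)):
            raise FormatError("dilution levels must be numeric and finite")
        if np.any(levels <= 0) or np.any(levels > 1):
            raise ValueError("dilution levels must lie in (0, 1]")
        if np.any(np.diff(levels) >= 0):
            raise ValueError("dilution levels must be strictly decreasing")
        ct = np.asarray(self.ct, dtype=float)
        if ct.shape != (len(pids), levels.size):
            raise ValueError(
                f"ct grid shape {ct.shape} does not match "
                f"({len(pids)} primers, {levels.size} levels)"
            )
        valid = ~np.isnan(ct)
        if np.any(~np.isfinite(ct[valid])) or np.any(ct[valid] <= 0):
            raise ValueError("non-missing CT values must be finite and > 0")
        object.__setattr__(self, "dilution_levels", levels)
        object.__setattr__(self, "ct", ct)
        object.__setattr__(self, "_index", {p: i for i, p in enumerate(pids)})

    # -- accessors ---------------------------------------------------------

    @property
    def n_primers(self) -> int:
        return len(self.primer_ids)

    @property
    def n_levels(self) -> int:
        return self.dilution_levels.size

    @property
    def log2_dilution(self) -> np.ndarray:
        """log2 of the dilution levels — the regressor of the standard curve."""
        return np.log2(self.dilution_levels)

    def row(self, primer_id: str) -> np.ndarray:
        """CT values of one primer across dilutions (NaN = missing)."""
        try:
            return self.ct[self._index[primer_id]]
        except KeyError:
            raise KeyError(f"unknown primer {primer_id!r}") from None

    def n_valid(self, primer_id: str) -> int:
        return int(np.sum(~np.isnan(self.row(primer_id))))

    def valid_counts(self) -> np.ndarray:
        return np.sum(~np.isnan(self.ct), axis=1).astype(int)

    def censor(self, ct_cutoff: float = DEFAULT_CT_CUTOFF) -> "DilutionTable":
        """Return a copy with every CT strictly above ``ct_cutoff`` set missing.

        Idempotent: censoring an already-censored table is a no-op.
        """
        ct = self.ct.copy()
        with np.errstate(invalid="ignore"):
            ct[ct > ct_cutoff] = np.nan
        return DilutionTable(self.primer_ids, self.dilution_levels, ct)

    def subset(self, primer_ids) -> "DilutionTable":
        idx = [self._index[p] for p in primer_ids]
        return DilutionTable(tuple(primer_ids), self.dilution_levels, self.ct[idx])

    def to_long_frame(self) -> pd.DataFrame:
        """Long-layout DataFrame with columns (primer, dilution, ct)."""
        recs = []
        for i, p in enumerate(self.primer_ids):
            for j, d in enumerate(self.dilution_levels):
                recs.append((p, d, self.ct[i, j]))
        return pd.DataFrame(recs, columns=list(LONG_COLUMNS))

    def to_wide_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.ct, columns=[repr(float(d)) for d in self.dilution_levels])
        df.insert(0, "primer", list(self.primer_ids))
        return df


def _sniff_sep(path: str) -> str:
    return "\t" if str(path).lower().endswith((".tsv", ".tab", ".txt")) else ","


def _from_long_frame(df: pd.DataFrame) -> DilutionTable:
    cols = {c.strip().lower(): c for c in df.columns}
    missing = [c for c in LONG_COLUMNS if c not in cols]
    if missing:
        raise FormatError(f"long layout requires columns {LONG_COLUMNS}, missing {missing}")
    sub = df[[cols["primer"], cols["dilution"], cols["ct"]]].copy()
    sub.columns = list(LONG_COLUMNS)
    try:
        sub["dilution"] = sub["dilution"].astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"non-numeric dilution value: {exc}") from None
    sub["ct"] = pd.to_numeric(sub["ct"], errors="coerce")
    if sub.duplicated(["primer", "dilution"]).any():
        dup = sub[sub.duplicated(["primer", "dilution"])].iloc[0]
        raise FormatError(f"duplicate cell for primer {dup['primer']!r} at dilution {dup['dilution']}")
    levels = np.sort(sub["dilution"].unique())[::-1]
    primers = tuple(pd.unique(sub["primer"].astype(str)))
    grid = np.full((len(primers), levels.size), np.nan)
    pidx = {p: i for i, p in enumerate(primers)}
    lidx = {d: j for j, d in enumerate(levels)}
    for p, d, ct in sub.itertuples(index=False):
        grid[pidx[str(p)], lidx[float(d)]] = ct
    return DilutionTable(primers, levels, grid)


def _from_wide_frame(df: pd.DataFrame) -> DilutionTable:
    if df.shape[1] < 3:
        raise ValueError("wide layout needs a primer column plus at least 2 dilution columns")
    primers = tuple(df.iloc[:, 0].astype(str))
    if len(set(primers)) != len(primers):
        raise FormatError("duplicate primer rows in wide table")
    try:
        levels = np.array([float(c) for c in df.columns[1:]])
    except ValueError:
        raise FormatError(
            "wide layout column headers (after the first) must be numeric dilution levels"
        ) from None
    if len(set(levels.tolist())) != levels.size:
        raise FormatError("duplicate dilution-level columns in wide table")
    grid = df.iloc[:, 1:].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    order = np.argsort(levels)[::-1]
    return DilutionTable(primers, levels[order], grid[:, order])


def read_dilution_table(
    path,
    layout: str = "long",
    ct_cutoff: float = DEFAULT_CT_CUTOFF,
) -> DilutionTable:
    """Read a dilution CT table from CSV/TSV and apply the detection cutoff.

    Parameters
    ----------
    path
        CSV (``.csv``) or TSV (``.tsv``/``.tab``/``.txt``) file.
    layout
        ``"long"`` — columns (primer, dilution, ct), any row order;
        ``"wide"`` — first column primer id, remaining column headers are the
        numeric dilution levels.
    ct_cutoff
        CT values strictly above this are undetectable and set missing
        (default 40 cycles).  Cells already empty/NA stay missing.
    """
    if layout not in ("long", "wide"):
        raise ValueError(f"layout must be 'long' or 'wide', got {layout!r}")
    # round_trip parsing so written tables reload bit-identically
    df = pd.read_csv(path, sep=_sniff_sep(path), float_precision="round_trip")
    table = _from_long_frame(df) if layout == "long" else _from_wide_frame(df)
    return table.censor(ct_cutoff)


def write_report(report: pd.DataFrame, path) -> None:
    """Write any result table as CSV with missing values as empty fields.

    Floats are written at full ``repr`` precision so a round-trip read with
    ``pandas.read_csv(..., float_precision="round_trip")`` reproduces them
    exactly; an empty report yields a header-only file.
    """
    report.to_csv(path, index=False, na_rep="")
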