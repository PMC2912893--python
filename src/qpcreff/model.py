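"""Model/Results front end tying the whole workflow together.

``PrimerEfficiencyModel`` wraps a dilution table; ``fit()`` runs the full
pipeline — per-primer regression, transformed confidence intervals, the
three-stage reliability purge, pooling diagnostics, efficiency clustering,
and CT adjustment — and returns a ``PrimerEfficiencyResults`` carrying every
intermediate product plus report writers and a text summary.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import adjustment, clustering, diagnostics
from .io_tables import DEFAULT_CT_CUTOFF, DilutionTable, read_dilution_table, write_report
from .reliability import ReliabilityReport, Status, purge

__all__ = ["PrimerEfficiencyModel", "PrimerEfficiencyResults"]

SUMMARY_SCHEMA_VERSION = 1


class PrimerEfficiencyModel:
    """Primer-efficiency analysis of a serial-dilution CT table.

    Parameters
    ----------
    table
        A :class:`~qpcreff.io_tables.DilutionTable` (already censored).

    Examples
    --------
    >>> model = PrimerEfficiencyModel.from_csv("dilutions.csv", layout="long")
    >>> res = model.fit()
    >>> print(res.summary())
    """

    def __init__(self, table: DilutionTable):
        self.table = table

    @classmethod
    def from_csv(cls, path, layout: str = "long", ct_cutoff: float = DEFAULT_CT_CUTOFF):
        return cls(read_dilution_table(path, layout=layout, ct_cutoff=ct_cutoff))

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, layout: str = "long", ct_cutoff: float = DEFAULT_CT_CUTOFF
    ):
        from .io_tables import _from_long_frame, _from_wide_frame

        table = _from_long_frame(df) if layout == "long" else _from_wide_frame(df)
        return cls(table.censor(ct_cutoff))

    def fit(
        self,
        alpha: float = 0.05,
        iqr_multiplier: float = 1.5,
        cluster_alpha: float = 0.05,
        k_max: int = clustering.DEFAULT_K_MAX,
        ci_level: float | None = None,
    ) -> "PrimerEfficiencyResults":
        """Run the full workflow and return the results object.

        ``ci_level`` defaults to ``1 - alpha`` so every primer surviving the
        slope test has a defined transformed confidence interval.
        """
        table = self.table
        report = purge(table, alpha=alpha, iqr_multiplier=iqr_multiplier, ci_level=ci_level)
        kept = list(report.kept)
        if not kept:
            raise RuntimeError("no primers survive the reliability purge")

        fitted = {p: f for p, f in report.fits.items() if f is not None}
        kept_fits = {p: fitted[p] for p in kept}

        diag: dict[str, tuple[float, float]] = {}
        if len(fitted) >= 2:
            diag["bartlett_pre"] = diagnostics.bartlett_residuals(fitted)
        if len(kept_fits) >= 2:
            diag["bartlett_post"] = diagnostics.bartlett_residuals(kept_fits)
            diag["shapiro"] = diagnostics.shapiro_residuals(kept_fits)
            diag["interaction"] = diagnostics.slope_heterogeneity_test(table, kept)

        if len(kept) >= 2:
            cluster_model, trace = clustering.select_clusters(
                table, kept, alpha=cluster_alpha, k_max=k_max
            )
        else:
            cluster_model = clustering.optimal_partition(table, kept, 1)
            trace = ()

        return PrimerEfficiencyResults(
            model=self,
            reliability=report,
            diagnostics=diag,
            cluster_model=cluster_model,
            trace=trace,
            params={
                "alpha": alpha,
                "ci_level": report.ci_level,
                "iqr_multiplier": iqr_multiplier,
                "cluster_alpha": cluster_alpha,
                "k_max": k_max,
            },
        )


@dataclass
class PrimerEfficiencyResults:
    """Everything the fitted workflow produced, with report writers."""

    model: PrimerEfficiencyModel
    reliability: ReliabilityReport
    diagnostics: dict[str, tuple[float, float]]
    cluster_model: clustering.ClusterModel
    trace: tuple
    params: dict

    # -- derived maps ------------------------------------------------------

    @property
    def table(self) -> DilutionTable:
        return self.model.table

    @property
    def kept(self) -> tuple[str, ...]:
        return self.reliability.kept

    @property
    def individual_efficiencies(self) -> dict[str, float]:
        return {p: self.reliability.estimates[p].efficiency for p in self.kept}

    @property
    def cluster_efficiencies(self) -> dict[str, float]:
        return clustering.cluster_efficiencies(self.cluster_model)

    def efficiencies(self, scheme: str = "cluster") -> dict[str, float]:
        """Per-kept-primer efficiency under one of the four schemes."""
        if scheme == "perfect":
            return {p: 2.0 for p in self.kept}
        if scheme == "global":
            e = float(np.mean(list(self.individual_efficiencies.values())))
            return {p: e for p in self.kept}
        if scheme == "cluster":
            return self.cluster_efficiencies
        if scheme == "individual":
            return self.individual_efficiencies
        raise ValueError(f"unknown scheme {scheme!r}; choose from {adjustment.SCHEMES}")

    # -- report frames -----------------------------------------------------

    @property
    def efficiency_frame(self) -> pd.DataFrame:
        """EfficiencyReport: one row per fitted primer."""
        rows = []
        for p in self.table.primer_ids:
            f = self.reliability.fits.get(p)
            if f is None:
                continue
            est = self.reliability.estimates.get(p)
            rows.append(
                {
                    "primer": p,
                    "n": f.n,
                    "beta1": f.beta1,
                    "se": f.se_beta1,
                    "t": f.t_stat,
                    "p": f.p_value,
                    "r_squared": f.r_squared,
                    "E": est.efficiency if est else math.nan,
                    "e_lower": est.e_lower if est else math.nan,
                    "e_upper": est.e_upper if est else math.nan,
                    "ci_length": est.ci_length if est else math.nan,
                }
            )
        return pd.DataFrame(
            rows,
            columns=["primer", "n", "beta1", "se", "t", "p", "r_squared", "E",
                     "e_lower", "e_upper", "ci_length"],
        )

    @property
    def purge_frame(self) -> pd.DataFrame:
        """PurgeReport: status and the thresholds behind each decision."""
        rows = []
        for p in self.table.primer_ids:
            f = self.reliability.fits.get(p)
            est = self.reliability.estimates.get(p)
            rows.append(
                {
                    "primer": p,
                    "status": self.reliability.statuses[p].value,
                    "p_value": f.p_value if f else math.nan,
                    "ci_length": est.ci_length if est else math.nan,
                    "ci_upper_fence": self.reliability.ci_upper_fence,
                }
            )
        return pd.DataFrame(rows, columns=["primer", "status", "p_value", "ci_length", "ci_upper_fence"])

    @property
    def cluster_frame(self) -> pd.DataFrame:
        """ClusterReport: group membership and group efficiency per primer."""
        cm = self.cluster_model
        rows = [
            {
                "primer": p,
                "group": g,
                "group_slope": cm.group_slopes[g],
                "group_E": cm.group_efficiencies[g],
            }
            for p, g in cm.assignment.items()
        ]
        return pd.DataFrame(rows, columns=["primer", "group", "group_slope", "group_E"])

    @property
    def trace_frame(self) -> pd.DataFrame:
        """TraceReport: the k -> k+1 selection steps."""
        rows = [
            {
                "k": s.k_from,
                "k_next": s.k_to,
                "rss": s.rss_from,
                "rss_next": s.rss_to,
                "F": s.F,
                "p": s.p,
                "accepted": s.accepted,
            }
            for s in self.trace
        ]
        return pd.DataFrame(rows, columns=["k", "k_next", "rss", "rss_next", "F", "p", "accepted"])

    def adjusted_frame(self, scheme: str = "cluster") -> pd.DataFrame:
        """AdjustedReport: CT* and fold difference for every valid cell."""
        emap = self.efficiencies(scheme)
        rows = []
        for p in self.kept:
            y = self.table.row(p)
            for d, ct in zip(self.table.dilution_levels, y):
                if np.isnan(ct):
                    continue
                r = adjustment.adjust_ct(float(ct), emap[p], p)
                rows.append(
                    {
                        "primer": p,
                        "dilution": d,
                        "scheme": scheme,
                        "E": r.efficiency_used,
                        "ct": r.ct,
                        "ct_star": r.ct_star,
                        "fold_difference": r.fold_difference,
                    }
                )
        return pd.DataFrame(
            rows, columns=["primer", "dilution", "scheme", "E", "ct", "ct_star", "fold_difference"]
        )

    def cov_frame(self) -> pd.DataFrame:
        """CoVReport: per-primer AFC coefficient of variation per scheme."""
        df = adjustment.compare_schemes(
            self.table, self.kept, self.cluster_model, self.individual_efficiencies
        )
        return df.reset_index().melt(
            id_vars="primer", var_name="scheme", value_name="cov"
        )[["primer", "scheme", "cov"]]

    # -- summaries ---------------------------------------------------------

    def summary_dict(self) -> dict:
        counts = self.reliability.counts()
        d = {
            "schema_version": SUMMARY_SCHEMA_VERSION,
            "n_primers": self.table.n_primers,
            "n_levels": self.table.n_levels,
            "counts": counts,
            "n_kept": counts["KEPT"],
            "ci_upper_fence": _none_if_nan(self.reliability.ci_upper_fence),
            "k_selected": self.cluster_model.k,
            "group_efficiencies": list(self.cluster_model.group_efficiencies),
            "group_sizes": list(self.cluster_model.sizes),
            "mean_E_kept": float(np.mean(list(self.individual_efficiencies.values()))),
            "diagnostics": {
                name: {"stat": _none_if_nan(s), "p": _none_if_nan(p)}
                for name, (s, p) in self.diagnostics.items()
            },
            "params": self.params,
        }
        return d

    def summary(self) -> str:
        """Human-readable run summary."""
        s = self.summary_dict()
        c = s["counts"]
        lines = [
            "Primer Efficiency Analysis",
            "==========================",
            f"primers: {s['n_primers']}  dilution levels: {s['n_levels']}",
            f"removed (missing values):     {c['REMOVED_MISSING']}",
            f"removed (insignificant slope): {c['REMOVED_SLOPE']}",
            f"removed (CI-length outlier):   {c['REMOVED_CI_OUTLIER']}",
            f"kept: {c['KEPT']}   mean individual E: {s['mean_E_kept']:.4f}",
            "",
            f"efficiency clusters: k = {s['k_selected']}",
        ]
        for g, (e, n) in enumerate(zip(s["group_efficiencies"], s["group_sizes"])):
            lines.append(f"  group {g}: {n:3d} primers, E = {e:.4f}")
        if self.diagnostics:
            lines.append("")
            lines.append("diagnostics (stat, p):")
            for name, (stat, p) in self.diagnostics.items():
                lines.append(f"  {name:13s} {stat:10.4f}  p = {p:.4g}")
        return "\n".join(lines)

    def save_reports(self, out_dir, scheme: str = "cluster") -> dict[str, str]:
        """Write every CSV report plus the JSON summary; returns the paths."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, frame in [
            ("efficiency", self.efficiency_frame),
            ("purge", self.purge_frame),
            ("cluster", self.cluster_frame),
            ("trace", self.trace_frame),
            ("adjusted", self.adjusted_frame(scheme)),
            ("cov", self.cov_frame()),
        ]:
            path = out / f"{name}_report.csv"
            write_report(frame, path)
            paths[name] = str(path)
        spath = out / "run_summary.json"
        spath.write_text(json.dumps(self.summary_dict(), indent=2, sort_keys=True))
        paths["summary"] = str(spath)
        return paths


def _none_if_nan(x):
    if x is None:
        return None
    x = float(x)
    return None if math.isnan(x) else x
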