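"""Model/Results facade over the estimation pipeline.

:class:`AvertedDeaths` is constructed from a service table (or directly from
a DataFrame) plus the fatality-rate and cost models; :meth:`AvertedDeaths.fit`
runs the deterministic ranges, the closed form, and the Monte Carlo, and
returns an :class:`AvertedDeathsResults` carrying the estimates, their
intervals, derived metrics, and a ``summary()`` table.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from .estimation import (
    DEFAULT_SEED,
    EstimationConfig,
    FatalityRateModel,
    MonteCarloResult,
    analytic_mean,
    analytic_quantile,
)
from .metrics import CostModel, build_report, report_to_markdown
from .services import ServiceRecord, ServiceTable, builtin_table1, load_service_table

__all__ = ["AvertedDeaths", "AvertedDeathsResults"]


class AvertedDeaths:
    """Deaths-averted model for a table of overdose-response services.

    Parameters
    ----------
    table : ServiceTable
        Observed emergency-response counts per service.
    rate_model : FatalityRateModel, optional
        Sensitivity distribution for the unwitnessed-poisoning fatality
        rate; Uniform(0.1, 0.8) by default.
    cost_model : CostModel, optional
        Societal value of one averted death (CAD).
    subset : str or iterable of str, optional
        Country-scope filter applied before estimation (``"all"`` keeps
        every record).
    """

    def __init__(
        self,
        table: ServiceTable,
        rate_model: FatalityRateModel | None = None,
        cost_model: CostModel | None = None,
        subset: str = "all",
    ) -> None:
        if subset != "all":
            scopes = {subset} if isinstance(subset, str) else set(subset)
            table = table.subset(scopes)
        self.table = table
        self.rate_model = rate_model or FatalityRateModel()
        self.cost_model = cost_model or CostModel()

    @classmethod
    def from_table1(cls, **kwargs) -> "AvertedDeaths":
        """Model over the packaged eleven-service North American table."""
        return cls(builtin_table1(), **kwargs)

    @classmethod
    def from_file(cls, path, format: str | None = None, **kwargs) -> "AvertedDeaths":
        return cls(load_service_table(path, format=format), **kwargs)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, label: str = "dataframe", **kwargs):
        records = tuple(
            ServiceRecord(
                **{
                    k: row[k]
                    for k in (
                        "name",
                        "modality",
                        "country_scope",
                        "n_events",
                        "jurisdiction",
                        "period_start",
                        "period_end",
                        "source_note",
                    )
                    if k in row and pd.notna(row[k])
                }
            )
            for _, row in frame.iterrows()
        )
        return cls(ServiceTable(records, label=label), **kwargs)

    def fit(
        self,
        n_draws: int = 10_000,
        seed: int = DEFAULT_SEED,
        draw_mode: str = "shared",
        draw_scheme: str = "midpoint",
        interval_mass: float = 0.95,
    ) -> "AvertedDeathsResults":
        """Run the full estimation and return results."""
        config = EstimationConfig(
            n_draws=n_draws,
            seed=seed,
            draw_mode=draw_mode,
            draw_scheme=draw_scheme,
            interval_mass=interval_mass,
        )
        report = build_report(self.table, config, self.rate_model, self.cost_model)
        return AvertedDeathsResults(self, config, report)


class AvertedDeathsResults:
    """Fitted estimates, intervals, derived metrics, and exports."""

    def __init__(self, model: AvertedDeaths, config: EstimationConfig, report: dict):
        self.model = model
        self.config = config
        self.report = report

    # -- headline quantities -------------------------------------------------
    @property
    def total_events(self) -> int:
        return self.report["total"]["n_events"]

    @property
    def mc_point(self) -> int:
        return self.report["total"]["mc_point"]

    @property
    def mc_ci(self) -> tuple[int, int]:
        return tuple(self.report["total"]["mc_ci"])

    @property
    def summed_range(self) -> tuple[int, int]:
        return tuple(self.report["total"]["summed_range"])

    @property
    def pooled_range(self) -> tuple[int, int]:
        return tuple(self.report["total"]["pooled_range_nearest"])

    @property
    def ratios(self) -> dict | None:
        return self.report["ratios"]

    @property
    def canada_exclusive(self) -> dict | None:
        return self.report["canada_exclusive"]

    def analytic_total(self) -> tuple[float, float, float]:
        """Closed-form (mean, 2.5%, 97.5%) for the pooled count, unrounded."""
        rm = self.model.rate_model
        n = self.total_events
        alpha = (1.0 - self.config.interval_mass) / 2.0
        return (
            analytic_mean(n, rm),
            analytic_quantile(n, rm, alpha),
            analytic_quantile(n, rm, 1.0 - alpha),
        )

    # -- exports ---------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Per-service rows plus the TOTAL row, Table-1 column order."""
        rows = [dict(r) for r in self.report["services"]]
        total = self.report["total"]
        rows.append(
            {
                "service": "TOTAL",
                "modality": "",
                "country_scope": "",
                "n_events": total["n_events"],
                "range_lower": total["summed_range"][0],
                "range_upper": total["summed_range"][1],
                "mc_point": total["mc_point"],
                "mc_ci_lower": total["mc_ci"][0],
                "mc_ci_upper": total["mc_ci"][1],
                "mc_raw_mean": total["mc_raw_mean"],
                "count_known": True,
            }
        )
        return pd.DataFrame(rows)

    def figure_data(self) -> pd.DataFrame:
        """Per-service range bounds and MC points, for external plotting."""
        frame = self.to_frame()
        frame = frame[frame["count_known"] & (frame["service"] != "TOTAL")]
        return frame[
            ["service", "n_events", "range_lower", "range_upper", "mc_point"]
        ].reset_index(drop=True)

    def to_markdown(self) -> str:
        return report_to_markdown(self.report)

    def save(self, outdir, formats=("csv", "json", "markdown")) -> list[Path]:
        """Write the report in the requested formats; returns written paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written: list[Path] = []
        if "csv" in formats:
            p = outdir / "report.csv"
            self.to_frame().to_csv(p, index=False)
            written.append(p)
            p = outdir / "figure_data.csv"
            self.figure_data().to_csv(p, index=False)
            written.append(p)
        if "json" in formats:
            p = outdir / "report.json"
            p.write_text(json.dumps(self.report, indent=1, default=str), encoding="utf-8")
            written.append(p)
        if "markdown" in formats:
            p = outdir / "report.md"
            p.write_text(self.to_markdown(), encoding="utf-8")
            written.append(p)
        return written

    def summary(self) -> str:
        """Human-readable summary table (plain text)."""
        rep = self.report
        total = rep["total"]
        prov = rep["provenance"]
        width = max(len(r["service"]) for r in rep["services"]) + 2
        lines = [
            "Potential drug-poisoning deaths averted",
            "=" * 72,
            f"{'Service':<{width}}{'Events':>8}  {'Range':>9}  Monte Carlo",
            "-" * 72,
        ]
        for row in rep["services"]:
            if row["count_known"]:
                rng = f"{row['range_lower']}-{row['range_upper']}"
                mc = f"{row['mc_point']} [{row['mc_ci_lower']}, {row['mc_ci_upper']}]"
                lines.append(
                    f"{row['service']:<{width}}{row['n_events']:>8}  {rng:>9}  {mc}"
                )
            else:
                lines.append(f"{row['service']:<{width}}{'unknown':>8}")
        lines.append("-" * 72)
        rng = f"{total['summed_range'][0]}-{total['summed_range'][1]}"
        mc = f"{total['mc_point']} [{total['mc_ci'][0]}, {total['mc_ci'][1]}]"
        lines.append(f"{'TOTAL':<{width}}{total['n_events']:>8}  {rng:>9}  {mc}")
        lines.append("")
        if rep["ratios"]:
            r = rep["ratios"]
            lines.append(
                f"Non-fatal:fatal ratio  {r['at_floor']}:1 (floor)  "
                f"{r['at_mc']}:1 (MC)  {r['at_ceiling']}:1 (ceiling)"
            )
        if rep["canada_exclusive"]:
            ca = rep["canada_exclusive"]
            lines.append(
                f"Canada-exclusive       {ca['summed_range'][0]}-{ca['summed_range'][1]} deaths averted, "
                f"${ca['cost_savings'][0]} to ${ca['cost_savings'][1]} {ca['currency']}"
            )
        lines.append(
            f"({prov['n_draws']} draws, {prov['draw_mode']}/{prov['draw_scheme']}, "
            f"seed {prov['seed']}, rate U[{prov['rate_lower']}, {prov['rate_upper']}])"
        )
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<AvertedDeathsResults: total {self.mc_point} "
            f"[{self.mc_ci[0]}, {self.mc_ci[1]}] from {self.total_events} events>"
        )
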