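"""Derived quantities: summed/pooled ranges, non-fatal:fatal ratios, cost savings.

Money is handled in exact rational/decimal arithmetic and only converted to
binary floating point for display, so printed totals are reproducible to the
cent.  The default per-averted-death societal value is stored as an exact
rational derived from published Canadian cost totals (see
:data:`DEFAULT_PER_DEATH_VALUE`); the two published totals are mutually
inconsistent below the dollar level, so the constant is anchored to the lower
one and the upper reproduces to within $0.38 (nine significant figures).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from fractions import Fraction
from typing import Iterable, Sequence

from .estimation import (
    EstimationConfig,
    FatalityRateModel,
    MonteCarloResult,
    RangeEstimate,
    analytic_mean,
    apply_rounding,
    mc_estimate,
    range_estimate,
    round_half_away,
)
from .services import ServiceTable, known_counts

__all__ = [
    "DEFAULT_PER_DEATH_VALUE",
    "CostModel",
    "RatioReport",
    "summed_range",
    "pooled_range",
    "nonfatal_fatal_ratio",
    "ratio_report",
    "cost_savings",
    "build_report",
    "report_to_markdown",
]

#: Societal value of one averted death, CAD: life lost to society plus
#: potential productive life years lost.  Exact rational
#: $34,878,360.40 / 18 = $1,937,686.688... (~$1.94M per death).
DEFAULT_PER_DEATH_VALUE = Fraction(3_487_836_040, 100) / 18

_CENT = Decimal("0.01")


def _to_fraction(value) -> Fraction:
    if isinstance(value, Fraction):
        return value
    if isinstance(value, Decimal):
        return Fraction(value)
    if isinstance(value, int):
        return Fraction(value)
    if isinstance(value, str):
        return Fraction(Decimal(value))
    if isinstance(value, float):
        # via repr so 1937686.69 means the decimal literal, not the float bits
        return Fraction(Decimal(repr(value)))
    raise TypeError(f"cannot interpret {value!r} as an exact money amount")


def _to_cents(value: Fraction) -> Decimal:
    return (Decimal(value.numerator) / Decimal(value.denominator)).quantize(
        _CENT, rounding=ROUND_HALF_UP
    )


@dataclass(frozen=True)
class CostModel:
    """Monetary value of one averted death (exact arithmetic)."""

    per_death_value: Fraction = DEFAULT_PER_DEATH_VALUE
    currency: str = "CAD"

    def __post_init__(self) -> None:
        object.__setattr__(self, "per_death_value", _to_fraction(self.per_death_value))
        if self.per_death_value <= 0:
            raise ValueError("per_death_value must be positive")

    @property
    def per_death_display(self) -> Decimal:
        return _to_cents(self.per_death_value)


@dataclass(frozen=True)
class RatioReport:
    """Non-fatal:fatal ratios at the rate floor, the MC point, and the rate ceiling."""

    ratio_at_floor: float
    ratio_at_mc: float
    ratio_at_ceiling: float
    denominator_policy: str = "nearest-rounded pooled averted count"

    def __post_init__(self) -> None:
        if not self.ratio_at_floor >= self.ratio_at_mc >= self.ratio_at_ceiling:
            raise ValueError(
                "ratios must be ordered floor >= mc >= ceiling, got "
                f"({self.ratio_at_floor}, {self.ratio_at_mc}, {self.ratio_at_ceiling})"
            )


def summed_range(
    counts: Sequence[tuple[str, int]], model: FatalityRateModel | None = None
) -> RangeEstimate:
    """Component-wise sum of per-service ceiling ranges.

    Every service with a nonzero count contributes at least one averted death
    at the lower rate, so this sum dominates the pooled range.
    """
    model = model or FatalityRateModel()
    lower = upper = 0
    for _, n in counts:
        est = range_estimate(n, model, rounding="ceiling")
        lower += est.lower
        upper += est.upper
    return RangeEstimate(lower=lower, upper=upper, rounding="ceiling")


def pooled_range(
    total_count: int,
    model: FatalityRateModel | None = None,
    rounding: str = "nearest",
) -> RangeEstimate:
    """Range from applying the rate endpoints to the pooled event count."""
    model = model or FatalityRateModel()
    return range_estimate(total_count, model, rounding=rounding)


def nonfatal_fatal_ratio(
    total_events: int, averted: int, decimals: int = 2
) -> float:
    """``(total_events - averted) / averted`` rounded to ``decimals`` places."""
    if averted == 0:
        raise ZeroDivisionError(
            "non-fatal:fatal ratio is undefined when no deaths are averted"
        )
    if not 0 < averted <= total_events:
        raise ValueError(
            f"averted must satisfy 0 < averted <= total_events, "
            f"got averted={averted}, total_events={total_events}"
        )
    return round((total_events - averted) / averted, decimals)


def ratio_report(
    total_events: int,
    mc_point: int,
    model: FatalityRateModel | None = None,
    decimals: int = 2,
) -> RatioReport:
    """Ratios at the nearest-rounded pooled floor/ceiling averted counts and the MC point."""
    model = model or FatalityRateModel()
    floor_averted = round_half_away(total_events * model.a)
    ceiling_averted = round_half_away(total_events * model.b)
    return RatioReport(
        ratio_at_floor=nonfatal_fatal_ratio(total_events, floor_averted, decimals),
        ratio_at_mc=nonfatal_fatal_ratio(total_events, mc_point, decimals),
        ratio_at_ceiling=nonfatal_fatal_ratio(total_events, ceiling_averted, decimals),
    )


def cost_savings(
    averted_range: RangeEstimate | tuple[int, int], cost: CostModel | None = None
) -> tuple[Decimal, Decimal]:
    """Monetary savings over an averted-death range, exact to the cent."""
    cost = cost or CostModel()
    if isinstance(averted_range, RangeEstimate):
        lower, upper = averted_range.as_tuple()
    else:
        lower, upper = averted_range
    return (
        _to_cents(_to_fraction(lower) * cost.per_death_value),
        _to_cents(_to_fraction(upper) * cost.per_death_value),
    )


def build_report(
    table: ServiceTable,
    config: EstimationConfig | None = None,
    model: FatalityRateModel | None = None,
    cost: CostModel | None = None,
) -> dict:
    """Full structured report: per-service rows, totals, ratios, subset costs.

    Unknown-count services appear as rows marked ``"unknown"`` rather than
    being dropped.  Every number in the report is re-derivable from the
    embedded ``provenance`` block.
    """
    config = config or EstimationConfig()
    model = model or FatalityRateModel()
    cost = cost or CostModel()

    counts = known_counts(table, "all")
    per_mc, total_mc = mc_estimate(counts, config, model)
    ranges = {name: range_estimate(n, model, config.range_rounding) for name, n in counts}
    count_of = dict(counts)

    rows = []
    for rec in table.records:
        if rec.count_known:
            est = ranges[rec.name]
            mc = per_mc[rec.name]
            rows.append(
                {
                    "service": rec.name,
                    "modality": rec.modality,
                    "country_scope": rec.country_scope,
                    "n_events": rec.n_events,
                    "range_lower": est.lower,
                    "range_upper": est.upper,
                    "mc_point": mc.point,
                    "mc_ci_lower": mc.ci_lower,
                    "mc_ci_upper": mc.ci_upper,
                    "mc_raw_mean": mc.raw_mean,
                    "count_known": True,
                }
            )
        else:
            rows.append(
                {
                    "service": rec.name,
                    "modality": rec.modality,
                    "country_scope": rec.country_scope,
                    "n_events": "unknown",
                    "range_lower": "unknown",
                    "range_upper": "unknown",
                    "mc_point": "unknown",
                    "mc_ci_lower": "unknown",
                    "mc_ci_upper": "unknown",
                    "mc_raw_mean": "unknown",
                    "count_known": False,
                }
            )

    total_events = sum(count_of.values())
    summed = summed_range(counts, model)
    pooled_nearest = pooled_range(total_events, model, rounding="nearest")
    pooled_raw = pooled_range(total_events, model, rounding="none")
    if total_events > 0 and total_mc.point > 0 and round_half_away(total_events * model.a) > 0:
        ratios = ratio_report(total_events, total_mc.point, model)
        ratios_block = {
            "at_floor": ratios.ratio_at_floor,
            "at_mc": ratios.ratio_at_mc,
            "at_ceiling": ratios.ratio_at_ceiling,
            "denominator_policy": ratios.denominator_policy,
        }
    else:
        ratios_block = None  # undefined when no deaths are averted

    canada_counts = known_counts(table, {"canada"})
    canada = None
    if canada_counts:
        canada_summed = summed_range(canada_counts, model)
        lo_cost, hi_cost = cost_savings(canada_summed, cost)
        canada = {
            "services": [name for name, _ in canada_counts],
            "total_events": sum(n for _, n in canada_counts),
            "summed_range": canada_summed.as_tuple(),
            "cost_savings": (str(lo_cost), str(hi_cost)),
            "currency": cost.currency,
        }

    return {
        "label": table.label,
        "services": rows,
        "total": {
            "n_events": total_events,
            "summed_range": summed.as_tuple(),
            "pooled_range_nearest": pooled_nearest.as_tuple(),
            "pooled_range_raw": pooled_raw.as_tuple(),
            "mc_point": total_mc.point,
            "mc_ci": (total_mc.ci_lower, total_mc.ci_upper),
            "mc_raw_mean": total_mc.raw_mean,
            "mc_raw_ci": total_mc.raw_ci,
        },
        "ratios": ratios_block,
        "canada_exclusive": canada,
        "n_unknown_services": table.n_unknown(),
        "provenance": {
            "n_draws": config.n_draws,
            "seed": config.seed,
            "draw_mode": config.draw_mode,
            "draw_scheme": config.draw_scheme,
            "interval_mass": config.interval_mass,
            "range_rounding": config.range_rounding,
            "mc_rounding": config.mc_rounding,
            "rate_family": model.family,
            "rate_lower": model.a,
            "rate_upper": model.b,
            "cost_per_death": str(cost.per_death_display),
            "currency": cost.currency,
        },
    }


def _md_row(cells: Iterable[str]) -> str:
    return "| " + " | ".join(str(c) for c in cells) + " |"


def report_to_markdown(report: dict) -> str:
    """Render a report as a Markdown table in the published column order."""
    header = [
        "Service",
        "Modality",
        "Scope",
        "Emergency responses",
        "Averted (range)",
        "Averted (Monte Carlo)",
    ]
    lines = [_md_row(header), _md_row(["---"] * len(header))]
    for row in report["services"]:
        if row["count_known"]:
            rng = f"{row['range_lower']}-{row['range_upper']}"
            mc = f"{row['mc_point']} [{row['mc_ci_lower']}, {row['mc_ci_upper']}]"
            n = row["n_events"]
        else:
            rng = mc = n = "Unknown"
        lines.append(
            _md_row([row["service"], row["modality"], row["country_scope"], n, rng, mc])
        )
    total = report["total"]
    lines.append(
        _md_row(
            [
                "TOTAL",
                "",
                "",
                total["n_events"],
                f"{total['summed_range'][0]}-{total['summed_range'][1]}",
                f"{total['mc_point']} [{total['mc_ci'][0]}, {total['mc_ci'][1]}]",
            ]
        )
    )
    lines.append("")
    r = report["ratios"]
    if r is not None:
        lines.append(
            f"Non-fatal:fatal ratio: {r['at_floor']}:1 (rate floor), "
            f"{r['at_mc']}:1 (Monte Carlo), {r['at_ceiling']}:1 (rate ceiling)."
        )
    if report["canada_exclusive"]:
        ca = report["canada_exclusive"]
        lines.append(
            f"Canada-exclusive services averted {ca['summed_range'][0]}-"
            f"{ca['summed_range'][1]} deaths; estimated savings "
            f"${ca['cost_savings'][0]} to ${ca['cost_savings'][1]} {ca['currency']}."
        )
    return "\n".join(lines) + "\n"
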