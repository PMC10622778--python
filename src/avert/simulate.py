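"""Synthetic MORS event logs with known counterfactual ground truth.

The services' raw call logs are not public, so validating the estimator
requires a generative stand-in: a cohort of simulated emergency callouts per
service, each carrying a latent flag for whether the client would have died
had they been using alone with no intervention.  The simulator reproduces the
qualitative features the observed data are known to have — repeat clients,
false-alarm callouts, per-service count variation — and exposes the true
number of averted deaths so interval coverage and estimator bias can be
measured by parameter recovery.

Generative model (per service, all draws from one seeded Generator):

* true emergencies ``M ~ Poisson(event_rate)`` — ``event_rate`` is the
  expected number of *true* emergency responses over the period;
* false callouts ``F ~ Poisson(event_rate * f / (1 - f))`` so a fraction
  ``f`` of all callouts is false in expectation while ``E[observed] = rate``;
* events are assigned to clients sequentially: a new client with probability
  ``1 / (1 + theta)``, otherwise the client of a uniformly chosen earlier
  event (size-biased attachment; ``theta = repeat_client_dispersion = 0``
  makes every event a distinct client);
* each true emergency is counterfactually fatal with probability
  ``true_fatality_rate``, independently; false callouts are never fatal.

``observed_counts`` contain true emergencies only — what a service's call
log records as emergency responses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.stats import binomtest

from .estimation import EstimationConfig, FatalityRateModel, mc_estimate

__all__ = [
    "SimulationScenario",
    "SyntheticCohort",
    "table1_scenario",
    "simulate_cohort",
    "uniqueness_gap",
    "CoverageReport",
    "coverage_experiment",
    "BiasReport",
    "estimator_bias_experiment",
]

#: The nine known per-service emergency-response counts of the builtin table,
#: used as event-rate defaults for study-scale scenarios.
TABLE1_RATES = (77.0, 18.0, 66.0, 3.0, 33.0, 28.0, 74.0)
_TABLE1_ALL = (77.0, 18.0, 66.0, 0.0, 3.0, 33.0, 28.0, 74.0, 0.0)


@dataclass(frozen=True)
class SimulationScenario:
    """Parameters of one synthetic cohort.

    ``true_fatality_rate`` may be a fixed probability or the string
    ``"random"``, in which case each replicate draws the rate once from the
    fatality-rate model under test (the regime in which the credible interval
    has a calibration claim).
    """

    event_rates: tuple[float, ...]
    true_fatality_rate: float | str = "random"
    repeat_client_dispersion: float = 0.0
    false_callout_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        rates = tuple(float(r) for r in self.event_rates)
        if not rates:
            raise ValueError("event_rates must be non-empty")
        if any(r < 0 for r in rates):
            raise ValueError(f"event_rates must be non-negative, got {rates}")
        object.__setattr__(self, "event_rates", rates)
        r = self.true_fatality_rate
        if isinstance(r, str):
            if r != "random":
                raise ValueError(
                    f"true_fatality_rate must be a probability or 'random', got {r!r}"
                )
        elif not 0.0 <= float(r) <= 1.0:
            raise ValueError(f"true_fatality_rate must be in [0, 1], got {r}")
        if self.repeat_client_dispersion < 0:
            raise ValueError("repeat_client_dispersion must be non-negative")
        if not 0.0 <= self.false_callout_fraction < 1.0:
            raise ValueError("false_callout_fraction must be in [0, 1)")

    @property
    def n_services(self) -> int:
        return len(self.event_rates)

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationScenario":
        allowed = {
            "event_rates",
            "true_fatality_rate",
            "repeat_client_dispersion",
            "false_callout_fraction",
            "seed",
        }
        bad = set(data) - allowed
        if bad:
            raise ValueError(f"unknown scenario field(s): {sorted(bad)}")
        if "event_rates" not in data:
            raise ValueError("scenario is missing required field 'event_rates'")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "SimulationScenario":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ValueError("scenario file must contain a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return {
            "event_rates": list(self.event_rates),
            "true_fatality_rate": self.true_fatality_rate,
            "repeat_client_dispersion": self.repeat_client_dispersion,
            "false_callout_fraction": self.false_callout_fraction,
            "seed": self.seed,
        }


def table1_scenario(**overrides) -> SimulationScenario:
    """Scenario at the scale of the builtin table (nine known services)."""
    defaults = dict(event_rates=_TABLE1_ALL, true_fatality_rate="random", seed=0)
    defaults.update(overrides)
    return SimulationScenario(**defaults)


@dataclass(frozen=True)
class SyntheticCohort:
    """Event log plus the latent ground truth the estimator should recover."""

    events: pd.DataFrame  # service, client_id, is_true_emergency, counterfactual_fatal
    observed_counts: tuple[tuple[str, int], ...]
    true_averted: int
    true_unique_lives: int
    true_fatality_rate: float
    scenario: SimulationScenario

    def __post_init__(self) -> None:
        if self.true_unique_lives > self.true_averted:
            raise ValueError("unique lives cannot exceed averted events")


def _assign_clients(n_events: int, theta: float, rng: np.random.Generator, prefix: str):
    """Sequential size-biased client assignment; theta=0 -> all singletons."""
    clients: list[str] = []
    n_clients = 0
    p_new = 1.0 / (1.0 + theta)
    for i in range(n_events):
        if i == 0 or rng.random() < p_new:
            n_clients += 1
            clients.append(f"{prefix}c{n_clients:04d}")
        else:
            clients.append(clients[rng.integers(i)])
    return clients


def simulate_cohort(
    scenario: SimulationScenario,
    rng: np.random.Generator | None = None,
    rate_model: FatalityRateModel | None = None,
) -> SyntheticCohort:
    """Draw one synthetic cohort under the scenario's generative model.

    Reproducible: the same scenario (including seed) yields the same cohort.
    When ``true_fatality_rate`` is ``"random"`` the rate is drawn once from
    ``rate_model`` (default Uniform(0.1, 0.8)).
    """
    rng = rng if rng is not None else np.random.default_rng(scenario.seed)
    if scenario.true_fatality_rate == "random":
        model = rate_model or FatalityRateModel()
        rate = float(rng.uniform(model.a, model.b))
    else:
        rate = float(scenario.true_fatality_rate)

    f = scenario.false_callout_fraction
    rows = []
    observed = []
    for s_idx, lam in enumerate(scenario.event_rates):
        service = f"service_{s_idx + 1:02d}"
        n_true = int(rng.poisson(lam))
        n_false = int(rng.poisson(lam * f / (1.0 - f))) if f > 0 else 0
        flags = np.concatenate(
            [np.ones(n_true, dtype=bool), np.zeros(n_false, dtype=bool)]
        )
        rng.shuffle(flags)
        clients = _assign_clients(
            len(flags), scenario.repeat_client_dispersion, rng, prefix=f"s{s_idx + 1:02d}-"
        )
        fatal = np.zeros(len(flags), dtype=bool)
        fatal[flags] = rng.random(n_true) < rate
        for client, is_true, is_fatal in zip(clients, flags, fatal):
            rows.append((service, client, bool(is_true), bool(is_fatal)))
        observed.append((service, n_true))

    events = pd.DataFrame(
        rows, columns=["service", "client_id", "is_true_emergency", "counterfactual_fatal"]
    )
    true_averted = int(events["counterfactual_fatal"].sum())
    fatal_events = events[events["counterfactual_fatal"]]
    true_unique = int(fatal_events["client_id"].nunique())
    return SyntheticCohort(
        events=events,
        observed_counts=tuple(observed),
        true_averted=true_averted,
        true_unique_lives=true_unique,
        true_fatality_rate=rate,
        scenario=scenario,
    )


def uniqueness_gap(cohort: SyntheticCohort) -> float:
    """Overstatement fraction if averted *events* are equated with *lives*.

    ``1 - unique_lives / averted``: 0 when every counterfactually fatal event
    belongs to a distinct client, approaching 1 when few clients account for
    all fatal events.
    """
    if cohort.true_averted == 0:
        raise ZeroDivisionError(
            "uniqueness gap is undefined when no deaths were averted"
        )
    return 1.0 - cohort.true_unique_lives / cohort.true_averted


@dataclass(frozen=True)
class CoverageReport:
    """Empirical interval coverage over replicated synthetic cohorts."""

    coverage: float
    n_replicates: int
    n_covered: int
    nominal: float
    binomial_se: float
    ci_lower: float  # exact (Clopper-Pearson) 95% bounds on the coverage rate
    ci_upper: float
    mean_true_averted: float
    mean_interval_width: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def coverage_experiment(
    scenario: SimulationScenario,
    config: EstimationConfig | None = None,
    model: FatalityRateModel | None = None,
    n_replicates: int = 1000,
) -> CoverageReport:
    """Does the credible interval contain the true averted count ~95% of the time?

    Each replicate simulates a cohort (re-drawing the fatality rate from
    ``model`` when the scenario says ``"random"`` — the prior-calibrated
    regime), runs :func:`mc_estimate` on the observed counts, and checks
    whether the rounded interval contains the cohort's true averted count.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    config = config or EstimationConfig()
    model = model or FatalityRateModel()
    rng = np.random.default_rng(scenario.seed)

    covered = 0
    widths = 0.0
    trues = 0.0
    for _ in range(n_replicates):
        cohort = simulate_cohort(scenario, rng=rng, rate_model=model)
        _, total = mc_estimate(list(cohort.observed_counts), config, model)
        if total.ci_lower <= cohort.true_averted <= total.ci_upper:
            covered += 1
        widths += total.ci_upper - total.ci_lower
        trues += cohort.true_averted

    p = covered / n_replicates
    test = binomtest(covered, n_replicates)
    ci = test.proportion_ci(confidence_level=0.95, method="exact")
    return CoverageReport(
        coverage=p,
        n_replicates=n_replicates,
        n_covered=covered,
        nominal=config.interval_mass,
        binomial_se=float(np.sqrt(p * (1.0 - p) / n_replicates)),
        ci_lower=float(ci.low),
        ci_upper=float(ci.high),
        mean_true_averted=trues / n_replicates,
        mean_interval_width=widths / n_replicates,
    )


@dataclass(frozen=True)
class BiasReport:
    """What the estimator converges to under a fixed true fatality rate.

    The point estimate divided by total events converges to the *prior mean*
    ``(a + b) / 2``, not to the true rate: the method propagates assumed
    uncertainty rather than learning the rate from data.  ``bias`` is
    ``prior_mean - true_rate``.
    """

    true_rate: float
    prior_mean: float
    mean_point_rate: float  # mean over replicates of point / total observed events
    bias: float
    n_replicates: int

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def estimator_bias_experiment(
    true_rate: float,
    scenario: SimulationScenario | None = None,
    config: EstimationConfig | None = None,
    model: FatalityRateModel | None = None,
    n_replicates: int = 200,
) -> BiasReport:
    """Measure the point-estimate rate against a fixed true fatality rate."""
    scenario = scenario or table1_scenario()
    scenario = replace(scenario, true_fatality_rate=float(true_rate))
    config = config or EstimationConfig()
    model = model or FatalityRateModel()
    rng = np.random.default_rng(scenario.seed)

    ratios = []
    for _ in range(n_replicates):
        cohort = simulate_cohort(scenario, rng=rng, rate_model=model)
        n_obs = sum(n for _, n in cohort.observed_counts)
        if n_obs == 0:
            continue
        _, total = mc_estimate(list(cohort.observed_counts), config, model)
        ratios.append(total.raw_mean / n_obs)
    if not ratios:
        raise ValueError("all replicates produced zero observed events")
    mean_rate = float(np.mean(ratios))
    return BiasReport(
        true_rate=float(true_rate),
        prior_mean=model.mean,
        mean_point_rate=mean_rate,
        bias=model.mean - float(true_rate),
        n_replicates=len(ratios),
    )
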