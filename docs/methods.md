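# Methods

## Estimand and model

A mobile overdose response service (MORS) records *emergency drug-poisoning
responses*: events where the service initiated an EMS or community-based
intervention for a presumed poisoning. The estimand is counterfactual: how
many of those events would have ended in death had the person been using
alone with no intervention. With `n` recorded events and an unwitnessed-
poisoning fatality probability `r`, potential deaths averted are `D = n·r`.

`r` is not identifiable from service data. It is modelled as a sensitivity
distribution, Uniform(a, b) with defaults `a = 0.1` and `b = 0.8` — the
published bracket from naloxone-impact modelling (floor) and expert Delphi
consensus (ceiling). These are taken as given; the package fits nothing to
external mortality data and performs no Bayesian updating. The closed forms
are elementary: `E[D] = n(a+b)/2` and the q-quantile `n(a + q(b−a))`, so the
default 95% equal-tailed interval is `n·[0.1175, 0.7825]`.

The key epistemic point, made explicit by the simulation harness: the
estimator *propagates assumed uncertainty*, it does not *learn* `r`. Under a
fixed true rate the point estimate divided by total events converges to the
prior mean 0.45 regardless of the truth (`estimator_bias_experiment` reports
the bias `(a+b)/2 − r`). The credible interval has a calibration claim only
when the true rate is itself drawn from the same uniform — which is the
regime `coverage_experiment` evaluates.

## Data model

Counts are per-service non-negative integers or the distinct state
*unknown*. Unknown counts are carried through tables and reports (rows
marked `"unknown"`) but excluded from every sum and estimate; they are never
imputed as zero, since a service that does not record responses is not a
service with none. Zero-count services are real rows contributing zero.
Observation periods are heterogeneous across services and enter no
computation; they are metadata. Country scope is one of
{canada, usa, both, global}; a "Canada-exclusive" analysis filters to
scope = canada only, which excludes services operating in both countries or
globally.

## Rounding policies

Two policies coexist, each recorded in its result object:

- **ceiling** for deterministic range cells (any nonzero count averts at
  least one whole death at the floor rate): 33·0.1 = 3.3 → 4, 18·0.8 = 14.4
  → 15;
- **nearest, halves away from zero** for Monte Carlo outputs: 77·0.45 =
  34.65 → 35.

Products of counts and rates are snapped to 9 decimals before integer
rounding to absorb binary-float representation noise (70·0.1 is
7.000000000000001 in IEEE arithmetic and must not ceil to 8).

Summing per-service ceiling ranges (33–243 over the nine known services)
necessarily dominates applying the endpoints to the pooled count
(299·[0.1, 0.8] = 29.9–239.2, nearest-rounded 30–239). Both are exposed;
ratio denominators default to the nearest-rounded pooled averted counts
(30 and 239), the convention consistent with the reported ratio endpoints,
and the policy string is carried in `RatioReport.denominator_policy`.

## Monte Carlo design

`n_draws` defaults to 10,000 and the interval is the equal-tailed
percentile interval of the draws, quantiles computed by linear interpolation
between order statistics at Hazen plotting positions (`p·n + 0.5`;
midpoint-unbiased).

**Draw modes.** `shared` (default): one rate draw per iteration multiplies
every service's count and the total, making per-service and total estimates
comonotone and exactly additive draw-by-draw — the convention that makes the
total's interval equal the pooled count times the uniform's quantiles.
`independent`: each service gets its own draw sequence (independent
Latin-hypercube permutations of the strata) and the total is the per-
iteration sum; its total interval is never wider than shared mode's, since
comonotone rates maximise the total's spread.

**Draw schemes.** With a single uniform parameter at 10,000 iid draws the
total's sample mean carries a standard error of ~0.6 deaths
(299·0.2021/√10⁴), larger than the 0.05 gap between 134.55 and the rounding
boundary 134.5 — i.e. plain pseudo-random sampling randomises the final
rounded integer between runs. The default scheme `midpoint` therefore draws
one rate at the centre of each of `n_draws` equal-probability strata: a
deterministic quadrature whose sample mean is the exact distribution mean
and whose Hazen quantiles are the exact distribution quantiles, so reported
integers are run-invariant and agree with the closed form for every count
(verified for 0…500). `stratified` (one uniform jitter per stratum) and
`pseudo` (iid) remain available for genuinely stochastic analyses; both are
driven by the seed, which is recorded in every result. The default seed
(20230531, arbitrary) is inert under `midpoint`.

Degenerate model `a = b` is allowed: all draws equal `a` and intervals
collapse to the point.

## Cost model

Savings are `averted × per-death value`, computed in exact rational
arithmetic and quantized to the cent (half-up) only at the end. The default
per-averted-death value is the exact rational $34,878,360.40 / 18 ≈
$1,937,686.69 CAD, derived from a published Canadian total divided by its
averted-death count ("life lost to society plus potential productive life
years lost"). The two published Canadian totals imply per-death constants
differing in the third decimal ($1,937,686.6889 vs $1,937,686.6917): no
single constant reproduces both printed totals to the cent. The constant is
anchored to the lower total, which it reproduces exactly; the upper then
computes to $257,712,329.62, within $0.38 (nine significant figures) of the
printed figure. This discrepancy is documented rather than resolved. No
discounting, no currency conversion, no per-service cost heterogeneity.

## Synthetic cohorts

The services' raw call logs are not public, so estimator validation uses a
generative stand-in with known ground truth. Per service, with one seeded
`numpy` Generator for everything:

- true emergencies `M ~ Poisson(event_rate)` — Poisson is the minimal count
  model given that only period totals are observed; `event_rate` defaults to
  the packaged per-service counts for study-scale scenarios;
- false-alarm callouts `F ~ Poisson(event_rate·f/(1−f))`, so a fraction `f`
  of all callouts is false in expectation while the expected *observed*
  count (true emergencies, what a call log records) stays `event_rate` for
  every `f`; false callouts are never counterfactually fatal;
- repeat clients: events are assigned sequentially — a new client with
  probability `1/(1+θ)`, otherwise the client of a uniformly chosen earlier
  event (size-biased attachment). `θ = 0` makes every event a distinct
  client; larger `θ` concentrates events on few clients. The *uniqueness
  gap* `1 − unique_lives/averted` quantifies how much equating averted
  events with saved lives overstates unique lives saved;
- each true emergency is counterfactually fatal with probability
  `true_fatality_rate`, independently; `"random"` draws the rate once per
  replicate from the fatality-rate model under test.

What the simulator does **not** emulate: pharmacology, response times,
EMS-vs-community outcome differences, temporal trends in drug-supply
toxicity, or any difference between "response initiated" and "life saved" —
the generator makes the response-equals-rescue equivalence assumption
explicit rather than resolving it. Passing coverage tests therefore show the
interval is calibrated *under the model's own prior and these structural
assumptions*, not that it covers the truth for real services.

## Experiment scales and tolerances

Coverage at study scale (nine services, rates equal to the packaged counts,
rate re-drawn each replicate) is evaluated with 1,000 replicates of a
10,000-draw estimator; the acceptance band [0.92, 0.98] is the nominal 0.95
± 3 binomial standard errors plus slack for Poisson/binomial count noise at
the interval edges. Coverage reports carry exact Clopper-Pearson 95% bounds
on the empirical rate. The bias harness uses 100–200 replicates (the
midpoint scheme makes the point-rate exactly 0.45 per replicate, so
replication only exercises the count noise). The mean-recovery check uses
1,000 cohort replicates against the binomial expectation 299·0.45 = 134.55
with a ±3 tolerance (~8 standard errors of the replicate mean).

## Known limitations

- The estimator is a sensitivity analysis, not inference: nothing in the
  data narrows the fatality-rate bracket, and the interval width is fixed by
  assumption at `n·0.665`.
- Averted *events* are not unique *lives*; the uniqueness gap is only
  computable in simulation, since services cannot link repeat callers
  reliably.
- Services that do not record response counts contribute nothing to totals,
  so all totals are understatements of the services' joint activity.
- The uniform family is the only rate model implemented; the interfaces
  accept alternatives structurally but none are provided.
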