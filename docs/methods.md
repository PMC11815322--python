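# Methods

## Model structure

The cohort model has six internal states: failure-free survival (FFS),
survival with failure, survival with transformation, post-autologous-
transplant, death from disease, and death from background causes. The two
death states are absorbing and may be merged for reporting. The cohort is a
unit mass starting 100 % in FFS, stepped over 30 half-year cycles (15
years). Re-entry into FFS is impossible: a patient who fails remains in the
failed state until death, and only the first failure is modelled — second
and later relapses, and strategy-specific second-line choices, are out of
scope.

### Transition probabilities

All disease transitions are parameterised as per-annum rates. Out of FFS
four exits compete: progression, transformation, death from disease, and
background mortality (the annual life-table probability converted to a
rate under a constant-hazard-within-year assumption). The per-cycle exit
probability is

    p_exit = 1 − exp(−(r_prog + r_trans + r_death + r_bg)·Δt),  Δt = 0.5 y

apportioned among destinations in proportion to their rates. This is the
exact distribution of the first event of competing exponential processes
and guarantees row-stochastic matrices for arbitrary non-negative rates;
the individual per-event conversion `1 − exp(−r·Δt)` is recovered in the
single-risk limit. Out of the three failed states, a common post-failure
disease-death rate competes with background mortality in the same way.

The cohort has a single age (start age 50, male, by default — the
life-table reference group; the trial's median age 57 is selectable). A
transformation occurring while the cohort is younger than 65 routes the
entire transforming fraction directly to the post-transplant state
(R-CHOP + ASCT); at 65 or older it routes to the transformation state
(R-CHOP only). This deterministic age gate is the cohort-level reading of
an individual-level eligibility rule; with the default start age every
transformation inside the horizon is transplanted.

### Rates from trial counts

Arm-level rates use the person-time approximation

    rate = events / (n × median follow-up),

with median follow-up 11.3 years for all arms. The synthetic-trial module
quantifies its bias: with total hazard Λ and horizon T the estimator
shrinks every hazard by (1 − e^(−ΛT))/(ΛT) — about 0.68 (a 32 % downward
bias) at the observed arm magnitudes, and negligible in the rare-event
regime. The printed per-strategy results of the source analysis were
produced from a supplementary input table that is not publicly available,
so these derived rates are a documented reconstruction, not a claim of
equivalence. Disease-death rates use all reported deaths per arm; whether
only lymphoma-attributed deaths should enter is not recoverable from the
published text.

### Rewards

QALYs: utility 0.88 in FFS and 0.74 in all three failed states, times the
half-cycle-corrected occupancy (the mean of start- and end-of-cycle
occupancy — the trapezoidal rule, which always lies midway between the
start-of-cycle and end-of-cycle accounting variants), times 0.5 years,
discounted at the cycle midpoint, (1+r)^(−(t+0.5)·Δt).

One-off flows attach to the first-entry ledger (the cohort fraction newly
entering a state each cycle) without half-cycle correction and discount at
the cycle start:

* cycle 1: radiotherapy course cost for every strategy plus six cycles of
  CVP or R-CVP for the systemic strategies; treatment disutility −0.05
  (RT) and −0.15 (systemic) for one cycle — six 3-weekly chemotherapy
  cycles fit inside ~4.5 months, i.e. a single model cycle; expected
  adverse-event cost (incidence × unit cost) as a one-off first-cycle
  event;
* first entry into failure, transformation or the post-transplant state:
  one R-CHOP retreatment course ($6,204.48);
* entry into the post-transplant state: transplant cost ($45,638.63) and a
  −0.20 disutility for that single cycle.

Retreatment itself carries no extra disutility beyond the lower progressed-
state utility; the 0.74 weight is taken to absorb the quality-of-life
burden of second-line therapy. Costs are held at full precision internally
and rounded only in report tables, so report-level sums can differ from
rounded components by a dollar.

## Key parameters

| parameter | default | unit | origin |
|---|---|---|---|
| cycle length / horizon | 0.5 / 15 | years | printed design |
| discount rate | 0.05 (0.03–0.07 in sensitivity) | per annum | guideline value |
| WTP threshold | 50,000 | AUD/QALY | printed design |
| start age / sex | 50 / male | — | life-table reference group |
| arm counts | 75/44/31 patients; 38/22/5 progressions; 11/4/1 transformations; 13/5/1 deaths | — | printed trial counts |
| unit costs | see `data/fixture_config.yaml` | 2022 AUD | printed schedule |
| utilities | 0.88 FFS, 0.74 progressed; −0.05/−0.15/−0.20 disutilities | — | printed table |
| post-failure death rate | 0.05 | per annum | **reconstructed** |
| adverse-event incidences | 0 (RT); 0.10 admission, 0.20 pegfilgrastim (systemic arms) | fraction | **reconstructed** |
| life table | Gompertz, q₅₀ = 0.0032, +9.3 %/yr | annual qx | **synthetic** |

The post-failure death rate (5 %/yr from any failed state) sits between
indolent post-relapse mortality and the worse outlook after transformation;
no published value exists for this cohort. The adverse-event incidences
reflect the materially higher grade ≥3 toxicity of the systemic arms; they
enter only as a ~$530 expected first-cycle cost. The synthetic life table
approximates a contemporary high-income-country male schedule (annual
mortality 0.3 % at 50, doubling roughly every 7.5 years). Every
reconstructed value is tagged in the config's `provenance` block and echoed
in the run log, keeping printed-value checks separable from
reconstruction-dependent outputs.

## Sensitivity analysis

One-way analysis re-runs the full model at both ends of each parameter's
range: ±30 % for costs and transition parameters, ±10 % for utilities
(disutilities vary on their magnitude), 3–7 % for the discount rate;
utilities and incidences are clipped to their domains. Tornado entries are
sorted by bar width; the outcome can be a pairwise ICER or incremental NMB
(the CLI uses incremental NMB, which remains finite when a draw is
dominant).

The PSA draws every varied parameter independently — no correlation
structure is published. Costs are gamma, utilities and probabilities beta,
fitted by method of moments with sd = (spread × mean)/1.96 so that the
one-way range is an approximate 95 % interval (the published analysis
states families and ranges but not variances; this mapping is the
package's choice). Disutilities are sampled as beta on the magnitude and
negated; transition rates are mapped to per-cycle probabilities, sampled
beta, and mapped back, which keeps draws in the valid domain by
construction (a rejection-resampling guard with a logged count backs the
rare numerically infeasible draw; more than 1 % rejections aborts). The
beta sd is capped just inside the feasibility bound √(m(1−m)). Zero-valued
parameters are held fixed — they admit no gamma/beta fit. With all spreads
zero the PSA reproduces the base case exactly, and a fixed seed gives
byte-identical outputs.

CEAC probabilities are the fraction of draws in which a strategy attains
the maximal NMB, with exact ties split equally; they sum to one across
strategies at every WTP. Quadrant summaries place boundary draws (a delta
of exactly zero) on the favourable side.

## Synthetic data and validation oracles

The trial generator draws, per patient, independent exponential times for
progression, transformation and death and records the earliest event
before the administrative censoring horizon (11.3 years; staggered entry
is not modelled). This is exactly the data-generating process under which
the model's constant-rate assumption is true, so parameter recovery tests
measure only the estimator's properties, not model misspecification. What
passing these tests does **not** show: robustness to time-varying hazards,
informative censoring, or patient heterogeneity present in real trial
data.

The microsimulation oracle pushes 100,000 individuals through the
identical per-cycle transition matrices and accumulates the identical
rewards (per-individual trapezoidal utility averaging, one-off costs at
state entry, Bernoulli adverse events), so its sample means estimate
exactly the cohort engine's expectations; agreement within 3 Monte-Carlo
standard errors on the packaged configuration is the package's strongest
correctness argument, standing in for the original (unavailable)
decision-tree implementation.

## Numerical choices and degenerate inputs

* Rate↔probability conversions use `expm1`/`log1p`; the round trip is
  exact to 1e-12 over the tested grid.
* Row sums are validated to 1e-10 at matrix construction and cohort mass
  to 1e-10 every cycle.
* A probability of exactly 1 cannot be converted back to a rate (infinite
  hazard) and raises; life-table qx = 1 yields a per-cycle probability of 1
  directly.
* Ages outside the life table raise rather than extrapolate.
* With equal QALYs and unequal costs the ICER is reported as signed
  infinity (dominant if cheaper, dominated if dearer); with both deltas
  zero the pair is indifferent (ICER NaN). In the cost-saving/QALY-losing
  quadrant the WTP verdict follows the sign of the incremental NMB.
* The efficiency frontier removes strictly dominated strategies, then
  extendedly dominated ones (non-increasing incremental ICERs along the
  frontier).

## Problem sizes

The default test suite runs the cohort engine (30 cycles, 6 states)
everywhere; the oracle-equivalence check uses 100,000 simulated patients,
distribution and recovery checks use 100,000 draws, and in-suite PSAs use
40–200 iterations; the acceptance script's PSA uses the full 1000
iterations of the published design. These sizes give Monte-Carlo standard
errors comfortably below the tested tolerances.

## Known limitations

* Strict base-case reproduction of the published per-strategy cost totals
  is not possible from printed inputs alone: with one-off retreatment and
  transplant costs (and follow-up costs explicitly excluded from the
  costing perspective), lifetime RT-arm costs cannot reach the published
  $43,994, and the downstream savings of RT+R-CVP cannot exceed its
  front-line cost increment once discounted. The reconstructed model
  therefore finds RT+R-CVP strongly cost-effective (ICER ≈ $1.9k/QALY,
  highest NMB at $50,000/QALY, ~100 % of PSA draws favourable) but not
  strictly cost-saving, whereas the published analysis reports dominance;
  the QALY side reproduces closely (gain vs RT 0.956 here vs 0.711
  published; CVP-vs-RT gain 0.186 vs 0.180).
* Transformation is modelled from FFS only; relapse-to-transformation is
  not allowed (not stated in the published description).
* One common post-failure mortality rate covers three clinically distinct
  states.
* The cohort age gate is all-or-nothing at 65; an age-distributed cohort
  would transplant a fraction.
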