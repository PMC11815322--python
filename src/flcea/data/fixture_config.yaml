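# Base-case parameter set: 2022 AUD, Australian tax-payer perspective.
# Provenance of every input is annotated at the bottom; "reconstructed"
# marks values not printed in any public source and chosen by this package
# (see docs/methods.md), "synthetic" marks generated stand-in data.

model:
  cycle_length: 0.5        # years
  n_cycles: 30             # 15-year horizon
  discount_rate: 0.05      # per annum, costs and QALYs
  wtp: 50000               # AUD per QALY
  start_age: 50
  sex: male
  currency_year: 2022

costs:
  rt_simulation: 739.35
  rt_planning: 3448.10
  rt_fraction: 190.35
  rt_verification: 79.70
  rt_n_fractions: 15
  drug_rituximab: 562.00
  drug_rcvp: 811.18
  drug_cvp: 249.18
  drug_rchop: 923.28
  day_care: 110.80
  n_cycles_systemic: 6
  asct: 45638.63
  adverse_event_admission: 5000.00
  pegfilgrastim: 142.00

utilities:
  u_ffs: 0.88
  u_progressed: 0.74
  d_rt: -0.05
  d_systemic: -0.15
  d_asct: -0.20

median_followup: 11.3      # years, all arms

arms:
  RT:
    n: 75
    progressions: 38
    transformations: 11
    deaths: 13
  RT+CVP:
    n: 44
    progressions: 22
    transformations: 4
    deaths: 5
  RT+R-CVP:
    n: 31
    progressions: 5
    transformations: 1
    deaths: 1

# Annual death rate from disease after first failure (applies in the
# failure, transformation and post-transplant states).
post_failure_death_rate: 0.05

# First-cycle grade >=3 adverse-event incidences per strategy.
adverse_events:
  RT:
    admission_incidence: 0.0
    pegfilgrastim_incidence: 0.0
  RT+CVP:
    admission_incidence: 0.10
    pegfilgrastim_incidence: 0.20
  RT+R-CVP:
    admission_incidence: 0.10
    pegfilgrastim_incidence: 0.20

life_table: life_table_male_synthetic.csv

provenance:
  model: printed
  costs: printed
  utilities: printed
  arms: printed
  median_followup: printed
  post_failure_death_rate: reconstructed
  adverse_events: reconstructed
  life_table: synthetic
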