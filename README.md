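# rhinosim

An economic-ecological simulation of rhino-horn trafficking and its impact
on South Africa's white rhinos (*Ceratotherium simum simum*). The package
is for conservation scientists and policy analysts who want to compare
anti-trafficking strategies — stepped-up anti-poaching patrols, demand
reduction campaigns, legal horn trade, and transnational disruption of the
criminal syndicates that run the supply chain — by their consequences for
rhino abundance and extinction risk over a 35-year horizon.

## The model

Two coupled sub-models run on a 12-week/weekly clock.

**Market (agent-based).** A pool of `n_pc` Asian consumer groups enters the
market each week as `N_c ~ Binomial(n_pc, 1 − p_m)`, where `p_m` is the
effectiveness of a demand-reduction campaign; each group buys 1 kg of horn
from the cheapest trader asking no more than the $60,000/kg reserve price.
The illegal trader (a meta-firm for the whole syndicate) restocks by
ordering poaching: `q_m` kg of demand implies `q_m / 5` attempted rhinos,
capped at 20 + 10 per week (Kruger + private ranches), with each
expedition intercepted with probability `p_a`; weekly orders above 30 are
cut 5% (the SEAR donation effect). A 5% hoarding rate diverts supply to a
speculation stockpile, selling below the $5,000/kg unit cost is forbidden,
and intra-syndicate prices evolve by ask-and-bid squeezing superimposed on
demand-driven growth.

**Population (individual-based).** Every rhino carries age, sex, an
energetic budget in weeks of reserve, a patch in one of two sub-regions,
and a calving clock. Rainfall, as a scaled proxy of available vegetation,
drives energetics and, with local density, the weekly calving probability
of eligible females (2.5-year intercalving floor). Each week the `m`
animals ordered by the market are removed at random from the mature
population. Ensembles of seeded replicates yield expected abundance and
extinction probability per week.

A policy scenario is the vector `(p_a, p_m, t, disruption)`; the ten
presets cross five strategies with and without criminal-network disruption
(which forces `p_a = 0.60`).

## Worked example

Validation statistics from the packaged survey table, then two scenario
ensembles:

```bash
$ rhinosim validate
{
  "fixture_mape_pct": 12.2,
  "fixture_ci_coverage": 9,
  "n_surveyed_years": 13
}

$ rhinosim run --scenario status_quo --horizon 35 --reps 2 --seed 1 --out out/sq
status_quo: final mean abundance 0, extinction probability 1.00

$ rhinosim run --scenario integrated_disruptive --horizon 35 --reps 2 --seed 1 --out out/int
integrated_disruptive: final mean abundance 15524, extinction probability 0.00
```

The first block says the model's hindcast of 1998-2012 abundance differs
from the aerial-survey estimates by 12.2% on average (mean absolute
percentage error over the 13 surveyed years) and falls inside the surveys'
95% confidence intervals in 9 of 13 years. The two runs show the headline
dichotomy: under the status quo (`p_a = 0.10`) the population collapses to
extinction within the horizon, while the integrated disruptive policy
(`p_a = 0.60`, demand reduction, legal trade) holds abundance at about
15,500 — at or above its 2014 starting value of 15,100 — with zero
extinction risk across replicates. Each output directory contains per-
replicate weekly trajectories, an ensemble summary, and a manifest with
seeds and a parameter hash; reruns are byte-identical.

`rhinosim sweep --config grid.yaml --out sweep.csv` scores a scenario grid
one row per scenario, and `rhinosim fixtures --export DIR` writes the
packaged empirical tables (supply-chain prices, Asian population
projections, poaching counts and retail prices, exchange rates, model
parameters, observed vs predicted abundance) as CSV.

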