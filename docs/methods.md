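# Methods

`rhinosim` couples an agent-based model of the rhino-horn market to an
individual-based model of the South African white-rhino meta-population and
uses the coupled system to score anti-trafficking policy scenarios. This
note records the model's assumptions, the parameters that matter, the
numerical choices, and what the tests do and do not establish.

## The coupled clock

The economic sub-model advances in 12-week cycles; the population sub-model
advances weekly. Each cycle the market converts consumer demand into a
poaching order: `q_m` kilograms wanted implies `q_m / 5` attempted rhinos
(a poached pair of horns weighs about 5 kg), attempts are capped at 20 per
week in Kruger National Park (KNP) plus 10 on private ranches, each attempt
is independently intercepted with probability `p_a`, and any week still
above 30 animals is cut by 5% (the SEAR donation effect). The resulting
integer weekly orders `m` are consumed by twelve weekly population steps;
the animals actually killed return to the market as `5 q_p` kilograms of
horn at the next cycle boundary. Supply is split 95% to sale inventory and
5% to a speculation stockpile that is never sold.

## The market

Two traders (one illegal; a legal one when the policy allows trade) face a
weekly pool of `n_pc` potential consumer groups; each group represents
roughly 18-30 real buyers and purchases exactly 1 kg from the cheapest
trader asking at or below the $60,000/kg reserve price. Entry is
`Binomial(n_pc, 1 - p_m)`, where `p_m` is demand-reduction campaign
effectiveness. The pool is 300 groups in 2014, growing with projected Asian
population to a hard cap of 325 in 2033. Whether the pool should halve when
no legal-trade channel exists is genuinely open (the 300 = 5 x 2 x 30
construction already embeds a legal-trade doubling); the default keeps 300
for every scenario and exposes `consumer_pool_halved_without_trade`.

Traders never sell below the $5,000/kg unit cost (no dumping; the cost
itemizes as $1,750 paid to poachers + $2,000 courier airfare + $100/kg
courier fee = $3,850, held conservatively at $5,000). Consumer asks adjust
multiplicatively with learning rate `r_a = 0.4` toward excess demand or
glut. Intra-syndicate prices combine two motions each cycle: a
market-level drift `g = 1.030 + 0.016 x` (with `x` the previous cycle's
unmet-demand fraction) applied to the whole chain, and an ask-and-bid
squeeze in which poachers raise their ask and the retailer lowers its bid
by 2% each, eroding the middleman's margin share until it floors at zero.
The 2% increment was calibrated so that a 2006-era chain traverses the
observed per-year poacher price corridors through 2013 and middleman-to-
retailer prices stay inside the observed $3,703-$18,299/kg envelope; 1%
increments push the retailer bid out of that envelope before 2013 under
any single drift consistent with the poacher series.

The per-cycle trader capacity of 35 horns bounds the legal trader's
replenishment (stockpile shavings, never poached horn). The illegal
trader's intake is its own poached supply, so the analogous bound is inert
in practice.

## The population

Each rhino carries age (weeks), sex, an energetic budget measured in weeks
of reserve (maximum 5, adults initialized at 4, juveniles at 3), a patch in
one of two sub-regions (KNP and private ranches, four closed patches each),
a weeks-since-calving clock, and a status. Initial ages are Gaussian
(mean 7.5 y, SD 3 y) truncated to [1 week, 38 y]; calving clocks are
staggered over one expected calving cycle so the initial population is not
synchronized.

Weekly, in order: ageing; energetics (per-capita food share relative to the
140 kg/week intake need replenishes or draws down the budget by the
surplus/shortfall fraction, with individual foraging noise of SD 0.30;
an exhausted budget is death); old-age and background natural death;
density- and vegetation-dependent calving; random removal of `m` mature
(age >= 4 y) animals by poaching, reported short if too few matures exist.
Poaching has a demographic echo: a calf still dependent on its mother
(younger than two years) is orphaned with the same probability that adult
females were removed from its sub-region that week, and orphans do not
survive — the well-documented fate of dependent white-rhino calves. This
is implemented statistically (random mother assignment) rather than by
tracking mother-calf links.

Food share uses rainfall as a vegetation proxy: each patch feeds
`capacity x (av / mean_av)` rhinos fully, with capacities 4,790 (KNP) and
2,055 (private) per patch — a total ceiling of roughly 27,400 at mean
rainfall. Rainfall is a quasi-periodic harmonic (annual cycle plus a slow
decadal modulation plus noise, clipped at zero); its published source
equation is not available, so the coefficients here are stand-ins chosen
for a realistic weekly scale (~0-4 cm) and are exposed in
`RainfallParams`.

Demographic rates are the model's calibration surface. Eligible females
(mature, past the 2.5-year intercalving interval, with at least one adult
male in the sub-region) calve weekly with probability
`b0 x f_veg x f_dens`, where `f_veg` is a saturating ramp in food share and
`f_dens = 1 / (1 + exp((x - 0.525) / 0.0827))` declines logistically in
relative patch density `x = n/K`. Background natural mortality is
`1.8e-4 + 3.6e-4 x^2` per week. With `b0 = 0.0176` these choices reproduce
the region's quantitative anchors simultaneously:

* at 2014 densities (~15,100 animals) an undisturbed population realizes
  ~7.8%/yr births and ~1.7%/yr natural mortality, inside the recorded
  7-8.5% and 1-2% bands;
* at late-1990s densities the population grows ~10%/yr, which carries the
  1998 abundance of 2,674 to the neighbourhood of the surveyed 1998-2012
  series (30-seed mean MAPE ~20%);
* without poaching the population is sustainable over 35 years, saturating
  around 17,600.

The mate-availability requirement and orphan mortality matter mostly in
end-game dynamics: once poaching has removed a sub-region's mature animals,
remaining females stop producing calves, dependent calves follow their
mothers, and the remnant dies out rather than persisting indefinitely as a
handful of unpoachable juveniles.

Management removals (<0.5%/yr historically) are ignored; there is no
dispersal between patches, no black-rhino population, and no genetics.

## Scenarios and epochs

A policy scenario is `(p_a, p_m, t, disruption)`. Interception presets:
0.04 (realized; derived from 174 arrests among an estimated 4,329 poacher
entries in 2014), 0.10 (optimistic status quo), 0.20 (pro-active
protection), 0.60 (criminal-network disruption plus legal economic
opportunities; `disruption = true` forces this value). `p_m` is 0.15 when
a demand-reduction campaign runs, else 0. Scenario runs start at the 2014
parameter epoch from 10,600 KNP + 4,500 private animals (the 2012 census
anchors, rounded) and cover 35 years.

Validation (hindcast) runs start at the observed 1998 estimate of 2,674,
split 70:30 between the sub-regions in proportion to the 2012 ownership
shares, and use `p_a = 0.04`. The historical demand side is anchored to
the recorded annual poached counts: the weekly consumer pool is sized so
that demand-led restocking, thinned at 4%, reproduces the observed
offtake (about 13/yr before the 2009 escalation — a documented stand-in
for unpublished pre-2009 records; fractional pools draw Poisson entries).
This anchoring parameterizes the demand scale only; prices, inventories,
poaching success, and the population trajectory remain emergent.

Extinction is abundance reaching zero (a configurable quasi-extinction
threshold defaults to 0). Ensembles seed replicates as `base_seed + i`.

## Problem sizes and tolerances

Default analysis sizes: 30 hindcast seeds; 50 replicates per scenario for
35-year ensembles; 10^5 draws for the consumer-entry moments. Trajectory
output rounds abundances to integers and prices to 2 decimals so reruns
from a manifest are byte-identical. Ties in market clearing resolve in
listing order; SEAR rounding is half-up; the 12-week order's remainder
lands on the earliest weeks; the SEAR cut lands on the KNP share.

## What the tests do and do not show

The synthetic-data generators (rainfall, initial populations, demand) are
the study's conditions, not observations. Passing tests establish internal
consistency with the published anchors — printed tables, rate bands, the
observed price envelope, and the qualitative scenario dichotomy (all
non-disruptive policies carry strictly higher 35-year extinction risk than
every disruption-backed policy, which holds the population at or above its
initial size). They do not establish forecasting skill for real rhino
abundance: the rainfall coefficients are stand-ins, demand is anchored
rather than estimated, and the published collapse years (2027/2028/2037)
depend on unpublished calibration detail and are deliberately not targets.
The hindcast MAPE band (<= 25%) is a property check, looser than the
published 12.2% fit, because the original birth/death response surfaces
are not printed.
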