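# Methods

`farmscape` is a discrete-time agent-based model of enterprise change on
a farmed catchment. One farmer agent operates each cadastral parcel and,
every 5-year step, receives the profit-maximising enterprise for the
farm from an economic sub-model, then decides stochastically whether to
act on it. Land use responds to a greenhouse-gas price, to a
generational succession cycle, and to information flowing through two
farmer networks. This note records the model's assumptions, parameters
and the design choices that were genuinely open.

## Model structure

**Landscape.** Parcels live on a 25-ha raster; a parcel is a contiguous
cell block with a single enterprise — Dairy, Sheep & Beef, plantation
Forestry or Carbon Forestry — and a productivity zone (Plains,
Foothills, Hills; mapped from Land Use Capability classes 1–4, 5–6 and
7–8 respectively). Farmer agents exist only on commercially farmed
parcels: area strictly greater than 100 ha (a 100.0-ha block is a
lifestyle property, not a farm) and an initial enterprise among the
three mainstream uses. Crown land and unrecognised land uses carry no
agents. Geographic adjacency is rook contiguity (shared cell edge, or
shared boundary of positive length for polygon inputs); corner contact
does not make neighbours, which avoids degenerate one-point
neighbourhoods.

**Economics.** Each (enterprise, zone) pair carries an annualised
per-hectare budget. Expected net revenue of enterprise *e* on a farm of
area *A* in zone *z* at step *t* under carbon price τ (NZD/tCO2e) is

    NR = A · [ r(e,z) · (1+g)^(5t) − c(e,z) − τ·m(e,z) + τ·s(e,z) ]

with commodity revenue *r* growing at g = 2 %/yr real, costs *c* held
in real terms, livestock emissions *m* taxed and Carbon Forestry
sequestration *s* paid, mirroring the Emissions Trading Scheme's
incidence: rotational plantation forestry neither pays nor is paid
(m = s = 0). The per-farm optimiser is a plain argmax over feasible
budgets — the farm-level answer a partial-equilibrium land-use model
would return to each agent. Exact ties keep the current enterprise if
it is among the maxima, otherwise the first enterprise in the fixed
order Dairy < Sheep & Beef < Forestry < Carbon Forestry. The levy is
applied to per-hectare emissions directly rather than through processor
output pricing; at farm level the incidence is the same.

Forestry cash flows are annualised rather than modelled as
rotation-age cash-flow profiles; the rotation length is carried instead
by the behavioural lock-in (below). Catchment environmental accounts
(gross GHG, sequestration, net GHG = gross − sequestration, N leaching,
P loss) are sums of area × per-ha export coefficients.

**Decisions.** Every agent starts each decision at conversion
likelihood 0.2 (reset after every decision). If the proposal differs
from the current enterprise the likelihood is adjusted by the two
networks, constrained, clamped to [0, 1] and compared with a uniform
draw:

* *Endorsement* (±0.1): the agent compares its profitability/ha with
  the equally-weighted mean of its social network — the 10 closest
  farmers (Euclidean centroid distance, ties to the lower parcel id)
  running the same enterprise. Above the mean → −0.1; below → +0.1;
  exactly equal or no peers → 0.
* *Imitation* (±0.05): the same comparison against adjacent farms
  already running the *proposed* enterprise; deliberately half the
  endorsement weight (passive observation versus an active peer
  network). Comparisons read profitabilities and enterprises as of the
  start of the step (synchronous read, asynchronous write), so the
  within-step evaluation order — a fresh seeded shuffle each step —
  cannot leak information.
* *Constraints*: a farm that converted into Forestry or Carbon
  Forestry is locked for 5 steps (25 years, the minimum economic stand
  age) — its conversion likelihood is forced to 0; a proposed
  conversion **to** Dairy keeps only 25 % of its likelihood, standing
  in for the up-front capital and lifestyle costs of dairy conversion,
  which are not modelled as cash flows.

With networks off both adjustments are computed as exact zeros rather
than skipped, so the decision pipeline is structurally identical in
both experiment arms; the final likelihood can then only be 0 (locked),
0.05 (Dairy-penalised) or 0.2.

**Demography.** Farmers move through a five-stage life-cycle, one stage
per step by default. Entering Stage 1 triggers a succession assessment:
a successor is found with probability 0.75. Completing Stage 5 with a
successor restarts the cycle on the same farm (the successor takes
over and runs their own Stage-1 assessment); without one the farm is
sold at the end of the step. The buyer is always a new agent created at
Stage 1 with base likelihood, inheriting the farm's running operation
and its current profitability; they immediately re-evaluate the land
use once at base likelihood with constraints applied but no network
input — the minimal mechanism that gives a sale its chance of a
land-use shift without inventing preference heterogeneity. The buyer's
own succession assessment happens at their first life-cycle advance;
intermediate stages are pass-through. Initial stages at t = 0 are
uniform over 1–5 (seeded), and every initial farmer gets an initial
successor draw, avoiding synchronised sale waves.

## Parameters

| Parameter | Default | Units / note |
|---|---|---|
| steps × step length | 10 × 5 yr | 50-year horizon |
| commodity price growth | 0.02 /yr | milk, meat and timber revenue only |
| base conversion likelihood | 0.2 | reset after every decision |
| endorsement / imitation delta | 0.1 / 0.05 | imitation half-weighted |
| social network size k | 10 | closest same-enterprise farmers |
| Dairy proposal penalty | 0.75 | likelihood × 0.25 |
| forest lock-in | 5 steps | 25 years |
| succession success rate | 0.75 | Stage-1 assessment |
| farm-size floor | 100 ha | strict inequality |
| carbon price grid | $0–60 by $10 | × network toggle × 50 seeds = 700 runs |

## Default calibration

Region-specific farm budgets for the modelled catchments are not
publicly available, so the shipped coefficient table is an
**uncalibrated placeholder** that reproduces qualitative orderings
only: Dairy is the most profitable use on Plains and Foothills and
infeasible in the Hills; Forestry out-earns Sheep & Beef in the Hills;
Carbon Forestry has no commodity revenue, so its flat carbon income
(τ · s) competes with timber returns only at carbon prices near the
top of the studied range, and — because timber revenue grows with the
commodity index while the carbon price is constant per scenario — only
in the early periods of a run. A sharp "enters exactly at $60"
threshold cannot hold at every step under 2 %/yr revenue growth; the
crossover price drifts upward with the index, which we document rather
than hide. Absolute revenue, emission and nutrient magnitudes are
placeholders; catchment-level totals produced under this table are
internally consistent but not calibrated to any real catchment, and
users with farm budget data should supply their own table (CSV with
the same columns).

## Synthetic catchment

The generator emulates the structure of a hill-country South Island
catchment: a rectangular grid of 25-ha cells (default 50 × 80 =
100,000 ha — a deliberately scaled-down study area that keeps a
700-run ensemble cheap), three horizontal zone bands (Plains 30 %,
Foothills 30 %, Hills 40 %), seeded region-growing partition into
contiguous farms with log-normal target sizes (mean 10 cells = 250 ha,
σ_log = 0.6, truncated at 4 cells), and initial enterprises drawn per
farm from zone shares dominated by Sheep & Beef (Plains 15/80/5 %
Dairy/Sheep & Beef/Forestry; Foothills 5/90/5; Hills 0/85/15). The
landscape seed is fixed (default 101) independently of the run seed:
the catchment is part of the study setup, so ensemble runs share
parcels and per-parcel probabilities are well defined; set it to null
to draw the landscape from the run seed.

What the generator does **not** emulate: real cadastral geometry and
road patterns, spatial autocorrelation of soil quality within zones,
multi-parcel ownership, irrigation command areas, and any correlation
between farm size and enterprise. Passing tests on synthetic
catchments therefore demonstrate the mechanisms (economics, networks,
succession, lock-in) and their directional consequences, not
calibrated magnitudes for any real catchment.

## Numerics and reproducibility

A run is a pure function of (config, seed). The seed feeds a
`SeedSequence` split into four named substreams — landscape,
initialisation, decisions, demography — so toggling one mechanism does
not shift another's draws; the network toggle consumes no draws at
all, making on/off arms seed-paired. Ledgers from identical (config,
seed) pairs are byte-identical. Likelihood clamping to [0, 1] is
applied after summing deltas (the defaults cannot exceed 0.35, so
clamping only matters under user-modified parameters). Ensemble
summaries use the normal approximation (mean ± 1.96 sd/√n); runs are
sorted deterministically before aggregation so float accumulation does
not depend on execution order.

## Known limitations

Single enterprise per farm; no within-farm management options,
irrigation development, climate or technology change; no farm
amalgamation (a sold farm always goes to a new agent — the conditions
for a neighbour purchase are unspecified); no conversion capital costs
beyond the Dairy likelihood penalty; no equilibrium feedback from
aggregate land-use change to prices; unweighted network stature.
Table-style catchment totals are calibration-dependent and should not
be read as predictions.
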