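# farmscape

Agent-based simulation of rural land-use change under greenhouse-gas
pricing.

Rural catchments change land use slowly, farm by farm, through
decisions that mix economics with family circumstance and what the
neighbours are doing. `farmscape` models this directly: one farmer
agent per cadastral parcel decides, every 5-year step over a 50-year
horizon, whether to convert among **Dairy**, **Sheep & Beef**,
**plantation Forestry** and **Carbon Forestry** under a carbon price
τ (NZD/tCO2e) levied on livestock emissions and paid for permanent
forest sequestration, as in New Zealand's Emissions Trading Scheme.
It is aimed at land-use and environmental-policy modellers who want a
transparent, fully reproducible sandbox for exploring how carbon
prices, farmer social networks and generational succession interact
to shape land use, farm income, greenhouse-gas balances and nutrient
losses.

## The model in brief

Each step, every farm of area *A* in productivity zone *z* receives
the enterprise maximising expected net revenue

    NR(e) = A · [ r(e,z)·(1+g)^(5t) − c(e,z) − τ·m(e,z) + τ·s(e,z) ]

(revenue *r* grows at g = 2 %/yr real; *m* = livestock emissions,
taxed; *s* = Carbon Forestry sequestration, paid; plantation Forestry
has m = s = 0). A proposal differing from the current enterprise is
adopted with probability

    L = clamp[ 0.2 + endorsement (±0.1) + imitation (±0.05) ],

where endorsement compares the farmer's profitability/ha with the 10
closest same-enterprise peers and imitation with adjacent farms
already running the proposed use; a new forest is locked in for 5
steps (25 years) and a proposed Dairy conversion keeps only 25 % of
its likelihood. Farmers age through a five-stage life-cycle with a
75 % succession success rate; successor-less farms are sold to new
operators who reconsider the land use once. The experiment engine
sweeps τ = $0–60 crossed with a network-effects toggle over 50 seeds
(700 runs) and reports ensemble means with 95 % CIs, zone-level
land-use shares with network-on/off deltas, and per-parcel enterprise
probabilities.

See `docs/methods.md` for assumptions, parameters and limitations.

## Worked example

```python
import farmscape as fs

cfg = fs.ModelConfig()             # synthetic ~96,800 ha catchment, 310 farms
cfg.market.ghg_price = 60.0        # $60/tCO2e scenario
traj = fs.run(cfg, seed=1)

print(traj.series("net_ghg").iloc[[0, -1]])
led = traj.ledger
for ent in ("Dairy", "SheepBeef", "Forestry", "CarbonForestry"):
    area = led[(led.variable == "area_ha") & (led.enterprise == ent)]
    by_step = area.groupby("step").value.sum()
    print(f"{ent:15s} {by_step.iloc[0]:9.0f} -> {by_step.iloc[-1]:9.0f} ha")
```

prints (seed 1):

```
step
0     282620.0
10    270222.5
Name: value, dtype: float64
Dairy                5700 ->     27850 ha
SheepBeef           81675 ->     27600 ha
Forestry             9425 ->     35150 ha
CarbonForestry          0 ->      6200 ha
```

Net emissions fall from 282,620 to 270,222 tCO2e/yr over the 50-year
horizon even as Dairy expands on the better land, because Sheep & Beef
hill country shifts into forestry and, under the $60 price, 6,200 ha of
permanent carbon forest (49,600 tCO2e/yr of sequestration) is
established. Magnitudes reflect the uncalibrated default budgets — the
directions, not the numbers, are the point.

From the shell:

```bash
farmscape run --seed 1 --out results/single      # one run, ledger CSVs
farmscape experiment --out results/grid --jobs 4 # 700-run scenario grid
```

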