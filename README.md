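# codevo

Individual-based eco-evolutionary simulator of Northeast Arctic (NEA) cod
(*Gadus morhua*) under concurrent fishing pressure and climate warming.

Fisheries remove large fish and select for earlier maturation at smaller
size; warming changes metabolic rates and, for a cold-water stock like NEA
cod, *widens* aerobic scope. `codevo` simulates individual fish through
annual cycles — energy acquisition under density dependence, an explicit
oxygen budget, growth, probabilistic maturation, six mortality components
including gear-selective fishing, and Beverton–Holt recruitment with
mid-parent inheritance of two traits — so that life histories and
population dynamics *emerge* from selection on lifetime reproductive
output rather than being imposed. It is aimed at researchers in
fisheries-induced evolution and eco-evolutionary modelling who want a
compact, fully scriptable testbed for fishing × warming interactions.

## Model core

Each fish carries two heritable traits:

- **Appetite** — a genetic scaling of target annual energy intake
  (J yr⁻¹). Realising the target takes foraging effort that rises when
  population biomass `B` depresses food availability
  `a(B) = 1/(1 + B/B_half)`, and effort carries both an energetic cost and
  a predation-exposure cost.
- **PMRN intercept** — the intercept (cm) of a probabilistic maturation
  reaction norm. An immature fish of length `L` and age `t` matures with
  probability `logit⁻¹((L − Lp50)/s)`, `Lp50 = intercept + slope·t`;
  higher intercepts mean later maturation at larger size.

Metabolic costs follow an allometric Q10 form; an oxygen budget converts
energy spent to oxygen demand and caps expenditure at a maximum uptake
whose temperature response is dome-shaped, so aerobic scope increases with
warming over 4–12.4 °C. Mortality is the sum of six instantaneous
components (fixed, predation, foraging, reproduction, respiration,
fishing), with annual survival `exp(−ΣM)`. Fishing mortality is
`F = F_max · U(L)`: each year 70% of individuals face a trawl
(`U_T`, half-Gaussian saturating at 1 above `L_max = 110 cm`) and 30% a
gillnet (`U_G`, Gaussian bell with `σ = 0.28·L_max`). Recruits arise from
total egg production via `R = αE/(1 + E/β)`; each recruit draws two
parents weighted by gonad mass and inherits mid-parent trait values plus
segregation noise, expressed with an environmental deviation calibrated so
the emergent mid-parent/offspring regression slope (h²) sits near 0.2.

Climate scenarios follow a saturating ramp from 4.0 °C to stabilised
means of 4.8 °C (SSP1), 7.0 °C (SSP2) or 12.4 °C (SSP3) within 100–500
years, plus interannual noise; `baseline` stays at 4.0 °C.

## Worked example

```python
from codevo import (ModelConfig, FisheryConfig, RunSpec, get_scenario,
                    spin_up, run_scenario, summaries)

cfg = ModelConfig().scaled(0.4)          # desk scale: ~2,000 fish
cfg.run.spinup_years = 600
pop, diag = spin_up(cfg, seed=3)         # equilibrate at F_max=0.2, 4 °C
print(pop.n, round(pop.total_biomass, 1))
# 1869 5143.0

spec = RunSpec(config=cfg, scenario=get_scenario("SSP2", noise_sd=0.5),
               fishery=FisheryConfig(f_max=0.2), years=300, replicates=4,
               seed=7, initial=pop)
runs = run_scenario(spec)
sums = [log.summary_frame() for _, log in runs]
print(summaries.maturation_summary(sums, window=100))
#             statistic       mean        sd
#     age_at_maturation   3.740169  0.037259
#  length_at_maturation  69.875753  0.380101
```

The spin-up returns an equilibrated snapshot of 1,869 fish (5,143 kg) and
stationarity diagnostics for the two trait means. After 300 years of SSP2
warming at moderate fishing, newly maturing fish average 3.74 years and
69.9 cm (mean ± SD across the four replicates); growth is faster and
maturation later than in the no-warming baseline, while raising `f_max`
pushes maturation earlier and shrinks the stock. Length-at-age, maturity
ogives, age structure, mortality decomposition, trait means and emergent
heritability come from the same `summaries` functions, or from the CLI:

```bash
codevo spinup --config cfg.yaml --out spin/
codevo run --config cfg.yaml --snapshot spin/snapshot.csv \
           --scenario ssp2 --fmax 0.2 --out runs/
codevo grid --snapshot spin/snapshot.csv --out grid/   # 4 scenarios × 4 F_max
codevo summarize --runs runs/ --out tables/ --plots
```

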