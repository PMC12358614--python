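# Methods

`codevo` is an individual-based, annual-step simulator of a long-lived
demersal fish stock (parameterised with Northeast Arctic cod in mind)
with two heritable traits and explicit energy and oxygen budgets. This
note documents the model equations, the defaults and why they were
chosen, what the synthetic populations do and do not emulate, and the
numerical conventions.

## Annual cycle

Within one model year each fish passes through, in order:

1. **Food availability** from total somatic biomass,
   `a(B) = 1/(1 + B/B_half)`.
2. **Foraging.** Target intake is `appetite · c_intake · W^b_intake`.
   Desired effort is `target / (a · c_intake · W^b_intake)`, i.e.
   `appetite / a`; effort is then capped by a hard ceiling and by the
   oxygen budget (below), and realised intake is
   `effort · a · c_intake · W^b_intake`.
3. **Metabolism.** `SMR = c_smr · W^b_smr · Q10^((T−T_ref)/10)`;
   total cost `SMR·(1 + c_act·effort)`.
4. **Allocation and growth.** Net energy goes entirely to soma if
   immature; mature fish allocate a gonad fraction
   `r = min(r_initial + r_slope·ypm, r_cap)` (ypm = years post
   maturation). Somatic energy converts to mass at `e_soma`; length
   follows `L = (W/k_cond)^(1/3)` and never shrinks. Negative net energy
   is paid from soma; a fish whose weight falls below
   `condition_floor · k_cond·L³` starves deterministically.
5. **Maturation.** Immature fish mature with probability
   `logit⁻¹((L − Lp50)/s)`, `Lp50 = intercept + slope·age`,
   `s = width/(2 ln 3)` so the envelope width is the length span between
   25% and 75% probability. Maturity is absorbing.
6. **Mortality and survival.** Six instantaneous components (below) add;
   survival is a Bernoulli draw at `exp(−ΣM)`.
7. **Reproduction.** Survivors' gonad energy becomes eggs
   (`E = gonad energy / egg_energy`); expected recruits follow
   Beverton–Holt `R = αE/(1 + E/β)` with stochastic rounding (floor plus
   Bernoulli on the fraction) to keep the expectation unbiased. Each
   recruit draws two parents independently, with replacement, weighted by
   current gonad mass; traits are mid-parent values plus Gaussian
   segregation noise, and the lifetime phenotype adds an environmental
   deviation drawn once. Gonads are spent and reset.
8. **Ageing.** Survivors age one year; fish past age 20 die. Recruits
   enter the next year at age 1 (size 20 cm, 0.08 kg) and first face
   mortality as one-year-olds.

This ordering makes the current year's gonads determine both reproductive
mortality and parental weighting, and keeps recruits out of their natal
year's mortality.

## Oxygen budget

Energy metabolised converts to oxygen demand through the oxycalorific
coefficient (13.6 J per mg O₂). Maximum uptake is
`MMR = c_mmr · W^b_mmr · g(T)` (energy units) with a Gaussian dome
`g(T) = exp(−(T−t_peak)²/(2·t_width²))`, `t_peak = 14 °C`,
`t_width = 6 °C`. The dome peak sits above the warmest scenario mean so
absolute aerobic scope (MMR − SMR) rises monotonically over 4–12.4 °C for
all body sizes and tightens as the warmest scenario approaches the peak.
Effort is capped so metabolic cost never exceeds MMR (usage ratio ≤ 1);
exhaustion mortality is convex in the usage ratio, so warming — by
raising MMR faster than SMR — simultaneously permits higher intake and
lowers natural mortality. At 4 °C the oxygen cap binds for most fish;
this is the mechanism through which warming releases both growth and
survival in the model.

## Mortality components (yr⁻¹)

| component | form | default constants |
|---|---|---|
| fixed | constant | 0.02 |
| predation | `c_pred·(L/L_ref)^(−γ) + floor` | 0.07, γ=1.7, L_ref=50 cm, floor=0.01 |
| foraging | `predation · c_f · effort^ψ` | c_f=0.08, ψ=2 |
| reproduction | `c_r · GSI^η` | c_r=0.8, η=2 |
| respiration | `c_o · usage^θ` | c_o=0.05, θ=3 |
| fishing | `F_max · U(L)` | gear-specific U, below |

Predation declines steeply with size to a floor, giving large fish a
natural refuge; foraging risk is convex in effort (ψ=2) so that the
appetite trait has an interior evolutionary optimum rather than running
to the effort ceiling. Cause-of-death for the decomposition log is a
categorical draw proportional to the component rates, conditional on
death; survival itself is resolved from the summed rate (competing
risks).

Gear selectivity: each year every fish is independently exposed to the
trawl fleet with probability 0.7, otherwise the gillnet fleet. Gillnet
selectivity is `U_G(L) = exp(−(L−L_max)²/(2σ²))` with `L_max = 110 cm`
and `σ = 0.28·L_max`; trawl selectivity equals `U_G` below `L_max` and 1
at or above it. Re-drawing gear annually represents fleet-level exposure
shares rather than a lifelong assignment.

## Climate scenarios

Mean temperature follows
`T(y) = T_inf − (T_inf − T0)·exp(−3y/ramp_years)` from `T0 = 4.0 °C`,
reaching ~95% of the increase at `ramp_years`; interannual noise is
i.i.d. Gaussian (SD 0.5 °C by default, 0 for deterministic tests).
Asymptotes are 4.8 / 7.0 / 12.4 °C for SSP1/2/3 with ramps of
100 / 250 / 500 years, spanning the 100–500-year stabilisation window;
`baseline` holds 4.0 °C. The saturating-exponential ramp shape and the
noise SD are modelling choices (smooth, monotone, configurable); results
depend on the asymptotes far more than on the ramp shape.

## Genetics and heritability calibration

Both traits are transmitted as mid-parent value plus segregation noise
(SD 0.05 for appetite, 1.5 cm for the PMRN intercept) and expressed with
an environmental deviation (SD 0.1414 and 4.243 cm). Under mid-parent
inheritance the equilibrium genetic variance is roughly twice the
segregation variance, so setting the environmental variance to eight
times the segregation variance centres the mid-parent/offspring
regression slope — the emergent narrow-sense heritability — near 0.2,
the typical value for life-history traits. Simulated populations give
h² ≈ 0.20–0.23 for both traits.

The h² estimator regresses offspring phenotype on mid-parent phenotype
over the **final century** of a run. Over longer windows the slow secular
trend in trait means (see Limitations) enters both regression variables
and inflates the slope with shared temporal covariance that has nothing
to do with transmission.

## Bioenergetic allometry and calibration

The predecessor parameter table is not public, so all rate constants here
are this package's own calibration. Two structural choices matter:

- **Cost exponent above intake exponent** (`b_smr = 0.85` vs
  `b_intake = 0.70`). If intake scaled faster than maintenance, body size
  would grow without bound; this pair produces von-Bertalanffy-like
  asymptotic growth (~33 cm at age 1, ~80 cm at age 5, asymptote near
  110 cm at the fished baseline) with the oxygen cap further limiting
  very large fish at cold temperatures.
- **Recruitment vs. food competition.** The Beverton–Holt ceiling
  (`α·β = 1,200` recruits at reference scale) is set well below what the
  food supply could carry (`B_half = 15,000 kg`), so equilibrium
  availability stays near 0.55 rather than collapsing to the maintenance
  margin. This keeps adult growth fast enough that delaying maturation
  can pay, which is what gives the maturation schedule an interior
  evolutionary equilibrium under selection.

Remaining constants (SMR level ≈ 6 MJ yr⁻¹ kg⁻⁰·⁸⁵ at 4 °C, factorial
aerobic scope ≈ 1.7 at 4 °C rising with warming, egg energy 1.2 J,
condition factor 10⁻⁵ kg cm⁻³) are ordinary fish-physiology magnitudes,
fixed once during spin-up calibration for persistence, size-declining
natural mortality and demographic stationarity.

## Scale

Absolute abundance is set jointly by `bh_beta` and `B_half`;
`ModelConfig.scaled(f)` multiplies both (and the founder count) by `f`,
preserving per-capita dynamics. The reference scale equilibrates near
4,700 fish at `F_max = 0.2`; tests and the acceptance script use
`scaled(0.4)` (~1,900 fish) with a 600-year spin-up and 300-year
experiments, which keeps the full replicated grid inside a few minutes on
one CPU. Directional results (fishing pushes maturation earlier and
shrinks the stock; warming does the opposite) are stable across these
scales; absolute abundances are not comparable across scales by design.

## Synthetic founder populations

`fixtures.make_population` draws ages uniformly, lengths from a
saturating age curve with 5% jitter, weights from the cubic condition
relation, and traits from Gaussians around configurable means. It
emulates only the *structure* of a plausible stock (size spread, partial
maturity, trait variation) — not survey length compositions, cohort
effects or spatial structure. Spin-up runs discard the founder state over
hundreds of years, so tests passing on these fixtures validate the
mechanics and invariants of the simulator, not agreement with field data;
the model deliberately omits seasons, space, trophic feedbacks, maternal
effects and temperature-dependent food supply.

## Numerical conventions

- Per-individual energy conservation holds to 1e-9 relative each year:
  realised intake = cost + soma + gonads − starvation deficit.
- Randomness is a single master seed; replicate `k` uses an independently
  spawned generator (`SeedSequence(seed, spawn_key=(k,))`), so results do
  not depend on replicate execution order and identical (config, seed)
  pairs are bit-reproducible.
- Recruit counts use stochastic rounding; parent draws are with
  replacement (a lone spawner can be both parents); inherited traits are
  clamped to positive support at 1e-6.
- Empty populations propagate as valid (logged) extinction states;
  spin-up aborts with a diagnostic on extinction.
- "End of runtime" summaries average the final 200 years by default
  (configurable); replicate aggregation is mean-of-replicate-means with
  between-replicate SD.

## Known limitations

- The PMRN intercept retains a slow secular drift at the reference
  calibration (≈ −0.01 cm yr⁻¹ unfished, roughly doubled at
  `F_max = 0.2`) rather than a strict equilibrium; the spin-up reports
  the trend ± SE as a stationarity diagnostic. Treatment contrasts are
  taken against a shared snapshot, so this drift cancels out of the
  fishing × warming comparisons.
- Desk-scale populations (10³–10⁴ fish) have meaningful demographic and
  genetic stochasticity; quantities reported from single replicates
  (e.g. h²) vary by a few hundredths across seeds.
- Warming enters only through metabolic rates and the oxygen budget;
  food supply, species interactions and recruitment biology are
  temperature-independent, so warm-scenario projections describe the
  physiological channel in isolation.
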