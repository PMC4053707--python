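# mcferm

Analysis toolkit for **extreme-thermophilic (70 °C) mixed-culture
fermentation** — the open, non-sterile process in which fermenting bacteria
convert glucose to acetate and hydrogen while hydrogenotrophic methanogens
keep the hydrogen partial pressure low enough that acetate stays the
dominant liquid product and methane leaves in the gas.

It is written for bioprocess engineers and environmental biotechnologists
who need to reason quantitatively about such reactors: which hydrogen sink
wins thermodynamically at a given temperature, whether a measured product
spectrum closes its electron balance, what the steady-state yields of a
CSTR run actually were, and whether a clone library agrees with the
bioenergetic prediction.

## What it computes

**Bioenergetics** (`mcferm.thermo`). Standard-transformed Gibbs energies
ΔG°′(T) (pH 7, 1 M / 1 atm standard states, inorganic carbon as
HCO₃⁻ + H⁺) from a packaged formation table, with the linear
Gibbs–Helmholtz temperature correction

```
ΔG°′(T) = ΔG°′(T₀)·(T/T₀) + ΔH°′·(1 − T/T₀),   T₀ = 298.15 K,
```

actual reaction energies ΔG = ΔG°′(T) + RT·ln Q, and closed-form hydrogen
threshold pressures P(ΔG = 0) for the competing sinks:

* hydrogenotrophic methanogenesis: 4 H₂ + HCO₃⁻ + H⁺ → CH₄ + 3 H₂O
* homoacetogenesis: 4 H₂ + 2 HCO₃⁻ + H⁺ → acetate⁻ + 4 H₂O
* aceticlastic methanogenesis: acetate⁻ + H₂O → CH₄ + HCO₃⁻

**COD accounting** (`mcferm.cod`). Theoretical oxygen demand
ThOD = 8·(4C + H − 2O − 3N − z) g O₂/mol, yield-table closure
(Σ yᵢ·CODᵢ / COD_glucose), and the theoretical spectrum of the overall
conversion glucose → 2 acetate + CH₄ + CO₂ with an electron fraction
diverted to biomass (CH₁.₈O₀.₅N₀.₂, 33.6 g COD per C-mol).

**Reactor metrics** (`mcferm.metrics`). Steady-state CSTR yields in
mol/mol-glucose (methane via gas rate × P_CH₄ × HRT / V_m), acetate purity
of the liquid phase, fed-batch rates (OLS slope) and cumulative yields
against a pulse-feed schedule, and batch-stability verdicts.

**Community summaries** (`mcferm.community`). Clone-library relative
abundances recomputed from counts, metabolic-guild fractions, and a
consistency check of observed guild dominance against the thermodynamic
ranking.

**Synthetic data** (`mcferm.simulate`). A regime-switching,
COD-conserving generator for CSTR / fed-batch / batch series with known
latent truth, plus multinomial clone-library sampling — every estimator in
the package is testable end-to-end without external data.

## Worked example

```python
from mcferm import thermo, datasets, metrics, cod
from mcferm import simulate as sim
from mcferm.community import guild_fractions, consistency_check

# 1. Which hydrogen sink wins at 70 °C?
for s in thermo.rank_h2_sinks(343.15):
    print(f"{s.reaction.name:34s} dG = {s.delta_g:7.1f} kJ/mol")

# 2. Threshold pressures at 25 °C
rx = thermo.load_reactions()
print(f"{thermo.h2_threshold(rx['hydrogenotrophic_methanogenesis']):.2f} Pa")
print(f"{thermo.h2_threshold(rx['nadh_h2_evolution']):.0f} Pa")

# 3. Sampling-day yield statistics and the community check
mean, std = cod.aggregate_yield_tables(datasets.load_cstr_yield_tables())
print(f"acetate yield {mean['acetate']:.1f} +/- {std['acetate']:.2f} mol/mol")
gf = guild_fractions(datasets.load_archaea_clones(), datasets.load_guild_map())
print(consistency_check(gf, thermo.rank_h2_sinks(343.15)).narrative)

# 4. Simulate a steady CSTR and recover its yields from the noisy series
cfg = sim.nominal_cstr_config(seed=1, hrt_schedule=((0.0, 8.9),),
                              ph_schedule=((0.0, 7.0),), horizon_d=60.0,
                              initial="steady")
truth, series = sim.simulate_cstr(cfg)
est = metrics.cstr_yields(series, metrics.SteadyStateWindow(35, 60),
                          influent_glucose=9.0)
print({k: round(v, 2) for k, v in est.yields.items()})
print(f"COD closure {cod.cod_balance(est):.1f} %")
```

prints

```
hydrogenotrophic_methanogenesis    dG =  -119.7 kJ/mol
homoacetogenesis                   dG =   -83.2 kJ/mol
aceticlastic_methanogenesis        dG =   -36.5 kJ/mol
0.12 Pa
68 Pa
acetate yield 1.5 +/- 0.06 mol/mol
CONSISTENT: dominant observed sink guild is hydrogenotrophic_methanogen
(97.9% of clones); the most favourable sink reaction is
hydrogenotrophic_methanogenesis (dG = -119.7 kJ/mol), i.e. guild
hydrogenotrophic_methanogen.
{'acetate': 1.49, 'propionate': 0.08, 'butyrate': 0.01, 'methane': 1.04, 'biomass': 0.49}
COD closure 98.2 %
```

Read: at 70 °C hydrogenotrophic methanogenesis yields the most energy per
reaction (and per mol H₂), so it outcompetes homoacetogenesis and
aceticlastic methanogenesis for reducing equivalents — which is exactly
what the clone library shows (97.9 % hydrogenotrophic methanogens among
Archaea). Methanogens can pull H₂ to ~0.1 Pa, far below the ~60–70 Pa
ceiling at which NADH-driven hydrogen evolution (and hence pure acetate
fermentation) remains feasible. The estimator recovers the generator's
true yields (1.5 acetate, ~1.08 methane, ~0.49 C-mol biomass per mol
glucose) from a noisy simulated series, with the electron balance closing
near 100 %.

A small CLI mirrors the common desk calculations:

```sh
mcferm dg --reaction hydrogenotrophic_methanogenesis --temp-c 70
mcferm h2-threshold --reaction nadh_h2_evolution --temp-c 25
mcferm summarize
mcferm simulate cstr --seed 1 --out series.csv --truth truth.csv
```

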