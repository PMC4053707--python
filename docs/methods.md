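# Methods

This note documents the models, conventions and numerical choices behind
`mcferm`, in the order the modules build on each other.

## Reaction energetics

**Standard-transformed quantities.** ΔG°′ is defined at pH 7, with 1 M
aqueous and 1 atm gaseous standard states and water activity 1. It is
computed as the stoichiometric sum of standard formation Gibbs energies at
298.15 K plus the proton activity term ν_H⁺·RT·ln(10⁻⁷). The formation
table (`data/species.tsv`) carries literature-compilation-style values for
the ~15 species needed; tables differ from source to source by up to about
1 kJ/mol per species, which is why downstream comparisons use a
±1.5 kJ/mol band on reaction energies.

**Temperature correction.** ΔG°′(T) = ΔG°′(T₀)·(T/T₀) + ΔH°′·(1 − T/T₀)
with T₀ = 298.15 K — the integrated Gibbs–Helmholtz relation under the
assumption that the reaction enthalpy is temperature-independent. Over
25–70 °C the neglected ΔCp term is small compared to the formation-table
spread, and the linear form has the convenient property that the pH
activity term (which is ∝ RT) scales correctly. The supported range is
restricted to 273–400 K to keep the approximation honest.

**Carbonate convention.** Inorganic carbon is written as aqueous
bicarbonate plus a proton (HCO₃⁻ + H⁺), the dominant species at pH 7.
This is the convention under which the three sink reactions take their
commonly tabulated values (−135.5 / −104.5 / −31.0 kJ/mol at 25 °C). A
gaseous-CO₂ variant of each reaction ships under `*_gas_co2` names (about
−131 / −95 / −36 kJ/mol); the two conventions differ by the hydration
energy of CO₂ and users should not mix them within one comparison.
H₂ and CH₄ are gas-phase species at 1 atm; dissolved-gas variants,
ionic-strength corrections and pKa speciation beyond the fixed bicarbonate
convention are out of scope.

**Hydrogen thresholds.** ΔG is affine in ln P_H₂, so the pressure at
which a reaction reverses has the closed form
P = exp(−ΔG_rest / (ν_H₂·R·T)) with ΔG_rest evaluated at P_H₂ = 1 atm and
all other activities as given. Thresholds are reported in Pa
(1 atm = 101 325 Pa) because that is the scale on which interspecies
hydrogen transfer is discussed; activities at the API boundary are in atm,
matching how reactor headspace data are recorded. The ~60 Pa feasibility
ceiling for pure acetate fermentation is represented by the NADH couple
(NADH + H⁺ → NAD⁺ + H₂, ΔG°′ = +18.1 kJ/mol from E°′ = −320 mV vs
−414 mV, NADH/NAD⁺ = 1): the computed threshold is ≈ 68 Pa. Literature
values for this bound vary with the assumed couple and ratio, so the
package treats agreement within a factor 1.5 as reproducing it, and states
the assumption rather than tuning to the number.

## COD accounting

Theoretical oxygen demand is 8·(4C + H − 2O − 3N − z) g O₂ per mol, i.e.
8 g per electron-mol of degree of reduction, with nitrogen released as
ammonia and z the net charge (an anion and its conjugate acid therefore
carry the same COD — yields are tabulated for the neutral forms).
Over-oxidized formulas clamp to zero with a warning instead of returning
negative demand. Degree of reduction is linear in the conserved elements
and charge, so any balanced O₂-free reaction conserves COD identically;
the test suite uses this as an oracle over the whole reaction registry.

Biomass is the per-carbon pseudo-formula CH₁.₈O₀.₅N₀.₂ (24.62 g and
33.6 g COD per C-mol); biomass yields are C-mol per mol glucose
throughout. This interpretation closes the sampling-day balances at
93–102 %, consistent with how they are reported.

The theoretical product spectrum combines acetate-type fermentation
(glucose → 2 acetate + 2 CO₂ + 4 H₂) with hydrogenotrophic methanogenesis
(4 H₂ + CO₂ → CH₄ + 2 H₂O), eliminating H₂: glucose → 2 acetate + CH₄ +
CO₂. The overall equation is a reconstruction from the two half-processes;
a requested electron fraction f goes to biomass and acetate/methane scale
by (1 − f), so the returned table closes at exactly 100 % by construction.

## Reactor metrics

* **Steady-state criterion**: a window is steady when each major
  metabolite (mean ≥ 0.2 g/L) shows a systematic trend — |OLS slope| ×
  window length / mean — below 10 %, and HRT is constant. A trend
  statistic is used rather than peak-to-peak drift because the latter
  grows with the number of observations under measurement noise.
* **Yields**: liquid yields from mean concentrations over the window;
  methane from mean(gas rate × P_CH₄) × HRT / V_m. The gas molar volume
  defaults to 24.45 L/mol (ideal gas, 25 °C, 1 atm) and is configurable
  because gas-meter reference temperatures are often unreported; at 70 °C
  the alternative convention (28.1 L/mol) changes methane yields by ~15 %,
  so callers comparing to a printed rate should check both.
* **Effluent glucose** below 0.1 g/L (a typical assay detection limit) is
  treated as zero.
* **Purity** is acetate over total liquid metabolites (glucose excluded),
  mass basis by default since concentrations are reported in g/L; a COD
  basis is available by flag.
* **Fed-batch rates** are ordinary least-squares slopes on the stated
  window, no smoothing; cumulative yields divide net mol formed by mol
  glucose added (consumption-corrected when glucose is measured). If no
  glucose was added in the window the rates are still returned but yields
  are undefined and omitted.
* **Batch stability**: stable iff every liquid metabolite stays within a
  tolerance (default 0.5 g/L) of its initial value and P_CH₄ rises by at
  most 0.05 atm. With noisy observations the tolerance should be sized to
  the measurement CV (the tests use 1.0 g/L at 5 % CV on ~4.4 g/L).

## Community summaries

Relative abundances are always recomputed from clone counts — printed
percent columns in literature tables can be internally inconsistent — and
reported to one decimal with half-up rounding. Guild assignment ships as
an editable YAML map keyed on closest-relative names, matched full-name
first and then by genus. The consistency check compares the most abundant
methanogenic/acetogenic guild against the guild of the most exergonic
sink reaction at the same temperature; with the packaged data the dominant
hydrogenotrophic fraction is 47/48 = 97.9 % of archaeal clones, matching
the 70 °C ranking. Whether the odd clone out (a *Methanosarcina*
relative) should be counted differently is exposed through the grouping
rather than hidden in the code.

## Synthetic-data generator

**What it emulates.** The generator reproduces the *structure* of the
three reactor experiments — a 100-day CSTR with HRT steps
2.2 → 8.9 → 5.0 → 6.5 d and pH steps 7.5 → 6.5 → 7.0; a pulse-fed batch
(1 g/L glucose at days 0 and 2, then 6 g/L roughly twice daily through
day 12.2); and a 14-day batch hold of effluent — with a known latent
truth. It is a regime-switching flux-partition model:

* glucose uptake is first-order (20 d⁻¹, fast against dilution) times a
  logistic acetate-inhibition factor centred at 34 g/L (width 0.5 g/L);
* consumed glucose COD is split exactly: fixed shares to biomass,
  propionate and butyrate per the true yield table (defaults 0.4 C-mol,
  0.08, 0.01 per mol glucose), and the remaining acetate+H₂ pool
  partitioned by the acetate yield (default 1.5). A fraction of the pool
  diverts to ethanol as P_H₂ rises above 0.005 atm (half-saturation
  0.005 atm, max 0.9) — the hydrogen-inhibition product shift;
* methanogens consume headspace H₂ down to a threshold partial pressure
  (default 60 Pa), capacity-limited by a methanogen biomass state
  (uptake 1 mol H₂ g⁻¹ d⁻¹, growth yield 0.5 g per mol H₂, growth capped
  at 1 d⁻¹, washed out at the dilution rate). Low HRT therefore thins the
  methanogens, H₂ accumulates, and ethanol appears — the start-up
  instability; high HRT re-enriches them. Acetate inhibition also slows
  H₂ uptake, which is what makes the fed-batch plateau come with hydrogen
  re-accumulation and an ethanol tail;
* the headspace is a well-mixed pool at 1 atm (0.6 L gas per L liquid,
  initially N₂); produced gas displaces outflow, integrated between
  observations into the observed gas rate. A fraction of produced CO₂
  (0.25) reports to the gas phase; the rest stays as bicarbonate at
  neutral pH;
* observations every 0.5 d get multiplicative lognormal noise (default
  CV 5 % on concentrations, pressures and gas rate), with partial
  pressures rescaled to at most 1.05 atm; the latent truth is noise-free.

COD is conserved exactly at every step: the per-step closure residual is
recomputed from the realized increments with the `cod` module and logged
in the truth frame (observed magnitudes ~1e-16 g COD/L, tested against a
1e-6 bound). An optional aceticlastic consumer (off by default) provides
the unstable-batch counter-case.

**What it does not emulate.** No Monod/ADM1 kinetics, no pH dynamics (pH
is a schedule), no gas–liquid transfer resistance, no temperature
dependence of rates, no biomass decay. The kinetic constants above are
fixtures chosen to produce the qualitative regimes, not estimates of any
real reactor; consequently, passing end-to-end tests demonstrates that
the estimators recover a known truth under the stated noise model — not
that the generator predicts real digester dynamics.

**Estimand for recovery tests.** `TrueState.realized_yields` integrates
the latent production fluxes over a window; estimator recovery is judged
against these realized yields (which include methanogen growth in the
biomass and its COD draw on methane) rather than against the configured
table, because that is the quantity a flux estimator can possibly see.

## Numerical choices and problem sizes

* Explicit Euler at dt = 0.05 d, guarded by an assertion dt ≤ min(HRT)/10;
  the H₂ pool is updated production-first, consumption-second within a
  step so recorded pressures reflect the post-uptake state a sampler sees.
* Seeds are explicit arguments everywhere (`numpy.random.default_rng`);
  identical config + seed reproduces output byte-for-byte, and
  observation noise never perturbs the latent truth.
* Recovery tests use a single-period CSTR (HRT 8.9 d, 60 days simulated,
  steady window days 35–60) over 20 seeds at 5 % CV; the multinomial
  sampling checks use 1000–2000 seeds at n = 48. These sizes keep the
  whole suite under ~10 s while leaving standard errors well inside the
  asserted bounds.
* Percent roundings follow the conventions of the summarized tables (one
  decimal, half-up); energies are reported to 0.1 kJ/mol.

## Known limitations

* Formation data are a single compiled table; swapping in another source
  shifts reaction energies by up to ~1 kJ/mol.
* The ~60 Pa feasibility bound depends on the assumed electron couple;
  only factor-level agreement is claimed.
* Methane-rate conventions (molar volume, meter temperature) are a real
  ambiguity in reported datasets; the package exposes the convention
  rather than resolving it.
* The generator's regime switches are smooth heuristics; quantities tied
  to switch timing (e.g. exactly when ethanol appears during start-up)
  are qualitative.
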