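# Packaged reaction registry.  One reaction per line:
#   name: coef species + coef species ... -> coef species + ...
# Species names refer to species.tsv.  All reactions are element- and
# charge-balanced; the loader verifies this.
#
# Bicarbonate convention (inorganic carbon as HCO3- + H+ at pH 7) — the
# default set used for the three competing hydrogen-sink / acetate-sink
# pathways of thermophilic anaerobic digestion.
hydrogenotrophic_methanogenesis: 4 H2 + 1 HCO3- + 1 H+ -> 1 CH4 + 3 H2O
homoacetogenesis: 4 H2 + 2 HCO3- + 1 H+ -> 1 acetate + 4 H2O
aceticlastic_methanogenesis: 1 acetate + 1 H2O -> 1 CH4 + 1 HCO3-
#
# Gaseous-CO2 convention variants (alternate set, clearly named).
hydrogenotrophic_methanogenesis_gas_co2: 4 H2 + 1 CO2 -> 1 CH4 + 2 H2O
homoacetogenesis_gas_co2: 4 H2 + 2 CO2 -> 1 acetate + 1 H+ + 2 H2O
aceticlastic_methanogenesis_gas_co2: 1 acetate + 1 H+ -> 1 CH4 + 1 CO2
#
# Glucose fermentations: acetate-type and butyrate-type.
glucose_to_acetate_h2: 1 glucose + 4 H2O -> 2 acetate + 2 HCO3- + 4 H+ + 4 H2
glucose_to_butyrate_h2: 1 glucose + 2 H2O -> 1 butyrate + 2 HCO3- + 3 H+ + 2 H2
#
# Overall acetate + methane conversion (acetate-type fermentation coupled to
# hydrogenotrophic methanogenesis with H2 eliminated).
glucose_to_acetate_methane: 1 glucose -> 2 acetate + 2 H+ + 1 CH4 + 1 CO2
#
# NADH-driven hydrogen evolution — the ferredoxin-independent couple whose
# feasibility sets the classic ~60 Pa ceiling for pure acetate fermentation.
nadh_h2_evolution: 1 NADH + 1 H+ -> 1 NAD+ + 1 H2
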