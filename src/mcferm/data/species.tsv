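# Standard formation properties at 298.15 K.
# dGf0: standard Gibbs energy of formation, kJ/mol (1 M aqueous, 1 atm gas, pure liquid water).
# dHf0: standard enthalpy of formation, kJ/mol.
# Values are literature-compilation style (Thauer-type biochemical tables / CODATA);
# NAD+/NADH are formal entries fixing the couple's dG0' (NADH + H+ -> NAD+ + H2) at +18.1 kJ/mol (pH 7).
# The biomass pseudo-species carries no formation data (used only for elemental/COD accounting).
name	formula	charge	phase	dGf0_kJ_mol	dHf0_kJ_mol
H2	H2	0	gas	0.0	0.0
CH4	CH4	0	gas	-50.75	-74.81
CO2	CO2	0	gas	-394.36	-393.51
HCO3-	CHO3	-1	aqueous	-586.85	-691.99
H2O	H2O	0	water	-237.18	-285.83
H+	H	1	aqueous	0.0	0.0
acetate	C2H3O2	-1	aqueous	-369.41	-486.01
glucose	C6H12O6	0	aqueous	-917.22	-1262.19
ethanol	C2H6O	0	aqueous	-181.75	-288.30
propionate	C3H5O2	-1	aqueous	-361.08	-510.80
butyrate	C4H7O2	-1	aqueous	-352.63	-535.00
NH4+	H4N	1	aqueous	-79.37	-132.51
NAD+	C21H26N7O14P2	-1	aqueous	0.0	0.0
NADH	C21H27N7O14P2	-2	aqueous	21.85	0.0
biomass	CH1.8O0.5N0.2	0	aqueous
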