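# Metabolic-guild assignment keyed on closest-relative names.
# Keys may be full relative names or genus-level prefixes (first word);
# full-name entries take precedence.  Guilds:
#   hydrogenotrophic_methanogen | aceticlastic_methanogen | homoacetogen |
#   fermenter | other
guilds:
  Methanobacterium: hydrogenotrophic_methanogen
  Methanothermobacter: hydrogenotrophic_methanogen
  Methanobacteriaceae: hydrogenotrophic_methanogen
  Methanofollis: hydrogenotrophic_methanogen
  Methanosarcina: aceticlastic_methanogen
  Caldanaerobacter: fermenter
  Thermoanaerobacter: fermenter
  Caldicoprobacter: fermenter
  Lactococcus: fermenter
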