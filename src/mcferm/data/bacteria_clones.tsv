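clone	closest_relative	similarity_percent	count
bac1-1	Caldanaerobacter subterraneus	99	37
bac1-2	Thermoanaerobacter brockii	95	1
bac1-3	Thermoanaerobacter tengcongensis	95	3
bac1-4	Caldicoprobacter oshimai	98	11
bac1-5	Lactococcus lactis subsp. lactis	99	1
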