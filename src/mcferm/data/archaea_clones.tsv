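clone	closest_relative	similarity_percent	count
arc1-1	Methanobacterium thermaggregans	99	5
arc1-2	Methanobacterium thermaggregans	100	1
arc1-3	Methanobacterium thermaggregans	99	25
arc1-4	Methanothermobacter thermautotrophicus	99	13
arc1-5	Methanobacteriaceae archaeon MG	99	1
arc1-6	Methanofollis liminatans	99	2
arc1-7	Methanosarcina mazei	99	1
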