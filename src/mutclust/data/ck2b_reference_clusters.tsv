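residue	n_samples	p_reported	annotation
32	7	1.04e-4	N-terminal segment (conserved surface cluster 1)
47	6	3.02e-4	N-terminal segment (destruction box; truncated protein)
1	6	3.12e-4	N-terminal segment (truncated protein)
86	4	2.08e-2	Conserved surface cluster 1
137	4	2.08e-2	Zinc finger (Cys bound to Zinc)
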