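residue	n_samples	p_reported	annotation
198	24	2.73e-34	Activation segment (P+1 loop)
50	11	1.28e-12	Gly-rich loop; ATP binding; CK2b binding
47	10	4.16e-11	Gly-rich loop; ATP binding; CK2b binding
80	6	1.64e-5	Polybasic stretch
191	5	2.60e-4	Activation segment (P+1 loop)
312	5	2.60e-4	Interdomain
51	4	3.03e-3	Gly-rich loop; ATP binding; CK2b binding
156	4	3.03e-3	Catalytic loop
160	4	3.03e-3	Catalytic loop
39	3	3.12e-2	N-terminal segment; CK2b binding
175	3	3.12e-2	Activation segment; Mg2+ binding loop
195	3	3.12e-2	Activation segment (P+1 loop)
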