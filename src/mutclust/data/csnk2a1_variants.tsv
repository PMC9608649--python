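gene	residue	cdna	protein_change	n_patients	source
CSNK2A1	1	c.1A>G	p.Met1?	1	Chiu2018/Xu2020/ClinVar
CSNK2A1	21	c.62G>A	p.Arg21Gln	1	ClinVar
CSNK2A1	27	c.79G>A	p.Glu27Lys	2	Lelieveld2016/Chiu2018;Trinh2017
CSNK2A1	32	c.96delA	p.Glu32Aspfs*14	1	ClinVar
CSNK2A1	36	c.106C>T	p.Gln36*	1	DECIPHER
CSNK2A1	39	c.116A>G	p.Tyr39Cys	1	Xu2020
CSNK2A1	39	c.116A>C	p.Tyr39Ser	1	DECIPHER
CSNK2A1	39	c.117C>A	p.Tyr39Ter	1	ClinVar
CSNK2A1	46	c.137G>T	p.Gly46Val	1	ClinVar
CSNK2A1	47	c.139C>G	p.Arg47Gly	2	ClinVar;SFARI
CSNK2A1	47	c.140G>A	p.Arg47Gln	8	Okur2016;Chiu2018;Owen2018/DECIPHER;DECIPHER;ClinVar
CSNK2A1	50	c.149A>G	p.Tyr50Cys	9	Nakashima2019;Wu2020a;ClinVar;DECIPHER
CSNK2A1	50	c.149A>T	p.Tyr50Phe	1	Dominguez2021
CSNK2A1	50	c.149A>C	p.Tyr50Ser	1	Okur2016
CSNK2A1	51	c.152G>A	p.Ser51Asn	1	Owen2018/DECIPHER
CSNK2A1	51	c.151A>C c.153T>A	p.Ser51Arg	2	Chiu2018;ClinVar
CSNK2A1	51	c.152G>T	p.Ser51Ile	1	Xu2020
CSNK2A1	52	c.154G>A	p.Glu52Lys	1	ClinVar
CSNK2A1	53	157G>C	p.Val53Leu	1	SFARI
CSNK2A1	73	c.218T>A	p.Val73Glu	1	Chiu2018
CSNK2A1	80	c.238C>T	p.Arg80Cys	1	Xu2020/Xu2021
CSNK2A1	80	c.239G>A	p.Arg80His	5	Owen2018/DECIPHER;ClinVar
CSNK2A1	107	c.319C>T	p.Arg107*	2	Xu2020;ClinVar
CSNK2A1	126	c.376delC	p.Gln126Argfs*2	1	ClinVar
CSNK2A1	127	c.380C>T	p.Thr127Met	1	Xu2020
CSNK2A1	128	c.383T>A	p.Leu128*	1	ClinVar
CSNK2A1	147	c.440G>A	p.Cys147Tyr	1	Xu2020
CSNK2A1	153	c.458T>G	p.Met153Arg	1	ClinVar
CSNK2A1	156	c.466G>C	p.Asp156His	1	Trinh2017/ClinVar
CSNK2A1	156	c.468T>A	p.Asp156Glu	2	ClinVar
CSNK2A1	156	c.466G>T	p.Asp156Tyr	1	ClinVar/SFARI
CSNK2A1	158	c.472A>G	p.Lys158Glu	1	ClinVar
CSNK2A1	158	473A>G	p.Lys158Arg	1	ClinVar
CSNK2A1	160	c.479A>G	p.His160Arg	4	Werhahn2021;Xu2021;ClinVar
CSNK2A1	161	c.482A>G	p.Asn161Ser	1	DECIPHER
CSNK2A1	161	c.481A>G	p.Asn161Asp	1	ClinVar
CSNK2A1	174	c.522A>G	p.Ile174Met	1	Owen2018/DECIPHER
CSNK2A1	175	c.524A>G	p.Asp175Gly	2	Okur2016/ClinVar;Martinez-Monseny2020
CSNK2A1	175	c.596G>A	p.Asp175Glu	1	ClinVar
CSNK2A1	177	529G>A	p.Gly177Ser	1	ClinVar
CSNK2A1	178	c.533T>G	p.Leu178Trp	1	DECIPHER
CSNK2A1	191	c.572G>A	p.Arg191Gln	2	Owen2018/DECIPHER;DECIPHER
CSNK2A1	191	c.571C>T	p.Arg191*	3	Nakashima2019b;Xu2020;ClinVar
CSNK2A1	194	581C>T	p.Ser194Phe	1	SFARI
CSNK2A1	195	c.583C>T	p.Arg195*	3	Xu2020;ClinVar
CSNK2A1	197	c.589T>A	p.Phe197Ile	1	Owen2018/DECIPHER
CSNK2A1	198	c.593A>G	p.Lys198Arg	24	Okur2016;Chiu2018;Akahira-Azuma2018;Owen2018/DECIPHER;Nakashima2019b;Werhahn2021;Yang2021;ClinVar;TGen
CSNK2A1	199	c.596G>A	p.Gly199Asp	1	ClinVar
CSNK2A1	210	c.628G>A	p.Asp210Asn	1	Xu2020
CSNK2A1	231	c.692C>G	p.Pro231Arg	1	Lelieveld2016/Chiu2018
CSNK2A1	261	c.783C>A	p.Tyr261Ter	1	ClinVar
CSNK2A1	306	c.916C>T	p.Arg306*	1	Xu2020
CSNK2A1	312	c.935G>A	p.Arg312Gln	2	Chiu2018;ClinVar
CSNK2A1	312	c.934C>T	p.Arg312Trp	3	Owen2018/DECIPHER;ClinVar
CSNK2A1	325	c.972_973dupCAG	p.Tyr325Serfs*5	1	Xu2020
CSNK2A1	326	c.976_977insG	p.T326Serfs*13	2	DECIPHER
CSNK2A1	333	c.997C>T	p.Arg333*	1	ClinVar
CSNK2A1	356	c.1066T>A	p.Ser356Thr	1	ClinVar
CSNK2A1	363	c.1088C>A	p.Pro363His	1	ClinVar
CSNK2A1	382	c.1145C>T	p.Pro382Leu	2	ClinVar
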