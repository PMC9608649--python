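gene	residue	cdna	protein_change	n_patients	source
CSNK2B	1	c.1A>G	p.Met1?	3	Ernst2021;ClinVar
CSNK2B	1	c.2T>A	p.Met1?	1	Ernst2021
CSNK2B	1	c.3G>A	p.Met1?	1	Ziegler2021
CSNK2B	1	c.2T>G	p.Met1?	1	ClinVar
CSNK2B	5	c.13G>T	p.Glu5Ter	1	Li2019
CSNK2B	9	c.27del	p.Trp9Ter	2	Ernst2021;ClinVar
CSNK2B	20	c.58G>T	p.Glu20Ter	1	Ernst2021
CSNK2B	21	c.63C>A	p.Phe21Leu	1	DECIPHER
CSNK2B	27	c.78_83dup	p.Glu27_Asp28dup	1	Ernst2021
CSNK2B	31	c.91C>T	p.Gln31Ter	1	ClinVar
CSNK2B	32	c.94G>A	p.Asp32Asn	6	Ernst2021;ClinVar;DECIPHER
CSNK2B	32	c.95A>C	p.Asp32Ala	1	DECIPHER
CSNK2B	34	c.101T>C	p.Phe34Ser	1	Ernst2021
CSNK2B	34	c.101T>G	p.Phe34Cys	1	ClinVar
CSNK2B	35	c.105T>A	p.Asn35Lys	1	Ernst2021
CSNK2B	37	c.108dupT	p.Thr37TyrfsTer5	2	Poirier2017;ClinVar
CSNK2B	42	c.124C>T	p.Gln42Ter	2	Sakaguchi2017;Ernst2021
CSNK2B	47	c.139C>T	p.Arg47Ter	6	Selvam2021;Ernst2021;ClinVar
CSNK2B	57	c.170del	p.Glu57Glyfs*15	1	Yang2021b
CSNK2B	61	c.181G>T	p.Glu61Ter	1	Ernst2021/ClinVar
CSNK2B	77	c.229G>A	p.Glu77Lys	2	Ernst2021;ClinVar
CSNK2B	77	c.229G>T	p.Glu77Ter	1	ClinVar
CSNK2B	80	c.238T>A	p. Tyr80Asn	1	ClinVar
CSNK2B	82	c. 245T>A	P.Leu82Ter	1	ClinVar
CSNK2B	86	c.256C>T	p.Arg86Cys	4	Li2019;Ernst2021;ClinVar
CSNK2B	88	c.264delC	p.Ile88Ilefs*46	1	Li2019
CSNK2B	90	c.268dupA	p.Thr90Asnfs*24	1	ClinVar
CSNK2B	97	c.291G>A	p.Met97Ile	1	Ernst2021
CSNK2B	101	c.303C>A c.303C>G	p.Tyr101Ter	3	Ernst2021;ClinVar
CSNK2B	106	c.316T>G	p.Phe106Val	1	Ernst2021
CSNK2B	111	c.332G>C	p.Arg111Pro	3	Li2019;ClinVar
CSNK2B	117	c.349C>T	p.Gln117Ter	1	DECIPHER
CSNK2B	132	c.394_404del	p.Met132LeufsTer110	1	Ernst2021
CSNK2B	137	c.409T>C	p.Cys137Arg	1	Ernst2021
CSNK2B	137	c.409T>G	p.Cys137Gly	1	Li2019
CSNK2B	137	c.410G>T	p.Cys137Phe	2	Li2019;Ziegler2021
CSNK2B	158	c.472del	p.Tyr158fs	1	ClinVar
CSNK2B	164	c.491C>G	p.Pro164Arg	1	ClinVar
CSNK2B	165	c.494A>G	p.His165Arg	3	Nakashima2019b;Ziegler2021;ClinVar
CSNK2B	167	c.499delC	Leu167Serfs*60	1	Ziegler2021
CSNK2B	179	c.533_534insGT	p.Pro179TyrfsTer49	1	Nakashima2019b/ClinVar
CSNK2B	181	c.542del	p.Asn181ThrfsTer46	1	Ernst2021
CSNK2B	186	c.554_555dupCC	p.Arg186fs	1	ClinVar
CSNK2B	187	c.560T>C	p.Leu187Pro	1	ClinVar
CSNK2B	187	c.560T>G	p.Leu187Arg	1	Li2019
CSNK2B	188	c.564del	p.Tyr188Ter	1	Bonanni2021
CSNK2B	189	c.566G>T	p.Gly189Val	1	ClinVar
CSNK2B	207	c.620_621insC	p.Phe207Phefs*39	1	Li2019
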