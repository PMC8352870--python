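# Published I-Mutant stability predictions (direction, reliability
# index 0-10, ddG in kcal/mol) and TM-align native-vs-mutant model
# comparisons (TM-score, RMSD in Angstroms) for the eight high-risk
# nsSNPs.
rsid	aa_change	gene	direction	ri	ddg	tm_score	rmsd
rs3124765	I58M	CACFD1	decrease	8	-1.19	0.346	4.84
rs9379084	D1171N	RREB1	decrease	7	-1.74	0.319	4.41
rs10936600	L286I	LRRC34	decrease	5	-1.00	0.934	2.06
rs1801591	T171I	ETFA	decrease	0	-0.48	0.975	1.13
rs117744081	Y168H	CPVL	decrease	4	-1.50	0.909	2.66
rs2277283	M506T	INCENP	decrease	6	-0.88	0.262	2.56
rs757978	T260N	FARP2	decrease	5	-1.01	0.929	3.21
rs1126809	R402Q	TYR	decrease	9	-1.39	0.938	2.56
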