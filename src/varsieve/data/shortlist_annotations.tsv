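# Published MutPred2 pathogenicity scores with top mechanism
# hypotheses (mechanism:p-value, |-separated) and ModPred PTM-site
# scores for the three shortlisted variants.  The accompanying prose
# prints 0.78/0.73 for two MutPred scores where the table prints
# 0.74/0.70; the table values are recorded here.
rsid	gene	aa_change	mutpred_score	mutpred_features	modpred_ptm	modpred_score
rs10936600	LRRC34	L286I	0.55	Altered Ordered interface:0.01|Altered Metal binding:0.04	Proteolytic cleavage	0.07
rs757978	FARP2	T260N	0.70	Altered DNA binding:0.0028|Gain of Allosteric site at F265:0.03|Altered Disordered interface:0.04	Proteolytic cleavage	0.49
rs1126809	TYR	R402Q	0.74	Altered Disordered interface:0.03|Loss of Allosteric site at R403:0.0063|Altered DNA binding:0.0091|Altered Transmembrane protein:0.0046	Proteolytic cleavage	0.58
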