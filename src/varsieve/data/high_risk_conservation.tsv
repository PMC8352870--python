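# Published ConSurf conservation grades (1-9) at the residues of the
# eight high-risk nsSNPs; 7-9 = highly conserved.
rsid	protein_accession	aa_change	consurf_score
rs9379084	Q92766	D1171N	9
rs3124765	Q9UGQ2	I58M	8
rs10936600	Q8IZ02	L286I	9
rs1801591	P13804	T171I	9
rs117744081	Q9H3G5	Y168H	8
rs2277283	Q9NQS7	M506T	9
rs1126809	P14679	R402Q	8
rs757978	O94887	T260N	8
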