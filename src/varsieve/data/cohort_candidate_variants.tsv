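# Published candidate set: cancer-associated nsSNPs observed in two
# Southeast-Asian cohorts, with categorical labels from the five
# functional-effect predictors.  The printed source table lists 52
# rows; 48 are recoverable from the available text and transcribed
# here (all eight high-risk variants are among them).  Coordinates are
# GRCh37.  Empty cell = not predicted.
rsid	trait	chrom	pos	gene	aa_change	sift_label	pp2_label	condel_label	provean_label	panther_label
rs12621643	Acute lymphoblastic leukemia (childhood)	2	223917983	KCNE4	D145E	Tol	benign	Neu	Neu	
rs13014235	Basal cell carcinoma	2	202215492	ALS2CR12	V43L	Tol	benign	Neu	Neu	Prob_ben
rs1050529	Basal cell carcinoma	6	31324615	HLA-B	A65T	Del_low_con	benign	Neu	Neu	Prob_ben
rs1126809	Basal cell carcinoma or squamous cell carcinoma	11	89017961	TYR	R402Q	Del	Prob_dam	Del	Neu	Prob_dam
rs11543198	Bladder cancer	15	74912328	CLK3	R78H	Tol_low_con			Neu	
rs35273427	Breast cancer	1	120436751	ADAM30	T737A	Tol	benign	Neu	Neu	Prob_ben
rs6964587	Breast cancer	7	91630620	AKAP9	M463I	Del	benign	Neu	Neu	
rs1053338	Breast cancer	3	63967900	ATXN7	K264R	Tol	benign	Neu	Neu	Prob_dam
rs3124765	Breast cancer	9	136328657	CACFD1	I58M	Del	Prob_dam	Del	Neu	
rs11552449	Breast cancer	1	114448389	DCLRE1B	H61Y	Del	benign		Neu	Prob_ben
rs3815308	Breast cancer	19	2226676	DOT1L	G1386S	Tol_low_con	benign	Neu	Neu	Prob_ben
rs11205303	Breast cancer	1	149906413	MTMR11	M159V	Tol	benign		Neu	
rs9379084	Breast cancer	6	7231843	RREB1	D1171N	Del	Prob_dam	Del	Del	Prob_dam
rs8050871	Breast cancer	16	71509796	ZNF19	Q218H	Del	pos_dam	Del	Neu	Prob_ben
rs757978	Chronic lymphocytic leukemia	2	242371101	FARP2	T260N	Del	Prob_dam	Del	Del	Prob_dam
rs11539086	Colorectal cancer	3	58552329	FAM107A	E141Q	Tol	Prob_dam	Del	Neu	Prob_dam
rs4836891	Colorectal cancer	9	125273574	OR1J2	R165Q	Tol_low_con	benign	Neu	Neu	Prob_ben
rs7248888	Colorectal cancer	19	46974003	PNMAL1	C97Y	Tol	benign	Neu	Neu	Prob_ben
rs16845107	Colorectal cancer	3	113127991	WDR52	K284N	Tol	benign		Neu	Prob_dam
rs3184504	Colorectal or endometrial cancer	12	111884608	SH2B3	W262R	Tol	benign	Neu	Neu	Prob_ben
rs1129506	Endometrial cancer	17	29646032	EVI2A	S23R	Del_low_con	benign		Neu	Pos_dam
rs2278868	Endometriosis or endometrial cancer (pleiotropy)	17	46262171	SKAP1	G161S	Tol	benign	Neu	Neu	Prob_ben
rs1229984	Esophageal cancer	4	100239319	ADH1B	H48R	Tol	benign	Neu	Neu	Prob_ben
rs671	Esophageal cancer	12	112241766	ALDH2	E504K	Del	pos_dam	Del	Del	
rs2274223	Esophageal cancer	10	96066341	PLCE1	H1927R	Tol	benign	Neu	Neu	Prob_ben
rs3765524	Esophageal cancer and gastric cancer	10	96058298	PLCE1	T1777I	Tol	benign	Neu	Neu	Prob_ben
rs20541	Hodgkin's lymphoma	5	131995964	IL13	Q144R	Tol	benign	Neu	Neu	
rs3734542	Lung cancer in ever smokers	6	26468326	BTN2A1	R378Q	Tol	benign	Neu	Neu	Prob_ben
rs10936600	Multiple myeloma	3	169514585	LRRC34	L286I	Del	Prob_dam	Del	Neu	Prob_dam
rs7193541	Multiple myeloma	16	74664743	RFWD3	I564V	Tol	benign	Neu	Neu	Prob_ben
rs34562254	Multiple myeloma	17	16842991	TNFRSF13B	P251L	Tol	benign	Neu	Neu	Prob_ben
rs1052501	Multiple myeloma	3	41925398	ULK4	A542P	Del	benign	Neu	Neu	Prob_ben
rs2272007	Multiple myeloma (hyperdiploidy)	3	41996136	ULK4	K39R	Tol	benign	Neu	Neu	Prob_dam
rs6793295	Multiple myeloma and monoclonal gammopathy	3	169518455	LRRC34	S249G	Tol	benign	Neu	Neu	Prob_ben
rs1801591	Non-glioblastoma glioma	15	76578762	ETFA	T171I	Del	Prob_dam	Del	Del	
rs117744081	Non-melanoma skin cancer	7	29132279	CPVL	Y168H	Del	Prob_dam	Del	Del	Prob_ben
rs11170164	Non-melanoma skin cancer	12	52913668	KRT5	G138E	Del	pos_dam	Del	Del	Pos_dam
rs1229984	Oral cavity and pharyngeal cancer	4	100239319	ADH1B	H48R	Tol	benign	Neu	Neu	Prob_ben
rs1494961	Oral cavity and pharyngeal cancer	4	84374480	HELQ	V306I	Tol	benign	Neu	Neu	
rs763780	Pancreatic cancer	6	52101739	IL17F	H161R	Tol	benign	Neu	Del	Prob_ben
rs2257205	Pancreatic cancer	17	56448297	RNF43	R117H	Tol	pos_dam	Neu	Neu	Pos_dam
rs3795244	Pancreatic cancer	17	30692396	ZNF207	A240S	Tol	benign	Neu	Neu	Prob_dam
rs130067	Prostate cancer	HSCHR6_MHC_MANN	31163464	CCHCR1	D275E	Tol	benign	Neu		Prob_dam
rs2066827	Prostate cancer	12	12871099	CDKN1B	V109D	Tol	benign	Neu	Neu	Prob_ben
rs2277283	Prostate cancer	11	61908440	INCENP	M506T	Del	Prob_dam	Del	Del	Prob_dam
rs2292884	Prostate cancer	2	238443226	MLPH	H347R	Tol	benign	Neu	Neu	Prob_ben
rs11071896	Testicular germ cell tumor	15	66821250	ZWILCH	S344G	Tol	benign	Neu	Neu	Prob_ben
rs6793295	Thyroid cancer	3	169518455	LRRC34	S249G	Tol	benign	Neu	Neu	Prob_ben
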