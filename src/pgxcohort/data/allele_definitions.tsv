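gene	allele	chrom	pos	ref	alt	rsid	activity_score
CYP2B6	*1						1.0
CYP2B6	*6	chr19	41512841	G	T	rs3745274	0.5
CYP2B6	*6	chr19	41515263	A	G	rs2279343	0.5
CYP2B6	*9	chr19	41512841	G	T	rs3745274	0.5
CYP2C9	*1						1.0
CYP2C9	*2	chr10	96702047	C	T	rs1799853	0.5
CYP2C9	*3	chr10	96741053	A	C	rs1057910	0.0
CYP2C19	*1						1.0
CYP2C19	*2	chr10	96541616	G	A	rs4244285	0.0
CYP2C19	*3	chr10	96540410	G	A	rs4986893	0.0
CYP2C19	*17	chr10	96521657	C	T	rs12248560	1.5
CYP2D6	*1						1.0
CYP2D6	*2	chr22	42522613	C	G	rs1135840	1.0
CYP2D6	*2	chr22	42523943	G	A	rs16947	1.0
CYP2D6	*4	chr22	42524947	C	T	rs3892097	0.0
CYP2D6	*5						0.0
CYP2D6	*10	chr22	42526694	G	A	rs1065852	0.5
CYP2D6	*41	chr22	42523805	C	T	rs28371725	0.5
CYP2D6	*36+*10						0.5
CYP2D6	*68+*4						0.0
CYP3A5	*1						1.0
CYP3A5	*3	chr7	99270539	T	C	rs776746	0.0
CYP4F2	*1						1.0
CYP4F2	*3	chr19	15990431	C	T	rs2108622	0.5
NUDT15	*1						1.0
NUDT15	*3	chr13	48611934	C	T	rs116855232	0.0
SLCO1B1	*1						1.0
SLCO1B1	*5	chr12	21331549	T	C	rs4149056	0.0
SLCO1B1	*15	chr12	21329738	A	G	rs2306283	0.0
SLCO1B1	*15	chr12	21331549	T	C	rs4149056	0.0
TPMT	*1						1.0
TPMT	*2	chr6	18143724	C	G	rs1800462	0.0
TPMT	*3A	chr6	18130918	A	G	rs1142345	0.0
TPMT	*3A	chr6	18139228	C	T	rs1800460	0.0
TPMT	*3C	chr6	18130918	A	G	rs1142345	0.0
UGT1A1	*1						1.0
UGT1A1	*6	chr2	234669144	G	A	rs4148323	0.5
UGT1A1	*28	chr2	234668879	C	CAT	rs3064744	0.5
UGT1A1	*37	chr2	234668879	C	CATAT	rs3064744	0.5
VKORC1	*1						1.0
VKORC1	*2	chr16	31107689	G	A	rs9923231
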