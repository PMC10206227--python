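gene	allele1	allele2	phenotype
CYP2B6	*1	*1	Normal Metabolizer
CYP2B6	*1	*6	Intermediate Metabolizer
CYP2B6	*1	*9	Intermediate Metabolizer
CYP2B6	*6	*6	Poor Metabolizer
CYP2B6	*6	*9	Poor Metabolizer
CYP2B6	*9	*9	Poor Metabolizer
CYP2C9	*1	*1	Normal Metabolizer
CYP2C9	*1	*2	Intermediate Metabolizer
CYP2C9	*1	*3	Intermediate Metabolizer
CYP2C9	*2	*2	Intermediate Metabolizer
CYP2C9	*2	*3	Poor Metabolizer
CYP2C9	*3	*3	Poor Metabolizer
CYP2C19	*1	*1	Normal Metabolizer
CYP2C19	*1	*2	Intermediate Metabolizer
CYP2C19	*1	*3	Intermediate Metabolizer
CYP2C19	*1	*17	Rapid Metabolizer
CYP2C19	*2	*2	Poor Metabolizer
CYP2C19	*2	*3	Poor Metabolizer
CYP2C19	*2	*17	Intermediate Metabolizer
CYP2C19	*3	*3	Poor Metabolizer
CYP2C19	*3	*17	Intermediate Metabolizer
CYP2C19	*17	*17	Ultrarapid Metabolizer
CYP3A5	*1	*1	Normal Metabolizer
CYP3A5	*1	*3	Intermediate Metabolizer
CYP3A5	*3	*3	Poor Metabolizer
NUDT15	*1	*1	Normal Metabolizer
NUDT15	*1	*3	Intermediate Metabolizer
NUDT15	*3	*3	Poor Metabolizer
SLCO1B1	*1	*1	Normal Function
SLCO1B1	*1	*5	Decreased Function
SLCO1B1	*1	*15	Decreased Function
SLCO1B1	*5	*5	Poor Function
SLCO1B1	*5	*15	Poor Function
SLCO1B1	*15	*15	Poor Function
TPMT	*1	*1	Normal Metabolizer
TPMT	*1	*2	Intermediate Metabolizer
TPMT	*1	*3A	Intermediate Metabolizer
TPMT	*1	*3C	Intermediate Metabolizer
TPMT	*2	*2	Poor Metabolizer
TPMT	*2	*3A	Poor Metabolizer
TPMT	*2	*3C	Poor Metabolizer
TPMT	*3A	*3A	Poor Metabolizer
TPMT	*3A	*3C	Poor Metabolizer
TPMT	*3C	*3C	Poor Metabolizer
UGT1A1	*1	*1	Normal Metabolizer
UGT1A1	*1	*6	Intermediate Metabolizer
UGT1A1	*1	*28	Intermediate Metabolizer
UGT1A1	*1	*37	Intermediate Metabolizer
UGT1A1	*6	*6	Poor Metabolizer
UGT1A1	*6	*28	Poor Metabolizer
UGT1A1	*6	*37	Poor Metabolizer
UGT1A1	*28	*28	Poor Metabolizer
UGT1A1	*28	*37	Poor Metabolizer
UGT1A1	*37	*37	Poor Metabolizer
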