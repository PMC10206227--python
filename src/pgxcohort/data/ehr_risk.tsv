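gene	phenotype	high_risk	priority_label
CYP2B6	Normal Metabolizer	0	Normal/Routine/Low Risk
CYP2B6	Intermediate Metabolizer	1	Abnormal/Priority/High Risk
CYP2B6	Poor Metabolizer	1	Abnormal/Priority/High Risk
CYP2B6	Indeterminate	0	Indeterminate
CYP2B6	Unknown	0	Indeterminate
CYP2C9	Normal Metabolizer	0	Normal/Routine/Low Risk
CYP2C9	Intermediate Metabolizer	1	Abnormal/Priority/High Risk
CYP2C9	Poor Metabolizer	1	Abnormal/Priority/High Risk
CYP2C9	Indeterminate	0	Indeterminate
CYP2C9	Unknown	0	Indeterminate
CYP2C19	Ultrarapid Metabolizer	1	Abnormal/Priority/High Risk
CYP2C19	Rapid Metabolizer	1	Abnormal/Priority/High Risk
CYP2C19	Normal Metabolizer	0	Normal/Routine/Low Risk
CYP2C19	Intermediate Metabolizer	1	Abnormal/Priority/High Risk
CYP2C19	Poor Metabolizer	1	Abnormal/Priority/High Risk
CYP2C19	Indeterminate	0	Indeterminate
CYP2C19	Unknown	0	Indeterminate
CYP2D6	Ultrarapid Metabolizer	1	Abnormal/Priority/High Risk
CYP2D6	Normal Metabolizer	0	Normal/Routine/Low Risk
CYP2D6	Intermediate Metabolizer	1	Abnormal/Priority/High Risk
CYP2D6	Poor Metabolizer	1	Abnormal/Priority/High Risk
CYP2D6	Indeterminate	0	Indeterminate
CYP2D6	Unknown	0	Indeterminate
CYP3A5	Normal Metabolizer	1	Abnormal/Priority/High Risk
CYP3A5	Intermediate Metabolizer	1	Abnormal/Priority/High Risk
CYP3A5	Poor Metabolizer	0	Normal/Routine/Low Risk
CYP3A5	Indeterminate	0	Indeterminate
CYP3A5	Unknown	0	Indeterminate
NUDT15	Normal Metabolizer	0	Normal/Routine/Low Risk
NUDT15	Intermediate Metabolizer	1	Abnormal/Priority/High Risk
NUDT15	Poor Metabolizer	1	Abnormal/Priority/High Risk
NUDT15	Indeterminate	0	Indeterminate
NUDT15	Unknown	0	Indeterminate
SLCO1B1	Normal Function	0	Normal/Routine/Low Risk
SLCO1B1	Increased Function	0	Normal/Routine/Low Risk
SLCO1B1	Decreased Function	1	Abnormal/Priority/High Risk
SLCO1B1	Poor Function	1	Abnormal/Priority/High Risk
SLCO1B1	Indeterminate	0	Indeterminate
SLCO1B1	Unknown	0	Indeterminate
TPMT	Normal Metabolizer	0	Normal/Routine/Low Risk
TPMT	Intermediate Metabolizer	1	Abnormal/Priority/High Risk
TPMT	Poor Metabolizer	1	Abnormal/Priority/High Risk
TPMT	Indeterminate	1	Abnormal/Priority/High Risk
TPMT	Unknown	0	Indeterminate
UGT1A1	Normal Metabolizer	0	Normal/Routine/Low Risk
UGT1A1	Intermediate Metabolizer	0	Normal/Routine/Low Risk
UGT1A1	Poor Metabolizer	1	Abnormal/Priority/High Risk
UGT1A1	Indeterminate	0	Indeterminate
UGT1A1	Unknown	0	Indeterminate
CYP4F2	Higher Warfarin Dose	1	Abnormal/Priority/High Risk
CYP4F2	Normal Warfarin Dose	0	Normal/Routine/Low Risk
VKORC1	Decreased Warfarin Dose	1	Abnormal/Priority/High Risk
VKORC1	Normal Warfarin Dose	0	Normal/Routine/Low Risk
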