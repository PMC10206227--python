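gene	chrom	start	end
CYP2B6	chr19	41497204	41524301
CYP2C9	chr10	96698415	96749148
CYP2C19	chr10	96521437	96612671
CYP2D6	chr22	42522000	42528000
CYP3A5	chr7	99245813	99277621
CYP4F2	chr19	15988833	16008884
NUDT15	chr13	48611702	48621358
SLCO1B1	chr12	21284127	21392730
TPMT	chr6	18128542	18155397
UGT1A1	chr2	234668500	234681945
VKORC1	chr16	31099162	31109000
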