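drug	gene	level
amitriptyline	CYP2C19	1A
citalopram	CYP2C19	1A
clomipramine	CYP2C19	1A
clopidogrel	CYP2C19	1A
escitalopram	CYP2C19	1A
imipramine	CYP2C19	1A
lansoprazole	CYP2C19	1A
omeprazole	CYP2C19	1A
pantoprazole	CYP2C19	1A
sertraline	CYP2C19	1A
amitriptyline	CYP2D6	1A
clomipramine	CYP2D6	1A
codeine	CYP2D6	1A
fluvoxamine	CYP2D6	1A
imipramine	CYP2D6	1A
metoprolol	CYP2D6	1A
nortriptyline	CYP2D6	1A
paroxetine	CYP2D6	1A
propafenone	CYP2D6	1A
risperidone	CYP2D6	1A
tramadol	CYP2D6	1A
venlafaxine	CYP2D6	1A
celecoxib	CYP2C9	1A
ibuprofen	CYP2C9	1A
meloxicam	CYP2C9	1A
phenytoin	CYP2C9	1A
piroxicam	CYP2C9	1A
tenoxicam	CYP2C9	1A
warfarin	CYP2C9	1A
simvastatin	SLCO1B1	1A
efavirenz	CYP2B6	1A
warfarin	CYP4F2	1A
warfarin	VKORC1	1A
azathioprine	TPMT	1A
mercaptopurine	TPMT	1A
thioguanine	TPMT	1A
azathioprine	NUDT15	1A
mercaptopurine	NUDT15	1A
thioguanine	NUDT15	1A
atazanavir	UGT1A1	1A
irinotecan	UGT1A1	1A
tacrolimus	CYP3A5	1A
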