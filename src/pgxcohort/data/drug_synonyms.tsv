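name	generic
amytriptiline	amitriptyline
amitriptiline	amitriptyline
elavil	amitriptyline
zocor	simvastatin
prilosec	omeprazole
losec	omeprazole
coumadin	warfarin
marevan	warfarin
advil	ibuprofen
motrin	ibuprofen
zoloft	sertraline
prozac	fluoxetine
plavix	clopidogrel
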