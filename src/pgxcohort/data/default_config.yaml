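# Default simulated-cohort configuration: an elderly, admixed, census-sampled
# urban Brazilian population of 1,171 unrelated individuals.  Haplotype
# frequencies and medication-use frequencies are generator parameters chosen
# to be realistic for that population; they are inputs to the simulation, not
# estimates produced by it.
n: 1171
seed: 20100501
haplotype_frequencies:
  CYP2B6:  {"*1": 0.696, "*6": 0.264, "*9": 0.040}
  CYP2C9:  {"*1": 0.835, "*2": 0.113, "*3": 0.052}
  CYP2C19: {"*1": 0.671, "*2": 0.146, "*3": 0.003, "*17": 0.180}
  CYP2D6:  {"*1": 0.420, "*2": 0.330, "*4": 0.080, "*10": 0.050, "*41": 0.060, "*5": 0.030, "*1x2": 0.030}
  CYP3A5:  {"*1": 0.183, "*3": 0.817}
  CYP4F2:  {"*1": 0.708, "*3": 0.292}
  NUDT15:  {"*1": 0.992, "*3": 0.008}
  SLCO1B1: {"*1": 0.895, "*5": 0.060, "*15": 0.045}
  TPMT:    {"*1": 0.956, "*2": 0.004, "*3A": 0.020, "*3C": 0.020}
  UGT1A1:  {"*1": 0.658, "*6": 0.001, "*28": 0.329, "*37": 0.012}
  VKORC1:  {"*1": 0.669, "*2": 0.331}
mean_coverage: 30.0
depth_sd: 3.0
positions_per_gene: 16
drug_frequencies:
  simvastatin: 0.201
  omeprazole: 0.195
  amitriptyline: 0.033
  sertraline: 0.023
  ibuprofen: 0.022
  warfarin: 0.013
  citalopram: 0.012
  clopidogrel: 0.012
  metoprolol: 0.012
  lansoprazole: 0.010
  pantoprazole: 0.010
  tramadol: 0.008
  meloxicam: 0.006
  escitalopram: 0.005
  paroxetine: 0.005
  venlafaxine: 0.005
  codeine: 0.005
  nortriptyline: 0.004
  risperidone: 0.004
  celecoxib: 0.004
  phenytoin: 0.004
  imipramine: 0.003
  piroxicam: 0.003
  clomipramine: 0.002
  fluvoxamine: 0.002
  propafenone: 0.002
  tenoxicam: 0.002
  efavirenz: 0.002
  azathioprine: 0.002
  mercaptopurine: 0.001
  tacrolimus: 0.001
  atazanavir: 0.001
missing_medication_fraction: 0.053
background_drug_rate: 3.6
demographics:
  sex: {F: 0.635, M: 0.365}
  color_race:
    White: 0.581
    Brown: 0.282
    Black: 0.064
    Yellow: 0.027
    Others: 0.021
    No answer: 0.025
  age_gamma_shape: 1.4
  age_gamma_scale: 10.0
  age_minimum: 60
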