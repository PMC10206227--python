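# Methods

## Scope and model

`pgxcohort` analyses one pharmacogene at a time.  A gene's variation is
represented as a finite set of *star alleles*: the reference haplotype `*1`
(no defining variants, activity score 1.0), SNV/indel-defined haplotypes, a
whole-gene deletion allele (`*5` for CYP2D6, `*DEL` elsewhere), `xN`
duplication labels formed from any base allele, and composite/tandem
rearrangement labels (`*68+*4`, `*36+*10`) that are named units with their own
activity score but no defining-variant set.  An individual's state per gene is
an unordered diplotype, rendered canonically with the numerically lower
allele first.

Coordinates are fixed to hg19 and chromosome labels are normalized to
`chrN`.  Indels must be left-normalized so they match definition rows
byte-for-byte; the matcher does no realignment.

## Reference tables

The shipped fixture bundle covers eleven genes (the nine PharmGKB level-1A
genes plus CYP4F2/VKORC1) with a curated minimal subset of 2–7 alleles per
gene — the canonical clinically tested variants (e.g. CYP2C19 \*2/\*3/\*17,
SLCO1B1 \*5/\*15, TPMT \*2/\*3A/\*3C, UGT1A1 \*28/\*37/\*6, CYP4F2 \*3,
VKORC1 \*2).  It is a synthetic curation intended for testing and
demonstration, not a PharmVar/PharmGKB dump; full tables load through the
same TSV formats.  Function class is always derived from the activity score
(0 → loss, (0,1) → decreased, [1,1.5) → normal, ≥ 1.5 → increased, undefined
→ unknown), never stored, so the two cannot disagree.  VKORC1 `*2`
deliberately carries no activity score: its function class is unknown and its
phenotype comes from the warfarin carrier rule, not from AS.

## Star-allele matching

Candidates for a haplotype are the non-composite alleles whose defining set
is a subset of the haplotype's variants; the candidate with the most defining
variants wins and ties resolve to the earlier allele in table order.  This
maximal-subset rule is the dominant convention among star-allele callers; it
makes nested definitions (CYP2B6 \*9 ⊂ \*6, TPMT \*3C ⊂ \*3A, SLCO1B1 \*5 ⊂
\*15) behave correctly.  The `exact` flag records whether the haplotype had
no residual unmatched variants; residuals demote the flag but never fail the
call.

## Copy number

Depth is normalized within sample against the mean depth over a diploid
control region (the VDR locus), so a two-copy gene sits at ratio 1.0.  The
whole-gene copy number is `clamp(round(2 · median ratio), 0, 3)` with .5
rounded away from zero; the cap at 3 covers the observed 0–3 range and
declares per-segment/hybrid events out of scope.  Placement rules where the
evidence is silent:

* **cn 1** — the deletion replaces the haplotype with fewer non-reference
  variants (tie: haplotype 2).  This is always consistent with the simulated
  truth, because a deleted haplotype emits no variants.
* **cn 3** — the `x2` suffix attaches to the unique non-reference allele if
  exactly one haplotype is non-reference, otherwise to haplotype 1.  When a
  duplication co-occurs with a *different* non-reference allele the
  VCF + depth evidence genuinely cannot localize the extra copy; the
  convention picks deterministically and the call's exact flag is cleared.
  Round-trip tests therefore draw duplications only in evidence-identifiable
  configurations (duplicated allele homozygous, with the reference, or of
  the reference itself); SNV alleles and deletions round-trip unrestricted.

Unphased genotypes are a hard error: the pipeline assumes statistically
phased input and refuses to guess.

## Phenotype translation

Non-CYP2D6 genes use the curated translation table; an absent diplotype is
`Unknown`.  CYP2D6 falls back to the activity-score sum with the current
consensus bins (0 / (0,1.25) / [1.25,2.25] / >2.25 for Poor / Intermediate /
Normal / Ultrarapid); an allele without an AS poisons the sum to
`Indeterminate`.  `xN` multiplies the base AS by N; composites use their own
AS.  CYP4F2 and VKORC1 have no translation tables; carriers of one or two
copies of CYP4F2 \*3 are assigned the higher-warfarin-dose phenotype and
carriers of VKORC1 \*2 the decreased-warfarin-dose phenotype, independently.
The higher-dose direction for CYP4F2 \*3 follows the warfarin dosing
guideline (carriers need a 5–10% dose increase).  "Likely/Possible"
phenotype qualifiers are collapsed onto their base phenotype.

## Risk and interactions

The EHR priority table marks, per gene, which phenotypes are high-risk; the
fixture follows CPIC/EHR practice (e.g. CYP3A5 expressers — normal and
intermediate metabolizers — are the risk group; TPMT indeterminate is
high-risk).  Interaction flags are the cross product of taken drugs and
high-risk genes restricted to the level-1A pair list; for CYP4F2/VKORC1 the
only listed drug is warfarin, so dose-phenotype flags fire only there.  Drug
names are lower-cased, trimmed and passed through a small synonym table
before matching; unmatched names pass through and simply never flag.
Individuals with missing medication data are excluded from all medication
denominators, and the share of individuals with ≥ 1 interaction is reported
against both the informative cohort and the drug users, since both readings
are in circulation.

## Synthetic cohort generator

The generator emulates an elderly (60+), census-sampled, admixed urban
cohort of 1,171 individuals:

* **Genotypes.** Per gene, two haplotypes drawn independently from a
  configured frequency vector (HWE), or a joint diplotype draw for genes
  listed in diplotype mode.  Genes are independent; within-gene LD is
  implicit in the haplotype units.  Default frequencies are set to published
  population values where available (UGT1A1 \*28 0.329, VKORC1 \*2 0.331,
  CYP4F2 \*3 0.292, CYP3A5 \*3 0.817, CYP2C9 \*2/\*3 0.113/0.052, …) and to
  realistic magnitudes otherwise; composites are excluded from the default
  because they cannot be rendered into VCF signal.
* **Signal.** One phased multi-sample VCF (haplotype k carries allele k's
  variants; deletions emit reference) and a depth TSV with 16 positions per
  gene plus control rows, expected depth `mean_coverage · cn/2` (30× default)
  with Gaussian noise (sd 3.0 ≈ 10% of coverage; the median over 16 positions
  makes copy-number misrounding negligible at these settings).
* **Medications.** Each listed drug is an independent Bernoulli draw
  (defaults: simvastatin 0.201, omeprazole 0.195, amitriptyline 0.033, the
  rest ≤ 2.3%); a Poisson(3.6) count of unlisted background drugs yields a
  median of ~4 total drugs and ~41% polypharmacy (≥ 5 drugs); 5.3% of
  individuals have missing medication data, reflecting questionnaire
  non-response.  Drug use is independent of genotype.
* **Demographics.** Sex 63.5% F / 36.5% M; Brazilian census color/race
  categories (White 58.1%, Brown 28.2%, Black 6.4%, Yellow 2.7%, Others
  2.1%, no answer 2.5%); age 60 + Gamma(1.4, 10) floored to years, giving a
  median near 71.

All draws derive from one seed through separate named streams
(demographics, genotypes, medications, depth noise), so equal seed + config
gives byte-identical outputs.

What the simulator does **not** capture — and what passing tests therefore
do not show about real data: gene–pseudogene homology artefacts, partial-gene
and hybrid structural variants, phasing errors, depth waviness/GC bias,
population structure and LD between genes, and any genotype–medication
correlation.  Round-trip fidelity demonstrates internal consistency of the
caller with the declared signal model, not calling accuracy on sequencing
data.

## Numerical conventions

Percentages are rounded half-up to one decimal (printed-report style).
Frequency denominators: 2N haplotype units per gene (an `xN` duplication
counts as one unit under its label), N diplotype/phenotype units.  "Common"
alleles are frequency > 0.05 strictly; rare bins are strict `< 0.05` /
`< 0.01`, so `total = below(0.05) + at_or_above(0.05)` always holds.
Statistical tests use 3-binomial-SE bands; the frequency-recovery check
aggregates (replicate × parameter) comparisons and requires ≥ 99% inside the
band, consistent with the ≈ 99.7% per-check coverage of a 3σ band.

## Problem sizes

The test suite and acceptance script use 20 replicate cohorts of n = 200 for
round-trip fidelity, 100 replicates at the study scale n = 1,171 for
frequency recovery, and one full n = 1,171 pipeline run for cohort
summaries — sizes chosen so the whole suite runs in well under a minute per
component while keeping binomial standard errors small relative to the
tested effects.

## Known limitations

Cohort-level observed values from the motivating study design (e.g. the
overall share of individuals with a high-risk genotype, or per-gene observed
frequencies) depend on the restricted source cohort; the package reports the
analogous quantities for its simulated cohorts, using published values only
as generator parameters.  Hybrid/tandem alleles are supported as named table
units and direct diplotype input but are never called from signal.  CN > 3,
partial-gene events and read-backed phasing are out of scope.
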