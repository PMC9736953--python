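# Methods

This note records the models, conventions and design choices behind
`fh_spectrum`, in the order the pipeline applies them.

## Lipids and eligibility

LDL-C is taken from the subject table when measured, otherwise derived by
the Friedewald equation `LDL = TC − HDL − TG/2.2` (all mmol/L). The
equation is refused for TG > 4.5 mmol/L, where the TG/2.2 proxy for VLDL
cholesterol is invalid; the simulator truncates TG below that bound so the
relation holds identically in synthetic data (TC is reconstructed as
`LDL + HDL + TG/2.2`, so conservation is exact to floating-point).

Eligibility reproduces a community-screen design: adults (≥18 y), no
secondary hypercholesterolaemia (hypothyroidism, CKD, nephrotic syndrome,
cholelithiasis) or pregnancy, and baseline LDL-C at or above a
PCAD-conditional cut-off — ≥4.0 mmol/L with personal premature coronary
disease, ≥4.9 mmol/L without. Both cut-offs are inclusive. When several
rules fail, the reported reason is the first in that order.

## DLCN scoring

The DLCN point table is data (`data/dlcn_points.json`), versioned so
criterion revisions swap in without code changes. Scoring takes the
**maximum** item within each of the five groups — family history (2/1),
clinical history (2/1), physical examination (tendon xanthomata 6,
premature corneal arcus 4), LDL-C band (≥8.5 → 8, 6.5–8.4 → 5, 5.0–6.4 →
3, 4.0–4.9 → 1) and DNA (8) — and sums the group maxima. Two conventions
are deliberate and test-pinned:

* LDL bands are half-open `[lower, upper)`; the printed band "4.0–4.9"
  is `[4.0, 5.0)`.
* Corneal arcus scores only when premature (<45 y). If no onset age was
  recorded, the subject's current age stands in for it.
* The DNA group is **disabled by default**: screening studies score
  subjects clinically before sequencing, and enabling DNA points by
  default would leak the outcome into the stratification. A flag
  re-enables it for post-genetic rescoring.
* Whether family-history sub-items may stack is not decidable from
  published category tables alone; max-per-group is asserted as the
  standard convention and pinned by tests.

Categories: definite >8, probable 6–8, possible 3–5, unlikely <3;
"potential FH" pools probable and definite. Cut-offs are configurable but
must be strictly increasing.

## Variant filtering

The pipeline is annotation-level: HGVS strings are opaque identifiers,
variants are keyed by (gene, hgvs_c), and coordinates are a VCF
passthrough. The MAF filter excludes a call iff a reference-panel MAF is
**present and strictly above** the threshold (default 5%). Absent MAF
retains the call: novel variants have no panel record, and missingness
must not exclude them. A MAF exactly at the threshold is retained.

In-silico predictions are categorical inputs (PolyPhen2, SIFT, REVEL);
the damaging count (0–3) is informational. Mapping predictor consensus to
ACMG PP3/BP4 is a curation policy with no single published convention, so
it is off by default and available as an explicit option (PP3 at ≥2
damaging calls; BP4 when all three tools reported and none is damaging).

## ACMG combination

Evidence codes are inputs; the engine only combines them. Clauses live in
`data/acmg_rules.json` as minimum-count conjunctions over the strength
classes (PVS/PS/PM/PP/BA/BS/BP, fixed by code prefix; strength-modified
usage is unsupported). Pathogenic clauses are evaluated before likely
pathogenic, benign before likely benign; the first matching clause is
reported as `fired_rule` for auditability. Evidence matching both sides is
conflicting and yields VUS, as does evidence matching neither. Pathogenic
and likely pathogenic pool as PV, the unit of "genetic confirmation".

The engine is cross-checked two ways: against a brute-force transcription
of the rule list over the full bounded lattice (nV≤1, nS≤3, nM≤4, nP≤5,
nBA≤1, nBS≤2, nBP≤3 — 5,760 evidence sets), and against the packaged
40-variant catalogue, where 39/40 published pooled labels agree. The one
disagreement (*APOB* c.1400C>G, PM2+PP3+PP4+PP5, published LP) is strictly
VUS; the package reports the strict tier rather than reproducing the
published label.

## Genotype profiles and cohort statistics

A subject is PV-positive when carrying ≥1 PV in a counted gene. By
default the counted genes are the dominant ones (*LDLR*, *APOB*,
*PCSK9*): *LDLRAP1* is autosomal recessive, so its heterozygotes are
labelled `LDLRAP1_het` but not counted as genetically confirmed — the only
convention under which the published genotype-class total (82) and the
dominant-gene detection tables are mutually consistent. A switch counts
them for sensitivity analyses. Subjects with PV in two genes get the
specific double-heterozygote label; two PV in one gene keep that gene's
heterozygote label (logged; not observed in the source data).

Reporting conventions, chosen to match every published figure and fixed
package-wide:

* percentages round half-up to one decimal (exact rational arithmetic via
  `decimal`/`fractions`, immune to binary-float ties);
* "1:N" ratios round N to the nearest integer with exact halves **down**
  (5130/12 = 427.5 → 1:427), the only convention consistent with all
  published ratios;
* an empty denominator reports an undefined (NaN) percent, never 0; a
  zero numerator reports the ratio sentinel `1:inf`.

Detection rates are computed over eligible, clinically diagnosed subjects
(DLCN ≥ possible) for three groups — all FH, potential only, possible
only — whose numerators and denominators partition exactly. Community
prevalence divides by everyone screened. The spectrum counts distinct
(gene, hgvs_c) variants per gene for PV and VUS separately.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, at
the scale of a national community screen:

* `n_subjects` defaults to 5,130, the screened-cohort size.
* Carrier status is an independent Bernoulli draw per subject per
  catalogue variant (`carrier_freq`); carriers are heterozygous. Because
  draws are independent across variants, double heterozygotes arise
  naturally at product frequencies; a switch restricts each subject to at
  most one variant. `panel_maf` is an annotation only — it feeds the MAF
  filter, never the planting frequency.
* Non-carrier LDL-C is N(3.4, 1.0²) mmol/L truncated at 0.5 — a
  community-scale distribution placing ~7% of adults above the clinical
  cut-offs, consistent with a screen that diagnoses 372/5130. Carriers
  get a per-gene additive shift (LDLR +2.5, APOB +2.0, PCSK9 +2.3,
  LDLRAP1 +1.0 mmol/L), reproducing the ordering of published carrier
  baselines (5.5–6.5 mmol/L for dominant genes, mild elevation for
  recessive-gene heterozygotes).
* TG ~ N(1.85, 0.7²) truncated to (0.2, 4.5] so Friedewald is always
  valid; HDL ~ N(1.35, 0.35²) truncated at 0.4; age ~ N(46, 15²)
  truncated at 18; clinical-sign probabilities are conditional on carrier
  status (e.g. tendon xanthomata 8% in carriers vs 0.1% otherwise,
  premature arcus 35% vs 2%), on the scale reported for clinically
  diagnosed community FH.
* Reproducibility: one root seed; every random quantity has its own named
  substream (`[seed, 0, field]` for clinical fields, `[seed, 1, j]` for
  catalogue variant *j*). Appending a catalogue variant or enlarging the
  cohort therefore never perturbs draws already made for earlier variants
  or subjects, and identical configs give byte-identical tables. Named
  per-quantity substreams realise the same isolation as per-subject
  counter streams while keeping every draw vectorised.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: polygenic LDL-C architecture, linkage and
haplotype structure, measurement and questionnaire error correlated with
disease status, ascertainment by convenience sampling, or homozygous FH.
Recovery tests demonstrate that the pipeline is an unbiased observer of
the generative model, not that the model is reality.

## Validation problem sizes

The parameter-recovery studies use 200 replicates at n = 5,130 (one
planted LDLR variant at frequency 12/5130) and check that the exact
Clopper–Pearson 95% interval around each replicate's recovered prevalence
covers the planted value in ≥90% of replicates; being exact, the interval
is conservative and observed coverage sits near 97%. The rule-engine
equivalence check enumerates the full 5,760-set evidence lattice. Both
sizes make the whole suite run in well under a minute while leaving the
binomial sampling error far below the tolerances being checked.

## Known limitations

* Evidence codes are trusted inputs; the package assigns no evidence from
  population databases, segregation or functional data.
* HGVS strings are not normalised; the same variant written two ways
  counts twice.
* DLCN scoring covers the standard point table only; Simon Broome
  criteria and treatment-adjusted LDL-C back-calculation are out of scope.
* Prevalence is reported without confidence intervals by default,
  matching the source study's presentation (the coverage machinery in the
  validation suite shows how to attach exact binomial intervals).
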