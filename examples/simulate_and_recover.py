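"""Simulate a community screen and recover the planted carrier prevalence.

Plants one LDLR pathogenic variant at the study-scale frequency of 12/5130,
runs the full pipeline (eligibility -> DLCN -> MAF filter -> ACMG ->
genotype profiling) and compares the recovered prevalence with the truth.
"""

from fh_spectrum import summarise_cohort
from fh_spectrum.synthetic_cohort import PlantedVariant, SimConfig, simulate_cohort

p_true = 12 / 5130
config = SimConfig(
    n_subjects=5130,
    seed=7,
    variant_catalogue=[
        PlantedVariant(
            gene="LDLR",
            hgvs_c="c.301G>A",
            evidence="PS3,PM1,PM2,PP2,PP3,PP4,PP5",
            carrier_freq=p_true,
        )
    ],
)
subjects, calls = simulate_cohort(config)
summary, scored, classified = summarise_cohort(subjects, calls)

print(f"screened {summary.n_screened}, planted prevalence {100 * p_true:.2f}%")
print(f"eligible subjects by category: {summary.n_by_category}")
print(f"recovered carrier prevalence: {summary.carrier_prevalence}")
print()
print(summary.detection.to_string(index=False))
# The recovered prevalence is the binomial realisation of the planted one
# (the pipeline finds every planted carrier); the detection table shows how
# many carriers also met the clinical DLCN criteria, mirroring the gap
# between community prevalence and clinical detection in a real screen.
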