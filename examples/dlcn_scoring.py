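"""Score two screening subjects on the Dutch Lipid Clinic Network criteria.

Builds one severe and one mild subject, derives LDL-C by Friedewald where it
was not measured, and prints the per-group points, total score and category.
"""

from fh_spectrum import SubjectRecord, dlcn_score, eligibility

subjects = [
    SubjectRecord(
        subject_id="severe",
        age=52,
        tc=11.2,
        tg=1.8,
        hdl=1.4,  # Friedewald LDL-C ~ 9.0 mmol/L
        tendon_xanthomata=True,
        family_first_degree_premature_cad_or_high_ldl=True,
    ),
    SubjectRecord(subject_id="mild", age=44, ldl_baseline=5.5, tc=7.0, tg=1.5, hdl=1.2),
]

for s in subjects:
    elig = eligibility(s)
    res = dlcn_score(s)
    print(f"{s.subject_id}: LDL-C {s.ldl():.1f} mmol/L, eligible={elig.included}")
    print(f"  group points {res.group_points}")
    print(f"  DLCN score {res.score} -> {res.category.value} (potential FH: {res.potential})")

# The severe subject scores 6 (xanthomata) + 1 (family) + 8 (LDL >= 8.5) = 15,
# i.e. definite FH; the mild one scores 3 from the 5.0-6.4 LDL band alone,
# i.e. possible FH. "Potential FH" pools probable and definite.
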