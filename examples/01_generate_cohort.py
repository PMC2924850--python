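"""Generate a grade-stratified synthetic cohort and inspect its ground truth.

Builds the default 115-patient cohort (40 normal, 21 mild, 45 moderate,
9 severe diastolic dysfunction), then prints the per-grade means of the
exact analytic filling indices.  Peak filling rate (PFR, ml/s) rises from
mild to severe dysfunction while the diastolic 80% volume-recovery time
(DVR80, % of diastole) is longest in mild dysfunction — the dissociation
the analysis chain is designed to detect.
"""

from cinefill import CohortSpec, generate_cohort

cohort = generate_cohort(CohortSpec(seed=0))
frame = cohort.frame

print(f"generated {len(cohort)} patients")
summary = frame.groupby("grade")[
    ["edv", "sv", "analytic_pfr", "analytic_tpfr", "analytic_dvr80", "analytic_ea"]
].mean().round(1)
print(summary)
print(
    "\nanalytic_* columns are the closed-form ground-truth indices implied "
    "by each patient's filling-lobe geometry."
)
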