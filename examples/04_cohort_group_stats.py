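"""Group statistics on a calibrated synthetic foot cohort.

Simulates resting foot acquisitions for a scaled-down cohort (5/5/5
subjects x 2 feet instead of the full 14/11/16), extracts digit ("toe")
and dorsum region parameters, and runs one-way ANOVA with Bonferroni
post hoc per parameter x region.  With the full cohort the group
ordering C > M > D for toe I_max/AUC and the delayed MTT of the D group
reproduce the published pattern.
"""

from icgflow import generate_cohort, stats_table

cohort = generate_cohort(n_subjects=(5, 5, 5), conditions=("rest",), seed=7)
table = cohort.region_table()

print("per-limb region rows:", len(table))
stats_df, results = stats_table(table)
cols = ["parameter", "region", "mean_C", "mean_D", "mean_M", "f", "p", "p_C_D"]
print(stats_df[cols].round(3).to_string(index=False))

toe_imax = stats_df.query("parameter == 'i_max' and region == 'digits'").iloc[0]
print(
    f"\ntoe I_max: C {toe_imax['mean_C']:.0f} vs D {toe_imax['mean_D']:.0f} A.U., "
    f"Bonferroni-adjusted p = {toe_imax['p_C_D']:.2e} "
    "(reduced arterial blood volume in uncomplicated diabetes)"
)
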