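"""Simulate the default paired cohort and run the full validation.

Generates 68 subjects at two timepoints with the study-condition
defaults, runs the measurement + statistics pipeline, and prints the
chin-offset comparison and post-surgery method-agreement summaries.
"""

from chinpoint import generate_cohort, paper_default_config, run_validation

config = paper_default_config(seed=1)
cohort, truth = generate_cohort(config)
results = run_validation(cohort)

t3 = results.table3
print("ACP-to-MCP distance |x| (mm):")
for row in t3.itertuples(index=False):
    print(
        f"  {row.timepoint}: mean {row.mean:5.2f} +/- {row.sd:4.2f}, "
        f"median {row.median:5.2f}, IQR {row.iqr25:4.2f}-{row.iqr75:5.2f}"
    )
print(f"  Wilcoxon signed-rank p = {t3['wilcoxon_p'].iloc[0]:.2g}")
print("\nPost-surgery method agreement (ACP - MCP, mm):")
for row in results.table4.itertuples(index=False):
    print(
        f"  {row.variable}: ME {row.me_mean:+5.2f} +/- {row.me_sd:4.2f}, "
        f"MAE {row.mae_mean:4.2f} +/- {row.mae_sd:4.2f}"
    )
print(
    "\nSurgery moves chins toward the 170-degree ray, so |x| drops from\n"
    "pre- to post-surgery; the near-zero post-surgery mean errors are\n"
    "what justify using the modified point as a surrogate chin reference."
)
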