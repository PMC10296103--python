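"""Group comparisons for the demographic and psychosexual variables.

Generates a synthetic cohort at the study's group sizes (14/15/17) and runs
the omnibus ANOVA, Levene's test, the robust Welch and Brown-Forsythe
statistics, and the appropriate post hoc for each variable.
"""

import json

from cortexmicro import pipeline, synthdata

participants, _ = synthdata.generate_cohort(seed=7)
report = pipeline.table1_report(participants)

for var, block in report.items():
    welch = block["welch"]
    print(f"{var}: F({block['df1']}, {block['df2']}) = {block['F']}, "
          f"p = {block['p']}; Levene p = {block['levene_p']}; "
          f"Welch F(2, {welch['df2']}) = {welch['F']}; "
          f"post hoc = {block['posthoc_method']}")

print()
print(json.dumps(report["gidyq_mean"]["descriptives"], indent=2))
print()
print("The GIDYQ-AA separates the gender-dysphoric group (mean ~2.2) from "
      "both cisgender groups (~4.9); its variances differ strongly across "
      "groups, so Levene's test is significant and the heteroscedasticity-"
      "robust Welch statistic and Games-Howell post hoc are reported.")
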