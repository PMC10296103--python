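"""Behavior PLS with permutation and bootstrap inference on planted data.

Generates a three-group cohort carrying a latent brain-behavior effect in
the cisgender-boy and GD AFAB groups only (38 of 152 ROI-metric columns
loaded), runs behavior PLS on the group-stacked within-group correlation
matrix, and prints the latent-variable summary, the group-wise brain-score-
behavior correlations with bootstrap CIs, and the stable-ROI table.
"""

from cortexmicro import bpls, pipeline, synthdata

spec = synthdata.CohortSpec(group_sizes=(50, 50, 50))
participants, _ = synthdata.generate_cohort(spec, seed=11)
wide = synthdata.generate_brain(participants, seed=12)
wide = wide.merge(participants[["id", "strength", "degree", "age_months"]],
                  on="id")
ing = pipeline.ingest_roi_table(wide)

result = bpls.run_bpls(
    ing["X_raw"], ing["Y"], ing["group_sizes"],
    n_perm=1000, n_boot=1000, seed=5,
    column_names=ing["columns"],
    group_labels=("cis_boy", "gd_afab", "cis_girl"),
)

print(f"LV1: {result.covariance_pct[0]:.2f}% of cross-block covariance, "
      f"permutation p {result.perm_p_display(0)}")
print(f"LV2: {result.covariance_pct[1]:.2f}%, p = {result.perm_p[1]:.3f}")
print()
print(bpls.correlation_table(result).round(3).to_string(index=False))
print()
stable = bpls.stable_roi_table(result)
print(f"stable columns at |bootstrap ratio| >= 3: "
      f"{int(result.stable_mask[:, 0].sum())} of 152 "
      f"({len(stable)} distinct regions)")
print()
print("The first latent variable captures the planted effect: brain-score "
      "correlations are reliably nonzero (95% CIs exclude 0) for the two "
      "affected groups and null for cisgender girls, reproducing the "
      "two-groups-share-one-pattern structure the method is designed to "
      "expose.")
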