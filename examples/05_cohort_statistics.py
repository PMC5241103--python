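"""Run a small synthetic cohort end to end and print the test table.

Each patient gets jittered tumor geometry; the cohort report collects
one ComparisonRecord per plan and runs paired t tests (sMRI vs
conventional volumes, recurrence coverage), a one-sample t of Dice
against 1.0, and ANOVA on PTV2 coverage across plan variants.
"""

import pandas as pd

from smrirt import CohortManifest, run_cohort

pd.set_option("display.width", 160)

out = run_cohort(CohortManifest(n_patients=4, seed=3, recurrence_mixing=1.0))
df = out["records"]

summary = (df[df["threshold"].notna()]
           .groupby("threshold")[["pct_increase_ctv2", "dice_ctv2",
                                  "seg_outside_idl2_cm3",
                                  "recurrence_cov_ctv_pct"]].mean())
print("cohort means by fold threshold:")
print(summary.round(2))
conv_cov = df[df["threshold"].isna()]["recurrence_cov_ctv_pct"].mean()
print(f"\nconventional CTV2 recurrence coverage: {conv_cov:.1f}%")
print("\nstatistics:")
print(out["stats"][["comparison", "threshold", "statistic", "df", "p_value"]]
      .round(4).to_string(index=False))
# Small one-sided p-values for the volume and recurrence-coverage tests
# say the sMRI-merged targets are systematically larger and cover more
# of the recurrence than the conventional chain; Dice significantly
# below 1.0 says they are also spatially different, not just inflated.
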