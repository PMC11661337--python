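"""Fit regression-based norms on robust controls and compute the CSS.

Each of the six test scores is regressed on age, sex and education within
the robust healthy-control reference; a participant's z-score is their
residual in reference-residual-SD units, and the cognitive summary score
(CSS) is the mean of the six z-scores.
"""

from nsdcog import (apply_norms, fit_all_norms, make_ppmi_like_cohort,
                    stage_cohort)

staged = stage_cohort(make_ppmi_like_cohort(seed=1))
reference = staged[staged["cohort_role"] == "robust_hc"]

models = fit_all_norms(reference)
print("Norm model for SDMT (raw-score units):")
m = models["sdmt"]
print(f"  intercept {m.intercept:.2f}, age {m.age_slope:+.3f}/yr, "
      f"male {m.male_slope:+.2f}, education {m.education_slope:+.3f}/yr")
print(f"  residual scale {m.residual_scale:.2f} on n={m.n_reference}")

scored = apply_norms(staged, models)
print("\nMean CSS by group (reference mean is 0 by construction):")
print(scored.groupby("group_label")["css"].agg(["count", "mean", "std"])
      .round(3).to_string())
print(f"\nNot evaluable (missing education or a test score): "
      f"{int((~scored['css_evaluable']).sum())} participants")
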