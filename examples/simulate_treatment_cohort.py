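"""Simulate a treatment-response cohort and run the marker statistics.

Generates 45 patients with paired pre/post marker panels (baselines and
treatment effects matched to the published cohort medians), runs the
normality-gated paired test for every marker, and tests whether an increase
in right-ventricular amyloid-affected volume predicts the composite endpoint
(death or heart-failure hospitalization) with a programmed hazard ratio of
3.19.
"""

import dpdquant as dq

cohort = dq.generate_cohort(45, hazard_ratio=3.19, seed=11)

rows = dq.marker_change_table(cohort)
print("Most significant marker changes (unadjusted p, pre -> post median):")
for r in rows[:8]:
    print(
        f"  {r.marker:32s} p={r.p_value:8.2e}  "
        f"{r.pre_median:7.1f} -> {r.post_median:7.1f}  [{r.test_used}]"
    )

res = dq.survival_association(cohort, "AFFECTED_VOLUME_RV")
print(
    f"\nDelta affected-volume RV >= 0 vs < 0 "
    f"({res.n_increase} vs {res.n_decrease} patients, {res.n_events} events):"
)
print(f"  univariate HR {res.univariate_hr:.2f} "
      f"(95% CI {res.univariate_ci[0]:.2f}-{res.univariate_ci[1]:.2f}), "
      f"log-rank p={res.logrank_p:.3f}")
if res.adjusted_hr is not None:
    print(f"  adjusted   HR {res.adjusted_hr:.2f} "
          f"(95% CI {res.adjusted_ci[0]:.2f}-{res.adjusted_ci[1]:.2f}), "
          f"p={res.adjusted_p:.3f}")
print(
    "\nAn HR > 1 means patients whose RV affected volume grew on therapy had a\n"
    "higher hazard of the composite endpoint; the simulator programs HR 3.19."
)
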