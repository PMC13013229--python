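"""Inter-rater agreement of manual marker readings via ICC(2,1).

Simulates three readers measuring myocardial SUVpeak on 20 patients with a
small independent per-reader error, then computes the single-rater,
absolute-agreement intraclass correlation.  An ICC near 1 means readers are
interchangeable; automated extraction removes this variability entirely
(identical "readers" give ICC exactly 1).
"""

import numpy as np

from dpdquant.cohort import icc_agreement

rng = np.random.default_rng(3)
true_suvpeak = rng.lognormal(np.log(14.6), 0.35, size=20)  # myocardial SUVpeak scale
readings = np.column_stack(
    [true_suvpeak + rng.normal(0, 0.9, 20) for _ in range(3)]
)

res = icc_agreement(readings)
print(f"3 readers x 20 patients: ICC(2,1) = {res.icc:.3f} (p = {res.p_value:.2e})")

automated = np.column_stack([true_suvpeak] * 3)  # deterministic pipeline
res_auto = icc_agreement(automated)
print(f"automated extraction (identical outputs): ICC = {res_auto.icc:.3f}")

print(
    "\nICC(2,1): two-way random effects, absolute agreement, single rater.\n"
    "Manual readers agree well but not perfectly; the automated pipeline is\n"
    "deterministic, so its inter-'reader' variability is zero by construction."
)
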