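"""Disentangle baseline confounding from the intervention effect.

Simulates a trial whose test arm has a lower baseline-MMSE mean (the
confounder raises that arm's hazard from day one) with zero true direct
intervention effect, then fits the joint model with and without baseline
MMSE in the survival sub-model. The time-constant direct effect soaks up
the baseline imbalance; correcting for MMSE shrinks it toward a hazard
ratio of 1 while the trajectory-mediated (indirect) components barely move.
"""

from dataclasses import replace

import jointtrial as jt

surv_truth = replace(jt.default_survival(), gamma_fortasyn=0.0)  # no direct effect
cfg = jt.confounded_variant(
    jt.default_config(n_subjects=311, seed=42, true_survival=surv_truth)
)
ds = jt.simulate_trial(cfg)

spec = jt.JointSpec("value", quadrature_points=9, n_baseline_intervals=5)
fit_no = jt.fit_joint(ds, replace(spec, include_bmmse_in_survival=False))
fit_yes = jt.fit_joint(ds, spec)

for label, fit in (("without", fit_no), ("with", fit_yes)):
    c = jt.decompose(fit, time_grid=[0.0, 2.0])
    print(f"{label:7s} bmmse correction: direct HR exp(gamma1) = {c.direct:5.2f}  "
          f"indirect constant = {c.indirect_constant:5.2f}  "
          f"total HR at 2y = {c.total[1]:5.2f}")

print(f"\nconventional time-fixed PH hazard ratio: "
      f"{jt.cox_reference_effect(ds, include_bmmse=False):.2f} (uncorrected), "
      f"{jt.cox_reference_effect(ds, include_bmmse=True):.2f} (corrected)")
print("The direct HR above 1 under no true direct effect is the baseline "
      "imbalance masquerading as harm; the MMSE-corrected fit moves it back "
      "toward 1.")
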