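# jointtrial

Joint models for longitudinal and time-to-event data in two-arm clinical
trials, built around the kind of design used in prodromal Alzheimer's disease
studies: a repeatedly measured cognition score (CDR-SB-like, visits near
0/6/12/24 months), a right-censored time until clinical dementia diagnosis,
and a baseline MMSE-like covariate that may be imbalanced between arms
despite randomization.

Analysing the two outcomes separately (a mixed model for the score, a Cox
model for the diagnosis time) ignores that they are driven by the same
underlying disease process, and a Cox model cannot carry an endogenous
time-varying biomarker. `jointtrial` fits the two sub-models as a single
likelihood coupled through shared subject-level random effects:

**Longitudinal sub-model** (linear mixed model for subject *i* at time *t*, years):

    y_i(t) = m_i(t) + eps_i(t)
    m_i(t) = b0 + b1 t + b2 arm_i + b3 arm_i t + b4 bmmse_i + b5' site_i
             + u_i0 + u_i1 t,         (u_i0, u_i1) ~ N(0, D),  eps ~ N(0, s^2)

**Survival sub-model** (proportional hazards with a piecewise-constant
baseline), with one of three association structures linking the trajectory to
the hazard:

    lambda_i(t) = lambda_0(t) exp{ g1 arm_i + g2 bmmse_i + g3' site_i + assoc_i(t) }

    assoc_i(t) = a1 m_i(t)                      current value
               | a1 m_i(t) + a2 m_i'(t)         value + slope
               | a3 \int_0^t m_i(s) ds          cumulative effect (AUC)

Under the current-value association the intervention hazard ratio between two
otherwise identical subjects factorizes into a **direct** effect, a constant
**indirect** effect and a time-varying indirect effect:

    HR(t) = exp{ g1 + a1 (b2 + b3 t) } = exp(g1) * exp(a1 b2) * exp(a1 b3 t)

Because the direct effect is time-constant while the trajectory-mediated
effect builds up gradually, any baseline imbalance that acts on the hazard
immediately is largely absorbed into `g1`: adding the baseline covariate to
the survival sub-model then shrinks the direct effect while leaving the
indirect components essentially unchanged. The package ships a trial
simulator with exactly this structure, so every claim is testable end to end
without any proprietary data.

## Worked example

```python
import jointtrial as jt
from jointtrial.io import joint_coefficient_table

ds = jt.simulate_trial(jt.default_config(n_subjects=311, seed=11))
fit = jt.fit_joint(ds, jt.JointSpec(association_type="value"))
print(joint_coefficient_table(fit))
```

prints (abridged; `examples/simulate_and_fit.py`):

```
         term  estimate       se  p_value
         Time     0.637    0.071    0.000
Time:Fortasyn    -0.334    0.096    0.000
        Bmmse    -0.079    0.029    0.007
surv:Fortasyn    -0.025    0.194    0.898
   surv:Bmmse    -0.270    0.052    0.000
  Assoc:value     0.678    0.095    0.000
```

The outcome worsens by 0.64 points/year in the control arm and 0.33
points/year less under the intervention; a one-unit higher current trajectory
value doubles the diagnosis hazard (exp(0.678) = 1.97); a one-point higher
baseline MMSE lowers it by ~24%. The generating truth for this simulated
trial was 0.6, -0.23 and alpha = 0.66. `jt.decompose(fit)` then evaluates the
direct/indirect/total hazard-ratio curve, and `jt.bootstrap_bands` adds 95%
percentile bands from a cluster bootstrap (resampling whole subjects and
refitting).

Each script in `examples/` demonstrates one capability: the standard fit,
the baseline-confounding decomposition, association-structure selection by
AIC/BIC, and bootstrap bands.

A thin CLI wraps the same functions for scripted runs:

```bash
jointtrial simulate --n-subjects 311 --seed 1 --out sim/
jointtrial fit --longitudinal sim/longitudinal.csv --survival sim/survival.csv \
    --association value --association value_slope --out fits/
jointtrial decompose --longitudinal sim/longitudinal.csv \
    --survival sim/survival.csv --out dec/ --plot
```

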