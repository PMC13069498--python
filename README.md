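# nlcsp

A deterministic, auditable implementation of the nodule management rules
of the Australian National Lung Cancer Screening Program (NLCSP): given
participant covariates and longitudinal pulmonary-nodule observations
from low-dose CT (LDCT), it assigns each nodule one of seven NLCSP
management categories (0–6) and each participant one overall
recommendation per screening episode, at baseline and at follow-up. A
synthetic screening-cohort simulator generates multi-round histories —
benign-stable, resolving, indolent slow-growing, and aggressive
fast-growing nodule trajectories with volumetric measurement noise — so
every rule path is testable without real imaging data.

It is intended for screening-program analysts, clinical-decision-support
developers, and researchers who need the protocol's behaviour to be
reproducible, traceable (every category carries a `rule_trace`), and easy
to probe under simulated cohorts. It is not a medical device and performs
no image analysis.

## The rules at the core

**Baseline.** After special subtypes are routed to dedicated rules
(radiologist-suspicious → 6; benign calcification / macroscopic fat /
probable intrapulmonary lymph node → 1; airway nodules → 2 or 4;
atypical cysts → 4), every other nodule is categorized by its PanCan
(Brock) probability of lung cancer within 2 years,

&nbsp;&nbsp;&nbsp;&nbsp;*p* = logit⁻¹(β₀ + β·x),

over nine variables (age, sex, family history, emphysema; nodule size,
morphology, upper-lobe location, spiculation, nodule count), with
half-open bands: *p* < 1.5 % → category 1 (24-month LDCT); 1.5–< 6 % → 2
(12-month); 6–< 10 % → 3 (6-month); 10–< 30 % → 4 (3-month); ≥ 30 % → 5
(referral). Coefficients ship as versioned configuration (the published
full model with spiculation); the model is baseline-only and is never
applied once a prior CT exists.

**Follow-up.** Interval change drives everything. With volumetry
(preferred), relative change ΔV and volume doubling time
VDT = Δt·ln 2 / ln(V₂/V₁) classify a nodule as *growing*
(ΔV > +25 % and VDT < 600 d), *slowly growing* (ΔV > +25 % and
VDT ≥ 600 d on more than one assessment), *decreased* (ΔV ≤ −25 %), or
*stable*; by calliper mean diameter the corridor is ±1.5 mm with a
24-month split between growth and slow growth. Growth of either kind
refers (category 5). Stable nodules step down 4 → 3 → 2, and return to
category 1 (biennial screening) only after ≥ 24 months of documented
stability. Per-nodule results aggregate to the participant by the
maximum-category rule.

See `docs/methods.md` for the full rule set, numerical edge policies,
and simulator model.

## Worked example

```python
import datetime as dt
from nlcsp import (ParticipantCovariates, NoduleObservation, NoduleHistory,
                   compute_pancan_risk, classify_baseline_nodule,
                   classify_followup_nodule, aggregate_episode)

cov = ParticipantCovariates(age=64, sex="female",
                            family_history_lung_cancer=True, emphysema=False)
obs = NoduleObservation(nodule_id="N1", scan_date=dt.date(2025, 7, 1),
                        composition="solid", long_axis_mm=9.2, short_axis_mm=7.8,
                        volume_mm3=310.0, lobe="RUL", spiculation=True)

risk = compute_pancan_risk(cov, obs)
print(f"PanCan 2-year risk: {risk.probability:.4f}")
decision = classify_baseline_nodule(cov, obs, risk=risk)
print(f"category: {decision.category.value}  trace: {decision.rule_trace}")
print(aggregate_episode([decision], "P001", obs.scan_date).summary_text)
```

prints

```
PanCan 2-year risk: 0.1850
category: 4  trace: ['baseline.pancan_band:4']
participant P001; scan 2025-07-01; 1 nodule(s) under management; overall category 4 (Moderate risk); repeat LDCT in 3 months
```

— an 8.5 mm spiculated upper-lobe solid nodule in a 64-year-old woman
with a family history lands at 18.5 % two-year risk, inside the
10–< 30 % band: category 4, repeat LDCT in 3 months. At that 3-month
scan the nodule has barely changed:

```python
obs2 = NoduleObservation(nodule_id="N1", scan_date=dt.date(2025, 10, 1),
                         composition="solid", long_axis_mm=9.3, short_axis_mm=7.9,
                         volume_mm3=335.0, lobe="RUL", spiculation=True)
hist = NoduleHistory(nodule_id="N1", observations=[obs, obs2],
                     prior_category=decision.category)
fu = classify_followup_nodule(hist, cov)
print(f"growth: {fu.growth.status.value}  dV: {fu.growth.relative_volume_change_pct:+.1f}%  "
      f"VDT: {fu.growth.vdt_days:.0f} d")
print(f"new category: {fu.category.value}  interval: {fu.management.interval_months} months")
```

```
growth: stable  dV: +8.1%  VDT: 822 d
new category: 3  interval: 6 months
```

The +8.1 % change sits inside the ±25 % measurement-variability corridor,
so the nodule is stable and steps down to category 3 (6-month LDCT) —
the first rung of the de-escalation ladder that ends, after 24 months of
documented stability, back at biennial screening.

A command-line interface wraps the same library for tabular workflows:

```
nlcsp classify-baseline --input observations.csv --output reports.json
nlcsp simulate --seed 17 --n 500 --out cohort/
nlcsp run-program --seed 17 --n 200 --out outcomes/
```

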