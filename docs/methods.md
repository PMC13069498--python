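# Methods

## What the engine does

`nlcsp` is a deterministic, auditable implementation of the nodule
management rules of the Australian National Lung Cancer Screening Program
(NLCSP): given participant covariates and longitudinal per-nodule
observations from low-dose CT (LDCT), it assigns each nodule one of seven
management categories and each participant one overall recommendation per
screening episode. The protocol couples a baseline risk model (PanCan) to
a Lung-RADS-style follow-up state machine adapted for biennial routine
screening. The engine is a pure function of its inputs: identical inputs
and configuration always produce identical outputs, and every category
carries a `rule_trace` naming the branch that produced it.

## Category and management model

Categories 1–6 order increasing cancer risk; category 0 is orthogonal
(incomplete examination, or suspected infection/inflammation). The
category → management map is fixed:

| category | descriptor            | management |
|----------|-----------------------|------------|
| 0        | Incomplete            | repeat LDCT in 1, 2, or 3 months (caller-chosen, default 3) |
| 1        | Very low risk         | 24-month LDCT |
| 2        | Low risk              | 12-month LDCT |
| 3        | Low to moderate risk  | 6-month LDCT |
| 4        | Moderate risk         | 3-month LDCT |
| 5        | High risk             | clinical referral |
| 6        | Very high risk        | clinical referral |

The protocol offers three category-0 intervals with no selection rule, so
the interval is an explicit input with a default of 3 months. "Months" in
management outputs are nominal labels; all internal arithmetic on
longitudinal data uses exact calendar-day differences.

## Baseline algorithm

A baseline (first-ever) nodule is routed down exactly one branch:

1. features judged suspicious by the reporting radiologist → 6;
2. clearly benign (complete/central/popcorn/concentric-ring calcification,
   or macroscopic fat) or probable intrapulmonary lymph node → 1;
3. airway nodule: subsegmental → 2, segmental or more proximal → 4;
4. atypical pulmonary cyst (thick-walled or multilocular) → 4;
5. otherwise PanCan 2-year probability bands: < 1.5 % → 1; 1.5–< 6 % → 2;
   6–< 10 % → 3; 10–< 30 % → 4; ≥ 30 % → 5. All band edges are half-open,
   so a risk of exactly 6 % is category 3.

The protocol specifies the branches but not their mutual precedence; the
ordering above is this engine's design choice, made safety-first:
radiologist suspicion outranks everything, and benign/lymph-node
recognition precedes the airway and cyst paths so that, e.g., a calcified
granuloma with an incidental cystic component is never escalated down the
cyst path. The probable-intrapulmonary-lymph-node predicate is the
conjunction of: small size (reported mean diameter < 10 mm OR volume
< 524 mm³), solid composition, smooth margin, oval/lentiform/triangular
shape, and pleural association (contact anywhere, or a middle/lower lobe
location within 15 mm of the pleura). A missing pleural distance fails
the proximity clause rather than guessing.

"Suspicious features" is an input flag, not a computed detector: the
protocol defines it as radiologist judgment, and computing it would claim
image-analysis capability the engine does not have.

## PanCan (Brock) risk model

The baseline risk is the inverse-logit of a linear predictor over nine
variables: age, sex, family history of lung cancer, emphysema, nodule
mean diameter (via the transform `(d/10)^-1/2`, centred), morphology
contrasts (solid reference; part-solid, ground-glass), upper-lobe
location, spiculation, and total nodule count (centred). Coefficients are
*configuration*: they ship as a versioned YAML file with a provenance
block naming the source publication (the published full model with
spiculation of McWilliams et al., NEJM 2013), and every classifier also
accepts a precomputed probability, so the rule logic is testable
independently of any coefficient set. The default horizon is 2 years —
the horizon the baseline risk bands are defined against — and requesting
a horizon the loaded coefficient set was not fitted for is a
configuration error, not a silent reuse.

Two applicability rules are enforced: the model is never used when a
prior CT is available (it has no growth term), and never for the special
subtypes listed above (their morphology or location already determines
management). `pancan_applicable` returns the machine-readable reason.

The upper-lobe flag treats the lingula as non-upper-lobe by default (the
protocol does not fix lobe granularity); callers can override per
observation. A Monte-Carlo property test confirms the band structure's
working assumption that nodules with risk in [10 %, 30 %) very rarely
report a mean diameter under 8 mm under these coefficients.

## Growth assessment

Volumetry is preferred; calliper mean diameter is the fallback when
either compared scan lacks a segmented volume (mixed-method histories
fall back too, and record the method used). The comparison reference is
the nodule's *first appearance*, not the immediately preceding scan, so
slowly accumulating change is judged from where the nodule started.

Volumetric rules (ΔV is relative change reference → current; VDT is the
doubling time `days · ln 2 / ln(v_cur/v_ref)` over the same span — the
standard exponential-growth definition):

* growing: ΔV > +25 % and VDT < 600 days;
* slowly growing: ΔV > +25 % and VDT ≥ 600 days, at the current *and* at
  least one earlier assessment against the same reference;
* decreased: ΔV ≤ −25 % (inclusive);
* stable: everything else, including a first-time slow increase.

Numerical edges are resolved as follows: ΔV of exactly +25 % is stable
("greater than" is strict), exactly −25 % is decreased ("or more" is
inclusive), and a VDT of exactly 600 days is *not* growing — the boundary
goes to the slow-growth surveillance side, which still escalates on
persistence, so nothing is lost by resolving conservatively. VDT is
undefined (reported absent) for unchanged or shrinking nodules; shrinkage
is handled by the decrease rule, never by a negative doubling time.

Diameter rules: change of more than +1.5 mm over ≤ 24 months (730 days)
is growing; over > 24 months, slowly growing; ≤ −1.5 mm is decreased;
within ±1.5 mm, stable. Diameters are carried at 0.1 mm resolution
(half-up rounding — the finest clinically reported precision), and the
diameter *difference* is quantized to the same grid before threshold
comparison, so binary floating-point artefacts (7.6 − 6.1 =
1.5000000000000002) cannot push a true 1.5 mm change across the strict
threshold.

Whether slow growth should be judged on per-interval VDTs or
reference-to-current VDT is genuinely open; this engine uses
reference-to-current for both the current and the historical qualifying
assessment, which makes the persistence requirement monotone in evidence
(an intermediate scan can only add a qualifying assessment, never erase
one). For part-solid nodules growth is judged on whole-nodule
measurements; the solid component is carried in the record but is not
decisional at follow-up.

## Follow-up algorithm

Decision order at a follow-up scan: radiologist suspicion → 6; suspected
infection → 0 (short-interval repeat; the stability clock is frozen, not
reset); nodule absent on the current scan → resolved, recorded, no
management contribution; persistent segmental-or-more-proximal airway
nodule → 5 regardless of stability; growing or slowly growing → 5; first
seen at follow-up → interim size band; stable or decreased → stepped
de-escalation.

Both growth and slow growth refer (category 5): the slow-growth
definition exists precisely to catch indolent cancers that the fast rule
misses, and parking them in a short-interval recheck would defeat it.

Stepped de-escalation for stable/decreased nodules: 4 → 3, 3 → 2, and
2 → 1 only once stability has been documented for at least 24 months;
otherwise 2 stays 2 with another 12-month scan. The stability clock
accumulates days since the last non-stable event; the clock an assessment
sees includes the current inter-scan interval (a stable comparison
documents stability over that interval too). Under these rules a
forever-stable category-4 nodule follows exactly 4 → 3 → 2 → 2 → 1 over
3 + 6 + 12 + 12 months, which the test suite asserts end-to-end.
Persistent *subsegmental* airway nodules follow ordinary stepped logic —
the high-risk-even-when-stable rule names segmental or more proximal
levels only.

Nodules first seen on a non-baseline scan cannot use the baseline risk
model. They receive an interim category from the solid/part-solid size
bands (solid: < 6 mm → 2, 6–< 8 → 3, 8–< 15 → 4, ≥ 15 → 5 flagged for
radiologist review; part-solid ≥ 6 mm total: solid component < 6 → 3,
6–< 8 → 4, ≥ 8 → 5 flagged), with the special-subtype branches still
taking precedence. This path is an extrapolation beyond the letter of
the protocol tables and is marked as such in every `rule_trace` it
emits. Two gaps the tables leave are closed the same way: new pure
ground-glass nodules are assigned category 2 (the bands only cover solid
and part-solid morphologies), and a nodule whose prior category was 0
(infection suspected) but which persists at the short-interval repeat
re-enters through the same size bands, since no stepped row exists for it.

## Participant aggregation

The overall category is the maximum per-nodule category over 1–6
(resolved nodules contribute nothing but are listed). Category 0 is
arbitrated safety-first: it overrides categories 1–4 but never a
referral. A participant with no nodules is category 1 (24-month LDCT),
the program's biennial routine for very-low-risk participants. The fold
is order-independent, and associative whenever no category-0 flag is in
play (category 0 deliberately breaks the lattice: it is a statement about
the *exam*, not the nodule).

## Synthetic cohorts

The simulator exists to exercise every rule path without imaging data; it
emulates nodule kinetics, not radiology. Each participant carries at most
one nodule from five classes with defaults chosen to be realistic for a
screening population while covering the engine's decision space:

* class mix: 55 % no nodule, 25 % benign-stable, 8 % resolving,
  6 % indolent, 6 % aggressive (nodule-bearing prevalence near one half,
  cancers a small minority);
* VDT: log-normal, median 180 d (σ=0.25) for aggressive — firmly inside
  the < 600 d growing rule — and median 900 d (σ=0.15) for indolent,
  reachable only through the slow-growth rule; resolving nodules shrink
  with a ~120 d halving time until they drop under a 15 mm³ detection
  limit;
* baseline mean diameter: log-normal, median 6 mm (σ=0.35), the
  small-nodule regime screening mostly sees;
* covariates: ages uniform 50–70 (the program's eligibility window),
  balanced sex, 15 % family history, 30 % emphysema;
* measurement: true volume follows the exponential law exactly;
  measured volume is truth × mean-one log-normal noise with CV 10 % by
  default — the variability regime the ±25 % corridor is designed to
  absorb; calliper diameters derive from measured volume assuming
  sphericity with a fixed 1.1/0.9 axis asymmetry.

Scheduling is either a fixed grid (open loop) or driven by the engine's
own recommendations (closed loop), with months converted at 30.4375
days/month and no scheduling jitter by default. All randomness flows from
one integer seed through split child streams (trajectories vs.
measurement noise), so identical configs are byte-identical.

What the simulator does *not* model — and therefore what passing tests do
not show about real data: inter-scanner and inter-reader systematic
biases (noise is i.i.d. multiplicative), nodule emergence after baseline
(all nodules exist at day 0; the new-nodule path is unit-tested
directly), multi-nodule participants, non-solid morphologies and the
special subtypes (benign patterns, lymph nodes, airway, cysts — covered
by constructed cases instead), participant attrition, and missed or
delayed scans. Closed-form checks the simulator *does* support: under
noise-free growth the measured inter-round volume ratio equals
`2^(Δt/VDT)` exactly; per-nodule regression of log volume on time
recovers the assigned VDT to machine precision (and within stated
tolerance at CV 10 % with ≥ 4 scans); and the rate at which truly static
nodules spuriously leave the ±25 % corridor matches the log-normal
closed form (the log-ratio of two measurements is normal with variance
2σ², σ² = ln(1 + CV²)), which quantifies why the corridor exists.

## Problem sizes and test design

The randomized conformance suites run 10⁵ cases against independently
coded literal decision tables (baseline tables and the volumetric change
table), and the spurious-change calibration uses 4 000 static nodule
pairs; closed-loop program simulations in tests use cohorts of 20–60
participants over up to 8 rounds. These sizes give exact agreement checks
and Monte-Carlo error well inside the asserted tolerances while keeping
the full suite around ten seconds.

## Known limitations

* The engine classifies; it does not schedule. Missed/delayed-scan
  handling and post-referral investigation pathways are out of scope by
  design (screening ends at referral).
* Coefficient values for the risk model are configuration shipped from
  the published full model; the engine performs no refitting or
  calibration, and risk-model numerical fidelity should be validated
  against the official calculator before clinical use.
* Lobe granularity for the upper-lobe flag, measurement rounding, and
  the precedence order of baseline branches are engine design decisions
  documented above; they should be revisited against the official
  protocol document where it is more specific than the published
  rationale.
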