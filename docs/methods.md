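# Methods

## Model structure

The core is a deterministic Markov cohort model with a 1-hour cycle length
and a 10 000-hour horizon, run separately for two arms that are identical in
every respect except the turnaround of the antimicrobial susceptibility
result: 48 h for standard urine culture and 5 h for the rapid impedance-
cytometry test. The cohort is stratified into 12 groups (age 16–64 /
65–100 × female / male × uncomplicated / complicated-oral / complicated-IV
UTI); each stratum is propagated independently (the model is linear in
cohort mass) and results aggregate by summation.

On entry, a fraction

    ρ = (resistance prevalence of the stratum's empirical antibiotic)
      × (inappropriate-prescribing proportion)

of each stratum starts in `EMP_INAPPROPRIATE` (resistant infection on
ineffective empirical treatment); the rest start in `EMP_APPROPRIATE`. The
product rule is used throughout; at the default inappropriate-prescribing
proportion of 0.30, a 5 % resistance prevalence yields a 1.5 %
resistant-and-inappropriately-treated share.

Every in-hospital state carries, per hour:

* a **BSI hazard** — the hourly rate 3.11×10⁻⁶ (derived as
  −ln(1 − 1253/280 462)/(60·24) from the printed cumulative inputs),
  converted to a probability via 1 − e^(−r). The hazard is the same in all
  UTI states; inappropriate treatment raises cumulative BSI risk only
  through longer stays.
* a **discharge hazard** — from the state class's mean length of stay L
  (days), daily probability 1 − e^(−1/L), converted to hourly via
  1 − (1 − p_daily)^(1/24). Three classes exist: susceptible-appropriate
  (also used for `POST_APPROPRIATE` and `POST_FALSE_RESISTANT`),
  resistant-inappropriate (`EMP_INAPPROPRIATE`, `POST_INAPPROPRIATE`), and
  BSI. The resistant class must not discharge faster than the susceptible
  one; this ordering is enforced structurally and during probabilistic
  sampling (offending joint draws are rejected and redrawn, logged).
* a **death share** — a constant fraction of exits are deaths, per class.
  The default gives resistant-inappropriate exits twice the susceptible
  death share; a resistant-vs-susceptible mortality contrast must exist for
  "impact of resistance on mortality" to be a meaningful sensitivity axis,
  and a factor ≈2 is consistent with the inappropriate-empirical-therapy
  outcome literature.
* **result arrival** (empirical states only) — by default a memoryless
  hourly rate 1/turnaround, applied as probability 1 − e^(−1/turnaround)
  ("rate" mode; valid down to a 1 h turnaround). A deterministic mode
  instead reallocates the empirical states exactly at t = turnaround; it is
  used for clean analytic checks and is exposed as a configuration switch.
  On arrival, resistant patients move to the second line with probability
  = sensitivity (0.95) and are otherwise missed (`POST_INAPPROPRIATE`);
  susceptible patients stay on empirical treatment with probability
  = specificity (0.85) and are otherwise switched unnecessarily
  (`POST_FALSE_RESISTANT`, treated effectively but billed at second-line
  drug cost). Culture and the rapid test share one sensitivity and one
  specificity.

Rows of every transition matrix are stochastic to 1×10⁻¹², competing risks
summing above 1 abort with an error naming the state, and total cohort mass
is conservation-checked at every cycle to 1×10⁻⁹ relative. Transient mass
remaining at the horizon (≲10⁻⁶ of the cohort under any realistic
configuration) is force-discharged alive and logged. No half-cycle
correction is applied; with 1-hour cycles the correction is negligible.

## Economics

Costs (2022 GBP): bed-hours priced at an ICU/general blend by state class
(complicated UTI 13.9 % ICU, uncomplicated 0 %, BSI 7.95 %; £24.6/h general,
£85.07/h ICU); antibiotic drug-days priced by the current regimen (empirical
agent in `EMP_*` and `POST_INAPPROPRIATE`, second-line agent in
`POST_APPROPRIATE` and `POST_FALSE_RESISTANT`; no additional drug cost is
attached to the BSI state); one susceptibility test per patient at the point
of use, with the rapid test priced equal to the standard test (£15.67 =
£4.98 urine test + £10.69 culture processing) because threshold pricing is
out of scope.

QALY losses: hourly decrements while in UTI or BSI states, plus, per death,
the discounted remaining quality-adjusted life expectancy at the age-band
midpoint, Σ_t u/(1.035)^t over whole years with the final partial year
prorated (two years at utility 1 give 1.96618). Only death losses are
discounted — everything else resolves within a year. The baseline utility
norm (0.8) and band life expectancies (42.5 y at age 40; 8.0 y at age 82.5)
are configurable placeholders for national life-table values.

Cost-effectiveness is reported as NMB = λ·ΔQALY − ΔCost at λ = £20 000/QALY,
with a dominance flag when the rapid test is both no more costly and no less
effective.

## Scenarios

Declaratively registered: `base_population` (nitrofurantoin 5 %, gentamicin
9 %, cefalexin 13 % resistance), `base_per_patient` (same, cohort mass 1),
`low_trimethoprim` (trimethoprim at 5 % replaces nitrofurantoin as the
uncomplicated empirical agent), `high_resistance` (40 % to every agent).
Only resistance to the empirical antibiotic enters the model; second-line
resistance is not configurable without an extension.

## Sensitivity analysis

Probabilistic: default 1000 joint draws. Each distributed parameter has its
configured distribution — uniforms with printed bounds where stated, ±25 %
bounds otherwise, and a gamma for the BSI rate. The printed gamma scale is
inconsistent with the point estimate under the shape–scale convention
(mean ≫ 3.11×10⁻⁶); the loader keeps the shape and rescales to centre the
distribution on the point estimate, with a warning. Draws violating a
structural invariant (proportion outside [0, 1], negative cost, LoS
ordering) are rejected and redrawn. Draw i of root seed s uses the seed
sequence (s, i, retry), so draws are independent and individually
reproducible, and the first draws of a longer run coincide with a shorter
one. Outputs: per-draw (ΔCost, ΔQALY, NMB), the acceptability curve
P(NMB(λ) > 0), and the cost-effectiveness plane.

Univariate: one-at-a-time re-evaluation at range endpoints, sorted by
|NMB_high − NMB_low|. Ranges default to each uniform parameter's bounds
plus the rapid-test turnaround (1 h to culture parity, where the NMB is
exactly zero) and two ratio pseudo-parameters ("impact of resistance")
scaling the resistant-inappropriate mortality share (1–3×) and length of
stay (1–2×) relative to the susceptible class.

## Synthetic cohort

The original cohort was extracted from restricted national admissions data,
so the generator reproduces its statistical structure, not its records:
280 462 total admissions; an 80/10/10 uncomplicated/complicated-oral/
complicated-IV split within every age–sex group; continuous (expected-value)
stratum masses that exactly partition the total, rounded half-up only in
report views (17 192 × 0.1 = 1719.2 → 1719). The 16–64-male weight is fixed
at 17 192/280 462 so the documented worked example is exact; the other three
weights are placeholders skewed toward 65–100 females, where most hospital
UTI admissions (and hence most population-level savings) sit. The generator
does not emulate per-hospital heterogeneity, seasonality, readmission,
catheter-associated or pregnancy pathways, or diagnosis-code noise — so
passing tests demonstrate the pipeline's correctness on the assumed
structure, not robustness to real extraction artefacts.

## Placeholder inputs and what reproduction means here

Length-of-stay means (5 / 7 / 12 days), death shares (0.03 / 0.06 / 0.15),
hourly QALY decrements (3.2×10⁻⁵ / 4.6×10⁻⁵), utility norm, life
expectancies, stratum weights and daily drug costs are synthetic
placeholders (flagged in `data/parameters.yaml`) for values that exist only
in non-public supplementary material. They were set to literature-typical
magnitudes, with one calibration: the uncomplicated second-line daily drug
cost, initially set at a shortage-era price, was reset to a typical 2022
formulary level after it alone dominated the incremental cost.
Consequently the pipeline reproduces the published analysis *structurally*
— identical inappropriate-day reductions in base and low-trimethoprim
scenarios, a ~7–8× NMB scale-up under 40 % resistance, the largest bed-day
savings in 65–100 female uncomplicated patients, per-patient NMB greatest
for complicated-oral strata, and high acceptability probabilities at
£20 000/QALY — while absolute totals (e.g. inappropriate prescribing days)
differ from the published figures by factors attributable to the
placeholders. Replacing the flagged entries with transcribed supplementary
values is a configuration-only change.

## Numerical and testing choices

* Propagation is dense (12 strata × 8 states × 10 000 cycles), ~0.1 s per
  arm; the 1000-draw PSA takes ~2 minutes on one CPU.
* Tests use reduced problem sizes where absorption allows (horizons of
  1500–3000 h, cohorts of 100–2000): these retain all structural properties
  at a fraction of the runtime.
* The engine is validated against an independent patient-level Monte-Carlo
  microsimulation (50 000 replicates, coarse fast-absorbing hazards) that
  shares only the hazard primitives, agreeing within three Monte-Carlo
  standard errors on hospital hours, inappropriate hours, BSI hours and
  deaths.
* Property tests (hypothesis, derandomised) cover conversion monotonicity
  and round-trips, mass conservation, allocation conservation and scaling
  invariance.

## Known limitations

No transmission dynamics (benefits of prevented onward spread are not
captured, so estimates are conservative by construction); constant hazards
(no time-in-state dependence); mortality applied as a fixed share of exits;
ICU use as a cost blend rather than explicit states; no catheterised,
paediatric or pregnancy pathways; no threshold-price search for the rapid
test; placeholder inputs as described above.
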