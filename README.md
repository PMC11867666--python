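# uticea

Cost-effectiveness analysis of rapid antimicrobial susceptibility testing
for hospital urinary tract infections (UTI), built as a reusable,
fully-tested Python pipeline.

## The problem

Hospital patients with a suspected UTI are started on empirical antibiotics
while a urine culture is processed; susceptibility results arrive only after
~48 hours. When the pathogen is resistant to the empirical agent, the
patient spends those hours on ineffective ("inappropriate") treatment, which
lengthens hospital stay, raises the risk of progression to bloodstream
infection (BSI), and increases mortality. A rapid bacterial impedance
cytometry test (BICT) returns susceptibilities in ~5 hours. This package
quantifies, from an NHS-England payer perspective, whether adopting the
rapid test is cost-effective.

## The model

An hourly-cycle Markov cohort model propagates a national cohort of
~280 000 UTI admissions (stratified by age band × sex × UTI type) through
the states

```
EMP_APPROPRIATE   susceptible, on empirical antibiotics
EMP_INAPPROPRIATE resistant, on ineffective empirical antibiotics
POST_APPROPRIATE  switched to an effective second-line agent
POST_INAPPROPRIATE resistant but missed by the test (false susceptible)
POST_FALSE_RESISTANT susceptible but switched unnecessarily (false resistant)
BSI               bloodstream infection
WELL / DEAD       absorbing discharge states
```

until absorption (horizon 10 000 h). The two arms differ **only** in the
result turnaround (48 h culture vs 5 h rapid test). Each state carries a
discharge hazard derived from its mean length of stay, a death share per
exit, a fixed hourly BSI hazard, and hourly bed-day costs (ICU/general
blend) and QALY decrements. Deaths incur the discounted (3.5 %/yr) remaining
quality-adjusted life expectancy at the age-band midpoint. Results are
summarised as the net monetary benefit

    NMB = λ · ΔQALY − ΔCost,     λ = £20 000/QALY,

with ΔCost = cost(rapid) − cost(culture) and ΔQALY the QALY gain. Four
scenarios are registered: base case (population and per-patient), low
trimethoprim resistance, and a hypothetical 40 % resistance to every
empirical agent. Univariate (tornado) and probabilistic (1000-draw)
sensitivity analyses produce the cost-effectiveness plane and acceptability
curve. Because the national admissions extract is access-restricted, a
synthetic cohort generator reproduces its statistical structure (stratum
weights, 80/10/10 uncomplicated/complicated-oral/complicated-IV split,
length-of-stay-derived discharge probabilities).

## Worked example

```python
from uticea import CostEffectivenessModel

model = CostEffectivenessModel.from_defaults()   # base case, 280 462 patients
res = model.fit()
print(res.summary())
```

```
Scenario: base_population  (cohort mass 280,462)
  Total cost      culture £898,213,415   rapid test £898,251,292
  Incremental cost        £37,877
  Incremental QALY gain   246.2
  NMB (£20,000/QALY)   £4,886,282
  Inappropriate days      culture 9,606 -> rapid test 2,933
  Bed days saved          1,901.8
  Inappropriate-day reduction  69.5%
  Deaths averted               28.53
  BSI person-days avoided      1.70
```

Reading: switching to the rapid test removes ~70 % of inappropriate
prescribing days, saves ~1900 bed days (≈ 0.007 days per patient) and averts
~29 deaths, worth a net monetary benefit of ≈ £4.9 million at £20 000/QALY.
(Numbers shown were produced by this exact snippet; small revisions of the
packaged placeholder inputs will shift them.)

Uncertainty and per-patient views:

```python
psa = model.fit_psa(n=1000, seed=1)
print(psa.summary())            # mean NMB and P(cost-effective) at £20k/QALY
psa.plot_ceac(); psa.plot_ce_plane()
res.per_patient()               # per-stratum NMB per patient case
model.tornado()                 # one-way sensitivity, sorted by bar width
```

A thin CLI wraps the same library calls:

```bash
uticea audit                    # parameter audit table (CSV)
uticea cohort --total 280462 --out cohort.csv
uticea run --scenario all --per-patient --out results/
uticea psa --n 1000 --seed 1 --out psa/
```

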