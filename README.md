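# desr

Dual-endpoint stopping rules for single-arm, two-stage phase II oncology
trials.

## The problem

Classical two-stage phase II designs (Gehan, Fleming, Simon) judge a new
drug by tumour response rate alone. Cytostatic and targeted agents may
shrink few tumours yet still be active — a signal visible as a *low* rate
of early progressive disease (EPD, progression at the first on-treatment
assessment). The Dual Endpoint Stopping Rule (DESR) treats each patient's
outcome as trinomial — response / early progression / other — and tests

- H<sub>nul</sub>: r ≤ r<sub>nul</sub> and epd ≥ epd<sub>nul</sub> (uninteresting drug)
- H<sub>alt</sub>: r ≥ r<sub>alt</sub> or epd ≤ epd<sub>alt</sub> (drug of interest)

With stage sizes n₁, n₂ and integer bounds (s_r, s_p, a_r, a_p), the trial

- **stops at stage I** (accepts H<sub>nul</sub>) if n<sub>1r</sub> ≤ s_r **and** n<sub>1p</sub> ≥ s_p;
- otherwise accrues stage II and **rejects H<sub>nul</sub>** if cumulative
  responses ≥ a_r **or** cumulative progressions ≤ a_p.

The package provides:

- the decision rules (DESR, Fleming, Gehan) applied to observed trial counts;
- exact operating characteristics (α, power, probability of early stopping
  PES, expected sample size EN = n₁ + n₂(1 − PES)) by full enumeration of
  the trinomial count lattice, with power under the borderline-value
  construction — drugs of interest modelled as a 50/50 mixture of
  (r<sub>alt</sub>, epd<sub>nul</sub>) and (r<sub>nul</sub>, epd<sub>alt</sub>);
- exhaustive threshold search under α/power constraints;
- a seedable Monte Carlo simulator (verification oracle and synthetic-cohort
  generator);
- bundled historical fixtures: DESR threshold tables and two trial-count
  cohorts (16 trials run under a Fleming design, 23 under a Gehan design)
  with their published verdicts, reproduced cell-for-cell by the code.

It is aimed at trial statisticians designing phase II studies with a
response + early-progression endpoint, and at methodologists comparing
stopping rules on historical data.

## Worked example

```python
from desr import (DualHypotheses, DesrThresholds, TrialRecord,
                  decide_desr, oc_for_design)

hyps = DualHypotheses(r_nul=0.05, r_alt=0.2, epd_nul=0.6, epd_alt=0.4)
th = DesrThresholds(n1=15, n2=15, s_r=1, s_p=8, a_r=4, a_p=14)

# a trial with 1/15 responses and 6/15 early progressions at stage I,
# 1/25 responses and 12/25 progressions cumulatively
rec = TrialRecord("13", n1=15, r1=1, p1=6, n_tot=25, r_tot=1, p_tot=12)
print(decide_desr(rec, th))
# Decision(stage1_stop=False, final=<Verdict.REJECT_NULL: 'reject_null'>)

print(oc_for_design(th, hyps))
# OperatingCharacteristics(alpha=0.11138644862329952, power=0.7625056131823753,
#   pes_nul=0.678978390471803, en_nul=19.815324142922954,
#   pes_alt=0.17737321521920005, en_alt=27.339401771711998)
```

The trial continues past stage I (6 progressions < 8) and, despite a single
response, rejects H<sub>nul</sub> because only 12 of 25 patients progressed
early (≤ 14) — exactly the verdict printed for this trial in the historical
comparison. The operating characteristics are exact enumeration values
under the point-null configuration (r, epd) = (0.05, 0.6) and the 50/50
borderline mixture; see `docs/methods.md` for why these differ from the
values printed alongside the historical threshold tables.

From the shell, the same comparisons:

```sh
desr compare --cohort gehan_cohort --rules desr-0.4-0.6,desr-0.3-0.5,gehan \
     --out decisions.csv --summary-out summary.json
```

`summary.json` reports 15 stage-I stops under either DESR parameter set
versus 8 under the Gehan rule, and identical final conclusions in all 23
trials.

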