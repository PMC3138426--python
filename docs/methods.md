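# Methods

## Outcome model

Each patient contributes one of three mutually exclusive outcomes:
tumour response (probability `p_r`), early progressive disease
(progression at the first on-treatment assessment, probability `p_p`), or
"other" (stable disease, late progression, not evaluable; probability
`1 - p_r - p_p`). Patients are i.i.d. given the true rates, so stage
counts are trinomial and the two stages are independent draws. Early
progression is a trial-level count; no time-to-event structure is
modelled.

## The dual-endpoint rule

A design is `(n1, n2, s_r, s_p, a_r, a_p)`. Stage-I stop (futility,
accept the null) iff stage-I responses `<= s_r` **and** progressions
`>= s_p`; final rejection of the null iff cumulative responses `>= a_r`
**or** cumulative progressions `<= a_p`. All bounds are inclusive integer
counts. Two degenerate encodings widen the search space: `s_p = n1 + 1`
(never stop on progression) and `a_p = -1` (never reject on progression),
which recover single-endpoint designs as special cases.

Two conventions matter when judging observed cohorts:

- **Absolute counts under off-plan accrual.** Historical trials
  under-accrued (one stage-I of 14 instead of 15; stage-II totals of 25 or
  29 instead of 30). Bounds are applied unchanged as absolute counts. This
  is the only reading that reproduces every published verdict cell in the
  bundled cohorts, including a trial rejected with 4/29 cumulative
  responses against a "4 or more of 30" bound.
- **Indeterminate verdicts.** A trial that continues past stage I but
  reports no stage-II counts gets final verdict `indeterminate` — the
  rule's conclusion is unknowable, not negative.

Trials halted by their investigators rather than by a rule carry an
`investigator_stopped` flag; summary tallies of "continuing" trials
exclude them, matching how the historical comparison counted its five
truly continuing studies.

## Exact operating characteristics

All probabilities are computed by exact summation over the count lattice.
The stage-II event `{j_r >= x or j_p <= y}` is tabulated once per rate
configuration via 2-D prefix/suffix sums of the trinomial pmf, so the
rejection probability is a single weighted gather over stage-I
continuation states. Category probabilities are evaluated in log space
(`lgamma`-based multinomial coefficients); zero rates use the `0·log 0 = 0`
convention so degenerate configurations ((0,1), (1,0)) are exact. The
summation order is fixed, making results bit-reproducible. Agreement with
an independently written brute-force enumeration (plain nested loops,
`math.comb`) is required to 1e-12 in the test suite for designs with
stage sizes up to 20.

- **Alpha** is evaluated at the point null `(r_nul, epd_nul)` — the
  least favourable point of the composite null for this rejection region.
- **Power** uses the borderline-value construction: a drug of interest is
  not assumed better than the alternative boundary on either endpoint, so
  the alternative population is a two-point mixture of
  `(r_alt, epd_nul)` (responds well, progresses at the null rate) and
  `(r_nul, epd_alt)` (rarely responds, rarely progresses early), weighted
  50/50 by default. Both the null point and the mixture are overridable
  parameters.
- `EN = n1 + n2 (1 - PES)` holds exactly on both sides by construction.

### The bundled tables' printed OC columns

The packaged threshold tables carry the power/alpha/EN/PES values printed
with the original designs. Those values came from the design authors'
simulation software, whose sampling scheme (in particular how drug rates
were drawn) is not fully documented; under the point-null model here they
are not reproducible — e.g. the Fleming-sized design `(1, 8, 4, 14)` has
exact `PES_nul = 0.679` and `alpha = 0.111` at `(r, epd) = (0.05, 0.6)`,
against printed values 0.90 and 0.025. The printed columns are therefore
shipped as descriptive fixture data, never asserted as recomputation
targets; the engine is validated instead against brute force and Monte
Carlo. The interpretation used here is exposed as configuration (null
point, mixture, weights) rather than guessed at.

## Threshold search

`search_thresholds` enumerates every quadruple over
`s_r in [0, n1]`, `s_p in [0, n1+1]`, `a_r in [s_r+1, n1+n2]`,
`a_p in [-1, n1+n2]`, keeps candidates with `alpha <= alpha_max` and
`power >= power_min` (exact values; simulation is never in the loop), and
returns the candidate preferred by an ordered criteria list — by default
maximise `PES_nul`, then minimise `EN_nul`, then maximise power,
reflecting the premium these designs place on stopping uninteresting
drugs early. Ties break on ascending `(s_r, s_p, a_r, a_p)`, so repeated
searches are identical. Infeasibility is returned as a flagged result,
not an error.

Because alpha here is the exact point-null value, the constraint pair
(0.05, 0.8) that accompanied the original tables is infeasible at
`n1 = n2 = 15` under this model — consistent with the published design
itself having exact alpha 0.111. At constraints that design can meet
(e.g. `alpha_max = 0.12`, `power_min = 0.75`) the search returns exactly
the published bounds `(s_r=1, s_p=8, a_r=4, a_p=14)`, which is the
validation the search is held to. Whether the original derivation split
alpha between stages is unknown; the four bounds are searched jointly.

## Classic comparator designs

- **Fleming-style**: integer response bounds taken as inputs (stage-I
  accept bound, optional stage-I reject bound — disabled by default, as
  the historical cohort never invoked it — and a cumulative rejection
  bound). Exact OC by binomial convolution.
- **Gehan**: stage-I size is the smallest `n` with
  `(1 - p_interest)^n <= beta` (14 at 20%/0.05); stage-I stop iff zero
  responses. Stage-II sizing targets a standard error for the response
  estimate: the plug-in rate is the exact one-sided upper 75%
  Clopper–Pearson bound for `r1/n1` (a conservative reading of
  estimation-driven sizing; no formula is fixed by the historical
  sources), then `n2 = max(0, ceil(p~(1-p~)/se² - n1))`. Gehan's
  procedure makes no final activity call, so the evaluation convention
  "active iff cumulative response rate >= r_alt_eval" (default 0.2) is a
  configurable parameter; with the default it reproduces all 23 published
  activity cells of the Gehan cohort.

## Monte Carlo simulator and synthetic cohorts

One `numpy` Generator per call, seeded explicitly; no global state; fixed
draw order, so outputs are byte-identical for a given seed. Mixture
alternatives draw the drug class once per simulated trial (a population
of drugs, each with fixed rates), not per patient. Standard errors are
binomial; expected-sample-size errors scale the stop-probability error by
`n2`.

The synthetic cohort generator emulates the bundled tables' shape —
stage-I counts plus cumulative totals, always over the full `n1 + n2`
(as historical investigators often continued trials past a formal stop).
It does not emulate under-accrual, investigator stops, missing stage-II
data, or between-trial rate heterogeneity; passing recovery tests on
synthetic cohorts therefore demonstrates correctness of the decision and
counting machinery under the trinomial model, not robustness to those
real-data features (the historical cohorts themselves cover under-accrual
and missingness).

## Problem sizes and numerical tolerances

Exact-vs-brute-force agreement is asserted at 1e-12 (both sides are plain
double summations of nonnegative terms). Monte Carlo checks use 200,000
replicates and a 3-standard-error band per field; synthetic-cohort
recovery uses 10,000 trials. Mixture weights must sum to 1 within 1e-12.
Searches at `n1 = n2 = 15` enumerate ~260 stop regions × ~1000 final-bound
pairs and complete in well under a second.

## Known limitations

- Alpha/power are exact only under the stated point-null/mixture
  interpretation; other derivation schemes for the same bounds will report
  different error rates.
- No response subcategories (complete/partial split) and no per-patient
  data model.
- The Gehan final activity rule and stage-2 plug-in bound are documented
  conventions, not claims about the original estimation-only procedure.
- Fleming bounds are inputs; deriving them from (alpha, beta, p0, p1) is
  out of scope.
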