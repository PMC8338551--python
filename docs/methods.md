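# Methods

## Model structure

The analysis compares two stem-cell mobilization strategies for multiple
myeloma patients awaiting autologous transplant over the horizon from
mobilization to apheresis (no discounting; transplant costs and interim
mortality are out of scope):

* **comparator** — cyclophosphamide 4 g/m² + G-CSF, on-demand plerixafor
  in 9% of patients;
* **treatment** — G-CSF alone, on-demand plerixafor in 47% of patients.

The decision tree is evaluated in expectation.  Intermediate chance nodes
(febrile neutropenia, red-cell and platelet transfusions) matter only
through expected resource quantities, so each arm reduces to an
effectiveness probability and one expected quantity per cost item.
Effectiveness is the plerixafor-weighted mixture
`E = p·e_with + (1−p)·e_without` with `e_with = 0.838` and
`e_without = 0.702` shared between the arms; at base case this gives
0.76592 (treatment) and 0.71424 (comparator), reported as 0.766 and 0.714,
and an incremental effectiveness with the closed form
`ΔE = (p₁ − p₂)(e_with − e_without) = 0.38 × 0.136 = 0.05168`.

## Costing conventions

The societal perspective partitions every cost by payer: INHS tariffs
(taken as a proxy for facility costs), patient out-of-pocket spending
(transport, parking), and patient/caregiver time.  Conventions
implemented in `mobcea.costing`:

* inpatient per-diem = tariff / mean length of stay
  (`daily_hospital_cost`);
* when a procedure inside a tariff is costed separately, the tariff is
  halved to keep only the hotel component (`hotel_cost`);
* lost working hours are valued at the gross wage rate, informal-care and
  leisure hours at the net (take-home) rate (`time_cost`); from the
  retirement age of 70 (or when unemployed) leisure substitutes for work
  (`working_time_kind`).  The base-case cohort enters at a mean age of
  57.62 years, so the leisure-substitution switch is inactive there;
* apheresis sessions missed through poor mobilization carry an INHS
  opportunity cost of ≈€439 per session.

Costs are computed in binary floats and summed with `math.fsum`;
reporting rounds half-away-from-zero to cents (`round_cents`).  All base
aggregates are reproduced within €0.02 of the printed tables, the slack
being penny-rounding of printed sub-items (the published sub-items
themselves sum to a few cents above the published totals).

### Fixture unit costs

The supplementary tariff tables behind the published cost table are not
public.  Items whose decomposition is recoverable by arithmetic store a
unit cost equal to (printed expected cost) / (base-case quantity) — e.g.
plerixafor €5064.86 per vial in the treatment arm, an inpatient
cyclophosphamide per-diem of €211.04, an apheresis session of €438.99 —
so the base case reproduces each printed item to the penny while the
sensitivity analyses can vary the quantity.  Where implied unit values
differ slightly between arms (the blended productivity rate is €21.7236/h
in one arm and €21.7193/h in the other; informal care €15.36/h vs
€16.17/h; plerixafor per treated patient €7648.36 vs €7647.89), the
per-arm exact value is kept rather than a blended constant: the
differences are printing artifacts, and per-arm values are what keep the
arm totals within €0.02.  Items with no recoverable decomposition (drug
totals, catheter, neutropenia, transfusions, handling, transport,
parking) are single items with quantity 1 at the printed amount.

## Parameter distributions

* **Gamma** for resource quantities.  Every strictly positive published
  95% CI is consistent with one coefficient of variation, CV = 0.4
  (shape 6.25) — the single exception is body height, whose printed CI
  implies CV ≈ 0.1 and is fitted on its own.  When a CI is declared the
  shape is recovered by a bounded 1-D minimization of summed squared
  relative quantile errors with the mean held exact
  (`fit_shape_to_quantiles`); rows whose printed lower bound is 0.00
  (febrile-neutropenia days, transfusion counts) fit to shapes below 1.
  Without a CI, the default CV applies (`gamma_from_mean_cv`).
* **Beta** for probabilities, moment-matched from the mean and
  sd = min(0.4·mean, 0.95·√(mean(1−mean))) — the gamma CV convention
  carried over, capped safely inside the feasibility bound.  This is an
  assumption: the elicited distributions are not public.
* **Bernoulli** gates for composite quantities.  Productivity and
  informal-care hours are employment/caregiver gates of probability 0.5
  times conditional gamma amounts with twice the printed per-patient
  mean (the published CIs of such rows are emergent, not targeted).  The
  caregiver-presence probability of 0.5 mirrors the employment fraction
  and is a modeling choice.
* **Fixed** point masses for unit costs; drug prices in particular are
  deliberately excluded from the sensitivity analyses.

Sampling uses one master seed with per-parameter substreams derived from
SHA-256 of `"{seed}:{name}"`, so adding or removing a parameter never
perturbs the draws of the others, and the shared effectiveness pair
automatically receives identical draws in both arms.

## Sensitivity analyses

* **One-way / tornado** — each parameter with a declared CI (or range) is
  set to its bounds, shared parameters moving in both arms; bars are
  sorted by the largest absolute percent deviation of the raw ICER ratio.
  Because the published per-parameter CIs for probabilities are
  assumptions here, the bar *ordering* can differ from the published
  chart (whose top bar is the plerixafor vial count); ordering is instead
  verified against brute-force enumeration on synthetic configurations.
* **Scenarios** — six named presets.  Effectiveness scenarios
  (equal/swapped mixtures) are structural; the four tariff scenarios
  whose underlying recombination is not recoverable carry the published
  arm totals as direct cost overrides.  The swapped-effectiveness preset
  reproduces the published rounded-increment arithmetic (ΔE to three
  decimals, ΔC to cents) because that is how its published ICER of
  €23,049.81 arises; every other analysis divides unrounded increments
  (the default, exposed as `rounding="unrounded" | "printed"`).
* **PSA** — 10,000 iterations by default.  Quadrant shares use the
  convention that the southern half-plane is exactly `ΔC < 0` and a zero
  ΔE goes south-east iff ΔC < 0, making two identities exact at the level
  of iteration counts: CEAC(0) = share(SE) + share(SW), and
  CEAC(λ→∞) = share(NE) + share(SE).  "Cost-effective" means a strictly
  positive incremental NMB; exact ties credit the comparator, as does the
  frontier argmax.  The λ grid runs from €0 to €100,000 in €1,000 steps
  and always contains the quoted willingness-to-pay anchors €0, €25,000
  and €40,000.

The published quadrant shares (23.14/4.40/59.92/12.54%) and CEAC values
(72.46/84.24/86.12%) depend on elicited distributions that are not
public; with the distribution conventions above the model reproduces the
qualitative claims (south-east modal, treatment on the frontier from €0)
but not those exact percentages, and the tests assert the identities and
qualitative structure rather than the unpublished numbers.

## Synthetic configurations

`mobcea.synthetic.random_model_config` generates valid two-arm
configurations with the same statistical skeleton: shared beta
effectiveness pair, gamma quantities whose declared CIs are computed from
their own fitted distribution (so CI fitting is exactly invertible, unlike
the real composite rows), optional Bernoulli-gated items, fixed unit
costs across all three payers.  Degenerate cases are injected on purpose
(probability ~0.12 each): exactly equal effectiveness, and identical item
lists giving ΔC = 0, so that all five dominance labels (strong/weak
dominance either way, indeterminate) occur across seeds.  What passing
tests on synthetic data show is internal consistency of the engine
(homogeneity, additivity, closed forms, classification); they do not
validate the elicited Italian inputs themselves.

`perturb` provides the metamorphic transformations used in testing:
`scale_costs k` (ΔC and the raw ratio scale by k), `add_common_item c`
(ΔC invariant), `widen_cis f` (f = 1 is the identity).

## Numerical choices and limitations

* ΔE within 1e-12 of zero counts as zero for dominance classification
  (measure-zero in the PSA, decisive in the equal-effectiveness
  scenario).
* The gamma shape search runs over log-shape in [1e-4, 1e6]; a zero CI
  bound contributes a residual scaled by the mean instead of the bound.
* Problem sizes in the shipped tests: PSA checks at 2,000–10,000
  iterations, the metamorphic sweep over 1,000 generated configurations
  (fit round-trips on a 200-instance subsample).
* Missed-session counts are primitive inputs, not derived from failure
  probabilities (the published 0.48/0.95 are not exactly
  (1−E)×sessions).
* No correlation between parameters beyond the shared effectiveness
  pair; no QALY/utility analysis, no >2-arm comparison, no inflation or
  currency-conversion engine, no value-of-information analysis.
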