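# Methods

## Model structure and assumptions

The decision problem compares two population-level strategies for
cisplatin-eligible muscle-invasive bladder cancer (cT2–T4aN0M0, age ≤ 76 at
radical cystectomy):

* **Current practice** — a fraction of patients receive three courses of
  neoadjuvant chemotherapy before cystectomy (NAC+RC); the rest get upfront
  RC, and of those the poor-prognosis minority (≥pT3 or pN+ in the
  specimen) continues to four courses of adjuvant chemotherapy (RC+AC).
* **Subtype-based de-escalation** — every tumour is molecularly subtyped;
  Uro/GU patients get NAC+RC, Ba/Sq patients get upfront RC with AC for the
  (much larger) poor-prognosis fraction.

Each strategy is a decision tree collapsed to terminal treatment arms, and
each arm drives a three-state Markov cohort: alive after RC, dead of
bladder cancer, dead of other causes. Death states are absorbing; there are
no tunnel states, no time-in-state utilities, and no recurrence state —
everything a patient experiences after surgery is summarized by the
yearly cause-specific death probabilities of their arm. Transitions are
indexed by model year since RC only (no age or calendar-time dependence).

**Cycle convention.** Cycle 0 is the treatment year, with the whole cohort
alive; an "N-year" horizon then applies N yearly transitions, so accrual
spans N+1 cycles and the undiscounted QALY ceiling at an N-year horizon is
N+1. This convention was chosen because published results of this model
class report, e.g., 2.16 QALYs at a "2-year" horizon — arithmetically
impossible unless accrual spans more than two year-cycles. It is an
inference, not a documented rule, and is the single most consequential
accounting choice in the package.

**Branch renormalization.** The printed subtype prevalences and prognosis
splits sum to 0.999 (rounding); branch probabilities are renormalized
proportionally at strategy construction, preserving the printed ratios.

**Half-cycle correction.** Off by default (the convention above already
spreads accrual across N+1 cycles). When enabled, recurring accruals use
the mean of each cycle's start and end alive fractions instead of the
end-of-cycle value; one-off cycle-0 quantities are untouched.

## Costs, utilities and discounting

All computation is in EUR (EU-27, 2022 price year); SEK enters only through
a configurable purchasing-power factor (default 13.4644 SEK/EUR, the factor
implied by the 100,000 SEK = €7,427 threshold pair).

* One-off costs at cycle 0, undiscounted: RC €14,711; NAC (3 courses)
  €2,270; AC (4 courses) €2,586; subtype identification €341, charged to
  **every** patient of the subtype-based strategy (all must be tested to be
  triaged).
* Surveillance cost €444/year and surveillance utility 0.914 accrue in
  every cycle t ≥ 1 in proportion to the alive fraction, discounted by
  (1.03)^-t. No stop rule: surveillance runs for the whole horizon.
* Cycle 0 accrues the cystectomy utility 0.80 minus a one-time
  chemotherapy toll: disutility magnitude 0.36 × toll duration, with
  default durations 0.25 years for NAC and 0.33 years for AC
  (treatment-period readings of 3 vs 4 three-to-four-week courses; both
  configurable). A toll driving cycle-0 utility negative is clamped at 0
  with a logged warning. Whether the original analysis applied the
  disutility once, per course, or per cycle is not public; the one-time
  treatment-period toll is the standard AUC reading.
* Discounting starts at year 1 (cycle-0 events are present value), rate
  3%/year for both costs and QALYs.

QALYs are the discrete area under the utility-weighted survival curve;
the ICER is ΔCost/ΔQALY with current practice as comparator, reported only
in the more-costly/more-effective quadrant (dominance is flagged
otherwise, and a zero QALY difference flags the ICER undefined);
incremental net monetary benefit is WTP·ΔQALY − ΔCost at WTP €7,427/QALY.

## Sensitivity analyses

* **Tornado.** Every parameter is set in turn to its low and high bound
  with all others at their points; the two ICERs and their span are
  recorded and sorted. Endpoints where the incremental analysis is
  degenerate (dominance, zero ΔQALY) are flagged rather than dropped.
  Tornado endpoints are identically `run_scenario` with one override, and
  tests enforce that equivalence exhaustively.
* **PSA.** 10,000 Monte Carlo iterations by default. Distribution families
  are an implementation choice (the original analysis does not state
  them): beta for probabilities/utilities/the disutility magnitude, gamma
  for costs, moment-matched so the mean equals the point estimate and
  sd = (high − low)/(2·1.96) — the plausible range read as an approximate
  95% interval. Infeasible beta matches fall back to uniform(low, high)
  with a warning. Draws are independent except complementary probability
  pairs (NAC/RC-only shares, good/poor splits, Uro-GU/Ba-Sq prevalences),
  which are one beta draw and its complement so branch probabilities keep
  summing to one. Transition schedules are **not** sampled: no ranges
  exist for them in the parameter table. Iterations are reproducible from
  a single seed; invalid draws are resampled with a capped retry count.
* **CEAC.** The exact empirical win fraction k/n at each willingness-to-pay
  on a grid of 0–50,000 in 500-EUR steps plus €7,427 and €10,000. A win is
  strictly positive incremental NMB; exact ties count as not
  cost-effective.
* **Scenarios.** Named parameter overrides through the same deterministic
  engine. Two example configs ship in `examples/`: NAC uptake at its 2022
  level (0.74, with the RC-only share complemented) and a high
  upfront-RC setting (RC-only 0.811).

## Synthetic registry and transition estimation

The survival schedules behind the original analysis come from a national
registry database that cannot be redistributed, so the package carries a
generator that emulates the statistical structure the model consumes:
patients are assigned a strategy branch by the mixture proportions, then a
death year by sequential yearly Bernoulli draws from their arm's
cause-specific hazards, with administrative censoring at a fixed horizon
(censoring assumed at year-end). NAC and AC are never combined in one
patient (the arms are mutually exclusive by construction, mirroring the
guideline exclusion). Prognosis labels are drawn directly from the
parameter-table proportions rather than simulating pT/pN stages; for
NAC+RC patients — whose pathology the decision tree never uses — the label
is drawn from the overall prognosis split so the record schema stays total.

Estimation is a discrete-time cause-specific life-table: for each schedule
group (upfront-RC arms pooled across strategies; the NAC+RC arm
strategy-scoped, since it represents the whole population under current
practice but only Uro/GU responders under triage) and each year,
p̂ = deaths of that cause / patients at risk entering the year. A year with
an empty risk set is flagged missing, never silently zero. This estimator
is exactly the quantity the Markov engine consumes; tests cross-check it
against Kaplan–Meier survival (lifelines) and verify parameter recovery
within three binomial standard errors at n = 50,000.

**Default generating hazards are synthetic and deliberately conservative.**
They encode the field's quantitative premise rather than any registry
curve: 5-year overall survival ≈ 57% after RC only; ≈ 61% for
population-wide NAC+RC (the ~5-point absolute NAC benefit reported in
meta-analysis); ≈ 64% for Uro/GU NAC+RC (the population benefit
concentrated in the ~70% of NAC recipients who are Uro/GU); ≈ 47% for
poor-prognosis RC+AC. Bladder-cancer hazard peaks in years 1–2 and
declines; other-cause hazard rises slowly; schedules cover 10 years.

Under these defaults the subtype strategy gains almost no QALYs: the
survival advantage of moving Uro/GU patients onto NAC (≈ +7 points among
those switched) is largely offset by routing the large poor-prognosis
Ba/Sq fraction (0.753 of 0.303) onto the worst-surviving arm and by the
extra chemotherapy toll (≈ 0.06 QALYs). Published results of this model
class report a much larger gain (+0.40 QALYs at 5 years), which requires
the Uro/GU NAC survival curve to separate far more strongly from the
RC-only curve than the average NAC benefit implies — plausible for the
small responder cohorts those curves came from, but not derivable from
printed values. The generator is therefore a *structural* test bed: passing
tests demonstrate that the pipeline (generation → estimation → Markov →
economics → PSA) is internally consistent and converges to its generating
truth, **not** that the synthetic verdict transfers to real registry data.
Real schedules can be supplied as CSV (`arm, year, p_death_bc,
p_death_other`) to evaluate actual survival inputs.

What the generator does not emulate: TNM stage migration, comorbidity and
socioeconomic structure, calendar-period effects, subtype-specific survival
within the upfront-RC arms, and informative censoring.

## Numerical choices and degenerate inputs

* Trace rows sum to 1 within 1e-12; branch probabilities within 1e-9 after
  renormalization (1e-6 tolerance at mixing time).
* Schedules shorter than the requested horizon raise; nothing is
  extrapolated. Yearly probability pairs must be non-negative and sum to
  ≤ 1.
* ICER reporting at exact zero cost difference with positive QALY gain is
  0 with no dominance flag; cheaper-and-better is flagged dominant with no
  finite ICER.
* Sub-milli-euro incremental differences are treated as renormalization
  round-off when phrasing the null verdict.
* PSA problem sizes: the deterministic model re-runs per iteration with
  cohort traces cached (they depend only on the fixed schedules), so a
  10,000-iteration PSA completes in seconds.

## Known limitations

* The cycle-0 accrual convention is inferred, not documented (above).
* The chemo toll duration and the PSA families are implementation choices
  surfaced in configuration, not published facts.
* Only one-way deterministic sensitivity is implemented (no multi-way
  grids, no EVPI/EVPPI).
* The societal perspective (productivity losses) and long-term cisplatin
  toxicity are out of scope, as is the molecular classifier itself: the
  model starts from subtype prevalences, not expression data.
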