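# subtypecea

A Markov cohort cost-effectiveness model asking whether **molecular-subtype-based
de-escalation of neoadjuvant chemotherapy (NAC)** is good value in
muscle-invasive bladder cancer (MIBC).

## The problem

Guidelines recommend cisplatin-based NAC before radical cystectomy (RC) for
every cisplatin-eligible MIBC patient, but tumours of the Basal/Squamous
(Ba/Sq) molecular subtype respond poorly to NAC, while Urothelial-like (Uro)
and Genomically Unstable (GU) tumours respond well. A subtype-based policy —
NAC+RC for Uro/GU, upfront RC for Ba/Sq with adjuvant chemotherapy (AC)
reserved for poor-prognosis pathology (≥pT3 or pN+) — trades an RNA-based
subtyping test and more chemotherapy exposure against better-targeted
treatment. This package implements the decision-analytic model that prices
that trade-off for a healthcare provider, for health economists and
uro-oncology researchers who want to reproduce, stress or re-parameterize
the analysis.

## The model

Three health states — alive after RC (`A`), dead of bladder cancer, dead of
other causes — with yearly cycles and absorbing death states. Cycle 0 is the
treatment year; an *N*-year horizon runs *N* yearly transitions (so *N*+1
accrual cycles). For a treatment arm with yearly cause-specific death
probabilities `p_bc(t)`, `p_oth(t)`:

```
A(t) = A(t-1) · (1 − p_bc(t) − p_oth(t)),   A(0) = 1
```

A *strategy* is the decision tree collapsed to terminal arms: current
practice mixes {NAC+RC: 0.280, RC only: 0.720 × (good 0.947 / poor 0.053 →
RC+AC)}; the subtype-based strategy mixes {Uro/GU → NAC+RC: 0.696, Ba/Sq:
0.303 × (poor 0.753 → RC+AC / good 0.246 → RC only)} and charges every
patient the subtyping cost (€341). Discounted outcomes per strategy:

```
Cost  = one-off treatment costs (cycle 0) + Σ_{t≥1} A(t) · c_surv / (1+r)^t
QALY  = A(0)·(u_RC − toll) + Σ_{t≥1} A(t) · u_surv / (1+r)^t      (AUC)
ICER  = ΔCost / ΔQALY,     NMB = WTP·ΔQALY − ΔCost
```

with r = 3%/year, WTP = €7,427/QALY (100,000 SEK), u_RC = 0.80,
u_surv = 0.914, and a one-time chemotherapy disutility toll (0.36 × 0.25 y
for 3 NAC courses; 0.36 × 0.33 y for 4 AC courses). One-way (tornado) and
probabilistic (10,000-draw Monte Carlo, beta/gamma, CEAC) sensitivity
analyses propagate the parameter ranges. Because the registry survival
schedules behind the original analysis are not public, a synthetic module
generates registry-like cohorts (competing risks, administrative censoring)
and re-estimates yearly transition probabilities with a cause-specific
life-table estimator, closing the full pipeline.

## Worked example

```python
from subtypecea import CostEffectivenessModel, default_schedules

model = CostEffectivenessModel(default_schedules())   # synthetic survival
print(model.fit().summary())
```

prints

```
Cost-effectiveness of subtype-based NAC de-escalation vs current practice
(discount rate 3.0%/yr, WTP 7,427 EUR/QALY)

 horizon strategy             cost (EUR)    QALYs     dCost   dQALY       ICER
      2y CURRENT_PRACTICE         16,144    2.208
      2y SUBTYPE_BASED            17,929    2.160     1,785  -0.048  dominated
         -> subtype-based strategy NOT cost-effective at WTP 7,427 EUR/QALY (incremental NMB -2,143 EUR)
      3y CURRENT_PRACTICE         16,419    2.774
      3y SUBTYPE_BASED            18,212    2.742     1,793  -0.032  dominated
         -> subtype-based strategy NOT cost-effective at WTP 7,427 EUR/QALY (incremental NMB -2,031 EUR)
      5y CURRENT_PRACTICE         16,883    3.729
      5y SUBTYPE_BASED            18,694    3.734     1,811   0.005    383,537
         -> subtype-based strategy NOT cost-effective at WTP 7,427 EUR/QALY (incremental NMB -1,776 EUR)
```

Each block gives the discounted per-patient cost and QALYs of both
strategies at one horizon, the incremental cost and QALY gain of the
subtype-based strategy, and the ICER with a verdict at the Swedish WTP.
Under the package's *synthetic* survival schedules the subtype strategy
buys almost no extra survival, so it is not cost-effective — the verdict is
a property of those synthetic inputs, not of the published registry data;
see `docs/methods.md` for why, and supply your own schedule CSV
(`CostEffectivenessModel.from_csv`) to evaluate real survival inputs.

Sensitivity analyses hang off the model:

```python
psa = model.psa(n=10_000, seed=1, horizon=5)
points = psa.ceac([7_427.0, 10_000.0])
top = model.tornado(horizon=5)[0]      # widest one-way ICER span
```

The same workflow is available from a shell:

```bash
subtypecea run --horizon 5 --out results/
subtypecea tornado --out results/
subtypecea ceac --seed 1 -n 10000 --out results/
subtypecea simulate --seed 1 --n 20000 --out results/
subtypecea estimate results/cohort.csv --out results/
subtypecea scenario examples/scenario_nac_uptake_2022.yaml --out results/
```

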