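# sympatry

Tools for asking two questions of a camera-trap survey of two co-occurring
carnivores and their prey:

1. **Do the two predators share space?** A maximum-likelihood *conditional
   two-species occupancy model* estimates, per site, the probability that a
   dominant species A occupies (ψ^A), the probability the subordinate B
   occupies given A does (ψ^BA) or does not (ψ^Ba), and five detection
   probabilities (p^A, p^B, r^A, r^BA, r^Ba) that allow detection of one
   species to depend on the presence — and per-occasion detection — of the
   other. Candidate models with site covariates (prey detection rates, a
   road flag, survey-year groups) are ranked by AICc, and the derived
   **Species Interaction Factor**

   φ = ψ^A ψ^BA / ( ψ^A [ψ^A ψ^BA + (1 − ψ^A) ψ^Ba] )

   summarises co-occurrence: φ = 1 under independence, φ > 1 when the
   subordinate aggregates with the dominant, φ < 1 under avoidance.

2. **Do they share time?** Photo timestamps, thinned to independent events
   (≥ 1 h apart per station) and mapped to *sun time* (sunrise → π/2,
   sunset → 3π/2), are smoothed with a von Mises kernel density; temporal
   overlap between two species is the coefficient

   Δ̂₁ = ∫ min(f̂₁, f̂₂) dθ ∈ [0, 1],

   with smoothed-bootstrap confidence intervals, and each species is
   classified diurnal / nocturnal / crepuscular by the probability mass in
   the corresponding sun-time windows (±1 h bands around sunrise and
   sunset).

The package is aimed at ecologists analysing detection/nondetection data
from fixed camera stations — in particular surveys of jaguar and puma with
deer, peccary and calves as prey — and at anyone needing a tested,
scriptable implementation of the conditional two-species likelihood or the
circular overlap estimator. A synthetic-survey generator with known truth
(latent occupancy states, true φ, true Δ) makes every stage testable
without field data.

## Worked example

```python
import numpy as np
from sympatry import (SimDesign, simulate_occupancy, simulate_activity,
                      fit_model, model_selection_table, overlap_delta1,
                      bootstrap_ci, true_overlap)

# a survey: 100 stations, one 30-day month in each of 4 years,
# psiA=0.28, psiBA=1.0, psiBa=0.28, daily detection 0.03-0.04
design = SimDesign(seed=1)
photos, history, truth = simulate_occupancy(design)

null = fit_model("psiA(.) psiBA(.) psiBa(.) pA=rA(.) pB=rBA=rBa(.)",
                 history, seed=0)
year_fx = fit_model("psiA(.) psiBA(.) psiBa(y) pA=rA(.) pB=rBA=rBa(.)",
                    history, seed=0)
tab = model_selection_table([null, year_fx])
print(tab[["model", "AICc", "delta_AICc", "weight", "K"]].round(2).to_string(index=False))
print(null.sif_.round(3).to_string(index=False))

events, act_truth = simulate_activity(design, n_events=200)
d = overlap_delta1(events["jaguar"].sun_times, events["puma"].sun_times)
ci = bootstrap_ci(events["jaguar"].sun_times, events["puma"].sun_times,
                  reps=1000, seed=0)
print(f"jaguar-puma overlap {d:.2f} "
      f"(95% CI {ci.ci_low:.2f}-{ci.ci_high:.2f}; "
      f"true {act_truth.true_deltas[('jaguar', 'puma')]:.2f})")
```

prints (exact numbers from this seed):

```
                                           model    AICc  delta_AICc  weight  K
psiA(.) psiBA(.) psiBa(.) pA=rA(.) pB=rBA=rBa(.) 3247.75        0.00    0.94  5
psiA(.) psiBA(.) psiBa(y) pA=rA(.) pB=rBA=rBa(.) 3253.21        5.47    0.06  8
 year  estimate    se
 2009     2.121 0.146
 2010     2.121 0.146
 2011     2.121 0.146
 2012     2.121 0.146
jaguar-puma overlap 0.65 (95% CI 0.58-0.74; true 0.64)
```

The AICc table says the intercept-only model is preferred (weight 0.94;
adding year structure to ψ^Ba costs 3 parameters and is not supported).
The fitted SIF of 2.12 ± 0.15 indicates aggregation — the subordinate
predator is about twice as likely to use a site occupied by the dominant
one as expected under independence (the generating truth is φ = 2.08).
The activity branch estimates a jaguar–puma temporal overlap of 0.65
against a generating-density truth of 0.64, with a seeded bootstrap
interval of 0.58–0.74.

The same pipeline runs from the shell:

```bash
sympatry simulate --seed 1 --outdir run/
sympatry build    --records run/photos.csv --stations run/stations.csv --outdir run/
sympatry fit      --history run/history.csv --outdir run/fit/
sympatry activity --events run/events.csv --stations run/stations.csv --outdir run/act/
sympatry report   --fit-dir run/fit/ --activity-dir run/act/ --out run/report.md
```

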