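# bearpva

Stochastic population viability projections and conditional-inference
classification trees for deriving **demographic monitoring thresholds**,
built around the post-delisting monitoring problem for the Louisiana black
bear (*Ursus americanus luteolus*) in the Tensas River Basin (TRB) and
Upper Atchafalaya River Basin (UARB).

## The problem

After a threatened species recovers, managers need cheap, reliable
triggers for intervention: a short-term demographic statistic and a
threshold such that staying above it predicts long-term persistence. This
package implements a two-stage answer:

1. **Stochastic projection.** Female abundance is projected 100 years with
   annual apparent survival φ_t and density-dependent per-capita
   recruitment f_t:

   - logit(φ_t) = μ_φ + ε_t, ε_t ~ Normal(0, σ_φ²)
   - log(f_t) = β_0f + β_1f·N_t + ε_t, ε_t ~ Normal(0, σ_f²)
   - survivors ~ Binomial(N_t, φ_t), recruits ~ Poisson(N_t·f_t)
   - λ_t = φ_t + f_t (apparent rates fold migration in)

   The five hyper-parameters are drawn independently from uniform
   distributions spanning the packaged posterior ranges of an upstream
   capture–mark–recapture analysis, giving a Monte-Carlo design over
   biologically plausible population dynamics. Each trajectory is labelled
   EXTANT (N₁₀₀ ≥ 1) or EXTINCT.

2. **Classification.** Conditional-inference trees and forests —
   recursive partitioning with permutation-test split selection,
   implemented from scratch in `bearpva.citree` — classify EXTANT against
   (a) the generating parameters (which long-term rates matter?) and
   (b) the 5-year means N̄₅, φ̄₅, λ̄₅ (what should a 5-year monitoring
   program watch?). Root-to-leaf branches of a single tree are *scenarios*;
   branches whose leaves show ≥ 95% persistence are *reliable*, and the
   smallest survival-only lower bound among them is the candidate
   monitoring trigger.

## Worked example

```python
import numpy as np
from bearpva import experiments as ex

table = ex.simulate_subpopulation("UARB", seed=1)   # 400 combos x 250 trajectories
print(len(table), table["extant"].mean())
# 100000 0.93302

cp = ex.conditional_persistence(table, trigger=0.91)
print(f"{cp.percent_extant:.1f}% of {cp.n_above} high-survival trajectories persist")
# 97.6% of 45716 high-survival trajectories persist

res = ex.survival_threshold_from_table(table, seed=2)
print(res.n_scenarios, res.n_reliable, res.threshold)
# 16 10 0.9484014476542436
```

The first numbers say that 93.3% of simulated UARB trajectories persist
100 years, rising to 97.6% among trajectories whose 5-year mean survival
exceeds 0.91. The last line grows the single classification tree on
(N̄₅, φ̄₅, λ̄₅): 16 branch scenarios, 10 of them reliable (≥ 95%
persistence), and the minimum survival-only trigger for this seed is
φ̄₅ > 0.95 (rounded). Because early mean abundance and growth rate compete
with survival as predictors under the packaged initial abundances, some
seeds yield no survival-only reliable branch at all — `threshold` is then
`None` and the scenario list tells you which mixed conditions are reliable
instead.

The numbered scripts under `analysis/` run the same steps as a narrative:
`01_simulate.py` (projection design and persistence summaries),
`02_rank_importance.py` (forest variable importance and holdout error
rates), `03_extract_thresholds.py` (trees, scenarios, triggers). Each
writes its tables under `results/`.

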