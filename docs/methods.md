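# Methods

## Projection model

The simulator projects female abundance of one subpopulation over a
100-year horizon with two nested layers of randomness.

**Temporal (environmental) stochasticity.** Each year draws latent annual
rates from hyper-distributions on link scales:

- apparent survival: logit(φ_t) = μ_φ + ε_t, ε_t ~ Normal(0, σ_φ²),
  so φ_t ∈ (0, 1) always;
- per-capita recruitment: log(f_t) = β_0f + β_1f·N_t + ε_t,
  ε_t ~ Normal(0, σ_f²), a log-linear density-dependence model (β_1f < 0
  in both subpopulations' ranges, so recruitment rises as abundance
  falls).

Apparent survival absorbs mortality *and* emigration; recruitment absorbs
births *and* immigration. Their sum λ_t = φ_t + f_t is the annual realised
growth rate. The recorded annual rates are the *latent* draws, not the
realised binomial proportions — realised proportions are undefined once
N_t = 0, while latent rates keep the 5-year summary statistics defined for
every trajectory, including ones that die in year 1.

**Demographic stochasticity.** Given the year's rates, individual fates
are realised as survivors ~ Binomial(N_t, φ_t) plus recruits ~
Poisson(N_t·f_t). These are the standard process distributions for
survival and recruitment counts. Zero abundance is absorbing (both
distributions return 0 at N_t = 0).

**Design space.** The five hyper-parameters (μ_φ, σ_φ, β_0f, β_1f, σ_f)
are sampled independently, each uniform over the packaged posterior
minima/maxima of the upstream capture–mark–recapture fit (stored on the
printed scales: logit for survival, natural log for recruitment).
Independent sampling deliberately breaks the joint-posterior correlation
structure so the design covers rate combinations never observed — that is
the point of the sensitivity analysis, but it also means corners of the
design (e.g. a huge recruitment intercept with a negligible
density-dependence slope) are biologically outlandish. Each sampled
combination is reused for all of its replicate trajectories, because the
downstream analysis relies on combination-level replication.

### Tunable parameters

| parameter | default | units / scale | rationale |
|---|---|---|---|
| `N0` | 300 (TRB), 60 (UARB) | females | assumed plausible post-recovery sizes; **not estimates**. Absolute persistence results are conditional on these. |
| `T` | 100 | years | the standard PVA horizon here; EXTANT ⇔ N_T ≥ 1 |
| `n_combos × n_traj` | 400 × 250 | — | 1/10 of the reference 2,000 × 500 design; chosen so a full two-subpopulation study runs in well under a minute on one core |
| `N_max` | 1e5 | females | abundance cap; arithmetic guard only |
| `f_max` | 1e12 | recruits/female/yr | latent-recruitment guard; see below |
| `window` | 5 | years | monitoring duration for the derived means (years 1..5; year 0 is a configuration input, not an observation) |

**The recruitment guard.** Sampled intercepts reach β_0f ≈ 43 on the log
scale, so latent f can reach ~1e18 and Poisson means N·f would leave the
sampler's domain. The guard caps latent f at 1e12 — orders of magnitude
above anything attainable by a bear population, so it changes no
extinction outcome and, critically, leaves the heavy upper tail of the
recorded λ̄₅ intact. An earlier candidate default of f_max = 10 looked
harmless ("recruitment above 10/female/yr is already absurd") but proved
to matter downstream: flattening λ̄₅'s tail turns it into an excellent
linear test statistic and the threshold tree then splits on λ̄₅
everywhere, never producing a survival-only branch. Guards must bound
arithmetic, not reshape predictor distributions.

### Random numbers

A master seed feeds a `numpy` `SeedSequence`; one child stream draws the
parameter combinations and one further child is spawned per combination.
Trajectories within a combination are vectorised (year-major) inside that
combination's stream in a fixed order. Any subset of combinations is
therefore exactly reproducible regardless of which other combinations run,
and the full pipeline is byte-identical across runs with the same seed
(the manifests contain no timestamps for this reason).

## Classification stage

`bearpva.citree` implements conditional-inference classification trees and
forests from scratch (this is the package's analytical core, not a
wrapper).

**Split selection.** At each node the candidate variable's association
with the binary label is tested with the linear statistic
T = Σ x_i·1(y_i = EXTANT), standardised by its exact permutation moments
(E[T] = m·x̄, Var[T] = m(n−m)/(n−1)·Var(x) for m positives among n rows).
The p-value is two-sided normal for nodes with n ≥ 30; smaller nodes use
the exact permutation distribution (full enumeration up to 2×10⁵
labelings, else 9,999 Monte-Carlo permutations, two-sided as
P(|T*−E| ≥ |T−E|)). Bonferroni adjustment over the `mtry` variables
tested at the node; growth stops when the best adjusted p exceeds
α = 0.05, when a node is pure, smaller than `minsplit` = 20, or at
`maxdepth` = 4 (root at depth 0, so four levels of splits). The split
point on the chosen variable maximises the absolute hypergeometric
z-score over observed values leaving ≥ `minbucket` = 7 rows per side,
ties to the smallest threshold. α/minsplit/minbucket follow the reference
recursive-partitioning framework's defaults; maxdepth = 4, mtry = all
variables (5 long-term, 3 short-term) and ntree = 100 are the study's
stated settings. When mtry equals the number of variables the "random"
candidate draw is the identity, implemented literally.

**Forests and importance.** Each of the 100 trees trains on a
without-replacement subsample of ⌈0.632·n⌉ rows (the unnamed default of
the referenced framework); in-bag indices are stored so out-of-bag (OOB)
computations are reproducible. Variable importance is the mean over trees
of (OOB accuracy − OOB accuracy with that variable's OOB values
permuted). Error rates come from an independent holdout partition:
overall misclassification, and Type II = truly-extinct rows predicted
extant over truly-extinct rows (reported as undefined, never 0, when the
holdout has no extinct rows). Prediction ties at probability 0.5 resolve
to EXTANT so ambiguity surfaces as Type II error rather than hiding.

**Scenarios and thresholds.** Each root-to-leaf path of the single
short-term tree is a scenario: a conjunction of conditions on
(N̄₅, φ̄₅, λ̄₅) with the leaf's extant fraction as its persistence
probability (the raw leaf fraction, not a smoothed estimate). Scenarios
with persistence ≥ 0.95 are reliable; among reliable scenarios whose
conditions reference φ̄₅ *only* and include a lower bound, the binding
lower bound is the largest ">" threshold on the path, and the reported
monitoring trigger is the minimum over such scenarios. Paths mixing
variables are reported but excluded from the headline number. Thresholds
are kept at full precision internally and rounded to two decimals only in
reports.

## What the generator emulates — and what passing tests show

The simulator *is* the study's data generator: there is no external data,
and the classification stage is tested against data whose generating
process is exactly known. Passing tests therefore demonstrate that (a) the
projection engine matches its closed-form limits (branching-process
extinction, binomial/Poisson moments, logit-normal symmetry), and (b) the
tree machinery recovers known structure — including a positive control in
which the design is modified to make extinction survival-driven and the
forests correctly rank μ_φ and φ̄₅ first.

They do **not** show that the packaged design reproduces the historical
monitoring data's answers. Two headline outcomes are conditional on the
initial abundances, which are packaged assumptions: under N₀ = 300/60 only
2–7% of trajectories go extinct, extinction is driven mainly by
recruitment failure (small β_0f, or small density-dependent equilibria)
rather than survival, and the short-term tree's root variable flips
between φ̄₅, N̄₅ and λ̄₅ across seeds. Consequences visible in this
package's own outputs: the long-term importance ranking is led by β_0f
rather than μ_φ/σ_φ; the survival-only trigger, when it exists, sits near
0.95 rather than 0.90 and for many seeds no reliable branch is
survival-only at all; and with a ~3% extinct class the short-term forest
approaches majority-class prediction, so its Type II error is large even
though overall error is a few percent. The persistence-conditional result
is robust, however: trajectories with φ̄₅ > 0.91 persist ≥ 95% of the time
in every configuration examined.

## Numerical and degenerate-input choices

- Recruitment is evaluated and clamped on the log scale, so no overflow
  can occur before the cap (log f ≤ ~53 over the whole design space).
- Degenerate parameter ranges (lo = hi) are legal and produce constant
  draws; σ = 0 disables the corresponding noise exactly.
- A constant predictor or a pure response yields statistic 0 and p = 1
  (never a division by zero); a node with no feasible split point under
  `minbucket` becomes a leaf.
- Exact-mode p-value comparisons use a relative tolerance of 1e-9 when
  counting permutations as extreme, guarding against float round-off in
  sums of equal magnitude.
- `build_datasets` draws one permutation and takes disjoint slices, so
  train/holdout disjointness holds by construction for every seed.
- Scenario routing validates the partition property (every row matches
  exactly one rule) and raises rather than silently double-counting.

## Known limitations

- No age/stage structure, no explicit migration, no density dependence in
  survival; all are folded into the two apparent rates, as in the source
  monitoring analysis.
- Independent uniform sampling of the hyper-parameters visits biologically
  impossible corners (astronomical recruitment); results are statements
  about the design, not about bear biology in those corners.
- The absolute persistence probabilities and therefore the extracted
  thresholds are conditional on the assumed initial abundances; any
  application to a real monitoring program must set `N0` from data.
- Only binary classification with numeric predictors and binary splits is
  implemented (no categorical predictors, surrogate splits, missing-value
  handling, or bias-corrected importance variants).
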