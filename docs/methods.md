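# Methods

## The foraging model

The colony is modelled in discrete time over a horizon of `T` steps. State
consists of the nectar stores `B_t` and, for each forager, an experience
counter `e` — the number of whole steps the bee has spent on complex
flowers. Per-step rewards are `s` on simple flowers and the logistic
`c(e) = m + K/(1 + exp(−(α·e − β)))` on complex flowers; a bee is paid at
the experience it holds at the *start* of a step, so a naive bee's first
complex step earns `c(0)`. Handling time is folded into the curve; there is
no travel cost, flower depletion, or social learning. All `N` bees
(sedentary included) consume `q` per step, and the stores must satisfy
`B_t ≥ 0` at every step. The objective is total net intake over the
horizon.

Conventions the model's headline numbers depend on (all exposed as
configuration):

* **Initial stores = 0.** This makes the step-0 budget bound binding:
  with defaults, 50 switchers are affordable
  (`50·s + 50·c(0) − N·q = +0.227`) but 51 are not (`−39.77`), which is
  what pins "half the foragers switch at the first step".
* **Survival as a per-step hazard.** The horizon survival probability is
  converted to the memoryless per-step hazard `μ = 1 − survival^{1/T}`,
  which reproduces the stated survival exactly at `t = T`. Expected-value
  (fractional-bee) dynamics are the default, so every headline run is
  deterministic; a seeded stochastic mode draws per-cohort Binomial deaths.
* **Order of events within a step:** allocate → earn → consume `N·q` →
  mortality/replacement (replacements are naive and join the simple pool) →
  experience increment for complex-assigned survivors.
* **Sedentary count** is `round(N·r)` with .5 rounded away from zero.
* **`T` and the step count** are a single parameter; `steps` is accepted in
  configs as an alias of `T`.

## The optimizer

Production solvers restrict the policy space to *switch once, permanently*:
the decision object is the vector `m_t` of foragers newly reassigned to
complex flowers at each step. The restriction is motivated by an exchange
argument — a bee's total earnings depend only on how many complex steps it
takes (it collects `c(0), c(1), …` in order regardless of scheduling), and
deferring the loss-making early learning steps can only help the stores —
and is *validated*, not assumed: an exhaustive enumeration over all
per-step, per-experience-class allocations (instances up to `N_f = 3`,
`T = 6`) agrees with the restricted optimum to 1e−6 on 50 randomized
instances in the test suite. No counterexample is known; if one is found it
should be recorded here as a limitation.

The greedy solver switches, at each step, the largest batch that keeps the
whole remaining trajectory solvent assuming no further switches (the future
stores path is affine in the batch size, so the bound is a one-shot
minimum over binding steps), and only while the survival-discounted
marginal value `Σ_{j<T−t} (1−μ)^j (c(j) − s)` is positive. The same policy
class is solved exactly as a mixed-integer program (HiGHS): the objective
and every stores constraint are linear in `m_t`. The pure LP relaxation is
available as a diagnostic upper bound. With two or more foragers batches
are integer; with a single forager (the solitary-bee limit) they are
continuous fractions of foraging time.

**Degeneracy.** When the stores constraint binds, moving a switch between
adjacent steps can leave the objective exactly unchanged, so the optimal
*schedule* is not unique even though the optimal *value* is; greedy and the
integer program may return different `m_t` vectors with objectives equal to
1e−9. Comparisons should therefore be made on objectives and on summary
statistics (initial batch, completion step), not per-step vectors.

**Integer rounding and colony-size invariance.** The model is linear in
colony size, so continuous (fractional-time) solutions scale exactly with
`N`: the fraction-of-foragers trajectories for `N = 50…400` are identical
to machine precision. Integer allocations introduce `O(1/N)` rounding in
the mid-run trickle of switches (the completion step, 22 at defaults, is
unaffected across `N = 50–200`). The colony-size sweep therefore runs in
fractional mode, which is also the natural reading of "allocation of
foraging effort" for small colonies.

Numerical tolerances: stores feasibility is checked at 1e−6 (solutions ride
the constraint and accumulate rounding at that scale); conservation and
mass bookkeeping at 1e−9; objective comparisons at 1e−6.

## Parameter sweeps

Grids: horizon `T ∈ {50, 60, 80, 100}` and learning position
`β ∈ {10, 13, 16, 17}` are fixed defaults; the sedentary grid
`r ∈ {0, 0.1, 0.2, 0.3}` spans the feasible range below the solvency bound
`r ≤ 1 − q/s = 0.4`, and the survival grid `{0.3, 0.5, 0.7, 0.9, 1.0}`
spans strong to no mortality; both are config-overridable choices. The
five directional predictions are evaluated on two metrics: total complex
bee-steps (`Σ_t` foragers on complex) and the completion step. "Delay" is
read off the completion step and the pointwise-lower fraction trajectory:
under these conventions a (smaller) first batch still switches at step 0
whenever switching pays at all, so the *first*-switch step is not an
informative delay metric. All sweeps use expected-value dynamics and are
bit-reproducible; plots are conveniences and no reported quantity is read
from a figure.

## Visitation-table analytics

The analysis layer consumes one row per captured bee (bee species/genus,
sociality coded strictly binary — rows with intermediate sociality are
dropped with a logged count — proboscis length, plant species, flower
symmetry, corolla tube length, round, plot). Complexity proxies: bilateral
symmetry, and "deep" corolla tubes strictly longer than 3 mm (a 3.0 mm tube
is shallow). Group summaries are species-level by default — each species
contributes one proportion or mean, and the group s.e. is
`sd(ddof=1)/√n_species` — because headline community statistics of this
kind are reported "per species"; visit-weighted means and the
population-sd (`ddof=0`) variant are computed alongside so either
convention can be read off. Proboscis size classes are 0–3, 3–6, 6–9,
9–12 mm, right-closed at the top; shares are of each flower class's visits.

`fit_choice_regression` is a deliberately simplified stand-in for a
phylogenetic generalized linear mixed model: ordinary ML logistic
regression of the complexity flag on sociality, proboscis length and their
interaction, with **no** random effects. It does not reproduce
phylogenetically corrected Wald statistics and should not be used for
inference on real communities; its role is sign/direction reporting and
synthetic-data calibration. Quasi-complete separation and rank-deficient
designs are flagged (`attrs["separation"]`), falling back to a weakly
regularized fit or NA coefficients rather than raising.

## Synthetic data

The generator emulates the field-table schema with known truth: 58 bee
species (20 eusocial), 67 plant species cross-classified by symmetry and
depth (the first four plants pin one species in every cell so any choice
outcome is servable), log-normal proboscis lengths (median ≈ 3.7 mm,
matching the few-mm scale of real communities), negative-binomial visit
counts (mean 187/species ⇒ ≈ 10.9 k rows, dispersion 1.5 for realistic
unevenness), and per-visit Bernoulli choices of bilateral and (independently)
deep flowers through a logit link with defaults
`(−1.4, 0.9, 0.15, 0)` chosen to give species-mean complex-visit
proportions near 0.52 (eusocial) and 0.32 (solitary) and a pooled bilateral
share just under one-half. A Brownian-motion species random effect is drawn
from the multivariate normal whose covariance is shared branch length on a
generated pure-birth ultrametric tree, normalized so `phylo_signal` is the
tip variance. The seed is mandatory and the same spec is byte-reproducible.

What the generator does *not* emulate: real sampling design beyond
round/plot labels, trait measurement error, plant abundance structure,
within-species proboscis variation, and any correlation between symmetry
and depth (independent by default; the field analyses treat them as
separate models). Passing tests on synthetic data therefore demonstrate
the correctness of the bookkeeping and the calibration of the regression
stand-in under the generator's assumptions — not the field conclusions
themselves. The documented failure mode is deliberate: with
`phylo_signal > 0` the naive regression's reported standard errors
understate the sampling spread of the sociality coefficient (tested at
signal 1.0), which is exactly why a phylogenetic mixed model is the right
tool on real communities.

## Problem sizes used in the test suite

Expected-vs-stochastic agreement uses 1000 replicates of a 10-bee, 10-step
colony; oracle validation uses 50 random instances with `N_f ≤ 3`,
`T ≤ 6`; regression calibration uses 200 replicates of 58 species at 200
visits/species for both the recovery and the null (type-I error) studies.
These sizes give Monte-Carlo error comfortably below the margins being
asserted while keeping the default test run fast.

## Known limitations

* The permanent-switch restriction is validated only on small instances;
  the exchange argument is informal, not a proof.
* The stand-in regression ignores all grouping structure (species, round,
  plot, phylogeny); its p-values are anti-conservative on clustered data.
* Expected-value mortality treats bees as divisible; integer stochastic
  runs match it only in the mean.
* No spatial structure, travel costs, flower depletion, or pollen/nectar
  distinction.
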