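# hiveforage

When should a bee colony invest in learning to forage on morphologically
complex flowers?

Complex flowers (bilateral symmetry, deep or narrow corolla tubes, concealed
nectaries) hold high food rewards but demand a handling technique each bee
must learn individually; simple, open flowers pay a modest reward
immediately. `hiveforage` implements a discrete-time optimization model of
this trade-off for a eusocial colony, together with descriptive analytics
for bee–flower visitation tables and a synthetic-data generator that
emulates their schema. It is aimed at behavioural and evolutionary
ecologists studying optimal foraging, pollinator–plant interactions, and
the life-history correlates of sociality.

## The model

A colony of `N` bees (a proportion `r` sedentary; `N_f = N − round(N·r)`
foragers) lives for `T` discrete steps. A forager with `e` steps of
experience on complex flowers earns, per step,

    c(e) = m + K / (1 + exp(−(α·e − β)))

on complex flowers (a logistic learning curve rising from `m` to `K + m`,
with inflection at `β/α`), or the flat reward `s` on simple flowers.
Experience is never forgotten. Every bee consumes `q` per step, so the
colony's nectar stores

    B_{t+1} = B_t + intake_t − N·q

must stay non-negative at every step. Each bee survives to the horizon with
probability `survival` (a constant per-step hazard `μ = 1 − survival^{1/T}`);
the dead are replaced by naive bees. The colony chooses, at each step, how
many foragers to reassign — permanently — from simple to complex flowers so
as to maximize total net intake `Σ_t intake_t − T·N·q`.

Defaults: `T = 100, N = 100, K = 100, m = 10, α = 0.45, β = 10, s = 50,
q = 30, r = 0, survival = 1`, empty initial stores.

Three solvers are provided: a greedy policy with whole-horizon feasibility
lookahead (the default), an exact mixed-integer programming solve of the
same policy class (HiGHS via `scipy.optimize.milp`), and an exhaustive
enumeration oracle for tiny instances that validates the permanent-switch
restriction against all possible per-step, per-experience-class allocations.

## Worked example

```python
from hiveforage import ColonyForagingModel

res = ColonyForagingModel().fit()
print(res.summary())
```

```
Colony foraging optimization
========================================
method:                  greedy
colony size N:           100  (foragers 100, sedentary 0)
horizon T:               100
survival to horizon:     1
simple reward s:         50   consumption q: 30
learning curve:          K=100 m=10 alpha=0.45 beta=10
breakeven experience:    22 steps
----------------------------------------
objective (net intake):  515776.979
switched at step 0:      50 of 100 foragers
first switch step:       0
all-complex step:        22
total complex bee-steps: 9050.0
final stores:            515776.979
feasible:                True
```

Half the foragers switch to complex flowers immediately — the largest batch
the step-0 energy budget can carry, since a naive bee earns only
`c(0) ≈ 10.005` while the colony burns `N·q = 3000` per step. As the first
cohort's learning curve climbs, the stores surplus grows and the remaining
foragers trickle over; by step 22 (the experience level at which
`c(e) > s`) every forager is on complex flowers. With a shorter horizon
(`T = 50`) the switch never completes and the colony forages on both types
roughly equally; more sedentary bees, slower learning, or lower individual
survival all delay and reduce complex-flower foraging, while colony size
has no effect on the allocation fractions.

The same objects drive parameter sweeps and visitation-table analytics:

```python
from hiveforage import experiments as ex
print(ex.table2_report()[["parameter", "prediction", "status"]])

from hiveforage.synth import GeneratorSpec, generate_interactions
from hiveforage import interactions as ia
table, truth, tree = generate_interactions(GeneratorSpec(seed=1))
print(ia.complexity_counts(ia.code_complexity(table)))
```

or from the shell: `hiveforage optimize|sweep|interactions|synth --help`.

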