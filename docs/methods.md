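# Methods

## The model

n actors sit on a complete network and play pairwise Prisoner's Dilemmas
(T > R > P > S, all in points). In every period one m-regular graph on the
n labeled actors is drawn uniformly at random — so every potential relation
is used with probability π = m/(n − 1) per period — and matched pairs play
simultaneously; each unmatched relation pays a fixed Q. Future payoffs are
discounted at β ∈ (0, 1) (equivalently, β is a continuation probability).
Two information regimes differ only in what is observed afterwards:
*atomized* actors see outcomes of their own dyads (plus who was matched with
whom), *embedded* actors see all outcomes in the group.

Conditional cooperation means everyone playing the trigger strategy:
cooperate with a partner until that partner is observed defecting against
anyone within one's information scope, then defect against that partner
forever. The equilibrium analysis compares ALL-C against ALL-D as responses
to a group of triggers, infinite horizon:

* `EU(ALL-C) = (mR + (n−1−m)Q) / (1 − β)` — identical in both regimes.
* Embedded deviant: one period of mT, then mP forever:
  `EU(ALL-D | emb) = mT + βmP/(1−β) + (n−1−m)Q/(1−β)`.
* Atomized deviant: each relation independently yields T on its first
  activation (probability π(1−π)^(t−1) in period t), P on later activations,
  Q when inactive:
  `EU(ALL-D | ato) = mP/(1−β) + m(T−P)/(1−β(1−π)) + (n−1−m)Q/(1−β)`.

Setting EU(ALL-C) = EU(ALL-D) gives the thresholds
`β_emb = (T−R)/(T−P)` and `β_ato = (T−R)/(T−P−(R−P)(1−π))`, with
β_ato ≥ β_emb and equality exactly at π = 1. Q cancels throughout. At the
experimental payoffs (T=60, R=40, P=20, S=0; n=6, m=2, π=0.4) these are 1/2
and 5/7.

The theory module evaluates the infinite-horizon model even though the
simulated game lasts 40 periods — the thresholds are infinite-horizon
objects, and the finite game approximates them. `finite_horizon_eu`
truncates the same sums for diagnostics and is explicitly non-equilibrium.
The equilibrium concept is Nash in trigger strategies; subgame perfection is
not checked. The strong-trigger variant (defect against everyone after any
observed defection) exists only as a simulator strategy; its equilibrium
algebra is out of scope.

## Matching

Uniformity over *labeled* m-regular graphs matters ("each relation with
equal probability"): greedy pairing schemes bias edge marginals. For small
groups (n ≤ 10 and at most 200,000 graphs) all labeled m-regular graphs are
enumerated once, cached, and sampled by index — exact uniformity; for the
default (n=6, m=2) the support is 70 graphs (60 labeled 6-cycles, 10
triangle pairs). Beyond the cap the sampler uses configuration-model
pairing with rejection of loops and multi-edges, which is *also* exactly
uniform (every simple m-regular graph corresponds to the same number (m!)^n
of stub pairings); rejection just becomes slow for dense degrees, which is
why enumeration is preferred at small n.

## Simulator

Each period: draw a matching; every matched actor decides against each
partner using only information through the previous period (simultaneity);
apply trembles; compute stage payoffs; update information states per the
regime. Records keep intended and realized actions so analyses can condition
on error events. Determinism: one numpy Generator drives the whole run;
identical seed and config give bit-identical records.

Parameters that matter:

* **tremble** (per-decision error probability, default 0) — flips the
  intended action symmetrically. The cascade analyses use 0.02, a small
  noise level at which trigger groups with reputation unravel visibly
  within 40 periods; noise magnitude is a configuration surface, not a
  claim about human subjects.
* **trigger discrimination** (off by default) — the trigger reading is
  non-discriminating: any observed D by j triggers against j, including j's
  own retaliations. This reading is what makes reputation a noise
  amplifier: one mistake in an embedded group cascades to group-wide
  defection, while atomized damage stays inside the affected dyad. An
  optional `discriminating` flag excuses Ds aimed at actors the observer
  already knows to be defectors, for exploring the gentler reading.
* **LEARNING** — Bush–Mosteller aspiration reinforcement per dyad: the
  propensity to cooperate with a partner moves by rate·stimulus·(headroom),
  stimulus = sign-normalized (payoff − aspiration). Defaults: aspiration 30
  points (= Q, the income of doing nothing), rate 0.5, initial propensity
  0.5. This is one standard backward-looking interpretation of learning
  accounts of cooperation, not a calibrated behavioral model.
* **ForcedDefection** — test fixture injecting one realized D into a chosen
  dyad; it fires at the first period ≥ its `period` field in which that
  dyad is actually matched, making hand-traced cascade tests deterministic
  under random matching.

## Synthetic data

`generate_experiment` emulates the two lab layouts: 7+7 (Experiment 1) or
6+6 (Experiment 2) independent 6-person groups per condition, 40 scored
periods (practice periods are not modeled), strategies drawn per actor from
a scenario mixture. The default mixture — 60% trigger with 5% tremble, 20%
ALL-C with 5% tremble, 20% ALL-D — was chosen once as a plausible
behavioral-lab composition producing intermediate, declining cooperation;
the real composition of any subject pool is unknown and mixtures are
scenario inputs, never estimates. An optional endgame ramp (extra
defection probability rising linearly from 0 at period 36 to a maximum at
period 40, 0.3 when enabled) mimics the endgame effects of finitely
repeated lab games for pipeline testing; it is an invented device, off by
default and in all theory-facing tests.

What the generator does *not* emulate: human heterogeneity beyond the
mixture, within-subject strategy switching, session or location effects,
demographics, and the anonymity differences between lab setups. Passing
tests therefore show that the *procedures* (accounting, tests, reports) are
correct on data with the lab's structure — not that any behavioral claim
about humans is reproduced.

Per-group seeds derive from the design seed through `SeedSequence` spawn
keys indexed by (condition, group index), so enlarging a design never
changes existing groups.

## Analysis

The group is the unit of analysis. Windows: main rate over periods 1–35
(the final five are excluded because endgame behavior biases them), first
interactions (each dyad's first matched period; action-level by default,
dyad-level both-C as an option), and periods 30–35 inclusive (six periods)
for the late-game variance table. All windows are parameters.

* **Mann-Whitney U**: for combined N ≤ 20 the p-value is exact — full
  enumeration of all C(N, n_a) rank assignments with midranks for ties;
  two-sided p = min(1, 2·min(P(U′ ≥ U), P(U′ ≤ U))). Above N = 20 the
  normal approximation with tie correction is used. Default sidedness is
  two-sided; directional alternatives are flags.
* **Variance comparison**: one-sided F on unbiased sample variances by
  default (the directional claim is larger spread under embeddedness), with
  a seeded label-permutation variant (default 10⁴ permutations) as a
  robustness guard against non-normality. Zero variance in an arm is a
  flagged degenerate case, not a number.
* **Power**: exact noncentral-t power of the two-sample t-test
  (noncentrality δ/σ·√(n/2), df 2n−2). One-sided by default because the
  hypotheses are directional; at δ = 0.19, σ = 0.1, n = 5 the one-sided
  power is 0.863 (two-sided would be 0.749), which is what licenses the
  claim that five groups per arm suffice at the 80% convention. The
  sidedness is stated in the report output.
* **Multiple testing**: none; all p-values are reported raw.
* `run_hypothesis_suite` is pure: identical input dataset gives a
  byte-identical JSON report (the permutation option is seeded).

## Numerical choices and problem sizes

* Closed-form EUs are tested against a horizon-10⁴ truncated series
  (relative tolerance 10⁻⁶; the tail is bounded by max-payoff·β^H/(1−β))
  and, for the atomized form, a Monte-Carlo relation-activation oracle
  (10⁵ replications, 5·SE tolerance). Indifference at the thresholds is
  checked to 10⁻⁹ and root-finding against closed forms to 10⁻⁸.
* Sampler uniformity: χ² goodness-of-fit over the 70-graph support on
  70,000 draws, rejected only below p = 0.01.
* Calibration: the type-I error of the H1 pipeline is measured on 1,000
  null experiments (identical condition-blind mixtures in both arms —
  ALL-C with tremble 0.3 — at the 6+6 layout) against the binomial 99%
  interval around α = 0.05. Condition-blind strategies are essential here:
  trigger-based mixtures react to the information regime and are not a
  null.
* The noise-cascade contrast uses 500 seeds per condition in the test
  suite and 300 in the acceptance script; both sizes give the mean and
  variance effects at far beyond the α = 0.01 checks applied.

## Known limitations

* Strategies are stationary and hard-coded; no strategy estimation from
  data, no within-run switching, no partner choice or dynamic networks.
* The learning model is one interpretation; its parameters are not fitted
  to anything.
* The exact Mann-Whitney enumerates C(N, n_a) splits — fine for the ≤ 26
  groups these designs produce, combinatorial beyond that (the asymptotic
  branch takes over).
* Empirical quantities from the original lab sessions (group-level
  cooperation levels, their reported p-values) cannot be recomputed without
  the raw data; this package reproduces the procedures and validates them
  on synthetic data only.
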