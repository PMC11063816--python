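# Methods

## Design generation (`loopmem.design`)

72 location–person–object events are split 18/18/18/18 across the
loop (closed/open) × delay (delay/no-delay) cells.  Open loops encode
only the two pairs through their common element; within each encoding
session the common element is balanced 6/6/6 across the three roles.
Encoding sessions hold 90 trials in blocks of 18/36/36: block 1 contains
only the first pair of each closed loop, so that the last encoding
exposure precedes retrieval by the same lag for both loop types; blocks 2
and 3 interleave the remaining pairs in randomized order.  Pair orders
follow three rotated sequences for closed loops and three two-pair
sequences for open loops whose prefixes coincide, making the loop types
structurally identical over their first two encoding trials.  The three
closed-loop orders are assigned in balanced thirds within each session
(the allocation rule is otherwise unconstrained, so we balance it);
open-loop orders are determined by the common element.

Retrieval tests every encoded pair in both directions (6 tests per closed
loop, 4 per open loop; the never-encoded open pair is never tested),
giving 360 trials in two runs of 180 with events nested in runs (9 events
per cell per run) plus 18 null trials per run.  No two successive
non-null trials come from the same event; ordering uses a uniform shuffle
with local repair swaps, bounded at 10,000 reshuffles before raising a
scheduling error.  Null positions are drawn uniformly over the run's 198
slots; since the non-null order is already adjacency-free, insertion
cannot create violations.  We generate presentation orders by constrained
uniform shuffling rather than BOLD-efficiency optimization: ordering
efficiency affects scanner-side power only and none of the statistics
implemented here.  On-screen left/right order at encoding is randomized
per trial and stored but unused downstream.

Timing written to the events TSVs uses the stated trial structure
(encoding: 0.5 s fixation + 6 s stimulus + 0.5 s blank, 10 s break every
18 trials; retrieval: 1 s fixation + up to 6 s + 1 s blank; null trials
6 s).

## Behavioral generator (`loopmem.behavior_sim`)

The generator is a latent all-or-none mixture — the minimal generative
model that produces retrieval dependency.  Per event, H ~ Bernoulli(ρ) of
its cell decides holistic accessibility; each directed test then succeeds
independently with p_hi if H=1 and p_lo otherwise (p_lo ≥ 1/6, the 6-AFC
guessing floor).  Missing responses occur independently per trial with
probability q and are scored incorrect.  Closed forms:

* marginal accuracy: (1−q)(ρ·p_hi + (1−ρ)·p_lo)
* expected dependency: 2ρ(1−ρ)((1−q)Δ)², Δ = p_hi − p_lo.

Defaults (q = 0.035; ρ = 0.5 in every cell) were solved once from these
forms to reproduce cell accuracies of 0.68 / 0.62 / 0.61 / 0.50
(closed-no-delay / open-no-delay / closed-delay / open-delay) with
dependency ≈ 0.04 / 0.02 / 0.06 / 0.01 — accuracy falling with delay,
dependency concentrated in closed loops, and a small open-loop no-delay
component:

| cell             | ρ   | p_hi  | p_lo  |
|------------------|-----|-------|-------|
| closed, no-delay | 0.5 | 0.846 | 0.563 |
| open,  no-delay  | 0.5 | 0.742 | 0.542 |
| closed, delay    | 0.5 | 0.805 | 0.459 |
| open,  delay     | 0.5 | 0.589 | 0.447 |

ρ is exposed per cell so users can emulate any dependency pattern without
committing to a mechanism for it.  Optional beta-distributed ρ across
subjects (`rho_dispersion`, default off) adds between-subject variance.
Response times are lognormal with median 2.86 s for format fidelity only
and never enter any statistic.

What the generator does *not* emulate: encoding/learning dynamics, sleep
consolidation, strategic inference of the untested open-loop pair,
item-level difficulty, or serial-position effects.  Passing tests
therefore certify the statistics' behavior under the assumed all-or-none
structure, not the veracity of that structure in real data.

## Dependency statistic (`loopmem.dependency`)

Observed tables count events by the joint correctness of two directed
tests; independent-model tables use the subject's condition-level mean
accuracy per direction, constant across events (with binary single-trial
outcomes, per-event probabilities are inestimable, so the per-event sums
reduce to N × products of marginals).  Per-table joint proportions are
averaged unweighted.  Closed loops contribute six tables (common-cue and
common-target for each choice of the shared element A); open loops
contribute four — common-cue, common-target, and the two mixed pairings
(A→B with C→A; B→A with A→C) — resolved against each event's own common
element, with B and C ordered canonically (location < person < object).
The statistic's known identities are used as test oracles: exact
factorization under ρ=0, dependency = 2p(1−p) for perfectly tied
all-or-none data, and agreement with a loop-based brute-force
re-implementation on small inputs.

## Behavioral inference (`loopmem.behav_stats`)

The 2×2 within-subject ANOVA is computed through orthogonal paired
contrasts: each 1-df effect is the squared one-sample t of its
per-subject contrast score, with ηp² = F/(F + df_den).  For a 2×2
within design this is identical to the classical repeated-measures
decomposition (asserted against `statsmodels` AnovaRM in the tests) and
exactly auditable.  Bonferroni-adjusted alphas keep full precision
internally; presentation values round half-up to three decimals
(0.05/4 → "0.013", 0.05/3 → "0.017", 0.05/6 → "0.008").  Power for the
one-sample two-tailed t uses the noncentral t distribution
(ncp = d·√n, df = n−1) including the opposite-tail term; the sample-size
routine scans n upward and returns the smallest n meeting the target
(d = 0.62, α = 0.05, power 0.90 → n = 30).

## ROI simulator (`loopmem.roi_sim`)

Per subject and condition: hipp ~ N(μ_h, σ_h²), and
nontarget = α_c + β_c·hipp + u_i + ε with u_i shared across the
subject's two conditions.  The shared random intercept is what makes the
mixed model's participant effect identifiable; condition-specific random
effects are unidentifiable with one observation per subject × condition
and are deliberately not generated.  Defaults (α = 0/0.25,
β = 1.0/0.55 for no-delay/delay, μ_h = 0.2, σ_h = 0.3, σ_u = 0.15,
σ_ε = 0.25) give a strong no-delay coupling (population r ≈ 0.7), a
weaker delay coupling (r ≈ 0.5), and a clearly nonzero delay intercept,
in arbitrary contrast units.  Cue/target channels default to null
coefficients and are configurable.  `compute_contrasts` also supports the
post hoc baseline that contrasts closed no-delay against *open delay* —
useful when the open no-delay condition itself shows holistic retrieval
and is thus a contaminated baseline.

## Coupling model (`loopmem.coupling`)

REML estimation via `statsmodels` MixedLM with a random intercept per
participant.  A stated random effect of "delay per participant" is not
identifiable with two observations per participant, so the intercept-only
structure (equivalently compound symmetry) is the implemented model.
Inference for the six contrasts uses t with df = N_obs − 4; Satterthwaite
or Kenward–Roger corrections are out of scope.  The hippocampal predictor
is uncentered by default (required for the intercept interpretation);
`center_hipp=True` is available for sensitivity analysis and leaves the
slope contrasts unchanged.  Degenerate paths: if the fixed design fits
the response exactly (all noise zero), exact least-squares estimates are
returned with zero SEs and infinite t for nonzero contrasts (REML is
undefined there); `subject_var=0.0` fixes the variance component at zero,
under which the model reduces exactly to OLS — the equivalence the tests
assert.  Boundary variance estimates are floored at zero.

Robustness: for each k, each of the (default 50) iterations removes k
subjects uniformly at random, refits, and compares each contrast's
decision at the decision alpha (default 0.05/6 ≈ 0.008) with the
full-sample decision.  Consistency is reported per contrast, plus a
`joint` row for the all-six-decisions-match criterion, since either
reading of "consistency" may be wanted.

## Pipeline and problem sizes

The pipeline simulates all subjects on one generated schedule; the
dependency and coupling statistics are invariant to per-subject schedule
rerandomization, which is presentation-side counterbalancing.  Every
stage derives its stream from the master seed; identical config + seed
gives byte-identical CSVs.  Test-suite simulation sizes (7,500 null
subjects for calibration, 500 replicate cohorts of 50 for parameter
recovery, 50-subject demo cohorts) were chosen as the smallest sizes at
which the Monte-Carlo tolerances in use are meaningful.

## Known limitations

* The all-or-none mixture is one of many generative models consistent
  with positive dependency; the package measures dependency, it does not
  adjudicate mechanism.
* The independent model uses condition-level marginal accuracies; real
  event-level heterogeneity in difficulty inflates dependency slightly, a
  property of the statistic itself.
* The mixed model assumes homoscedastic residuals across delay
  conditions and linear coupling.
* Guessing-corrected dependency variants are not implemented.
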