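# Methods

This note documents the models behind `triagesim`, the defaults and why
they were chosen, and what the simulator does and does not capture.

## The decision engine

A triage algorithm is a rooted tree.  Each internal node tests one finding
(a boolean, an enumerated token, or an integer in a declared range); each
edge carries a predicate over that finding's domain and leads to a child or
to a leaf triage category; an edge may additionally indicate one life-saving
intervention (bleeding control or oropharyngeal tube).  Because finding
domains are declared in the config header, the loader can *prove* totality:
for every node, the edge predicates must partition the finding's domain
(for integer findings every value in the range is checked to match exactly
one edge).  Cycles, unreachable nodes and dangling references are rejected
at load time, so traversal is guaranteed to terminate at a leaf for every
complete findings map — the engine itself is a pure function.

The shipped `asav.yaml` encodes the ASAV sieve as a START-family tree:
walking test → GREEN; severe bleeding → RED with bleeding control; no
spontaneous breathing → airway opening, then DEAD (still apneic) or RED
with an oropharyngeal tube; respiratory rate ≥ 30/min → RED; absent radial
pulse → RED; impaired consciousness → RED; otherwise YELLOW.  The numeric
cut-offs are the family-standard values; since the engine is data-driven,
a different transcription (or START/mSTART itself) is a config edit, not a
code change.  RED, YELLOW and DEAD patients are tagged with the respective
band color (black for DEAD); GREEN patients are deliberately not tagged.

## Vignette pools

A pool of 40 dummy-description vignettes is generated by rejection
sampling: findings are drawn uniformly over the declared domains (plus
descriptive context — age, sex, pain level — the algorithm never tests)
until the reference tree reproduces a target category drawn from the pool
mix.  Stored ground truths and indicated interventions are therefore
consistent with the engine by construction.  The default mix
(RED 0.35 / YELLOW 0.35 / GREEN 0.25 / DEAD 0.05) over-represents red and
yellow patients, as training collectives do for didactic reasons; the exact
mix is a config choice.  Each assessment session draws 20 vignettes from
the pool uniformly without replacement, in random order.

## Skill dynamics

Every provider has a correct-execution probability for each of eight
checklist skills (categorization, airway indication, bleeding indication,
documentation, labeling, role behavior, communication, algorithm
compliance).  Between training events the probabilities relax toward a
floor,

    p_s(t) = floor + (p_base − floor) · exp(−rate · (t − t_train)),

and a re-training event resets the base to the post-initial level plus
`retrain_gain` (clipped to [floor, 1]).  A single exponential toward a
floor is the most parsimonious form that is monotone, bounded and
re-settable; with only two or three observation times per study no richer
shape is identifiable anyway.

### Categorization errors

A procedure is mis-categorized with probability `1 − p_categorization`:
one error event, localized at a node of the true decision path, where the
leader takes a wrong branch and then follows the algorithm faithfully.
Deviations that coincidentally end at the true category are excluded when a
differing outcome is reachable, so the procedure-level accuracy *equals*
`p_categorization` — the parameter is directly identifiable from observed
accuracy (verified by simulation in the test suite).  Localizing the error
on the path keeps the near-miss structure of real triage errors: most wrong
branches land one urgency step away.  The `under_bias` knob (default 1 =
unbiased) multiplies the weight of wrong branches ending in a *less* urgent
category, reproducing the under-triage excess reported for START-family
algorithms; intervention decisions (airway, bleeding) are separate
Bernoulli draws at their own skill levels, and the remaining checklist
items are Bernoulli draws at theirs.  The "correct labeling" criterion
counts an untagged GREEN patient as correct.

### Times

Triage duration is drawn from a per-category lognormal (defaults: mean
45 s RED, 40 s YELLOW, 20 s GREEN, 15 s DEAD, log-scale σ = 0.35), with
walking time between dummies folded into the draw rather than modeled
separately.  The simulated interventions add zero time by default (they are
just placed on the dummy); `intervention_time_s` makes them costly if
desired.  For reporting, mean times are re-weighted to an idealized
casualty mix of 20% red, 20% yellow, 60% green (dead weight 0), the
consensus distribution for realistic MCI cohorts; the weighted mean's CI is
a delta-method combination of the per-category stratum variances.

## Study simulation

The default study runs three sessions at 0, 14.6 and 25.1 months with a
33-provider roster (qualification mix paramedic/EMT/other ≈ 58/12/30%,
professional/volunteer ≈ 73/27%), Bernoulli retention of 0.667 and 0.864
between sessions (expected 33 → 22 → 19), and a re-training event granted
to third-session attendees immediately before that session.  Teams are
paired at random within each session (an odd provider sits out); each team
triages the same 20 drawn vignettes and swaps roles after ten, so every
paired provider accrues exactly 10 leader and 10 assistant ratings (a
100-point ceiling).  After each session the pass rate (score ≥ 90) is
checked against the 70% early-stopping threshold.  At an individual pass
probability of exactly 0.70 a two-person team retains a qualified member
with probability 1 − 0.3² = 0.91, which is the safety argument behind that
threshold.  The analysis-inclusion rule keeps a triage run only if at least
one team member attended both the baseline and a follow-up; `N1`/`N2`
report the included procedure and provider counts.

### Calibration of the demonstration config

A provider's session score is approximately Binomial(100, p) when all
skills sit at a common level p, so P(score ≥ 90) ≈ 0.9 requires p ≈ 0.93
and ≈ 0.5 requires p ≈ 0.895.  The shipped defaults therefore use
`skill_base_p = 0.93`, `floor = 0.75` and `rate = 0.0148 /month` (the value
that brings p to 0.895 at 14.6 months), with a small re-training gain
(+0.005) and per-provider jitter (sd 0.015).  This produces the
decline-and-recovery shape — pass rate near 0.9 at baseline, near 0.5 at
~15 months, near 0.9 after re-training — end to end through
simulate → evaluate → compare.

## Statistics

Procedure-derived endpoints (accuracy, sensitivity, specificity, the four
error rates, intervention accuracies, times) are compared across sessions
by one-way ANOVA with Bonferroni-adjusted pairwise t tests (raw p × number
of comparisons, capped at 1).  Because procedures are clustered within
providers, the default unit of analysis is the per-provider rate; pooled
procedure-level values can be supplied instead — the package exposes both
because pooled-procedure and provider-averaged estimates genuinely differ
under unequal cluster sizes, and published tables of this kind are often
ambiguous about which was used (their error rates need not sum to 100%
under provider averaging).  Provider-level endpoints use paired tests on
providers matched across the two sessions (unmatched providers are dropped
and counted): paired t for the performance score, Wilcoxon signed-rank for
the binary pass indicator with Pratt handling of zero differences (on a
binary indicator this is effectively a sign test).  Shapiro–Wilk is
available for normality checks.  α = 0.05 throughout.  Degenerate inputs
are flagged, not guessed at: identical paired vectors yield a NaN p value
with a note, zero expected-RED records yield an undefined (NaN)
sensitivity, and an empty score list is an error.

Proportions carry Wilson score 95% CIs (well-behaved near 0 and 1, where
triage accuracies live); means carry t-based CIs.

## Problem sizes

The bundled demonstration study simulates ~660 triage procedures per run
(16 + 11 + 9 teams × 20 vignettes), and the test suite's Monte-Carlo checks
use 1,000 procedures per operating point and 1,000 replicates per
statistical-calibration check — large enough for binomial 95% CIs of ±2–3
percentage points, which is the precision at which the simulated effects
are interpreted.

## What the simulator does not capture

Synthetic providers are exchangeable given their stratum and skill level:
there is no cognitive model of *why* a particular vignette is
mis-triaged, no vignette-difficulty heterogeneity, no learning or fatigue
within a session, no re-test effect across sessions, and no team-dynamics
beyond the checklist booleans (the two human raters of a real study are
collapsed into one consensus rating).  Passing tests therefore demonstrate
that the pipeline's estimators and tests behave correctly under a known
generative model — not that real triage skills decay at the default rate.
Secondary triage, treatment beyond the two simulated interventions and
pediatric algorithm variants are out of scope.
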