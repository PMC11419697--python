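# Methods

This note documents the models and procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
study design does and does not establish about real data.

## Maze geometries and task rules

Each maze has four reward locations (arm ends, ids 1–4) and is represented
purely combinatorially: a map from ordered location pairs to egocentric
action strings over {L, S, R}, one character per intersection traversed.
Every map satisfies a mirror constraint — retracing a path reverses the
action string and swaps L↔R — which the `MazeSpec` validator enforces, and
which is used to complete the full 4-end maps from the rewarded-path
fragments that are pinned down by the tasks.

* **Plus maze.** One four-way intersection; every transition is a single
  action.  Arm 3 is placed opposite arm 1 (so 1↔3 is S), arm 2 on the
  left-turn side of 1 and arm 4 on the right (the L/R assignment of the
  1↔2 leg is a convention; only the mirror-symmetric action multiset is
  geometrically determined).  The rewarded cycle 1→2→1→3→1 executes the
  multiset {L, R, S, S}.
* **H and 2T mazes.** Topologically both are the same tree — two
  three-way junctions joined by a central segment — but geometrically
  distinct, which changes the action strings.  Rewarded ends are labelled 3
  and 4.  On H the rewarded cycle is {R, R, L, L} (cross the crossbar with
  two same-direction turns); on 2T it is {S, R, L, S} (one straight run plus
  a stem).  Same-junction transitions take one action; cross-junction
  transitions take two.  Published descriptions of these tasks disagree
  internally about which direction is "left" on these paths, so only the
  multisets are treated as authoritative and the wiring is configurable.

**Reward automata.**  The plus-maze controller tracks the most recently
visited outer arm (`last_outer` ∈ {2, 3}) and whether the animal must next
return home (`need_home`).  Visiting 1 is rewarded whenever a return home is
due; visiting an outer arm is rewarded only when departing home for the
not-previously-visited outer arm.  Arm 4 is inert: never rewarded, never
advances the controller.  An out-of-sequence outer visit is not rewarded but
*does* update `last_outer` — the animal has now "previously visited" that
arm — without advancing the repeating 1-2-1-3 sequence.  H/2T use plain
two-end alternation with the non-rewarded ends inert.  Sessions start at a
uniformly random phase of the reward sequence (4 phases on the plus maze,
2 on H/2T), mirroring the control program's random initialization.

## Behavior encoding

First-order behavior is the visit sequence; second-order behavior the
flattened action sequence (on H/2T a single transition contributes two
actions, and third-order pairs are taken over the flattened sequence,
including the within-transition pair); third-order behavior classifies each
consecutive action pair as repeat-turn (LL, RR), repeat-straight (SS),
turn↔turn (LR, RL) or turn↔straight (LS, SL, RS, SR) — a partition, so the
four proportions sum to one.

Analysis windows ("first 30 trials", "first 50 trials") count *visits*, not
actions.  When a window spans sessions, each session is encoded separately
and the action traces concatenated: the pair spanning a session boundary is
not a real transition (the animal is carried off the maze between sessions)
and encoding it was found to visibly distort fitted timescales.

Two turn/straight statistics coexist and must not be conflated: the
*proportion* of turn↔straight pairs among all pairs (4/9 for uniform
actions), and the *conditional* probability of a turn given the previous
action was straight (2/3 for uniform actions).  The mixture model predicts
the conditional statistic; group comparisons of session behavior use the
proportion.

## Sequence probabilities

For each animal the probability of every action sequence of length 1–3
(3 + 9 + 27 = 39 entries) is the count of that sequence among overlapping
windows of its length divided by the number of such windows.  Overlapping
windows maximize the information in 30-trial traces.  Because the window
denominators differ across lengths, P(prefix) ≥ P(extension) holds exactly
only at the count level; probabilities obey the denominator-corrected bound
P(s[:-1]) ≥ P(s)·(n−k+1)/(n−k+2) and dendrogram edge weights
P(child)/P(parent) can marginally exceed 1 near the end of a short trace.

PCA is applied to mean-centered rows without variance scaling (all entries
are probabilities, sharing units); all components are retained, so pairwise
cosine similarity over component scores equals cosine similarity of the
centered probability vectors.  Cosine similarity is computed for all animal
pairs and split into within-group (both same-group kinds pooled) and
across-group samples.  Group tests are two-sided Wilcoxon rank-sum
(`scipy.stats.mannwhitneyu`) with Benjamini–Hochberg correction applied
across the comparison family of one analysis (e.g. all sessions of one
panel).

## The modified ddCRP choice model

The model and its interpretation are described in the README.  Numerical
and structural choices:

* **First trial.**  G_1 has no anchor action, so the first choice is
  uniform and the history sum empty.
* **Early contexts.**  m_d(i, j) requires d preceding actions at both
  trials; when either is unavailable the context counts as mismatching
  (an undefined context must not confer context-match weight).
* **Base-measure normalization.**  G_i is normalized (β/(β+2) on the
  previous action, 1/(β+2) elsewhere) before multiplying by α, making α
  comparable across β.
* **Context depth** is fixed at D = 2 by default and configurable.
* **Likelihood.**  The exact sequential product; per-trace context and
  distance matrices are precomputed once, making one likelihood evaluation
  a handful of O(n²) elementwise operations (~0.1 ms at n = 100).
* **Sampler.**  Adaptive random-walk Metropolis in transformed coordinates
  (log τ, logit C_d, log α, log β) with per-dimension scales learned during
  warmup (Robbins–Monro on the acceptance rate toward 0.3 plus a running
  variance estimate), then frozen.  Defaults: 4 chains × 1000 retained
  draws after 1000 warmup steps, independent chains initialized from prior
  draws.  Convergence is assessed with rank-normalized split R̂ (arviz);
  a fit is flagged non-converged above 1.05 (reported, never silently
  ignored).  The posterior median of the pooled draws is the point
  estimate.
* **Reduced-cost fits.**  The parameter-recovery study (2 parameter sets ×
  20 sequences × 10/25/50/100 trials) uses 2 chains × 500 draws per fit so
  the whole study runs in under a minute; single-animal fits elsewhere use
  the full defaults.

Identifiability at 50 trials is limited: C is confounded with a stay-biased
base measure (β > 1 produces action runs, and context-matched past trials
then genuinely predict better even when the generating C is 0), so fitted C
for a low-C repeat-biased animal settles near the prior median rather than
near 0.  τ is prior-dominated below ~50 trials (prior median ≈ 33.6).  These
are properties of the inference problem, not sampler defects; the recovery
suite demonstrates both the prior-dominated regime at 10 trials and the
approach to truth by 100 trials, with the context parameter separating
distinct regimes at the smallest trial count.

## Markov strategy mixture

Second-order chains use add-one regularization,
P(c | b, a) = (N_abc + 1)/Σ_c(N_abc + 1), so all entries are positive.  For
each rat, P_M and P_A are estimated from the morning (session 1) and
afternoon (session 2) sessions of the last five calendar days present in
the Phase-1 log; P_E is flat (1/3 everywhere).  The behavioral-state matrix
uses M→E = A→E = q_E, M→A = A→M = q_S(1−q_E), and E→M = E→A = q_E/2 with
E→E = 1−q_E — the only reading of the exit probabilities that makes the row
stochastic.  The composite 27-state chain over (s, y_{t−1}, y_{t−2}) has
structural zeros wherever the action bookkeeping is inconsistent
(y_{t−1} of the source must equal y_{t−2} of the target).

The stationary distribution is obtained from the null space of (Tᵀ − I)
via SVD, which handles periodic-but-irreducible chains (e.g. q_E = 1,
q_S = 0) exactly; when the null space has dimension > 1 (reducible
boundaries such as q_E = 0) the Cesàro average of power iteration from a
uniform start is returned with a warning.  The sweep grid defaults to
q_E, q_S ∈ {0, 0.05, …, 1}.

## Lapse-error analysis

Error decisions are classified by departure location; a decision enters the
tallies only when the four visits immediately before it were all rewarded
(the lapse definition), so rates are conditional on demonstrated knowledge
of the rule.  Departures from arm 4 are excluded from both error types, but
any unrewarded visit — including a visit to 4 — breaks the run of correct
visits.  The two contexts of each decision type are averaged with equal
weight (each alternation phase is equally likely under the rule); empirical
weighting is available as an option.  For the location-bias model, a
context whose reachable weights are all zero yields NaN with a warning
(e.g. weights [1,0,0,0] leave the reference rate well-defined at 0 while
the alternation rate is undefined).

## Synthetic study design

The generator reproduces the experimental schedule exactly: 19 rats
(10 non-switching, 5 per maze; 9 switching, counterbalanced 5 running
2T-then-H), Phase 1 of up to 10 days × two sessions on H/2T, Phase 2 of
5 days × two sessions on the plus maze with a random rule phase per
session.  40 trials per session is the chosen default — session trial
counts are not published for this class of task; 40 is consistent with a
10-minute session at the training criterion of ~20 rewards per 10 minutes
and places the 30- and 50-trial analysis windows within the first day.
Rewards are always computed by the task automata, so every generated log
replays exactly.

Agent policies define the study conditions:

* **Phase 1** (both groups): a lapse agent with p_lapse = 0.2 and uniform
  location bias over the other arms — ≈80 % performance, matching the
  training criterion.  (Turn-bias lapse sampling is undefined on H/2T,
  where transitions take two actions.)
* **Phase 2, sessions 1–4** (early learning): group-specific ddCRP agents.
  Non-switching: τ = 1.5, C = (0.02, 0.01), α = 3, β = 1.8 — short-memory,
  repeat-biased, context-insensitive.  Switching: τ = 80, C = (0.99, 0.95),
  α = 0.6, β = 0.35 — persistent, strongly context-dependent,
  switch-biased.  One choice process persists per rat across sessions (the
  session break does not erase the animal's history).  These values were
  fixed by a design-time identifiability analysis: the contrasts must be
  recoverable from 50-trial fits at n = 10 vs 9, and C in particular is
  only identifiable when the high-C group also has a small α (history
  dominated) while the low-C group's repetition is carried by the base
  measure.
* **Phase 2, sessions 5–10** (stable performance): group-specific lapse
  agents.  Non-switching: location bias [3, 1, 1, 0] with p_lapse = 0.22 —
  a strong home-arm preference, giving alternation > reference errors.
  Switching: turn bias (0.6, 0.4, 0.0) with p_lapse = 0.13 — giving
  reference > alternation errors.  Overall error rates are comparable
  between groups while the error *types* oppose, the signature contrast of
  the study design.

**What passing tests show — and what they do not.**  The synthetic agents
are stationary within their regime, emit exactly one action per plus-maze
transition, have no timing, position, satiety or learning-curve dynamics,
and switch from "early" to "late" policy at a fixed session.  Tests passing
on these cohorts demonstrate that the pipeline recovers known generative
contrasts at the study's sample sizes — they do not certify that real rats
follow these generative families, only that if comparable effects exist the
pipeline will detect them.

## Determinism and problem sizes

All randomness flows through `numpy.random.Generator` seeded via
`SeedSequence` spawning (per rat, per chain, per stage), so every artifact
is reproducible from a single seed.  The default test suite runs in ~2
minutes on one CPU: Monte-Carlo checks use 2 × 10⁴-trial agents and
2 × 10⁵-step walks; the acceptance suite scales these to 10⁵-trial agents,
a 10⁶-step walk (batch-means standard errors, 1000 batches), the recovery
study above, and one full 19-rat cohort analysis with 4 × 1000-draw fits.

## Known limitations

* The ddCRP fit is per-animal; there is no hierarchical pooling across
  animals and no model comparison.
* q_E and q_S are swept, not fitted by maximum likelihood.
* β is weakly identified whenever α is small (the base measure is rarely
  consulted by the generative process), as the recovery study shows.
* The plus-maze arm layout and the H/2T wiring beyond the rewarded paths
  are conventions; analyses depending only on action multisets and rule
  logic are invariant to them, but raw action traces are not.
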