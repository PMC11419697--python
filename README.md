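# altmaze

Analysis of rodent spatial-alternation choice sequences: how prior training
history shapes the way rats explore and err in a new maze task, inferred
purely from the order of reward-location visits.

The package is built for behavioral researchers who have per-trial visit
logs from continuous alternation tasks (W-track-style rules) and want to go
beyond reward-rate curves: it encodes visits as egocentric actions, compares
action-sequence statistics between experience groups, fits a Bayesian
sequence model of choice, simulates strategy mixtures, and decomposes errors
into working-memory and reference-memory types.  Because such datasets are
rarely public, a first-class synthetic-cohort generator reproduces the whole
study design (19 rats in switching/non-switching groups, two training phases
on H, 2T and plus mazes) with agent policies whose parameters the pipeline
must then recover — every analysis stage is testable end to end.

## What it computes

**Task engines** (`altmaze.mazes`). Three mazes are encoded as maps from
ordered location pairs (1–4) to egocentric action strings over
{L(eft), S(traight), R(ight)}, plus reward-rule automata: the plus-maze
continuous alternation 1, 2, 1, 3, … with a never-rewarded fourth arm, and
two-end alternation on the H and 2T mazes.

**Behavior codec** (`altmaze.codec`). Visit logs → action traces
(second-order behavior) → transition categories between consecutive actions
(third-order behavior: repeat-turn, repeat-straight, turn↔turn,
turn↔straight), with per-session proportions and reward rates.

**Sequence statistics** (`altmaze.seqstats`). For each animal, the
probability of every action sequence of length 1–3 (39 entries) from
overlapping windows; conditional-probability dendrograms (CSV/GraphML);
PCA embedding of the animals × sequences matrix; within- vs across-group
pairwise cosine similarity; Wilcoxon rank-sum tests with Benjamini–Hochberg
correction.

**Choice model** (`altmaze.ddcrp`). A modified sequential distance-dependent
Chinese restaurant process.  The probability of action A on trial i is

    p(y_i = A | y_1..y_{i-1}) ∝ α·G_i(A) + Σ_{j<i, y_j=A} f(i, j)
    f(i, j) = exp(−|i−j|/τ) · Π_{d=1,2} (1 − C_d)^{m_d(i,j)}

where m_d(i,j) = 0 iff trials i and j share the same depth-d action context,
and the base measure G_i puts weight β on repeating the previous action.
τ > 0 is the influence timescale of past trials, C_d ∈ [0,1] the context
dependence, α > 0 the concentration toward the base measure, and β > 0 a
stay/switch bias.  With C_d = 0 and τ → ∞ the model reduces to the standard
CRP.  Fitting is Bayesian (priors τ ~ Gamma(2, 20), C_d ~ U(0,1),
α ~ Gamma(2, 2), β ~ Gamma(20, 1/20); shape/scale) by adaptive random-walk
Metropolis MCMC, 4 chains × 1000 draws, rank-normalized split R̂
diagnostics, posterior-median point estimates.  `DistanceDependentCRP` is a
scikit-learn-style estimator.

**Strategy simulator** (`altmaze.markov`). Second-order Markov chains
P(y_t | y_{t−1}, y_{t−2}) with add-one regularization estimated from each
rat's late Phase-1 sessions (morning chain P_M, afternoon chain P_A, flat
exploration chain P_E), composed with a latent behavioral state s ∈ {M, A, E}
switching with rates q_S (between task models) and q_E (to exploration).
The 27-state composite chain's steady state π yields analytic statistics
such as P(turn | previous action straight), swept over a (q_E, q_S) grid
against observed behavior.

**Error analysis** (`altmaze.lapse`). Plus-maze errors split by departure
location: alternation errors (departing Location 1; working memory) vs
reference-location errors (departing 2 or 3; reference memory), counted only
as lapses — the first error after four consecutive correct visits.  Two
analytic lapse strategies give closed-form conditional error rates: a
turn-bias lapse with the plus/2T ideal action probabilities
(0.25, 0.5, 0.25) yields 5/8 for both error types; with the H-maze ideal
probabilities (0.5, 0, 0.5) both become 3/4; a location-bias lapse with
weights [2, 1, 1, 0] yields 1/2 (alternation) vs 1/3 (reference).

## Worked example

```python
import numpy as np
from altmaze import (
    CohortConfig, generate_cohort, encode_actions, PLUS_MAZE,
    DistanceDependentCRP, turn_bias_lapse_rates, location_bias_lapse_rates,
)
from altmaze.codec import turn_straight_proportion, encode_first_n

# analytic lapse-error rates
print(turn_bias_lapse_rates((0.25, 0.5, 0.25)))   # (0.625, 0.625)
print(location_bias_lapse_rates((2, 1, 1, 0)))    # (0.5, 0.33333333333333337)

# synthetic cohort, one switching-group rat's early plus-maze behavior
logs = generate_cohort(CohortConfig(seed=0))
rat = [l for l in logs if l.rat_id == "SW01" and l.phase == 2]
rat.sort(key=lambda l: (l.day, l.session))
trace = encode_first_n(rat, PLUS_MAZE, 50)
print(turn_straight_proportion(trace))            # 0.723404255319149

est = DistanceDependentCRP(seed=0).fit(trace)
print({k: round(v, 2) for k, v in est.params_.as_dict().items()})
# {'tau': 48.6, 'alpha': 1.3, 'beta': 0.86, 'C1': 0.92, 'C2': 0.69}
print(max(est.rhat_.values()) < 1.05)             # True
```

The fitted parameters recover this rat's generating regime: a long influence
timescale τ, strong context dependence C, and a switch-biased base measure
(β < 1) — the signature the switching-experience group carries in the
synthetic study design, in contrast to non-switching rats (short τ, small C,
β > 1).

The same stages are available from the shell:

```bash
altmaze simulate --out results --seed 0
altmaze classify  --input results/visits.csv --out results
altmaze seqstats  --input results/visits.csv --out results
altmaze fit-ddcrp --input results/visits.csv --rat SW01 --first-n 50 --seed 0 --out results
altmaze markov-sim --input results/visits.csv --out results
altmaze errors    --input results/visits.csv --last-sessions 5 --out results
altmaze run-all   --out results --seed 0
```

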