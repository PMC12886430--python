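# Methods

## The model

The simulator couples two random objects: an environment `R` that emits
vector-valued stimuli in sequences, and an agent memory `M` that stores
classified stimuli. The distance between them is the entropy metric
(variation of information)

    D_H(R, M) = H(R|M) + H(M|R) = H(R, M) − I(R; M),

measured in bits throughout (log base 2, with the 0·log 0 = 0 convention).
The two conditional-entropy terms are read as the agent's *surprise* (how
uncertain the next stimulus is given what memory predicts) and
*uncertainty* (how uncertain the memorized continuation is given the
current stimulus). Two routes shrink the distance: learning (move `M`
toward `R`) or constraining the environment to what is already memorized
(move `R` toward `M`). The second route, made operational as the
`constrain` policy, is the model's reading of insistence on sameness; the
package exists to make that contrast, and its consequences, simulatable
and measurable.

### Memory

Memory is an append-only directed graph. Items hold a prototype vector and
an observation count; edges hold transition counts; a registry stores every
traversed item-id sequence (repeated traversals appear as repeated entries,
so registry multiplicity doubles as a sequence count). There is no
forgetting, no decay, and no abstraction over items — each stimulus is a
raw snapshot and classification is pure nearest neighbour: the closest
stored prototype is always returned, however far away, and the stimulus
counts as *new* when that distance exceeds the novelty radius ε. Ties are
broken by lowest item id so every run is reproducible.

Prediction conditions on the running context of classified items.
`option_set` matches the trailing context as a contiguous subsequence of
the registry; in the default full-suffix mode the longest suffix with at
least one registered continuation wins, so whole-sequence structure
dominates (a depth-1 mode gives the Markov contrast). The per-step
quantities are:

* predictive uncertainty — entropy of the option set; a new stimulus, or a
  context with no registered continuation, carries no information and falls
  back to the full memory entropy H(M) (count-weighted by default; a
  uniform weighting is available since the intended weighting of H(M) is
  genuinely open);
* perceptual surprise (set-entropy form) — option-set entropy mixed with a
  novelty prior λ that is assigned a configured `baseline_bits` proxy for
  H(R); the agent cannot know the true stimulus entropy, so the baseline
  defaults to log2 of the expected environment alphabet size;
* realized surprisal — −log2 of the smoothed probability assigned to the
  item that actually arrived. Registered continuations share mass
  1 − ν_mass in proportion to counts; the reserved novelty mass ν_mass is
  split over every unseen slot (memorized items not among the
  continuations, plus one slot for a genuinely novel item). This keeps the
  score finite everywhere: a unique memorized continuation costs
  −log2(1 − ν_mass) ≈ 0.0014 bits at the default ν_mass = 2⁻¹⁰, an unseen
  continuation costs −log2(ν_mass / n_slots).

*Disappointment* is the whole-sequence version of the same check: condition
on the entire current-sequence context and flag the step when the memory
registers continuations for that full prefix but the observed item is not
among them.

### Environment

Environments are directed graphs of emitting states built from a
declarative spec: `n_sequences` chains of `seq_length` states, splitting at
`branch_positions` into `branch_arity` sub-chains, prototypes drawn by
rejection sampling until all pairwise distances exceed
`prototype_min_separation`. Emission adds isotropic Gaussian white noise of
sd σ (optionally norm-clipped, which is how the sub-radius noise-invariance
property is made exact rather than probabilistic). Novelty injection
emits, at rate λ_new, a brand-new prototype respecting the separation
margin — novelty is therefore never ambiguous — and by default the new
state persists in the graph (a transient mode is available; which of the
two a real environment resembles is situation-dependent, so both exist
behind a flag). The deprivation environment has no prototypes at all:
emissions are pure endogenous noise, so at ordinary ε every percept is new.

Three transforms encode uncertainty-reducing countermeasures:

* `transform_amulets` appends one indicator coordinate per sequence path,
  duplicating shared states, so formerly identical activities become
  perceptually distinct chains and memorized branch uncertainty drops to 0;
* `transform_branch_to_start` rotates each path at its first branch state
  so the distinguishing segment is experienced first: the choice collapses
  into the start-state draw and the within-sequence remainder is
  deterministic (with several branch positions only the first is rotated —
  a deliberate simplification);
* `transform_limit_options` prunes lowest-probability branch successors to
  at most ν_max and renormalizes, lowering a balanced memorized branch from
  log2 ν to log2 ν_max bits.

### Processing loop

Each step: the environment advances and emits; the agent scores surprise
(per its event rule), classifies, scores uncertainty, samples thresholds
T_so and T_a, and records `overload` iff surprise > T_so and `anxiety` iff
uncertainty > T_a — the trace stores measures and sampled thresholds so
every event flag is re-derivable. Thresholds are random variables
(lognormal by default: strictly positive, time-varying, individual;
`constant` is the degenerate family), sampled per step or per episode.

The event rule defaults to the realized surprisal because thresholds are
compared against each incoming stimulus; the set-entropy rule is the purely
distributional reading and is the one under which a fully memorized
deterministic chain scores an exact 0.0 at every interior step (the
surprisal reading leaves the −log2(1 − ν_mass) smoothing residue). Both
rules are first-class config options.

Policies: `learn` inserts every observation; `passive` only records;
`constrain` rejects a novel percept (logged as `rejection`) and redraws the
environment step restricted to states whose prototypes classify as known —
the minimal mechanism for holding `R` inside `M`. If the constrained draw
is infeasible the agent falls back to an unconstrained restart. An episode
break is detected when a known item arrives while the current context has
no registered continuation; the context (and, when learning, the registry
sequence) then restarts, which keeps registered sequences whole. A novel
first item of an unseen sequence is chained to the previous sequence —
a known mis-structuring we accept to keep the boundary rule observation-only.

Self-stimulation, when enabled, fires when the ambient percept is novel
and its prospective surprisal exceeds min(T_so, floor). The agent then
substitutes the prototype of its favourite memorized item (self-loop items
preferred, then highest count). Because the agent generated the stimulus
itself it is fully self-predicted: the step's surprise is
−log2(1 − ν_mass) ≈ 0 (0 exactly under the set-entropy rule) and
uncertainty is computed on the substituted percept. Under deprivation this
replaces near-certain overload events, which is precisely the
comfort-zone-preserving role conjectured for stimming.

### Therapy planner

The curriculum problem is: given the current memory, choose what to present
next to maximize I(R;M) while keeping predicted surprise and uncertainty
below the thresholds. Since the thresholds are latent random variables they
are first estimated from traces: each step is current-status data (the
event flag says whether that step's threshold draw was below the measure),
so P(event | measure) is the threshold CDF, fitted by isotonic regression
and inverted at a quantile q (default 0.1, conservative). A channel that
never produced an event returns max observed measure + 1 bit, flagged
censored.

The planner is greedy over a finite candidate set of *complete* environment
sequences (fragments read as new and are disallowed). Per candidate it
simulates the presentation on a copy of the memory with exactly the agent's
measure code — so predicted and realized per-step measures agree — and
takes the max over steps as the constraint reading (the constraints are
per-step, the objective stationary; max-over-steps is the conservative
resolution). Feasible candidates are ranked by MI gain, estimated as the
difference of I(R;M) on matched-seed rollouts before and after
hypothetically learning the candidate; matched seeds cancel most rollout
noise, making gains non-negative up to ~0.05 bits. The chosen candidate is
learned into the simulated memory and the loop repeats until gains fall
below a floor (default 0.01 bits) or nothing is feasible. Because measures
below the q-quantile estimate cross a threshold draw with probability ≤ q,
the realized event rate during a planned presentation stays near q.
Option-capping (ν_max) is applied as the limit-options transform before
planning; a round-0 dead end may, if permitted, trigger the
branch-to-start rewrite to unlock an entry point. The other guidelines are
structural: the environment simply has no symbolic or abstract channel.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| novelty radius ε | 0.5 | stimulus distance | operational known/new test; presets use separation 2.0 > 2ε so classification is noise-proof |
| `baseline_bits` | 3.0 | bits | H(R) proxy for the novel-case fallback, log2 of a nominal 8-state alphabet |
| `novelty_mass` ν_mass | 2⁻¹⁰ | probability | smoothing reserve; keeps surprisal finite while leaving known continuations ≈ exact |
| `novelty_prior` λ | 0.0 | probability | set-entropy mixture weight on the baseline; 0 recovers the pure case analysis |
| threshold medians / sigmas | 4.0 / 0.5 | bits / log-sd | lognormal keeps T > 0; medians sit between memorized (≈0) and novel (≈baseline+) measures so both event regimes occur |
| planner quantile q | 0.1 | — | probability budget for threshold crossings during therapy |
| MI rollout steps | 200 | steps | plug-in MI estimate; paired seeds make differences stable at this size |

Therapy scenarios use a larger ν_mass (0.25) and higher threshold medians
(12 bits): with the tiny default mass a never-seen continuation costs
≈ 10 + log2(n_slots) bits, which no plausible threshold admits, i.e. the
default agent cannot safely be taught anything new — an interpretable but
degenerate regime for a curriculum study.

## What the synthetic data does and does not emulate

The generator reproduces the structures the framework assumes:
deterministic chains, ν-way branch points, white-noise perturbation,
unambiguous novelty injection, and sensory deprivation. It does not emulate
naturalistic sensory streams (no temporal correlation inside a stimulus, no
overlapping or hierarchical features, prototypes are well separated by
construction), threshold dynamics driven by physiology, or any semantics.
Passing tests therefore show that the mechanisms behave as the theory
predicts under the theory's own assumptions — not that real behavioral
data would follow, which would require the validation pathways (clinical
or digital-twin inspection by experts) that are out of scope here.

## Numerical choices

Exact identities are asserted at 1e-12 (entropy closed forms, oracle
agreement) or 1e-9 (metric identity on random joints); sampling-based
checks carry explicit tolerances (0.05 bits for empirical D_H at n≈4000,
0.05 bits for MI-gain noise, 0.2 bits for threshold recovery at n=500).
−0.0 entropies are folded to 0.0 so exact-zero assertions are meaningful.
Classification ties break to the lowest item id; branch-prune ties to the
lowest state id. Empty distributions are a legal sentinel (entropy 0) for
"no registered continuation"; an empty memory has H(M) = 0 with a warning.
All stochastic behavior flows from explicit integer seeds through
`numpy.random.Generator`; emission noise can be driven by a separate seed
so noise invariance is checkable bit-for-bit. Problem sizes in the test
and acceptance runs (chains of length 5–8, 2–4 sequences, episodes of
150–500 steps, 20 matched replicates) are the smallest at which every
contrast of interest is strict and stable.

## Known limitations

* The H(R) baseline is a configured constant, not an estimate; agents in
  richer environments than their baseline assumes will under-score novelty.
* Sequence-boundary detection is heuristic (known item + dead context); a
  novel sequence head is chained to the previous sequence once.
* `transform_branch_to_start` reorders activities; whether that is
  admissible for a given real activity sequence is a modelling judgement,
  and only the first branch per path is relocated.
* The planner is greedy; on candidate sets with strong ordering
  interactions it can be suboptimal (the test suite logs its ratio to the
  exhaustive-permutation optimum on small instances).
* MI and D_H estimates are plug-in values on visited supports and biased
  upward on short rollouts; Miller–Madow correction is available for
  entropies but not applied by default.
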