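# sameness

An agent-based simulator for studying **insistence on sameness** as
entropy-distance minimization. An agent with a sequence-graph memory `M`
processes stimuli from a branching environment `R` through a
perception → classification → prediction loop, tracking *surprise*
H(R|M=m) and *uncertainty* H(M|R=r) — the two halves of the entropy metric

    D_H(R, M) = H(R|M) + H(M|R) = H(R, M) − I(R; M)   [bits]

When either measure exceeds its stochastic threshold (T_so, T_a), a
*sensory overload* or *anxiety* event fires. The distance can be reduced by
**learning** (storing stimuli and their sequences in memory) or by
**constraining** the environment to what is already memorized — the second
strategy is the model's operationalization of insistence on sameness, and
the simulator lets you measure how it emerges and what it trades away.
A therapy planner closes the loop: it schedules complete stimulus
sequences to maximize I(R;M) while keeping predicted surprise and
uncertainty below estimated thresholds.

Intended users: computational-psychiatry and cognitive-modelling
researchers who want a reproducible sandbox for entropy-based accounts of
rigidity, overload, self-stimulation and curriculum design.

## The pieces

| module | contents |
|---|---|
| `sameness.information` | finite/joint distributions; entropy, conditional entropy, D_H, mutual information; plug-in estimators |
| `sameness.memory` | append-only prototype graph, nearest-neighbour classification, option sets, surprise/uncertainty/disappointment, GraphML + JSON export |
| `sameness.environment` | branching sequence-graph generators, noise and novelty injection, deprivation regime, amulet / branch-to-start / option-limiting transforms, presets |
| `sameness.agent` | the processing loop, threshold models, learn/constrain/passive policies, self-stimulation, behavior summaries, digital-twin comparison |
| `sameness.therapy` | threshold estimation from traces, MI-gain scoring, greedy constrained curriculum planning and execution |
| `sameness.cli` | `sameness simulate / therapy / twin / export-memory / presets` |

## Worked example: does sameness-seeking pay?

Pre-train a memory on a stable two-sequence world, then drop matched
agents into the same world with novel stimuli injected (rate 0.15) and
learning disabled — one agent rejects novelty and redraws from known
states (`constrain`), the other just watches (`passive`):

```python
import sameness as sn

env = sn.generate_environment(sn.preset_spec("nonstationary"))
base = sn.generate_environment(
    sn.preset_spec("nonstationary").model_copy(update={"novelty_rate": 0.0})
)
memory = sn.run_episode(sn.AgentConfig(policy="learn"), base, 200, seed=5).memory

table = sn.twin_compare(
    sn.AgentConfig(policy="constrain"),   # a
    sn.AgentConfig(policy="passive"),     # b
    env, n_steps=150, n_reps=20, seed=0, initial_memory=memory,
)
print(table.round(3).to_string())
```

```
                       mean_a  mean_b  mean_diff  n_pos  n_neg  sign_test_p
metric
overload_rate           0.044   0.228     -0.183      0     20          0.0
anxiety_rate            0.029   0.091     -0.061      0     20          0.0
disappointment_rate     0.005   0.126     -0.121      0     20          0.0
rejection_rate          0.166   0.000      0.166     20      0          0.0
self_stim_rate          0.000   0.000      0.000      0      0          1.0
route_diversity_bits    3.558   4.316     -0.758      0     20          0.0
mean_surprise_bits      0.504   2.767     -2.262      0     20          0.0
mean_uncertainty_bits   0.362   0.827     -0.466      0     20          0.0
comfort_zone            0.926   0.746      0.180     20      0          0.0
entropy_distance_bits   0.000   0.781     -0.781      0     20          0.0
```

Reading the table: the constraining agent rejects about 17% of steps
(`rejection_rate`, the rigidity proxy) and in exchange cuts overload and
anxiety events several-fold, keeps its empirical entropy distance at
exactly 0 bits while the passive agent's drifts to 0.78, and stays inside
its comfort zone 93% of the time versus 75% — at the cost of a narrower
world (`route_diversity` 3.56 vs 4.32 bits of visited-state entropy).
Sameness-seeking is, in this model, a rational response to fixed memory
and finite thresholds.

The same experiment from the shell:

```sh
sameness twin -c config.yaml -o out/   # config: agent/agent_b + nonstationary preset
```

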