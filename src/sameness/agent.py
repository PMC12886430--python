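"""The stimuli-processing loop: perception, classification, prediction, events.

Each step the environment emits a stimulus; the agent scores its
*surprise* (perception), classifies the stimulus against memory
(nearest-neighbour), scores its *uncertainty* over memorized continuations
(prediction), compares both against freshly sampled stochastic thresholds
T_so (sensory overload) and T_a (anxiety), and then acts according to its
policy:

* ``learn`` — store the observation in memory (items, edges, sequences);
* ``constrain`` — insistence on sameness: reject novel stimuli and redraw
  the environment step restricted to already-known states;
* ``passive`` — record only.

Self-stimulation, when enabled, replaces a threatening novel percept with a
self-generated known stimulus, keeping the measured surprise near zero —
the mechanism conjectured to hold an agent inside its comfort zone under
sensory deprivation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field
from scipy import stats

from . import memory as mem
from .environment import ConstraintInfeasibleError, EnvironmentModel, step_environment
from .information import (
    empirical_distribution,
    empirical_joint,
    entropy,
    entropy_distance,
)

__all__ = [
    "ThresholdModel",
    "AgentConfig",
    "StepTrace",
    "EpisodeTrace",
    "run_episode",
    "selfstim_stimulus",
    "comfort_zone_occupancy",
    "behavior_summary",
    "twin_compare",
    "SUMMARY_METRICS",
]

_CONTEXT_CAP = 64  # suffix matching never needs more history than this


class ThresholdModel(BaseModel):
    """Stochastic overload/anxiety thresholds.

    Thresholds are random variables: unknown, time-varying and individual.
    The lognormal family keeps them strictly positive; ``*_sigma = 0`` (or
    family ``constant``) makes them deterministic. Units are bits; medians
    are on the bit scale.
    """

    model_config = ConfigDict(extra="forbid")

    family: Literal["lognormal", "constant"] = "lognormal"
    so_median: float = Field(4.0, gt=0)
    so_sigma: float = Field(0.5, ge=0)
    a_median: float = Field(4.0, gt=0)
    a_sigma: float = Field(0.5, ge=0)
    sampling_schedule: Literal["per_step", "per_episode"] = "per_step"

    def sample(self, rng: np.random.Generator) -> tuple[float, float]:
        z1, z2 = rng.normal(size=2)
        if self.family == "constant":
            return self.so_median, self.a_median
        return (
            self.so_median * math.exp(self.so_sigma * z1),
            self.a_median * math.exp(self.a_sigma * z2),
        )


class AgentConfig(BaseModel):
    """Full configuration of one simulated agent."""

    model_config = ConfigDict(extra="forbid")

    policy: Literal["learn", "constrain", "passive"] = "learn"
    novelty_radius: float = Field(0.5, gt=0)
    context_depth: Optional[int] = Field(None, ge=1)  # None = full-suffix matching
    baseline_bits: float = Field(3.0, ge=0)
    novelty_mass: float = Field(2.0 ** -10, gt=0, lt=1)
    novelty_prior: float = Field(0.0, ge=0, le=1)
    event_rule: Literal["set_entropy", "realized_surprisal"] = "realized_surprisal"
    selfstim_enabled: bool = False
    selfstim_floor_bits: float = Field(1.0, ge=0)
    thresholds: ThresholdModel = Field(default_factory=ThresholdModel)


@dataclass(frozen=True)
class StepTrace:
    """Per-step record: measures, sampled thresholds, and triggered events."""

    step: int
    env_state: int
    item_id: Optional[int]
    is_new: bool
    surprise_bits: float
    uncertainty_bits: float
    t_so: float
    t_a: float
    events: tuple[str, ...]


@dataclass
class EpisodeTrace:
    """An episode's ordered step records plus the final memory state."""

    steps: list[StepTrace]
    config: AgentConfig
    env_hash: str
    memory: mem.MemoryGraph
    seed: int

    def __len__(self) -> int:
        return len(self.steps)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": [s.step for s in self.steps],
                "env_state": [s.env_state for s in self.steps],
                "item_id": [s.item_id for s in self.steps],
                "is_new": [s.is_new for s in self.steps],
                "surprise_bits": [s.surprise_bits for s in self.steps],
                "uncertainty_bits": [s.uncertainty_bits for s in self.steps],
                "t_so": [s.t_so for s in self.steps],
                "t_a": [s.t_a for s in self.steps],
                "events": ["|".join(s.events) for s in self.steps],
            }
        )


def selfstim_stimulus(g: mem.MemoryGraph) -> tuple[int, np.ndarray]:
    """The agent's self-generated stimulus: its favourite memorized item.

    Items with a self-loop edge (directly repeatable) are preferred; among
    candidates the most frequently observed wins, ties broken by lowest id.
    """
    if g.is_empty:
        raise ValueError("cannot self-stimulate with an empty memory")
    loopable = [i for i in g.items if (i, i) in g.edges]
    pool = loopable if loopable else list(g.items)
    best = min(pool, key=lambda i: (-g.items[i].count, i))
    return best, g.items[best].prototype.copy()


def _measures(
    g: mem.MemoryGraph,
    config: AgentConfig,
    context: list[int],
    cls: mem.ClassificationResult,
) -> tuple[float, float]:
    """(surprise, uncertainty) for an observed stimulus in a context."""
    if config.event_rule == "set_entropy":
        surprise = mem.perceptual_surprise(
            g, context, config.context_depth, config.baseline_bits, config.novelty_prior
        )
    else:
        surprise = mem.surprisal_of(
            g, context, cls, config.context_depth, config.baseline_bits, config.novelty_mass
        )
    pred_context = context + [cls.item_id] if not cls.is_new else list(context)
    uncertainty = mem.predictive_uncertainty(g, cls, pred_context, config.context_depth)
    return surprise, uncertainty


def run_episode(
    config: AgentConfig,
    env: EnvironmentModel,
    n_steps: int,
    seed: int,
    initial_memory: Optional[mem.MemoryGraph] = None,
    noise_seed: Optional[int] = None,
) -> EpisodeTrace:
    """Run the processing loop for ``n_steps`` against a copy of ``env``.

    All stochastic behavior is a pure function of ``seed`` (and the optional
    ``noise_seed``, which drives emission noise only — vary it to check that
    sub-radius perturbations leave every downstream value unchanged while
    transitions and thresholds stay fixed). The passed environment and
    initial memory are never mutated.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    env = env.copy()
    g = initial_memory.copy() if initial_memory is not None else mem.MemoryGraph(env.dim)
    if g.dim is not None and g.dim != env.dim:
        raise ValueError(f"memory dim {g.dim} != environment dim {env.dim}")

    ss = np.random.SeedSequence(seed)
    kids = ss.spawn(3)
    trans_rng = np.random.default_rng(kids[0])
    thresh_rng = np.random.default_rng(kids[1])
    noise_rng = np.random.default_rng(kids[2] if noise_seed is None else noise_seed)

    known_cache: dict[int, bool] = {}

    def state_is_known(sid: int) -> bool:
        if sid not in known_cache:
            if g.is_empty:
                known_cache[sid] = False
            else:
                res = mem.classify(g, env.states[sid], config.novelty_radius)
                known_cache[sid] = not res.is_new
        return known_cache[sid]

    steps: list[StepTrace] = []
    context: list[int] = []
    cur_state: Optional[int] = None
    t_so = t_a = None
    if config.thresholds.sampling_schedule == "per_episode":
        t_so, t_a = config.thresholds.sample(thresh_rng)

    for n in range(n_steps):
        if config.thresholds.sampling_schedule == "per_step":
            t_so, t_a = config.thresholds.sample(thresh_rng)
        events: list[str] = []

        state, stimulus = step_environment(env, cur_state, trans_rng, noise_rng=noise_rng)
        cls = mem.classify(g, stimulus, config.novelty_radius)

        # -- constrain policy: reject novelty, redraw inside known territory
        if config.policy == "constrain" and cls.is_new:
            events.append("rejection")
            known = {s for s in env.states if state_is_known(s)}
            try:
                state, stimulus = step_environment(
                    env, cur_state, trans_rng, constrain_to=known, noise_rng=noise_rng
                )
            except ConstraintInfeasibleError:
                state, stimulus = step_environment(
                    env, None, trans_rng, noise_rng=noise_rng
                )
            cls = mem.classify(g, stimulus, config.novelty_radius)

        # -- self-stimulation: displace a threatening novel percept
        selfstim = False
        if config.selfstim_enabled and cls.is_new and not g.is_empty:
            prospective = mem.surprisal_of(
                g, context, cls, config.context_depth,
                config.baseline_bits, config.novelty_mass,
            )
            if prospective > min(t_so, config.selfstim_floor_bits):
                _, stimulus = selfstim_stimulus(g)
                cls = mem.classify(g, stimulus, config.novelty_radius)
                selfstim = True
                events.append("self_stim")

        if selfstim:
            # the agent generated the stimulus itself, so it is fully predicted
            surprise = (
                -math.log2(1.0 - config.novelty_mass)
                if config.event_rule == "realized_surprisal"
                else 0.0
            )
            pred_context = context + [cls.item_id]
            uncertainty = mem.predictive_uncertainty(
                g, cls, pred_context, config.context_depth
            )
        else:
            surprise, uncertainty = _measures(g, config, context, cls)

        if context and not g.is_empty and not selfstim:
            dis_flag, _ = mem.disappointment(g, context, cls, config.novelty_mass)
            if dis_flag:
                events.append("disappointment")

        if surprise > t_so:
            events.append("overload")
        if uncertainty > t_a:
            events.append("anxiety")

        # -- memory / context update
        boundary = (
            (not cls.is_new)
            and bool(context)
            and mem.option_set(g, context, config.context_depth).is_empty
        )
        if config.policy == "learn":
            prev = None if (boundary or not context) else context[-1]
            item_id = mem.insert_observation(g, prev, stimulus, config.novelty_radius)
            context = [item_id] if (boundary or not context) else context + [item_id]
        else:
            if cls.is_new:
                context = []
            elif boundary:
                context = [cls.item_id]
            else:
                context = context + [cls.item_id]
        context = context[-_CONTEXT_CAP:]

        steps.append(
            StepTrace(
                step=n,
                env_state=state,
                item_id=cls.item_id,
                is_new=cls.is_new,
                surprise_bits=surprise,
                uncertainty_bits=uncertainty,
                t_so=t_so,
                t_a=t_a,
                events=tuple(events),
            )
        )
        cur_state = state

    return EpisodeTrace(
        steps=steps, config=config, env_hash=env.content_hash(), memory=g, seed=seed
    )


def comfort_zone_occupancy(trace: EpisodeTrace) -> float:
    """Fraction of steps with both measures below their sampled thresholds."""
    if not trace.steps:
        raise ValueError("empty trace")
    bad = sum(
        1 for s in trace.steps if "overload" in s.events or "anxiety" in s.events
    )
    return 1.0 - bad / len(trace.steps)


SUMMARY_METRICS = [
    "overload_rate",
    "anxiety_rate",
    "disappointment_rate",
    "rejection_rate",
    "self_stim_rate",
    "route_diversity_bits",
    "mean_surprise_bits",
    "mean_uncertainty_bits",
    "comfort_zone",
    "entropy_distance_bits",
]


def behavior_summary(trace: EpisodeTrace) -> dict[str, float]:
    """Per-episode behavioral metrics.

    Event rates proxy the clinical observables (rejection rate for rigidity,
    route diversity for vigilance/pedantry); the final entropy-distance
    estimate comes from the empirical joint of (environment state,
    classified memory item) over the whole episode.
    """
    if not trace.steps:
        raise ValueError("empty trace")
    n = len(trace.steps)

    def rate(name: str) -> float:
        return sum(1 for s in trace.steps if name in s.events) / n

    pairs = [
        (s.env_state, s.item_id if s.item_id is not None else "none")
        for s in trace.steps
    ]
    return {
        "overload_rate": rate("overload"),
        "anxiety_rate": rate("anxiety"),
        "disappointment_rate": rate("disappointment"),
        "rejection_rate": rate("rejection"),
        "self_stim_rate": rate("self_stim"),
        "route_diversity_bits": entropy(
            empirical_distribution([s.env_state for s in trace.steps])
        ),
        "mean_surprise_bits": float(np.mean([s.surprise_bits for s in trace.steps])),
        "mean_uncertainty_bits": float(
            np.mean([s.uncertainty_bits for s in trace.steps])
        ),
        "comfort_zone": comfort_zone_occupancy(trace),
        "entropy_distance_bits": entropy_distance(empirical_joint(pairs)),
    }


def twin_compare(
    config_a: AgentConfig,
    config_b: AgentConfig,
    env: EnvironmentModel,
    n_steps: int,
    n_reps: int,
    seed: int,
    initial_memory: Optional[mem.MemoryGraph] = None,
) -> pd.DataFrame:
    """Matched-seed digital-twin comparison of two agent configurations.

    Runs ``n_reps`` episode pairs with identical seeds and environments and
    tabulates per-metric means, mean differences (a - b) and a paired
    sign-test p-value — the inspection surface for Turing-test-like
    validation of simulated behavior.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rows_a, rows_b = [], []
    for rep in range(n_reps):
        rep_seed = seed + rep
        ta = run_episode(config_a, env, n_steps, rep_seed, initial_memory)
        tb = run_episode(config_b, env, n_steps, rep_seed, initial_memory)
        rows_a.append(behavior_summary(ta))
        rows_b.append(behavior_summary(tb))
    fa = pd.DataFrame(rows_a)
    fb = pd.DataFrame(rows_b)
    out = []
    for metric in SUMMARY_METRICS:
        diff = fa[metric] - fb[metric]
        n_pos = int((diff > 0).sum())
        n_neg = int((diff < 0).sum())
        if n_pos + n_neg > 0:
            p = stats.binomtest(n_pos, n_pos + n_neg, 0.5).pvalue
        else:
            p = 1.0
        out.append(
            {
                "metric": metric,
                "mean_a": fa[metric].mean(),
                "mean_b": fb[metric].mean(),
                "mean_diff": diff.mean(),
                "n_pos": n_pos,
                "n_neg": n_neg,
                "sign_test_p": p,
            }
        )
    return pd.DataFrame(out).set_index("metric")
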