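"""Curriculum planning as constrained mutual-information maximization.

A learning therapy presents new stimulus sequences so as to maximize the
mutual information I(R;M) between environment and memory — equivalently,
at fixed joint entropy, to minimize the entropy distance
D_H(R,M) = H(R,M) - I(R;M) — while keeping the predicted per-step surprise
and uncertainty below (estimates of) the stochastic overload and anxiety
thresholds.

The true thresholds are never observable; they are estimated from episode
traces as quantiles of the threshold distribution via isotonic regression
of event occurrence on the measured bits (current-status censoring: an
event step upper-bounds that step's threshold, a quiet step lower-bounds
it). The planner is greedy over a finite candidate set of complete
environment sequences: at each round it schedules the feasible candidate
with the largest predicted MI gain, simulating the learning so later
rounds see the updated memory.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field
from sklearn.isotonic import IsotonicRegression

from . import memory as mem
from .agent import AgentConfig, EpisodeTrace, StepTrace
from .environment import (
    EnvironmentModel,
    emit,
    step_environment,
    transform_branch_to_start,
    transform_limit_options,
)
from .information import empirical_joint, mutual_information

__all__ = [
    "ThresholdEstimate",
    "TherapyCandidate",
    "TherapyPlan",
    "GuidelinesConfig",
    "estimate_thresholds",
    "mi_estimate",
    "mi_gain",
    "predict_candidate_profile",
    "plan_therapy",
    "run_therapy",
]


@dataclass(frozen=True)
class ThresholdEstimate:
    """q-quantile estimates of the overload/anxiety threshold distributions.

    ``censored`` marks a channel for which no event was ever observed, so
    only a lower bound (max observed measure plus a margin) is available.
    """

    t_so: float
    t_a: float
    q: float
    n_so_events: int
    n_a_events: int
    n_steps: int
    so_censored: bool = False
    a_censored: bool = False


@dataclass(frozen=True)
class TherapyCandidate:
    """A complete environment sequence with its predicted margins and gain."""

    sequence: tuple[int, ...]
    predicted_surprise_bits: float
    predicted_uncertainty_bits: float
    predicted_mi_gain_bits: float

    def to_dict(self) -> dict:
        return {
            "sequence": list(self.sequence),
            "predicted_surprise_bits": self.predicted_surprise_bits,
            "predicted_uncertainty_bits": self.predicted_uncertainty_bits,
            "predicted_mi_gain_bits": self.predicted_mi_gain_bits,
        }


@dataclass
class TherapyPlan:
    """An ordered curriculum; every entry was feasible when scheduled."""

    candidates: list[TherapyCandidate]
    q: float
    thresholds: ThresholdEstimate
    stopping_reason: str
    transforms_applied: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.candidates)

    def total_predicted_gain(self) -> float:
        return sum(c.predicted_mi_gain_bits for c in self.candidates)

    def to_json(self) -> str:
        return json.dumps(
            {
                "q": self.q,
                "thresholds": {
                    "t_so": self.thresholds.t_so,
                    "t_a": self.thresholds.t_a,
                    "q": self.thresholds.q,
                },
                "stopping_reason": self.stopping_reason,
                "transforms_applied": self.transforms_applied,
                "candidates": [c.to_dict() for c in self.candidates],
            },
            indent=2,
        )


class GuidelinesConfig(BaseModel):
    """Planner-side knobs realizing the therapy design guidelines."""

    model_config = ConfigDict(extra="forbid")

    nu_max: Optional[int] = Field(None, ge=1)  # cap on options per branch
    allow_transforms: bool = False  # may request env transforms to unlock candidates
    gain_floor_bits: float = Field(0.01, ge=0)
    mi_rollout_steps: int = Field(200, ge=10)


def _channel_quantile(
    measures: np.ndarray, events: np.ndarray, q: float
) -> tuple[float, bool]:
    """q-quantile of a threshold distribution from current-status data.

    Each step reports whether its measure exceeded that step's threshold
    draw, so P(event | measure = m) is the threshold CDF at m; isotonic
    regression gives its monotone MLE and we invert it at q.
    """
    if events.sum() == 0:
        return float(measures.max()) + 1.0, True
    if events.all():
        return float(measures.min()), True
    iso = IsotonicRegression(y_min=0.0, y_max=1.0, increasing=True, out_of_bounds="clip")
    iso.fit(measures, events.astype(float))
    grid = np.unique(measures)
    cdf = iso.predict(grid)
    above = np.nonzero(cdf >= q)[0]
    if above.size == 0:
        return float(measures.max()) + 1.0, True
    return float(grid[above[0]]), False


def estimate_thresholds(
    traces: Sequence[EpisodeTrace], q: float
) -> ThresholdEstimate:
    """Estimate the q-quantiles of T_so and T_a from episode traces."""
    if not (0.0 < q < 1.0):
        raise ValueError("q must be in (0, 1)")
    steps = [s for t in traces for s in t.steps]
    if not steps:
        raise ValueError("no steps in traces")
    surprise = np.array([s.surprise_bits for s in steps])
    uncertainty = np.array([s.uncertainty_bits for s in steps])
    overload = np.array(["overload" in s.events for s in steps])
    anxiety = np.array(["anxiety" in s.events for s in steps])
    t_so, so_c = _channel_quantile(surprise, overload, q)
    t_a, a_c = _channel_quantile(uncertainty, anxiety, q)
    return ThresholdEstimate(
        t_so=t_so,
        t_a=t_a,
        q=q,
        n_so_events=int(overload.sum()),
        n_a_events=int(anxiety.sum()),
        n_steps=len(steps),
        so_censored=so_c,
        a_censored=a_c,
    )


def mi_estimate(
    g: mem.MemoryGraph,
    env: EnvironmentModel,
    n_steps: int,
    seed: int,
    novelty_radius: float = 0.5,
) -> float:
    """I(R;M) from the empirical joint of (state, classified item) on a rollout."""
    env = env.copy()
    rng = np.random.default_rng(seed)
    pairs = []
    state: Optional[int] = None
    for _ in range(n_steps):
        state, stimulus = step_environment(env, state, rng)
        cls = mem.classify(g, stimulus, novelty_radius)
        pairs.append((state, cls.item_id if cls.item_id is not None else "none"))
    return mutual_information(empirical_joint(pairs))


def _teach(
    g: mem.MemoryGraph,
    env: EnvironmentModel,
    sequence: Sequence[int],
    novelty_radius: float,
) -> None:
    """Present a sequence of environment states to a memory, in place."""
    prev: Optional[int] = None
    for s in sequence:
        prev = mem.insert_observation(g, prev, env.states[s], novelty_radius)


def mi_gain(
    g: mem.MemoryGraph,
    env: EnvironmentModel,
    candidate: Sequence[int],
    n_rollout_steps: int = 200,
    seed: int = 0,
    novelty_radius: float = 0.5,
) -> float:
    """Predicted MI gain from learning one candidate sequence.

    Estimates I(R;M) on matched-seed rollouts before and after hypothetically
    learning the candidate on a copied memory; the paired design cancels most
    of the rollout sampling noise, so the gain is non-negative up to a small
    estimation tolerance.
    """
    before = mi_estimate(g, env, n_rollout_steps, seed, novelty_radius)
    g2 = g.copy()
    if g2.dim is None:
        g2.dim = env.dim
    _teach(g2, env, candidate, novelty_radius)
    after = mi_estimate(g2, env, n_rollout_steps, seed, novelty_radius)
    return after - before


def predict_candidate_profile(
    g: mem.MemoryGraph,
    env: EnvironmentModel,
    candidate: Sequence[int],
    config: AgentConfig,
) -> tuple[float, float]:
    """(max surprise, max uncertainty) over a simulated presentation.

    Replays the candidate against a copy of the memory with the same
    surprisal and uncertainty rules the processing loop uses, learning as it
    goes, and returns the per-step maxima — the planner's per-candidate
    reading of the per-step threshold constraints.
    """
    g2 = g.copy()
    if g2.dim is None:
        g2.dim = env.dim
    context: list[int] = []
    max_s = max_u = 0.0
    prev: Optional[int] = None
    for s in candidate:
        stimulus = env.states[s]
        cls = mem.classify(g2, stimulus, config.novelty_radius)
        surprise = mem.surprisal_of(
            g2, context, cls, config.context_depth,
            config.baseline_bits, config.novelty_mass,
        )
        pred_context = context + [cls.item_id] if not cls.is_new else list(context)
        uncertainty = mem.predictive_uncertainty(
            g2, cls, pred_context, config.context_depth
        )
        max_s = max(max_s, surprise)
        max_u = max(max_u, uncertainty)
        prev = mem.insert_observation(g2, prev, stimulus, config.novelty_radius)
        context = context + [prev]
    return max_s, max_u


def plan_therapy(
    g: mem.MemoryGraph,
    env: EnvironmentModel,
    candidates: Sequence[Sequence[int]],
    thresholds: ThresholdEstimate,
    config: Optional[AgentConfig] = None,
    guidelines: Optional[GuidelinesConfig] = None,
    seed: int = 0,
) -> TherapyPlan:
    """Greedy constrained curriculum over complete environment sequences.

    Candidates must be complete registered environment sequences (fragments
    and shortcuts read as new and defeat the purpose). Each round schedules
    the candidate with the largest predicted MI gain among those whose
    predicted per-step surprise and uncertainty stay below the threshold
    estimates; the pick is learned into a simulated memory so later rounds
    are conditioned on it. Stops when gains fall below the floor or nothing
    is feasible. With ``nu_max`` set, branches are first capped via the
    option-limiting transform; with ``allow_transforms``, a round-0 dead end
    triggers a branch-to-start rewrite to try to unlock an entry point.
    """
    if not candidates:
        raise ValueError("candidate list is empty")
    config = config or AgentConfig()
    guidelines = guidelines or GuidelinesConfig()

    env_work = env
    transforms: list[str] = []
    if guidelines.nu_max is not None and any(
        env.out_degree(s) > guidelines.nu_max for s in env.states
    ):
        env_work = transform_limit_options(env, guidelines.nu_max)
        transforms.append(f"limit_options({guidelines.nu_max})")

    paths = {tuple(p) for p in env_work.paths}
    pool = [tuple(c) for c in candidates if tuple(c) in paths]
    if guidelines.nu_max is None:
        bad = [tuple(c) for c in candidates if tuple(c) not in paths]
        if bad:
            raise ValueError(
                f"candidates must be complete environment sequences; invalid: {bad[:3]}"
            )

    sim = g.copy()
    if sim.dim is None:
        sim.dim = env_work.dim
    scheduled: list[TherapyCandidate] = []
    reason = "exhausted candidates"
    round_no = 0
    while pool:
        feasible = []
        for cand in pool:
            s_max, u_max = predict_candidate_profile(sim, env_work, cand, config)
            if s_max < thresholds.t_so and u_max < thresholds.t_a:
                gain = mi_gain(
                    sim, env_work, cand, guidelines.mi_rollout_steps,
                    seed, config.novelty_radius,
                )
                feasible.append((cand, s_max, u_max, gain))
        if not feasible:
            if round_no == 0 and guidelines.allow_transforms and "branch_to_start" not in transforms:
                env_work = transform_branch_to_start(env_work)
                transforms.append("branch_to_start")
                pool = [tuple(p) for p in env_work.paths]
                round_no += 1
                continue
            reason = "no safe entry point" if not scheduled else "no feasible candidate"
            break
        cand, s_max, u_max, gain = max(feasible, key=lambda t: t[3])
        if gain < guidelines.gain_floor_bits:
            reason = "no positive gain"
            break
        scheduled.append(
            TherapyCandidate(
                sequence=cand,
                predicted_surprise_bits=s_max,
                predicted_uncertainty_bits=u_max,
                predicted_mi_gain_bits=gain,
            )
        )
        _teach(sim, env_work, cand, config.novelty_radius)
        pool.remove(cand)
        round_no += 1
    return TherapyPlan(
        candidates=scheduled,
        q=thresholds.q,
        thresholds=thresholds,
        stopping_reason=reason,
        transforms_applied=transforms,
    )


def run_therapy(
    config: AgentConfig,
    env: EnvironmentModel,
    plan: TherapyPlan,
    seed: int,
    initial_memory: Optional[mem.MemoryGraph] = None,
    mi_rollout_steps: int = 200,
) -> tuple[EpisodeTrace, list[float]]:
    """Present a scheduled plan to a learning agent and track the MI trajectory.

    Each scheduled sequence is presented in order to a learn-policy agent;
    after every candidate the mutual information between environment states
    and classified memory items is re-estimated on a matched-seed rollout.
    The realized event rate can be read off the returned trace and, with
    calibrated thresholds, stays near the planning quantile q.
    """
    if not plan.candidates:
        raise ValueError("plan is empty")
    env = env.copy()
    g = initial_memory.copy() if initial_memory is not None else mem.MemoryGraph(env.dim)
    if g.dim is None:
        g.dim = env.dim
    ss = np.random.SeedSequence(seed)
    thresh_rng = np.random.default_rng(ss.spawn(2)[0])
    noise_rng = np.random.default_rng(ss.spawn(2)[1])
    t_so = t_a = None
    if config.thresholds.sampling_schedule == "per_episode":
        t_so, t_a = config.thresholds.sample(thresh_rng)

    steps: list[StepTrace] = []
    mi_trajectory: list[float] = []
    n = 0
    context: list[int] = []
    for cand in plan.candidates:
        prev: Optional[int] = None
        context = []
        for s in cand.sequence:
            if config.thresholds.sampling_schedule == "per_step":
                t_so, t_a = config.thresholds.sample(thresh_rng)
            stimulus = emit(env, s, noise_rng)
            cls = mem.classify(g, stimulus, config.novelty_radius)
            surprise = mem.surprisal_of(
                g, context, cls, config.context_depth,
                config.baseline_bits, config.novelty_mass,
            )
            pred_context = context + [cls.item_id] if not cls.is_new else list(context)
            uncertainty = mem.predictive_uncertainty(
                g, cls, pred_context, config.context_depth
            )
            events = []
            if surprise > t_so:
                events.append("overload")
            if uncertainty > t_a:
                events.append("anxiety")
            prev = mem.insert_observation(g, prev, stimulus, config.novelty_radius)
            context = context + [prev]
            steps.append(
                StepTrace(
                    step=n, env_state=s, item_id=prev, is_new=cls.is_new,
                    surprise_bits=surprise, uncertainty_bits=uncertainty,
                    t_so=t_so, t_a=t_a, events=tuple(events),
                )
            )
            n += 1
        mi_trajectory.append(
            mi_estimate(g, env, mi_rollout_steps, seed, config.novelty_radius)
        )
    trace = EpisodeTrace(
        steps=steps, config=config, env_hash=env.content_hash(), memory=g, seed=seed
    )
    return trace, mi_trajectory
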