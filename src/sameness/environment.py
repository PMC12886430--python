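"""Synthetic stimulus environments: branching sequence graphs of prototypes.

The environment ``R`` is a directed graph of emitting states. Each state
holds a prototype vector; an emission is the prototype plus isotropic
Gaussian white noise. Sequences are root-to-leaf paths: deterministic chains
except at branch states, where one of ``nu`` continuations is sampled. Two
perturbation regimes are built in: *novelty injection* (with a configured
rate, a brand-new prototype — well separated from every existing one, so
novelty is unambiguous — is emitted and, by default, persists as a new
state) and *sensory deprivation* (no prototypes at all; every emission is
pure endogenous noise).

Three environment transforms mirror common uncertainty-reduction
countermeasures for multi-option situations: tagging otherwise-identical
activities with unique amulet-like markers, relocating choice points to the
start of a sequence, and capping the number of options at a branch.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "EnvSpec",
    "EnvironmentModel",
    "ConstraintInfeasibleError",
    "generate_environment",
    "emit",
    "step_environment",
    "transform_amulets",
    "transform_branch_to_start",
    "transform_limit_options",
    "deprivation_environment",
    "PRESETS",
    "preset_spec",
]


class ConstraintInfeasibleError(RuntimeError):
    """A constrained environment step has empty support."""


class EnvSpec(BaseModel):
    """Declarative specification of a synthetic environment.

    ``branch_positions`` are sequence indices at which the chain splits into
    ``branch_arity`` alternative continuations (each continuing as its own
    sub-chain to the end of the sequence). ``novelty_rate`` is the per-step
    probability of emitting a brand-new stimulus. ``noise_clip``, when set,
    rescales any noise vector whose norm exceeds it — useful to keep
    perturbations strictly inside a classification radius.
    """

    model_config = ConfigDict(extra="forbid")

    n_sequences: int = Field(1, ge=1)
    seq_length: int = Field(6, ge=1)
    branch_positions: list[int] = Field(default_factory=list)
    branch_arity: int = Field(2, ge=2)
    branch_probs: Optional[list[float]] = None
    prototype_dim: int = Field(8, ge=1)
    prototype_min_separation: float = Field(2.0, gt=0)
    noise_sd: float = Field(0.0, ge=0)
    noise_clip: Optional[float] = Field(None, gt=0)
    novelty_rate: float = Field(0.0, ge=0, le=1)
    novelty_persistent: bool = True
    deprivation: bool = False
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "EnvSpec":
        for p in self.branch_positions:
            if not (0 <= p < self.seq_length - 1):
                raise ValueError(
                    f"branch position {p} must lie in [0, seq_length-2]"
                )
        if self.branch_probs is not None:
            if len(self.branch_probs) != self.branch_arity:
                raise ValueError("branch_probs length must equal branch_arity")
            if any(q < 0 for q in self.branch_probs):
                raise ValueError("branch_probs must be non-negative")
            if abs(sum(self.branch_probs) - 1.0) > 1e-9:
                raise ValueError("branch_probs must sum to 1")
        return self


@dataclass
class EnvironmentModel:
    """A generative branching sequence graph (the random variable R)."""

    dim: int
    states: dict[int, np.ndarray] = field(default_factory=dict)
    successors: dict[int, list[tuple[int, float]]] = field(default_factory=dict)
    start_states: list[tuple[int, float]] = field(default_factory=list)
    paths: list[list[int]] = field(default_factory=list)
    path_probs: list[float] = field(default_factory=list)
    noise_sd: float = 0.0
    noise_clip: Optional[float] = None
    novelty_rate: float = 0.0
    novelty_persistent: bool = True
    prototype_min_separation: float = 1.0
    deprivation: bool = False
    _next_state_id: int = 0

    def copy(self) -> "EnvironmentModel":
        return EnvironmentModel(
            dim=self.dim,
            states={s: p.copy() for s, p in self.states.items()},
            successors={s: list(v) for s, v in self.successors.items()},
            start_states=list(self.start_states),
            paths=[list(p) for p in self.paths],
            path_probs=list(self.path_probs),
            noise_sd=self.noise_sd,
            noise_clip=self.noise_clip,
            novelty_rate=self.novelty_rate,
            novelty_persistent=self.novelty_persistent,
            prototype_min_separation=self.prototype_min_separation,
            deprivation=self.deprivation,
            _next_state_id=self._next_state_id,
        )

    def prototype_matrix(self) -> np.ndarray:
        ids = sorted(self.states)
        return np.vstack([self.states[s] for s in ids]) if ids else np.empty((0, self.dim))

    def out_degree(self, state: int) -> int:
        return len(self.successors.get(state, []))

    def content_hash(self) -> str:
        doc = {
            "dim": self.dim,
            "states": {str(s): np.round(p, 12).tolist() for s, p in sorted(self.states.items())},
            "successors": {str(s): v for s, v in sorted(self.successors.items())},
            "start": self.start_states,
            "noise_sd": self.noise_sd,
            "novelty_rate": self.novelty_rate,
            "deprivation": self.deprivation,
        }
        return hashlib.sha256(json.dumps(doc, sort_keys=True).encode()).hexdigest()[:16]

    def to_networkx(self) -> nx.DiGraph:
        G = nx.DiGraph()
        G.graph["dim"] = self.dim
        G.graph["paths"] = json.dumps([list(p) for p in self.paths])
        for s, proto in self.states.items():
            G.add_node(s, prototype=",".join(repr(x) for x in proto.tolist()))
        for s, succ in self.successors.items():
            for t, q in succ:
                G.add_edge(s, t, prob=q)
        return G


def _sample_separated(
    rng: np.random.Generator,
    existing: list[np.ndarray],
    dim: int,
    min_sep: float,
    max_tries: int = 20000,
) -> np.ndarray:
    """Rejection-sample a prototype at least ``min_sep`` from all existing ones."""
    n = len(existing)
    scale = min_sep * max(2.0, (n + 1) ** (1.0 / dim))
    mat = np.vstack(existing) if existing else None
    for _ in range(max_tries):
        cand = rng.normal(0.0, scale, size=dim)
        if mat is None or np.min(np.linalg.norm(mat - cand[None, :], axis=1)) >= min_sep:
            return cand
    raise RuntimeError(
        "could not place a separated prototype; increase prototype_dim or "
        "decrease the number of states / prototype_min_separation"
    )


def generate_environment(spec: EnvSpec) -> EnvironmentModel:
    """Build an environment from its spec; deterministic given the seed."""
    if spec.deprivation:
        return deprivation_environment(spec.prototype_dim, spec.noise_sd, spec.seed)
    rng = np.random.default_rng(spec.seed)
    env = EnvironmentModel(
        dim=spec.prototype_dim,
        noise_sd=spec.noise_sd,
        noise_clip=spec.noise_clip,
        novelty_rate=spec.novelty_rate,
        novelty_persistent=spec.novelty_persistent,
        prototype_min_separation=spec.prototype_min_separation,
    )
    branch_set = set(spec.branch_positions)
    bp = (
        list(spec.branch_probs)
        if spec.branch_probs is not None
        else [1.0 / spec.branch_arity] * spec.branch_arity
    )

    def alloc() -> int:
        sid = env._next_state_id
        env._next_state_id += 1
        return sid

    def build(index: int) -> int:
        sid = alloc()
        if index < spec.seq_length - 1:
            if index in branch_set:
                kids = [build(index + 1) for _ in range(spec.branch_arity)]
                env.successors[sid] = list(zip(kids, bp))
            else:
                env.successors[sid] = [(build(index + 1), 1.0)]
        else:
            env.successors[sid] = []
        return sid

    roots = [build(0) for _ in range(spec.n_sequences)]
    env.start_states = [(r, 1.0 / len(roots)) for r in roots]

    # enumerate root-to-leaf paths with their probabilities
    def dfs(sid: int, prefix: list[int], prob: float) -> None:
        prefix = prefix + [sid]
        succ = env.successors.get(sid, [])
        if not succ:
            env.paths.append(prefix)
            env.path_probs.append(prob)
            return
        for t, q in succ:
            dfs(t, prefix, prob * q)

    for r, q0 in env.start_states:
        dfs(r, [], q0)

    protos: list[np.ndarray] = []
    for sid in range(env._next_state_id):
        protos.append(
            _sample_separated(rng, protos, spec.prototype_dim, spec.prototype_min_separation)
        )
        env.states[sid] = protos[-1]
    return env


def deprivation_environment(
    dim: int, noise_sd: float, seed: int = 0
) -> EnvironmentModel:
    """An environment with no prototypes: emissions are pure endogenous noise.

    Models sensory deprivation, where internal stimuli dominate; with an
    ordinary novelty radius every emission classifies as new.
    """
    if noise_sd <= 0:
        raise ValueError("deprivation environment requires noise_sd > 0")
    env = EnvironmentModel(dim=dim, noise_sd=noise_sd, deprivation=True)
    env.states[0] = np.zeros(dim)  # anchor state; never emitted as-is
    env.successors[0] = [(0, 1.0)]
    env.start_states = [(0, 1.0)]
    env._next_state_id = 1
    return env


def emit(env: EnvironmentModel, state: int, rng: np.random.Generator) -> np.ndarray:
    """Emit a stimulus from a state: prototype plus white noise.

    In a deprivation environment the emission is the noise alone. When
    ``noise_clip`` is set the noise vector is rescaled onto the clip radius
    whenever its norm exceeds it.
    """
    if state not in env.states:
        raise KeyError(f"unknown environment state {state}")
    noise = rng.normal(0.0, env.noise_sd, size=env.dim) if env.noise_sd > 0 else np.zeros(env.dim)
    if env.noise_clip is not None:
        nrm = float(np.linalg.norm(noise))
        if nrm > env.noise_clip:
            noise = noise * (env.noise_clip / nrm)
    if env.deprivation:
        return noise
    return env.states[state] + noise


def _sample_from(
    rng: np.random.Generator, options: Sequence[tuple[int, float]]
) -> int:
    ids = [t for t, _ in options]
    probs = np.asarray([q for _, q in options], dtype=float)
    probs = probs / probs.sum()
    return int(rng.choice(ids, p=probs))


def step_environment(
    env: EnvironmentModel,
    current: Optional[int],
    rng: np.random.Generator,
    constrain_to: Optional[set[int]] = None,
    noise_rng: Optional[np.random.Generator] = None,
) -> tuple[int, np.ndarray]:
    """Advance the environment one step and emit the next stimulus.

    From a terminal state (or ``current=None``) the stream restarts at a
    start state. With probability ``novelty_rate`` a brand-new prototype is
    emitted instead; if novelty is persistent the new state is spliced into
    the graph before the sampled successor. ``constrain_to`` restricts the
    successor draw to the given state set — the hook a sameness-seeking
    agent uses to hold the environment inside known territory; novelty
    injection is suppressed under a constrained draw, and an empty
    constrained support raises :class:`ConstraintInfeasibleError`.

    ``noise_rng`` optionally separates emission noise from transition
    randomness so noise seeds can be varied while the visited state sequence
    stays fixed.
    """
    noise_rng = noise_rng if noise_rng is not None else rng
    candidates = (
        env.successors.get(current, []) if current is not None else []
    )
    if not candidates:
        candidates = env.start_states
    if constrain_to is not None:
        allowed = [(t, q) for t, q in candidates if t in constrain_to]
        if not allowed:
            allowed = [(t, q) for t, q in env.start_states if t in constrain_to]
        if not allowed:
            raise ConstraintInfeasibleError(
                "no successor or start state lies in the constrained set"
            )
        nxt = _sample_from(rng, allowed)
        return nxt, emit(env, nxt, noise_rng)

    if env.novelty_rate > 0 and rng.random() < env.novelty_rate and not env.deprivation:
        nxt = _sample_from(rng, candidates)
        proto = _sample_separated(
            rng, list(env.states.values()), env.dim, env.prototype_min_separation
        )
        if env.novelty_persistent:
            sid = env._next_state_id
            env._next_state_id += 1
            env.states[sid] = proto
            env.successors[sid] = [(nxt, 1.0)]
            noise = noise_rng.normal(0.0, env.noise_sd, size=env.dim) if env.noise_sd > 0 else 0.0
            return sid, proto + noise
        # transient: the underlying state advances, the percept is novel
        return nxt, proto
    nxt = _sample_from(rng, candidates)
    return nxt, emit(env, nxt, noise_rng)


# -- transforms ----------------------------------------------------------


def transform_amulets(env: EnvironmentModel) -> EnvironmentModel:
    """Make every sequence perceptually distinct with unique marker coordinates.

    Appends one indicator coordinate per path to every prototype, set high
    on the path owning the state; states shared between paths are duplicated
    per path. After memorization, every former branch point is disambiguated
    by the marker: each path is its own deterministic chain, so mid-sequence
    choice uncertainty vanishes. Pairwise separation is preserved (the
    marker offset alone separates duplicated states).
    """
    if env.deprivation:
        return env.copy()
    n_paths = len(env.paths)
    amp = max(env.prototype_min_separation, 1.0)
    new = EnvironmentModel(
        dim=env.dim + n_paths,
        noise_sd=env.noise_sd,
        noise_clip=env.noise_clip,
        novelty_rate=env.novelty_rate,
        novelty_persistent=env.novelty_persistent,
        prototype_min_separation=env.prototype_min_separation,
    )
    for j, (path, q) in enumerate(zip(env.paths, env.path_probs)):
        marker = np.zeros(n_paths)
        marker[j] = amp
        ids = []
        for s in path:
            sid = new._next_state_id
            new._next_state_id += 1
            new.states[sid] = np.concatenate([env.states[s], marker])
            ids.append(sid)
        for a, b in zip(ids, ids[1:]):
            new.successors[a] = [(b, 1.0)]
        new.successors[ids[-1]] = []
        new.start_states.append((ids[0], q))
        new.paths.append(ids)
        new.path_probs.append(q)
    total = sum(q for _, q in new.start_states)
    new.start_states = [(s, q / total) for s, q in new.start_states]
    new.path_probs = [q / total for q in new.path_probs]
    return new


def transform_branch_to_start(env: EnvironmentModel) -> EnvironmentModel:
    """Relocate each sequence's first choice point to the sequence beginning.

    Every root-to-leaf path is rotated at its first branch state: the
    branch-specific tail comes first and the formerly shared prefix follows.
    The choice among alternatives is thereby made at step 0 (as a start-state
    draw over perceptually distinct heads) and the remainder of every
    sequence is deterministic, so the cumulative uncertainty profile peaks at
    the first step instead of mid-sequence. Branchless environments are
    returned unchanged.
    """
    if env.deprivation or all(env.out_degree(s) <= 1 for s in env.states):
        return env.copy()
    new = EnvironmentModel(
        dim=env.dim,
        states={s: p.copy() for s, p in env.states.items()},
        noise_sd=env.noise_sd,
        noise_clip=env.noise_clip,
        novelty_rate=env.novelty_rate,
        novelty_persistent=env.novelty_persistent,
        prototype_min_separation=env.prototype_min_separation,
        _next_state_id=env._next_state_id,
    )
    succ: dict[int, set[tuple[int, float]]] = {s: set() for s in env.states}
    for path, q in zip(env.paths, env.path_probs):
        cut = next(
            (i for i, s in enumerate(path) if env.out_degree(s) > 1), None
        )
        rotated = path[cut + 1:] + path[: cut + 1] if cut is not None else list(path)
        new.paths.append(rotated)
        new.path_probs.append(q)
        new.start_states.append((rotated[0], q))
        for a, b in zip(rotated, rotated[1:]):
            succ[a].add((b, 1.0))
    for s, pairs in succ.items():
        opts = sorted(pairs)
        new.successors[s] = [(t, 1.0 / len(opts)) for t, _ in opts]
    # merge duplicate start entries
    agg: dict[int, float] = {}
    for s, q in new.start_states:
        agg[s] = agg.get(s, 0.0) + q
    new.start_states = sorted(agg.items())
    return new


def transform_limit_options(env: EnvironmentModel, nu_max: int) -> EnvironmentModel:
    """Cap the number of options at every branch at ``nu_max``.

    The lowest-probability successors are pruned (ties broken by state id)
    and the remaining branch probabilities renormalized; paths through
    pruned edges are dropped and unreachable states removed. With ``nu_max``
    at or above the maximum out-degree this is the identity.
    """
    if nu_max < 1:
        raise ValueError("nu_max must be >= 1")
    new = env.copy()
    if env.deprivation:
        return new
    for s, succ in list(new.successors.items()):
        if len(succ) > nu_max:
            kept = sorted(succ, key=lambda tq: (-tq[1], tq[0]))[:nu_max]
            total = sum(q for _, q in kept)
            new.successors[s] = [(t, q / total) for t, q in sorted(kept)]
    kept_edges = {
        (s, t) for s, succ in new.successors.items() for t, _ in succ
    }
    surviving = []
    surviving_probs = []
    for path, q in zip(new.paths, new.path_probs):
        if all((a, b) in kept_edges for a, b in zip(path, path[1:])):
            surviving.append(path)
            surviving_probs.append(q)
    total = sum(surviving_probs)
    new.paths = surviving
    new.path_probs = [q / total for q in surviving_probs] if total > 0 else []
    reachable = {s for p in surviving for s in p}
    new.states = {s: p for s, p in new.states.items() if s in reachable}
    new.successors = {
        s: [(t, q) for t, q in succ if t in reachable]
        for s, succ in new.successors.items()
        if s in reachable
    }
    start = [(s, q) for s, q in new.start_states if s in reachable]
    ztot = sum(q for _, q in start)
    new.start_states = [(s, q / ztot) for s, q in start]
    return new


# -- presets -------------------------------------------------------------

PRESETS: dict[str, dict] = {
    "chain": dict(
        n_sequences=1, seq_length=8, prototype_dim=6,
        prototype_min_separation=2.0, noise_sd=0.0, novelty_rate=0.0, seed=7,
    ),
    "branching": dict(
        n_sequences=2, seq_length=6, branch_positions=[2], branch_arity=2,
        prototype_dim=8, prototype_min_separation=2.0, noise_sd=0.0,
        novelty_rate=0.0, seed=11,
    ),
    "nonstationary": dict(
        n_sequences=2, seq_length=6, prototype_dim=8,
        prototype_min_separation=2.0, noise_sd=0.0, novelty_rate=0.15,
        novelty_persistent=True, seed=13,
    ),
    "deprivation": dict(
        prototype_dim=8, noise_sd=1.0, deprivation=True, seed=17,
    ),
}


def preset_spec(name: str) -> EnvSpec:
    """One of the shipped environment presets: chain, branching, nonstationary, deprivation."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    return EnvSpec(**PRESETS[name])
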