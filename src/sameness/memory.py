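"""The agent's memory: a persistent directed graph of stimulus prototypes.

Memory ``M`` stores classified stimuli as *items* (prototype vectors with
observation counts), directed transition edges between consecutively observed
items, and a registry of complete memorized item-id sequences. Classification
is nearest-neighbour: a raw stimulus is always mapped to the closest stored
prototype, however far away; it is *new* when that distance exceeds the
novelty radius. Memory is append-only — there is no deletion or decay.

Surprise and uncertainty are conditional entropies of the distributions the
memory induces over continuations:

* ``predictive_uncertainty`` — the entropy over memorized successors of the
  current context (0 on a deterministic chain, log2(nu) at a balanced
  nu-way branch, and the full memory entropy H(M) when the stimulus is new
  or no continuation is registered);
* ``perceptual_surprise`` — the set-entropy of the predicted next stimulus,
  mixed with a configurable novelty prior assigned a baseline H(R) proxy;
* ``surprisal_of`` — the realized per-event score, -log2 of the smoothed
  probability the memory assigned to what actually arrived.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import networkx as nx
import numpy as np

from .information import FiniteDistribution, entropy

__all__ = [
    "MemoryItem",
    "MemoryGraph",
    "ClassificationResult",
    "classify",
    "insert_observation",
    "option_set",
    "predictive_uncertainty",
    "perceptual_surprise",
    "surprisal_of",
    "disappointment",
    "memory_entropy",
    "export_memory",
    "import_memory",
]


class MemoryFormatError(ValueError):
    """Raised when a serialized memory document is malformed."""


@dataclass
class MemoryItem:
    """A memorized stimulus prototype with its observation count."""

    id: int
    prototype: np.ndarray
    count: int = 1


@dataclass(frozen=True)
class ClassificationResult:
    """Outcome of nearest-neighbour classification of one stimulus.

    ``item_id`` is None only when the memory is empty. ``is_new`` is True
    when the memory is empty or the nearest prototype lies farther than the
    novelty radius.
    """

    item_id: Optional[int]
    distance: float
    is_new: bool


class MemoryGraph:
    """Directed graph of memory items with a full-sequence registry.

    The registry stores every traversed sequence as a list of item ids;
    repeated traversals appear as repeated entries, so registry multiplicity
    doubles as the sequence count. Sequences are extended incrementally by
    :func:`insert_observation`; an observation with ``prev_item_id=None``
    opens a new sequence.
    """

    def __init__(self, dim: Optional[int] = None):
        self.dim = dim
        self.items: dict[int, MemoryItem] = {}
        self.edges: dict[tuple[int, int], int] = {}
        self.sequences: list[list[int]] = []
        self._next_id = 0
        self._active_seq: Optional[int] = None

    # -- basic accessors -------------------------------------------------

    def __len__(self) -> int:
        return len(self.items)

    @property
    def is_empty(self) -> bool:
        return not self.items

    def successors(self, item_id: int) -> dict[int, int]:
        """Successor item ids with edge transition counts."""
        if item_id not in self.items:
            raise KeyError(f"unknown item id {item_id}")
        return {v: c for (u, v), c in self.edges.items() if u == item_id}

    def prototype_matrix(self) -> np.ndarray:
        ids = sorted(self.items)
        return np.vstack([self.items[i].prototype for i in ids])

    def copy(self) -> "MemoryGraph":
        g = MemoryGraph(self.dim)
        g.items = {
            i: MemoryItem(it.id, it.prototype.copy(), it.count)
            for i, it in self.items.items()
        }
        g.edges = dict(self.edges)
        g.sequences = [list(s) for s in self.sequences]
        g._next_id = self._next_id
        g._active_seq = self._active_seq
        return g

    # -- mutation --------------------------------------------------------

    def _add_item(self, prototype: np.ndarray) -> int:
        item_id = self._next_id
        self._next_id += 1
        self.items[item_id] = MemoryItem(item_id, np.asarray(prototype, float).copy())
        return item_id

    def _bump_edge(self, u: int, v: int) -> None:
        self.edges[(u, v)] = self.edges.get((u, v), 0) + 1

    def _extend_sequence(self, prev: Optional[int], item_id: int) -> None:
        if prev is None:
            self.sequences.append([item_id])
            self._active_seq = len(self.sequences) - 1
            return
        if (
            self._active_seq is not None
            and self.sequences[self._active_seq]
            and self.sequences[self._active_seq][-1] == prev
        ):
            self.sequences[self._active_seq].append(item_id)
        else:
            # observation chain broke; open a fresh sequence from the edge
            self.sequences.append([prev, item_id])
            self._active_seq = len(self.sequences) - 1


def classify(
    g: MemoryGraph,
    stimulus: np.ndarray,
    novelty_radius: float,
) -> ClassificationResult:
    """Nearest-neighbour classification of a stimulus against the memory.

    Always returns the closest stored prototype under Euclidean distance,
    regardless of how far it is; ``is_new`` marks whether the distance
    exceeds ``novelty_radius`` (or the memory is empty). Ties are broken by
    lowest item id for determinism.
    """
    stimulus = np.asarray(stimulus, dtype=float)
    if g.dim is not None and stimulus.shape != (g.dim,):
        raise ValueError(f"stimulus shape {stimulus.shape} != memory dim ({g.dim},)")
    if g.is_empty:
        return ClassificationResult(None, math.inf, True)
    ids = sorted(g.items)
    protos = np.vstack([g.items[i].prototype for i in ids])
    d = np.linalg.norm(protos - stimulus[None, :], axis=1)
    best = int(np.argmin(d))  # argmin takes the first minimum: lowest id
    dist = float(d[best])
    return ClassificationResult(ids[best], dist, dist > novelty_radius)


def insert_observation(
    g: MemoryGraph,
    prev_item_id: Optional[int],
    stimulus: np.ndarray,
    novelty_radius: float,
) -> int:
    """Store one observed stimulus, updating items, edges and the registry.

    A new item is created when classification reports the stimulus as new;
    otherwise the matched item's count is incremented. A directed edge from
    ``prev_item_id`` (when given) is created or incremented, and the sequence
    registry is extended. Mutates ``g`` in place; returns the item id.
    """
    stimulus = np.asarray(stimulus, dtype=float)
    if g.dim is None:
        g.dim = stimulus.shape[0]
    res = classify(g, stimulus, novelty_radius)
    if res.is_new:
        item_id = g._add_item(stimulus)
    else:
        item_id = res.item_id  # type: ignore[assignment]
        g.items[item_id].count += 1
    if prev_item_id is not None and prev_item_id not in g.items:
        raise KeyError(f"unknown predecessor item id {prev_item_id}")
    if prev_item_id is not None:
        g._bump_edge(prev_item_id, item_id)
    g._extend_sequence(prev_item_id, item_id)
    return item_id


def option_set(
    g: MemoryGraph,
    context: Sequence[int],
    depth: Optional[int] = None,
) -> FiniteDistribution:
    """Distribution over memorized successors of a context.

    Matches the trailing ``depth`` items of ``context`` (the full context
    when ``depth`` is None) as a contiguous subsequence against the sequence
    registry and counts the items that follow each match. With ``depth=None``
    the *longest* suffix with at least one registered continuation is used,
    so whole-sequence structure dominates but the lookup degrades gracefully
    to shorter contexts. Probabilities are proportional to match counts.

    An empty result signals that the memory registers no continuation — the
    novel case, where prediction falls back to the full memory entropy.
    """
    context = list(context)
    for item_id in context:
        if item_id not in g.items:
            raise KeyError(f"unknown item id {item_id} in context")
    if not context:
        return FiniteDistribution((), ())
    if depth is not None:
        suffixes = [context[-depth:]] if depth > 0 else []
    else:
        max_len = min(len(context), max((len(s) for s in g.sequences), default=0))
        suffixes = [context[len(context) - k:] for k in range(max_len, 0, -1)]
    for suffix in suffixes:
        counts: dict[int, float] = {}
        k = len(suffix)
        for seq in g.sequences:
            for i in range(len(seq) - k):
                if seq[i:i + k] == suffix:
                    nxt = seq[i + k]
                    counts[nxt] = counts.get(nxt, 0.0) + 1.0
        if counts:
            return FiniteDistribution.from_counts(counts)
    return FiniteDistribution((), ())


def memory_entropy(
    g: MemoryGraph,
    weighting: Literal["counts", "uniform"] = "counts",
) -> float:
    """H(M): entropy of the distribution over memorized items, in bits.

    By default items are weighted by observation counts; ``uniform`` weights
    every item equally. An empty memory has entropy 0 (with a warning).
    """
    if g.is_empty:
        warnings.warn("memory_entropy of an empty memory is defined as 0", stacklevel=2)
        return 0.0
    if weighting == "uniform":
        return math.log2(len(g.items))
    return entropy(
        FiniteDistribution.from_counts({i: it.count for i, it in g.items.items()})
    )


def predictive_uncertainty(
    g: MemoryGraph,
    r_classified: ClassificationResult,
    context: Sequence[int],
    depth: Optional[int] = None,
) -> float:
    """Prediction-phase uncertainty H(M_next | R = r_n), in bits.

    For a known stimulus with registered continuations this is the entropy
    of the option set; a new stimulus, or a context with no registered
    continuation, carries no information about the memory and falls back to
    the full memory entropy H(M). A deterministic continuation gives 0.
    """
    if g.is_empty:
        return 0.0
    if r_classified.is_new:
        return memory_entropy(g)
    options = option_set(g, context, depth)
    if options.is_empty:
        return memory_entropy(g)
    return entropy(options)


def perceptual_surprise(
    g: MemoryGraph,
    context: Sequence[int],
    depth: Optional[int] = None,
    baseline_bits: float = 0.0,
    novelty_prior: float = 0.0,
) -> float:
    """Perception-phase surprise H(R | M = context), in bits.

    The memory-predicted next-stimulus distribution contributes its entropy
    with weight ``1 - novelty_prior``; the remaining mass is assigned the
    configured ``baseline_bits`` proxy for the unconditional H(R) (the agent
    cannot know the true stimulus entropy). When the context has no
    registered continuation at all, the surprise is ``baseline_bits``
    regardless of the prior: memory carries no information about what comes
    next. With ``novelty_prior`` 0 or 1 this reduces to the pure
    set-entropy and pure-fallback cases.
    """
    if not (0.0 <= novelty_prior <= 1.0):
        raise ValueError("novelty_prior must be in [0, 1]")
    if g.is_empty:
        return baseline_bits
    options = option_set(g, context, depth)
    if options.is_empty:
        return baseline_bits
    return (1.0 - novelty_prior) * entropy(options) + novelty_prior * baseline_bits


def _smoothed_probability(
    g: MemoryGraph,
    options: FiniteDistribution,
    observed: ClassificationResult,
    novelty_mass: float,
) -> float:
    """Probability the memory assigns to the observed next item.

    Registered continuations share mass ``1 - novelty_mass`` in proportion
    to their counts; ``novelty_mass`` is split uniformly over the unseen
    slots — every memorized item not among the registered continuations,
    plus one slot for a genuinely novel item.
    """
    if not (0.0 < novelty_mass < 1.0):
        raise ValueError("novelty_mass must be in (0, 1)")
    seen = set(options.outcomes)
    n_unseen_slots = len([i for i in g.items if i not in seen]) + 1
    if (not observed.is_new) and observed.item_id in seen:
        return (1.0 - novelty_mass) * options.prob(observed.item_id)
    return novelty_mass / n_unseen_slots


def surprisal_of(
    g: MemoryGraph,
    context: Sequence[int],
    observed: ClassificationResult,
    depth: Optional[int] = None,
    baseline_bits: float = 0.0,
    novelty_mass: float = 2.0 ** -10,
) -> float:
    """Realized surprisal -log2 p(observed | context), in bits; always finite.

    Uses the smoothed continuation probability: the unique memorized
    continuation scores -log2(1 - novelty_mass) (about 0.0014 bits at the
    default mass), one of nu balanced continuations about log2(nu), and an
    unseen continuation -log2(novelty_mass / n_unseen_slots). When the
    context has no registered continuation the memory's count-weighted item
    marginal is used instead; an entirely empty memory scores
    ``baseline_bits``.
    """
    if g.is_empty:
        return baseline_bits
    options = option_set(g, context, depth) if context else FiniteDistribution((), ())
    if options.is_empty:
        options = FiniteDistribution.from_counts(
            {i: it.count for i, it in g.items.items()}
        )
    p = _smoothed_probability(g, options, observed, novelty_mass)
    return -math.log2(p)


def disappointment(
    g: MemoryGraph,
    full_context: Sequence[int],
    observed: ClassificationResult,
    novelty_mass: float = 2.0 ** -10,
) -> tuple[bool, float]:
    """Whole-sequence deviation check: did the sequence break its memorized course?

    Conditions on the *entire* observed history (not just the last item): the
    flag is raised when the memory registers continuations for the full
    context yet the observed item deviates from every one of them. The bits
    are the full-depth realized surprisal. When no registered sequence
    matches the context the flag is False and the bits fall back to the
    context-free surprisal (there was no memorized course to deviate from).
    """
    context = list(full_context)
    if not context or g.is_empty:
        return False, surprisal_of(g, context, observed, novelty_mass=novelty_mass)
    options = option_set(g, context, depth=len(context))
    bits = surprisal_of(
        g, context, observed, depth=len(context), novelty_mass=novelty_mass
    )
    if options.is_empty:
        return False, bits
    deviates = observed.is_new or observed.item_id not in options.outcomes
    return deviates, bits


# -- serialization -------------------------------------------------------


def export_memory(g: MemoryGraph) -> dict:
    """Lossless JSON-style document for a memory graph."""
    return {
        "dim": g.dim,
        "items": [
            {"id": it.id, "prototype": it.prototype.tolist(), "count": it.count}
            for it in sorted(g.items.values(), key=lambda it: it.id)
        ],
        "edges": [
            {"from": u, "to": v, "count": c}
            for (u, v), c in sorted(g.edges.items())
        ],
        "sequences": [list(s) for s in g.sequences],
        "next_id": g._next_id,
    }


def import_memory(doc: dict) -> MemoryGraph:
    """Inverse of :func:`export_memory`; validates referential integrity."""
    try:
        g = MemoryGraph(doc.get("dim"))
        for rec in doc["items"]:
            g.items[int(rec["id"])] = MemoryItem(
                int(rec["id"]), np.asarray(rec["prototype"], float), int(rec["count"])
            )
        for rec in doc["edges"]:
            u, v = int(rec["from"]), int(rec["to"])
            if u not in g.items or v not in g.items:
                raise MemoryFormatError(f"dangling edge {u}->{v}")
            g.edges[(u, v)] = int(rec["count"])
        for si, seq in enumerate(doc["sequences"]):
            seq = [int(i) for i in seq]
            for i in seq:
                if i not in g.items:
                    raise MemoryFormatError(f"sequence {si} references unknown item {i}")
            for a, b in zip(seq, seq[1:]):
                if (a, b) not in g.edges:
                    raise MemoryFormatError(
                        f"sequence {si} step {a}->{b} is not an edge"
                    )
            g.sequences.append(seq)
        g._next_id = int(doc.get("next_id", max(g.items, default=-1) + 1))
    except (KeyError, TypeError) as exc:
        raise MemoryFormatError(f"malformed memory document: {exc}") from exc
    return g


def to_networkx(g: MemoryGraph) -> nx.DiGraph:
    """Memory as a networkx DiGraph (GraphML-compatible attributes only)."""
    G = nx.DiGraph()
    G.graph["dim"] = -1 if g.dim is None else int(g.dim)
    G.graph["sequences"] = json.dumps([list(s) for s in g.sequences])
    G.graph["next_id"] = g._next_id
    for it in g.items.values():
        G.add_node(
            it.id,
            prototype=",".join(repr(x) for x in it.prototype.tolist()),
            count=it.count,
        )
    for (u, v), c in g.edges.items():
        G.add_edge(u, v, count=c)
    return G


def from_networkx(G: nx.DiGraph) -> MemoryGraph:
    dim = G.graph.get("dim", -1)
    doc = {
        "dim": None if dim in (-1, None) else int(dim),
        "items": [
            {
                "id": n,
                "prototype": [float(x) for x in str(d["prototype"]).split(",")] if d.get("prototype") else [],
                "count": d.get("count", 1),
            }
            for n, d in G.nodes(data=True)
        ],
        "edges": [
            {"from": u, "to": v, "count": d.get("count", 1)}
            for u, v, d in G.edges(data=True)
        ],
        "sequences": json.loads(G.graph.get("sequences", "[]")),
        "next_id": G.graph.get("next_id", 0),
    }
    return import_memory(doc)


def write_graphml(g: MemoryGraph, path) -> None:
    nx.write_graphml(to_networkx(g), path)


def read_graphml(path) -> MemoryGraph:
    G = nx.read_graphml(path, node_type=int)
    return from_networkx(G)
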