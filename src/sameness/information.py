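"""Discrete information-theoretic primitives.

Everything downstream — surprise and uncertainty bookkeeping, the entropy
distance between an environment ``R`` and a memory ``M``, and the
mutual-information objective of the curriculum planner — is computed on the
two containers defined here: :class:`FiniteDistribution` (a distribution over
an arbitrary finite outcome set) and :class:`JointDistribution` (a joint over
a pair of finite outcome sets).

All quantities are in bits (logarithm base 2), so a balanced :math:`\\nu`-way
choice carries exactly :math:`\\log_2 \\nu` bits. Zero probabilities follow
the :math:`0 \\log 0 = 0` convention.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "FiniteDistribution",
    "JointDistribution",
    "entropy",
    "conditional_entropy",
    "entropy_distance",
    "joint_entropy",
    "mutual_information",
    "empirical_joint",
    "empirical_distribution",
]

_ATOL = 1e-9


class DistributionError(ValueError):
    """Raised when probability data violate distribution invariants."""


def _validate_probs(p: np.ndarray, *, allow_empty: bool = False) -> None:
    if p.size == 0:
        if allow_empty:
            return
        raise DistributionError("empty probability vector")
    if np.any(p < 0):
        raise DistributionError(f"negative probability: min={p.min()}")
    total = float(p.sum())
    if abs(total - 1.0) > _ATOL:
        raise DistributionError(f"probabilities sum to {total}, expected 1")


@dataclass(frozen=True)
class FiniteDistribution:
    """A probability distribution over a finite set of opaque outcomes.

    Outcomes may be any hashable symbols (memory item ids, environment state
    ids, ...). Zero-probability outcomes are permitted. An *empty*
    distribution (no outcomes at all) is allowed as a sentinel for "the
    memory registers no continuation here"; its entropy is defined as 0.
    """

    outcomes: tuple[Hashable, ...]
    probs: np.ndarray = field(repr=False)

    def __init__(self, outcomes: Iterable[Hashable], probs: Iterable[float]):
        outcomes = tuple(outcomes)
        p = np.asarray(list(probs), dtype=float)
        if len(outcomes) != p.size:
            raise DistributionError("outcomes and probs length mismatch")
        if len(set(outcomes)) != len(outcomes):
            raise DistributionError("duplicate outcomes")
        _validate_probs(p, allow_empty=True)
        object.__setattr__(self, "outcomes", outcomes)
        object.__setattr__(self, "probs", p)

    @classmethod
    def from_counts(cls, counts: dict[Hashable, float]) -> "FiniteDistribution":
        if not counts:
            return cls((), ())
        keys = sorted(counts, key=repr)
        c = np.asarray([counts[k] for k in keys], dtype=float)
        if np.any(c < 0):
            raise DistributionError("negative count")
        total = c.sum()
        if total <= 0:
            raise DistributionError("counts sum to zero")
        return cls(keys, c / total)

    @classmethod
    def uniform(cls, outcomes: Iterable[Hashable]) -> "FiniteDistribution":
        outcomes = tuple(outcomes)
        n = len(outcomes)
        return cls(outcomes, np.full(n, 1.0 / n) if n else ())

    @property
    def is_empty(self) -> bool:
        return len(self.outcomes) == 0

    def prob(self, outcome: Hashable) -> float:
        try:
            return float(self.probs[self.outcomes.index(outcome)])
        except ValueError:
            return 0.0

    def entropy(self) -> float:
        return entropy(self)

    def mode(self) -> Hashable:
        """Most probable outcome; ties broken by outcome order."""
        if self.is_empty:
            raise DistributionError("empty distribution has no mode")
        return self.outcomes[int(np.argmax(self.probs))]

    def to_dict(self) -> dict:
        return {"outcomes": list(self.outcomes), "probs": self.probs.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "FiniteDistribution":
        return cls(d["outcomes"], d["probs"])

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "FiniteDistribution":
        return cls.from_dict(json.loads(s))


@dataclass(frozen=True)
class JointDistribution:
    """A joint distribution over pairs drawn from two finite outcome sets.

    By convention the first axis indexes the environment variable ``R`` and
    the second the memory variable ``M``; all the pairwise quantities —
    conditional entropies H(R|M) and H(M|R), joint entropy H(R,M), mutual
    information I(R;M) and the entropy distance
    D_H(R,M) = H(R|M) + H(M|R) — are functions of this object.
    """

    r_outcomes: tuple[Hashable, ...]
    m_outcomes: tuple[Hashable, ...]
    probs: np.ndarray = field(repr=False)

    def __init__(
        self,
        r_outcomes: Iterable[Hashable],
        m_outcomes: Iterable[Hashable],
        probs: Iterable[Iterable[float]],
    ):
        r_outcomes = tuple(r_outcomes)
        m_outcomes = tuple(m_outcomes)
        p = np.asarray(probs, dtype=float)
        if p.ndim != 2 or p.shape != (len(r_outcomes), len(m_outcomes)):
            raise DistributionError(
                f"probs shape {p.shape} does not match outcome sets "
                f"({len(r_outcomes)}, {len(m_outcomes)})"
            )
        if len(set(r_outcomes)) != len(r_outcomes) or len(set(m_outcomes)) != len(m_outcomes):
            raise DistributionError("duplicate outcomes")
        _validate_probs(p.ravel())
        object.__setattr__(self, "r_outcomes", r_outcomes)
        object.__setattr__(self, "m_outcomes", m_outcomes)
        object.__setattr__(self, "probs", p)

    @classmethod
    def from_counts(
        cls,
        counts: dict[tuple[Hashable, Hashable], float],
    ) -> "JointDistribution":
        if not counts:
            raise DistributionError("empty count table")
        r_keys = sorted({r for r, _ in counts}, key=repr)
        m_keys = sorted({m for _, m in counts}, key=repr)
        mat = np.zeros((len(r_keys), len(m_keys)))
        for (r, m), c in counts.items():
            mat[r_keys.index(r), m_keys.index(m)] = c
        total = mat.sum()
        if total <= 0:
            raise DistributionError("counts sum to zero")
        return cls(r_keys, m_keys, mat / total)

    def marginal_r(self) -> FiniteDistribution:
        return FiniteDistribution(self.r_outcomes, self.probs.sum(axis=1))

    def marginal_m(self) -> FiniteDistribution:
        return FiniteDistribution(self.m_outcomes, self.probs.sum(axis=0))

    def conditional_r_given_m(self, m: Hashable) -> FiniteDistribution:
        """The per-realization conditional distribution p(R | M = m).

        Exposed separately because, unlike the averaged conditional entropy,
        the entropy of a *specific* slice H(R | M = m) may exceed the
        unconditional H(R): a locally uniform option set at one memory item
        can be more uncertain than the global stimulus distribution.
        """
        j = self.m_outcomes.index(m)
        col = self.probs[:, j]
        total = col.sum()
        if total <= 0:
            raise DistributionError(f"conditioning event M={m!r} has probability 0")
        return FiniteDistribution(self.r_outcomes, col / total)

    def conditional_m_given_r(self, r: Hashable) -> FiniteDistribution:
        i = self.r_outcomes.index(r)
        row = self.probs[i, :]
        total = row.sum()
        if total <= 0:
            raise DistributionError(f"conditioning event R={r!r} has probability 0")
        return FiniteDistribution(self.m_outcomes, row / total)

    def swap(self) -> "JointDistribution":
        return JointDistribution(self.m_outcomes, self.r_outcomes, self.probs.T)

    def to_dict(self) -> dict:
        return {
            "r_outcomes": list(self.r_outcomes),
            "m_outcomes": list(self.m_outcomes),
            "probs": self.probs.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "JointDistribution":
        return cls(d["r_outcomes"], d["m_outcomes"], d["probs"])

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "JointDistribution":
        return cls.from_dict(json.loads(s))


def _plugin_entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    if p.size == 0:
        return 0.0
    return float(-np.sum(p * np.log2(p))) + 0.0  # + 0.0 folds -0.0 into 0.0


def entropy(
    p: FiniteDistribution,
    *,
    miller_madow: bool = False,
    n_samples: int | None = None,
) -> float:
    """Shannon entropy H(p) in bits.

    The default is the plug-in value of the given probabilities. When the
    distribution is an empirical estimate from ``n_samples`` observations,
    ``miller_madow=True`` adds the first-order bias correction
    (k_observed - 1) / (2 n ln 2).
    """
    h = _plugin_entropy(p.probs)
    if miller_madow:
        if not n_samples or n_samples <= 0:
            raise ValueError("miller_madow correction requires n_samples > 0")
        k = int(np.count_nonzero(p.probs))
        h += (k - 1) / (2.0 * n_samples * np.log(2.0))
    return h


def joint_entropy(j: JointDistribution) -> float:
    """H(R,M): entropy of the flattened joint, in bits."""
    return _plugin_entropy(j.probs.ravel())


def conditional_entropy(
    j: JointDistribution,
    direction: Literal["R_given_M", "M_given_R"],
) -> float:
    """Averaged conditional entropy H(X|Y) = sum_y p(y) H(X|Y=y), in bits."""
    if direction == "R_given_M":
        return joint_entropy(j) - _plugin_entropy(j.probs.sum(axis=0))
    if direction == "M_given_R":
        return joint_entropy(j) - _plugin_entropy(j.probs.sum(axis=1))
    raise ValueError(f"unknown direction {direction!r}")


def entropy_distance(j: JointDistribution) -> float:
    """Entropy distance D_H(R,M) = H(R|M) + H(M|R), in bits.

    A metric on random variables (the variation of information): zero exactly
    when each variable determines the other, and H(R)+H(M) under
    independence.
    """
    return conditional_entropy(j, "R_given_M") + conditional_entropy(j, "M_given_R")


def mutual_information(j: JointDistribution) -> float:
    """I(R;M) = H(R) + H(M) - H(R,M), in bits; symmetric and >= 0."""
    return (
        _plugin_entropy(j.probs.sum(axis=1))
        + _plugin_entropy(j.probs.sum(axis=0))
        - joint_entropy(j)
    )


def empirical_distribution(
    samples: Sequence[Hashable],
) -> FiniteDistribution:
    """Plug-in (maximum-likelihood) distribution from observed symbols."""
    if len(samples) == 0:
        raise DistributionError("no samples")
    counts: dict[Hashable, float] = {}
    for s in samples:
        counts[s] = counts.get(s, 0.0) + 1.0
    return FiniteDistribution.from_counts(counts)


def empirical_joint(
    pairs: Sequence[tuple[Hashable, Hashable]],
) -> JointDistribution:
    """Plug-in joint distribution from observed (r, m) co-occurrence pairs.

    The outcome sets are the observed supports; probabilities are relative
    co-occurrence frequencies.
    """
    if len(pairs) == 0:
        raise DistributionError("no pairs")
    counts: dict[tuple[Hashable, Hashable], float] = {}
    for rm in pairs:
        r, m = rm
        counts[(r, m)] = counts.get((r, m), 0.0) + 1.0
    return JointDistribution.from_counts(counts)
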