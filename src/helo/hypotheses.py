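"""Hypothesis sets: elimination, Bayes updating and experiment selection.

A hypothesis set is a mutually exclusive, exhaustive collection of candidate
hypotheses whose probabilities sum to one.  Closed-loop experimentation
systems (robot scientists) maintain such sets over candidate explanations —
e.g. which gene was deleted from a yeast strain — and shrink them cycle by
cycle: each experiment outcome rejects one or more hypotheses, the survivors
are renormalized, and the loop stops when a single hypothesis holds the
entire probability mass.

Experiment selection trades off how informative an experiment is against its
cost.  The policy implemented here scores each candidate experiment by
expected Shannon information gain per unit cost; it is a deliberately simple,
replaceable strategy object covering the three ingredients such systems use
(current hypothesis probabilities, experiment cost, predicted information
gain).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np

from .errors import ValidationError
from .evidence import (
    EstimationMethod,
    KnowledgeBase,
    ProbabilityKind,
    ProbabilityRecord,
)

__all__ = [
    "HypothesisSet",
    "ExperimentSpec",
    "uniform_set",
    "eliminate",
    "bayes_update",
    "entropy_bits",
    "expected_information_gain",
    "select_experiment",
]

logger = logging.getLogger("helo")

_SUM_TOL = 1e-9
_COST_EPS = 1e-9


@dataclass(frozen=True)
class HypothesisSet:
    """Immutable set of hypothesis ids with a probability vector summing to 1."""

    members: Tuple[str, ...]
    probs: Tuple[float, ...]

    def __post_init__(self) -> None:
        members = tuple(self.members)
        probs = tuple(float(p) for p in self.probs)
        object.__setattr__(self, "members", members)
        object.__setattr__(self, "probs", probs)
        if len(members) == 0:
            raise ValidationError("empty hypothesis set")
        if len(set(members)) != len(members):
            raise ValidationError("hypothesis ids must be unique")
        if len(probs) != len(members):
            raise ValidationError("probs and members must have equal length")
        if any(p < 0.0 or p > 1.0 for p in probs):
            raise ValidationError("hypothesis probabilities must lie in [0, 1]")
        if abs(sum(probs) - 1.0) > _SUM_TOL:
            raise ValidationError(
                f"hypothesis probabilities sum to {sum(probs)}, expected 1"
            )

    def probability_of(self, member_id: str) -> float:
        try:
            return self.probs[self.members.index(member_id)]
        except ValueError:
            raise ValidationError(f"unknown hypothesis {member_id!r}") from None

    def as_dict(self) -> Dict[str, float]:
        return dict(zip(self.members, self.probs))


@dataclass(frozen=True)
class ExperimentSpec:
    """A candidate experiment with a cost and an outcome likelihood table.

    ``likelihood[h][o]`` is P(outcome o | hypothesis h); each hypothesis row
    must sum to one.  Costs are in arbitrary currency units.
    """

    id: str
    cost: float
    outcomes: Tuple[str, ...]
    likelihood: Mapping[str, Mapping[str, float]]

    def __post_init__(self) -> None:
        object.__setattr__(self, "outcomes", tuple(self.outcomes))
        if self.cost < 0:
            raise ValidationError("experiment cost must be nonnegative")
        if len(set(self.outcomes)) != len(self.outcomes) or not self.outcomes:
            raise ValidationError("outcomes must be non-empty and unique")
        like = {h: dict(row) for h, row in self.likelihood.items()}
        object.__setattr__(self, "likelihood", like)
        for h, row in like.items():
            if set(row) != set(self.outcomes):
                raise ValidationError(
                    f"likelihood row for {h!r} does not cover all outcomes"
                )
            if any(p < 0 for p in row.values()):
                raise ValidationError(f"negative likelihood in row {h!r}")
            if abs(sum(row.values()) - 1.0) > _SUM_TOL:
                raise ValidationError(
                    f"likelihood row for {h!r} sums to {sum(row.values())}"
                )

    def __hash__(self) -> int:  # rows are dicts; hash by identity-relevant parts
        return hash((self.id, self.cost, self.outcomes))


def _renormalize(probs: np.ndarray) -> Tuple[float, ...]:
    total = float(probs.sum())
    if total <= 0:
        raise ValidationError("zero total probability mass")
    return tuple(float(p) for p in probs / total)


def _record(
    kb: Optional[KnowledgeBase],
    hset: HypothesisSet,
    method: EstimationMethod,
    timestamp: Optional[str],
    zeros: Iterable[str] = (),
    source: Optional[str] = None,
) -> None:
    """Append posterior records for every member (and rejected ids at 0)."""
    if kb is None or timestamp is None:
        return
    for member, p in zip(hset.members, hset.probs):
        kb.attach_probability(
            member,
            ProbabilityRecord(p, ProbabilityKind.posterior, method, timestamp,
                              source=source),
        )
    for member in zeros:
        kb.attach_probability(
            member,
            ProbabilityRecord(0.0, ProbabilityKind.posterior, method, timestamp,
                              source=source),
        )


def uniform_set(member_ids: Sequence[str]) -> HypothesisSet:
    """Hypothesis set with a uniform prior 1/n over unique members."""
    members = tuple(member_ids)
    if not members:
        raise ValidationError("need at least one hypothesis")
    if len(set(members)) != len(members):
        raise ValidationError("duplicate hypothesis ids")
    n = len(members)
    probs = np.full(n, 1.0 / n)
    return HypothesisSet(members, _renormalize(probs))


def eliminate(
    hset: HypothesisSet,
    rejected_ids: Sequence[str],
    kb: Optional[KnowledgeBase] = None,
    timestamp: Optional[str] = None,
    evidence_id: Optional[str] = None,
) -> HypothesisSet:
    """Reject hypotheses and renormalize the survivors' probabilities.

    Rejected members are removed from the set.  When a ``kb`` and
    ``timestamp`` are given, every survivor gets a new posterior record
    (method ``deduction``) and every rejected hypothesis a record at 0.
    """
    rejected = set(rejected_ids)
    unknown = rejected - set(hset.members)
    if unknown:
        raise ValidationError(f"cannot reject unknown hypotheses {sorted(unknown)}")
    if rejected >= set(hset.members):
        raise ValidationError("cannot reject every hypothesis: empty hypothesis set")
    if not rejected:
        return hset
    keep = [i for i, m in enumerate(hset.members) if m not in rejected]
    survivors = tuple(hset.members[i] for i in keep)
    probs = np.array([hset.probs[i] for i in keep])
    new = HypothesisSet(survivors, _renormalize(probs))
    _record(kb, new, EstimationMethod.deduction, timestamp,
            zeros=sorted(rejected), source=evidence_id)
    return new


def bayes_update(
    hset: HypothesisSet,
    experiment: ExperimentSpec,
    observed_outcome: str,
    kb: Optional[KnowledgeBase] = None,
    timestamp: Optional[str] = None,
    evidence_id: Optional[str] = None,
) -> HypothesisSet:
    """Posterior ∝ prior × P(observed outcome | hypothesis), renormalized."""
    if observed_outcome not in experiment.outcomes:
        raise ValidationError(
            f"outcome {observed_outcome!r} not among {experiment.outcomes}"
        )
    _require_cover(hset, experiment)
    like = np.array(
        [experiment.likelihood[m][observed_outcome] for m in hset.members]
    )
    weighted = np.array(hset.probs) * like
    if weighted.sum() <= 0:
        raise ValidationError("outcome impossible under every hypothesis")
    new = HypothesisSet(hset.members, _renormalize(weighted))
    _record(kb, new, EstimationMethod.bayesian_inference, timestamp,
            source=evidence_id)
    return new


def entropy_bits(hset: HypothesisSet) -> float:
    """Shannon entropy of the set in bits, with 0·log0 := 0."""
    return float(sum(-p * math.log2(p) for p in hset.probs if p > 0.0))


def _require_cover(hset: HypothesisSet, experiment: ExperimentSpec) -> None:
    missing = set(hset.members) - set(experiment.likelihood)
    if missing:
        raise ValidationError(
            f"likelihood table missing rows for {sorted(missing)}"
        )


def expected_information_gain(
    hset: HypothesisSet, experiment: ExperimentSpec
) -> float:
    """Expected reduction in entropy (bits) from running the experiment.

    H(set) − Σ_o P(o) · H(set | o), with P(o) = Σ_h P(h) P(o|h).  Always in
    [0, H(set)] up to float rounding.
    """
    _require_cover(hset, experiment)
    prior = np.array(hset.probs)
    h_prior = entropy_bits(hset)
    expected_post = 0.0
    for outcome in experiment.outcomes:
        like = np.array([experiment.likelihood[m][outcome] for m in hset.members])
        joint = prior * like
        p_outcome = float(joint.sum())
        if p_outcome <= 0.0:
            continue
        post = joint / p_outcome
        h_post = float(sum(-p * math.log2(p) for p in post if p > 0.0))
        expected_post += p_outcome * h_post
    return max(0.0, h_prior - expected_post)


def select_experiment(
    hset: HypothesisSet, candidates: Sequence[ExperimentSpec]
) -> str:
    """Pick the candidate maximizing information gain per unit cost.

    Score is ``gain / (cost + 1e-9)``; ties (and the all-zero-gain case) are
    broken by candidate order.  Returns the chosen experiment's id.
    """
    if not candidates:
        raise ValidationError("no candidate experiments")
    scores = [
        expected_information_gain(hset, exp) / (exp.cost + _COST_EPS)
        for exp in candidates
    ]
    best = int(np.argmax(scores))
    if max(scores) <= 0.0:
        logger.warning(
            "all candidate experiments are uninformative; picking %r by order",
            candidates[best].id,
        )
    return candidates[best].id
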