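"""Probability trajectories, evidence links and the knowledge base.

Every research statement in a :class:`KnowledgeBase` carries an ordered,
append-only trajectory of :class:`ProbabilityRecord` objects.  A record is a
value in [0, 1] stamped with a kind (prior/posterior), the estimation method
that produced it, a timestamp and an optional evidence source.  Changes in
belief are always recorded as new records, never as in-place edits, so the
full history of how a probability was obtained and revised is auditable.

Evidence items are linked to statements with the supports / refutes /
disputes relations.  Belief can be transferred between hypotheses about
homologous genes in different organisms ("homological inference") via
:meth:`KnowledgeBase.homological_update`: the target's probability moves by a
link weight times the change in the source's probability, clipped to [0, 1].
The transfer rule is deliberately simple — linear, monotone and bounded — so
that each recorded step is easy to audit.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from datetime import datetime
from enum import Enum
from typing import Dict, List, Optional, Tuple

from .errors import ValidationError
from .statements import Entity, ResearchStatement

__all__ = [
    "ProbabilityKind",
    "EstimationMethod",
    "ProbabilityRecord",
    "EvidenceSourceType",
    "EvidenceItem",
    "EvidenceRelation",
    "EvidenceLink",
    "HomologyLink",
    "KnowledgeBase",
]


class ProbabilityKind(str, Enum):
    prior = "prior"
    posterior = "posterior"


class EstimationMethod(str, Enum):
    bayesian_inference = "bayesian_inference"
    expert_estimation = "expert_estimation"
    statistical_calculation = "statistical_calculation"
    deduction = "deduction"
    abduction = "abduction"
    induction = "induction"
    homological_inference = "homological_inference"


class EvidenceSourceType(str, Enum):
    publication = "publication"
    experiment = "experiment"
    database = "database"
    expert = "expert"


class EvidenceRelation(str, Enum):
    supports = "supports"
    refutes = "refutes"
    disputes = "disputes"


def _parse_timestamp(ts: str) -> datetime:
    try:
        return datetime.fromisoformat(ts)
    except (TypeError, ValueError):
        raise ValidationError(f"timestamp {ts!r} is not ISO-8601") from None


@dataclass(frozen=True)
class ProbabilityRecord:
    """One timestamped probability value with full provenance.

    ``procedure`` may name the specific algorithm or implementation that
    produced the value; ``source`` references the evidence item that
    triggered the update, when there is one.
    """

    value: float
    kind: ProbabilityKind
    method: EstimationMethod
    timestamp: str
    procedure: Optional[str] = None
    source: Optional[str] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0:
            raise ValidationError(f"probability {self.value} outside [0, 1]")
        object.__setattr__(self, "kind", ProbabilityKind(self.kind))
        object.__setattr__(self, "method", EstimationMethod(self.method))
        _parse_timestamp(self.timestamp)

    @property
    def time(self) -> datetime:
        return _parse_timestamp(self.timestamp)


@dataclass(frozen=True)
class EvidenceItem:
    id: str
    description: str
    source_type: EvidenceSourceType
    date: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("evidence id must be non-empty")
        object.__setattr__(self, "source_type", EvidenceSourceType(self.source_type))
        _parse_timestamp(self.date)


@dataclass(frozen=True)
class EvidenceLink:
    statement_id: str
    evidence_id: str
    relation: EvidenceRelation

    def __post_init__(self) -> None:
        object.__setattr__(self, "relation", EvidenceRelation(self.relation))


@dataclass(frozen=True)
class HomologyLink:
    """Directed belief-transfer channel between two hypotheses.

    ``weight`` scales how strongly a change in the source hypothesis's
    probability moves the target's (default 0.5).
    """

    source_statement_id: str
    target_statement_id: str
    weight: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.weight <= 1.0:
            raise ValidationError(f"homology weight {self.weight} outside [0, 1]")
        if self.source_statement_id == self.target_statement_id:
            raise ValidationError("homology link may not be a self-link")


class KnowledgeBase:
    """Mutable container of entities, statements, evidence and probabilities.

    Probability trajectories are append-only; :meth:`trajectory` returns the
    records sorted by timestamp with ties broken by insertion order.
    """

    def __init__(self) -> None:
        self.entities: Dict[str, Entity] = {}
        self.statements: Dict[str, ResearchStatement] = {}
        self.evidence: Dict[str, EvidenceItem] = {}
        self.links: List[EvidenceLink] = []
        self.homology_links: List[HomologyLink] = []
        self.hypothesis_sets: Dict[str, "object"] = {}
        self._trajectories: Dict[str, List[ProbabilityRecord]] = {}

    # -- population ---------------------------------------------------------

    def add_entity(self, entity: Entity) -> Entity:
        if entity.id in self.entities and self.entities[entity.id] != entity:
            raise ValidationError(f"entity id {entity.id!r} already used")
        self.entities[entity.id] = entity
        self._check_parent_chain(entity.id)
        return entity

    def _check_parent_chain(self, start: str) -> None:
        seen = set()
        cur: Optional[str] = start
        while cur is not None and cur in self.entities:
            if cur in seen:
                raise ValidationError(f"entity parent chain cycles at {cur!r}")
            seen.add(cur)
            cur = self.entities[cur].parent_id

    def add_statement(self, statement: ResearchStatement) -> ResearchStatement:
        if (
            statement.id in self.statements
            and self.statements[statement.id] != statement
        ):
            raise ValidationError(f"statement id {statement.id!r} already used")
        self.statements[statement.id] = statement
        self._trajectories.setdefault(statement.id, [])
        return statement

    def add_evidence(self, item: EvidenceItem) -> EvidenceItem:
        if item.id in self.evidence and self.evidence[item.id] != item:
            raise ValidationError(f"evidence id {item.id!r} already used")
        self.evidence[item.id] = item
        return item

    def add_homology_link(self, link: HomologyLink) -> HomologyLink:
        self._require_statement(link.source_statement_id)
        self._require_statement(link.target_statement_id)
        if link not in self.homology_links:
            self.homology_links.append(link)
        return link

    def _require_statement(self, statement_id: str) -> ResearchStatement:
        try:
            return self.statements[statement_id]
        except KeyError:
            raise ValidationError(f"unknown statement id {statement_id!r}") from None

    # -- probability trajectories -------------------------------------------

    def attach_probability(
        self, statement_id: str, record: ProbabilityRecord
    ) -> "KnowledgeBase":
        """Append a record to a statement's trajectory (never overwrites)."""
        self._require_statement(statement_id)
        if record.source is not None and record.source not in self.evidence:
            raise ValidationError(f"unknown evidence id {record.source!r}")
        self._trajectories[statement_id].append(record)
        return self

    def trajectory(self, statement_id: str) -> Tuple[ProbabilityRecord, ...]:
        """Records sorted by timestamp; equal timestamps keep insertion order."""
        self._require_statement(statement_id)
        records = self._trajectories.get(statement_id, [])
        return tuple(sorted(records, key=lambda r: r.time))

    def current_probability(self, statement_id: str) -> Optional[ProbabilityRecord]:
        """Latest record by timestamp (ties: last inserted); None if empty."""
        traj = self.trajectory(statement_id)
        return traj[-1] if traj else None

    def probability_at(
        self, statement_id: str, timestamp: str
    ) -> Optional[ProbabilityRecord]:
        """Latest record with ``record.timestamp <= timestamp``."""
        cutoff = _parse_timestamp(timestamp)
        candidates = [r for r in self.trajectory(statement_id) if r.time <= cutoff]
        return candidates[-1] if candidates else None

    # -- evidence -----------------------------------------------------------

    def link_evidence(
        self,
        statement_id: str,
        evidence_id: str,
        relation: EvidenceRelation | str,
    ) -> "KnowledgeBase":
        """Record an evidence link; duplicate identical links are ignored."""
        self._require_statement(statement_id)
        if evidence_id not in self.evidence:
            raise ValidationError(f"unknown evidence id {evidence_id!r}")
        link = EvidenceLink(statement_id, evidence_id, EvidenceRelation(relation))
        if link not in self.links:
            self.links.append(link)
        return self

    def evidence_for(
        self, statement_id: str
    ) -> Dict[EvidenceRelation, List[EvidenceItem]]:
        """Evidence items linked to a statement, grouped by relation."""
        self._require_statement(statement_id)
        out: Dict[EvidenceRelation, List[EvidenceItem]] = {
            rel: [] for rel in EvidenceRelation
        }
        for link in self.links:
            if link.statement_id == statement_id:
                out[link.relation].append(self.evidence[link.evidence_id])
        return out

    # -- homological inference ----------------------------------------------

    def homological_update(
        self,
        link: HomologyLink,
        new_source_prob: float,
        timestamp: str,
        evidence_id: Optional[str] = None,
        source_method: EstimationMethod = EstimationMethod.bayesian_inference,
    ) -> ProbabilityRecord:
        """Propagate a source-hypothesis probability change to its homolog.

        The source statement first receives a posterior record with
        ``new_source_prob``.  The target then receives a posterior record with
        value ``clip(p_target + weight * (new_source_prob - p_source_old), 0, 1)``
        and method ``homological_inference``.  Both endpoints must already
        carry at least one probability record.  Returns the new target record.
        """
        if not 0.0 <= new_source_prob <= 1.0:
            raise ValidationError(f"probability {new_source_prob} outside [0, 1]")
        src = self._require_statement(link.source_statement_id)
        tgt = self._require_statement(link.target_statement_id)
        old_src = self.current_probability(src.id)
        old_tgt = self.current_probability(tgt.id)
        if old_src is None or old_tgt is None:
            raise ValidationError(
                "both endpoints need a probability record before a homological "
                "update; seed priors first"
            )
        self.attach_probability(
            src.id,
            ProbabilityRecord(
                value=new_source_prob,
                kind=ProbabilityKind.posterior,
                method=source_method,
                timestamp=timestamp,
                source=evidence_id,
            ),
        )
        delta = link.weight * (new_source_prob - old_src.value)
        new_value = min(1.0, max(0.0, old_tgt.value + delta))
        record = ProbabilityRecord(
            value=new_value,
            kind=ProbabilityKind.posterior,
            method=EstimationMethod.homological_inference,
            timestamp=timestamp,
            procedure=f"linear transfer, weight={link.weight}",
            source=evidence_id,
        )
        self.attach_probability(tgt.id, record)
        return record

    # -- misc ----------------------------------------------------------------

    def copy(self) -> "KnowledgeBase":
        return copy.deepcopy(self)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KnowledgeBase):
            return NotImplemented
        return (
            self.entities == other.entities
            and self.statements == other.statements
            and self.evidence == other.evidence
            and set(self.links) == set(other.links)
            and set(self.homology_links) == set(other.homology_links)
            and self.hypothesis_sets == other.hypothesis_sets
            and {k: v for k, v in self._trajectories.items() if v}
            == {k: v for k, v in other._trajectories.items() if v}
        )

    def __repr__(self) -> str:
        return (
            f"KnowledgeBase(statements={len(self.statements)}, "
            f"evidence={len(self.evidence)}, links={len(self.links)})"
        )
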