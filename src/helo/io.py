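"""Knowledge-base JSON serialization and compound-library file handling.

The working format is plain JSON (lightly JSON-LD flavoured: every object
carries a ``helo_class`` string naming its ontology class, and the document
an ``@context`` IRI) rather than OWL/RDF — the reasoning engines need a data
format, not a description-logic file.  ``import_kb(export_kb(kb))`` is the
identity, and exports are byte-deterministic: arrays are sorted by id and
keys are sorted.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Dict, Union

import pandas as pd

from .active import ActiveRunResult, CompoundLibrary
from .errors import ValidationError
from .evidence import (
    EstimationMethod,
    EvidenceItem,
    EvidenceRelation,
    KnowledgeBase,
    ProbabilityKind,
    ProbabilityRecord,
)
from .hypotheses import HypothesisSet
from .statements import (
    Entity,
    ResearchStatement,
    StatementRole,
    parse_statement,
    render,
)

__all__ = [
    "SCHEMA_VERSION",
    "export_kb",
    "import_kb",
    "save_kb",
    "load_kb",
    "load_library_csv",
    "write_library_csv",
    "run_result_to_json",
]

SCHEMA_VERSION = "1.0"
CONTEXT_IRI = "https://github.com/larisa-soldatova/HELO"

_ROLE_CLASS = {
    StatementRole.research_hypothesis: "research hypothesis",
    StatementRole.assumption: "assumption",
    StatementRole.conclusion: "conclusion",
    StatementRole.scientific_law: "scientific law",
    StatementRole.theorem: "theorem",
}
_KIND_CLASS = {
    ProbabilityKind.prior: "prior probability",
    ProbabilityKind.posterior: "posterior probability",
}
_METHOD_CLASS = {
    EstimationMethod.bayesian_inference: "Bayesian inference",
    EstimationMethod.expert_estimation: "expert estimation",
    EstimationMethod.statistical_calculation: "statistical calculation",
    EstimationMethod.deduction: "deduction",
    EstimationMethod.abduction: "abduction",
    EstimationMethod.induction: "induction",
    EstimationMethod.homological_inference: "homological inference",
}
_RELATION_CLASS = {
    EvidenceRelation.supports: "HAS-SUPPORTING-EVIDENCE",
    EvidenceRelation.refutes: "HAS-REFUTING-EVIDENCE",
    EvidenceRelation.disputes: "HAS-DISPUTING-EVIDENCE",
}
_KNOWN_CLASSES = (
    set(_ROLE_CLASS.values())
    | set(_KIND_CLASS.values())
    | set(_RELATION_CLASS.values())
    | {"entity", "evidence", "hypotheses set", "homological inference"}
)


def export_kb(kb: KnowledgeBase) -> str:
    """Serialize a knowledge base to deterministic JSON text."""
    doc = {
        "@context": CONTEXT_IRI,
        "schema_version": SCHEMA_VERSION,
        "entities": [
            {
                "id": e.id,
                "label": e.label,
                "source_ontology": e.source_ontology,
                "parent_id": e.parent_id,
                "helo_class": "entity",
            }
            for e in sorted(kb.entities.values(), key=lambda e: e.id)
        ],
        "statements": [
            {
                "id": s.id,
                "expression": render(s.expression),
                "role": s.role.value,
                "free_text": s.free_text,
                "helo_class": _ROLE_CLASS[s.role],
            }
            for s in sorted(kb.statements.values(), key=lambda s: s.id)
        ],
        "evidence": [
            {
                "id": e.id,
                "description": e.description,
                "source_type": e.source_type.value,
                "date": e.date,
                "helo_class": "evidence",
            }
            for e in sorted(kb.evidence.values(), key=lambda e: e.id)
        ],
        "links": [
            {
                "statement_id": l.statement_id,
                "evidence_id": l.evidence_id,
                "relation": l.relation.value,
                "helo_class": _RELATION_CLASS[l.relation],
            }
            for l in sorted(
                kb.links, key=lambda l: (l.statement_id, l.evidence_id,
                                         l.relation.value)
            )
        ],
        "homology_links": [
            {
                "source_statement_id": h.source_statement_id,
                "target_statement_id": h.target_statement_id,
                "weight": h.weight,
                "helo_class": "homological inference",
            }
            for h in sorted(
                kb.homology_links,
                key=lambda h: (h.source_statement_id, h.target_statement_id),
            )
        ],
        "probability_records": [
            {
                "statement_id": sid,
                "value": r.value,
                "kind": r.kind.value,
                "method": r.method.value,
                "procedure": r.procedure,
                "timestamp": r.timestamp,
                "source": r.source,
                "helo_class": _KIND_CLASS[r.kind],
            }
            for sid in sorted(kb.statements)
            for r in kb._trajectories.get(sid, [])
        ],
        "hypothesis_sets": [
            {
                "id": hid,
                "members": list(hs.members),
                "probs": list(hs.probs),
                "helo_class": "hypotheses set",
            }
            for hid, hs in sorted(kb.hypothesis_sets.items())
        ],
    }
    return json.dumps(doc, indent=2, sort_keys=True, ensure_ascii=False) + "\n"


def _check_class(obj: dict, context: str) -> None:
    cls = obj.get("helo_class")
    if cls is not None and cls not in _KNOWN_CLASSES:
        warnings.warn(
            f"unknown helo_class {cls!r} on {context}; object preserved",
            stacklevel=3,
        )


def import_kb(document: Union[str, dict]) -> KnowledgeBase:
    """Parse and validate a knowledge-base JSON document.

    All invariants are enforced on load: probabilities in bounds, known
    relation names, referential integrity (dangling references raise a
    :class:`ValidationError` naming the missing id).  Unknown ``helo_class``
    strings only produce a warning.
    """
    if isinstance(document, str):
        document = json.loads(document)
    if "schema_version" not in document:
        raise ValidationError("document is missing schema_version")
    kb = KnowledgeBase()
    for obj in document.get("entities", []):
        _check_class(obj, f"entity {obj.get('id')!r}")
        kb.add_entity(
            Entity(
                id=obj["id"],
                label=obj.get("label", ""),
                source_ontology=obj.get("source_ontology"),
                parent_id=obj.get("parent_id"),
            )
        )
    for eid, entity in kb.entities.items():
        if entity.parent_id is not None and entity.parent_id not in kb.entities:
            raise ValidationError(
                f"entity {eid!r} references missing parent {entity.parent_id!r}"
            )
    for obj in document.get("statements", []):
        _check_class(obj, f"statement {obj.get('id')!r}")
        try:
            role = StatementRole(obj.get("role", "research_hypothesis"))
        except ValueError:
            raise ValidationError(
                f"unknown statement role {obj.get('role')!r}"
            ) from None
        kb.add_statement(
            ResearchStatement(
                id=obj["id"],
                expression=parse_statement(obj["expression"], kb.entities),
                role=role,
                free_text=obj.get("free_text"),
            )
        )
    for obj in document.get("evidence", []):
        _check_class(obj, f"evidence {obj.get('id')!r}")
        try:
            kb.add_evidence(
                EvidenceItem(
                    id=obj["id"],
                    description=obj.get("description", ""),
                    source_type=obj["source_type"],
                    date=obj["date"],
                )
            )
        except ValueError as exc:
            raise ValidationError(str(exc)) from None
    for obj in document.get("links", []):
        _check_class(obj, "evidence link")
        try:
            relation = EvidenceRelation(obj["relation"])
        except ValueError:
            raise ValidationError(
                f"unknown evidence relation {obj['relation']!r}"
            ) from None
        kb.link_evidence(obj["statement_id"], obj["evidence_id"], relation)
    for obj in document.get("homology_links", []):
        _check_class(obj, "homology link")
        from .evidence import HomologyLink

        kb.add_homology_link(
            HomologyLink(
                source_statement_id=obj["source_statement_id"],
                target_statement_id=obj["target_statement_id"],
                weight=obj.get("weight", 0.5),
            )
        )
    for obj in document.get("probability_records", []):
        _check_class(obj, f"probability record on {obj.get('statement_id')!r}")
        try:
            record = ProbabilityRecord(
                value=obj["value"],
                kind=obj["kind"],
                method=obj["method"],
                timestamp=obj["timestamp"],
                procedure=obj.get("procedure"),
                source=obj.get("source"),
            )
        except ValueError as exc:
            raise ValidationError(str(exc)) from None
        kb.attach_probability(obj["statement_id"], record)
    for obj in document.get("hypothesis_sets", []):
        _check_class(obj, f"hypothesis set {obj.get('id')!r}")
        for member in obj["members"]:
            if member not in kb.statements:
                raise ValidationError(
                    f"hypothesis set {obj['id']!r} references missing "
                    f"statement {member!r}"
                )
        kb.hypothesis_sets[obj["id"]] = HypothesisSet(
            tuple(obj["members"]), tuple(obj["probs"])
        )
    return kb


def save_kb(kb: KnowledgeBase, path: Union[str, Path]) -> None:
    Path(path).write_text(export_kb(kb), encoding="utf-8")


def load_kb(path: Union[str, Path]) -> KnowledgeBase:
    return import_kb(Path(path).read_text(encoding="utf-8"))


# ---------------------------------------------------------------------------
# Compound libraries and run results
# ---------------------------------------------------------------------------


def load_library_csv(path: Union[str, Path], sep: str = ",") -> CompoundLibrary:
    """Read a library table: compound_id, feature columns, optional activity.

    Every column other than ``compound_id`` and ``activity`` is treated as a
    numeric feature.  Use ``sep='\\t'`` for TSV.
    """
    frame = pd.read_csv(path, sep=sep)
    if "compound_id" not in frame.columns:
        raise ValidationError("library file needs a compound_id column")
    feature_cols = [c for c in frame.columns if c not in ("compound_id", "activity")]
    if not feature_cols:
        raise ValidationError("library file has no feature columns")
    activity = (
        frame["activity"].to_numpy(dtype=float)
        if "activity" in frame.columns
        else None
    )
    return CompoundLibrary(
        compound_ids=[str(c) for c in frame["compound_id"]],
        features=frame[feature_cols].to_numpy(dtype=float),
        true_activity=activity,
    )


def write_library_csv(
    library: CompoundLibrary, path: Union[str, Path], sep: str = ","
) -> None:
    data = {"compound_id": library.compound_ids}
    for j in range(library.n_features):
        data[f"feature_{j + 1}"] = library.features[:, j]
    if library.true_activity is not None:
        data["activity"] = library.true_activity
    pd.DataFrame(data).to_csv(path, sep=sep, index=False)


def run_result_to_json(result: ActiveRunResult) -> str:
    """Serialize an active-screening run (per-iteration log plus summary)."""
    doc = {
        "strategy": result.strategy,
        "k": result.k,
        "bootstrap_ids": result.bootstrap_ids,
        "iterations": [
            {
                "n_measured": r.n_measured,
                "selected_id": r.selected_id,
                "score": r.score,
                "P1": r.p_improve_bootstrap,
                "P2": r.p_improve_current,
                "P3": r.p_max_remaining,
            }
            for r in result.records
        ],
        "top_k": result.top_k,
        "best_found": result.best_found,
    }
    return json.dumps(doc, indent=2) + "\n"
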