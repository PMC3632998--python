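"""Research statements as logical expressions over ontology-style entities.

A research statement is either an atomic relation ``predicate(subject, object)``
between two entities, or a tree of such atoms combined with the propositional
connectives AND, OR, NOT, IMPLIES, IFF.  Statements are immutable values with
structural identity: two statements are equal when their expression trees are
equal, except that operand order is ignored for the commutative connectives
AND and OR.

Generality is expressed by substituting an entity with a more generic one
(e.g. a specific gene replaced by a Gene Ontology parent class) rather than by
quantification; see :func:`substitute_entity`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Mapping, Optional, Union

from .errors import ValidationError

__all__ = [
    "Connective",
    "Entity",
    "AtomicStatement",
    "CompoundStatement",
    "Statement",
    "StatementRole",
    "ResearchStatement",
    "make_atomic",
    "combine",
    "substitute_entity",
    "evaluate_statement",
    "iter_atoms",
    "render",
    "render_infix",
    "parse_statement",
]


class Connective(str, Enum):
    AND = "AND"
    OR = "OR"
    NOT = "NOT"
    IMPLIES = "IMPLIES"
    IFF = "IFF"


#: (min, max) operand counts per connective; ``None`` means unbounded.
_ARITY: dict[Connective, tuple[int, Optional[int]]] = {
    Connective.NOT: (1, 1),
    Connective.IMPLIES: (2, 2),
    Connective.IFF: (2, 2),
    Connective.AND: (2, None),
    Connective.OR: (2, None),
}

_INFIX_SYMBOL = {
    Connective.AND: "∧",
    Connective.OR: "∨",
    Connective.IMPLIES: "→",
    Connective.IFF: "↔",
}


@dataclass(frozen=True)
class Entity:
    """A class or instance from a domain ontology (or an ad-hoc identifier).

    ``parent_id`` points at a more generic entity (e.g. a GO parent class) and
    drives generalization via :func:`substitute_entity`.
    """

    id: str
    label: str = ""
    source_ontology: Optional[str] = None
    parent_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("entity id must be non-empty")


@dataclass(frozen=True, eq=False)
class AtomicStatement:
    """``predicate(subject, object)`` over two ontology entities."""

    predicate: str
    subject: Entity
    object: Entity

    def __post_init__(self) -> None:
        if not self.predicate:
            raise ValidationError("predicate must be non-empty")

    def key(self) -> tuple:
        return ("atom", self.predicate, self.subject.id, self.object.id)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, (AtomicStatement, CompoundStatement)):
            return NotImplemented
        return self.key() == other.key()

    def __hash__(self) -> int:
        return hash(self.key())

    def __repr__(self) -> str:
        return f"<{render(self)}>"


@dataclass(frozen=True, eq=False)
class CompoundStatement:
    """A connective applied to an ordered list of operand statements.

    Operand order is preserved for display, but equality ignores order for
    the commutative connectives AND and OR.
    """

    connective: Connective
    operands: tuple["Statement", ...]

    def __post_init__(self) -> None:
        conn = Connective(self.connective)
        object.__setattr__(self, "connective", conn)
        object.__setattr__(self, "operands", tuple(self.operands))
        lo, hi = _ARITY[conn]
        n = len(self.operands)
        if n < lo or (hi is not None and n > hi):
            bound = f"exactly {lo}" if hi == lo else f"at least {lo}"
            raise ValidationError(
                f"{conn.value} takes {bound} operand(s), got {n}"
            )
        for op in self.operands:
            if not isinstance(op, (AtomicStatement, CompoundStatement)):
                raise ValidationError(f"operand {op!r} is not a statement")

    def key(self) -> tuple:
        child = tuple(op.key() for op in self.operands)
        if self.connective in (Connective.AND, Connective.OR):
            child = tuple(sorted(child))
        return ("comp", self.connective.value, child)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, (AtomicStatement, CompoundStatement)):
            return NotImplemented
        return self.key() == other.key()

    def __hash__(self) -> int:
        return hash(self.key())

    def __repr__(self) -> str:
        return f"<{render(self)}>"


Statement = Union[AtomicStatement, CompoundStatement]


class StatementRole(str, Enum):
    """Where a statement sits in the research-statement hierarchy."""

    research_hypothesis = "research_hypothesis"
    assumption = "assumption"
    conclusion = "conclusion"
    scientific_law = "scientific_law"
    theorem = "theorem"


@dataclass(frozen=True)
class ResearchStatement:
    """A statement with an identity, a hierarchy role and optional free text.

    Production-rule laws (``statement_i IMPLIES statement_j``) are
    ResearchStatements whose role is ``scientific_law`` and whose expression
    is an IMPLIES compound.
    """

    id: str
    expression: Statement
    role: StatementRole = StatementRole.research_hypothesis
    free_text: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("statement id must be non-empty")
        object.__setattr__(self, "role", StatementRole(self.role))


def make_atomic(predicate: str, subject: Entity, object: Entity) -> AtomicStatement:
    """Build a canonical atomic statement ``predicate(subject, object)``."""
    return AtomicStatement(predicate, subject, object)


def combine(connective: Union[Connective, str], operands: list) -> CompoundStatement:
    """Combine statements with a connective, validating arity."""
    return CompoundStatement(Connective(connective), tuple(operands))


def substitute_entity(stmt: Statement, old: Entity, new: Entity) -> Statement:
    """Return a copy of ``stmt`` with every occurrence of ``old`` replaced.

    Typical use is generalization: replacing a specific gene entity by its
    parent ontology class.  The input statement is never modified; zero
    occurrences returns an equal statement.
    """
    if isinstance(stmt, AtomicStatement):
        subj = new if stmt.subject == old else stmt.subject
        obj = new if stmt.object == old else stmt.object
        return AtomicStatement(stmt.predicate, subj, obj)
    return CompoundStatement(
        stmt.connective,
        tuple(substitute_entity(op, old, new) for op in stmt.operands),
    )


def iter_atoms(stmt: Statement) -> Iterator[AtomicStatement]:
    """Yield every atomic leaf of ``stmt`` (duplicates included)."""
    if isinstance(stmt, AtomicStatement):
        yield stmt
    else:
        for op in stmt.operands:
            yield from iter_atoms(op)


def evaluate_statement(
    stmt: Statement, assignment: Mapping[AtomicStatement, bool]
) -> bool:
    """Evaluate ``stmt`` under a truth assignment of its atoms.

    Standard propositional semantics; every atom occurring in the statement
    must be a key of ``assignment``.
    """
    if isinstance(stmt, AtomicStatement):
        try:
            return bool(assignment[stmt])
        except KeyError:
            raise ValidationError(
                f"no truth value assigned to atom {render(stmt)}"
            ) from None
    vals = [evaluate_statement(op, assignment) for op in stmt.operands]
    conn = stmt.connective
    if conn is Connective.AND:
        return all(vals)
    if conn is Connective.OR:
        return any(vals)
    if conn is Connective.NOT:
        return not vals[0]
    if conn is Connective.IMPLIES:
        return (not vals[0]) or vals[1]
    return vals[0] == vals[1]  # IFF


def render(stmt: Statement) -> str:
    """Render to the plain-text prefix syntax, e.g. ``AND(p(a, b), q(c, d))``."""
    if isinstance(stmt, AtomicStatement):
        return f"{stmt.predicate}({stmt.subject.id}, {stmt.object.id})"
    inner = ", ".join(render(op) for op in stmt.operands)
    return f"{stmt.connective.value}({inner})"


def render_infix(stmt: Statement) -> str:
    """Human-oriented rendering with logical symbols, e.g. ``(a ∧ b) → c``."""
    if isinstance(stmt, AtomicStatement):
        return render(stmt)
    if stmt.connective is Connective.NOT:
        return f"¬{render_infix(stmt.operands[0])}"
    sym = _INFIX_SYMBOL[stmt.connective]
    inner = f" {sym} ".join(render_infix(op) for op in stmt.operands)
    return f"({inner})"


_TOKEN_RE = re.compile(r"[A-Za-z0-9_\-.:]+|[(),]")
_NAME_RE = re.compile(r"[A-Za-z0-9_\-.:]+\Z")
_CONNECTIVE_NAMES = {c.value for c in Connective}


def parse_statement(
    text: str, entities: Optional[Mapping[str, Entity]] = None
) -> Statement:
    """Parse the prefix text syntax back into a statement tree.

    If ``entities`` is given, every entity id in the text must resolve in it
    (a missing id raises :class:`ValidationError` naming the id); otherwise
    bare entities are created on the fly with ``label == id``.
    """
    tokens = _TOKEN_RE.findall(text)
    if "".join(tokens).replace(" ", "") != re.sub(r"\s+", "", text):
        raise ValidationError(f"unparseable characters in statement: {text!r}")
    pos = 0

    def peek() -> Optional[str]:
        return tokens[pos] if pos < len(tokens) else None

    def take(expected: Optional[str] = None) -> str:
        nonlocal pos
        if pos >= len(tokens):
            raise ValidationError(f"unexpected end of statement: {text!r}")
        tok = tokens[pos]
        if expected is not None and tok != expected:
            raise ValidationError(f"expected {expected!r}, got {tok!r} in {text!r}")
        pos += 1
        return tok

    def resolve(entity_id: str) -> Entity:
        if entities is None:
            return Entity(id=entity_id, label=entity_id)
        try:
            return entities[entity_id]
        except KeyError:
            raise ValidationError(f"unknown entity id {entity_id!r}") from None

    def expr() -> Statement:
        name = take()
        if not _NAME_RE.match(name):
            raise ValidationError(f"expected a name, got {name!r} in {text!r}")
        take("(")
        if name in _CONNECTIVE_NAMES:
            operands = [expr()]
            while peek() == ",":
                take(",")
                operands.append(expr())
            take(")")
            return combine(name, operands)
        subj = take()
        take(",")
        obj = take()
        take(")")
        return make_atomic(name, resolve(subj), resolve(obj))

    out = expr()
    if pos != len(tokens):
        raise ValidationError(f"trailing tokens after statement: {text!r}")
    return out
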