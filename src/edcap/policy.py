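"""The identification-policy language.

Servers (and each group on a server) carry two boolean policies over the
presence of identity attributes: an *upload* policy, the minimum a subject
record must satisfy before a client may send data at all, and a stricter
*finalizing* policy, required before records may be moved permanently to
the server and erased from the device.

Policies are plain text such as::

    sex AND idnum1
    sex AND idnum1 AND NOT (forename OR surname OR dob)
    forename AND surname AND dob AND sex AND (idnum1 OR idnum2 OR idnum3)

Grammar (case-insensitive tokens, precedence NOT > AND > OR,
left-associative)::

    expr   := term (OR term)*
    term   := factor (AND factor)*
    factor := NOT factor | "(" expr ")" | ATTR

Attributes are the identity field names (forename, surname, dob, sex,
address, email, gp, otherdetails), ``idnumN`` for configured ID number
type N, and the pseudo-attribute ``anyidnum`` (true when any ID number at
all is present) provided as an extension point.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Iterator, Optional, Sequence

from .identity import PatientRecord

__all__ = [
    "PolicyError",
    "PolicySyntaxError",
    "UnknownTokenError",
    "Node",
    "Attr",
    "And",
    "Or",
    "Not",
    "IdPolicy",
    "parse_policy",
    "evaluate_policy",
]

BASE_ATTRS = frozenset(
    {"forename", "surname", "dob", "sex", "address", "email", "gp",
     "otherdetails", "anyidnum"}
)

_IDNUM_RE = re.compile(r"^idnum(\d+)$")
_TOKEN_RE = re.compile(r"\(|\)|[A-Za-z_][A-Za-z0-9_]*|\S")


class PolicyError(ValueError):
    """Base class for policy-language errors."""


class PolicySyntaxError(PolicyError):
    pass


class UnknownTokenError(PolicyError):
    def __init__(self, token: str):
        super().__init__(f"unknown policy token: {token!r}")
        self.token = token


# ---------------------------------------------------------------- AST nodes

@dataclass(frozen=True)
class Node:
    def evaluate(self, patient: PatientRecord) -> bool:  # pragma: no cover
        raise NotImplementedError

    def attributes(self) -> frozenset[str]:  # pragma: no cover
        raise NotImplementedError


@dataclass(frozen=True)
class Attr(Node):
    name: str

    def evaluate(self, patient: PatientRecord) -> bool:
        return patient.has(self.name)

    def attributes(self) -> frozenset[str]:
        return frozenset({self.name})


@dataclass(frozen=True)
class And(Node):
    operands: tuple[Node, ...]

    def evaluate(self, patient: PatientRecord) -> bool:
        return all(op.evaluate(patient) for op in self.operands)

    def attributes(self) -> frozenset[str]:
        return frozenset().union(*(op.attributes() for op in self.operands))


@dataclass(frozen=True)
class Or(Node):
    operands: tuple[Node, ...]

    def evaluate(self, patient: PatientRecord) -> bool:
        return any(op.evaluate(patient) for op in self.operands)

    def attributes(self) -> frozenset[str]:
        return frozenset().union(*(op.attributes() for op in self.operands))


@dataclass(frozen=True)
class Not(Node):
    operand: Node

    def evaluate(self, patient: PatientRecord) -> bool:
        return not self.operand.evaluate(patient)

    def attributes(self) -> frozenset[str]:
        return self.operand.attributes()


def _serialize(node: Node, parent_prec: int = 0) -> str:
    # precedence: OR=1, AND=2, NOT=3, ATTR=4
    if isinstance(node, Attr):
        return node.name
    if isinstance(node, Not):
        inner = _serialize(node.operand, 3)
        text, prec = f"NOT {inner}", 3
    elif isinstance(node, And):
        text = " AND ".join(_serialize(op, 2) for op in node.operands)
        prec = 2
    elif isinstance(node, Or):
        text = " OR ".join(_serialize(op, 1) for op in node.operands)
        prec = 1
    else:  # pragma: no cover
        raise TypeError(f"not a policy node: {node!r}")
    if prec < parent_prec:
        return f"({text})"
    return text


@dataclass(frozen=True)
class IdPolicy:
    """A parsed identification policy."""

    source_text: str
    ast: Node
    flavor: str = "upload"  # "upload" or "finalize"

    def to_text(self) -> str:
        """Canonical text form; re-parsing it yields a structurally equal AST."""
        return _serialize(self.ast)

    def attributes(self) -> frozenset[str]:
        return self.ast.attributes()

    def satisfied_by(self, patient: PatientRecord) -> bool:
        return self.ast.evaluate(patient)


# ------------------------------------------------------------------- parser

def _tokenize(text: str) -> list[str]:
    tokens = []
    for match in _TOKEN_RE.finditer(text):
        tok = match.group(0)
        if tok not in "()" and not re.match(r"^[A-Za-z_][A-Za-z0-9_]*$", tok):
            raise PolicySyntaxError(f"unexpected character {tok!r}")
        tokens.append(tok if tok in "()" else tok.lower())
    return tokens


class _Parser:
    def __init__(self, tokens: Sequence[str], known_idnums: Optional[set[int]],
                 strict_idnums: bool):
        self.tokens = list(tokens)
        self.pos = 0
        self.known_idnums = known_idnums
        self.strict_idnums = strict_idnums

    def peek(self) -> Optional[str]:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise PolicySyntaxError("unexpected end of policy (dangling operator?)")
        self.pos += 1
        return tok

    def parse(self) -> Node:
        node = self.expr()
        if self.peek() is not None:
            raise PolicySyntaxError(f"unexpected token {self.peek()!r}")
        return node

    @staticmethod
    def _flatten(cls, operands: list[Node]) -> Node:
        # AND/OR are associative; flattening makes the AST canonical, so
        # "(a AND b) AND c" and "a AND b AND c" parse identically and
        # serialization round-trips structurally.
        if len(operands) == 1:
            return operands[0]
        flat: list[Node] = []
        for op in operands:
            if isinstance(op, cls):
                flat.extend(op.operands)
            else:
                flat.append(op)
        return cls(tuple(flat))

    def expr(self) -> Node:
        operands = [self.term()]
        while self.peek() == "or":
            self.next()
            operands.append(self.term())
        return self._flatten(Or, operands)

    def term(self) -> Node:
        operands = [self.factor()]
        while self.peek() == "and":
            self.next()
            operands.append(self.factor())
        return self._flatten(And, operands)

    def factor(self) -> Node:
        tok = self.next()
        if tok == "not":
            return Not(self.factor())
        if tok == "(":
            node = self.expr()
            if self.next() != ")":
                raise PolicySyntaxError("unbalanced parentheses")
            return node
        if tok == ")":
            raise PolicySyntaxError("unbalanced parentheses")
        if tok in ("and", "or"):
            raise PolicySyntaxError(f"dangling operator {tok.upper()!r}")
        return self._attr(tok)

    def _attr(self, tok: str) -> Attr:
        if tok in BASE_ATTRS:
            return Attr(tok)
        m = _IDNUM_RE.match(tok)
        if m:
            which = int(m.group(1))
            if which < 1:
                raise UnknownTokenError(tok)
            if self.known_idnums is not None and which not in self.known_idnums:
                msg = f"policy references unconfigured ID number type {which}"
                if self.strict_idnums:
                    raise UnknownTokenError(tok)
                warnings.warn(msg, stacklevel=4)
            return Attr(tok)
        raise UnknownTokenError(tok)


def parse_policy(
    source_text: str,
    flavor: str = "upload",
    known_idnums: Optional[set[int]] = None,
    strict_idnums: bool = False,
) -> IdPolicy:
    """Parse policy text into an :class:`IdPolicy`.

    Parameters
    ----------
    source_text:
        The policy expression; tokens are case-insensitive.
    flavor:
        ``"upload"`` or ``"finalize"`` (informational).
    known_idnums:
        If given, ``idnumN`` tokens with N outside this set either warn
        (default) or raise, per ``strict_idnums``.  If None, any positive N
        is accepted.
    """
    if flavor not in ("upload", "finalize"):
        raise ValueError("flavor must be 'upload' or 'finalize'")
    if not source_text or not source_text.strip():
        raise PolicySyntaxError("empty policy")
    tokens = _tokenize(source_text)
    ast = _Parser(tokens, known_idnums, strict_idnums).parse()
    return IdPolicy(source_text=source_text, ast=ast, flavor=flavor)


def evaluate_policy(policy: IdPolicy, patient: PatientRecord) -> bool:
    """True iff the patient record satisfies the policy.

    An absent field is simply false; evaluation never errors on missing
    information.
    """
    return policy.satisfied_by(patient)
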