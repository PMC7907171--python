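"""Boolean program trees over the robot's 12-variable vocabulary.

A wall-following controller is a boolean expression over eight
wall-contact sensors (``n``, ``ne``, ``e``, ``se``, ``s``, ``sw``, ``w``,
``nw``) and four move indicators (``north``, ``east``, ``south``,
``west``), built from ``If``, ``&&``, ``||``, ``!`` and the constants
``True``/``False`` (a Mathematica-flavoured dialect).  This module
provides the grammar, parser, serializer, evaluator, and the exhaustive
semantic fingerprint: a program's *truth vector*, its output on all
2^12 = 4,096 assignments.  Two programs are semantically equivalent iff
their truth vectors are identical; the number of positions where two
vectors differ is the disagreement count used throughout the package.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Mapping

import numpy as np

__all__ = [
    "VARIABLES",
    "N_STATES",
    "BoolExpr",
    "ParseError",
    "var",
    "const",
    "not_",
    "and_",
    "or_",
    "if_",
    "parse_expression",
    "serialize",
    "evaluate",
    "evaluate_on_columns",
    "truth_vector",
    "assignment_from_index",
    "disagreement_count",
    "support_variables",
    "read_program",
    "write_program",
    "write_truth_vector",
    "read_truth_vector",
]

#: Fixed variable enumeration order.  Assignment ``i`` (0 <= i < 4096) binds
#: the variables to the 12-bit binary expansion of ``i`` with ``n`` as the
#: most significant bit and ``west`` as the least significant bit.
VARIABLES: tuple[str, ...] = (
    "n", "ne", "e", "se", "s", "sw", "w", "nw",
    "north", "east", "south", "west",
)

N_STATES = 1 << len(VARIABLES)  # 4,096

_VAR_INDEX = {name: i for i, name in enumerate(VARIABLES)}

_ARITY = {"var": 0, "const": 0, "not": 1, "and": 2, "or": 2, "if": 3}


class BoolExpr:
    """Immutable expression tree node.

    ``kind`` is one of ``var``, ``const``, ``not``, ``and``, ``or``,
    ``if``; ``children`` holds 0, 1, 2 or 3 sub-expressions accordingly;
    ``name`` is set for variable leaves and ``value`` for constant leaves.
    """

    __slots__ = ("kind", "children", "name", "value", "_hash")

    def __init__(self, kind: str, children: tuple["BoolExpr", ...] = (),
                 name: str | None = None, value: bool | None = None):
        if kind not in _ARITY:
            raise ValueError(f"unknown node kind {kind!r}")
        if len(children) != _ARITY[kind]:
            raise ValueError(
                f"{kind} node requires {_ARITY[kind]} children, got {len(children)}")
        if kind == "var":
            if name not in _VAR_INDEX:
                raise ValueError(f"unknown variable {name!r}")
        elif name is not None:
            raise ValueError("only variable nodes carry a name")
        if kind == "const":
            if not isinstance(value, bool):
                raise ValueError("constant nodes require a bool value")
        elif value is not None:
            raise ValueError("only constant nodes carry a value")
        object.__setattr__(self, "kind", kind)
        object.__setattr__(self, "children", children)
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "value", value)
        object.__setattr__(self, "_hash", None)

    def __setattr__(self, *args):  # pragma: no cover - guard
        raise AttributeError("BoolExpr is immutable")

    def __eq__(self, other) -> bool:
        if not isinstance(other, BoolExpr):
            return NotImplemented
        return (self.kind == other.kind and self.name == other.name
                and self.value == other.value and self.children == other.children)

    def __hash__(self) -> int:
        h = self._hash
        if h is None:
            h = hash((self.kind, self.name, self.value, self.children))
            object.__setattr__(self, "_hash", h)
        return h

    def __repr__(self) -> str:
        return f"BoolExpr({serialize(self)!r})"

    # -- tree utilities used by the GP operators ------------------------

    def walk(self) -> Iterator["BoolExpr"]:
        """Yield every node in pre-order."""
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    @property
    def size(self) -> int:
        """Total node count."""
        return sum(1 for _ in self.walk())

    @property
    def depth(self) -> int:
        """Edge-depth of the tree (0 for a leaf)."""
        if not self.children:
            return 0
        return 1 + max(c.depth for c in self.children)

    def node_at(self, index: int) -> "BoolExpr":
        """Return the node with the given pre-order index."""
        for i, node in enumerate(self.walk()):
            if i == index:
                return node
        raise IndexError(index)

    def replace_at(self, index: int, replacement: "BoolExpr") -> "BoolExpr":
        """Return a copy with the subtree at pre-order ``index`` replaced."""
        counter = [0]

        def rec(node: BoolExpr) -> BoolExpr:
            if counter[0] == index:
                counter[0] += 1
                return replacement
            counter[0] += 1
            new_children = []
            changed = False
            for c in node.children:
                nc = rec(c)
                changed = changed or (nc is not c)
                new_children.append(nc)
            if not changed:
                return node
            return BoolExpr(node.kind, tuple(new_children), node.name, node.value)

        out = rec(self)
        if counter[0] <= index:
            raise IndexError(index)
        return out


# -- constructors --------------------------------------------------------

def var(name: str) -> BoolExpr:
    return BoolExpr("var", name=name)


def const(value: bool) -> BoolExpr:
    return BoolExpr("const", value=bool(value))


def not_(x: BoolExpr) -> BoolExpr:
    return BoolExpr("not", (x,))


def and_(a: BoolExpr, b: BoolExpr) -> BoolExpr:
    return BoolExpr("and", (a, b))


def or_(a: BoolExpr, b: BoolExpr) -> BoolExpr:
    return BoolExpr("or", (a, b))


def if_(c: BoolExpr, t: BoolExpr, f: BoolExpr) -> BoolExpr:
    return BoolExpr("if", (c, t, f))


TRUE = const(True)
FALSE = const(False)


# -- lexer / parser ------------------------------------------------------

class ParseError(ValueError):
    """Raised for malformed program text; carries the source position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


_PUNCT = {"[": "[", "]": "]", "(": "(", ")": ")", ",": ","}


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    """Return (type, value, position) triples.

    Asterisks are ignored entirely: printed program listings italicize
    single-letter variables as ``*s*`` etc., a typesetting artifact.  The
    typographic divides sign is accepted as an OR bar.
    """
    tokens: list[tuple[str, str, int]] = []
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch.isspace() or ch == "*":
            i += 1
            continue
        if ch in _PUNCT:
            tokens.append(("punct", ch, i))
            i += 1
            continue
        if ch == "!":
            tokens.append(("not", "!", i))
            i += 1
            continue
        if ch == "&":
            if text[i:i + 2] != "&&":
                raise ParseError("single '&' (expected '&&')", i)
            tokens.append(("and", "&&", i))
            i += 2
            continue
        if ch in "|∣":  # '|' or the DIVIDES bar
            if i + 1 < n and text[i + 1] in "|∣":
                tokens.append(("or", "||", i))
                i += 2
                continue
            raise ParseError("single '|' (expected '||')", i)
        if ch.isalpha():
            j = i
            while j < n and text[j].isalpha():
                j += 1
            tokens.append(("name", text[i:j], i))
            i = j
            continue
        raise ParseError(f"unexpected character {ch!r}", i)
    return tokens


class _Parser:
    def __init__(self, tokens: list[tuple[str, str, int]], length: int):
        self.tokens = tokens
        self.pos = 0
        self.length = length

    def _peek(self) -> tuple[str, str, int] | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def _next(self) -> tuple[str, str, int]:
        tok = self._peek()
        if tok is None:
            raise ParseError("unexpected end of input", self.length)
        self.pos += 1
        return tok

    def _expect(self, value: str) -> None:
        tok = self._next()
        if tok[1] != value:
            raise ParseError(f"expected {value!r}, found {tok[1]!r}", tok[2])

    def parse(self) -> BoolExpr:
        expr = self.or_expr()
        tok = self._peek()
        if tok is not None:
            raise ParseError(f"trailing input {tok[1]!r}", tok[2])
        return expr

    def or_expr(self) -> BoolExpr:
        node = self.and_expr()
        while (tok := self._peek()) is not None and tok[0] == "or":
            self._next()
            node = or_(node, self.and_expr())
        return node

    def and_expr(self) -> BoolExpr:
        node = self.not_expr()
        while (tok := self._peek()) is not None and tok[0] == "and":
            self._next()
            node = and_(node, self.not_expr())
        return node

    def not_expr(self) -> BoolExpr:
        tok = self._peek()
        if tok is not None and tok[0] == "not":
            self._next()
            return not_(self.not_expr())
        return self.primary()

    def primary(self) -> BoolExpr:
        tok = self._next()
        ttype, value, pos = tok
        if ttype == "punct" and value == "(":
            node = self.or_expr()
            self._expect(")")
            return node
        if ttype == "name":
            if value == "If":
                self._expect("[")
                cond = self.or_expr()
                self._expect(",")
                then = self.or_expr()
                nxt = self._next()
                if nxt[1] == "]":
                    raise ParseError("If requires 3 arguments, got 2", nxt[2])
                if nxt[1] != ",":
                    raise ParseError(f"expected ',' or ']', found {nxt[1]!r}", nxt[2])
                other = self.or_expr()
                closing = self._next()
                if closing[1] == ",":
                    raise ParseError("If requires 3 arguments, got more", closing[2])
                if closing[1] != "]":
                    raise ParseError(f"expected ']', found {closing[1]!r}", closing[2])
                return if_(cond, then, other)
            if value == "True":
                return TRUE
            if value == "False":
                return FALSE
            if value in _VAR_INDEX:
                return var(value)
            raise ParseError(f"unknown identifier {value!r}", pos)
        raise ParseError(f"unexpected token {value!r}", pos)


def parse_expression(text: str) -> BoolExpr:
    """Parse program text in the ``If[.,.,.]``/``&&``/``||``/``!`` dialect.

    Operator precedence: ``!`` binds tighter than ``&&``, which binds
    tighter than ``||``.  Raises :class:`ParseError` (with the offending
    position) on unbalanced brackets, unknown identifiers or a wrong
    ``If`` arity.
    """
    return _Parser(_tokenize(text), len(text)).parse()


def serialize(expr: BoolExpr) -> str:
    """Render an expression back to the program dialect.

    Emits parentheses only where precedence requires them, so
    ``parse(serialize(t)) == t`` for every valid tree.
    """
    # precedence levels: or=1, and=2, not=3, atoms=4
    def rec(node: BoolExpr, parent_level: int) -> str:
        if node.kind == "var":
            return node.name
        if node.kind == "const":
            return "True" if node.value else "False"
        if node.kind == "if":
            parts = ", ".join(rec(c, 1) for c in node.children)
            return f"If[{parts}]"
        if node.kind == "not":
            return "!" + rec(node.children[0], 3)
        level = 2 if node.kind == "and" else 1
        op = "&&" if node.kind == "and" else "||"
        # left child may share the level (left-assoc chains re-parse equal)
        left = rec(node.children[0], level)
        right = rec(node.children[1], level + 1)
        body = f"{left}{op}{right}"
        if level < parent_level:
            return f"({body})"
        return body

    return rec(expr, 1)


# -- evaluation ----------------------------------------------------------

def evaluate(expr: BoolExpr, assignment: Mapping[str, bool]) -> bool:
    """Evaluate under a total assignment of the 12 variables.

    ``If[c, t, f]`` yields ``t``'s value when ``c`` is true, else ``f``'s;
    ``&&``/``||``/``!`` are the classical connectives.  The evaluator is
    defined by full recursion (the calculus is pure, so short-circuiting
    is unobservable).
    """
    k = expr.kind
    if k == "var":
        return bool(assignment[expr.name])
    if k == "const":
        return expr.value
    if k == "not":
        return not evaluate(expr.children[0], assignment)
    if k == "and":
        a = evaluate(expr.children[0], assignment)
        b = evaluate(expr.children[1], assignment)
        return a and b
    if k == "or":
        a = evaluate(expr.children[0], assignment)
        b = evaluate(expr.children[1], assignment)
        return a or b
    # if
    c = evaluate(expr.children[0], assignment)
    return evaluate(expr.children[1 if c else 2], assignment)


def assignment_from_index(i: int) -> dict[str, bool]:
    """Assignment number ``i``: 12-bit expansion of ``i``, ``n`` = MSB."""
    if not 0 <= i < N_STATES:
        raise ValueError(f"assignment index out of range: {i}")
    return {name: bool((i >> (11 - k)) & 1) for k, name in enumerate(VARIABLES)}


_VAR_COLUMNS: np.ndarray | None = None


def _var_columns() -> np.ndarray:
    """(12, 4096) bool matrix; row k is variable k under every assignment."""
    global _VAR_COLUMNS
    if _VAR_COLUMNS is None:
        idx = np.arange(N_STATES, dtype=np.uint16)
        cols = np.empty((len(VARIABLES), N_STATES), dtype=bool)
        for k in range(len(VARIABLES)):
            cols[k] = (idx >> (11 - k)) & 1
        cols.setflags(write=False)
        _VAR_COLUMNS = cols
    return _VAR_COLUMNS


def evaluate_on_columns(expr: BoolExpr, cols: np.ndarray) -> np.ndarray:
    """Vectorized evaluation over a batch of assignments.

    ``cols`` has shape (12, M): row ``k`` gives variable ``VARIABLES[k]``
    under each of M assignments.  One numpy operation per tree node.
    """

    def rec(node: BoolExpr) -> np.ndarray:
        k = node.kind
        if k == "var":
            return cols[_VAR_INDEX[node.name]]
        if k == "const":
            return np.full(cols.shape[1], node.value, dtype=bool)
        if k == "not":
            return ~rec(node.children[0])
        if k == "and":
            return rec(node.children[0]) & rec(node.children[1])
        if k == "or":
            return rec(node.children[0]) | rec(node.children[1])
        c = rec(node.children[0])
        return np.where(c, rec(node.children[1]), rec(node.children[2]))

    return np.ascontiguousarray(rec(expr), dtype=bool)


def truth_vector(expr: BoolExpr) -> np.ndarray:
    """Evaluate on all 4,096 assignments at once.

    Returns a read-only boolean vector of length 4,096 whose element ``i``
    is the program's output under :func:`assignment_from_index` ``(i)``.
    """
    out = evaluate_on_columns(expr, _var_columns())
    out.setflags(write=False)
    return out


def disagreement_count(v1: np.ndarray, v2: np.ndarray) -> int:
    """Number of assignments on which two truth vectors differ.

    Symmetric, zero iff the programs are semantically equivalent.
    """
    v1 = np.asarray(v1, dtype=bool)
    v2 = np.asarray(v2, dtype=bool)
    if v1.shape != (N_STATES,) or v2.shape != (N_STATES,):
        raise ValueError(
            f"truth vectors must have length {N_STATES}, got {v1.shape} and {v2.shape}")
    return int(np.count_nonzero(v1 != v2))


def support_variables(expr: BoolExpr) -> set[str]:
    """The set of variable names occurring in the tree."""
    return {node.name for node in expr.walk() if node.kind == "var"}


# -- external formats ----------------------------------------------------

def read_program(path) -> BoolExpr:
    """Read one expression from a program text file."""
    with open(path, "r", encoding="utf-8") as fh:
        return parse_expression(fh.read())


def write_program(path, expr: BoolExpr) -> None:
    """Write an expression to a program text file (same dialect)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(serialize(expr) + "\n")


_TV_HEADER = "# truth vector; variable order: " + ", ".join(VARIABLES)


def write_truth_vector(path, v: np.ndarray) -> None:
    """Write a truth vector as 4,096 lines of 0/1 after a header line."""
    v = np.asarray(v, dtype=bool)
    if v.shape != (N_STATES,):
        raise ValueError(f"truth vector must have length {N_STATES}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_TV_HEADER + "\n")
        fh.write("\n".join("1" if b else "0" for b in v))
        fh.write("\n")


def read_truth_vector(path) -> np.ndarray:
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if not lines or not lines[0].startswith("#"):
        raise ValueError("missing truth-vector header line")
    bits = lines[1:]
    if len(bits) != N_STATES or any(b not in "01" for b in bits):
        raise ValueError("malformed truth-vector body")
    return np.array([b == "1" for b in bits], dtype=bool)
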