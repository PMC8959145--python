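"""Boolean regulatory formulas.

A regulatory rule is a Boolean formula over two kinds of literals:

* ``protein(g)`` — the protein state of gene ``g`` in the same cell, and
* ``input(x)`` — the state of an extrinsic timer input ``x`` (e.g. ``cad``,
  ``opa``) imposed by a schedule,

combined with ``AND`` / ``OR`` / ``NOT``, parentheses, and the constants
``TRUE`` / ``FALSE``.  Formulas are parsed into a small expression tree which
can be evaluated either on scalar booleans (one cell at a time) or on numpy
boolean arrays (one evaluation per global state, used by the exhaustive
attractor machinery).

The grammar, in decreasing precedence::

    atom   := 'TRUE' | 'FALSE' | 'protein' '(' name ')' | 'input' '(' name ')'
            | '(' expr ')'
    unary  := 'NOT' unary | atom
    conj   := unary ('AND' unary)*
    expr   := conj ('OR' conj)*

Keywords are case-insensitive; gene and input names are case-sensitive
identifiers.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Callable, Iterator


class FormulaError(ValueError):
    """Raised for syntax errors or unresolvable literals in a rule."""


class Formula:
    """Base class for nodes of a parsed regulatory rule."""

    def evaluate(self, protein: Callable[[str], object], inputs: Callable[[str], object]):
        raise NotImplementedError

    def literals(self) -> Iterator[tuple[str, str]]:
        """Yield ``(kind, name)`` pairs, kind in {'protein', 'input'}."""
        raise NotImplementedError

    def __str__(self) -> str:  # pragma: no cover - exercised via subclasses
        raise NotImplementedError

    def __eq__(self, other):
        return type(self) is type(other) and str(self) == str(other)

    def __hash__(self):
        return hash((type(self).__name__, str(self)))


@dataclass(frozen=True, eq=False)
class Const(Formula):
    value: bool

    def evaluate(self, protein, inputs):
        return self.value

    def literals(self):
        return iter(())

    def __str__(self):
        return "TRUE" if self.value else "FALSE"


@dataclass(frozen=True, eq=False)
class ProteinLit(Formula):
    gene: str

    def evaluate(self, protein, inputs):
        return protein(self.gene)

    def literals(self):
        yield ("protein", self.gene)

    def __str__(self):
        return f"protein({self.gene})"


@dataclass(frozen=True, eq=False)
class InputLit(Formula):
    name: str

    def evaluate(self, protein, inputs):
        return inputs(self.name)

    def literals(self):
        yield ("input", self.name)

    def __str__(self):
        return f"input({self.name})"


@dataclass(frozen=True, eq=False)
class Not(Formula):
    operand: Formula

    def evaluate(self, protein, inputs):
        v = self.operand.evaluate(protein, inputs)
        return ~v if _is_array(v) else not v

    def literals(self):
        yield from self.operand.literals()

    def __str__(self):
        return f"NOT {_paren(self.operand, (And, Or))}"


@dataclass(frozen=True, eq=False)
class And(Formula):
    left: Formula
    right: Formula

    def evaluate(self, protein, inputs):
        a = self.left.evaluate(protein, inputs)
        b = self.right.evaluate(protein, inputs)
        return (a & b) if _is_array(a) or _is_array(b) else (a and b)

    def literals(self):
        yield from self.left.literals()
        yield from self.right.literals()

    def __str__(self):
        return f"{_paren(self.left, (Or,))} AND {_paren(self.right, (Or,))}"


@dataclass(frozen=True, eq=False)
class Or(Formula):
    left: Formula
    right: Formula

    def evaluate(self, protein, inputs):
        a = self.left.evaluate(protein, inputs)
        b = self.right.evaluate(protein, inputs)
        return (a | b) if _is_array(a) or _is_array(b) else (a or b)

    def literals(self):
        yield from self.left.literals()
        yield from self.right.literals()

    def __str__(self):
        return f"{self.left} OR {self.right}"


def _is_array(v) -> bool:
    return hasattr(v, "__and__") and not isinstance(v, bool)


def _paren(f: Formula, wrap_types: tuple[type, ...]) -> str:
    s = str(f)
    return f"({s})" if isinstance(f, wrap_types) else s


_WORD = re.compile(r"[A-Za-z_][A-Za-z0-9_\-]*")


def _tokenize(text: str) -> list[str]:
    tokens, pos = [], 0
    while pos < len(text):
        ch = text[pos]
        if ch.isspace():
            pos += 1
        elif ch in "()":
            tokens.append(ch)
            pos += 1
        else:
            m = _WORD.match(text, pos)
            if not m:
                raise FormulaError(f"unexpected character {ch!r} at column {pos}")
            tokens.append(m.group(0))
            pos = m.end()
    return tokens


class _Parser:
    def __init__(self, tokens: list[str], source: str):
        self.tokens = tokens
        self.pos = 0
        self.source = source

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self) -> str:
        tok = self.peek()
        if tok is None:
            raise FormulaError(f"unexpected end of rule in {self.source!r}")
        self.pos += 1
        return tok

    def expect(self, tok: str):
        got = self.take()
        if got != tok:
            raise FormulaError(f"expected {tok!r}, got {got!r} in {self.source!r}")

    def expr(self) -> Formula:
        node = self.conj()
        while (p := self.peek()) is not None and p.upper() == "OR":
            self.take()
            node = Or(node, self.conj())
        return node

    def conj(self) -> Formula:
        node = self.unary()
        while (p := self.peek()) is not None and p.upper() == "AND":
            self.take()
            node = And(node, self.unary())
        return node

    def unary(self) -> Formula:
        if (p := self.peek()) is not None and p.upper() == "NOT":
            self.take()
            return Not(self.unary())
        return self.atom()

    def atom(self) -> Formula:
        tok = self.take()
        up = tok.upper()
        if tok == "(":
            node = self.expr()
            self.expect(")")
            return node
        if up == "TRUE":
            return Const(True)
        if up == "FALSE":
            return Const(False)
        if up in ("PROTEIN", "INPUT"):
            self.expect("(")
            name = self.take()
            if name in ("(", ")") or name.upper() in ("AND", "OR", "NOT"):
                raise FormulaError(f"bad literal name {name!r} in {self.source!r}")
            self.expect(")")
            return ProteinLit(name) if up == "PROTEIN" else InputLit(name)
        raise FormulaError(f"unexpected token {tok!r} in {self.source!r}")


def parse_formula(text: str) -> Formula:
    """Parse a rule string such as ``"NOT protein(eve) AND input(cad)"``."""
    tokens = _tokenize(text)
    if not tokens:
        raise FormulaError("empty rule")
    parser = _Parser(tokens, text)
    node = parser.expr()
    if parser.peek() is not None:
        raise FormulaError(f"trailing tokens {parser.tokens[parser.pos:]} in {text!r}")
    return node
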