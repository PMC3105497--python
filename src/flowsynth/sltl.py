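"""Linear-time logic over finite service executions, with taxonomy-aware atoms.

Formulas are interpreted over finite traces ``s0 a1 s1 ... an sn`` of states
and executed services (LTLf-style semantics with an explicit ``End`` atom):

* ``Exec(C)`` holds at position ``i < n`` iff the service executed next,
  ``a_{i+1}``, is subsumed by ``C`` in the service taxonomy — so an abstract
  service class stands for all of its concrete instances;
* ``Avail(T)`` holds at position ``i`` iff the state ``s_i`` satisfies the
  type requirement ``T`` through the type taxonomy;
* ``End`` holds only at the final position ``n``; ``Next`` is strong (false
  at ``n``); ``WeakUntil(p, q)`` is ``Globally(p) | Until(p, q)``.

Besides direct evaluation, the module provides *formula progression*: the
residual formula that must hold on the remainder of a trace after one step.
Progression is what lets synthesis evaluate the constraint formula in
parallel with the expansion of the configuration universe.
"""

from __future__ import annotations

import difflib
import re
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

from .domain_model import DomainModel, State, Taxonomy, satisfies_requirement, subsumes
from .errors import ParseError, UnknownNameError


# ---------------------------------------------------------------------------
# AST
# ---------------------------------------------------------------------------

class Formula:
    """Base class; all nodes are frozen, hashable dataclasses."""

    __slots__ = ()


@dataclass(frozen=True)
class TrueF(Formula):
    pass


@dataclass(frozen=True)
class FalseF(Formula):
    pass


@dataclass(frozen=True)
class End(Formula):
    pass


@dataclass(frozen=True)
class Exec(Formula):
    """The next executed service is an instance of (or equals) ``name``."""

    name: str


@dataclass(frozen=True)
class Avail(Formula):
    """The current state satisfies the type requirement ``name``."""

    name: str


@dataclass(frozen=True)
class Not(Formula):
    sub: Formula


@dataclass(frozen=True)
class And(Formula):
    left: Formula
    right: Formula


@dataclass(frozen=True)
class Or(Formula):
    left: Formula
    right: Formula


@dataclass(frozen=True)
class Implies(Formula):
    left: Formula
    right: Formula


@dataclass(frozen=True)
class Next(Formula):
    sub: Formula


@dataclass(frozen=True)
class Eventually(Formula):
    sub: Formula


@dataclass(frozen=True)
class Globally(Formula):
    sub: Formula


@dataclass(frozen=True)
class Until(Formula):
    left: Formula
    right: Formula


@dataclass(frozen=True)
class WeakUntil(Formula):
    left: Formula
    right: Formula


TRUE = TrueF()
FALSE = FalseF()
END = End()


# -- simplifying constructors (used by progression to keep residues small) --

def _not(p: Formula) -> Formula:
    if isinstance(p, TrueF):
        return FALSE
    if isinstance(p, FalseF):
        return TRUE
    if isinstance(p, Not):
        return p.sub
    return Not(p)


def _and(p: Formula, q: Formula) -> Formula:
    if isinstance(p, FalseF) or isinstance(q, FalseF):
        return FALSE
    if isinstance(p, TrueF):
        return q
    if isinstance(q, TrueF):
        return p
    if p == q:
        return p
    return And(p, q)


def _or(p: Formula, q: Formula) -> Formula:
    if isinstance(p, TrueF) or isinstance(q, TrueF):
        return TRUE
    if isinstance(p, FalseF):
        return q
    if isinstance(q, FalseF):
        return p
    if p == q:
        return p
    return Or(p, q)


def conjoin(formulas: Iterable[Formula]) -> Formula:
    """Right-folded conjunction of constraints; empty collection gives True."""
    items = list(formulas)
    if not items:
        return TRUE
    out = items[-1]
    for f in reversed(items[:-1]):
        out = And(f, out)
    return out


def atoms(formula: Formula) -> set[Formula]:
    """All Exec/Avail atoms occurring in the formula."""
    found: set[Formula] = set()
    stack = [formula]
    while stack:
        f = stack.pop()
        if isinstance(f, (Exec, Avail)):
            found.add(f)
        elif isinstance(f, (Not, Next, Eventually, Globally)):
            stack.append(f.sub)
        elif isinstance(f, (And, Or, Implies, Until, WeakUntil)):
            stack.extend((f.left, f.right))
    return found


# ---------------------------------------------------------------------------
# Traces and evaluation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Trace:
    """A finite execution: ``len(states) == len(services) + 1``."""

    states: tuple[State, ...]
    services: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.states) != len(self.services) + 1:
            raise ValueError("trace needs exactly one more state than services")

    def __len__(self) -> int:
        return len(self.services)

    @staticmethod
    def from_replay(states: Sequence[State], services: Sequence[str]) -> "Trace":
        return Trace(tuple(frozenset(s) for s in states), tuple(services))


def evaluate(
    formula: Formula,
    trace: Trace,
    service_taxonomy: Taxonomy,
    type_taxonomy: Taxonomy | None = None,
    position: int = 0,
) -> bool:
    """Finite-trace satisfaction of *formula* at *position* (default 0)."""
    n = len(trace)

    @lru_cache(maxsize=None)
    def sat(f: Formula, i: int) -> bool:
        if isinstance(f, TrueF):
            return True
        if isinstance(f, FalseF):
            return False
        if isinstance(f, End):
            return i == n
        if isinstance(f, Exec):
            return i < n and subsumes(service_taxonomy, f.name, trace.services[i])
        if isinstance(f, Avail):
            if type_taxonomy is None:
                raise UnknownNameError(f.name, "no type taxonomy supplied for Avail atom")
            return satisfies_requirement(trace.states[i], f.name, type_taxonomy)
        if isinstance(f, Not):
            return not sat(f.sub, i)
        if isinstance(f, And):
            return sat(f.left, i) and sat(f.right, i)
        if isinstance(f, Or):
            return sat(f.left, i) or sat(f.right, i)
        if isinstance(f, Implies):
            return (not sat(f.left, i)) or sat(f.right, i)
        if isinstance(f, Next):
            return i < n and sat(f.sub, i + 1)
        if isinstance(f, Eventually):
            return any(sat(f.sub, j) for j in range(i, n + 1))
        if isinstance(f, Globally):
            return all(sat(f.sub, j) for j in range(i, n + 1))
        if isinstance(f, Until):
            return any(
                sat(f.right, j) and all(sat(f.left, k) for k in range(i, j))
                for j in range(i, n + 1)
            )
        if isinstance(f, WeakUntil):
            return sat(Globally(f.left), i) or sat(Until(f.left, f.right), i)
        raise TypeError(f"not a formula: {f!r}")

    return sat(formula, position)


# ---------------------------------------------------------------------------
# Progression
# ---------------------------------------------------------------------------

def progress(
    formula: Formula,
    state: State,
    action: str,
    service_taxonomy: Taxonomy,
    type_taxonomy: Taxonomy,
) -> Formula:
    """Residual obligation after executing *action* from *state*.

    The current position is known not to be final (an action is taken), so
    ``End`` progresses to false and ``Next p`` to ``p``.  The result is kept
    simplified so that equal obligations compare equal during search.
    """

    def prog(f: Formula) -> Formula:
        if isinstance(f, (TrueF, FalseF)):
            return f
        if isinstance(f, End):
            return FALSE
        if isinstance(f, Exec):
            return TRUE if subsumes(service_taxonomy, f.name, action) else FALSE
        if isinstance(f, Avail):
            return TRUE if satisfies_requirement(state, f.name, type_taxonomy) else FALSE
        if isinstance(f, Not):
            return _not(prog(f.sub))
        if isinstance(f, And):
            return _and(prog(f.left), prog(f.right))
        if isinstance(f, Or):
            return _or(prog(f.left), prog(f.right))
        if isinstance(f, Implies):
            return _or(_not(prog(f.left)), prog(f.right))
        if isinstance(f, Next):
            return f.sub
        if isinstance(f, Eventually):
            return _or(prog(f.sub), f)
        if isinstance(f, Globally):
            return _and(prog(f.sub), f)
        if isinstance(f, Until):
            return _or(prog(f.right), _and(prog(f.left), f))
        if isinstance(f, WeakUntil):
            return _or(prog(f.right), _and(prog(f.left), f))
        raise TypeError(f"not a formula: {f!r}")

    return prog(formula)


def accepts_empty(
    formula: Formula,
    state: State,
    service_taxonomy: Taxonomy,
    type_taxonomy: Taxonomy,
) -> bool:
    """Satisfaction at a final position (the trace ends in *state* now)."""
    return evaluate(
        formula,
        Trace((frozenset(state),), ()),
        service_taxonomy,
        type_taxonomy,
    )


# ---------------------------------------------------------------------------
# Natural-language constraint templates
# ---------------------------------------------------------------------------

_TEMPLATES: list[tuple[re.Pattern, str]] = [
    (re.compile(r"^enforce the use of (?:module|service|type)?\s*(?P<name>\S+)$", re.I), "enforce"),
    (re.compile(r"^use (?P<name>\S+) as last service in solution$", re.I), "last"),
    (re.compile(r"^do not use (?:module|service)?\s*(?P<name>\S+)$", re.I), "avoid"),
    (re.compile(r"^use (?P<a>\S+) before (?P<b>\S+)$", re.I), "before"),
]


def _resolve_service_name(name: str, domain: DomainModel) -> str:
    tax = domain.service_taxonomy
    if tax.known(name):
        return name
    known = sorted(tax.classes | tax.instances)
    raise UnknownNameError(name, "not in service taxonomy", tuple(difflib.get_close_matches(name, known, n=3)))


def template_to_formula(text: str, domain: DomainModel) -> Formula:
    """Parse a natural-language constraint template into a formula.

    Supported shapes (case-insensitive keywords; names resolve against the
    service taxonomy, abstract class names standing for all instances):

    * ``Enforce the use of module X``  ->  ``F Exec(X)``
    * ``Use X as last service in solution``  ->  ``F (Exec(X) & X End)``
    * ``Do not use X``  ->  ``G !Exec(X)``
    * ``Use A before B``  ->  ``!Exec(B) WU Exec(A)``
    """
    stripped = " ".join(text.split())
    for pattern, kind in _TEMPLATES:
        m = pattern.match(stripped)
        if not m:
            continue
        if kind == "enforce":
            return Eventually(Exec(_resolve_service_name(m["name"], domain)))
        if kind == "last":
            return Eventually(And(Exec(_resolve_service_name(m["name"], domain)), Next(END)))
        if kind == "avoid":
            return Globally(Not(Exec(_resolve_service_name(m["name"], domain))))
        if kind == "before":
            a = _resolve_service_name(m["a"], domain)
            b = _resolve_service_name(m["b"], domain)
            return WeakUntil(Not(Exec(b)), Exec(a))
    raise ParseError(f"unrecognised constraint template: {text!r}")


def formula_to_template(formula: Formula) -> str | None:
    """Render a template-shaped formula back to its constraint sentence."""
    if isinstance(formula, Eventually):
        sub = formula.sub
        if isinstance(sub, Exec):
            return f"Enforce the use of module {sub.name}"
        if (
            isinstance(sub, And)
            and isinstance(sub.left, Exec)
            and isinstance(sub.right, Next)
            and isinstance(sub.right.sub, End)
        ):
            return f"Use {sub.left.name} as last service in solution"
    if isinstance(formula, Globally) and isinstance(formula.sub, Not) and isinstance(formula.sub.sub, Exec):
        return f"Do not use {formula.sub.sub.name}"
    if (
        isinstance(formula, WeakUntil)
        and isinstance(formula.left, Not)
        and isinstance(formula.left.sub, Exec)
        and isinstance(formula.right, Exec)
    ):
        return f"Use {formula.right.name} before {formula.left.sub.name}"
    return None


# ---------------------------------------------------------------------------
# Concrete syntax (used for logs, process files and the checker CLI)
# ---------------------------------------------------------------------------

_PRECEDENCE = {Implies: 1, Or: 2, And: 3, Until: 4, WeakUntil: 4}


def render(formula: Formula) -> str:
    """Serialise a formula in the infix grammar accepted by :func:`parse`."""

    def prec(f: Formula) -> int:
        return _PRECEDENCE.get(type(f), 9)

    def wrap(sub: Formula, parent_prec: int) -> str:
        text = render(sub)
        return f"({text})" if prec(sub) < parent_prec else text

    if isinstance(formula, TrueF):
        return "true"
    if isinstance(formula, FalseF):
        return "false"
    if isinstance(formula, End):
        return "end"
    if isinstance(formula, Exec):
        return formula.name
    if isinstance(formula, Avail):
        return f"@{formula.name}"
    if isinstance(formula, Not):
        return "!" + wrap(formula.sub, 9)
    if isinstance(formula, Next):
        return "X " + wrap(formula.sub, 9)
    if isinstance(formula, Eventually):
        return "F " + wrap(formula.sub, 9)
    if isinstance(formula, Globally):
        return "G " + wrap(formula.sub, 9)
    if isinstance(formula, Implies):
        return f"{wrap(formula.left, 2)} => {wrap(formula.right, 1)}"
    if isinstance(formula, Or):  # left-assoc: parenthesise an Or on the right
        return f"{wrap(formula.left, 2)} | {wrap(formula.right, 3)}"
    if isinstance(formula, And):
        return f"{wrap(formula.left, 3)} & {wrap(formula.right, 4)}"
    if isinstance(formula, Until):
        return f"{wrap(formula.left, 5)} U {wrap(formula.right, 4)}"
    if isinstance(formula, WeakUntil):
        return f"{wrap(formula.left, 5)} WU {wrap(formula.right, 4)}"
    raise TypeError(f"not a formula: {formula!r}")


_TOKEN_RE = re.compile(
    r"\s*(?:(?P<lpar>\()|(?P<rpar>\))|(?P<impl>=>|->)|(?P<and>&&?|∧)|(?P<or>\|\|?|∨)"
    r"|(?P<not>!|¬)|(?P<avail>@)|(?P<word>[A-Za-z_][A-Za-z0-9_.-]*))"
)

_UNARY = {"X": Next, "F": Eventually, "G": Globally}
_CONST = {"true": TRUE, "false": FALSE, "end": END}


class _Parser:
    """Recursive-descent parser for the infix PLTL grammar.

    Precedence, loosest first: ``=>`` (right-assoc), ``|``, ``&``,
    ``U``/``WU`` (right-assoc), unary ``! X F G``, atoms.  Bare identifiers
    are service atoms (``Exec``); ``@name`` is a type-availability atom.
    """

    def __init__(self, text: str):
        self.text = text
        self.tokens: list[tuple[str, str, int]] = []
        pos = 0
        while pos < len(text):
            m = _TOKEN_RE.match(text, pos)
            if not m or m.end() == m.start():
                if text[pos:].strip():
                    bad = text[pos:].strip()[0]
                    raise ParseError(f"unexpected character {bad!r} in formula", column=pos + 1)
                break
            for kind, value in m.groupdict().items():
                if value is not None:
                    self.tokens.append((kind, value, m.start()))
                    break
            pos = m.end()
        self.i = 0

    def peek(self) -> tuple[str, str, int] | None:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def take(self) -> tuple[str, str, int]:
        tok = self.peek()
        if tok is None:
            raise ParseError("unexpected end of formula", column=len(self.text) + 1)
        self.i += 1
        return tok

    def parse(self) -> Formula:
        f = self.implication()
        if self.peek() is not None:
            kind, value, start = self.peek()
            raise ParseError(f"unexpected token {value!r}", column=start + 1)
        return f

    def implication(self) -> Formula:
        left = self.disjunction()
        tok = self.peek()
        if tok and tok[0] == "impl":
            self.take()
            return Implies(left, self.implication())
        return left

    def disjunction(self) -> Formula:
        left = self.conjunction()
        while self.peek() and self.peek()[0] == "or":
            self.take()
            left = Or(left, self.conjunction())
        return left

    def conjunction(self) -> Formula:
        left = self.until()
        while self.peek() and self.peek()[0] == "and":
            self.take()
            left = And(left, self.until())
        return left

    def until(self) -> Formula:
        left = self.unary()
        tok = self.peek()
        if tok and tok[0] == "word" and tok[1] in ("U", "WU"):
            op = self.take()[1]
            right = self.until()
            return Until(left, right) if op == "U" else WeakUntil(left, right)
        return left

    def unary(self) -> Formula:
        tok = self.peek()
        if tok is None:
            raise ParseError("unexpected end of formula", column=len(self.text) + 1)
        kind, value, start = tok
        if kind == "not":
            self.take()
            return Not(self.unary())
        if kind == "word" and value in _UNARY:
            self.take()
            return _UNARY[value](self.unary())
        return self.atom()

    def atom(self) -> Formula:
        kind, value, start = self.take()
        if kind == "lpar":
            f = self.implication()
            tok = self.take()
            if tok[0] != "rpar":
                raise ParseError(f"expected ')' but found {tok[1]!r}", column=tok[2] + 1)
            return f
        if kind == "avail":
            tok = self.take()
            if tok[0] != "word":
                raise ParseError("expected a type name after '@'", column=tok[2] + 1)
            return Avail(tok[1])
        if kind == "word":
            low = value.lower()
            if low in _CONST:
                return _CONST[low]
            return Exec(value)
        raise ParseError(f"unexpected token {value!r}", column=start + 1)


def parse(text: str) -> Formula:
    """Parse the infix PLTL syntax (see :class:`_Parser` for the grammar)."""
    return _Parser(text).parse()
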