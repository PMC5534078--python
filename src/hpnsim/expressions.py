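"""Rate, guard and arc-weight expression language.

Expressions are small ASTs over numeric literals, parameter references,
place references (and colour variables in coloured nets), the arithmetic
operators ``+ - * / ^``, unary minus, comparisons and boolean connectives
(guards only), and call forms such as ``MassAction(k)``.

The module provides parsing, tree-walk evaluation, dependency extraction,
interval-arithmetic bounds (used for rejection-sampling propensity bounds
and for guard pruning during coloured-net unfolding), and compilation to
plain Python callables for the simulation hot paths.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

__all__ = [
    "Expression", "Num", "Ref", "BinOp", "Neg", "Compare", "BoolOp", "Call",
    "SymbolTable", "ExpressionError", "ParseError", "EvaluationError",
    "parse_expression", "evaluate", "dependencies", "parameters_of",
    "variables_of", "bounds", "bounds_bool", "expand_mass_action",
    "compile_expression", "substitute", "to_text", "constant_value",
]


class ExpressionError(Exception):
    """Base class for expression-language errors."""


class ParseError(ExpressionError):
    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class EvaluationError(ExpressionError):
    pass


# ---------------------------------------------------------------------------
# AST
# ---------------------------------------------------------------------------

class Expression:
    """Base class of all AST nodes."""

    __slots__ = ()

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<{type(self).__name__} {to_text(self)}>"


@dataclass(frozen=True, eq=True)
class Num(Expression):
    value: float


@dataclass(frozen=True, eq=True)
class Ref(Expression):
    name: str
    kind: str  # "place" | "param" | "var"


@dataclass(frozen=True, eq=True)
class BinOp(Expression):
    op: str  # + - * / ^
    left: Expression
    right: Expression


@dataclass(frozen=True, eq=True)
class Neg(Expression):
    operand: Expression


@dataclass(frozen=True, eq=True)
class Compare(Expression):
    op: str  # < <= > >= = !=
    left: Expression
    right: Expression


@dataclass(frozen=True, eq=True)
class BoolOp(Expression):
    op: str  # "and" | "or" | "not"
    terms: tuple


@dataclass(frozen=True, eq=True)
class Call(Expression):
    func: str
    args: tuple


@dataclass
class SymbolTable:
    """Declares the identifiers an expression may reference."""

    places: frozenset = frozenset()
    params: frozenset = frozenset()
    variables: frozenset = frozenset()
    functions: frozenset = frozenset({"MassAction"})

    @classmethod
    def make(cls, places: Iterable[str] = (), params: Iterable[str] = (),
             variables: Iterable[str] = (),
             functions: Iterable[str] = ("MassAction",)) -> "SymbolTable":
        return cls(frozenset(places), frozenset(params),
                   frozenset(variables), frozenset(functions))


# ---------------------------------------------------------------------------
# Parsing (hand-written tokenizer + recursive descent / precedence climbing)
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"\s*(?:(?P<num>\d+\.\d*(?:[eE][+-]?\d+)?|\.\d+(?:[eE][+-]?\d+)?"
    r"|\d+(?:[eE][+-]?\d+)?)"
    r"|(?P<id>[A-Za-z_][A-Za-z0-9_.]*)"
    r"|(?P<op><=|>=|!=|==|[-+*/^()<>=,&|!]))"
)

_KEYWORDS = {"and", "or", "not", "true", "false", "all"}


def _tokenize(text: str):
    pos = 0
    tokens = []
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            stripped = text[pos:].lstrip()
            if not stripped:
                break
            raise ParseError(f"unexpected character {stripped[0]!r}", pos)
        if m.lastgroup == "num":
            tokens.append(("num", m.group("num"), m.start("num")))
        elif m.lastgroup == "id":
            tokens.append(("id", m.group("id"), m.start("id")))
        else:
            tokens.append(("op", m.group("op"), m.start("op")))
        pos = m.end()
    tokens.append(("end", "", len(text)))
    return tokens


class _Parser:
    def __init__(self, tokens, symbols: SymbolTable):
        self.toks = tokens
        self.i = 0
        self.symbols = symbols

    def peek(self):
        return self.toks[self.i]

    def next(self):
        tok = self.toks[self.i]
        self.i += 1
        return tok

    def expect(self, value: str):
        kind, val, pos = self.next()
        if val != value:
            raise ParseError(f"expected {value!r}, found {val or 'end of input'!r}", pos)

    # grammar: or_expr > and_expr > not_expr > comparison > additive >
    #          multiplicative > unary > power (right assoc) > atom
    def parse(self) -> Expression:
        node = self.or_expr()
        kind, val, pos = self.peek()
        if kind != "end":
            raise ParseError(f"unexpected trailing input {val!r}", pos)
        return node

    def or_expr(self):
        node = self.and_expr()
        terms = [node]
        while self._match_kw("or") or self._match_op("|"):
            terms.append(self.and_expr())
        return BoolOp("or", tuple(terms)) if len(terms) > 1 else node

    def and_expr(self):
        node = self.not_expr()
        terms = [node]
        while self._match_kw("and") or self._match_op("&"):
            terms.append(self.not_expr())
        return BoolOp("and", tuple(terms)) if len(terms) > 1 else node

    def not_expr(self):
        if self._match_kw("not") or self._match_op("!"):
            return BoolOp("not", (self.not_expr(),))
        return self.comparison()

    def comparison(self):
        node = self.additive()
        kind, val, pos = self.peek()
        if kind == "op" and val in ("<", "<=", ">", ">=", "=", "==", "!="):
            self.next()
            right = self.additive()
            op = "=" if val in ("=", "==") else val
            return Compare(op, node, right)
        return node

    def additive(self):
        node = self.multiplicative()
        while True:
            kind, val, _ = self.peek()
            if kind == "op" and val in ("+", "-"):
                self.next()
                node = BinOp(val, node, self.multiplicative())
            else:
                return node

    def multiplicative(self):
        node = self.unary()
        while True:
            kind, val, _ = self.peek()
            if kind == "op" and val in ("*", "/"):
                self.next()
                node = BinOp(val, node, self.unary())
            else:
                return node

    def unary(self):
        kind, val, _ = self.peek()
        if kind == "op" and val == "-":
            self.next()
            return Neg(self.unary())
        if kind == "op" and val == "+":
            self.next()
            return self.unary()
        return self.power()

    def power(self):
        base = self.atom()
        kind, val, _ = self.peek()
        if kind == "op" and val == "^":
            self.next()
            return BinOp("^", base, self.unary())  # right-assoc via unary
        return base

    def atom(self):
        kind, val, pos = self.next()
        if kind == "num":
            return Num(float(val))
        if kind == "op" and val == "(":
            node = self.or_expr()
            self.expect(")")
            return node
        if kind == "id":
            low = val.lower()
            if low == "true":
                return Num(1.0)
            if low == "false":
                return Num(0.0)
            nxt_kind, nxt_val, _ = self.peek()
            if nxt_kind == "op" and nxt_val == "(":
                self.next()
                args = []
                if not (self.peek()[0] == "op" and self.peek()[1] == ")"):
                    args.append(self.or_expr())
                    while self.peek()[1] == ",":
                        self.next()
                        args.append(self.or_expr())
                self.expect(")")
                if val not in self.symbols.functions:
                    raise ParseError(f"unknown function {val!r}", pos)
                return Call(val, tuple(args))
            if val in self.symbols.places:
                return Ref(val, "place")
            if val in self.symbols.params:
                return Ref(val, "param")
            if val in self.symbols.variables:
                return Ref(val, "var")
            raise ParseError(f"unknown identifier {val!r}", pos)
        raise ParseError(f"unexpected token {val or 'end of input'!r}", pos)

    def _match_kw(self, kw: str) -> bool:
        kind, val, _ = self.peek()
        if kind == "id" and val == kw:
            self.next()
            return True
        return False

    def _match_op(self, op: str) -> bool:
        kind, val, _ = self.peek()
        if kind == "op" and val == op:
            self.next()
            return True
        return False


def parse_expression(text: str, symbols: SymbolTable) -> Expression:
    """Parse ``text`` against the declared ``symbols``.

    Raises :class:`ParseError` with a character position on syntax errors or
    undeclared identifiers.
    """
    return _Parser(_tokenize(text), symbols).parse()


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def evaluate(expr: Expression, marking: Mapping[str, float],
             params: Mapping[str, float] | None = None,
             variables: Mapping[str, float] | None = None,
             context: str = "") -> float:
    """Tree-walk evaluation to an IEEE double.

    Boolean sub-expressions evaluate to 1.0 / 0.0.  Division by zero raises
    :class:`EvaluationError` naming ``context`` (typically the transition id).
    """
    params = params or {}
    variables = variables or {}

    def rec(e: Expression) -> float:
        if isinstance(e, Num):
            return e.value
        if isinstance(e, Ref):
            if e.kind == "place":
                return float(marking[e.name])
            if e.kind == "param":
                return float(params[e.name])
            return float(variables[e.name])
        if isinstance(e, Neg):
            return -rec(e.operand)
        if isinstance(e, BinOp):
            a, b = rec(e.left), rec(e.right)
            if e.op == "+":
                return a + b
            if e.op == "-":
                return a - b
            if e.op == "*":
                return a * b
            if e.op == "/":
                if b == 0.0:
                    where = f" in {context}" if context else ""
                    raise EvaluationError(f"division by zero{where}")
                return a / b
            if e.op == "^":
                return float(a ** b)
        if isinstance(e, Compare):
            a, b = rec(e.left), rec(e.right)
            ok = {"<": a < b, "<=": a <= b, ">": a > b,
                  ">=": a >= b, "=": a == b, "!=": a != b}[e.op]
            return 1.0 if ok else 0.0
        if isinstance(e, BoolOp):
            if e.op == "not":
                return 0.0 if rec(e.terms[0]) != 0.0 else 1.0
            if e.op == "and":
                return 1.0 if all(rec(t) != 0.0 for t in e.terms) else 0.0
            return 1.0 if any(rec(t) != 0.0 for t in e.terms) else 0.0
        if isinstance(e, Call):
            raise EvaluationError(
                f"call {e.func!r} must be expanded before evaluation"
                + (f" (in {context})" if context else ""))
        raise EvaluationError(f"cannot evaluate node {e!r}")

    return float(rec(expr))


def constant_value(expr: Expression) -> float | None:
    """Value of ``expr`` if it references no symbols, else ``None``."""
    try:
        return evaluate(expr, {}, {}, {})
    except (KeyError, EvaluationError):
        return None


# ---------------------------------------------------------------------------
# Structure queries and rewriting
# ---------------------------------------------------------------------------

def _walk(expr: Expression):
    yield expr
    if isinstance(expr, BinOp):
        yield from _walk(expr.left)
        yield from _walk(expr.right)
    elif isinstance(expr, Compare):
        yield from _walk(expr.left)
        yield from _walk(expr.right)
    elif isinstance(expr, Neg):
        yield from _walk(expr.operand)
    elif isinstance(expr, BoolOp):
        for t in expr.terms:
            yield from _walk(t)
    elif isinstance(expr, Call):
        for a in expr.args:
            yield from _walk(a)


def dependencies(expr: Expression) -> set:
    """Place ids syntactically present in ``expr``."""
    return {n.name for n in _walk(expr) if isinstance(n, Ref) and n.kind == "place"}


def parameters_of(expr: Expression) -> set:
    return {n.name for n in _walk(expr) if isinstance(n, Ref) and n.kind == "param"}


def variables_of(expr: Expression) -> set:
    return {n.name for n in _walk(expr) if isinstance(n, Ref) and n.kind == "var"}


def substitute(expr: Expression, mapping: Mapping[Expression, Expression]) -> Expression:
    """Structurally replace nodes (used for colour binding and renaming)."""
    if expr in mapping:
        return mapping[expr]
    if isinstance(expr, BinOp):
        return BinOp(expr.op, substitute(expr.left, mapping),
                     substitute(expr.right, mapping))
    if isinstance(expr, Compare):
        return Compare(expr.op, substitute(expr.left, mapping),
                       substitute(expr.right, mapping))
    if isinstance(expr, Neg):
        return Neg(substitute(expr.operand, mapping))
    if isinstance(expr, BoolOp):
        return BoolOp(expr.op, tuple(substitute(t, mapping) for t in expr.terms))
    if isinstance(expr, Call):
        return Call(expr.func, tuple(substitute(a, mapping) for a in expr.args))
    return expr


def expand_mass_action(expr: Expression,
                       inputs: Sequence[tuple[str, float]]) -> Expression:
    """Expand ``MassAction(k)`` into ``k * prod(place ^ weight)``.

    ``inputs`` are the (place id, constant arc weight) pairs of the owning
    transition's standard/read input arcs.  The product is formed in sorted
    place order so the expansion is independent of arc declaration order.
    """
    def build(k: Expression) -> Expression:
        node = k
        for pid, w in sorted(inputs):
            factor: Expression = Ref(pid, "place")
            if w != 1:
                factor = BinOp("^", factor, Num(float(w)))
            node = BinOp("*", node, factor)
        return node

    if isinstance(expr, Call) and expr.func == "MassAction":
        if len(expr.args) != 1:
            raise ExpressionError("MassAction takes exactly one argument")
        return build(expr.args[0])
    if isinstance(expr, BinOp):
        return BinOp(expr.op, expand_mass_action(expr.left, inputs),
                     expand_mass_action(expr.right, inputs))
    if isinstance(expr, Neg):
        return Neg(expand_mass_action(expr.operand, inputs))
    if isinstance(expr, Compare):
        return Compare(expr.op, expand_mass_action(expr.left, inputs),
                       expand_mass_action(expr.right, inputs))
    if isinstance(expr, BoolOp):
        return BoolOp(expr.op, tuple(expand_mass_action(t, inputs) for t in expr.terms))
    return expr


# ---------------------------------------------------------------------------
# Interval arithmetic
# ---------------------------------------------------------------------------

def _iv_mul(a, b):
    prods = (a[0] * b[0], a[0] * b[1], a[1] * b[0], a[1] * b[1])
    return (min(prods), max(prods))


def _iv_pow(base, exp):
    lo, hi = base
    if exp == int(exp) and exp >= 0:
        n = int(exp)
        if n == 0:
            return (1.0, 1.0)
        if lo >= 0:
            return (lo ** n, hi ** n)
        if n % 2 == 1:
            return (lo ** n, hi ** n)
        mags = (abs(lo), abs(hi))
        return (0.0 if lo < 0 < hi else min(mags) ** n, max(mags) ** n)
    if lo < 0:
        raise EvaluationError(
            f"interval power with negative base [{lo}, {hi}] and "
            f"non-integer exponent {exp}")
    return (lo ** exp, hi ** exp)


def bounds(expr: Expression, interval_marking: Mapping[str, tuple],
           params: Mapping[str, float] | None = None,
           variables: Mapping[str, tuple] | None = None) -> tuple:
    """Interval-arithmetic enclosure ``(lo, hi)`` of ``expr``.

    Every pointwise evaluation inside ``interval_marking`` is guaranteed to
    lie in the returned interval; the enclosure is exact (tight) for
    products of non-negative monomials, and merely valid for non-monotone
    expressions.  An interval containing a division-by-zero point raises
    :class:`EvaluationError`.
    """
    params = params or {}
    variables = variables or {}

    def rec(e) -> tuple:
        if isinstance(e, Num):
            return (e.value, e.value)
        if isinstance(e, Ref):
            if e.kind == "place":
                lo, hi = interval_marking[e.name]
                return (float(lo), float(hi))
            if e.kind == "param":
                v = float(params[e.name])
                return (v, v)
            lo, hi = variables[e.name]
            return (float(lo), float(hi))
        if isinstance(e, Neg):
            lo, hi = rec(e.operand)
            return (-hi, -lo)
        if isinstance(e, BinOp):
            a, b = rec(e.left), rec(e.right)
            if e.op == "+":
                return (a[0] + b[0], a[1] + b[1])
            if e.op == "-":
                return (a[0] - b[1], a[1] - b[0])
            if e.op == "*":
                return _iv_mul(a, b)
            if e.op == "/":
                if b[0] <= 0.0 <= b[1]:
                    raise EvaluationError(
                        f"interval [{b[0]}, {b[1]}] of divisor contains zero")
                return _iv_mul(a, (1.0 / b[1], 1.0 / b[0]))
            if e.op == "^":
                if b[0] != b[1]:
                    raise EvaluationError("interval exponent not supported")
                return _iv_pow(a, b[0])
        if isinstance(e, (Compare, BoolOp)):
            t = bounds_bool(e, interval_marking, params, variables)
            if t is True:
                return (1.0, 1.0)
            if t is False:
                return (0.0, 0.0)
            return (0.0, 1.0)
        raise EvaluationError(f"cannot bound node {e!r}")

    return rec(expr)


def bounds_bool(expr: Expression, interval_marking: Mapping[str, tuple],
                params: Mapping[str, float] | None = None,
                variables: Mapping[str, tuple] | None = None):
    """Tri-state interval truth of a guard: True, False, or None (unknown)."""
    params = params or {}
    variables = variables or {}

    def rec(e):
        if isinstance(e, Compare):
            a = bounds(e.left, interval_marking, params, variables)
            b = bounds(e.right, interval_marking, params, variables)
            if e.op in ("<", "<="):
                strict = e.op == "<"
                if (a[1] < b[0]) or (not strict and a[1] <= b[0]):
                    return True
                if (a[0] > b[1]) or (strict and a[0] >= b[1]):
                    return False
                return None
            if e.op in (">", ">="):
                return rec(Compare("<" if e.op == ">" else "<=", e.right, e.left))
            if e.op == "=":
                if a[1] < b[0] or b[1] < a[0]:
                    return False
                if a[0] == a[1] == b[0] == b[1]:
                    return True
                return None
            if e.op == "!=":
                t = rec(Compare("=", e.left, e.right))
                return None if t is None else (not t)
        if isinstance(e, BoolOp):
            subs = [rec(t) for t in e.terms]
            if e.op == "not":
                return None if subs[0] is None else (not subs[0])
            if e.op == "and":
                if any(s is False for s in subs):
                    return False
                if all(s is True for s in subs):
                    return True
                return None
            if any(s is True for s in subs):
                return True
            if all(s is False for s in subs):
                return False
            return None
        # numeric expression used as truth value
        lo, hi = bounds(e, interval_marking, params, variables)
        if lo == hi == 0.0:
            return False
        if lo > 0.0 or hi < 0.0:
            return True
        return None

    return rec(expr)


# ---------------------------------------------------------------------------
# Compilation
# ---------------------------------------------------------------------------

def compile_expression(expr: Expression,
                       place_index: Mapping[str, int] | None = None,
                       param_index: Mapping[str, int] | None = None,
                       var_index: Mapping[str, int] | None = None) -> Callable:
    """Compile to a Python callable ``f(x, c, v)``.

    ``x``, ``c`` and ``v`` are indexables holding place markings, parameter
    values and colour-variable values as positioned by the given index maps.
    Used on hot paths (propensities, ODE right-hand sides, binding guards);
    must agree with :func:`evaluate` (property-tested).
    """
    place_index = place_index or {}
    param_index = param_index or {}
    var_index = var_index or {}

    def gen(e) -> str:
        if isinstance(e, Num):
            return repr(e.value)
        if isinstance(e, Ref):
            if e.kind == "place":
                return f"x[{place_index[e.name]}]"
            if e.kind == "param":
                return f"c[{param_index[e.name]}]"
            return f"v[{var_index[e.name]}]"
        if isinstance(e, Neg):
            return f"(-{gen(e.operand)})"
        if isinstance(e, BinOp):
            op = {"+": "+", "-": "-", "*": "*", "/": "/", "^": "**"}[e.op]
            return f"({gen(e.left)}{op}{gen(e.right)})"
        if isinstance(e, Compare):
            op = {"=": "==", "!=": "!=", "<": "<", "<=": "<=",
                  ">": ">", ">=": ">="}[e.op]
            return f"(1.0 if {gen(e.left)}{op}{gen(e.right)} else 0.0)"
        if isinstance(e, BoolOp):
            if e.op == "not":
                return f"(0.0 if {gen(e.terms[0])}!=0.0 else 1.0)"
            joiner = " and " if e.op == "and" else " or "
            body = joiner.join(f"({gen(t)}!=0.0)" for t in e.terms)
            return f"(1.0 if {body} else 0.0)"
        if isinstance(e, Call):
            raise ExpressionError(
                f"call {e.func!r} must be expanded before compilation")
        raise ExpressionError(f"cannot compile node {e!r}")

    src = f"lambda x, c=None, v=None: {gen(expr)}"
    return eval(src, {"__builtins__": {}})  # noqa: S307 - generated from our own AST


def compile_numpy(expr: Expression,
                  param_index: Mapping[str, int] | None = None,
                  var_index: Mapping[str, int] | None = None) -> Callable:
    """Compile to a vectorised callable ``f(c, v)`` over numpy arrays.

    Entries of ``v`` may be scalars or broadcastable arrays; comparisons and
    boolean connectives map onto element-wise numpy operations.  Used to
    evaluate binding guards over whole colour-range grids at once during
    coloured-net unfolding.
    """
    import numpy as _np
    param_index = param_index or {}
    var_index = var_index or {}

    def gen(e) -> str:
        if isinstance(e, Num):
            return repr(e.value)
        if isinstance(e, Ref):
            if e.kind == "param":
                return f"c[{param_index[e.name]}]"
            if e.kind == "var":
                return f"v[{var_index[e.name]}]"
            raise ExpressionError("place references are not allowed in guards")
        if isinstance(e, Neg):
            return f"(-{gen(e.operand)})"
        if isinstance(e, BinOp):
            op = {"+": "+", "-": "-", "*": "*", "/": "/", "^": "**"}[e.op]
            return f"({gen(e.left)}{op}{gen(e.right)})"
        if isinstance(e, Compare):
            op = {"=": "==", "!=": "!=", "<": "<", "<=": "<=",
                  ">": ">", ">=": ">="}[e.op]
            return f"({gen(e.left)}{op}{gen(e.right)})"
        if isinstance(e, BoolOp):
            if e.op == "not":
                return f"(~(({gen(e.terms[0])})!=0))"
            joiner = "&" if e.op == "and" else "|"
            return "(" + joiner.join(f"((({gen(t)}))!=0)" for t in e.terms) + ")"
        raise ExpressionError(f"cannot compile node {e!r}")

    src = f"lambda c, v: {gen(expr)}"
    return eval(src, {"__builtins__": {}, "np": _np})  # noqa: S307


# ---------------------------------------------------------------------------
# Pretty printing (canonical text form, used by the ANDL writer)
# ---------------------------------------------------------------------------

_PREC = {"or": 1, "and": 2, "not": 3, "cmp": 4, "+": 5, "-": 5,
         "*": 6, "/": 6, "neg": 7, "^": 8, "atom": 9}


def to_text(expr: Expression) -> str:
    """Canonical text rendering; ``parse(to_text(e))`` is structurally ``e``."""

    def rec(e, parent_prec: int) -> str:
        if isinstance(e, Num):
            v = e.value
            s = repr(int(v)) if v == int(v) and abs(v) < 1e16 else repr(v)
            return s
        if isinstance(e, Ref):
            return e.name
        if isinstance(e, Neg):
            s = "-" + rec(e.operand, _PREC["neg"])
            return f"({s})" if parent_prec > _PREC["neg"] else s
        if isinstance(e, BinOp):
            p = _PREC[e.op]
            if e.op == "^":  # right-associative
                s = f"{rec(e.left, p + 1)} ^ {rec(e.right, p)}"
            else:            # left-associative: parenthesise equal-prec right
                s = f"{rec(e.left, p)} {e.op} {rec(e.right, p + 1)}"
            return f"({s})" if parent_prec > p else s
        if isinstance(e, Compare):
            s = f"{rec(e.left, _PREC['+'])} {e.op} {rec(e.right, _PREC['+'])}"
            return f"({s})" if parent_prec > _PREC["cmp"] else s
        if isinstance(e, BoolOp):
            if e.op == "not":
                s = "not " + rec(e.terms[0], _PREC["not"])
                return f"({s})" if parent_prec > _PREC["not"] else s
            p = _PREC[e.op]
            s = f" {e.op} ".join(rec(t, p + 1) for t in e.terms)
            return f"({s})" if parent_prec > p else s
        if isinstance(e, Call):
            return f"{e.func}({', '.join(rec(a, 0) for a in e.args)})"
        raise ExpressionError(f"cannot render node {e!r}")

    return rec(expr, 0)
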