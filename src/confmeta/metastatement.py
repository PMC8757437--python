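"""The metastatement expression language.

A metastatement is a single expression evaluated once per record of an
Ensemble, with access to the record's metadata, its atom block, its molecule
group and the whole file.  The result for each record is an anonymous value
(single, list or dict) or ABSENT; ABSENT propagates through sub-expressions,
so a record missing any referenced metadata simply produces no value.

Grammar (precedence low to high)::

    statement  := or
    or         := and ('|' and)*
    and        := cmp ('&' cmp)*
    cmp        := add (CMPOP add)?
    add        := mul (('+'|'-') mul)*
    mul        := unary (('*'|'/') unary)*
    unary      := '-' unary | postfix
    postfix    := primary ( '(' CMPOP raw ')' | '(' args ')' | '{' '}' )*
    primary    := NUMBER | 'string' | "meta name" | IDENT | '(' or ')'

Comparators are the glyphs ``< ≤ > ≥ = ≠`` or the ASCII digraphs
``<= >= == !=``.  ``name(...)`` is a function call when ``name`` is a
registered builtin; otherwise a parenthesized comparator+scalar slices the
value by comparison and a parenthesized expression indexes a dict by keys.
``name{}`` extracts the keys of a dict as a list.

Builtins: file-scope aggregates ``max min avg sum``, group-scope aggregates
``mmax mmin mavg msum``, math ``log10 ln abs sqrt pow``, group bookkeeping
``mrank mcount``, atom access ``confcol`` (atom-block column as an atom-keyed
dict) and ``dist`` (distances to an x,y,z point).
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass
from typing import Union

from confmeta.sdf_core import (
    ABSENT,
    ConformationRecord,
    Ensemble,
    MetaValue,
    Scalar,
    coerce_scalar,
    format_scalar,
)

log = logging.getLogger("confmeta")

AGGREGATES = {"max", "min", "avg", "sum", "mmax", "mmin", "mavg", "msum"}
MATH_FUNCS = {"log10", "ln", "abs", "sqrt", "pow"}
BUILTINS = AGGREGATES | MATH_FUNCS | {"mrank", "mcount", "confcol", "dist"}

_CMP_CANON = {"<=": "≤", ">=": "≥", "==": "=", "!=": "≠"}
_CMP_GLYPHS = ("≤", "≥", "≠", "<", ">", "=")


class StatementError(ValueError):
    """Syntax or evaluation error in a metastatement."""


# ---------------------------------------------------------------------------
# AST


@dataclass
class Literal:
    value: Scalar


@dataclass
class MetaRef:
    name: str


@dataclass
class Unary:
    op: str
    operand: "Node"


@dataclass
class Binary:
    op: str
    left: "Node"
    right: "Node"


@dataclass
class Compare:
    op: str
    left: "Node"
    right: "Node"


@dataclass
class Logic:
    op: str  # '&' or '|'
    left: "Node"
    right: "Node"


@dataclass
class Call:
    func: str
    args: list


@dataclass
class Slice:
    target: "Node"
    op: str
    threshold: Scalar


@dataclass
class KeyExtract:
    target: "Node"


@dataclass
class KeyIndex:
    source: "Node"
    keys: "Node"


Node = Union[Literal, MetaRef, Unary, Binary, Compare, Logic, Call, Slice, KeyExtract, KeyIndex]


# ---------------------------------------------------------------------------
# lexer / parser

_IDENT_RE = re.compile(r"[A-Za-z_][A-Za-z0-9_]*")
_NUMBER_RE = re.compile(r"(?:[0-9]+\.[0-9]*|\.[0-9]+|[0-9]+)(?:[eE][+-]?[0-9]+)?")


class _Parser:
    def __init__(self, text: str):
        self.text = text.replace("−", "-")  # unicode minus
        self.pos = 0

    # -- low-level ---------------------------------------------------------

    def error(self, msg: str):
        raise StatementError(f"{msg} at offset {self.pos} in {self.text!r}")

    def skip_ws(self) -> None:
        while self.pos < len(self.text) and self.text[self.pos].isspace():
            self.pos += 1

    def peek_char(self) -> str:
        self.skip_ws()
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def eat(self, s: str) -> bool:
        self.skip_ws()
        if self.text.startswith(s, self.pos):
            self.pos += len(s)
            return True
        return False

    def expect(self, s: str) -> None:
        if not self.eat(s):
            self.error(f"expected {s!r}")

    def peek_cmp(self) -> str | None:
        self.skip_ws()
        for dig, glyph in _CMP_CANON.items():
            if self.text.startswith(dig, self.pos):
                return glyph
        for glyph in _CMP_GLYPHS:
            if self.text.startswith(glyph, self.pos):
                return glyph
        return None

    def eat_cmp(self) -> str | None:
        self.skip_ws()
        for dig, glyph in _CMP_CANON.items():
            if self.text.startswith(dig, self.pos):
                self.pos += len(dig)
                return glyph
        for glyph in _CMP_GLYPHS:
            if self.text.startswith(glyph, self.pos):
                self.pos += len(glyph)
                return glyph
        return None

    def _quoted(self, quote: str) -> str:
        """Consume a quoted token; no escape processing, quotes cannot nest."""
        assert self.text[self.pos] == quote
        end = self.text.find(quote, self.pos + 1)
        if end < 0:
            self.error(f"unterminated {quote} quote")
        s = self.text[self.pos + 1:end]
        self.pos = end + 1
        return s

    def raw_until_rparen(self) -> str:
        """Raw scalar text up to the next ')' (slice thresholds like O.3)."""
        end = self.text.find(")", self.pos)
        if end < 0:
            self.error("unbalanced parentheses")
        raw = self.text[self.pos:end].strip()
        self.pos = end
        if not raw:
            self.error("empty slice threshold")
        return raw

    # -- grammar -----------------------------------------------------------

    def parse(self) -> Node:
        node = self.or_expr()
        self.skip_ws()
        if self.pos != len(self.text):
            self.error("unexpected trailing text")
        return node

    def or_expr(self) -> Node:
        node = self.and_expr()
        while self.eat("|"):
            node = Logic("|", node, self.and_expr())
        return node

    def and_expr(self) -> Node:
        node = self.cmp_expr()
        while self.eat("&"):
            node = Logic("&", node, self.cmp_expr())
        return node

    def cmp_expr(self) -> Node:
        node = self.add_expr()
        op = self.eat_cmp()
        if op is not None:
            node = Compare(op, node, self.add_expr())
        return node

    def add_expr(self) -> Node:
        node = self.mul_expr()
        while True:
            self.skip_ws()
            c = self.peek_char()
            if c == "+" and self.eat("+"):
                node = Binary("+", node, self.mul_expr())
            elif c == "-" and self.eat("-"):
                node = Binary("-", node, self.mul_expr())
            else:
                return node

    def mul_expr(self) -> Node:
        node = self.unary_expr()
        while True:
            c = self.peek_char()
            if c == "*" and self.eat("*"):
                node = Binary("*", node, self.unary_expr())
            elif c == "/" and self.eat("/"):
                node = Binary("/", node, self.unary_expr())
            else:
                return node

    def unary_expr(self) -> Node:
        if self.eat("-"):
            return Unary("-", self.unary_expr())
        return self.postfix_expr()

    def postfix_expr(self) -> Node:
        node = self.primary()
        while True:
            self.skip_ws()
            c = self.peek_char()
            if c == "(":
                self.expect("(")
                op = self.peek_cmp()
                if op is not None:
                    self.eat_cmp()
                    raw = self.raw_until_rparen()
                    self.expect(")")
                    node = Slice(node, op, coerce_scalar(raw))
                else:
                    keys = self.or_expr()
                    self.expect(")")
                    node = KeyIndex(node, keys)
            elif c == "{":
                self.expect("{")
                self.expect("}")
                node = KeyExtract(node)
            else:
                return node

    def primary(self) -> Node:
        self.skip_ws()
        if self.pos >= len(self.text):
            self.error("unexpected end of statement")
        c = self.text[self.pos]
        if c == "(":
            self.expect("(")
            node = self.or_expr()
            self.expect(")")
            return node
        if c == "'":
            return Literal(self._quoted("'"))
        if c == '"':
            return MetaRef(self._quoted('"'))
        m = _NUMBER_RE.match(self.text, self.pos)
        if m:
            self.pos = m.end()
            return Literal(coerce_scalar(m.group(0)))
        m = _IDENT_RE.match(self.text, self.pos)
        if m:
            name = m.group(0)
            self.pos = m.end()
            if name in BUILTINS:
                self.expect("(")
                args: list[Node] = []
                if not self.eat(")"):
                    args.append(self.or_expr())
                    while self.eat(","):
                        args.append(self.or_expr())
                    self.expect(")")
                return Call(name, args)
            return MetaRef(name)
        self.error(f"unexpected character {c!r}")


def parse_statement(text: str) -> Node:
    """Parse a metastatement into its AST."""
    if not text or not text.strip():
        raise StatementError("empty statement")
    return _Parser(text).parse()


# ---------------------------------------------------------------------------
# unparse


def unparse(node: Node) -> str:
    """Canonical text form; parse(unparse(ast)) reproduces the AST."""
    if isinstance(node, Literal):
        if isinstance(node.value, str):
            return f"'{node.value}'"
        return format_scalar(node.value)
    if isinstance(node, MetaRef):
        if _IDENT_RE.fullmatch(node.name) and node.name not in BUILTINS:
            return node.name
        return f'"{node.name}"'
    if isinstance(node, Unary):
        return f"(-{unparse(node.operand)})"
    if isinstance(node, Binary):
        return f"({unparse(node.left)}{node.op}{unparse(node.right)})"
    if isinstance(node, Compare):
        return f"({unparse(node.left)}{node.op}{unparse(node.right)})"
    if isinstance(node, Logic):
        return f"({unparse(node.left)}{node.op}{unparse(node.right)})"
    if isinstance(node, Call):
        return f"{node.func}({','.join(unparse(a) for a in node.args)})"
    if isinstance(node, Slice):
        return f"{unparse(node.target)}({node.op}{format_scalar(node.threshold)})"
    if isinstance(node, KeyExtract):
        return f"{unparse(node.target)}{{}}"
    if isinstance(node, KeyIndex):
        return f"{unparse(node.source)}({unparse(node.keys)})"
    raise TypeError(f"not a node: {node!r}")


# ---------------------------------------------------------------------------
# evaluation

# internal value representation: scalar | str | list | dict | ABSENT
Value = Union[Scalar, list, dict, type(ABSENT)]

_FLOAT_EQ_RTOL = 1e-9


def _num_eq(a, b) -> bool:
    if isinstance(a, int) and isinstance(b, int):
        return a == b
    return math.isclose(a, b, rel_tol=_FLOAT_EQ_RTOL, abs_tol=0.0)


def _compare_scalars(op: str, a, b):
    a_num = isinstance(a, (int, float))
    b_num = isinstance(b, (int, float))
    if a_num != b_num:
        return None  # incomparable
    if not a_num:  # both strings: only (in)equality
        if op == "=":
            return a == b
        if op == "≠":
            return a != b
        return None
    if op == "<":
        return a < b and not _num_eq(a, b)
    if op == "≤":
        return a < b or _num_eq(a, b)
    if op == ">":
        return a > b and not _num_eq(a, b)
    if op == "≥":
        return a > b or _num_eq(a, b)
    if op == "=":
        return _num_eq(a, b)
    if op == "≠":
        return not _num_eq(a, b)
    raise StatementError(f"unknown comparator {op!r}")


def slice_by_value(value: Value, op: str, threshold: Scalar) -> Value:
    """Keep the entries of a value passing ``<entry> op threshold``.

    Dicts keep passing items, lists keep passing elements, a single passes
    or not as a whole; an empty result is ABSENT, as are entries that are
    not comparable with the threshold.
    """
    if value is ABSENT:
        return ABSENT
    if isinstance(value, dict):
        out = {}
        for k, v in value.items():
            r = _compare_scalars(op, v, threshold)
            if r:
                out[k] = v
        return out if out else ABSENT
    if isinstance(value, list):
        out_l = [v for v in value if _compare_scalars(op, v, threshold)]
        return out_l if out_l else ABSENT
    r = _compare_scalars(op, value, threshold)
    return value if r else ABSENT


def key_extract(value: Value) -> Value:
    """Keys of a dict as an ordered list; non-dict input is ABSENT."""
    if isinstance(value, dict):
        return list(value.keys())
    if value is not ABSENT:
        log.warning("key extraction {} applied to non-dict value; no result")
    return ABSENT


def key_index(source: Value, keys: Value) -> Value:
    """Sub-dict of ``source`` restricted to ``keys``; missing keys skipped."""
    if not isinstance(source, dict) or keys is ABSENT:
        return ABSENT
    if isinstance(keys, dict):
        wanted = list(keys.keys())
    elif isinstance(keys, list):
        wanted = keys
    else:
        wanted = [keys]
    out = {k: source[k] for k in wanted if k in source}
    return out if out else ABSENT


def regex_subtract(s: str, pattern: str) -> str:
    """Remove all non-overlapping matches of ``pattern`` from ``s``.

    String subtraction is always a regular-expression operation.
    """
    try:
        return re.sub(pattern, "", s)
    except re.error as exc:
        raise StatementError(f"invalid regular expression {pattern!r}: {exc}") from exc


def _scalar_op(op: str, a, b):
    a_num = isinstance(a, (int, float))
    b_num = isinstance(b, (int, float))
    if a_num and b_num:
        if op == "+":
            return a + b
        if op == "-":
            return a - b
        if op == "*":
            return a * b
        if op == "/":
            if b == 0:
                return ABSENT
            return a / b
        raise StatementError(f"unknown operator {op!r}")
    if isinstance(a, str) and isinstance(b, str):
        if op == "+":
            return a + b
        if op == "-":
            return regex_subtract(a, b)
        log.warning("operator %r not defined for strings; no result", op)
        return ABSENT
    log.warning("operator %r on mixed string/number; no result", op)
    return ABSENT


def _lift2(op: str, a: Value, b: Value) -> Value:
    """Elementwise-lift a scalar operation over lists and dicts.

    dict⊕scalar applies to every value, dict⊕dict joins on keys (inner
    join), list⊕list pairs positionally; any element-level failure makes
    the whole result ABSENT.
    """
    if a is ABSENT or b is ABSENT:
        return ABSENT
    if isinstance(a, dict) and isinstance(b, dict):
        out = {}
        for k in a:
            if k in b:
                r = _scalar_op(op, a[k], b[k])
                if r is ABSENT:
                    return ABSENT
                out[k] = r
        return out if out else ABSENT
    if isinstance(a, dict):
        out = {}
        for k, v in a.items():
            r = _lift2(op, v, b)
            if r is ABSENT:
                return ABSENT
            out[k] = r
        return out if out else ABSENT
    if isinstance(b, dict):
        out = {}
        for k, v in b.items():
            r = _lift2(op, a, v)
            if r is ABSENT:
                return ABSENT
            out[k] = r
        return out if out else ABSENT
    if isinstance(a, list) and isinstance(b, list):
        out_l = []
        for x, y in zip(a, b):
            r = _scalar_op(op, x, y)
            if r is ABSENT:
                return ABSENT
            out_l.append(r)
        return out_l if out_l else ABSENT
    if isinstance(a, list):
        out_l = []
        for x in a:
            r = _scalar_op(op, x, b)
            if r is ABSENT:
                return ABSENT
            out_l.append(r)
        return out_l if out_l else ABSENT
    if isinstance(b, list):
        out_l = []
        for y in b:
            r = _scalar_op(op, a, y)
            if r is ABSENT:
                return ABSENT
            out_l.append(r)
        return out_l if out_l else ABSENT
    return _scalar_op(op, a, b)


def _negate(v: Value) -> Value:
    return _lift2("*", v, -1)


def _numeric_values(v: Value) -> list | None:
    """Flat numeric values of a result, or None if any is non-numeric."""
    if isinstance(v, dict):
        vals = list(v.values())
    elif isinstance(v, list):
        vals = v
    else:
        vals = [v]
    if all(isinstance(x, (int, float)) for x in vals):
        return vals
    return None


_REDUCERS = {
    "max": max,
    "min": min,
    "sum": sum,
    "avg": lambda xs: sum(xs) / len(xs),
}


class Evaluator:
    """Evaluates one AST once per record against a whole Ensemble."""

    def __init__(self, ens: Ensemble, ignore: set[str] | None = None):
        from confmeta.geometry import IgnoreList

        self.ens = ens
        self.ignore = ignore if ignore is not None else IgnoreList()

    def run(self, node: Node) -> list[Value]:
        return self._eval(node)

    # each _eval returns one value per record, aligned with ens.records
    def _eval(self, node: Node) -> list[Value]:
        n = len(self.ens.records)
        if isinstance(node, Literal):
            return [node.value] * n
        if isinstance(node, MetaRef):
            out = []
            for rec in self.ens.records:
                mv = rec.meta.get(node.name)
                if mv is None:
                    out.append(ABSENT)
                elif mv.structure == "single":
                    out.append(mv.payload)
                elif mv.structure == "list":
                    out.append(list(mv.payload))
                else:
                    out.append(dict(mv.payload))
            return out
        if isinstance(node, Unary):
            return [_negate(v) for v in self._eval(node.operand)]
        if isinstance(node, Binary):
            lefts = self._eval(node.left)
            rights = self._eval(node.right)
            return [_lift2(node.op, a, b) for a, b in zip(lefts, rights)]
        if isinstance(node, Compare):
            lefts = self._eval(node.left)
            rights = self._eval(node.right)
            return [self._compare(node.op, a, b) for a, b in zip(lefts, rights)]
        if isinstance(node, Logic):
            lefts = self._eval(node.left)
            rights = self._eval(node.right)
            out = []
            for a, b in zip(lefts, rights):
                if node.op == "&":
                    out.append(a if (a is not ABSENT and b is not ABSENT) else ABSENT)
                else:
                    out.append(a if a is not ABSENT else b)
            return out
        if isinstance(node, Slice):
            return [slice_by_value(v, node.op, node.threshold) for v in self._eval(node.target)]
        if isinstance(node, KeyExtract):
            return [key_extract(v) for v in self._eval(node.target)]
        if isinstance(node, KeyIndex):
            sources = self._eval(node.source)
            keys = self._eval(node.keys)
            return [key_index(s, k) for s, k in zip(sources, keys)]
        if isinstance(node, Call):
            return self._call(node)
        raise TypeError(f"not a node: {node!r}")

    def _compare(self, op: str, a: Value, b: Value) -> Value:
        """A comparison passes a value through or yields ABSENT.

        Collection vs scalar behaves like slicing; scalar vs scalar keeps
        the left value when the comparison holds.
        """
        if a is ABSENT or b is ABSENT:
            return ABSENT
        if isinstance(a, (dict, list)) and not isinstance(b, (dict, list)):
            return slice_by_value(a, op, b)
        if isinstance(a, (dict, list)) or isinstance(b, (dict, list)):
            log.warning("comparison between collections is not defined; no result")
            return ABSENT
        r = _compare_scalars(op, a, b)
        return a if r else ABSENT

    # -- builtins ----------------------------------------------------------

    def _call(self, node: Call) -> list[Value]:
        name = node.func
        if name in AGGREGATES:
            self._arity(node, 1)
            return self._aggregate(name, self._eval(node.args[0]))
        if name in MATH_FUNCS:
            return self._math(node)
        if name == "mrank":
            self._arity(node, 1)
            return self._mrank(self._eval(node.args[0]))
        if name == "mcount":
            self._arity(node, 0)
            return [len(self.ens.groups[rec.group_key]) for rec in self.ens.records]
        if name == "confcol":
            self._arity(node, 1)
            cols = self._eval(node.args[0])
            return [
                self._confcol(rec, col)
                for rec, col in zip(self.ens.records, cols)
            ]
        if name == "dist":
            self._arity(node, 3)
            from confmeta.geometry import distances_to_point

            xs = self._eval(node.args[0])
            ys = self._eval(node.args[1])
            zs = self._eval(node.args[2])
            out = []
            for rec, x, y, z in zip(self.ens.records, xs, ys, zs):
                if ABSENT in (x, y, z):
                    out.append(ABSENT)
                else:
                    d = distances_to_point(rec, (float(x), float(y), float(z)), self.ignore)
                    out.append(d if d is not ABSENT else ABSENT)
            return out
        raise StatementError(f"unknown builtin {name!r}")

    @staticmethod
    def _arity(node: Call, k: int) -> None:
        if len(node.args) != k:
            raise StatementError(
                f"{node.func}() takes {k} argument(s), got {len(node.args)}"
            )

    def _aggregate(self, name: str, values: list[Value]) -> list[Value]:
        group_scope = name in ("mmax", "mmin", "mavg", "msum")
        base = name[1:] if group_scope else name
        reduce_ = _REDUCERS[base]
        # per-record reduction of collections first
        reduced: list[Value] = []
        for v in values:
            if v is ABSENT:
                reduced.append(ABSENT)
                continue
            nums = _numeric_values(v)
            if nums is None:
                log.warning("aggregate %s over non-numeric value; no result", name)
                reduced.append(ABSENT)
            else:
                reduced.append(reduce_(nums))
        if group_scope:
            per_group: dict[str, Value] = {}
            idx_of = {id(r): i for i, r in enumerate(self.ens.records)}
            for key, recs in self.ens.groups.items():
                vals = [reduced[idx_of[id(r)]] for r in recs]
                vals = [v for v in vals if v is not ABSENT]
                per_group[key] = reduce_(vals) if vals else ABSENT
            return [per_group[rec.group_key] for rec in self.ens.records]
        vals = [v for v in reduced if v is not ABSENT]
        agg = reduce_(vals) if vals else ABSENT
        return [agg] * len(self.ens.records)

    def _math(self, node: Call) -> list[Value]:
        name = node.func
        if name == "pow":
            self._arity(node, 2)
            xs = self._eval(node.args[0])
            ys = self._eval(node.args[1])
            return [_lift2_math(_pow, x, y) for x, y in zip(xs, ys)]
        self._arity(node, 1)
        fn = {"log10": _log10, "ln": _ln, "abs": _abs, "sqrt": _sqrt}[name]
        return [_lift1_math(fn, v) for v in self._eval(node.args[0])]

    def _mrank(self, values: list[Value]) -> list[Value]:
        """1-based ascending rank within the record's group; ties broken by
        conformation number for deterministic reruns."""
        out: list[Value] = [ABSENT] * len(values)
        idx_of = {id(r): i for i, r in enumerate(self.ens.records)}
        for recs in self.ens.groups.values():
            entries = []
            for rec in recs:
                i = idx_of[id(rec)]
                v = values[i]
                if v is ABSENT:
                    continue
                nums = _numeric_values(v)
                if nums is None or len(nums) != 1 or not isinstance(v, (int, float)):
                    continue
                entries.append((v, rec.conf_number, i))
            entries.sort(key=lambda e: (e[0], e[1]))
            for rank, (_, _, i) in enumerate(entries, start=1):
                out[i] = rank
        return out

    def _confcol(self, rec: ConformationRecord, col: Value) -> Value:
        if col is ABSENT:
            return ABSENT
        if not isinstance(col, int) or col < 1:
            raise StatementError(f"confcol column must be a positive integer, got {col!r}")
        out = {}
        for atom in rec.molfile.atoms:
            if atom.element in self.ignore:
                continue
            fields = atom.fields()
            if col > len(fields):
                raise StatementError(
                    f"confcol({col}) out of range: atom line has {len(fields)} columns"
                )
            out[atom.index] = coerce_scalar(fields[col - 1])
        return out if out else ABSENT


def _log10(x):
    return math.log10(x) if x > 0 else ABSENT


def _ln(x):
    return math.log(x) if x > 0 else ABSENT


def _abs(x):
    return abs(x)


def _sqrt(x):
    return math.sqrt(x) if x >= 0 else ABSENT


def _pow(x, y):
    try:
        r = x ** y
    except (OverflowError, ZeroDivisionError):
        return ABSENT
    if isinstance(r, complex):
        return ABSENT
    return r


def _lift1_math(fn, v: Value) -> Value:
    if v is ABSENT:
        return ABSENT
    if isinstance(v, dict):
        out = {}
        for k, x in v.items():
            if not isinstance(x, (int, float)):
                return ABSENT
            r = fn(x)
            if r is ABSENT:
                return ABSENT
            out[k] = r
        return out if out else ABSENT
    if isinstance(v, list):
        out_l = []
        for x in v:
            if not isinstance(x, (int, float)):
                return ABSENT
            r = fn(x)
            if r is ABSENT:
                return ABSENT
            out_l.append(r)
        return out_l if out_l else ABSENT
    if not isinstance(v, (int, float)):
        return ABSENT
    return fn(v)


def _lift2_math(fn, a: Value, b: Value) -> Value:
    if a is ABSENT or b is ABSENT:
        return ABSENT
    if isinstance(a, (dict, list)):
        if isinstance(b, (dict, list)):
            return ABSENT
        return _lift1_math(lambda x: fn(x, b), a)
    if isinstance(b, (dict, list)):
        return _lift1_math(lambda y: fn(a, y), b)
    if not isinstance(a, (int, float)) or not isinstance(b, (int, float)):
        return ABSENT
    return fn(a, b)


def evaluate(
    node_or_text: Node | str,
    ens: Ensemble,
    ignore: set[str] | None = None,
) -> list[Value]:
    """Evaluate a metastatement for every record of ``ens``.

    Returns one value per record (aligned with ``ens.records``): a scalar,
    list, dict, or ABSENT.
    """
    node = parse_statement(node_or_text) if isinstance(node_or_text, str) else node_or_text
    return Evaluator(ens, ignore).run(node)


def evaluate_meta(
    node_or_text: Node | str,
    ens: Ensemble,
    ignore: set[str] | None = None,
) -> list:
    """Like :func:`evaluate` but wraps results as anonymous MetaValues."""
    out = []
    for v in evaluate(node_or_text, ens, ignore):
        out.append(ABSENT if v is ABSENT else MetaValue.of(v))
    return out
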