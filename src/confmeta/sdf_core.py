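"""SDfile (MDL SDF, V2000 molfiles) parsing, writing and ensemble bookkeeping.

An SDfile is a concatenation of entries, each a V2000 molfile followed by
named data items and a ``$$$$`` delimiter line.  Data items use an extended
notation with three value structures (single, list, dictionary) and three
scalar types (int, float, string); scalars are interpreted in that order.
Dictionaries are serialized as whitespace-separated ``key:value`` pairs and
are used internally for atom-wise data (keys are atom numbers).

Records sharing a group key (by default the header molecule name) form a
molecule group; within a group every record carries a unique positive
conformation number, either encoded in the name with the ``{[conf|N]}`` tag
or assigned in file order.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Union

log = logging.getLogger("confmeta")

Scalar = Union[int, float, str]


class ParseError(ValueError):
    """Malformed SDfile input."""


class SerializationError(ValueError):
    """Ensemble state that cannot be written as a valid SDfile."""


class MetaError(ValueError):
    """Invalid metadata operation (missing field, name clash, ...)."""


class _Absent:
    """Singleton marking 'no value' — metadata cannot exist without a value."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "ABSENT"

    def __bool__(self) -> bool:
        return False


#: Sentinel for a record on which an expression produced no value.
ABSENT = _Absent()


# ---------------------------------------------------------------------------
# scalar coercion


_INT_RE = re.compile(r"^[+-]?[0-9]+$")
_NONNUMERIC_FLOATS = {"inf", "-inf", "+inf", "infinity", "nan", "-nan", "+nan"}


def coerce_scalar(token: str) -> Scalar:
    """Interpret ``token`` as int, then float, then fall back to string."""
    if _INT_RE.match(token):
        return int(token)
    if token.lower() not in _NONNUMERIC_FLOATS:
        try:
            return float(token)
        except ValueError:
            pass
    return token


def dtype_of(value: Scalar) -> str:
    if isinstance(value, bool):  # bools never arise from coercion; be strict
        return "str"
    if isinstance(value, int):
        return "int"
    if isinstance(value, float):
        return "float"
    return "str"


def format_scalar(value: Scalar) -> str:
    """Canonical text form: ints bare, floats via shortest round-trip repr."""
    if isinstance(value, float):
        return repr(value)
    return str(value)


# ---------------------------------------------------------------------------
# domain types


@dataclass
class Atom:
    """One atom-block line.  ``raw_line`` preserves the line verbatim."""

    index: int
    element: str
    x: float
    y: float
    z: float
    raw_line: str

    @property
    def coords(self) -> tuple[float, float, float]:
        return (self.x, self.y, self.z)

    def fields(self) -> list[str]:
        """Whitespace-delimited columns of the atom line (1-based outside)."""
        return self.raw_line.split()


@dataclass
class Molfile:
    name: str
    comments: list[str]
    counts_line: str
    atoms: list[Atom]
    bond_block: list[str]
    property_block: list[str]

    def copy(self) -> "Molfile":
        return Molfile(
            self.name,
            list(self.comments),
            self.counts_line,
            [Atom(a.index, a.element, a.x, a.y, a.z, a.raw_line) for a in self.atoms],
            list(self.bond_block),
            list(self.property_block),
        )


@dataclass
class MetaValue:
    """A named or anonymous metadata value.

    ``structure`` is one of ``single``/``list``/``dict``; ``dtype`` is the
    shared scalar type of the payload values (``int``/``float``/``str``).
    The payload is never empty: valueless metadata does not exist.
    """

    structure: str
    dtype: str
    payload: Union[Scalar, list, dict]
    name: str | None = None

    def __post_init__(self) -> None:
        if self.structure not in ("single", "list", "dict"):
            raise MetaError(f"bad structure {self.structure!r}")
        if self.structure == "list" and not self.payload:
            raise MetaError("empty list metadata is not allowed")
        if self.structure == "dict" and not self.payload:
            raise MetaError("empty dict metadata is not allowed")

    # -- constructors ------------------------------------------------------

    @staticmethod
    def single(value: Scalar, name: str | None = None) -> "MetaValue":
        return MetaValue("single", dtype_of(value), value, name)

    @staticmethod
    def from_list(values: list, name: str | None = None) -> "MetaValue":
        values, dt = _harmonize(list(values))
        return MetaValue("list", dt, values, name)

    @staticmethod
    def from_dict(mapping: dict, name: str | None = None) -> "MetaValue":
        vals, dt = _harmonize(list(mapping.values()))
        return MetaValue("dict", dt, dict(zip(mapping.keys(), vals)), name)

    @staticmethod
    def of(payload, name: str | None = None):
        """Build from a plain python value; empty collections yield ABSENT."""
        if isinstance(payload, MetaValue):
            return MetaValue(payload.structure, payload.dtype, payload.payload, name)
        if isinstance(payload, dict):
            return MetaValue.from_dict(payload, name) if payload else ABSENT
        if isinstance(payload, (list, tuple)):
            return MetaValue.from_list(list(payload), name) if payload else ABSENT
        return MetaValue.single(payload, name)

    # -- views -------------------------------------------------------------

    def values(self) -> list:
        if self.structure == "single":
            return [self.payload]
        if self.structure == "list":
            return list(self.payload)
        return list(self.payload.values())

    def is_numeric(self) -> bool:
        return self.dtype in ("int", "float")

    def renamed(self, name: str | None) -> "MetaValue":
        return MetaValue(self.structure, self.dtype, self.payload, name)

    def copy(self) -> "MetaValue":
        payload = self.payload
        if isinstance(payload, list):
            payload = list(payload)
        elif isinstance(payload, dict):
            payload = dict(payload)
        return MetaValue(self.structure, self.dtype, payload, self.name)


def _harmonize(values: list) -> tuple[list, str]:
    """Promote mixed int/float to float; any string degrades all to string."""
    if not values:
        raise MetaError("empty metadata payload")
    dts = {dtype_of(v) for v in values}
    if dts == {"int"}:
        return values, "int"
    if dts <= {"int", "float"}:
        return [float(v) for v in values], "float"
    if dts == {"str"}:
        return values, "str"
    return [format_scalar(v) for v in values], "str"


@dataclass
class ConformationRecord:
    molfile: Molfile
    meta: dict[str, MetaValue] = field(default_factory=dict)
    group_key: str = ""
    conf_number: int = 0

    @property
    def name(self) -> str:
        return self.molfile.name

    def copy(self) -> "ConformationRecord":
        return ConformationRecord(
            self.molfile.copy(),
            {k: v.copy() for k, v in self.meta.items()},
            self.group_key,
            self.conf_number,
        )


class Ensemble:
    """Ordered conformation records plus a grouping index.

    Iteration order is input-file order; ``groups`` maps each group key to
    its records in that same order.
    """

    def __init__(
        self,
        records: Iterable[ConformationRecord] = (),
        group_field: str = "name",
        assign_confs: bool = True,
    ):
        self.records: list[ConformationRecord] = list(records)
        self.group_field = group_field
        self.groups: dict[str, list[ConformationRecord]] = {}
        self.rebuild_groups()
        if assign_confs:
            assign_conf_numbers(self)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ConformationRecord]:
        return iter(self.records)

    def rebuild_groups(self) -> None:
        groups: dict[str, list[ConformationRecord]] = {}
        for rec in self.records:
            if self.group_field == "name":
                key = rec.molfile.name
            else:
                mv = rec.meta.get(self.group_field)
                if mv is None:
                    raise MetaError(
                        f"record {rec.molfile.name!r} lacks grouping field "
                        f"{self.group_field!r}"
                    )
                key = format_scalar(mv.payload if mv.structure == "single" else mv.values()[0])
            rec.group_key = key
            groups.setdefault(key, []).append(rec)
        self.groups = groups

    def copy(self) -> "Ensemble":
        ens = Ensemble.__new__(Ensemble)
        ens.records = [r.copy() for r in self.records]
        ens.group_field = self.group_field
        ens.groups = {}
        ens.rebuild_groups()
        return ens

    def meta_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for rec in self.records:
            for name in rec.meta:
                seen.setdefault(name)
        return list(seen)


# ---------------------------------------------------------------------------
# conformation tags


_CONF_TAG_RE = re.compile(r"^(?P<base>.*)\{\[conf\|(?P<num>[0-9]+)\]\}$")


def encode_conf_tag(name: str, conf_number: int) -> str:
    """Append the ``{[conf|N]}`` tag to a molecule name."""
    return f"{name}{{[conf|{conf_number}]}}"


def decode_conf_tag(name: str) -> tuple[str, int | None]:
    """Split a tagged name into (base name, conf number); malformed tags pass through."""
    m = _CONF_TAG_RE.match(name)
    if m:
        return m.group("base"), int(m.group("num"))
    return name, None


def assign_conf_numbers(ens: Ensemble) -> Ensemble:
    """Number records 1..k per group in file order; encoded numbers win.

    A record whose ``conf_number`` is already positive (decoded from a name
    tag at parse time) keeps it; the remaining records fill the smallest
    unused positive integers in order.
    """
    for key, recs in ens.groups.items():
        taken: dict[int, int] = {}
        for i, rec in enumerate(recs):
            if rec.conf_number > 0:
                if rec.conf_number in taken:
                    raise ParseError(
                        f"duplicate conformation number {rec.conf_number} in group "
                        f"{key!r} (entries {taken[rec.conf_number]} and {i})"
                    )
                taken[rec.conf_number] = i
        nxt = 1
        for rec in recs:
            if rec.conf_number <= 0:
                while nxt in taken:
                    nxt += 1
                rec.conf_number = nxt
                taken[nxt] = -1
                nxt += 1
    return ens


def regroup(ens: Ensemble, group_field: str) -> Ensemble:
    """Rebuild groups on a metafield (or "name") and renumber conformations."""
    out = ens.copy()
    out.group_field = group_field
    for rec in out.records:
        rec.conf_number = 0
    out.rebuild_groups()
    assign_conf_numbers(out)
    return out


# ---------------------------------------------------------------------------
# data items (extended notation)


_OVERRIDES = {"%%single%%": "single", "%%list%%": "list", "%%dict%%": "dict"}
_WRAP_WIDTH = 200


def parse_data_item(header_line: str, body_lines: list[str]) -> MetaValue | _Absent:
    """Interpret one ``>  <NAME>`` data item.

    Structure detection: an explicit override prefix line wins; otherwise a
    body whose every token is ``key:value`` is a dict, a multi-token body a
    list, and anything else a single value.  Any body is at worst a single
    string, so this never fails.  An empty body yields ABSENT.
    """
    m = re.match(r"^>.*?<(.*?)>", header_line)
    if not m:
        raise ParseError(f"malformed data item header: {header_line!r}")
    name = m.group(1)

    lines = list(body_lines)
    structure = None
    if lines and lines[0].strip() in _OVERRIDES:
        structure = _OVERRIDES[lines[0].strip()]
        lines = lines[1:]

    if structure == "single":
        text = "\n".join(lines)
        if text == "":
            return ABSENT
        return MetaValue("single", "str", text, name)

    tokens: list[str] = []
    for line in lines:
        tokens.extend(line.split())
    if not tokens:
        return ABSENT

    if structure is None:
        if all(_is_pair(t) for t in tokens):
            structure = "dict"
        elif len(tokens) > 1:
            structure = "list"
        else:
            structure = "single"

    if structure == "dict":
        mapping: dict = {}
        for t in tokens:
            k, _, v = t.partition(":")
            key = coerce_scalar(k)
            if key in mapping:
                raise ParseError(f"duplicate dict key {k!r} in data item {name!r}")
            mapping[key] = coerce_scalar(v)
        return MetaValue.from_dict(mapping, name)
    if structure == "list":
        return MetaValue.from_list([coerce_scalar(t) for t in tokens], name)
    return MetaValue.single(coerce_scalar(tokens[0]), name)


def _is_pair(token: str) -> bool:
    k, sep, v = token.partition(":")
    return bool(sep) and bool(k) and bool(v)


def serialize_meta(mv: MetaValue, name: str | None = None) -> list[str]:
    """Render one data item (header + body lines, no trailing blank line)."""
    name = name if name is not None else mv.name
    if name is None:
        raise SerializationError("cannot serialize anonymous metadata")
    if ">" in name or "<" in name or "\n" in name:
        raise SerializationError(f"illegal character in metadata name {name!r}")

    if mv.structure == "dict":
        tokens = [f"{format_scalar(k)}:{format_scalar(v)}" for k, v in mv.payload.items()]
        body = _wrap(tokens)
        override = not all(_is_pair(t) for t in tokens)
    elif mv.structure == "list":
        tokens = [format_scalar(v) for v in mv.payload]
        body = _wrap(tokens)
        override = (
            len(tokens) == 1
            or any(_is_pair(t) for t in tokens)
            or any(t.strip() == "" for t in tokens)
        )
    else:
        text = format_scalar(mv.payload)
        body = text.split("\n") if text else [""]
        # re-detection must reproduce the value exactly; otherwise mark it
        override = not (
            len(body) == 1
            and len(body[0].split()) == 1
            and not _is_pair(body[0])
            and coerce_scalar(body[0]) == mv.payload
            and dtype_of(coerce_scalar(body[0])) == mv.dtype
        )

    lines = [f">  <{name}>"]
    if override:
        lines.append(f"%%{mv.structure}%%")
    lines.extend(body)
    return lines


def _wrap(tokens: list[str]) -> list[str]:
    lines: list[str] = []
    cur = ""
    for t in tokens:
        if cur and len(cur) + 1 + len(t) > _WRAP_WIDTH:
            lines.append(cur)
            cur = t
        else:
            cur = f"{cur} {t}" if cur else t
    if cur:
        lines.append(cur)
    return lines


# ---------------------------------------------------------------------------
# SDfile parse / write


def parse_sdfile(text: str) -> Ensemble:
    """Parse SDfile content into an Ensemble grouped by molecule name."""
    lines = text.split("\n")
    # drop a single trailing empty element produced by a final newline
    if lines and lines[-1] == "":
        lines.pop()
    records: list[ConformationRecord] = []
    i = 0
    n = len(lines)
    entry_idx = 0
    while i < n:
        # skip stray blank lines between entries / at EOF
        if lines[i].strip() == "":
            i += 1
            continue
        rec, i = _parse_entry(lines, i, entry_idx)
        records.append(rec)
        entry_idx += 1
    return Ensemble(records)


def _parse_entry(lines: list[str], i: int, entry_idx: int) -> tuple[ConformationRecord, int]:
    n = len(lines)
    if n - i < 4:
        raise ParseError(f"entry {entry_idx}: truncated header block")
    raw_name = lines[i]
    comments = [lines[i + 1], lines[i + 2]]
    counts_line = lines[i + 3]
    if "V3000" in counts_line:
        raise ParseError(
            f"entry {entry_idx}: V3000 molfiles are not supported (V2000 only)"
        )
    try:
        natoms = int(counts_line[0:3])
        nbonds = int(counts_line[3:6])
    except ValueError as exc:
        raise ParseError(f"entry {entry_idx}: bad counts line {counts_line!r}") from exc
    i += 4

    atoms: list[Atom] = []
    for a in range(natoms):
        if i >= n or lines[i].strip() == "$$$$":
            raise ParseError(
                f"entry {entry_idx}: atom count mismatch (counts line says "
                f"{natoms}, found {a})"
            )
        raw = lines[i]
        parts = raw.split()
        if len(parts) < 4:
            raise ParseError(f"entry {entry_idx}: truncated atom line {raw!r}")
        try:
            x, y, z = float(parts[0]), float(parts[1]), float(parts[2])
        except ValueError as exc:
            raise ParseError(f"entry {entry_idx}: bad coordinates in {raw!r}") from exc
        if _INT_RE.match(parts[3]):
            # the element column can never be a number: the counts line
            # points past the real atom block (atom count mismatch) or the
            # atom line is truncated and bond fields leaked in
            raise ParseError(
                f"entry {entry_idx}: bad atom line {raw!r} — atom count "
                f"mismatch with the counts line or truncated atom line"
            )
        atoms.append(Atom(a + 1, parts[3], x, y, z, raw))
        i += 1

    bond_block = []
    for _ in range(nbonds):
        if i >= n or lines[i].strip() == "$$$$":
            raise ParseError(f"entry {entry_idx}: bond count mismatch")
        bond_block.append(lines[i])
        i += 1

    property_block = []
    while True:
        if i >= n:
            raise ParseError(f"entry {entry_idx}: missing 'M  END'")
        property_block.append(lines[i])
        if lines[i].rstrip() == "M  END":
            i += 1
            break
        i += 1

    # data items until $$$$
    meta: dict[str, MetaValue] = {}
    while True:
        if i >= n:
            raise ParseError(f"entry {entry_idx}: missing '$$$$' before end of file")
        line = lines[i]
        if line.strip() == "$$$$":
            i += 1
            break
        if line.startswith(">"):
            header = line
            i += 1
            body: list[str] = []
            while i < n and lines[i].strip() != "$$$$" and lines[i].strip() != "":
                if lines[i].startswith(">"):
                    break
                body.append(lines[i])
                i += 1
            mv = parse_data_item(header, body)
            if mv is not ABSENT:
                if mv.name in meta:
                    log.warning("entry %d: duplicate data item %r, keeping last", entry_idx, mv.name)
                meta[mv.name] = mv
        else:
            i += 1  # blank separators or stray text between items

    base, conf = decode_conf_tag(raw_name)
    mol = Molfile(base, comments, counts_line, atoms, bond_block, property_block)
    if base.strip() == "" and base != "":
        log.warning("entry %d: whitespace-only molecule name", entry_idx)
    rec = ConformationRecord(mol, meta, group_key=base, conf_number=conf or 0)
    return rec, i


def write_sdfile(ens: Ensemble, conf_tags: str = "auto") -> str:
    """Serialize an Ensemble back to SDfile text.

    ``conf_tags``: "never" writes plain names, "always" tags every name with
    ``{[conf|N]}``, and "auto" (default) tags only groups whose numbering
    would not be reproduced by in-order assignment on re-parse.
    """
    if conf_tags not in ("auto", "always", "never"):
        raise ValueError(f"bad conf_tags option {conf_tags!r}")
    needs_tag: set[int] = set()
    if conf_tags == "always":
        needs_tag = {id(r) for r in ens.records}
    elif conf_tags == "auto":
        by_name: dict[str, list[ConformationRecord]] = {}
        for rec in ens.records:
            by_name.setdefault(rec.molfile.name, []).append(rec)
        for recs in by_name.values():
            if [r.conf_number for r in recs] != list(range(1, len(recs) + 1)):
                needs_tag.update(id(r) for r in recs)

    out: list[str] = []
    for rec in ens.records:
        mol = rec.molfile
        name = mol.name
        if id(rec) in needs_tag:
            name = encode_conf_tag(name, rec.conf_number)
        out.append(name)
        out.extend(mol.comments)
        out.append(mol.counts_line)
        out.extend(a.raw_line for a in mol.atoms)
        out.extend(mol.bond_block)
        out.extend(mol.property_block)
        for meta_name, mv in rec.meta.items():
            out.extend(serialize_meta(mv, meta_name))
            out.append("")
        out.append("$$$$")
    if not out:
        return ""
    return "\n".join(out) + "\n"


def read_sdfile(path: str | Path) -> Ensemble:
    """Read an SDfile from disk; UTF-8 with Latin-1 fallback for legacy files."""
    data = Path(path).read_bytes()
    try:
        text = data.decode("utf-8")
    except UnicodeDecodeError:
        text = data.decode("latin-1")
    return parse_sdfile(text)
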