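"""Record-level filtering, renaming and metadata bookkeeping.

Filtering uses existence semantics: a record is kept when the statement
produces any value at all (ABSENT and empty collections are false; a present
0 or 0.0 is true).  This matches the proximity-filter idiom, where a sliced
distance dictionary either retains entries or vanishes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from confmeta.geometry import IgnoreList
from confmeta.metastatement import Node, evaluate
from confmeta.sdf_core import (
    ABSENT,
    Ensemble,
    MetaError,
    MetaValue,
    SerializationError,
    assign_conf_numbers,
    format_scalar,
)

log = logging.getLogger("confmeta")


def filter_records(
    ens: Ensemble,
    statement: Node | str,
    invert: bool = False,
    ignore: IgnoreList | None = None,
    renumber: bool = False,
) -> Ensemble:
    """Keep records for which the statement evaluates to a value.

    Order and conformation numbers of survivors are preserved; pass
    ``renumber=True`` to renumber conformations 1..k afterwards.
    """
    results = evaluate(statement, ens, ignore)
    kept = []
    for rec, res in zip(ens.records, results):
        present = res is not ABSENT
        if present != invert:
            kept.append(rec.copy())
    out = Ensemble.__new__(Ensemble)
    out.records = kept
    out.group_field = ens.group_field
    out.rebuild_groups()
    if renumber:
        for rec in out.records:
            rec.conf_number = 0
        assign_conf_numbers(out)
    return out


def rename_records(ens: Ensemble, statement: Node | str, ignore: IgnoreList | None = None) -> Ensemble:
    """Replace each header name with the statement's single string value.

    Grouping and conformation numbers are recomputed; molecules that
    collapse onto one name merge into one group (with a warning) and their
    conformations are renumbered.
    """
    results = evaluate(statement, ens, ignore)
    out = ens.copy()
    old_names = {r.molfile.name for r in ens.records}
    new_names = set()
    for rec, res in zip(out.records, results):
        if res is ABSENT:
            raise MetaError(
                f"rename statement produced no value for record "
                f"{rec.molfile.name!r} conf {rec.conf_number}: a molecule cannot be nameless"
            )
        if isinstance(res, (dict, list)):
            raise MetaError(
                f"rename statement must produce a single value, got a "
                f"{type(res).__name__} for {rec.molfile.name!r}"
            )
        rec.molfile.name = format_scalar(res)
        new_names.add(rec.molfile.name)
    if len(new_names) < len(old_names):
        log.warning(
            "rename merged %d names into %d groups; conformations renumbered",
            len(old_names), len(new_names),
        )
    for rec in out.records:
        rec.conf_number = 0
    out.group_field = "name"
    out.rebuild_groups()
    assign_conf_numbers(out)
    return out


def store_header_as_meta(ens: Ensemble, meta_name: str, overwrite: bool = False) -> Ensemble:
    """Copy each record's header molecule name into a single string metadata."""
    out = ens.copy()
    for rec in out.records:
        if meta_name in rec.meta and not overwrite:
            raise MetaError(f"metadata {meta_name!r} already exists (use overwrite)")
        rec.meta[meta_name] = MetaValue.single(rec.molfile.name, meta_name)
    return out


@dataclass
class MetaReportEntry:
    name: str
    structures: set[str]
    dtypes: set[str]
    count: int


def list_meta(ens: Ensemble) -> list[MetaReportEntry]:
    """Per metadata name: structures, dtypes and number of carrying records."""
    report: dict[str, MetaReportEntry] = {}
    for rec in ens.records:
        for name, mv in rec.meta.items():
            entry = report.setdefault(name, MetaReportEntry(name, set(), set(), 0))
            entry.structures.add(mv.structure)
            entry.dtypes.add(mv.dtype)
            entry.count += 1
    return list(report.values())


def format_meta_report(entries: list[MetaReportEntry]) -> str:
    lines = [f"{'name':<24} {'structure':<12} {'dtype':<10} records"]
    for e in entries:
        lines.append(
            f"{e.name:<24} {'/'.join(sorted(e.structures)):<12} "
            f"{'/'.join(sorted(e.dtypes)):<10} {e.count}"
        )
    return "\n".join(lines)


def remove_meta(ens: Ensemble, names: list[str]) -> Ensemble:
    """Delete the listed metadata names wherever they occur."""
    out = ens.copy()
    drop = set(names)
    for rec in out.records:
        rec.meta = {k: v for k, v in rec.meta.items() if k not in drop}
    return out


def keep_meta(ens: Ensemble, names: list[str]) -> Ensemble:
    """Delete every metadata name except the listed ones."""
    out = ens.copy()
    keep = set(names)
    for rec in out.records:
        rec.meta = {k: v for k, v in rec.meta.items() if k in keep}
    return out


def new_meta(
    ens: Ensemble,
    name: str,
    statement: Node | str,
    ignore: IgnoreList | None = None,
) -> Ensemble:
    """Store the per-record statement results under a new metadata name.

    Records for which the statement is ABSENT simply lack the new metadata:
    there is no metadata if there is no value.
    """
    if ">" in name or "<" in name or "\n" in name:
        raise SerializationError(f"illegal character in metadata name {name!r}")
    results = evaluate(statement, ens, ignore)
    out = ens.copy()
    for rec, res in zip(out.records, results):
        mv = MetaValue.of(res, name) if res is not ABSENT else ABSENT
        if mv is ABSENT:
            rec.meta.pop(name, None)
            continue
        rec.meta[name] = mv
    return out
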