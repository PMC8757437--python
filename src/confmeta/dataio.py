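"""External-data interchange: CSV import/export, SDF combine, mol2 atom types.

CSV files are keyed by molecule name in their first column (overridable); a
key may carry a ``{[conf|N]}`` tag, in which case the row attaches to that
single conformation, otherwise it attaches to every conformation of the
name.  Cells holding whitespace-separated ``key:value`` pairs round-trip as
dict metadata.  mol2 (TRIPOS) files are consulted read-only for SYBYL atom
types, matched to the ensemble positionally (file order), because format
converters routinely mangle molecule names.
"""

from __future__ import annotations

import csv
import io
import logging
from dataclasses import dataclass, field

from confmeta.sdf_core import (
    ConformationRecord,
    Ensemble,
    MetaError,
    MetaValue,
    ParseError,
    coerce_scalar,
    decode_conf_tag,
    encode_conf_tag,
    format_scalar,
)

log = logging.getLogger("confmeta")


@dataclass
class CsvTable:
    header: list[str]
    rows: list[list[str]] = field(default_factory=list)
    delimiter: str = ","

    def __post_init__(self) -> None:
        for i, row in enumerate(self.rows):
            if len(row) != len(self.header):
                raise ParseError(
                    f"CSV row {i + 1} has {len(row)} cells, header has {len(self.header)}"
                )

    @staticmethod
    def parse(text: str, delimiter: str | None = None) -> "CsvTable":
        """Parse CSV/TSV text; the delimiter is auto-detected from the header
        line (tab wins over comma if present) unless given explicitly."""
        first = text.split("\n", 1)[0]
        if delimiter is None:
            delimiter = "\t" if "\t" in first else ","
        reader = csv.reader(io.StringIO(text), delimiter=delimiter)
        rows = [row for row in reader if row]
        if not rows:
            raise ParseError("empty CSV file")
        return CsvTable(rows[0], rows[1:], delimiter)

    def to_text(self) -> str:
        buf = io.StringIO()
        writer = csv.writer(buf, delimiter=self.delimiter, lineterminator="\n")
        writer.writerow(self.header)
        writer.writerows(self.rows)
        return buf.getvalue()

    def column_index(self, col: int | str) -> int:
        if isinstance(col, int):
            if not 0 <= col < len(self.header):
                raise MetaError(f"no CSV column {col}")
            return col
        try:
            return self.header.index(col)
        except ValueError as exc:
            raise MetaError(f"no CSV column named {col!r}") from exc


def _parse_cell(cell: str):
    """Interpret one CSV cell with the data-item structure rules."""
    tokens = cell.split()
    if not tokens:
        return None
    if all(":" in t and t.partition(":")[0] and t.partition(":")[2] for t in tokens):
        mapping = {}
        for t in tokens:
            k, _, v = t.partition(":")
            mapping[coerce_scalar(k)] = coerce_scalar(v)
        return MetaValue.from_dict(mapping)
    if len(tokens) > 1:
        return MetaValue.from_list([coerce_scalar(t) for t in tokens])
    return MetaValue.single(coerce_scalar(tokens[0]))


def _format_cell(mv: MetaValue) -> str:
    if mv.structure == "dict":
        return " ".join(f"{format_scalar(k)}:{format_scalar(v)}" for k, v in mv.payload.items())
    if mv.structure == "list":
        return " ".join(format_scalar(v) for v in mv.payload)
    return format_scalar(mv.payload)


def import_csv(
    ens: Ensemble,
    table: CsvTable,
    name_col: int | str = 0,
    overwrite: bool = True,
) -> Ensemble:
    """Merge CSV columns into matching records as metadata.

    Rows whose key matches no record are reported at warning level and
    skipped; duplicate (name, conformation) keys in the CSV are an error.
    """
    key_idx = table.column_index(name_col)
    seen: dict[tuple[str, int | None], int] = {}
    dups = []
    for i, row in enumerate(table.rows):
        key = decode_conf_tag(row[key_idx])
        if key in seen:
            dups.append((row[key_idx], seen[key] + 1, i + 1))
        seen[key] = i
    if dups:
        detail = "; ".join(f"{k!r} (rows {a} and {b})" for k, a, b in dups)
        raise MetaError(f"duplicate keys in CSV: {detail}")

    out = ens.copy()
    by_name: dict[str, list[ConformationRecord]] = {}
    for rec in out.records:
        by_name.setdefault(rec.molfile.name, []).append(rec)

    unmatched = 0
    for row in table.rows:
        name, conf = decode_conf_tag(row[key_idx])
        targets = by_name.get(name, [])
        if conf is not None:
            targets = [r for r in targets if r.conf_number == conf]
        if not targets:
            unmatched += 1
            continue
        for col, cell in enumerate(row):
            if col == key_idx:
                continue
            mv = _parse_cell(cell)
            if mv is None:
                continue  # no metadata without a value
            meta_name = table.header[col]
            for rec in targets:
                if meta_name in rec.meta and not overwrite:
                    continue
                rec.meta[meta_name] = mv.renamed(meta_name).copy()
    if unmatched:
        log.warning("import_csv: %d CSV row(s) matched no record", unmatched)
    return out


def export_csv(ens: Ensemble, meta_names: list[str], delimiter: str = ",") -> CsvTable:
    """One row per record with the conf-tagged name as key column.

    Dict metadata is flattened to ``key:value`` pairs inside one cell, so
    :func:`import_csv` restores it.  Requesting only names that resolve on
    no record at all is an error.
    """
    resolving = [n for n in meta_names if any(n in r.meta for r in ens.records)]
    if meta_names and not resolving and len(ens.records) > 0:
        raise MetaError(f"none of {meta_names!r} resolves on any record")
    rows = []
    for rec in ens.records:
        row = [encode_conf_tag(rec.molfile.name, rec.conf_number)]
        for name in meta_names:
            mv = rec.meta.get(name)
            row.append("" if mv is None else _format_cell(mv))
        rows.append(row)
    return CsvTable(["name"] + list(meta_names), rows, delimiter)


def combine_sdf(ens: Ensemble, other: Ensemble, overwrite: bool = False) -> Ensemble:
    """Copy metadata from ``other`` onto matching records of ``ens``.

    A name whose group in ``other`` holds a single record carries
    molecule-level data: it attaches to every conformation of that name.
    Multi-conformer groups match on (name, conformation number); a name
    match with a conformation mismatch transfers nothing.  Structures are
    never touched; existing metadata is kept unless ``overwrite``.
    """
    out = ens.copy()
    other_by_name: dict[str, list[ConformationRecord]] = {}
    for rec in other.records:
        other_by_name.setdefault(rec.molfile.name, []).append(rec)

    matched = 0
    for rec in out.records:
        sources = other_by_name.get(rec.molfile.name)
        if not sources:
            continue
        if len(sources) == 1:
            src = sources[0]
        else:
            src = next((s for s in sources if s.conf_number == rec.conf_number), None)
            if src is None:
                continue
        matched += 1
        for name, mv in src.meta.items():
            if name in rec.meta and not overwrite:
                continue
            rec.meta[name] = mv.copy()
    log.info("combine_sdf: %d of %d records received metadata", matched, len(out.records))
    return out


# ---------------------------------------------------------------------------
# mol2 (TRIPOS)


def parse_mol2_atomtypes(mol2_text: str) -> list[list[tuple[int, str]]]:
    """SYBYL atom types per molecule from TRIPOS MOLECULE/ATOM sections.

    Returns, per molecule in file order, a list of (atom id, SYBYL type)
    taken from column 6 of the ATOM lines.
    """
    molecules: list[list[tuple[int, str]]] = []
    lines = mol2_text.split("\n")
    i = 0
    while i < len(lines):
        if lines[i].strip() == "@<TRIPOS>MOLECULE":
            molecules.append([])
            i += 1
        elif lines[i].strip() == "@<TRIPOS>ATOM":
            if not molecules:
                raise ParseError("mol2 ATOM section before any MOLECULE section")
            i += 1
            while i < len(lines) and not lines[i].startswith("@<TRIPOS>") and lines[i].strip():
                parts = lines[i].split()
                if len(parts) < 6:
                    raise ParseError(f"truncated mol2 ATOM line: {lines[i]!r}")
                molecules[-1].append((int(parts[0]), parts[5]))
                i += 1
        else:
            i += 1
    return molecules


def import_mol2_atomtypes(ens: Ensemble, mol2_text: str, meta_name: str = "sybyl") -> Ensemble:
    """Attach SYBYL atom types as an atom-keyed dict metadata.

    Matching is positional: the i-th mol2 molecule types the i-th record,
    and atom counts must agree, because converted files rarely keep usable
    names.
    """
    per_mol = parse_mol2_atomtypes(mol2_text)
    if len(per_mol) != len(ens.records):
        raise MetaError(
            f"mol2 holds {len(per_mol)} molecules but the ensemble has "
            f"{len(ens.records)} records"
        )
    out = ens.copy()
    for idx, (rec, atoms) in enumerate(zip(out.records, per_mol)):
        if len(atoms) != len(rec.molfile.atoms):
            raise MetaError(
                f"atom count mismatch at molecule {idx} ({rec.molfile.name!r}): "
                f"mol2 has {len(atoms)}, SDF has {len(rec.molfile.atoms)}"
            )
        mapping = {atom_id: sybyl for atom_id, sybyl in atoms}
        rec.meta[meta_name] = MetaValue.from_dict(mapping, meta_name)
    return out
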