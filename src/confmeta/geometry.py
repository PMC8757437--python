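"""Atom-level spatial computations against points of interest.

All atom-wise operations honor an element ignore list; by default hydrogens
are ignored, so distance dictionaries and centroids cover heavy atoms only
unless the list is cleared.
"""

from __future__ import annotations

from typing import Iterable, Iterator

import numpy as np

from confmeta.sdf_core import ABSENT, ConformationRecord

Point = tuple[float, float, float]


class IgnoreList:
    """Set of element symbols excluded from atom-wise operations.

    Matching is case-sensitive on the stripped V2000 element field.  The
    default is ``{"H"}``; pass an empty iterable to include every atom.
    """

    def __init__(self, elements: Iterable[str] | None = None):
        self.elements: frozenset[str] = (
            frozenset({"H"}) if elements is None else frozenset(elements)
        )

    def __contains__(self, element: str) -> bool:
        return element in self.elements

    def __iter__(self) -> Iterator[str]:
        return iter(self.elements)

    def __repr__(self) -> str:
        return f"IgnoreList({sorted(self.elements)})"

    @staticmethod
    def none() -> "IgnoreList":
        """An empty ignore list: no element is excluded."""
        return IgnoreList(())


def _kept_atoms(rec: ConformationRecord, ignore: IgnoreList):
    return [a for a in rec.molfile.atoms if a.element not in ignore]


def distances_to_point(
    rec: ConformationRecord,
    point: Point,
    ignore: IgnoreList | None = None,
):
    """Euclidean distance (Å) from each non-ignored atom to ``point``.

    Returns a dict keyed by atom number, or ABSENT when every atom of the
    record is ignored.
    """
    ignore = ignore if ignore is not None else IgnoreList()
    p = np.asarray(point, dtype=float)
    if not np.all(np.isfinite(p)) or p.shape != (3,):
        raise ValueError(f"point of interest must be three finite coordinates, got {point!r}")
    atoms = _kept_atoms(rec, ignore)
    if not atoms:
        return ABSENT
    xyz = np.array([a.coords for a in atoms], dtype=float)
    d = np.sqrt(((xyz - p) ** 2).sum(axis=1))
    return {a.index: float(di) for a, di in zip(atoms, d)}


def centroid(
    recs: ConformationRecord | Iterable[ConformationRecord],
    ignore: IgnoreList | None = None,
) -> Point:
    """Unweighted mean position of the non-ignored atoms.

    For one record this is the mean of its atom coordinates.  For an
    iterable of records (e.g. the top-ranked poses of a group) the result
    is the mean of the per-record centroids, so each pose contributes
    equally regardless of its atom count.
    """
    ignore = ignore if ignore is not None else IgnoreList()
    if isinstance(recs, ConformationRecord):
        recs = [recs]
    centers = []
    for rec in recs:
        atoms = _kept_atoms(rec, ignore)
        if not atoms:
            continue
        centers.append(np.array([a.coords for a in atoms], dtype=float).mean(axis=0))
    if not centers:
        raise ValueError("centroid of an empty atom selection")
    c = np.asarray(centers).mean(axis=0)
    return (float(c[0]), float(c[1]), float(c[2]))
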