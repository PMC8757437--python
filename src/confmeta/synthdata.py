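"""Deterministic docking-style fixture generator.

Emulates the output of a Plants-like docking run on a ligand set: an SDfile
of N molecules x K conformers with mangled names
(``<name>_entry_<5-digit>_conf_<2-digit>``), a name-correspondence CSV, a
per-conformer score ranking CSV (lower score = better pose), a per-molecule
activity CSV (IC50 in nM, coupled to the best score through a linear model
on the pIC50 scale), and a positionally matching mol2 file with SYBYL atom
types.

Molecules are simple alkanol-like chains (carbons, a hydroxyl oxygen, and
its hydrogen); conformers are rigid-body placements near a binding-site
point.  A seeded, controllable subset of conformers is planted with the
hydroxyl O and H both within 2.5 Å of the site point; all other conformers
keep both atoms beyond 3.0 Å, so the planted set is exactly the ground
truth for hydroxyl-proximity filters.  A manifest records that truth.

The same seed always yields byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

#: Binding-site point of interest (Å) used by the example pipelines: the
#: carboxylate oxygen of a key glutamate in the receptor pocket.
SITE_POINT = (24.31, -3.29, 25.59)

# score <-> activity coupling, all in one place so correlation tests can
# reason about the noise level: pIC50 = PIC50_OFFSET + PIC50_SLOPE * best
# score + Normal(0, PIC50_NOISE_SD)
SCORE_BASE_RANGE = (30.0, 90.0)   # per-molecule best-pose quality
SCORE_SPREAD = 25.0               # extra per-conformer penalty, U(0, spread)
PIC50_OFFSET = 12.0
PIC50_SLOPE = -0.08               # lower (better) score -> higher pIC50
PIC50_NOISE_SD = 0.3

_SYBYL = {"C": "C.3", "O": "O.3", "H": "H"}


@dataclass
class Fixture:
    """Generated fixture files as text, plus the planted-truth manifest."""

    sdf_text: str
    corresponding_names_csv: str
    ranking_csv: str
    activity_csv: str
    mol2_text: str
    manifest: dict

    def write_to(self, directory: str | Path) -> dict[str, Path]:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        paths = {
            "sdf": d / "docked_structures.sdf",
            "names": d / "correspondingNames.csv",
            "ranking": d / "ranking.csv",
            "activity": d / "activity.csv",
            "mol2": d / "docked_structures.mol2",
            "manifest": d / "manifest.json",
        }
        paths["sdf"].write_text(self.sdf_text)
        paths["names"].write_text(self.corresponding_names_csv)
        paths["ranking"].write_text(self.ranking_csv)
        paths["activity"].write_text(self.activity_csv)
        paths["mol2"].write_text(self.mol2_text)
        paths["manifest"].write_text(json.dumps(self.manifest, indent=1))
        return paths


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix, sign-fixed)."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _base_molecule(rng: np.random.Generator) -> tuple[list[str], np.ndarray, list[tuple[int, int]]]:
    """An alkanol-like chain: C...C-O-H with roughly bond-length geometry."""
    n_c = int(rng.integers(3, 9))
    elements = ["C"] * n_c + ["O", "H"]
    coords = np.zeros((n_c + 2, 3))
    for i in range(n_c):
        coords[i] = (1.54 * i, 0.5 * (i % 2), 0.0)
    coords[:n_c] += rng.normal(0.0, 0.05, size=(n_c, 3))  # mild jitter
    coords[n_c] = coords[n_c - 1] + (1.10, 0.92, 0.0)     # O, ~1.43 Å from last C
    coords[n_c + 1] = coords[n_c] + (0.30, 0.91, 0.0)     # H, ~0.96 Å from O
    bonds = [(i + 1, i + 2) for i in range(n_c)] + [(n_c + 1, n_c + 2)]
    return elements, coords, bonds


def _place(
    coords: np.ndarray,
    rng: np.random.Generator,
    planted: bool,
    point: np.ndarray,
) -> np.ndarray:
    """Rigid-body placement; planted poses put the O-H midpoint within
    ~1.6 Å of the site point (so O and H are both well inside 2.5 Å),
    other poses keep it at 3.5 Å or further (both outside 3.0 Å)."""
    rot = _random_rotation(rng)
    placed = coords @ rot.T
    mid = (placed[-2] + placed[-1]) / 2.0
    u = rng.normal(size=3)
    u /= np.linalg.norm(u)
    dist = rng.uniform(0.8, 1.6) if planted else rng.uniform(3.5, 8.0)
    return placed + (point + u * dist - mid)


def _sdf_entry(name: str, elements: list[str], coords: np.ndarray,
               bonds: list[tuple[int, int]]) -> list[str]:
    lines = [name, "  confmeta synthetic docking pose", ""]
    lines.append(f"{len(elements):3d}{len(bonds):3d}  0  0  0  0  0  0  0  0999 V2000")
    for el, (x, y, z) in zip(elements, coords):
        lines.append(
            f"{x:10.4f}{y:10.4f}{z:10.4f} {el:<3} 0  0  0  0  0  0  0  0  0  0  0  0"
        )
    for a, b in bonds:
        lines.append(f"{a:3d}{b:3d}  1  0")
    lines.append("M  END")
    lines.append("$$$$")
    return lines


def _mol2_entry(name: str, elements: list[str], coords: np.ndarray,
                bonds: list[tuple[int, int]]) -> list[str]:
    lines = [
        "@<TRIPOS>MOLECULE",
        name,
        f" {len(elements)} {len(bonds)} 0 0 0",
        "SMALL",
        "NO_CHARGES",
        "",
        "@<TRIPOS>ATOM",
    ]
    counts: dict[str, int] = {}
    for i, (el, (x, y, z)) in enumerate(zip(elements, coords), start=1):
        counts[el] = counts.get(el, 0) + 1
        lines.append(
            f"{i:7d} {el}{counts[el]:<4d} {x:10.4f} {y:10.4f} {z:10.4f} "
            f"{_SYBYL[el]:<5} 1 LIG1 0.0000"
        )
    lines.append("@<TRIPOS>BOND")
    for i, (a, b) in enumerate(bonds, start=1):
        lines.append(f"{i:6d} {a:5d} {b:5d} 1")
    return lines


def generate_fixture(
    n_molecules: int = 99,
    n_confs: int = 10,
    seed: int = 1,
    planted_fraction: float = 0.1,
    site_point: tuple[float, float, float] = SITE_POINT,
) -> Fixture:
    """Generate the full fixture set.

    ``planted_fraction`` of all conformers (rounded, chosen without
    replacement) receive a hydroxyl placed within 2.5 Å of ``site_point``.
    """
    if n_molecules < 1 or n_confs < 1:
        raise ValueError("need at least one molecule and one conformer")
    rng = np.random.default_rng(seed)
    point = np.asarray(site_point, dtype=float)

    total = n_molecules * n_confs
    n_planted = int(round(planted_fraction * total))
    planted_idx = set(
        rng.choice(total, size=n_planted, replace=False).tolist()
    ) if n_planted else set()

    entry_ids = rng.choice(np.arange(1, 100000), size=n_molecules, replace=False)

    sdf: list[str] = []
    mol2: list[str] = []
    names_rows = ["PLANTS_LIGAND_DESCRIPTION,OLD_LIGAND_DESCRIPTION"]
    ranking_rows = ["LIGAND_ENTRY,TOTAL_SCORE,SCORE_RB_PEN,EVAL,TIME"]
    activity_rows = ["name,IC50_nM"]
    planted_manifest = []

    flat = 0
    for i in range(n_molecules):
        real = f"CHEMBLSYN{i + 1}"
        elements, base_coords, bonds = _base_molecule(rng)
        base_quality = rng.uniform(*SCORE_BASE_RANGE)
        best_score = None
        for j in range(n_confs):
            mangled = f"{real}_entry_{int(entry_ids[i]):05d}_conf_{j + 1:02d}"
            planted = flat in planted_idx
            coords = _place(base_coords, rng, planted, point)
            score = base_quality + rng.uniform(0.0, SCORE_SPREAD)
            best_score = score if best_score is None else min(best_score, score)
            sdf.extend(_sdf_entry(mangled, elements, coords, bonds))
            mol2.extend(_mol2_entry(mangled, elements, coords, bonds))
            names_rows.append(f"{mangled},{real}")
            ranking_rows.append(
                f"{mangled},{score:.4f},{rng.uniform(0, 5):.4f},"
                f"{int(rng.integers(1000, 9999))},{rng.uniform(0.5, 30):.2f}"
            )
            if planted:
                planted_manifest.append(
                    {"name": real, "conf": j + 1, "plants_name": mangled}
                )
            flat += 1
        pic50 = PIC50_OFFSET + PIC50_SLOPE * best_score + rng.normal(0.0, PIC50_NOISE_SD)
        ic50_nm = 10.0 ** (9.0 - pic50)
        activity_rows.append(f"{real},{ic50_nm:.6g}")

    manifest = {
        "n_molecules": n_molecules,
        "n_confs": n_confs,
        "seed": seed,
        "site_point": list(site_point),
        "n_planted": len(planted_manifest),
        "planted": planted_manifest,
    }
    return Fixture(
        sdf_text="\n".join(sdf) + "\n",
        corresponding_names_csv="\n".join(names_rows) + "\n",
        ranking_csv="\n".join(ranking_rows) + "\n",
        activity_csv="\n".join(activity_rows) + "\n",
        mol2_text="\n".join(mol2) + "\n",
        manifest=manifest,
    )
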