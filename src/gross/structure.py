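"""Seven-helix transmembrane bundle abstraction and structure-file I/O.

A GPCR's membrane-spanning region is modelled as a :class:`TMBundle`: seven
ordered runs of residues (TM1..TM7), each residue carrying its heavy atoms.
TM extents are *input* — a per-structure annotation (membrane-slab core from
OPM-style placement, optionally widened to the full DSSP α-helix) — because
membrane placement and secondary-structure assignment are external to this
package.  Author residue numbering (the numbering printed in the structure
file) is used throughout; helix anchors such as ``L134`` refer to it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

HELICES = (1, 2, 3, 4, 5, 6, 7)

_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

#: Modified residues mapped to their standard parent (contact counting needs
#: side-chain bulk, not chemistry).  Selenium atoms keep their own vdW radius.
MODIFIED_PARENTS: Mapping[str, str] = {
    "MSE": "MET",
    "CSO": "CYS",
    "OCS": "CYS",
    "SEP": "SER",
    "TPO": "THR",
    "PTR": "TYR",
    "MLY": "LYS",
    "HYP": "PRO",
    "PCA": "GLU",
}

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}
_ONE_TO_THREE["X"] = "UNK"


class StructureError(ValueError):
    """Raised when a structure file cannot be resolved into a 7-helix bundle."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom: name, element symbol, position in Å."""

    name: str
    element: str
    position: np.ndarray
    is_heavy: bool = True

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)
        expected_heavy = self.element.upper() not in ("H", "D")
        if self.is_heavy != expected_heavy:
            raise ValueError(f"atom {self.name}: heavy flag inconsistent with element {self.element}")


@dataclass(frozen=True)
class ResidueRecord:
    """One residue in author numbering with its (heavy) atoms."""

    author_index: int
    aa: str
    atoms: tuple[AtomRecord, ...]

    def __post_init__(self) -> None:
        if self.aa not in _STANDARD_AA and self.aa != "X":
            raise ValueError(f"residue {self.author_index}: aa {self.aa!r} not a standard letter or 'X'")

    @property
    def ca(self) -> AtomRecord | None:
        for atom in self.atoms:
            if atom.name == "CA":
                return atom
        return None

    def heavy_atoms(self) -> tuple[AtomRecord, ...]:
        return tuple(a for a in self.atoms if a.is_heavy)


@dataclass(frozen=True)
class TMAnnotation:
    """Inclusive author-numbered (start, end) range for each of TM1..TM7."""

    ranges: Mapping[int, tuple[int, int]]

    def __post_init__(self) -> None:
        ranges = {int(n): (int(s), int(e)) for n, (s, e) in dict(self.ranges).items()}
        if set(ranges) != set(HELICES):
            raise ValueError(f"annotation must cover helices 1..7, got {sorted(ranges)}")
        prev_end = None
        for n in HELICES:
            s, e = ranges[n]
            if s > e:
                raise ValueError(f"TM{n}: start {s} > end {e}")
            if prev_end is not None and s <= prev_end:
                raise ValueError(f"TM{n} range overlaps or precedes TM{n - 1}")
            prev_end = e
        object.__setattr__(self, "ranges", ranges)

    def __getitem__(self, helix: int) -> tuple[int, int]:
        return self.ranges[helix]


@dataclass(frozen=True)
class TMBundle:
    """A 7-helix bundle: the TM residues of one structure.

    ``helices`` maps helix number (1..7) to the ordered run of residues that
    the TM annotation resolved in the structure file.
    """

    structure_id: str
    helices: Mapping[int, tuple[ResidueRecord, ...]]
    protein_id: str = ""
    class_label: str = ""
    state: str = "unknown"

    def __post_init__(self) -> None:
        helices = {int(n): tuple(res) for n, res in dict(self.helices).items()}
        if set(helices) != set(HELICES):
            raise ValueError(f"{self.structure_id}: bundle needs exactly helices 1..7")
        for n in HELICES:
            run = helices[n]
            if not run:
                raise ValueError(f"{self.structure_id}: TM{n} is empty")
            idx = [r.author_index for r in run]
            if any(b <= a for a, b in zip(idx, idx[1:])):
                raise ValueError(f"{self.structure_id}: TM{n} author indices not strictly increasing")
        object.__setattr__(self, "helices", helices)
        if self.state not in ("active", "inactive", "unknown"):
            raise ValueError(f"state must be active/inactive/unknown, got {self.state!r}")

    def helix(self, n: int) -> tuple[ResidueRecord, ...]:
        return self.helices[n]

    def residue(self, helix: int, author_index: int) -> ResidueRecord | None:
        for r in self.helices[helix]:
            if r.author_index == author_index:
                return r
        return None

    def tm_range(self, helix: int) -> tuple[int, int]:
        run = self.helices[helix]
        return run[0].author_index, run[-1].author_index

    def n_residues(self) -> int:
        return sum(len(run) for run in self.helices.values())

    def ca_coords(self, helix: int) -> np.ndarray:
        """(L, 3) Cα coordinates of one helix (residues lacking Cα skipped)."""
        coords = [r.ca.position for r in self.helices[helix] if r.ca is not None]
        return np.array(coords, dtype=float).reshape(-1, 3)

    def with_state(self, state: str) -> "TMBundle":
        return replace(self, state=state)


# ---------------------------------------------------------------------------
# structure file reading


def _collapse_altlocs(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """One atom per name: highest occupancy wins, ties broken by altloc order."""
    best: dict[str, gemmi.Atom] = {}
    for atom in residue:
        altloc = atom.altloc if atom.altloc not in ("\x00",) else ""
        prev = best.get(atom.name)
        if prev is None:
            best[atom.name] = atom
            continue
        prev_altloc = prev.altloc if prev.altloc not in ("\x00",) else ""
        if (-atom.occ, altloc or "A") < (-prev.occ, prev_altloc or "A"):
            best[atom.name] = atom
    return list(best.values())


def _one_letter(resname: str) -> str:
    name = MODIFIED_PARENTS.get(resname, resname)
    return _THREE_TO_ONE.get(name, "X")


def load_structure(
    path: str | Path,
    chain: str,
    annotation: TMAnnotation,
    *,
    structure_id: str | None = None,
    protein_id: str = "",
    class_label: str = "",
    state: str = "unknown",
) -> TMBundle:
    """Read a PDB/mmCIF file and return the annotated 7-helix bundle.

    The first model is used; hydrogens are dropped, alternate locations are
    collapsed to the highest-occupancy atom (ties → altloc 'A'), zero-occupancy
    atoms are excluded, and modified residues are mapped to their standard
    parents.  A helix range that resolves to zero residues is a hard error
    naming the helix.
    """
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise StructureError(f"{path}: no models")
    model = st[0]
    gchain = model.find_chain(chain)
    if gchain is None:
        raise StructureError(f"{path}: chain {chain!r} not found")

    by_index: dict[int, ResidueRecord] = {}
    for gres in gchain:
        info = gemmi.find_tabulated_residue(gres.name)
        is_aa = info.is_amino_acid() if info is not None else gres.name in MODIFIED_PARENTS
        if not is_aa:
            continue
        atoms = []
        for atom in _collapse_altlocs(gres):
            element = atom.element.name.upper()
            if element in ("H", "D") or atom.occ <= 0.0:
                continue
            atoms.append(
                AtomRecord(
                    name=atom.name,
                    element=element,
                    position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                )
            )
        if not atoms:
            continue
        num = gres.seqid.num
        if num in by_index:
            continue  # e.g. microheterogeneity; first residue wins
        by_index[num] = ResidueRecord(author_index=num, aa=_one_letter(gres.name), atoms=tuple(atoms))

    helices: dict[int, tuple[ResidueRecord, ...]] = {}
    for n in HELICES:
        start, end = annotation[n]
        run = tuple(by_index[i] for i in range(start, end + 1) if i in by_index)
        if not run:
            raise StructureError(f"{path}: TM{n} range {start}..{end} resolves to no residues in chain {chain!r}")
        helices[n] = run

    return TMBundle(
        structure_id=structure_id or Path(str(path)).stem,
        helices=helices,
        protein_id=protein_id,
        class_label=class_label,
        state=state,
    )


def write_bundle_pdb(bundle: TMBundle, path: str | Path, chain: str = "A") -> None:
    """Write a bundle back to a single-chain PDB file (TM residues only)."""
    st = gemmi.Structure()
    st.name = bundle.structure_id
    model = gemmi.Model("1")
    gchain = gemmi.Chain(chain)
    for n in HELICES:
        for res in bundle.helix(n):
            gres = gemmi.Residue()
            gres.name = _ONE_TO_THREE.get(res.aa, "UNK")
            gres.seqid = gemmi.SeqId(res.author_index, " ")
            for atom in res.atoms:
                gatom = gemmi.Atom()
                gatom.name = atom.name
                gatom.element = gemmi.Element(atom.element.capitalize())
                gatom.pos = gemmi.Position(*atom.position)
                gatom.occ = 1.0
                gres.add_atom(gatom)
            gchain.add_residue(gres)
    model.add_chain(gchain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# TM-extent handling


def extend_tm_by_helix(annotation: TMAnnotation, helix_assignment: Mapping[int, str]) -> TMAnnotation:
    """Widen each TM core outward while the residue stays α-helical ('H').

    ``helix_assignment`` maps author residue numbers to one-letter secondary
    structure codes (DSSP convention).  The membrane-slab core of each TM is
    extended in both directions until the α-helix ends; ranges are never
    shrunk.  Missing labels inside a core are an error; missing labels outside
    simply stop the extension.
    """
    new_ranges: dict[int, tuple[int, int]] = {}
    for n in HELICES:
        start, end = annotation[n]
        missing = [i for i in range(start, end + 1) if i not in helix_assignment]
        if missing:
            raise ValueError(f"TM{n}: secondary-structure labels missing inside core at {missing[:3]}")
        s = start
        while helix_assignment.get(s - 1) == "H":
            s -= 1
        e = end
        while helix_assignment.get(e + 1) == "H":
            e += 1
        new_ranges[n] = (s, e)
    return TMAnnotation(new_ranges)


def helix_labels_from_dssp(path: str | Path, chain: str) -> dict[int, str]:
    """Per-residue secondary-structure codes from a classic DSSP output file."""
    from Bio.PDB.DSSP import make_dssp_dict

    dssp, _keys = make_dssp_dict(str(path))
    labels: dict[int, str] = {}
    for (ch, res_id), values in dssp.items():
        if ch != chain:
            continue
        labels[res_id[1]] = values[1]
    return labels


# ---------------------------------------------------------------------------
# annotation table I/O (columns: structure_id, chain, tm1_start..tm7_end)


def read_annotations(path: str | Path) -> dict[tuple[str, str], TMAnnotation]:
    """Read a TM-annotation CSV keyed by (structure_id, chain)."""
    df = pd.read_csv(path)
    out: dict[tuple[str, str], TMAnnotation] = {}
    for _, row in df.iterrows():
        ranges = {n: (int(row[f"tm{n}_start"]), int(row[f"tm{n}_end"])) for n in HELICES}
        out[(str(row["structure_id"]), str(row["chain"]))] = TMAnnotation(ranges)
    return out


def write_annotations(annotations: Mapping[tuple[str, str], TMAnnotation], path: str | Path) -> None:
    rows = []
    for (sid, chain), ann in annotations.items():
        row: dict[str, object] = {"structure_id": sid, "chain": chain}
        for n in HELICES:
            row[f"tm{n}_start"], row[f"tm{n}_end"] = ann[n]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
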