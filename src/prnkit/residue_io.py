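"""Parse PDB structures into the residue model that defines network nodes.

Residues — exactly as delimited in the PDB file — become the nodes of every
residue network built downstream, so this module is deliberately conservative:
coordinates and residue numbers are used as printed (no renumbering), only the
first model of multi-model files is read, and alternate locations are resolved
to the highest-occupancy conformer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.Atom import DisorderedAtom

__all__ = [
    "Atom",
    "ResidueId",
    "StructureModel",
    "NoAtomsError",
    "MalformedRecordError",
    "parse_pdb",
    "center_of_mass",
]

# IUPAC 2021 standard atomic weights (abridged), u.  Covers the elements that
# occur in protein/nucleic-acid/ligand PDB files; unknowns fall back to carbon.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008, "D": 2.014, "HE": 4.0026,
    "LI": 6.94, "BE": 9.0122, "B": 10.81, "C": 12.011, "N": 14.007,
    "O": 15.999, "F": 18.998, "NE": 20.180, "NA": 22.990, "MG": 24.305,
    "AL": 26.982, "SI": 28.085, "P": 30.974, "S": 32.06, "CL": 35.45,
    "AR": 39.95, "K": 39.098, "CA": 40.078, "MN": 54.938, "FE": 55.845,
    "CO": 58.933, "NI": 58.693, "CU": 63.546, "ZN": 65.38, "SE": 78.971,
    "BR": 79.904, "MO": 95.95, "I": 126.90, "W": 183.84,
}
_DEFAULT_MASS = 12.011

_WATER_NAMES = {"HOH", "WAT", "H2O", "DOD"}


class NoAtomsError(ValueError):
    """The file contains no ATOM/HETATM records (after filtering)."""


class MalformedRecordError(ValueError):
    """An atom record has unreadable coordinates; carries the line number."""

    def __init__(self, line_number: int, line: str):
        self.line_number = line_number
        super().__init__(
            f"unreadable coordinates on line {line_number}: {line.rstrip()!r}"
        )


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    coord: np.ndarray  # shape (3,), Å
    mass: float  # u
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self):
        object.__setattr__(self, "coord", np.asarray(self.coord, dtype=float))
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name}: coordinate must be a finite 3-vector")
        if not self.mass > 0:
            raise ValueError(f"atom {self.name}: mass must be positive")


@dataclass(frozen=True, order=True)
class ResidueId:
    """Identity of one residue node: chain, PDB number, insertion code, name."""

    chain: str
    number: int
    insertion_code: str = ""
    name: str = ""

    @property
    def label(self) -> str:
        """Canonical node label ``chain:number[:icode]:name``."""
        icode = f":{self.insertion_code}" if self.insertion_code else ""
        return f"{self.chain}:{self.number}{icode}:{self.name}"


@dataclass
class StructureModel:
    """Ordered residues with atoms; the node set of a residue network."""

    residues: list[tuple[ResidueId, list[Atom]]]
    chain_ids: list[str] = field(default_factory=list)
    gaps: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self):
        seen: set[tuple[str, int, str]] = set()
        for rid, atoms in self.residues:
            key = (rid.chain, rid.number, rid.insertion_code)
            if key in seen:
                raise ValueError(f"duplicate residue id {key}")
            seen.add(key)
            if not atoms:
                raise ValueError(f"residue {rid.label} has no atoms")
        if not self.chain_ids:
            self.chain_ids = list(dict.fromkeys(r.chain for r, _ in self.residues))

    def __len__(self) -> int:
        return len(self.residues)

    def residue_ids(self) -> list[ResidueId]:
        return [rid for rid, _ in self.residues]

    def get(self, rid: ResidueId) -> list[Atom]:
        for r, atoms in self.residues:
            if r == rid:
                return atoms
        raise KeyError(rid)


def _element_of(bio_atom) -> str:
    elem = (bio_atom.element or "").strip().upper()
    if elem:
        return elem
    # PDB files are inconsistent; fall back to the first alphabetic character
    # of the atom name (strips the leading digits of names like "1HB").
    for ch in bio_atom.get_name():
        if ch.isalpha():
            return ch.upper()
    return "C"


def _mass_of(element: str) -> float:
    return ATOMIC_MASSES.get(element.upper(), _DEFAULT_MASS)


def _validate_atom_lines(path: Path) -> int:
    """Pre-scan raw records; return count of atom records, raise on bad coords."""
    n = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM  ", "HETATM")):
                n += 1
                try:
                    float(line[30:38])
                    float(line[38:46])
                    float(line[46:54])
                except (ValueError, IndexError):
                    raise MalformedRecordError(lineno, line) from None
            if line.startswith("ENDMDL"):  # only the first model counts
                break
    return n


def parse_pdb(
    path: str | Path,
    *,
    include_het: bool = False,
    drop_waters: bool = True,
) -> StructureModel:
    """Parse a PDB file into a :class:`StructureModel`.

    Waters (HOH/WAT) are excluded when ``drop_waters`` is set; HETATM residues
    (ligands, nucleic acids, saccharides) become nodes only when
    ``include_het`` is set.  For alternate locations only the
    highest-occupancy conformer is kept (ties broken by altloc letter order).
    Numbering gaps within each chain are recorded in ``gaps`` as
    ``(chain, preceding residue number)``.
    """
    path = Path(path)
    if _validate_atom_lines(path) == 0:
        raise NoAtomsError(f"{path}: no ATOM/HETATM records")

    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure("s", str(path))
    model = next(structure.get_models())  # first model only

    residues: list[tuple[ResidueId, list[Atom]]] = []
    for chain in model:
        for res in chain:
            hetflag, resseq, icode = res.get_id()
            name = res.get_resname().strip()
            is_het = hetflag.strip() != ""
            if name in _WATER_NAMES and drop_waters:
                continue
            if is_het and not include_het:
                continue
            atoms: list[Atom] = []
            for a in res:
                if isinstance(a, DisorderedAtom):
                    # highest occupancy, ties broken by altloc letter order
                    best = min(
                        a.disordered_get_list(),
                        key=lambda x: (-(x.get_occupancy() or 0.0), x.get_altloc()),
                    )
                else:
                    best = a
                elem = _element_of(best)
                atoms.append(
                    Atom(
                        name=best.get_name(),
                        element=elem,
                        coord=np.array(best.get_coord(), dtype=float),
                        mass=_mass_of(elem),
                        occupancy=best.get_occupancy() or 1.0,
                        altloc=(best.get_altloc() or "").strip(),
                    )
                )
            if not atoms:
                continue
            rid = ResidueId(
                chain=chain.id, number=resseq, insertion_code=icode.strip(), name=name
            )
            residues.append((rid, atoms))

    if not residues:
        raise NoAtomsError(f"{path}: no residues kept after filtering")

    gaps: list[tuple[str, int]] = []
    by_chain: dict[str, list[int]] = {}
    for rid, _ in residues:
        by_chain.setdefault(rid.chain, []).append(rid.number)
    for chain_id, numbers in by_chain.items():
        for a, b in zip(numbers, numbers[1:]):
            if b > a + 1:
                gaps.append((chain_id, a))

    return StructureModel(residues=residues, gaps=gaps)


def center_of_mass(residue: tuple[ResidueId, Sequence[Atom]] | Iterable[Atom]) -> np.ndarray:
    """Mass-weighted mean coordinate of a residue's atoms, in Å.

    Hydrogens contribute whenever they are present in the file.
    """
    if isinstance(residue, tuple) and len(residue) == 2 and isinstance(residue[0], ResidueId):
        atoms = residue[1]
    else:
        atoms = list(residue)  # bare atom list is accepted too
    if not atoms:
        raise ValueError("residue has no atoms")
    masses = np.array([a.mass for a in atoms])
    coords = np.array([a.coord for a in atoms])
    total = masses.sum()
    if total <= 0:
        raise ValueError("degenerate residue: zero total mass")
    return (masses[:, None] * coords).sum(axis=0) / total
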