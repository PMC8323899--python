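"""Residue/fragment pair interaction energies (PIEs) from FMO output or a force field.

Two sources feed the energy-based residue networks:

* **FMO** — the two-body pair interaction energy table (IFIEs) printed by a
  Gamess fragment molecular orbital run, optionally with the PIEDA
  decomposition (electrostatic ES, exchange repulsion EX, charge transfer+mix
  CT, dispersion DI, solvation screening).  Energies reported in Hartree are
  converted to kcal/mol.
* **Force field** — bare pairwise Coulomb + Lennard-Jones 12-6 sums over the
  static structure, with charges and LJ coefficients taken from an Amber
  ``.prmtop`` topology.  No cutoff, no periodic boundary: the energies refer
  to the structure exactly as it sits in the PDB file.

All energies are stored in kcal/mol.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np

from .residue_io import ResidueId, StructureModel

__all__ = [
    "HARTREE_TO_KCAL",
    "COULOMB_CONSTANT",
    "AMBER_CHARGE_FACTOR",
    "PieComponents",
    "PieTable",
    "FragmentMap",
    "NotAnFmoOutputError",
    "AmbiguousPairError",
    "TopologyMismatchError",
    "AmberTopology",
    "parse_gamess_fmo",
    "parse_prmtop",
    "compute_ff_pies",
    "map_fragments_to_residues",
]

HARTREE_TO_KCAL = 627.5095
#: Coulomb constant in kcal Å mol⁻¹ e⁻²
COULOMB_CONSTANT = 332.0636
#: Amber stores charges multiplied by this factor (≈ √(Coulomb const))
AMBER_CHARGE_FACTOR = 18.2223
#: Amber default 1-4 scaling divisors (SCEE, SCNB)
DEFAULT_SCEE = 1.2
DEFAULT_SCNB = 2.0


class NotAnFmoOutputError(ValueError):
    """No two-body pair-interaction table could be located in the file."""


class AmbiguousPairError(ValueError):
    """The same fragment pair appears more than once with conflicting energies."""


class TopologyMismatchError(ValueError):
    """Atom count/order in the topology does not match the structure."""


@dataclass(frozen=True)
class PieComponents:
    """Energy components of one residue/fragment pair, kcal/mol.

    ``e_tot`` is always present.  PIEDA fields are present iff the source
    provides them; none is sign-constrained (exchange repulsion in particular
    is usually positive).
    """

    e_tot: float
    es: float | None = None
    ex: float | None = None
    ct: float | None = None
    di: float | None = None
    solv: float | None = None
    elec_ff: float | None = None
    vdw_ff: float | None = None

    @property
    def has_pieda(self) -> bool:
        return self.es is not None and self.di is not None

    def as_dict(self) -> dict[str, float]:
        out = {"e_tot": self.e_tot}
        for k in ("es", "ex", "ct", "di", "solv", "elec_ff", "vdw_ff"):
            v = getattr(self, k)
            if v is not None:
                out[k] = v
        return out


@dataclass
class PieTable:
    """Symmetric table of pair interaction energies, stored once per unordered pair.

    ``node_labels`` fixes the node universe (fragment or residue labels);
    pair keys are label pairs.  Querying ``(j, i)`` returns the same
    components as ``(i, j)``.
    """

    node_labels: list[str]
    pairs: dict[tuple[str, str], PieComponents] = field(default_factory=dict)
    source: str = "fmo"  # {"fmo", "forcefield"}
    units: str = "kcal/mol"

    def _key(self, i: str, j: str) -> tuple[str, str]:
        if i == j:
            raise KeyError("self-pairs are not stored")
        order = {lbl: n for n, lbl in enumerate(self.node_labels)}
        return (i, j) if order[i] < order[j] else (j, i)

    def set(self, i: str, j: str, comp: PieComponents) -> None:
        self.pairs[self._key(i, j)] = comp

    def get(self, i: str, j: str) -> PieComponents | None:
        return self.pairs.get(self._key(i, j))

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return self._key(*pair) in self.pairs

    def iter_pairs(self) -> Iterator[tuple[str, str, PieComponents]]:
        for (i, j), comp in sorted(self.pairs.items()):
            yield i, j, comp

    def term(self, i: str, j: str, term: str) -> float | None:
        comp = self.get(i, j)
        if comp is None:
            return None
        return getattr(comp, term)

    def relabel(self, mapping: Mapping[str, str]) -> "PieTable":
        """Return a copy with node labels (and pair keys) renamed."""
        new_labels = [mapping.get(l, l) for l in self.node_labels]
        out = PieTable(node_labels=new_labels, source=self.source, units=self.units)
        for (i, j), comp in self.pairs.items():
            out.set(mapping.get(i, i), mapping.get(j, j), comp)
        return out

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for i, j, comp in self.iter_pairs():
            rows.append({"i": i, "j": j, **comp.as_dict()})
        cols = ["i", "j", "e_tot", "es", "ex", "ct", "di", "solv", "elec_ff", "vdw_ff"]
        df = pd.DataFrame(rows)
        return df.reindex(columns=[c for c in cols if c in df.columns or c in ("i", "j", "e_tot")])


@dataclass
class FragmentMap:
    """Fragment index (1-based, as printed) → fragment name / residue label.

    ``offset_note`` flags that for amino-acid fragments the backbone C,O atoms
    are assigned to the neighbouring fragment, so FMO fragments do not
    coincide exactly with PDB residues.
    """

    names: dict[int, str] = field(default_factory=dict)
    offset_note: bool = True


# --------------------------------------------------------------------------
# Gamess FMO output
# --------------------------------------------------------------------------

_FMO_HEADER_RE = re.compile(
    r"(?:two.?body.*pair|pair\s+interaction|properties\s+of\s+the\s+pairs|PIEDA)",
    re.IGNORECASE,
)
_UNIT_RE = re.compile(r"units?\s*[:=]?\s*(hartree|a\.?\s?u\.?|kcal)", re.IGNORECASE)
_FRAG_RE = re.compile(r"^\s*(?:FRAGMENT|INDAT)?\s*(\d+)\s+NAME\s*=\s*(\S+)", re.IGNORECASE)
_ROW_RE = re.compile(r"^\s*(\d+)\s+(\d+)\s+(.*)$")
_FLOAT_RE = re.compile(r"[-+]?\d+\.\d+(?:[EeDd][-+]?\d+)?")


def parse_gamess_fmo(path: str | Path) -> tuple[PieTable, FragmentMap]:
    """Parse the two-body pair-interaction table of a Gamess FMO output.

    The table is located by a tolerant regular expression on the section
    header, so minor print-format drift between Gamess versions does not
    break parsing.  Rows are ``I  J  [flags]  E_tot [ES EX CT DI [SOLV]]``;
    energies are converted from Hartree to kcal/mol unless the section
    carries an explicit kcal unit tag.  Abinit-MP / PAICS outputs are not
    supported and are rejected as :class:`NotAnFmoOutputError`.
    """
    text = Path(path).read_text()
    lines = text.splitlines()

    header_idx = None
    for n, line in enumerate(lines):
        if _FMO_HEADER_RE.search(line):
            header_idx = n
            break
    if header_idx is None:
        raise NotAnFmoOutputError(f"{path}: no two-body pair-interaction table found")

    in_kcal = False
    for line in lines[header_idx : header_idx + 6]:
        m = _UNIT_RE.search(line)
        if m:
            in_kcal = m.group(1).lower().startswith("kcal")
            break
    scale = 1.0 if in_kcal else HARTREE_TO_KCAL

    frag_map = FragmentMap()
    for line in lines:
        m = _FRAG_RE.match(line)
        if m:
            frag_map.names[int(m.group(1))] = m.group(2)

    pairs: dict[tuple[int, int], PieComponents] = {}
    max_frag = 0
    for line in lines[header_idx + 1 :]:
        m = _ROW_RE.match(line)
        if not m:
            if pairs and line.strip() and not _FLOAT_RE.search(line):
                break  # table ended at the next prose/section line
            continue
        i, j = int(m.group(1)), int(m.group(2))
        vals = [float(v.replace("D", "E").replace("d", "e")) for v in _FLOAT_RE.findall(m.group(3))]
        if not vals or i == j:
            continue
        e = [v * scale for v in vals]
        comp = PieComponents(e_tot=e[0])
        if len(e) >= 5:
            comp = replace(comp, es=e[1], ex=e[2], ct=e[3], di=e[4])
        if len(e) >= 6:
            comp = replace(comp, solv=e[5])
        key = (min(i, j), max(i, j))
        if key in pairs:
            if abs(pairs[key].e_tot - comp.e_tot) > 1e-9:
                raise AmbiguousPairError(f"conflicting entries for fragment pair {key}")
            continue
        pairs[key] = comp
        max_frag = max(max_frag, i, j)

    if not pairs:
        raise NotAnFmoOutputError(f"{path}: pair-interaction table is empty")

    n_frag = max(max_frag, max(frag_map.names, default=0))
    labels = [frag_map.names.get(k, str(k)) for k in range(1, n_frag + 1)]
    table = PieTable(node_labels=labels, source="fmo")
    for (i, j), comp in pairs.items():
        table.set(labels[i - 1], labels[j - 1], comp)
    return table, frag_map


def map_fragments_to_residues(
    frag_map: FragmentMap,
    structure: StructureModel,
    mode: str = "by_index",
    user_mapping: Mapping[int, ResidueId] | None = None,
) -> dict[int, ResidueId]:
    """Assign FMO fragments to structure residues.

    ``by_index`` pairs fragments with residues in file order (requires equal
    counts or an explicit ``user_mapping`` for the remainder); ``by_number``
    parses residue numbers out of fragment names like ``ALA12`` and matches
    them against PDB residue numbers.  The mapping must be total and
    injective.  Note that for amino-acid fragments the backbone C,O atoms
    belong to the neighbouring fragment (``offset_note``), so the
    correspondence is by identity, not by exact atom content.
    """
    rids = structure.residue_ids()
    frag_indices = sorted(frag_map.names) if frag_map.names else []
    if not frag_indices:
        raise ValueError("fragment map is empty")

    mapping: dict[int, ResidueId] = dict(user_mapping or {})
    unmapped = [k for k in frag_indices if k not in mapping]

    if mode == "by_index":
        if len(frag_indices) > len(rids) and not user_mapping:
            raise ValueError(
                f"cannot map {len(frag_indices)} fragments onto {len(rids)} residues "
                "without an explicit user mapping"
            )
        for k in unmapped:
            pos = frag_indices.index(k)
            mapping[k] = rids[pos]
    elif mode == "by_number":
        by_number = {rid.number: rid for rid in rids}
        num_re = re.compile(r"(\d+)$")
        for k in unmapped:
            m = num_re.search(frag_map.names[k])
            if not m or int(m.group(1)) not in by_number:
                raise ValueError(f"unmappable fragment {k} ({frag_map.names[k]!r})")
            mapping[k] = by_number[int(m.group(1))]
    else:
        raise ValueError(f"unknown mode {mode!r}")

    if len(set(mapping.values())) != len(mapping):
        raise ValueError("fragment→residue mapping is not injective")
    return mapping


# --------------------------------------------------------------------------
# Amber topology and force-field pair energies
# --------------------------------------------------------------------------


@dataclass
class AmberTopology:
    """The subset of a prmtop needed for pairwise Coulomb + LJ energies."""

    natom: int
    charges: np.ndarray  # elementary charges (prmtop value / 18.2223)
    masses: np.ndarray
    atom_type_index: np.ndarray  # 1-based
    nb_parm_index: np.ndarray  # 1-based, ntypes² entries
    lj_acoef: np.ndarray
    lj_bcoef: np.ndarray
    bonds: list[tuple[int, int]]  # 0-based atom indices
    scee: float = DEFAULT_SCEE
    scnb: float = DEFAULT_SCNB

    @property
    def ntypes(self) -> int:
        return int(round(np.sqrt(len(self.nb_parm_index))))

    def lj_ab(self, a: int, b: int) -> tuple[float, float]:
        """A, B Lennard-Jones coefficients for atom indices a, b (0-based)."""
        ta, tb = self.atom_type_index[a], self.atom_type_index[b]
        idx = self.nb_parm_index[self.ntypes * (ta - 1) + tb - 1]
        if idx <= 0:  # 10-12 potentials unsupported; treat as no LJ
            return 0.0, 0.0
        return float(self.lj_acoef[idx - 1]), float(self.lj_bcoef[idx - 1])


_FLAG_RE = re.compile(r"^%FLAG\s+(\S+)")


def _read_prmtop_sections(path: Path) -> dict[str, list[str]]:
    sections: dict[str, list[str]] = {}
    current: str | None = None
    for line in path.read_text().splitlines():
        if line.startswith("%VERSION") or line.startswith("%COMMENT"):
            continue
        m = _FLAG_RE.match(line)
        if m:
            current = m.group(1)
            sections[current] = []
            continue
        if line.startswith("%FORMAT"):
            continue
        if current is not None:
            sections[current].append(line)
    return sections


def _floats(section: list[str]) -> np.ndarray:
    return np.array([float(t) for line in section for t in line.split()])


def _ints(section: list[str]) -> np.ndarray:
    return np.array([int(t) for line in section for t in line.split()], dtype=int)


def parse_prmtop(path: str | Path) -> AmberTopology:
    """Read the charge/LJ/bond information from an Amber prmtop file."""
    path = Path(path)
    sections = _read_prmtop_sections(path)
    required = ["POINTERS", "CHARGE", "ATOM_TYPE_INDEX", "NONBONDED_PARM_INDEX",
                "LENNARD_JONES_ACOEF", "LENNARD_JONES_BCOEF"]
    missing = [k for k in required if k not in sections]
    if missing:
        raise ValueError(f"{path}: not a prmtop (missing sections {missing})")

    pointers = _ints(sections["POINTERS"])
    natom = int(pointers[0])

    bonds: list[tuple[int, int]] = []
    for key in ("BONDS_INC_HYDROGEN", "BONDS_WITHOUT_HYDROGEN"):
        if key in sections and sections[key]:
            vals = _ints(sections[key])
            # triples of (i*3, j*3, bond type)
            for k in range(0, len(vals), 3):
                bonds.append((int(vals[k] // 3), int(vals[k + 1] // 3)))

    def _scalar(key: str, default: float) -> float:
        if key in sections and sections[key]:
            arr = _floats(sections[key])
            if arr.size:
                return float(arr[0])
        return default

    masses = (
        _floats(sections["MASS"]) if "MASS" in sections else np.ones(natom)
    )

    return AmberTopology(
        natom=natom,
        charges=_floats(sections["CHARGE"]) / AMBER_CHARGE_FACTOR,
        masses=masses,
        atom_type_index=_ints(sections["ATOM_TYPE_INDEX"]),
        nb_parm_index=_ints(sections["NONBONDED_PARM_INDEX"]),
        lj_acoef=_floats(sections["LENNARD_JONES_ACOEF"]),
        lj_bcoef=_floats(sections["LENNARD_JONES_BCOEF"]),
        bonds=bonds,
        scee=_scalar("SCEE_SCALE_FACTOR", DEFAULT_SCEE),
        scnb=_scalar("SCNB_SCALE_FACTOR", DEFAULT_SCNB),
    )


def bonded_separations(natom: int, bonds: list[tuple[int, int]], max_sep: int = 3) -> dict[tuple[int, int], int]:
    """Bond-path length (≤ max_sep) for every atom pair connected that closely.

    Breadth-first search over the bond graph; the shortest path decides, so a
    pair that is both 1-3 and 1-4 around a ring counts as 1-3 (excluded).
    """
    adj: dict[int, set[int]] = {i: set() for i in range(natom)}
    for a, b in bonds:
        adj[a].add(b)
        adj[b].add(a)
    sep: dict[tuple[int, int], int] = {}
    for start in range(natom):
        frontier = {start}
        seen = {start}
        for depth in range(1, max_sep + 1):
            nxt: set[int] = set()
            for u in frontier:
                nxt |= adj[u]
            nxt -= seen
            for v in nxt:
                if start < v:
                    sep[(start, v)] = depth
            seen |= nxt
            frontier = nxt
    return sep


def compute_ff_pies(
    structure: StructureModel,
    topology: AmberTopology | str | Path,
) -> PieTable:
    """Residue-pair Coulomb + Lennard-Jones energies over the static structure.

    For every residue pair: ``elec_ff = Σ k_e q_a q_b / r_ab`` over
    inter-residue atom pairs (k_e = 332.0636 kcal Å mol⁻¹ e⁻²) and ``vdw_ff``
    is the 12-6 sum ``A/r¹² − B/r⁶`` with prmtop coefficients.  Bonded 1-2 and
    1-3 pairs are skipped; 1-4 pairs are divided by SCEE (electrostatics,
    default 1.2) and SCNB (van der Waals, default 2.0).  No distance cutoff
    and no periodic images — bare sums over the structure as-is.
    """
    if not isinstance(topology, AmberTopology):
        topology = parse_prmtop(topology)

    coords: list[np.ndarray] = []
    res_of_atom: list[int] = []
    for r_idx, (_, atoms) in enumerate(structure.residues):
        for a in atoms:
            coords.append(a.coord)
            res_of_atom.append(r_idx)
    xyz = np.array(coords)
    if len(xyz) != topology.natom:
        raise TopologyMismatchError(
            f"structure has {len(xyz)} atoms but topology has {topology.natom}"
        )

    sep = bonded_separations(topology.natom, topology.bonds)
    labels = [rid.label for rid in structure.residue_ids()]
    n_res = len(labels)
    elec = np.zeros((n_res, n_res))
    vdw = np.zeros((n_res, n_res))

    q = topology.charges
    for a in range(topology.natom):
        ra = res_of_atom[a]
        for b in range(a + 1, topology.natom):
            rb = res_of_atom[b]
            if ra == rb:
                continue
            s = sep.get((a, b), 0)
            if s in (1, 2):
                continue
            r = float(np.linalg.norm(xyz[a] - xyz[b]))
            e_el = COULOMB_CONSTANT * q[a] * q[b] / r
            A, B = topology.lj_ab(a, b)
            e_vdw = A / r**12 - B / r**6
            if s == 3:
                e_el /= topology.scee
                e_vdw /= topology.scnb
            i, j = min(ra, rb), max(ra, rb)
            elec[i, j] += e_el
            vdw[i, j] += e_vdw

    table = PieTable(node_labels=labels, source="forcefield")
    for i in range(n_res):
        for j in range(i + 1, n_res):
            e, v = float(elec[i, j]), float(vdw[i, j])
            table.set(labels[i], labels[j], PieComponents(e_tot=e + v, elec_ff=e, vdw_ff=v))
    return table
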