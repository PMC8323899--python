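"""Synthetic toy complexes with known ground truth.

Everything downstream — PDB parsing, network construction, interface
analyses, force-field energies — is testable without downloads: this module
generates small two-chain "protein complexes" (a few pseudo-residues of
three backbone-like atoms each), pseudo-FMO pair-energy files in the dialect
the parser accepts, and minimal Amber-style topologies.  All outputs are
fully determined by their parameters and the seed.

The geometry emulates the demonstration setup of a short helix (monomer A)
docked against a larger partner (monomer B): a chosen subset of cross-chain
residue pairs is planted inside a stated centre-of-mass contact distance,
every other cross pair is placed far outside it.  These are toy models —
no physically realistic conformations or energies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .energy_sources import AMBER_CHARGE_FACTOR, PieComponents, PieTable
from .residue_io import Atom, ResidueId, StructureModel

__all__ = [
    "FixtureManifest",
    "make_toy_complex",
    "make_toy_pie_table",
    "make_toy_prmtop",
]

#: fixed atom offsets (Å) of the three pseudo-backbone atoms from the residue base point
_ATOM_OFFSETS = {
    "N": np.array([-1.0, 0.0, -0.6]),
    "CA": np.array([0.0, 0.0, 0.0]),
    "C": np.array([1.0, 0.0, 0.6]),
}
_ELEMENTS = {"N": "N", "CA": "C", "C": "C"}
_MASSES = {"N": 14.007, "CA": 12.011, "C": 12.011}

_SPACING = 6.0  # Å along the chain axis
_CONTACT_X = 5.0  # Å chain separation for planted contacts
_FAR_X = 20.0  # Å chain separation for non-contacts
_JITTER = 0.15  # Å uniform jitter per base-point coordinate


@dataclass
class FixtureManifest:
    """Ground truth of one toy complex."""

    seed: int
    n_a: int
    n_b: int
    contact_cutoff: float  # Å; planted pairs are the only cross pairs within it
    residues: list[tuple[str, int, str, np.ndarray]]  # (chain, number, name, base point)
    planted_pairs: list[tuple[str, str]]  # (label_A, label_B)
    expected_gaps: list[tuple[str, int]] = field(default_factory=list)

    def labels(self, chain: str | None = None) -> list[str]:
        return [
            f"{c}:{n}:{name}"
            for c, n, name, _ in self.residues
            if chain is None or c == chain
        ]

    def membership(self) -> dict[str, str]:
        return {f"{c}:{n}:{name}": c for c, n, name, _ in self.residues}


def _pdb_atom_line(serial, name, resname, chain, resseq, coord, element) -> str:
    pad_name = f" {name:<3}" if len(name) < 4 else name
    return (
        f"ATOM  {serial:>5} {pad_name}{'':1}{resname:<3} {chain}{resseq:>4}    "
        f"{coord[0]:8.3f}{coord[1]:8.3f}{coord[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {element:>2}"
    )


def make_toy_complex(
    n_a: int,
    n_b: int,
    seed: int,
    gap_after: int | None = None,
    contact_fraction: float = 0.6,
) -> tuple[str, dict[str, str], FixtureManifest]:
    """Two-chain toy complex with planted interface contacts.

    Chains A (``n_a`` residues) and B (``n_b`` residues) run parallel at a
    residue spacing of 6 Å.  A seeded subset of index-matched cross pairs
    (about ``contact_fraction`` of the possible ones, at least one) is placed
    5 Å apart; all other B residues sit 20 Å away, so with the manifest's
    contact cutoff (6 Å) the planted pairs are exactly the cross-chain pairs
    a distance network would accept.  ``gap_after`` skips one residue number
    in chain B to plant a numbering gap.  Same seed → byte-identical PDB.
    """
    if n_a < 1 or n_b < 1:
        raise ValueError("n_a and n_b must be ≥ 1")
    rng = np.random.default_rng(seed)

    n_contact_slots = min(n_a, n_b)
    n_planted = max(1, int(round(contact_fraction * n_contact_slots)))
    planted_idx = sorted(rng.choice(n_contact_slots, size=n_planted, replace=False))

    residues: list[tuple[str, int, str, np.ndarray]] = []
    names = ["GLY", "ALA", "SER", "VAL", "LEU", "THR", "ASP", "LYS"]

    def jitter() -> np.ndarray:
        return rng.uniform(-_JITTER, _JITTER, size=3)

    for i in range(n_a):
        base = np.array([0.0, 0.0, _SPACING * i]) + jitter()
        residues.append(("A", i + 1, names[i % len(names)], base))

    number = 0
    for i in range(n_b):
        number += 1
        if gap_after is not None and number == gap_after + 1:
            number += 1  # skip one number → numbering gap after `gap_after`
        x = _CONTACT_X if i in planted_idx else _FAR_X
        base = np.array([x, 0.0, _SPACING * i]) + jitter()
        residues.append(("B", number, names[(i + 3) % len(names)], base))

    planted_pairs = []
    b_residues = [r for r in residues if r[0] == "B"]
    for i in planted_idx:
        a_chain, a_num, a_name, _ = residues[i]
        b_chain, b_num, b_name, _ = b_residues[i]
        planted_pairs.append((f"A:{a_num}:{a_name}", f"B:{b_num}:{b_name}"))

    lines = []
    serial = 0
    prev_chain = None
    for chain, num, name, base in residues:
        if prev_chain is not None and chain != prev_chain:
            lines.append("TER")
        prev_chain = chain
        for atom_name in ("N", "CA", "C"):
            serial += 1
            coord = base + _ATOM_OFFSETS[atom_name]
            lines.append(
                _pdb_atom_line(serial, atom_name, name, chain, num, coord, _ELEMENTS[atom_name])
            )
    lines.append("TER")
    lines.append("END")
    pdb_text = "\n".join(lines) + "\n"

    gaps = [("B", gap_after)] if gap_after is not None and gap_after < number else []
    manifest = FixtureManifest(
        seed=seed,
        n_a=n_a,
        n_b=n_b,
        contact_cutoff=6.0,
        residues=residues,
        planted_pairs=planted_pairs,
        expected_gaps=gaps,
    )
    return pdb_text, manifest.membership(), manifest


def _round6(x: float) -> float:
    return float(f"{x:.6f}")


def _pieda_split(e_tot: float) -> PieComponents:
    """Deterministic PIEDA-style split: positive exchange term, the attractive
    remainder divided between electrostatics, charge transfer and dispersion."""
    ex = _round6(0.25 * abs(e_tot))
    attr = e_tot - ex
    es = _round6(0.5 * attr)
    ct = _round6(0.2 * attr)
    di = _round6(0.3 * attr)
    e = _round6(es + ex + ct + di)
    return PieComponents(e_tot=e, es=es, ex=ex, ct=ct, di=di)


def make_toy_pie_table(
    manifest: FixtureManifest,
    energy_scale: float = 8.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> tuple[PieTable, str]:
    """Pair-energy table + pseudo-FMO text for a toy complex.

    Planted cross pairs get attractive energies of magnitude ``energy_scale``
    (exactly −energy_scale when ``noise_sd`` = 0); sequence-adjacent
    intra-chain pairs get a peptide-bond-like −3 kcal/mol; everything is
    PIEDA-decomposed deterministically.  The returned text is in the dialect
    ``parse_gamess_fmo`` accepts (kcal/mol unit tag, so parsing it reproduces
    the table exactly).
    """
    rng = np.random.default_rng(manifest.seed if seed is None else seed)
    labels = manifest.labels()
    table = PieTable(node_labels=labels, source="fmo")

    def noisy(mu: float) -> float:
        return _round6(mu + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0))

    by_chain: dict[str, list[tuple[int, str]]] = {}
    for c, n, name, _ in manifest.residues:
        by_chain.setdefault(c, []).append((n, f"{c}:{n}:{name}"))

    for chain, members in by_chain.items():
        for (_, l1), (_, l2) in zip(members, members[1:]):
            table.set(l1, l2, _pieda_split(noisy(-3.0)))

    for la, lb in manifest.planted_pairs:
        table.set(la, lb, _pieda_split(noisy(-energy_scale)))

    index = {lbl: k + 1 for k, lbl in enumerate(labels)}
    lines = [
        " pseudo two-body FMO output (synthetic fixture)",
        "",
    ]
    for lbl, k in index.items():
        lines.append(f" FRAGMENT {k:4d}  NAME={lbl}")
    lines += [
        "",
        "          Two-body pair interaction energies (PIEDA)",
        "          Units: KCAL/MOL",
        "    I    J      E_TOT           ES           EX           CT           DI",
    ]
    for i_lbl, j_lbl, c in table.iter_pairs():
        lines.append(
            f" {index[i_lbl]:4d} {index[j_lbl]:4d} "
            f"{c.e_tot:12.6f} {c.es:12.6f} {c.ex:12.6f} {c.ct:12.6f} {c.di:12.6f}"
        )
    return table, "\n".join(lines) + "\n"


# --------------------------------------------------------------------------
# Toy Amber topology
# --------------------------------------------------------------------------


def _fmt_block(values, fmt: str, per_line: int) -> list[str]:
    out = []
    for k in range(0, len(values), per_line):
        out.append("".join(fmt % v for v in values[k : k + per_line]))
    return out or [""]


def make_toy_prmtop(
    n_res: int = 4,
    atoms_per_res: int = 2,
    seed: int = 0,
) -> tuple[StructureModel, str, dict]:
    """Small random structure + matching Amber-style topology text.

    Residues of ``atoms_per_res`` atoms on a jittered grid; random charges
    (net-neutral pairs not enforced), two Lennard-Jones atom types with
    Lorentz–Berthelot-combined A/B coefficients, bonds within each residue
    and one linking bond between consecutive residues (so inter-residue 1-2,
    1-3 and 1-4 relationships all occur).  Returns the structure, the prmtop
    text and a manifest of the exact parameters for independent energy
    oracles.
    """
    rng = np.random.default_rng(seed)
    natom = n_res * atoms_per_res

    charges = np.round(rng.uniform(-0.8, 0.8, size=natom), 4)
    eps_by_type = np.array([0.1094, 0.0157])  # kcal/mol, C/H-like
    rmin_by_type = np.array([1.9080, 0.6000])  # Å (Rmin/2)
    type_index = rng.integers(1, 3, size=natom)  # 1-based, two types

    ntypes = 2
    nb_parm_index = np.zeros(ntypes * ntypes, dtype=int)
    acoef, bcoef = [], []
    k = 0
    pair_slot = {}
    for i in range(1, ntypes + 1):
        for j in range(1, i + 1):
            k += 1
            pair_slot[(i, j)] = pair_slot[(j, i)] = k
            eps = float(np.sqrt(eps_by_type[i - 1] * eps_by_type[j - 1]))
            rmin = float(rmin_by_type[i - 1] + rmin_by_type[j - 1])
            acoef.append(eps * rmin**12)
            bcoef.append(2.0 * eps * rmin**6)
    for i in range(1, ntypes + 1):
        for j in range(1, ntypes + 1):
            nb_parm_index[ntypes * (i - 1) + (j - 1)] = pair_slot[(i, j)]

    bonds: list[tuple[int, int]] = []
    for r in range(n_res):
        base = r * atoms_per_res
        for a in range(atoms_per_res - 1):
            bonds.append((base + a, base + a + 1))
        if r > 0:
            bonds.append((base - 1, base))  # link consecutive residues

    residues: list[tuple[ResidueId, list[Atom]]] = []
    coords = []
    for r in range(n_res):
        atoms = []
        for a in range(atoms_per_res):
            idx = r * atoms_per_res + a
            coord = np.array([2.2 * idx, 0.0, 0.0]) + rng.uniform(-0.4, 0.4, size=3)
            coords.append(coord)
            atoms.append(
                Atom(name=f"X{a+1}", element="C", coord=coord, mass=12.011)
            )
        residues.append((ResidueId(chain="A", number=r + 1, name="TOY"), atoms))
    structure = StructureModel(residues=residues)

    pointers = [0] * 31
    pointers[0] = natom
    pointers[1] = ntypes
    pointers[11] = n_res

    lines = ["%VERSION  VERSION_STAMP = V0001.000  (synthetic toy topology)"]

    def section(flag: str, fmt_note: str, body: list[str]):
        lines.append(f"%FLAG {flag}")
        lines.append(f"%FORMAT{fmt_note}")
        lines.extend(body)

    section("TITLE", "(20a4)", ["TOY"])
    section("POINTERS", "(10I8)", _fmt_block(pointers, "%8d", 10))
    section("CHARGE", "(3E24.16)",
            _fmt_block(list(charges * AMBER_CHARGE_FACTOR), "%24.16E", 3))
    section("MASS", "(3E24.16)", _fmt_block([12.011] * natom, "%24.16E", 3))
    section("ATOM_TYPE_INDEX", "(10I8)", _fmt_block(list(type_index), "%8d", 10))
    section("NONBONDED_PARM_INDEX", "(10I8)", _fmt_block(list(nb_parm_index), "%8d", 10))
    section("LENNARD_JONES_ACOEF", "(3E24.16)", _fmt_block(acoef, "%24.16E", 3))
    section("LENNARD_JONES_BCOEF", "(3E24.16)", _fmt_block(bcoef, "%24.16E", 3))
    bond_triplets = [v for (a, b) in bonds for v in (a * 3, b * 3, 1)]
    section("BONDS_WITHOUT_HYDROGEN", "(10I8)", _fmt_block(bond_triplets, "%8d", 10))
    prmtop_text = "\n".join(lines) + "\n"

    manifest = {
        "seed": seed,
        "charges": charges,
        "type_index": type_index,
        "eps_by_type": eps_by_type,
        "rmin_half_by_type": rmin_by_type,
        "bonds": bonds,
        "coords": np.array(coords),
        "atoms_per_res": atoms_per_res,
    }
    return structure, prmtop_text, manifest
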