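"""Shared fixtures: toy complexes, pair-energy tables and small helper builders."""

from __future__ import annotations

import numpy as np
import pytest

from prnkit import BuildCriteria, build_pieprn, parse_pdb, split_supersystem
from prnkit.fixtures import make_toy_complex, make_toy_pie_table
from prnkit.residue_io import Atom, ResidueId, StructureModel


@pytest.fixture
def toy_complex(tmp_path):
    """A parsed 4+6-residue two-chain complex with a planted gap in chain B."""
    pdb_text, membership, manifest = make_toy_complex(4, 6, seed=11, gap_after=2)
    path = tmp_path / "toy.pdb"
    path.write_text(pdb_text)
    structure = parse_pdb(path)
    return structure, membership, manifest, path


@pytest.fixture
def toy_pie(toy_complex):
    structure, membership, manifest, _ = toy_complex
    table, fmo_text = make_toy_pie_table(manifest, energy_scale=8.0)
    return structure, membership, manifest, table, fmo_text


@pytest.fixture
def toy_split(toy_pie):
    structure, membership, manifest, table, _ = toy_pie
    g = build_pieprn(table, BuildCriteria(e_lim=-1.0), structure)
    return split_supersystem(g, membership), table, manifest


def simple_structure(coords_by_residue, chain="A", masses=None, names=None):
    """Build a StructureModel from {resnum: [(atom_name, xyz), ...]}."""
    residues = []
    for num, atoms in coords_by_residue.items():
        atom_objs = []
        for atom_name, xyz in atoms:
            elem = atom_name[0]
            mass = (masses or {}).get(atom_name, 12.011 if elem == "C" else 14.007)
            atom_objs.append(
                Atom(name=atom_name, element=elem, coord=np.asarray(xyz, float), mass=mass)
            )
        residues.append(
            (ResidueId(chain=chain, number=num, name=(names or {}).get(num, "GLY")), atom_objs)
        )
    return StructureModel(residues=residues)


def chain_from_dihedrals(dihedrals, bond_length=1.5, bond_angle_deg=111.0):
    """Backbone coordinates from a dihedral sequence (NeRF construction).

    Returns an (n_atoms, 3) array for n_atoms = len(dihedrals) + 3 atoms.
    """
    theta = np.deg2rad(180.0 - bond_angle_deg)
    coords = [
        np.array([0.0, 0.0, 0.0]),
        np.array([bond_length, 0.0, 0.0]),
        np.array([bond_length + bond_length * np.cos(theta), bond_length * np.sin(theta), 0.0]),
    ]
    for phi_deg in dihedrals:
        phi = np.deg2rad(phi_deg)
        a, b, c = coords[-3], coords[-2], coords[-1]
        bc = c - b
        bc /= np.linalg.norm(bc)
        n = np.cross(b - a, bc)
        n /= np.linalg.norm(n)
        m = np.cross(n, bc)
        d2 = np.array(
            [
                -bond_length * np.cos(np.deg2rad(bond_angle_deg)),
                bond_length * np.cos(phi) * np.sin(np.deg2rad(bond_angle_deg)),
                bond_length * np.sin(phi) * np.sin(np.deg2rad(bond_angle_deg)),
            ]
        )
        coords.append(c + d2[0] * bc + d2[1] * m + d2[2] * n)
    return np.array(coords)


def backbone_structure(coords, chain="A"):
    """Wrap an (n,3) backbone coordinate array into residues of N, CA, C atoms."""
    residues_coords = {}
    names = ["N", "CA", "C"]
    for i in range(0, len(coords) - len(coords) % 3, 3):
        residues_coords[i // 3 + 1] = [
            (names[k], coords[i + k]) for k in range(3)
        ]
    return simple_structure(residues_coords, chain=chain)
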