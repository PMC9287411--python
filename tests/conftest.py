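"""Shared fixtures: inline PDB writers and small parameterized structures."""

import numpy as np
import pytest
from hypothesis import settings

from foldbind.structure_model import Atom, ParameterizedStructure, Residue

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


def pdb_atom_line(
    serial, name, res, chain, seq, x, y, z, *, altloc=" ", icode=" ", occ=1.0,
    element=None, record="ATOM",
):
    """One fixed-column PDB coordinate line."""
    element = element or name[0]
    padded = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"{record:<6s}{serial:5d} {padded:<4s}{altloc}{res:<3s} {chain}"
        f"{seq:4d}{icode}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}"
        f"          {element:>2s}"
    )


def write_pdb_text(path, lines):
    path.write_text("\n".join(lines) + "\nEND\n")
    return path


def single_atom_residue(name, chain, index, position, charge=0.0, eps=0.1, rmin_half=1.9):
    atom = Atom(
        name="CA",
        element="C",
        position=np.asarray(position, dtype=float),
        charge=charge,
        lj_epsilon=eps,
        lj_rmin_half=rmin_half,
        parameterized=True,
    )
    return Residue(name=name, chain_id=chain, index=index, atoms=[atom])


def chain_structure(structure_id, chain, residues):
    st = ParameterizedStructure(id=structure_id)
    st.chains[chain] = residues
    return st


@pytest.fixture()
def two_residue_pdb(tmp_path):
    """Minimal clean two-residue PDB file."""
    lines = [
        pdb_atom_line(1, "N", "ALA", "A", 1, 0.0, 0.0, 0.0),
        pdb_atom_line(2, "CA", "ALA", "A", 1, 1.458, 0.0, 0.0),
        pdb_atom_line(3, "C", "ALA", "A", 1, 2.0, 1.4, 0.0),
        pdb_atom_line(4, "O", "ALA", "A", 1, 1.5, 2.5, 0.0),
        pdb_atom_line(5, "CB", "ALA", "A", 1, 1.9, -0.8, 1.2),
        pdb_atom_line(6, "N", "GLY", "A", 2, 3.3, 1.3, 0.0),
        pdb_atom_line(7, "CA", "GLY", "A", 2, 4.1, 2.5, 0.2),
        pdb_atom_line(8, "C", "GLY", "A", 2, 5.5, 2.2, 0.7),
        pdb_atom_line(9, "O", "GLY", "A", 2, 5.9, 1.0, 0.8),
    ]
    return write_pdb_text(tmp_path / "two.pdb", lines)


@pytest.fixture()
def blob_structure():
    """A generic asymmetric 8-residue single-atom blob (for surfaces)."""
    rng = np.random.default_rng(42)
    residues = [
        single_atom_residue("GLY", "A", i + 1, rng.normal(0.0, 4.0, 3)) for i in range(8)
    ]
    return chain_structure("blob", "A", residues)
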