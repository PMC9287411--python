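"""Structure input and force-field parameterization.

Reads protein (or protein-protein complex) structures from PDB files into a
light residue/atom representation, and attaches non-bonded parameters --
partial charge ``q`` (e), Lennard-Jones well depth ``epsilon`` (kcal/mol)
and half-minimum radius ``rmin_half`` (Angstrom) -- from a TSV parameter
table.

Preprocessing mirrors the conventions of comparative energy studies:
heteroatoms (waters, ligands, ions) are discarded, alternate locations are
resolved to the highest-occupancy conformer, and residues are renumbered
1-based and gap-free per chain so that sequence separation is well defined.
Hydrogens are not required: the bundled parameter table is a united-charge
heavy-atom set in which hydrogen partial charges are absorbed into their
bonded heavy atom, so unprotonated crystal structures work out of the box.
Protonation and energy minimization are treated as external preprocessing.
"""

from __future__ import annotations

import copy
import csv
import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import gemmi
import numpy as np
from scipy.spatial.distance import cdist

from .constants import STANDARD_RESIDUES, data_path
from .errors import (
    CoverageError,
    EmptyStructureError,
    InputError,
    ValidationError,
)

#: Name of the bundled united-charge parameter table.
BUNDLED_FORCEFIELD = "forcefield_united_synthetic.tsv"


@dataclass
class Atom:
    """A heavy (or any) atom with coordinates and non-bonded parameters."""

    name: str
    element: str
    position: np.ndarray  # (3,) Angstrom
    charge: float = 0.0  # e
    lj_epsilon: float = 0.0  # kcal/mol, well depth (>= 0)
    lj_rmin_half: float = 1.0  # Angstrom (> 0 when parameterized)
    parameterized: bool = False

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValidationError(f"atom {self.name}: position must be a finite 3-vector")
        if self.parameterized and (self.lj_epsilon < 0 or self.lj_rmin_half <= 0):
            raise ValidationError(f"atom {self.name}: invalid LJ parameters")


@dataclass
class Residue:
    """One amino-acid residue; ``index`` is the renumbered (gap-free) position."""

    name: str
    chain_id: str
    index: int
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int]:
        return (self.chain_id, self.index)

    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class ParameterizedStructure:
    """An ordered collection of chains of residues.

    ``chains`` maps chain id to the ordered residue list; iteration order of
    the dict follows file order. ``size`` is the total residue count N used
    to normalize total energies.
    """

    id: str
    chains: dict[str, list[Residue]] = field(default_factory=dict)

    @property
    def residues(self) -> list[Residue]:
        return [r for ch in self.chains.values() for r in ch]

    @property
    def size(self) -> int:
        return sum(len(ch) for ch in self.chains.values())

    @property
    def chain_ids(self) -> list[str]:
        return list(self.chains)

    def validate(self) -> None:
        if self.size == 0:
            raise EmptyStructureError(f"{self.id}: no residues")
        for cid, residues in self.chains.items():
            for pos, res in enumerate(residues, start=1):
                if res.index != pos:
                    raise ValidationError(
                        f"{self.id}/{cid}: residue indices not consecutive from 1"
                    )
                if res.name not in STANDARD_RESIDUES:
                    raise ValidationError(f"{self.id}/{cid}: non-standard residue {res.name}")


@dataclass
class ForceFieldTable:
    """(residue name, atom name) -> (q, epsilon, rmin_half) lookup."""

    entries: dict[tuple[str, str], tuple[float, float, float]]
    source: str = "user"

    def get(self, residue: str, atom: str):
        return self.entries.get((residue, atom))

    def residue_charge_sums(self) -> dict[str, float]:
        sums: dict[str, float] = {}
        for (res, _atom), (q, _e, _r) in self.entries.items():
            sums[res] = sums.get(res, 0.0) + q
        return sums


# ---------------------------------------------------------------------------
# PDB input / output
# ---------------------------------------------------------------------------

def _resolve_altlocs(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one atom per name: highest occupancy, ties broken by altloc id."""
    by_name: dict[str, gemmi.Atom] = {}
    for atom in residue:
        prev = by_name.get(atom.name)
        # higher occupancy wins; on a tie the lexicographically smaller
        # altloc ('A' before 'B') wins
        if (
            prev is None
            or atom.occ > prev.occ
            or (atom.occ == prev.occ and (atom.altloc or "A") < (prev.altloc or "A"))
        ):
            by_name[atom.name] = atom
    return list(by_name.values())


def read_pdb(path: str | Path, model_index: int = 0, structure_id: str | None = None) -> ParameterizedStructure:
    """Read a PDB file into an (unparameterized) :class:`ParameterizedStructure`.

    Heteroatom records (waters, ligands, ions) are discarded; alternate
    locations are resolved to the highest-occupancy conformer; residues are
    renumbered consecutively (1-based) per chain, removing insertion codes
    and numbering gaps. ``model_index`` selects the model (0 = first).

    Raises
    ------
    InputError
        If the file cannot be parsed or contains a non-standard polymer
        residue (structure repair is out of scope).
    EmptyStructureError
        If no standard residues remain after preprocessing.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise InputError(f"cannot parse PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models")
    if not 0 <= model_index < len(st):
        raise InputError(f"{path}: model index {model_index} out of range")
    model = st[model_index]

    out = ParameterizedStructure(id=structure_id or path.stem)
    for chain in model:
        residues: list[Residue] = []
        for res in chain:
            if res.het_flag == "H":
                continue  # heteroatoms trimmed off
            if res.name not in STANDARD_RESIDUES:
                raise InputError(
                    f"{path}: non-standard residue {res.name} in chain {chain.name}; "
                    "replace or remove it upstream"
                )
            atoms = [
                Atom(
                    name=a.name,
                    element=a.element.name.upper() or a.name[:1],
                    position=np.array([a.pos.x, a.pos.y, a.pos.z]),
                )
                for a in _resolve_altlocs(res)
            ]
            if not atoms:
                continue
            residues.append(Residue(name=res.name, chain_id=chain.name, index=len(residues) + 1, atoms=atoms))
        if residues:
            out.chains[chain.name] = residues
    if out.size == 0:
        raise EmptyStructureError(f"{path}: no standard residues after preprocessing")
    out.validate()
    return out


def write_pdb(structure: ParameterizedStructure, path: str | Path) -> None:
    """Write the structure back to a PDB file (round-trip safe to 1e-3 A)."""
    st = gemmi.Structure()
    st.name = structure.id
    model = gemmi.Model("1")
    for cid, residues in structure.chains.items():
        chain = gemmi.Chain(cid)
        for res in residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.index, " ")
            for a in res.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*a.position)
                ga.occ = 1.0
                gres.add_atom(ga)
            chain.add_residue(gres)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Force-field tables
# ---------------------------------------------------------------------------

def load_forcefield(source: str | Path = "bundled") -> ForceFieldTable:
    """Load and validate a non-bonded parameter table.

    ``source`` is a TSV path, or the string ``"bundled"`` for the packaged
    united-charge heavy-atom set. Rows are
    ``residue<TAB>atom<TAB>q<TAB>epsilon<TAB>rmin_half``; a header line and
    ``#`` comments are allowed. Validation enforces epsilon >= 0,
    rmin_half > 0 and per-residue charge sums within 0.01 e of the nearest
    integer (the residue's formal charge).
    """
    if source == "bundled":
        text = data_path(BUNDLED_FORCEFIELD).read_text()
        label = "bundled"
    else:
        p = Path(source)
        if not p.exists():
            raise InputError(f"no such parameter table: {p}")
        text = p.read_text()
        label = str(p)

    entries: dict[tuple[str, str], tuple[float, float, float]] = {}
    reader = csv.reader(io.StringIO(text), delimiter="\t")
    for row in reader:
        if not row or row[0].startswith("#"):
            continue
        if row[0] == "residue":  # header
            continue
        if len(row) != 5:
            raise ValidationError(f"{label}: malformed row {row!r}")
        res, atom = row[0].strip(), row[1].strip()
        try:
            q, eps, rmh = float(row[2]), float(row[3]), float(row[4])
        except ValueError as exc:
            raise ValidationError(f"{label}: non-numeric row {row!r}") from exc
        if eps < 0:
            raise ValidationError(f"{label}: negative epsilon for {res}/{atom}")
        if rmh <= 0:
            raise ValidationError(f"{label}: non-positive rmin_half for {res}/{atom}")
        if (res, atom) in entries:
            raise ValidationError(f"{label}: duplicate entry {res}/{atom}")
        entries[(res, atom)] = (q, eps, rmh)
    if not entries:
        raise ValidationError(f"{label}: empty parameter table")

    table = ForceFieldTable(entries=entries, source=label)
    for res, total in table.residue_charge_sums().items():
        if abs(total - round(total)) > 0.01:
            raise ValidationError(
                f"{label}: residue {res} charge sum {total:.3f} is not near-integer"
            )
    return table


def write_forcefield(table: ForceFieldTable, path: str | Path) -> None:
    """Write a parameter table as TSV (inverse of :func:`load_forcefield`)."""
    with open(path, "w") as fh:
        fh.write("residue\tatom\tq\tepsilon\trmin_half\n")
        for (res, atom), (q, eps, rmh) in sorted(table.entries.items()):
            fh.write(f"{res}\t{atom}\t{q:.6g}\t{eps:.6g}\t{rmh:.6g}\n")


@dataclass
class AssignmentReport:
    """Which atoms received parameters and which did not."""

    n_atoms: int
    n_assigned: int
    unmatched: list[tuple[str, int, str, str]]  # (chain, residue index, residue, atom)

    @property
    def n_unmatched(self) -> int:
        return len(self.unmatched)

    @property
    def unmatched_fraction(self) -> float:
        return self.n_unmatched / self.n_atoms if self.n_atoms else 0.0


def assign_parameters(
    structure: ParameterizedStructure,
    table: ForceFieldTable,
    max_unmatched_fraction: float = 0.20,
) -> tuple[ParameterizedStructure, AssignmentReport]:
    """Attach (q, epsilon, rmin_half) to every atom with a table entry.

    Returns a new structure plus a report of unmatched atoms; unmatched
    atoms keep ``parameterized=False`` and are skipped by energy sums. More
    than ``max_unmatched_fraction`` unmatched atoms raises
    :class:`CoverageError`, which usually signals a wrong atom-naming
    dialect. Assignment is idempotent.
    """
    new = copy.deepcopy(structure)
    unmatched: list[tuple[str, int, str, str]] = []
    n_atoms = 0
    for res in new.residues:
        for atom in res.atoms:
            n_atoms += 1
            entry = table.get(res.name, atom.name)
            if entry is None:
                atom.parameterized = False
                unmatched.append((res.chain_id, res.index, res.name, atom.name))
            else:
                atom.charge, atom.lj_epsilon, atom.lj_rmin_half = entry
                atom.parameterized = True
    report = AssignmentReport(n_atoms=n_atoms, n_assigned=n_atoms - len(unmatched), unmatched=unmatched)
    if n_atoms and report.unmatched_fraction > max_unmatched_fraction:
        raise CoverageError(
            f"{structure.id}: {report.n_unmatched}/{n_atoms} atoms "
            f"({100 * report.unmatched_fraction:.0f}%) have no parameters"
        )
    if report.unmatched:
        warnings.warn(
            f"{structure.id}: {report.n_unmatched} atoms without parameters "
            "(excluded from energy sums)",
            stacklevel=2,
        )
    return new, report


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def residue_min_distance(res_i: Residue, res_j: Residue) -> float:
    """Minimum Euclidean distance (Angstrom) over all atom pairs."""
    if not res_i.atoms or not res_j.atoms:
        raise InputError("residue_min_distance: empty residue")
    return float(cdist(res_i.coords(), res_j.coords()).min())


def iter_residue_pairs(residues: Iterable[Residue]):
    """All unordered residue pairs (i < j in flattened order)."""
    rs = list(residues)
    for i in range(len(rs)):
        for j in range(i + 1, len(rs)):
            yield rs[i], rs[j]
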