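"""Dot molecular surfaces, solvent accessibility and interface detection.

The solvent-accessible surface (SAS) is generated deterministically: each
atom sphere of radius ``r_vdw + probe`` is covered with a Fibonacci spiral
lattice at the requested point density, and lattice points buried inside a
neighbouring atom's solvent-accessible sphere are removed. The outward unit
normal of a surviving point is exact for the SAS -- the radial direction
from its owner atom. Per-residue SASA follows by counting surviving points
(area = points / density), and relative solvent accessibility (RSA) divides
by a bundled table of theoretical per-residue maxima. A reentrant
(Connolly) surface is deliberately not computed; downstream patch analysis
only assumes a point cloud with normals.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from math import pi
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .constants import (
    BINDING_SITE_CUTOFF,
    CONTACT_CUTOFF,
    DEFAULT_PROBE_RADIUS,
    DEFAULT_SURFACE_DENSITY,
    RSA_THRESHOLD,
    VDW_RADII,
    VDW_RADIUS_DEFAULT,
    data_path,
)
from .errors import FoldbindError, InputError, ScopeError
from .structure_model import ParameterizedStructure

MAX_SASA_TABLE = "max_sasa_theoretical.tsv"


@dataclass
class MolecularSurface:
    """Dot surface: points, unit outward normals and per-point ownership."""

    points: np.ndarray  # (n, 3) Angstrom
    normals: np.ndarray  # (n, 3), unit
    owner_atom: np.ndarray  # (n,) flat atom index
    owner_residue: list[tuple[str, int]]  # (chain id, residue index) per point
    density: float  # requested points per Angstrom^2

    @property
    def n_points(self) -> int:
        return int(self.points.shape[0])

    def area(self) -> float:
        """Total SAS area estimate (A^2) from the point count."""
        return self.n_points / self.density


def fibonacci_sphere(n: int) -> np.ndarray:
    """n near-uniform unit vectors on the sphere (golden-angle spiral)."""
    k = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * k + 1.0) / n
    phi = k * pi * (3.0 - np.sqrt(5.0))
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def _atom_arrays(structure: ParameterizedStructure):
    centers, radii, owners = [], [], []
    for res in structure.residues:
        for atom in res.atoms:
            centers.append(atom.position)
            r = VDW_RADII.get(atom.element.upper())
            if r is None:
                warnings.warn(
                    f"unknown vdW radius for element {atom.element!r}; using "
                    f"{VDW_RADIUS_DEFAULT} A",
                    stacklevel=3,
                )
                r = VDW_RADIUS_DEFAULT
            radii.append(r)
            owners.append(res.key)
    return np.array(centers, dtype=float), np.array(radii, dtype=float), owners


def _molecular_frames(centers: np.ndarray) -> list[np.ndarray]:
    """A per-atom orthonormal frame built from the molecule's own geometry.

    Anchoring the spiral lattice to these frames (instead of the global
    axes) makes the dot surface equivariant under rigid motions for
    generic structures: the lattice z-axis is the centroid-to-atom
    direction and the in-plane spin is fixed by the principal axis of the
    coordinate covariance (sign pinned to the atom farthest from the
    centroid). Perfectly symmetric or collinear arrangements fall back to
    deterministic but frame-arbitrary choices.
    """
    centroid = centers.mean(axis=0)
    rel = centers - centroid
    if len(centers) > 1 and np.any(np.linalg.norm(rel, axis=1) > 1e-9):
        cov = rel.T @ rel
        w_eig, v_eig = np.linalg.eigh(cov)
        p = v_eig[:, -1]
        far = rel[np.argmax(np.linalg.norm(rel, axis=1))]
        if np.dot(p, far) < 0:
            p = -p
        q = v_eig[:, -2]
        if np.dot(q, far) < 0:
            q = -q
    else:
        p = np.array([1.0, 0.0, 0.0])
        q = np.array([0.0, 1.0, 0.0])

    frames = []
    for i in range(len(centers)):
        w = rel[i]
        nw = np.linalg.norm(w)
        w = w / nw if nw > 1e-9 else np.array([0.0, 0.0, 1.0])
        a = p - np.dot(p, w) * w
        if np.linalg.norm(a) < 1e-6:
            a = q - np.dot(q, w) * w
        if np.linalg.norm(a) < 1e-6:  # fully degenerate: any perpendicular
            a = np.array([1.0, 0.0, 0.0]) if abs(w[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
            a = a - np.dot(a, w) * w
        a /= np.linalg.norm(a)
        b = np.cross(w, a)
        frames.append(np.column_stack([a, b, w]))
    return frames


def compute_surface(
    structure: ParameterizedStructure,
    density: float = DEFAULT_SURFACE_DENSITY,
    probe: float = DEFAULT_PROBE_RADIUS,
) -> MolecularSurface:
    """Deterministic solvent-accessible dot surface with outward normals."""
    centers, radii, owners = _atom_arrays(structure)
    if centers.size == 0:
        raise InputError(f"{structure.id}: no atoms")
    sas_radii = radii + probe
    tree = cKDTree(centers)
    max_r = float(sas_radii.max())
    frames = _molecular_frames(centers)

    pts_out, nrm_out, atom_out, res_out = [], [], [], []
    # occlusion tolerance: a point exactly on a neighbour sphere is kept
    tol = 1e-9
    for ia in range(len(centers)):
        r = sas_radii[ia]
        n_pts = max(1, int(round(4.0 * pi * r * r * density)))
        dirs = fibonacci_sphere(n_pts) @ frames[ia].T
        pts = centers[ia] + r * dirs
        neighbours = tree.query_ball_point(centers[ia], r + max_r)
        neighbours = [j for j in neighbours if j != ia]
        keep = np.ones(n_pts, dtype=bool)
        for j in neighbours:
            # identical spheres would occlude each other symmetrically;
            # keep the copy of the lowest atom index only
            if abs(sas_radii[j] - r) < 1e-12 and np.linalg.norm(centers[j] - centers[ia]) < 1e-12:
                if j < ia:
                    keep[:] = False
                continue
            d = np.linalg.norm(pts - centers[j], axis=1)
            keep &= d >= sas_radii[j] - tol
        if keep.any():
            pts_out.append(pts[keep])
            nrm_out.append(dirs[keep])
            atom_out.append(np.full(int(keep.sum()), ia))
            res_out.extend([owners[ia]] * int(keep.sum()))

    if not pts_out:
        raise FoldbindError(f"{structure.id}: surface has no points")
    return MolecularSurface(
        points=np.vstack(pts_out),
        normals=np.vstack(nrm_out),
        owner_atom=np.concatenate(atom_out),
        owner_residue=res_out,
        density=density,
    )


def write_surface_tsv(surface: MolecularSurface, path) -> None:
    """Write points and normals as TSV (x y z nx ny nz chain residue)."""
    with open(path, "w") as fh:
        fh.write("x\ty\tz\tnx\tny\tnz\tchain\tresidue\n")
        for p, n, (cid, idx) in zip(surface.points, surface.normals, surface.owner_residue):
            fh.write(
                "\t".join(f"{v:.4f}" for v in (*p, *n)) + f"\t{cid}\t{idx}\n"
            )


# ---------------------------------------------------------------------------
# Accessibility
# ---------------------------------------------------------------------------

@dataclass
class AccessibilityRecord:
    """Per-residue SASA, reference maximum and relative accessibility."""

    sasa: dict[tuple[str, int], float]  # A^2
    max_sasa: dict[tuple[str, int], float]  # A^2
    rsa: dict[tuple[str, int], float]  # dimensionless


def load_max_sasa(source: str = "bundled") -> dict[str, float]:
    """Residue -> theoretical maximum SASA (A^2) table."""
    text = (
        data_path(MAX_SASA_TABLE).read_text()
        if source == "bundled"
        else open(source).read()
    )
    table: dict[str, float] = {}
    for row in csv.reader(text.splitlines(), delimiter="\t"):
        if not row or row[0].startswith("#") or row[0] == "residue":
            continue
        table[row[0]] = float(row[1])
    return table


def residue_sasa(
    structure: ParameterizedStructure,
    probe: float = DEFAULT_PROBE_RADIUS,
    density: float = DEFAULT_SURFACE_DENSITY,
    surface: MolecularSurface | None = None,
    max_sasa_table: dict[str, float] | None = None,
) -> AccessibilityRecord:
    """Per-residue SASA (point count / density) and RSA (SASA / max SASA)."""
    if surface is None:
        surface = compute_surface(structure, density=density, probe=probe)
    table = max_sasa_table or load_max_sasa()

    counts: dict[tuple[str, int], int] = {r.key: 0 for r in structure.residues}
    for key in surface.owner_residue:
        counts[key] += 1

    sasa, max_sasa, rsa = {}, {}, {}
    for res in structure.residues:
        if res.name not in table:
            raise InputError(f"no max-SASA reference for residue {res.name}")
        a = counts[res.key] / surface.density
        sasa[res.key] = a
        max_sasa[res.key] = table[res.name]
        rsa[res.key] = a / table[res.name]
    return AccessibilityRecord(sasa=sasa, max_sasa=max_sasa, rsa=rsa)


def surface_residues(
    structure: ParameterizedStructure,
    rsa_threshold: float = RSA_THRESHOLD,
    accessibility: AccessibilityRecord | None = None,
    **kwargs,
) -> set[tuple[str, int]]:
    """Residues with RSA strictly above the threshold (default 0.25)."""
    acc = accessibility or residue_sasa(structure, **kwargs)
    return {key for key, r in acc.rsa.items() if r > rsa_threshold}


# ---------------------------------------------------------------------------
# Interfaces and binding sites
# ---------------------------------------------------------------------------

def interface_residues(
    complex_structure: ParameterizedStructure | Sequence[ParameterizedStructure],
    cutoff: float = CONTACT_CUTOFF,
) -> dict[str, set[tuple[str, int]]]:
    """Per-chain sets of residues with any atom < cutoff from the partner.

    Accepts a two-chain structure or a pair of single-chain structures.
    """
    if isinstance(complex_structure, ParameterizedStructure):
        structures = [complex_structure]
    else:
        structures = list(complex_structure)
    residues = [r for st in structures for r in st.residues]
    chains = sorted({r.chain_id for r in residues})
    if len(chains) != 2:
        raise ScopeError(f"interface_residues needs exactly two chains, got {chains}")

    per_chain = {c: [r for r in residues if r.chain_id == c] for c in chains}
    trees = {
        c: cKDTree(np.vstack([r.coords() for r in per_chain[c]])) for c in chains
    }
    out: dict[str, set[tuple[str, int]]] = {c: set() for c in chains}
    for c, other in ((chains[0], chains[1]), (chains[1], chains[0])):
        for r in per_chain[c]:
            d, _ = trees[other].query(r.coords(), k=1)
            if float(np.min(d)) < cutoff:
                out[c].add(r.key)
    return out


def binding_site_points(
    template_surface: MolecularSurface,
    ligand_surface: MolecularSurface,
    cutoff: float = BINDING_SITE_CUTOFF,
) -> np.ndarray:
    """Indices of template points within cutoff of any ligand point."""
    tree = cKDTree(ligand_surface.points)
    d, _ = tree.query(template_surface.points, k=1)
    return np.flatnonzero(d < cutoff)
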