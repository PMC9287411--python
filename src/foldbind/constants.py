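"""Physical constants, residue vocabulary and bundled data-file locations."""

from importlib import resources

#: Vacuum Coulomb constant 1/(4 pi eps0) in kcal * Angstrom / (mol * e^2),
#: derived once from CODATA values of e, eps0 and N_A (with 1 kcal = 4184 J)
#: and frozen here. Relative permittivity is 1 (no solvent screening).
COULOMB_K = 332.0637133

#: The 20 standard amino-acid three-letter codes.
STANDARD_RESIDUES = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

#: Canonical alphabetical ordering used for composition vectors.
AA_ORDER = tuple(sorted(STANDARD_RESIDUES))

#: Bondi van der Waals radii (Angstrom) by element symbol.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20, "P": 1.80}

#: Fallback vdW radius for elements missing from the table (Angstrom).
VDW_RADIUS_DEFAULT = 1.70

#: Water probe radius (Angstrom) for solvent-accessible surfaces.
DEFAULT_PROBE_RADIUS = 1.4

#: Default surface point density (points per Angstrom^2).
DEFAULT_SURFACE_DENSITY = 5.0

#: Contact cutoff (Angstrom) defining interface residues and the
#: minimum-distance filter for energy distributions.
CONTACT_CUTOFF = 4.0

#: Cutoff (Angstrom) between surface point clouds defining binding-site points.
BINDING_SITE_CUTOFF = 3.0

#: Relative solvent accessibility threshold for "surface" residues.
RSA_THRESHOLD = 0.25

#: Patch sphere radius (Angstrom) for shape-complementarity patches.
PATCH_RADIUS = 8.0

#: Cone half-angle (degrees) used in the patch-to-disk projection.
CONE_ANGLE_DEG = 45.0

#: Default Zernike expansion order; yields 121 rotation invariants.
ZERNIKE_ORDER = 20

#: SG-SG distance (Angstrom) under which a CYS-CYS pair is treated as a
#: disulfide bridge and excluded from Lennard-Jones networks.
DISULFIDE_SG_CUTOFF = 2.5


def data_path(name: str):
    """Return a traversable path to a bundled data file."""
    return resources.files("foldbind.data").joinpath(name)
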