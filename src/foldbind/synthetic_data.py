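"""Synthetic fixtures: toy structures with controlled energetics and
surface patches with exact complementary molds.

Everything downstream of structure input can be exercised on these
generators: parameterized "toy" monomers and dimers whose single-atom
pseudo-residues carry chosen charges and Lennard-Jones parameters and whose
contact geometry is laid out exactly; dot-surface patches drawn from simple
analytic height fields with exact normals, paired with their geometric
molds (the same points displaced along inverted normals) and with unrelated
random decoys; and labelled datasets in which a single generator knob
(cross-chain contact count, or intramolecular salt-bridge count) drives the
synthetic experimental label through a monotone link plus Gaussian noise.

Label sign conventions follow the experimental ones: lower B_a = log10(K_d)
means stronger binding, higher melting temperature T_m means a more stable
fold. The contact knob pushes B_a *down* (and the inter LJ total down), the
salt-bridge knob pushes T_m *up* (and the intra Coulomb total down).

All generators are pure functions of (spec, seed); a single
``numpy.random.default_rng`` per call, no global state. None of this
attempts realistic protein folds -- residues are pseudo-atoms placed for
exact control of the energetics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import GenerationError
from .pipeline import DatasetRecord
from .structure_model import (
    Atom,
    ForceFieldTable,
    ParameterizedStructure,
    Residue,
    write_forcefield,
    write_pdb,
)

GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))

#: Separation (A) at which a +1/-1 pseudo-salt-bridge contributes -100
#: kcal/mol of Coulomb energy.
SALT_BRIDGE_DISTANCE = 3.320636


def _pseudo_residue(
    chain_id: str,
    index: int,
    position: np.ndarray,
    charge: float,
    eps: float,
    rmin_half: float,
) -> Residue:
    """Single-atom residue; the residue name encodes the integer charge
    (ARG = +1, ASP = -1, LEU = 0) so a matching parameter table can be
    written alongside PDB output."""
    if charge > 0.5:
        name = "ARG"
    elif charge < -0.5:
        name = "ASP"
    else:
        name = "LEU"
    atom = Atom(
        name="CA",
        element="C",
        position=np.asarray(position, dtype=float),
        charge=charge,
        lj_epsilon=eps,
        lj_rmin_half=rmin_half,
        parameterized=True,
    )
    return Residue(name=name, chain_id=chain_id, index=index, atoms=[atom])


# ---------------------------------------------------------------------------
# Toy dimers and monomers
# ---------------------------------------------------------------------------

@dataclass
class ToyDimerSpec:
    """Two facing single-atom chains with a controlled number of contacts.

    The first ``contact_count`` residues of chain B sit exactly
    ``contact_distance`` across from their chain-A partner; the rest are
    retracted far beyond any contact cutoff. ``charge_pattern`` is cycled
    over the contact pairs, the chain-A member getting +q and the chain-B
    member -q (favourable pairing); non-contact residues are neutral.
    """

    n_residues: int = 12
    contact_count: int = 4
    contact_distance: float = 3.8
    charge_pattern: tuple[float, ...] = (0.0,)
    #: how many of the contacts carry the charge pattern; None = all of them.
    charged_contact_count: int | None = None
    lj_epsilon: float = 0.1
    lj_rmin_half: float | None = None  # default: contact_distance / 2 (pair at its LJ minimum)
    residue_spacing: float = 8.0
    retract_distance: float = 25.0
    seed: int = 0


def make_toy_dimer(spec: ToyDimerSpec) -> tuple[ParameterizedStructure, ParameterizedStructure]:
    """Deterministic two-chain toy complex; returns (chain A, chain B)."""
    if spec.contact_distance <= 0:
        raise GenerationError("contact_distance must be > 0")
    if not 0 <= spec.contact_count <= spec.n_residues:
        raise GenerationError(
            f"contact_count {spec.contact_count} infeasible for {spec.n_residues} residues"
        )
    if spec.retract_distance <= spec.contact_distance:
        raise GenerationError("retract_distance must exceed contact_distance")
    rmh = spec.lj_rmin_half if spec.lj_rmin_half is not None else spec.contact_distance / 2.0

    chain_a = ParameterizedStructure(id=f"toy_dimer_{spec.seed}_A")
    chain_b = ParameterizedStructure(id=f"toy_dimer_{spec.seed}_B")
    res_a, res_b = [], []
    n_charged = spec.contact_count if spec.charged_contact_count is None else spec.charged_contact_count
    if n_charged > spec.contact_count:
        raise GenerationError("charged_contact_count exceeds contact_count")
    for i in range(spec.n_residues):
        x = i * spec.residue_spacing
        is_contact = i < spec.contact_count
        q = spec.charge_pattern[i % len(spec.charge_pattern)] if i < n_charged else 0.0
        z_b = spec.contact_distance if is_contact else spec.retract_distance
        res_a.append(
            _pseudo_residue("A", i + 1, np.array([x, 0.0, 0.0]), q, spec.lj_epsilon, rmh)
        )
        res_b.append(
            _pseudo_residue("B", i + 1, np.array([x, 0.0, z_b]), -q, spec.lj_epsilon, rmh)
        )
    chain_a.chains["A"] = res_a
    chain_b.chains["B"] = res_b
    chain_a.validate()
    chain_b.validate()
    return chain_a, chain_b


@dataclass
class ToyMonomerSpec:
    """A single chain with a controlled number of intramolecular salt bridges.

    Residues sit on a line, grouped in blocks of four. In every block the
    first and third residues (sequence separation 2, so the pair survives
    the bonded exclusion) form a contact at ``bridge_distance``; in the
    first ``bridge_count`` blocks that contact is a +1/-1 salt bridge,
    elsewhere it is uncharged. The contact count is therefore fixed by
    ``n_residues`` and only the charged fraction varies with the knob,
    which makes the strong-interaction probability of the Coulomb contact
    network scale with ``bridge_count``. Needs
    ``bridge_count <= n_residues // 4``.
    """

    n_residues: int = 24
    bridge_count: int = 2
    bridge_distance: float = SALT_BRIDGE_DISTANCE
    lj_epsilon: float = 0.1
    lj_rmin_half: float = 1.9
    residue_spacing: float = 7.0
    seed: int = 0


def make_toy_monomer(spec: ToyMonomerSpec) -> ParameterizedStructure:
    """Deterministic single-chain toy protein with exact salt bridges."""
    n_blocks = spec.n_residues // 4
    if spec.bridge_count < 0 or spec.bridge_count > n_blocks:
        raise GenerationError(
            f"{spec.bridge_count} bridges infeasible for {spec.n_residues} residues"
        )
    positions = [np.array([i * spec.residue_spacing, 0.0, 0.0]) for i in range(spec.n_residues)]
    charges = [0.0] * spec.n_residues
    for k in range(n_blocks):
        i, j = 4 * k, 4 * k + 2
        positions[j] = positions[i] + np.array([0.0, spec.bridge_distance, 0.0])
        if k < spec.bridge_count:
            charges[i], charges[j] = 1.0, -1.0
    st = ParameterizedStructure(id=f"toy_monomer_{spec.seed}")
    st.chains["A"] = [
        _pseudo_residue("A", i + 1, positions[i], charges[i], spec.lj_epsilon, spec.lj_rmin_half)
        for i in range(spec.n_residues)
    ]
    st.validate()
    return st


# ---------------------------------------------------------------------------
# Patches with molds
# ---------------------------------------------------------------------------

@dataclass
class Patch:
    """A bare point cloud with unit normals (no owning structure)."""

    points: np.ndarray
    normals: np.ndarray


@dataclass
class PatchPairSpec:
    """A base surface patch, its exact mold, and random decoy patches.

    ``base_shape`` picks the height-field family; ``noise_sigma`` (A)
    displaces patch and mold points independently along their normals, so
    sigma = 0 and gap = 0 give an exact geometric complement. Decoys are
    independent draws of the same family with perturbed curvature.
    """

    base_shape: str = "bumpy"  # paraboloid | sphere_cap | bumpy
    radius: float = 6.0  # in-plane disk radius, A
    curvature: float = 0.5
    n_bumps: int = 4
    bump_amplitude: float = 1.2
    noise_sigma: float = 0.0
    density: float = 5.0  # points per A^2
    gap: float = 0.0  # patch-mold separation along normals, A
    n_decoys: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise GenerationError("density must be > 0")
        if self.base_shape not in ("paraboloid", "sphere_cap", "bumpy"):
            raise GenerationError(f"unknown base shape {self.base_shape!r}")


def _sunflower_disk(n: int, radius: float) -> tuple[np.ndarray, np.ndarray]:
    k = np.arange(n, dtype=float)
    rho = radius * np.sqrt((k + 0.5) / n)
    phi = k * GOLDEN_ANGLE
    return rho * np.cos(phi), rho * np.sin(phi)


def _height_field(spec: PatchPairSpec, rng: np.random.Generator):
    """Return (f, grad) callables for the chosen analytic family."""
    if spec.base_shape == "paraboloid":
        c = spec.curvature / spec.radius

        def f(x, y):
            return c * (x * x + y * y)

        def grad(x, y):
            return 2 * c * x, 2 * c * y

        return f, grad

    if spec.base_shape == "sphere_cap":
        # sphere of radius Rc through the rim (z=0 at rho=radius)
        rc = spec.radius / max(min(spec.curvature, 0.999), 1e-3)
        z0 = -np.sqrt(rc * rc - spec.radius**2)

        def f(x, y):
            return np.sqrt(np.maximum(rc * rc - x * x - y * y, 1e-9)) + z0

        def grad(x, y):
            s = np.sqrt(np.maximum(rc * rc - x * x - y * y, 1e-9))
            return -x / s, -y / s

        return f, grad

    # bumpy: gentle paraboloid plus random Gaussian bumps
    c = spec.curvature / spec.radius
    cx = rng.uniform(-0.6 * spec.radius, 0.6 * spec.radius, spec.n_bumps)
    cy = rng.uniform(-0.6 * spec.radius, 0.6 * spec.radius, spec.n_bumps)
    amp = rng.uniform(-spec.bump_amplitude, spec.bump_amplitude, spec.n_bumps)
    width = rng.uniform(1.2, 2.5, spec.n_bumps)

    def f(x, y):
        z = c * (x * x + y * y)
        for a, u, v, w in zip(amp, cx, cy, width):
            z = z + a * np.exp(-((x - u) ** 2 + (y - v) ** 2) / (2 * w * w))
        return z

    def grad(x, y):
        gx, gy = 2 * c * x, 2 * c * y
        for a, u, v, w in zip(amp, cx, cy, width):
            g = a * np.exp(-((x - u) ** 2 + (y - v) ** 2) / (2 * w * w)) / (w * w)
            gx = gx - g * (x - u)
            gy = gy - g * (y - v)
        return gx, gy

    return f, grad


def _base_patch(spec: PatchPairSpec, rng: np.random.Generator) -> Patch:
    n = max(8, int(round(spec.density * np.pi * spec.radius**2)))
    x, y = _sunflower_disk(n, spec.radius)
    f, grad = _height_field(spec, rng)
    z = f(x, y)
    gx, gy = grad(x, y)
    normals = np.column_stack([-gx, -gy, np.ones_like(gx)])
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    return Patch(points=np.column_stack([x, y, z]), normals=normals)


def _add_normal_noise(patch: Patch, sigma: float, rng: np.random.Generator) -> Patch:
    if sigma <= 0:
        return patch
    disp = rng.normal(0.0, sigma, patch.points.shape[0])
    return Patch(points=patch.points + disp[:, None] * patch.normals, normals=patch.normals)


def make_patch_with_mold(spec: PatchPairSpec) -> tuple[Patch, Patch, list[Patch]]:
    """(patch, mold, decoys): the mold is the base offset by ``gap`` along
    inverted normals (a perfect shape complement at zero noise)."""
    seeds = np.random.SeedSequence(spec.seed).spawn(3 + spec.n_decoys)
    base = _base_patch(spec, np.random.default_rng(seeds[0]))
    mold = Patch(points=base.points - spec.gap * base.normals, normals=-base.normals)
    patch = _add_normal_noise(base, spec.noise_sigma, np.random.default_rng(seeds[1]))
    mold = _add_normal_noise(mold, spec.noise_sigma, np.random.default_rng(seeds[2]))
    decoys = []
    for i in range(spec.n_decoys):
        rng_i = np.random.default_rng(seeds[3 + i])
        decoy_spec = PatchPairSpec(
            base_shape=spec.base_shape,
            radius=spec.radius,
            curvature=spec.curvature * rng_i.uniform(0.5, 1.5),
            n_bumps=spec.n_bumps,
            bump_amplitude=spec.bump_amplitude,
            noise_sigma=0.0,
            density=spec.density,
            seed=spec.seed,  # unused below; geometry comes from rng_i
        )
        decoys.append(_base_patch(decoy_spec, rng_i))
    return patch, mold, decoys


# ---------------------------------------------------------------------------
# Labelled datasets
# ---------------------------------------------------------------------------

@dataclass
class LabelModel:
    """Monotone knob -> label link with Gaussian noise.

    ``label = intercept + slope * knob + N(0, noise_sd)``.
    """

    kind: str  # "T_m" | "B_a"
    intercept: float
    slope: float
    noise_sd: float

    def expected_correlation_magnitude(self, knobs: np.ndarray) -> float:
        """|Pearson r| between a noiseless linear readout of the knob and
        the label, in the large-sample limit: |s| sd(k) / sqrt(s^2 var(k) + sd^2)."""
        var_k = float(np.var(knobs))
        denom = np.sqrt(self.slope**2 * var_k + self.noise_sd**2)
        if denom == 0:
            return 1.0
        return abs(self.slope) * np.sqrt(var_k) / denom


#: Contact count drives binding: more contacts -> lower (stronger) B_a and
#: a more negative inter LJ total, hence a positive r(LJ total, B_a).
AFFINITY_CONTACTS = LabelModel(kind="B_a", intercept=-4.0, slope=-0.55, noise_sd=0.4)

#: Salt-bridge count drives stability: more bridges -> higher T_m and a
#: more negative intra Coulomb total, hence a negative r(C total, T_m).
STABILITY_SALT_BRIDGES = LabelModel(kind="T_m", intercept=45.0, slope=6.0, noise_sd=2.0)


def make_labelled_dataset(
    n_structures: int,
    label_model: str | LabelModel = "affinity_contacts",
    seed: int = 0,
    lj_epsilon: float = 0.5,
) -> list[DatasetRecord]:
    """Generate labelled records whose knob is stored as ground truth.

    ``label_model`` is "affinity_contacts" (toy dimers; knob = cross-chain
    contact count, 1..10) or "stability_saltbridges" (toy monomers; knob =
    salt-bridge count, 0..5), or a custom :class:`LabelModel` for the
    former geometry.
    """
    if label_model == "affinity_contacts":
        model = AFFINITY_CONTACTS
    elif label_model == "stability_saltbridges":
        model = STABILITY_SALT_BRIDGES
    elif isinstance(label_model, LabelModel):
        model = label_model
    else:
        raise GenerationError(f"unknown label model {label_model!r}")

    rng = np.random.default_rng(seed)
    records: list[DatasetRecord] = []
    for i in range(n_structures):
        if model.kind == "B_a":
            knob = int(rng.integers(1, 11))
            # one or two of the contacts are +1/-1 pairs, so the Coulomb
            # contact network carries a strong-interaction fraction that is
            # unrelated to the LJ-driving knob
            a, b = make_toy_dimer(
                ToyDimerSpec(
                    n_residues=12,
                    contact_count=knob,
                    charge_pattern=(1.0,),
                    charged_contact_count=min(1 + i % 2, knob),
                    lj_epsilon=lj_epsilon,
                    seed=seed * 10_000 + i,
                )
            )
            structures: tuple[ParameterizedStructure, ...] = (a, b)
        else:
            knob = int(rng.integers(0, 6))
            # jittered bridge length and spacing spread the strength and LJ
            # totals continuously without breaking the knob -> Coulomb link
            structures = (
                make_toy_monomer(
                    ToyMonomerSpec(
                        n_residues=24,
                        bridge_count=knob,
                        bridge_distance=float(rng.uniform(3.2, 3.45)),
                        residue_spacing=float(rng.uniform(6.5, 7.5)),
                        seed=seed * 10_000 + i,
                    )
                ),
            )
        label = model.intercept + model.slope * knob + rng.normal(0.0, model.noise_sd)
        records.append(
            DatasetRecord(
                id=f"syn{i:03d}",
                structures=structures,
                label_kind=model.kind,
                label_value=float(label),
                knob=knob,
            )
        )
    return records


def write_dataset(records: list[DatasetRecord], outdir: str | Path) -> Path:
    """Write records as PDB files + a manifest TSV + a matching parameter
    table, so the file-based pipeline runs on them unchanged.

    Returns the manifest path; the parameter table is ``toy_forcefield.tsv``
    in the same directory.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries: dict[tuple[str, str], tuple[float, float, float]] = {}
    rows = []
    for rec in records:
        merged = ParameterizedStructure(id=rec.id)
        for st in rec.structures:
            for cid, residues in st.chains.items():
                merged.chains[cid] = residues
        pdb_path = outdir / f"{rec.id}.pdb"
        write_pdb(merged, pdb_path)
        for res in merged.residues:
            for atom in res.atoms:
                key = (res.name, atom.name)
                params = (atom.charge, atom.lj_epsilon, atom.lj_rmin_half)
                if key in entries and entries[key] != params:
                    raise GenerationError(f"conflicting parameters for {key} across records")
                entries[key] = params
        rows.append((rec.id, pdb_path.name, rec.label_kind, rec.label_value))
    write_forcefield(ForceFieldTable(entries=entries, source="toy"), outdir / "toy_forcefield.tsv")
    manifest = outdir / "manifest.tsv"
    with open(manifest, "w") as fh:
        fh.write("id\tpdb_path\tlabel_kind\tlabel_value\n")
        for rid, pdb_name, kind, value in rows:
            fh.write(f"{rid}\t{pdb_name}\t{kind}\t{value:.4f}\n")
    return manifest
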