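# Methods

This note documents the models, parameters, numerical choices and known
limitations of `foldbind`, in the order the pipeline applies them.

## Structure input and parameterization

Structures are read from PDB files (via gemmi). Preprocessing is fixed and
deliberate: heteroatom records (waters, ligands, ions) are discarded;
alternate locations are resolved to the highest-occupancy conformer (ties
to the alphabetically first altloc); residues are renumbered 1-based and
gap-free per chain, removing insertion codes, so that sequence separation
is well defined for the bonded-exclusion rule below. Non-standard polymer
residues are an input error — structure repair, protonation and energy
minimization are treated as external preprocessing steps, not replicated
here.

Non-bonded parameters `(q, ε, Rmin/2)` per (residue, atom name) come from
a TSV table. The bundled table
(`data/forcefield_united_synthetic.tsv`) is a **synthetic united-charge
heavy-atom set** with CHARMM-style conventions: hydrogen partial charges
are absorbed into their bonded heavy atom, per-residue charges sum exactly
to the residue's formal charge, and Lennard-Jones parameters are assigned
per element (C: ε 0.078 kcal/mol, Rmin/2 2.04 Å; N: 0.200/1.85;
O: 0.120/1.70; S: 0.450/2.00). It is *not* an official force-field
release; it exists so unprotonated crystal structures work out of the box
and so the whole pipeline is reproducible without downloads. Any table
with the same five-column schema can be swapped in (`--forcefield`), which
is the supported way to use genuine CHARMM charges. Table validation
rejects negative well depths, non-positive radii and residues whose charge
sum is further than 0.01 e from an integer. Atoms without a table entry
are flagged, counted and excluded from energy sums; more than 20%
unmatched atoms aborts with a coverage error (it almost always means a
different atom-naming dialect).

## Energy networks

Atom-pair energies are the vacuum Coulomb term with
`K = 1/(4πε₀) = 332.0637133 kcal·Å/(mol·e²)` (derived once from CODATA
constants and frozen; relative permittivity 1, i.e. no solvent screening)
and the 12-6 Lennard-Jones potential whose pair minimum sits at the *sum*
of the two per-atom `Rmin/2` values. Residue-pair energies sum over all
parameterized atom pairs.

Network construction choices:

* **Bonded exclusion (intra):** same-chain pairs with sequence separation
  < 2 are excluded. Adjacent residues share bonded terms (bond, angle,
  dihedral) that a purely non-bonded model cannot represent; the
  renumbered gap-free indices make the rule well defined.
* **Totals vs distributions:** total energies sum over *all* allowed
  pairs (no distance cutoff); pooled energy *distributions* and node
  strengths use only pairs whose minimum atom-atom distance is below 4 Å.
  Both knobs are exposed (`distance_cutoff`).
* **Disulfides:** CYS–CYS pairs with SG–SG < 2.5 Å are excluded from LJ
  networks by default (the covalent contact makes the 12-6 term
  divergent/unphysical); they are kept in Coulomb networks.
* **Normalization:** totals can be divided by the residue count N; the
  study drivers report both raw and normalized totals for complexes.
* **Regions:** the distribution is partitioned as E < −100 (very strong
  favorable), −100 ≤ E < −10 (strong favorable), |E| ≤ 10 (weak),
  E > 10 kcal/mol (strong unfavorable); the boundary at −100 is assigned
  to the strong-favorable region so the four regions partition the line.
  The strong-interaction probability is P(|E| > 10) = 1 − P(weak).
* **High-strength threshold:** the "beginning of the favorable tail" of
  the strength distribution has no canonical value; the default is the
  5th percentile of the pooled strengths (configurable), recomputed per
  study.

Not modeled, by design: solvent/implicit electrostatics, 1-4 scaling,
Ewald/periodicity, minimization.

## Surfaces and accessibility

The solvent-accessible surface is generated deterministically: each atom
sphere of radius `r_vdW + probe` (Bondi radii, 1.4 Å water probe) carries
a Fibonacci spiral lattice at the requested density (default 5 pts/Å²;
the achieved density is within the lattice rounding of the request), and
lattice points inside any neighbouring solvent-accessible sphere are
removed. Outward normals are exact (radial). The spiral is anchored to a
per-atom frame built from the molecule's own geometry (centroid-to-atom
direction plus the principal axis of the coordinate covariance), which
makes the point set equivariant under rigid motions for generic
structures; perfectly symmetric arrangements fall back to deterministic
but frame-arbitrary choices. A reentrant (Connolly) molecular surface is
deliberately not computed — the patch machinery downstream assumes only
points with normals, and the solvent-accessible variant keeps normals
exact. Whether the reentrant surface would change patch-level conclusions
is untested here.

Per-residue SASA is (surviving points)/density; RSA divides by bundled
theoretical maxima (Tien et al. 2013 normalisation). Surface residues:
RSA > 0.25. Interface residues: any atom < 4 Å from the partner chain.
Binding-site points: surface points < 3 Å from the partner surface.

## 2D Zernike shape descriptors

Patch pipeline, in order:

1. **Patch**: all surface points within `R_s = 8 Å` of a binding-site
   point (template and ligand patches share the same sphere center — the
   wording of the underlying construction supports the shared center, and
   it is what is implemented).
2. **Orient**: translate the centroid to the origin; rotate the mean
   normal onto +z ("up", template) or −z ("down", ligand). A vanishing
   mean normal (a closed shell) is a degenerate-orientation error.
3. **Project**: the apex C sits on the z-axis where the widest secant
   angle to the patch equals 45°, found by bisection on the apex height
   (bracket up to 200 Å above the patch, tolerance 0.01 Å). In-plane
   coordinates are divided by the patch's maximum in-plane radius, so the
   image always fills the unit disk. Each pixel of a G×G grid (default
   G = 25, roughly several surface points per pixel at 5 pts/Å² and
   R_s = 8 Å) stores the mean distance r to C of its points; interior
   empty pixels are filled with the mean of their valid 8-neighbours,
   iterated to closure, and still-empty pixels stay masked.
4. **Expand**: `c_nm = (n+1)/π ⟨Z_nm|f⟩` for 0 ≤ m ≤ n ≤ N, n−m even,
   N = 20 (121 coefficients). The radial polynomial is evaluated exactly
   from its factorial sum. The disk integral is a pixel-wise quadrature:
   basis values are averaged over 4×4 subpixel centers inside the disk
   and pixels are weighted by their in-disk area. This boundary-aware
   rule is what keeps numerical orthogonality of the basis within ~0.2%
   up to order 8 on a 101×101 grid (naive center-sampling is ~2%).
5. **Invariants**: `z_nm = |c_nm|`, in canonical order (n ascending, m
   ascending) — invariant to in-plane rotation. Reconstruction (for
   diagnostics) takes the real part of the truncated sum with positive-m
   coefficients doubled, the standard convention for real images.

The complementarity score of a complex scans every (optionally strided)
binding-site point of the *template* (the partner with more residues;
ties go to file order), pairs the "up" template patch with the "down"
ligand patch from the same center, and records the Euclidean distance
between their 121-dimensional invariant vectors; the minimum over centers
is the score. Centers capturing fewer than 20 ligand (or template) points
are skipped and logged. Grid size, order, stride, patch radius and the
minimum point count are all configurable; G and the empty-pixel rule have
no canonical published value and are flagged as package choices, not
canonical ones.

## Composition and hydropathy

Amino-acid profiles are pooled residue counts (not per-structure
averages) over whole structures, surface subsets or interface subsets,
normalised to relative abundances. Interface hydropathy is the mean index
H over each chain's interface residues. The default bundled scale is a
**synthetic stand-in** for a molecular-dynamics water-affinity scale: an
affine rescaling of the inverted Kyte–Doolittle index onto [0, 2.6], so
H = 0 is the purely hydrophobic extreme and the class thresholds
(hydrophobic < 1.3, hydrophilic > 1.7, intermediate band inclusive) are
meaningful in structure. The raw Kyte–Doolittle table is bundled as an
alternative (note its opposite orientation — the 1.3/1.7 thresholds do
not apply to it); the genuine water-orientation scale can be supplied as
a two-column TSV to reproduce it exactly. Hydropathy windows (width 0.6,
overlapping, step 0.2 in the study drivers) keep a complex only when
*both* interface means fall inside the window.

## Studies, stratification, statistics

Labels: T_m in °C for monomers; B_a = log₁₀(K_d in M) for two-chain
complexes (lower B_a = tighter binding). K_d values in manifests are
converted to B_a; K_i and IC50 are treated as K_d-equivalent on the log
scale unless strict mode excludes them. Strata use a right-closed
boundary convention so printed shared endpoints resolve
deterministically — T_m: (<55), [55,60], (60,70], (>70); B_a: (<−9),
[−9,−8], (−8,−7], (−7,−5], (>−5). Correlations are plain Pearson r with
a two-sided t-test p-value and no multiple-testing correction; a
correlation is reported as undefined (not zero) below n = 3 or at zero
variance. Every exclusion — unparseable structure, failed
parameterization, empty interface, skipped patch center — is logged with
its id and reason in the report.

## Synthetic data: what it emulates, and what it does not

The generators produce the *statistical structure* of the two study
designs with exactly controllable energetics, not realistic proteins:

* **Toy dimers** — two facing chains of single-atom pseudo-residues
  (8 Å spacing); the first `contact_count` residues of chain B sit at the
  contact distance (default 3.8 Å = the LJ pair minimum for the default
  parameters) across from their chain-A partner, the rest are retracted
  to 25 Å. One or two contacts per dimer carry a ±1 e charge pair; the
  residue names (ARG/ASP/LEU) encode the integer charge so a matching
  parameter table can be written next to PDB output. The affinity label
  model sets B_a = −4 − 0.55·contacts + N(0, 0.4) with contacts uniform
  in 1..10, spanning all five strata: more contacts ⇒ more negative
  inter-LJ total and lower B_a, hence a *positive* r(LJ total, B_a).
* **Toy monomers** — one chain in blocks of four residues; each block has
  a contact at separation-2; in the first `bridge_count` blocks it is a
  ±1 e salt bridge (3.32 Å ⇒ ≈ −100 kcal/mol), elsewhere uncharged, so
  the contact count is fixed and only the charged fraction varies. The
  stability label model sets T_m = 45 + 6·bridges + N(0, 2) with bridges
  uniform in 0..5, spanning all four strata: more bridges ⇒ more negative
  Coulomb total and higher T_m, hence a *negative* r(C total, T_m). The
  bridge length and residue spacing are jittered (U(3.2, 3.45) and
  U(6.5, 7.5) Å) so strengths and LJ totals vary continuously.
* **Patch/mold pairs** — analytic height fields (paraboloid, sphere cap,
  or a bumpy paraboloid with random Gaussian bumps) sampled on a
  sunflower disk lattice with exact normals; the mold is the base
  displaced by `gap` along inverted normals (an exact complement at zero
  noise); noise displaces patch and mold independently along normals;
  decoys are independent draws of the same family.

All generators are pure functions of (spec, seed) with a single named RNG
per call. What passing tests on these fixtures shows: the machinery —
kernels, network assembly, stratification, surface/patch/descriptor
pipeline, correlation reporting — recovers designed effects with the
correct sign and magnitude. What it does not show: that real side-chain
packing, protonation states, or crystallographic artifacts behave like
the toys; conclusions about real datasets require real structures through
the same pipeline.

Problem sizes used by the test suite and the acceptance script — 40
structures per synthetic study, 20 patch/mold pairs, 101–128 pixel grids,
order-8 orthogonality scans — were chosen as the smallest sizes at which
the recovered statistics are stable across seeds.

## Numerical notes

* Coulomb constant frozen at 332.0637133; agreement of the unit-charge
  anchor (−100 kcal/mol at 3.320636 Å) to ±0.01 is a regression test.
* Apex bisection tolerance 0.01 Å; cone angle honored to ±0.1°.
* Quadrature: pixel-midpoint Riemann sums with subpixel-averaged basis
  values and in-disk area weights (see above); tolerances are stated per
  test rather than globally because they depend on the image's boundary
  behaviour — rotation invariance of the invariants is ~1e-4 relative for
  images that fade at the rim and ~1e-3 for images with full rim content.
* Degenerate inputs raise typed errors (`foldbind.errors`): empty
  structures, unparameterized residue pairs, single-chain inter scope,
  vanishing mean normals, unbracketable apex searches, empty pools.

## Known limitations

* Vacuum electrostatics overweight surface charge pairs relative to
  solvated reality; all study outputs are comparative, not absolute.
* The bundled parameter table and the default hydropathy scale are
  synthetic stand-ins (documented above); swap in measured tables for
  production analyses.
* The solvent-accessible (not reentrant) surface is used for patches.
* Single-model, two-chain complexes only; no disorder, no conformational
  ensembles, no binding kinetics — the score addresses the bound-state
  geometry under a lock-and-key assumption.
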