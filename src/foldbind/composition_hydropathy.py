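"""Amino-acid composition profiles and interface hydropathy.

Composition profiles are pooled residue counts (over whole structures,
solvent-exposed subsets or interface subsets) normalised to relative
abundances. Hydropathy uses a per-residue index H; the default bundled
scale is oriented so that H = 0.0 is the purely hydrophobic extreme and
larger H means more hydrophilic. That default is a synthetic stand-in --
an affine rescaling of the inverted Kyte-Doolittle index onto [0, 2.6] --
for the molecular-dynamics water-affinity scale it emulates; the genuine
table can be swapped in via a two-column TSV (residue, H). The raw
Kyte-Doolittle scale (opposite orientation) is also bundled.

Complexes are classified by the mean H of their interface residues:
hydrophobic below 1.3, hydrophilic above 1.7, intermediate in between
(thresholds meaningful only for the water-affinity orientation and
configurable).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .constants import AA_ORDER, CONTACT_CUTOFF, STANDARD_RESIDUES, data_path
from .errors import FoldbindError, InputError, ValidationError
from .structure_model import ParameterizedStructure
from .surface_model import interface_residues

#: Bundled scales, loadable by name.
BUNDLED_SCALES = {
    "water_affinity": "hydropathy_water_affinity_synthetic.tsv",
    "kyte_doolittle": "hydropathy_kyte_doolittle.tsv",
}

#: Class thresholds for the water-affinity orientation.
HYDROPHOBIC_MAX = 1.3
HYDROPHILIC_MIN = 1.7


@dataclass
class HydropathyScale:
    """Residue code -> hydropathy index H."""

    name: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        missing = STANDARD_RESIDUES - set(self.values)
        if missing:
            raise ValidationError(f"scale {self.name}: missing residues {sorted(missing)}")
        if not all(np.isfinite(list(self.values.values()))):
            raise ValidationError(f"scale {self.name}: non-finite values")

    def __getitem__(self, residue: str) -> float:
        return self.values[residue]


def load_hydropathy_scale(source: str | Path = "water_affinity") -> HydropathyScale:
    """Load a bundled scale by name or a user TSV (residue<TAB>H)."""
    if str(source) in BUNDLED_SCALES:
        text = data_path(BUNDLED_SCALES[str(source)]).read_text()
        name = str(source)
    else:
        p = Path(source)
        if not p.exists():
            raise InputError(f"no such hydropathy scale: {p}")
        text = p.read_text()
        name = p.stem
    values: dict[str, float] = {}
    for row in csv.reader(text.splitlines(), delimiter="\t"):
        if not row or row[0].startswith("#") or row[0] == "residue":
            continue
        values[row[0].strip()] = float(row[1])
    return HydropathyScale(name=name, values=values)


@dataclass
class CompositionProfile:
    """Relative abundances of the 20 amino acids (alphabetical order)."""

    abundances: np.ndarray  # (20,), sums to 1
    population: str = "all"  # all | surface | interface
    stratum: str = ""

    def as_dict(self) -> dict[str, float]:
        return dict(zip(AA_ORDER, map(float, self.abundances)))


def aa_frequencies(
    residue_names: Iterable[str], population: str = "all", stratum: str = ""
) -> CompositionProfile:
    """Pooled relative abundance of each amino-acid type."""
    counts = dict.fromkeys(AA_ORDER, 0)
    total = 0
    for name in residue_names:
        if name not in counts:
            raise InputError(f"aa_frequencies: unknown residue {name!r}")
        counts[name] += 1
        total += 1
    if total == 0:
        raise FoldbindError("aa_frequencies: empty residue pool")
    ab = np.array([counts[a] / total for a in AA_ORDER])
    return CompositionProfile(abundances=ab, population=population, stratum=stratum)


def interface_hydropathy(
    complex_structure: ParameterizedStructure | Sequence[ParameterizedStructure],
    scale: HydropathyScale,
    cutoff: float = CONTACT_CUTOFF,
) -> tuple[float, float]:
    """Mean interface H per chain, in chain-id order (the 4 A contact rule)."""
    iface = interface_residues(complex_structure, cutoff=cutoff)
    if isinstance(complex_structure, ParameterizedStructure):
        structures = [complex_structure]
    else:
        structures = list(complex_structure)
    name_of = {r.key: r.name for st in structures for r in st.residues}
    means = []
    for chain in sorted(iface):
        keys = iface[chain]
        if not keys:
            raise FoldbindError(f"chain {chain}: empty interface")
        means.append(float(np.mean([scale[name_of[k]] for k in keys])))
    return means[0], means[1]


def hydropathy_window_select(
    records: Sequence, center: float, width: float = 0.6
) -> list:
    """Records whose BOTH per-chain interface H values lie inside the window.

    Records must expose ``h_interface`` as a pair (H_chainA, H_chainB);
    the window is [center - width/2, center + width/2], inclusive.
    """
    lo, hi = center - width / 2.0, center + width / 2.0
    out = []
    for rec in records:
        h1, h2 = rec.h_interface
        if lo <= h1 <= hi and lo <= h2 <= hi:
            out.append(rec)
    return out


def hydropathy_class(
    mean_h: float,
    hydrophobic_max: float = HYDROPHOBIC_MAX,
    hydrophilic_min: float = HYDROPHILIC_MIN,
) -> str:
    """'hydrophobic' (H < 1.3), 'hydrophilic' (H > 1.7) or 'intermediate'."""
    if mean_h < hydrophobic_max:
        return "hydrophobic"
    if mean_h > hydrophilic_min:
        return "hydrophilic"
    return "intermediate"
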