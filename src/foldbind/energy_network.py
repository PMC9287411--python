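"""Residue-level non-bonded interaction-energy networks.

Atom-pair energies are the vacuum Coulomb term

    E^C_lm = K q_l q_m / r_lm,      K = 332.0637 kcal A / (mol e^2)

and the 12-6 Lennard-Jones potential

    E^LJ_lm = sqrt(eps_l eps_m) [ (Rmin/r)^12 - 2 (Rmin/r)^6 ],
    Rmin = Rmin_l + Rmin_m,

summed over all atom pairs of two residues to give the residue-pair energy
E^X_ij. Residues become nodes of a weighted graph whose edge weights are
these energies; the node strength s_i is the sum of a residue's incident
edge weights. Networks come in two scopes: *intra* (pairs within one
structure, excluding same-chain neighbours with sequence separation < 2,
which share bonded terms a non-bonded model cannot represent) and *inter*
(pairs across exactly two chains or structures of a complex).

No solvent screening, 1-4 scaling, cutoff smoothing or periodicity is
applied; energies are plain pairwise sums in vacuum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .constants import COULOMB_K, CONTACT_CUTOFF, DISULFIDE_SG_CUTOFF
from .errors import FoldbindError, ScopeError, UndefinedEnergyError
from .structure_model import ParameterizedStructure, Residue

Kind = Literal["C", "LJ"]
Scope = Literal["intra", "inter"]

#: Region boundaries (kcal/mol) of the interaction-energy distribution.
#: The four regions partition the real line: very strong favorable
#: (E < -100), strong favorable (-100 <= E < -10), weak (-10 <= E <= 10)
#: and strong unfavorable (E > 10).
VERY_STRONG_BOUND = -100.0
STRONG_BOUND = 10.0


# ---------------------------------------------------------------------------
# Pair kernels
# ---------------------------------------------------------------------------

def coulomb_pair(q_l: float, q_m: float, r_lm: float) -> float:
    """Vacuum Coulomb energy (kcal/mol) of two point charges (e) at r (A)."""
    if r_lm <= 0:
        raise ValueError(f"coulomb_pair: r must be > 0, got {r_lm}")
    return COULOMB_K * q_l * q_m / r_lm


def lj_pair(eps_l: float, eps_m: float, rmin_l: float, rmin_m: float, r_lm: float) -> float:
    """12-6 Lennard-Jones energy (kcal/mol).

    ``rmin_l`` and ``rmin_m`` are the per-atom half-minimum radii
    (``rmin_half`` of the parameter table); the pair minimum sits at their
    sum, where the energy is ``-sqrt(eps_l * eps_m)``.
    """
    if r_lm <= 0:
        raise ValueError(f"lj_pair: r must be > 0, got {r_lm}")
    if eps_l < 0 or eps_m < 0:
        raise ValueError("lj_pair: epsilon must be >= 0")
    s6 = ((rmin_l + rmin_m) / r_lm) ** 6
    return math.sqrt(eps_l * eps_m) * (s6 * s6 - 2.0 * s6)


def _residue_param_arrays(res: Residue):
    atoms = [a for a in res.atoms if a.parameterized]
    if not atoms:
        return None
    pos = np.array([a.position for a in atoms])
    q = np.array([a.charge for a in atoms])
    eps = np.array([a.lj_epsilon for a in atoms])
    rmh = np.array([a.lj_rmin_half for a in atoms])
    return pos, q, eps, rmh


def residue_pair_energy(res_i: Residue, res_j: Residue, kind: Kind) -> float:
    """Residue-pair energy E^X_ij: sum over all parameterized atom pairs."""
    pi = _residue_param_arrays(res_i)
    pj = _residue_param_arrays(res_j)
    if pi is None and pj is None:
        raise UndefinedEnergyError(
            f"no parameterized atoms in {res_i.key} nor {res_j.key}"
        )
    if pi is None or pj is None:
        raise UndefinedEnergyError(
            f"one of {res_i.key}, {res_j.key} has no parameterized atoms"
        )
    pos_i, q_i, eps_i, rmh_i = pi
    pos_j, q_j, eps_j, rmh_j = pj
    r = cdist(pos_i, pos_j)
    if np.any(r <= 0):
        raise ValueError("residue_pair_energy: coincident atoms (r = 0)")
    if kind == "C":
        return float(COULOMB_K * (np.outer(q_i, q_j) / r).sum())
    if kind == "LJ":
        s6 = ((rmh_i[:, None] + rmh_j[None, :]) / r) ** 6
        return float((np.sqrt(np.outer(eps_i, eps_j)) * (s6 * s6 - 2.0 * s6)).sum())
    raise ValueError(f"unknown energy kind {kind!r}")


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------

@dataclass
class EnergyNetwork:
    """Weighted residue-residue graph of one structure or complex."""

    structure_id: str
    scope: Scope
    kind: Kind
    #: node key = (chain id, renumbered residue index); edge keys are sorted.
    edges: dict[tuple[tuple[str, int], tuple[str, int]], float] = field(default_factory=dict)
    min_distances: dict[tuple[tuple[str, int], tuple[str, int]], float] = field(default_factory=dict)
    nodes: list[tuple[str, int]] = field(default_factory=list)
    size: int = 0  # residue count N of the underlying structure/complex

    def edge_energies(self) -> np.ndarray:
        return np.array(list(self.edges.values()), dtype=float)


def _collect_residues(
    structures: ParameterizedStructure | Sequence[ParameterizedStructure],
) -> tuple[str, list[Residue], dict[tuple[str, int], str]]:
    """Flatten one structure or a pair into residues with unique chain ids."""
    if isinstance(structures, ParameterizedStructure):
        structures = [structures]
    structures = list(structures)
    residues: list[Residue] = []
    seen_chains: set[str] = set()
    for k, st in enumerate(structures):
        for cid in st.chain_ids:
            if cid in seen_chains:
                raise ScopeError(
                    f"duplicate chain id {cid!r} across structures; rename chains"
                )
            seen_chains.add(cid)
        residues.extend(st.residues)
    sid = "+".join(st.id for st in structures)
    names = {r.key: r.name for r in residues}
    return sid, residues, names


def _is_disulfide(res_i: Residue, res_j: Residue) -> bool:
    if res_i.name != "CYS" or res_j.name != "CYS":
        return False
    sg_i, sg_j = res_i.atom("SG"), res_j.atom("SG")
    if sg_i is None or sg_j is None:
        return False
    return float(np.linalg.norm(sg_i.position - sg_j.position)) < DISULFIDE_SG_CUTOFF


def build_network(
    structures: ParameterizedStructure | Sequence[ParameterizedStructure],
    kind: Kind,
    scope: Scope = "intra",
    distance_cutoff: float | None = None,
    exclude_cys_bridges: bool | None = None,
) -> EnergyNetwork:
    """Assemble the residue-pair energy network.

    Parameters
    ----------
    structures
        One structure (intra scope, or inter if it has exactly two chains)
        or a sequence of two single-structure partners (inter scope).
    kind
        ``"C"`` (Coulomb) or ``"LJ"`` (Lennard-Jones).
    scope
        ``"intra"``: all pairs within the structure except same-chain pairs
        with sequence separation < 2. ``"inter"``: only cross-chain pairs;
        requires exactly two chains in total.
    distance_cutoff
        If set, keep only pairs whose minimum atom-atom distance is below
        the cutoff (A). ``None`` keeps all pairs (used for total energies).
    exclude_cys_bridges
        Drop CYS-CYS pairs whose SG-SG distance marks a disulfide bond
        (< 2.5 A). Default (``None``) enables this for LJ networks only,
        where the covalent contact makes the 12-6 term unphysical.
    """
    sid, residues, _names = _collect_residues(structures)
    if exclude_cys_bridges is None:
        exclude_cys_bridges = kind == "LJ"

    chain_of = {r.key: r.chain_id for r in residues}
    if scope == "inter":
        chains = sorted({c for c in chain_of.values()})
        if len(chains) != 2:
            raise ScopeError(f"inter scope needs exactly two chains, got {chains}")

    net = EnergyNetwork(
        structure_id=sid,
        scope=scope,
        kind=kind,
        nodes=[r.key for r in residues],
        size=len(residues),
    )
    coords = [r.coords() for r in residues]
    for i in range(len(residues)):
        ri = residues[i]
        for j in range(i + 1, len(residues)):
            rj = residues[j]
            same_chain = ri.chain_id == rj.chain_id
            if scope == "intra" and same_chain and abs(ri.index - rj.index) < 2:
                continue
            if scope == "inter" and same_chain:
                continue
            dmin = float(cdist(coords[i], coords[j]).min())
            if distance_cutoff is not None and dmin >= distance_cutoff:
                continue
            if exclude_cys_bridges and _is_disulfide(ri, rj):
                continue
            e = residue_pair_energy(ri, rj, kind)
            key = (ri.key, rj.key)
            net.edges[key] = e
            net.min_distances[key] = dmin
    return net


@dataclass
class StrengthVector:
    """Node strengths s_i = sum of incident edge energies (kcal/mol)."""

    structure_id: str
    kind: Kind
    scope: Scope
    strengths: dict[tuple[str, int], float]

    def values(self) -> np.ndarray:
        return np.array(list(self.strengths.values()), dtype=float)


def node_strengths(network: EnergyNetwork) -> StrengthVector:
    """Strength of every node; isolated residues get s_i = 0."""
    s = {node: 0.0 for node in network.nodes}
    for (ki, kj), e in network.edges.items():
        s[ki] += e
        s[kj] += e
    return StrengthVector(network.structure_id, network.kind, network.scope, s)


def total_energy(network: EnergyNetwork, normalize_by_size: bool = False) -> float:
    """Sum of all edge energies, optionally divided by residue count N."""
    tot = float(sum(network.edges.values()))
    if normalize_by_size:
        if network.size == 0:
            raise FoldbindError("cannot normalize: network has size 0")
        tot /= network.size
    return tot


# ---------------------------------------------------------------------------
# Distributions
# ---------------------------------------------------------------------------

REGION_NAMES = ("very_strong_favorable", "strong_favorable", "weak", "strong_unfavorable")


@dataclass
class EnergyDistribution:
    """Pooled edge energies with a density histogram and region probabilities."""

    energies: np.ndarray
    bin_edges: np.ndarray
    density: np.ndarray
    region_probabilities: dict[str, float]

    @property
    def n(self) -> int:
        return int(self.energies.size)


def region_probabilities(energies: np.ndarray) -> dict[str, float]:
    e = np.asarray(energies, dtype=float)
    n = e.size
    if n == 0:
        raise FoldbindError("empty energy pool")
    return {
        "very_strong_favorable": float((e < VERY_STRONG_BOUND).sum()) / n,
        "strong_favorable": float(((e >= VERY_STRONG_BOUND) & (e < -STRONG_BOUND)).sum()) / n,
        "weak": float(((e >= -STRONG_BOUND) & (e <= STRONG_BOUND)).sum()) / n,
        "strong_unfavorable": float((e > STRONG_BOUND).sum()) / n,
    }


def energy_distribution(
    networks: Iterable[EnergyNetwork], bin_width: float = 2.0
) -> EnergyDistribution:
    """Pool edge energies of several networks into a density histogram.

    Default bin width 2 kcal/mol suits Coulomb pools; use ~0.2 for LJ.
    """
    pooled = np.concatenate([net.edge_energies() for net in networks] or [np.array([])])
    if pooled.size == 0:
        raise FoldbindError("energy_distribution: empty pool")
    lo = math.floor(pooled.min() / bin_width) * bin_width
    hi = math.ceil(pooled.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    density, edges = np.histogram(pooled, bins=edges, density=True)
    return EnergyDistribution(
        energies=pooled,
        bin_edges=edges,
        density=density,
        region_probabilities=region_probabilities(pooled),
    )


def strong_interaction_probability(distribution: EnergyDistribution) -> float:
    """P(|E| > 10 kcal/mol): the strong favorable-or-unfavorable tail mass."""
    return 1.0 - distribution.region_probabilities["weak"]


def high_strength_probability(
    strength_vectors: Iterable[StrengthVector], threshold: float
) -> float:
    """Fraction of residues with strength below a (negative) threshold."""
    if threshold >= 0:
        raise ValueError("high_strength_probability: threshold must be < 0 (favorable tail)")
    pooled = np.concatenate([sv.values() for sv in strength_vectors])
    if pooled.size == 0:
        raise FoldbindError("high_strength_probability: no strengths")
    return float((pooled < threshold).sum()) / pooled.size


def default_strength_threshold(strength_vectors: Iterable[StrengthVector], percentile: float = 5.0) -> float:
    """Data-adaptive 'beginning of the favorable tail': a low percentile of the pooled strengths."""
    pooled = np.concatenate([sv.values() for sv in strength_vectors])
    if pooled.size == 0:
        raise FoldbindError("default_strength_threshold: no strengths")
    return float(np.percentile(pooled, percentile))
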