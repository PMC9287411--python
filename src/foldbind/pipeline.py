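"""Study orchestration: stratification, correlations and figure-level tables.

Two study drivers mirror the comparative analysis this package implements:

* :func:`run_stability_study` -- monomers labelled with a melting
  temperature T_m (deg C). Per protein, intramolecular Coulomb and
  Lennard-Jones totals (normalized by residue count N); pooled and
  per-stratum interaction-energy distributions under the 4 A
  minimum-distance contact filter; the probability of a strong
  (|E| > 10 kcal/mol) interaction per stratum against the stratum's mean
  T_m; node-strength tail probabilities.

* :func:`run_affinity_study` -- two-chain complexes labelled with
  B_a = log10(K_d). Intermolecular totals against B_a; stratified Coulomb
  distributions; interface amino-acid composition; per-chain interface
  hydropathy with windowed correlations r(LJ total, B_a); optional
  2D-Zernike shape-complementarity scores and their relation to B_a and to
  interface hydropathy classes.

Stratification uses fixed label ranges with a right-closed boundary
convention so shared printed endpoints resolve deterministically:
T_m: (<55), [55, 60], (60, 70], (>70); B_a: (<-9), [-9, -8], (-8, -7],
(-7, -5], (>-5). Correlations are plain Pearson r with a two-sided p value
and no multiple-testing correction.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import composition_hydropathy as ch
from . import energy_network as en
from . import surface_model as sm
from . import zernike2d as zk
from .errors import (
    EmptyReportError,
    FoldbindError,
    InputError,
    UndefinedCorrelationError,
)
from .structure_model import (
    ParameterizedStructure,
    assign_parameters,
    load_forcefield,
    read_pdb,
)

# ---------------------------------------------------------------------------
# Records, config
# ---------------------------------------------------------------------------

#: Label kinds accepted in manifests. K_d is converted to B_a = log10(K_d in M);
#: K_i and IC50 entries are treated as K_d-equivalent on the log scale unless
#: strict mode excludes them.
LABEL_KINDS = ("T_m", "B_a", "K_d", "K_i", "IC50")


@dataclass
class DatasetRecord:
    """One structure (or complex) plus its experimental label."""

    id: str
    structures: tuple[ParameterizedStructure, ...]
    label_kind: str  # "T_m" (deg C) or "B_a" (= log10 K_d, dimensionless)
    label_value: float
    stratum: str | None = None
    knob: int | None = None  # synthetic ground truth, if any
    h_interface: tuple[float, float] | None = None
    path: str | None = None


@dataclass
class StudyConfig:
    """Every threshold of the analysis, in one place."""

    contact_cutoff: float = 4.0  # A; interface residues & distribution filter
    binding_site_cutoff: float = 3.0  # A; surface-point binding regions
    rsa_threshold: float = 0.25
    patch_radius: float = 8.0  # A
    cone_angle_deg: float = 45.0
    zernike_order: int = 20
    zernike_grid: int = 25
    zernike_stride: int = 1
    surface_density: float = 5.0  # points / A^2
    probe_radius: float = 1.4  # A
    bin_width_coulomb: float = 2.0  # kcal/mol
    bin_width_lj: float = 0.2  # kcal/mol
    hydropathy_window_width: float = 0.6
    hydrophobic_max: float = 1.3
    hydrophilic_min: float = 1.7
    strength_tail_percentile: float = 5.0
    normalize_totals: bool = True
    hydropathy_scale: str = "water_affinity"
    min_ligand_points: int = 20
    strict_kd_only: bool = False  # exclude K_i / IC50-labelled records

    @classmethod
    def from_file(cls, path: str | Path) -> "StudyConfig":
        """Read a TOML key = value file; unknown keys are rejected."""
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - fields
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for f in dataclasses.fields(self):
                v = getattr(self, f.name)
                if isinstance(v, bool):
                    fh.write(f"{f.name} = {str(v).lower()}\n")
                elif isinstance(v, str):
                    fh.write(f'{f.name} = "{v}"\n')
                else:
                    fh.write(f"{f.name} = {v}\n")


# ---------------------------------------------------------------------------
# Stratification
# ---------------------------------------------------------------------------

TM_STRATA = ("very_low", "low", "high", "very_high")
BA_STRATA = ("very_high_affinity", "high_affinity", "medium_affinity", "low_affinity", "very_low_affinity")


def tm_stratum(tm: float) -> str:
    """Melting-temperature class: (<55), [55,60], (60,70], (>70) deg C."""
    if tm < 55.0:
        return "very_low"
    if tm <= 60.0:
        return "low"
    if tm <= 70.0:
        return "high"
    return "very_high"


def ba_stratum(ba: float) -> str:
    """Binding-affinity class of B_a = log10(K_d):
    (<-9), [-9,-8], (-8,-7], (-7,-5], (>-5). Lower B_a = stronger binding."""
    if ba < -9.0:
        return "very_high_affinity"
    if ba <= -8.0:
        return "high_affinity"
    if ba <= -7.0:
        return "medium_affinity"
    if ba <= -5.0:
        return "low_affinity"
    return "very_low_affinity"


def stratify(records: Sequence[DatasetRecord]) -> tuple[list[DatasetRecord], list[tuple[str, str]]]:
    """Attach a stratum to every labelled record; skip unlabelled ones.

    Returns (stratified records, exclusion log of (id, reason)).
    """
    out, excluded = [], []
    for rec in records:
        if rec.label_value is None or not math.isfinite(rec.label_value):
            excluded.append((rec.id, "missing or non-finite label"))
            continue
        if rec.label_kind == "T_m":
            rec.stratum = tm_stratum(rec.label_value)
        elif rec.label_kind == "B_a":
            rec.stratum = ba_stratum(rec.label_value)
        else:
            excluded.append((rec.id, f"unknown label kind {rec.label_kind!r}"))
            continue
        out.append(rec)
    return out, excluded


# ---------------------------------------------------------------------------
# Correlation
# ---------------------------------------------------------------------------

def correlate(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, int]:
    """Pearson r with two-sided t-test p value; returns (r, p, n)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InputError("correlate: length mismatch")
    if x.size < 3:
        raise UndefinedCorrelationError(f"need n >= 3, got {x.size}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise InputError("correlate: non-finite values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedCorrelationError("zero variance")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), int(x.size)


def _maybe_correlate(x, y):
    try:
        return correlate(x, y)
    except (UndefinedCorrelationError, InputError):
        return None


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

@dataclass
class StudyReport:
    """Figure-level statistics as tables.

    ``correlations`` maps a quantity-pair name to (r, p, n) or None when
    the correlation was undefined (too few points, zero variance).
    """

    kind: str  # "stability" | "affinity"
    totals: pd.DataFrame
    correlations: dict[str, tuple[float, float, int] | None]
    strata: pd.DataFrame
    composition: pd.DataFrame | None = None
    hydropathy_windows: pd.DataFrame | None = None
    zernike: pd.DataFrame | None = None
    exclusions: list[tuple[str, str]] = field(default_factory=list)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "kind": self.kind,
            "totals": self.totals.to_dict(orient="records"),
            "correlations": {
                k: (None if v is None else {"r": v[0], "p": v[1], "n": v[2]})
                for k, v in self.correlations.items()
            },
            "strata": self.strata.to_dict(orient="records"),
            "exclusions": [list(e) for e in self.exclusions],
        }
        for name in ("composition", "hydropathy_windows", "zernike"):
            df = getattr(self, name)
            if df is not None:
                payload[name] = df.to_dict(orient="records")
        text = json.dumps(payload, indent=2, allow_nan=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def _merged(rec: DatasetRecord) -> ParameterizedStructure:
    if len(rec.structures) == 1:
        return rec.structures[0]
    merged = ParameterizedStructure(id=rec.id)
    for st in rec.structures:
        for cid, residues in st.chains.items():
            if cid in merged.chains:
                raise InputError(f"{rec.id}: duplicate chain id {cid}")
            merged.chains[cid] = residues
    return merged


def _stratum_rows(records, order, config):
    """Per-stratum pooled distribution statistics and strength tails."""
    strengths_c = {r.id: en.node_strengths(r._nets[("C", "cut")]) for r in records}
    strengths_lj = {r.id: en.node_strengths(r._nets[("LJ", "cut")]) for r in records}
    threshold = en.default_strength_threshold(
        strengths_c.values(), config.strength_tail_percentile
    )
    threshold_lj = en.default_strength_threshold(
        strengths_lj.values(), config.strength_tail_percentile
    )
    rows = []
    nan = float("nan")
    for stratum in order:
        group = [r for r in records if r.stratum == stratum]
        if not group:
            continue
        try:
            pooled = en.energy_distribution(
                [r._nets[("C", "cut")] for r in group], bin_width=config.bin_width_coulomb
            )
            probs = pooled.region_probabilities
            strong = en.strong_interaction_probability(pooled)
        except FoldbindError:  # no contacts at all in this stratum
            probs = dict.fromkeys(en.REGION_NAMES, nan)
            strong = nan
        rows.append(
            {
                "stratum": stratum,
                "n": len(group),
                "mean_label": float(np.mean([r.label_value for r in group])),
                "strong_interaction_probability": strong,
                "p_very_strong_favorable": probs["very_strong_favorable"],
                "p_strong_favorable": probs["strong_favorable"],
                "p_weak": probs["weak"],
                "p_strong_unfavorable": probs["strong_unfavorable"],
                "high_strength_probability_C": en.high_strength_probability(
                    [strengths_c[r.id] for r in group], threshold
                )
                if threshold < 0
                else float("nan"),
                "high_strength_probability_LJ": en.high_strength_probability(
                    [strengths_lj[r.id] for r in group], threshold_lj
                )
                if threshold_lj < 0
                else float("nan"),
            }
        )
    return pd.DataFrame(rows), threshold


def _build_record_networks(rec, scope, config):
    """Cache intra/inter C and LJ networks (full + 4 A filtered) on the record."""
    target = rec.structures if len(rec.structures) > 1 else rec.structures[0]
    nets = {}
    for kind in ("C", "LJ"):
        nets[(kind, "full")] = en.build_network(target, kind, scope=scope)
        nets[(kind, "cut")] = en.build_network(
            target, kind, scope=scope, distance_cutoff=config.contact_cutoff
        )
    rec._nets = nets


def run_stability_study(
    records: Sequence[DatasetRecord], config: StudyConfig | None = None
) -> StudyReport:
    """Full melting-temperature study on a monomer dataset."""
    config = config or StudyConfig()
    records = [r for r in records if r.label_kind == "T_m"]
    records, excluded = stratify(records)
    usable = []
    for rec in records:
        try:
            _build_record_networks(rec, "intra", config)
            usable.append(rec)
        except FoldbindError as exc:
            excluded.append((rec.id, str(exc)))
    if not usable:
        raise EmptyReportError("stability study: no usable records")

    rows = []
    for rec in usable:
        n = rec.structures[0].size
        rows.append(
            {
                "id": rec.id,
                "T_m": rec.label_value,
                "stratum": rec.stratum,
                "n_residues": n,
                "E_C_total": en.total_energy(rec._nets[("C", "full")]),
                "E_LJ_total": en.total_energy(rec._nets[("LJ", "full")]),
                "E_C_total_norm": en.total_energy(rec._nets[("C", "full")], True),
                "E_LJ_total_norm": en.total_energy(rec._nets[("LJ", "full")], True),
            }
        )
    totals = pd.DataFrame(rows)

    suffix = "_norm" if config.normalize_totals else ""
    correlations = {
        "C_total_vs_Tm": _maybe_correlate(totals["E_C_total" + suffix], totals["T_m"]),
        "LJ_total_vs_Tm": _maybe_correlate(totals["E_LJ_total" + suffix], totals["T_m"]),
    }
    strata, threshold = _stratum_rows(usable, TM_STRATA, config)
    ok = strata[np.isfinite(strata["strong_interaction_probability"])]
    if len(ok) >= 3:
        correlations["strong_interaction_prob_vs_mean_Tm"] = _maybe_correlate(
            ok["strong_interaction_probability"], ok["mean_label"]
        )
    ok_s = strata[np.isfinite(strata["high_strength_probability_C"])]
    if len(ok_s) >= 3:
        correlations["high_strength_prob_vs_mean_Tm"] = _maybe_correlate(
            ok_s["high_strength_probability_C"], ok_s["mean_label"]
        )
    strata.attrs["strength_threshold"] = threshold
    return StudyReport(
        kind="stability",
        totals=totals,
        correlations=correlations,
        strata=strata,
        exclusions=excluded,
    )


def run_affinity_study(
    records: Sequence[DatasetRecord],
    config: StudyConfig | None = None,
    with_zernike: bool = False,
) -> StudyReport:
    """Full binding-affinity study on a two-chain complex dataset."""
    config = config or StudyConfig()
    records = [r for r in records if r.label_kind == "B_a"]
    records, excluded = stratify(records)
    scale = ch.load_hydropathy_scale(config.hydropathy_scale)
    usable = []
    for rec in records:
        try:
            _build_record_networks(rec, "inter", config)
            rec.h_interface = ch.interface_hydropathy(
                rec.structures if len(rec.structures) > 1 else rec.structures[0],
                scale,
                cutoff=config.contact_cutoff,
            )
            usable.append(rec)
        except FoldbindError as exc:
            excluded.append((rec.id, str(exc)))
    if not usable:
        raise EmptyReportError("affinity study: no usable records")

    rows = []
    for rec in usable:
        merged = _merged(rec)
        rows.append(
            {
                "id": rec.id,
                "B_a": rec.label_value,
                "stratum": rec.stratum,
                "n_residues": merged.size,
                "E_C_inter": en.total_energy(rec._nets[("C", "full")]),
                "E_LJ_inter": en.total_energy(rec._nets[("LJ", "full")]),
                "E_C_inter_norm": en.total_energy(rec._nets[("C", "full")], True),
                "E_LJ_inter_norm": en.total_energy(rec._nets[("LJ", "full")], True),
                "H_interface_A": rec.h_interface[0],
                "H_interface_B": rec.h_interface[1],
                "H_interface_mean": float(np.mean(rec.h_interface)),
            }
        )
    totals = pd.DataFrame(rows)

    suffix = "_norm" if config.normalize_totals else ""
    correlations = {
        "C_inter_vs_Ba": _maybe_correlate(totals["E_C_inter" + suffix], totals["B_a"]),
        "LJ_inter_vs_Ba": _maybe_correlate(totals["E_LJ_inter" + suffix], totals["B_a"]),
        "C_inter_raw_vs_Ba": _maybe_correlate(totals["E_C_inter"], totals["B_a"]),
        "LJ_inter_raw_vs_Ba": _maybe_correlate(totals["E_LJ_inter"], totals["B_a"]),
    }

    strata, threshold = _stratum_rows(usable, BA_STRATA, config)
    ok = strata[np.isfinite(strata["strong_interaction_probability"])]
    if len(ok) >= 3:
        correlations["strong_interaction_prob_vs_mean_Ba"] = _maybe_correlate(
            ok["strong_interaction_probability"], ok["mean_label"]
        )
    strata.attrs["strength_threshold"] = threshold

    # interface amino-acid composition per stratum
    comp_rows = []
    for stratum in BA_STRATA:
        group = [r for r in usable if r.stratum == stratum]
        if not group:
            continue
        names = []
        for rec in group:
            merged = _merged(rec)
            iface = sm.interface_residues(merged, cutoff=config.contact_cutoff)
            name_of = {res.key: res.name for res in merged.residues}
            for keys in iface.values():
                names.extend(name_of[k] for k in keys)
        if names:
            profile = ch.aa_frequencies(names, population="interface", stratum=stratum)
            comp_rows.append({"stratum": stratum, **profile.as_dict()})
    composition = pd.DataFrame(comp_rows) if comp_rows else None

    # hydropathy-windowed correlations of the LJ total with B_a
    window_rows = []
    h_all = totals["H_interface_mean"]
    centers = np.arange(
        math.floor(h_all.min() * 5) / 5, h_all.max() + 0.2, 0.2
    )
    for center in centers:
        members = ch.hydropathy_window_select(
            usable, center, width=config.hydropathy_window_width
        )
        sub = totals[totals["id"].isin([r.id for r in members])]
        res = _maybe_correlate(sub["E_LJ_inter" + suffix], sub["B_a"]) if len(sub) >= 3 else None
        window_rows.append(
            {
                "center": float(center),
                "n": len(sub),
                "r": None if res is None else res[0],
                "p": None if res is None else res[1],
            }
        )
    hydropathy_windows = pd.DataFrame(window_rows)

    zernike_df = None
    if with_zernike:
        z_rows = []
        for rec in usable:
            try:
                score = complex_zernike_score(rec, config)
            except FoldbindError as exc:
                excluded.append((rec.id, f"zernike: {exc}"))
                continue
            if score is None:
                excluded.append((rec.id, "zernike: empty binding site"))
                continue
            z_rows.append(
                {
                    "id": rec.id,
                    "B_a": rec.label_value,
                    "zernike_min_distance": score,
                    "E_LJ_inter": float(totals.loc[totals["id"] == rec.id, "E_LJ_inter"].iloc[0]),
                    "H_interface_mean": float(np.mean(rec.h_interface)),
                    "h_class": ch.hydropathy_class(
                        float(np.mean(rec.h_interface)),
                        config.hydrophobic_max,
                        config.hydrophilic_min,
                    ),
                }
            )
        zernike_df = pd.DataFrame(z_rows) if z_rows else None
        if zernike_df is not None and len(zernike_df) >= 3:
            correlations["zernike_min_vs_Ba"] = _maybe_correlate(
                zernike_df["zernike_min_distance"], zernike_df["B_a"]
            )
            correlations["zernike_min_vs_LJ_inter"] = _maybe_correlate(
                zernike_df["zernike_min_distance"], zernike_df["E_LJ_inter"]
            )

    return StudyReport(
        kind="affinity",
        totals=totals,
        correlations=correlations,
        strata=strata,
        composition=composition,
        hydropathy_windows=hydropathy_windows,
        zernike=zernike_df,
        exclusions=excluded,
    )


def complex_zernike_score(rec: DatasetRecord, config: StudyConfig) -> float | None:
    """Minimum Zernike distance over the binding region of one complex.

    The template is the partner with more residues (ties: first by order).
    Returns None when the binding region is empty or every center was
    skipped.
    """
    merged = _merged(rec)
    chains = merged.chain_ids
    if len(chains) != 2:
        raise InputError(f"{rec.id}: zernike score needs exactly two chains")
    parts = []
    for cid in chains:
        part = ParameterizedStructure(id=f"{rec.id}_{cid}")
        part.chains[cid] = merged.chains[cid]
        parts.append(part)
    parts.sort(key=lambda p: -p.size)  # template first (stable for ties)
    template, ligand = parts
    surf_t = sm.compute_surface(template, config.surface_density, config.probe_radius)
    surf_l = sm.compute_surface(ligand, config.surface_density, config.probe_radius)
    result = zk.complementarity_scan(
        surf_t,
        surf_l,
        patch_radius=config.patch_radius,
        order=config.zernike_order,
        stride=config.zernike_stride,
        grid=config.zernike_grid,
        binding_cutoff=config.binding_site_cutoff,
        min_ligand_points=config.min_ligand_points,
    )
    return result.minimum


# ---------------------------------------------------------------------------
# Manifests
# ---------------------------------------------------------------------------

def load_manifest(
    manifest_path: str | Path,
    forcefield: str | Path = "bundled",
    strict_kd_only: bool = False,
) -> tuple[list[DatasetRecord], list[tuple[str, str]]]:
    """Load a TSV manifest (id, pdb_path, label_kind, label_value).

    Paths are resolved relative to the manifest's directory. K_d values (M)
    are converted to B_a = log10(K_d); K_i and IC50 are treated as
    K_d-equivalent unless ``strict_kd_only``. Structures failing to read or
    parameterize are excluded with a logged reason.
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise InputError(f"no such manifest: {manifest_path}")
    table = load_forcefield(forcefield)
    records, excluded = [], []
    with open(manifest_path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"id", "pdb_path", "label_kind", "label_value"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise InputError(f"manifest must have columns {sorted(required)}")
        for row in reader:
            rid = row["id"]
            kind = row["label_kind"]
            if kind not in LABEL_KINDS:
                excluded.append((rid, f"unknown label kind {kind!r}"))
                continue
            try:
                value = float(row["label_value"])
            except ValueError:
                excluded.append((rid, f"bad label value {row['label_value']!r}"))
                continue
            if kind in ("K_d", "K_i", "IC50"):
                if strict_kd_only and kind != "K_d":
                    excluded.append((rid, f"{kind} excluded in strict mode"))
                    continue
                if value <= 0:
                    excluded.append((rid, f"non-positive {kind}"))
                    continue
                value = math.log10(value)
                kind = "B_a"
            pdb = manifest_path.parent / row["pdb_path"]
            try:
                st = read_pdb(pdb, structure_id=rid)
                st, _report = assign_parameters(st, table)
            except FoldbindError as exc:
                excluded.append((rid, str(exc)))
                continue
            records.append(
                DatasetRecord(
                    id=rid,
                    structures=(st,),
                    label_kind=kind,
                    label_value=value,
                    path=str(pdb),
                )
            )
    return records, excluded
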