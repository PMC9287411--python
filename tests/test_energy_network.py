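"""Energy kernels, networks, strengths and distributions."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from foldbind.energy_network import (
    EnergyNetwork,
    build_network,
    coulomb_pair,
    default_strength_threshold,
    energy_distribution,
    high_strength_probability,
    lj_pair,
    node_strengths,
    region_probabilities,
    residue_pair_energy,
    strong_interaction_probability,
    total_energy,
)
from foldbind.errors import FoldbindError, ScopeError, UndefinedEnergyError
from foldbind.structure_model import Atom, Residue
from foldbind.synthetic_data import ToyDimerSpec, make_toy_dimer

from conftest import chain_structure, single_atom_residue


def lj_oracle(eps_l, eps_m, rmin_l, rmin_m, r):
    """Independent transcription of the 12-6 form (kept separate from the
    implementation on purpose)."""
    rmin = rmin_l + rmin_m
    return math.sqrt(eps_l * eps_m) * ((rmin / r) ** 12 - 2.0 * (rmin / r) ** 6)


class TestPairKernels:
    def test_coulomb_zero_charge(self):
        assert coulomb_pair(0.0, 1.0, 2.5) == 0.0

    def test_coulomb_unit_charges_reference_distance(self):
        # K / 3.320636 A == 100 kcal/mol with the CODATA-derived constant
        assert coulomb_pair(1.0, -1.0, 3.320636) == pytest.approx(-100.0, abs=0.01)

    @given(st.floats(-2, 2), st.floats(-2, 2), st.floats(0.5, 20))
    def test_coulomb_antisymmetry_in_charge_sign(self, ql, qm, r):
        assert coulomb_pair(-ql, qm, r) == pytest.approx(-coulomb_pair(ql, qm, r), rel=1e-12)

    def test_coulomb_domain_error(self):
        with pytest.raises(ValueError):
            coulomb_pair(1.0, 1.0, 0.0)

    def test_lj_minimum_value_at_rmin_sum(self):
        assert lj_pair(0.2, 0.45, 1.8, 2.1, 1.8 + 2.1) == pytest.approx(
            -math.sqrt(0.2 * 0.45), rel=1e-12
        )

    def test_lj_zero_epsilon(self):
        for r in (1.0, 3.0, 10.0):
            assert lj_pair(0.0, 0.3, 1.9, 1.9, r) == 0.0

    def test_lj_matches_independent_transcription(self):
        assert lj_pair(0.1, 0.1, 1.9, 1.9, 3.0) == pytest.approx(
            lj_oracle(0.1, 0.1, 1.9, 1.9, 3.0), abs=1e-10
        )

    def test_lj_grid_search_confirms_minimum_location(self):
        eps_l, eps_m, rl, rm = 0.12, 0.31, 1.7, 2.2
        rs = np.linspace(2.0, 10.0, 800_001)
        vals = np.sqrt(eps_l * eps_m) * (((rl + rm) / rs) ** 12 - 2 * ((rl + rm) / rs) ** 6)
        k = int(np.argmin(vals))
        assert abs(rs[k] - (rl + rm)) < 1e-2
        assert vals[k] == pytest.approx(-math.sqrt(eps_l * eps_m), abs=1e-6)

    def test_kernels_decay_monotonically_beyond_minimum(self):
        rs = np.linspace(4.0, 40.0, 200)
        lj = np.array([abs(lj_pair(0.1, 0.1, 1.9, 1.9, r)) for r in rs])
        cc = np.array([abs(coulomb_pair(1.0, 1.0, r)) for r in rs])
        assert np.all(np.diff(lj) < 0)
        assert np.all(np.diff(cc) < 0)


class TestResiduePairEnergy:
    def _res(self, chain, idx, atoms):
        r = single_atom_residue("GLY", chain, idx, atoms[0][0], *atoms[0][1:])
        for pos, q, e, rmh in atoms[1:]:
            r.atoms.append(
                Atom("C", "C", np.asarray(pos, float), q, e, rmh, parameterized=True)
            )
        return r

    def test_single_atom_residues_equal_atom_kernel(self):
        a = single_atom_residue("GLY", "A", 1, [0, 0, 0], charge=0.5)
        b = single_atom_residue("GLY", "A", 3, [3, 0, 0], charge=-1.0)
        assert residue_pair_energy(a, b, "C") == pytest.approx(coulomb_pair(0.5, -1.0, 3.0))
        assert residue_pair_energy(a, b, "LJ") == pytest.approx(lj_pair(0.1, 0.1, 1.9, 1.9, 3.0))

    def test_two_by_two_matches_brute_force(self):
        rng = np.random.default_rng(7)
        atoms_i = [(rng.normal(0, 1, 3), 0.3, 0.1, 1.8), (rng.normal(0, 1, 3), -0.2, 0.2, 2.0)]
        atoms_j = [(rng.normal(5, 1, 3), 0.4, 0.15, 1.9), (rng.normal(5, 1, 3), -0.1, 0.05, 2.1)]
        ri = self._res("A", 1, atoms_i)
        rj = self._res("A", 4, atoms_j)
        for kind, kernel in (("C", None), ("LJ", None)):
            brute = 0.0
            for pi, qi, ei, rhi in atoms_i:
                for pj, qj, ej, rhj in atoms_j:
                    r = float(np.linalg.norm(np.asarray(pi) - np.asarray(pj)))
                    brute += (
                        coulomb_pair(qi, qj, r)
                        if kind == "C"
                        else lj_pair(ei, ej, rhi, rhj, r)
                    )
            assert residue_pair_energy(ri, rj, kind) == pytest.approx(brute, rel=1e-10)
            assert residue_pair_energy(rj, ri, kind) == pytest.approx(brute, rel=1e-10)

    def test_unparameterized_pair_is_undefined(self):
        a = single_atom_residue("GLY", "A", 1, [0, 0, 0])
        b = single_atom_residue("GLY", "A", 3, [3, 0, 0])
        for r in (a, b):
            r.atoms[0].parameterized = False
        with pytest.raises(UndefinedEnergyError):
            residue_pair_energy(a, b, "C")


def _cys_bridge_structure(sg_distance):
    def cys(chain, idx, ca_pos, sg_pos):
        ca = Atom("CA", "C", np.asarray(ca_pos, float), 0.0, 0.1, 1.9, parameterized=True)
        sg = Atom("SG", "S", np.asarray(sg_pos, float), 0.0, 0.45, 2.0, parameterized=True)
        return Residue("CYS", chain, idx, [ca, sg])

    top = 1.0 + sg_distance
    st_ = chain_structure("cys", "A", [cys("A", 1, [0, 0, 0], [0, 1.0, 0])])
    st_.chains["A"].append(cys("A", 2, [20, 0, 0], [20, 1.0, 0]))  # spacer: sep >= 2
    st_.chains["A"].append(cys("A", 3, [0, top + 1.5, 0], [0, top, 0]))
    return st_


class TestBuildNetwork:
    def test_far_apart_chains_give_empty_inter_network(self):
        a = chain_structure("a", "A", [single_atom_residue("GLY", "A", 1, [0, 0, 0])])
        b = chain_structure("b", "B", [single_atom_residue("GLY", "B", 1, [50, 0, 0])])
        net = build_network((a, b), "LJ", "inter", distance_cutoff=4.0)
        assert net.edges == {}
        assert net.size == 2

    def test_single_contact_dimer_yields_exactly_that_edge(self):
        a, b = make_toy_dimer(ToyDimerSpec(n_residues=5, contact_count=1, seed=0))
        net = build_network((a, b), "LJ", "inter", distance_cutoff=4.0)
        assert set(net.edges) == {(("A", 1), ("B", 1))}
        assert net.min_distances[(("A", 1), ("B", 1))] == pytest.approx(3.8)

    def test_disulfide_pair_excluded_from_lj_by_default(self):
        st_ = _cys_bridge_structure(2.05)
        lj = build_network(st_, "LJ", "intra", distance_cutoff=4.0)
        assert (("A", 1), ("A", 3)) not in lj.edges
        lj_keep = build_network(st_, "LJ", "intra", distance_cutoff=4.0, exclude_cys_bridges=False)
        assert (("A", 1), ("A", 3)) in lj_keep.edges
        # a CYS pair beyond the disulfide bond length is a normal edge
        far = build_network(_cys_bridge_structure(3.5), "LJ", "intra", distance_cutoff=5.0)
        assert (("A", 1), ("A", 3)) in far.edges

    def test_intra_excludes_adjacent_residues(self):
        residues = [
            single_atom_residue("GLY", "A", i + 1, [i * 3.0, 0, 0]) for i in range(4)
        ]
        net = build_network(chain_structure("s", "A", residues), "C", "intra")
        assert all(abs(ki[1] - kj[1]) >= 2 for ki, kj in net.edges)
        assert len(net.edges) == 3  # (1,3), (1,4), (2,4)

    def test_inter_scope_requires_two_chains(self):
        a = chain_structure("a", "A", [single_atom_residue("GLY", "A", 1, [0, 0, 0])])
        with pytest.raises(ScopeError):
            build_network(a, "C", "inter")


class TestStrengthsAndTotals:
    def test_single_edge_strengths(self):
        net = EnergyNetwork("x", "intra", "C", edges={(("A", 1), ("A", 2)): -5.0},
                            nodes=[("A", 1), ("A", 2)], size=2)
        s = node_strengths(net)
        assert s.strengths == {("A", 1): -5.0, ("A", 2): -5.0}

    def test_triangle_hand_sum(self):
        edges = {
            (("A", 1), ("A", 2)): -1.0,
            (("A", 1), ("A", 3)): -2.0,
            (("A", 2), ("A", 3)): 4.0,
        }
        net = EnergyNetwork("x", "intra", "C", edges=edges,
                            nodes=[("A", 1), ("A", 2), ("A", 3)], size=3)
        s = node_strengths(net).strengths
        assert (s[("A", 1)], s[("A", 2)], s[("A", 3)]) == (-3.0, 3.0, 2.0)

    def test_isolated_residue_has_zero_strength(self):
        net = EnergyNetwork("x", "intra", "C", edges={(("A", 1), ("A", 3)): -1.0},
                            nodes=[("A", 1), ("A", 2), ("A", 3)], size=3)
        assert node_strengths(net).strengths[("A", 2)] == 0.0

    @given(st.integers(0, 10_000))
    def test_double_counting_identity_on_random_networks(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 30))
        nodes = [("A", i + 1) for i in range(n)]
        edges = {}
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < 0.3:
                    edges[(nodes[i], nodes[j])] = float(rng.normal(0, 50))
        net = EnergyNetwork("r", "intra", "C", edges=edges, nodes=nodes, size=n)
        lhs = sum(node_strengths(net).strengths.values())
        rhs = 2.0 * sum(edges.values())
        assert lhs == pytest.approx(rhs, rel=1e-6, abs=1e-9)

    def test_totals_and_normalization(self):
        net = EnergyNetwork("x", "intra", "C",
                            edges={(("A", 1), ("A", 3)): -3.0, (("A", 2), ("A", 5)): -7.0},
                            nodes=[("A", i) for i in range(1, 6)], size=5)
        assert total_energy(net) == -10.0
        assert total_energy(net, normalize_by_size=True) == pytest.approx(-2.0)
        empty = EnergyNetwork("e", "intra", "C", size=4)
        assert total_energy(empty) == 0.0


def _net_with(energies):
    nodes = [("A", i + 1) for i in range(len(energies) + 1)]
    edges = {(nodes[i], nodes[i + 1]): e for i, e in enumerate(energies)}
    return EnergyNetwork("d", "intra", "C", edges=edges, nodes=nodes, size=len(nodes))


class TestDistributions:
    def test_four_region_probabilities_partition(self):
        dist = energy_distribution([_net_with([-200.0, -50.0, 0.0, 50.0])])
        probs = dist.region_probabilities
        assert probs == {
            "very_strong_favorable": 0.25,
            "strong_favorable": 0.25,
            "weak": 0.25,
            "strong_unfavorable": 0.25,
        }
        assert sum(probs.values()) == pytest.approx(1.0)

    def test_all_weak_pool_has_zero_strong_probability(self):
        dist = energy_distribution([_net_with([-9.0, 0.5, 3.0])])
        assert strong_interaction_probability(dist) == 0.0

    def test_histogram_density_integrates_to_one(self):
        rng = np.random.default_rng(1)
        dist = energy_distribution([_net_with(list(rng.normal(0, 30, 200)))], bin_width=2.0)
        area = float(np.sum(dist.density * np.diff(dist.bin_edges)))
        assert area == pytest.approx(1.0, abs=1e-9)

    def test_strong_probability_is_complement_of_weak(self):
        dist = energy_distribution([_net_with([-12.0, -5.0, 15.0, 1.0])])
        assert strong_interaction_probability(dist) == pytest.approx(0.5)
        assert strong_interaction_probability(dist) == pytest.approx(
            1.0 - dist.region_probabilities["weak"]
        )

    def test_empty_pool_is_an_error(self):
        with pytest.raises(FoldbindError):
            energy_distribution([_net_with([])])
        with pytest.raises(FoldbindError):
            region_probabilities(np.array([]))


class TestHighStrengthProbability:
    def _sv(self, values):
        net = _net_with([])
        from foldbind.energy_network import StrengthVector

        return StrengthVector("x", "C", "intra", {("A", i): v for i, v in enumerate(values)})

    def test_threshold_below_minimum_gives_zero(self):
        assert high_strength_probability([self._sv([-5, -2, 0])], -100.0) == 0.0

    def test_counting(self):
        assert high_strength_probability([self._sv([-50, -5, 0])], -10.0) == pytest.approx(1 / 3)

    def test_monotone_as_threshold_decreases(self):
        sv = self._sv(list(np.random.default_rng(3).normal(-10, 20, 100)))
        probs = [high_strength_probability([sv], t) for t in (-1e-6, -5, -10, -20, -40)]
        assert all(a >= b for a, b in zip(probs, probs[1:]))

    def test_nonnegative_threshold_rejected(self):
        with pytest.raises(ValueError):
            high_strength_probability([self._sv([-1.0])], 0.0)

    def test_default_threshold_is_low_percentile(self):
        sv = self._sv(list(np.linspace(-100, 0, 101)))
        assert default_strength_threshold([sv], 5.0) == pytest.approx(-95.0)


class TestMonotonicityOnSyntheticDimers:
    def test_extra_favorable_contact_strictly_lowers_inter_lj_total(self):
        totals = []
        for k in (1, 2, 3, 4):
            a, b = make_toy_dimer(ToyDimerSpec(n_residues=8, contact_count=k, lj_epsilon=0.3, seed=0))
            net = build_network((a, b), "LJ", "inter")
            totals.append(total_energy(net))
        assert all(t2 < t1 for t1, t2 in zip(totals, totals[1:]))

    def test_network_total_equals_brute_force_atom_double_loop(self):
        a, b = make_toy_dimer(
            ToyDimerSpec(n_residues=6, contact_count=3, charge_pattern=(1.0,), seed=0)
        )
        net = build_network((a, b), "C", "inter")
        brute = 0.0
        for ra in a.residues:
            for rb in b.residues:
                for at_a in ra.atoms:
                    for at_b in rb.atoms:
                        r = float(np.linalg.norm(at_a.position - at_b.position))
                        brute += coulomb_pair(at_a.charge, at_b.charge, r)
        assert total_energy(net) == pytest.approx(brute, rel=1e-10)
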