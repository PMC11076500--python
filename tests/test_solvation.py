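"""SASA against analytic and Monte Carlo oracles; ASP energetics."""

from __future__ import annotations

import math

import numpy as np
import pytest

from fgtools import structio as io
from fgtools import synthetic_data as syn
from fgtools.solvation import (
    ASPSet,
    SASAResult,
    compute_sasa,
    fibonacci_sphere,
    identify_stabilizing_patches,
    load_asp_set,
    middle_index,
    position_means,
    solvation_free_energy,
    stabilization_energy,
)
from fgtools.structio import Atom, Chain, Residue, StructureModel

from oracles import mc_sasa, sphere_area, two_sphere_area


def atom_model(coords, radii, res_name="ALA", names=None):
    """Model of bare carbon atoms at given coordinates with given radii."""
    names = names or [f"C{i}" for i in range(len(coords))]
    residues = [
        Residue(
            chain_id="A",
            seq_id=i + 1,
            res_name=res_name,
            atoms=[Atom(serial=i + 1, name=names[i], element="C", coord=c, vdw_radius=r)],
        )
        for i, (c, r) in enumerate(zip(coords, radii))
    ]
    return StructureModel(id="atoms", chains=[Chain("A", residues)])


def test_fibonacci_points_unit_and_deterministic():
    pts = fibonacci_sphere(960)
    assert np.allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)
    assert np.array_equal(pts, fibonacci_sphere(960))


class TestSASAOracles:
    def test_isolated_atom_matches_analytic_sphere(self):
        model = atom_model([np.zeros(3)], [1.9])
        sasa = compute_sasa(model, probe=1.4, n_points=960)
        expect = sphere_area(1.9, 1.4)  # 4π(3.3)² ≈ 136.8 Å²
        assert sasa.per_atom_area[0] == pytest.approx(expect, rel=5e-3)

    def test_two_spheres_match_cap_formula(self):
        d = 3.3
        model = atom_model([np.zeros(3), np.array([d, 0.0, 0.0])], [1.9, 1.9])
        sasa = compute_sasa(model, probe=1.4, n_points=960)
        expect = two_sphere_area(1.9, 1.4, d)
        assert sasa.per_atom_area == pytest.approx(expect, rel=1e-2)

    def test_random_cluster_matches_monte_carlo(self):
        rng = np.random.default_rng(5)
        coords = rng.uniform(0, 8, size=(20, 3))
        radii = rng.uniform(1.5, 2.0, size=20)
        sasa = compute_sasa(atom_model(coords, radii), n_points=960)
        oracle = mc_sasa(coords, radii, n_per_atom=100_000, seed=1)
        assert sasa.total_area == pytest.approx(oracle.sum(), rel=1e-2)

    def test_occlusion_monotonicity(self):
        rng = np.random.default_rng(6)
        coords = rng.uniform(0, 6, size=(8, 3))
        radii = np.full(8, 1.7)
        base = compute_sasa(atom_model(coords, radii)).per_atom_area
        grown = compute_sasa(
            atom_model(np.vstack([coords, coords.mean(axis=0)]), np.append(radii, 1.7))
        ).per_atom_area[:8]
        assert np.all(grown <= base + 1e-12)

    def test_point_density_convergence(self, two_chain_contact):
        coarse = compute_sasa(two_chain_contact, n_points=960).total_area
        fine = compute_sasa(two_chain_contact, n_points=3840).total_area
        assert abs(fine - coarse) / fine < 0.005

    def test_missing_radius_raises(self):
        model = atom_model([np.zeros(3)], [1.9])
        model.chains[0].residues[0].atoms[0].vdw_radius = None
        with pytest.raises(ValueError, match="no vdW radius"):
            compute_sasa(model)

    def test_coarse_point_count_warns(self):
        with pytest.warns(UserWarning, match="coarse"):
            compute_sasa(atom_model([np.zeros(3)], [1.9]), n_points=16)


class TestASP:
    def test_default_set_classification(self):
        asp = load_asp_set()
        assert asp.classify("ALA", "CB", "C") == "carbon"
        assert asp.classify("ALA", "N", "N") == "neutral_N"
        assert asp.classify("ASP", "OD1", "O") == "charged_O"
        assert asp.classify("LYS", "NZ", "N") == "charged_N"
        assert asp.classify("GLY", "OXT", "O") == "charged_O"
        assert asp.classify("MET", "SD", "S") == "sulfur"
        with pytest.raises(KeyError, match="MSE"):
            asp.classify("MSE", "SE", "SE")

    def test_energy_linear_in_area_and_parameters(self):
        asp = load_asp_set()
        model = atom_model([np.zeros(3)], [1.9])
        res, atom = model.chains[0].residues[0], model.chains[0].residues[0].atoms[0]
        sasa = SASAResult(entries=[(res, atom)], per_atom_area=np.array([100.0]), probe_radius=1.4, n_points=960)
        atom_e, res_e = solvation_free_energy(sasa, asp)
        # 100 Å² of carbon at parameter p cal/(mol·Å²) is 0.1·p kcal/mol
        assert atom_e[0] == pytest.approx(0.1 * asp.mapping["carbon"])
        assert res_e[("A", 1)] == pytest.approx(atom_e[0])
        # homogeneity: doubling areas doubles energies
        sasa2 = SASAResult(entries=sasa.entries, per_atom_area=sasa.per_atom_area * 2, probe_radius=1.4, n_points=960)
        assert solvation_free_energy(sasa2, asp)[0][0] == pytest.approx(2 * atom_e[0])
        # scaling the ASP set scales energies identically
        assert solvation_free_energy(sasa, asp.scaled(3.0))[0][0] == pytest.approx(3 * atom_e[0])

    def test_zero_area_zero_energy(self):
        asp = load_asp_set()
        model = atom_model([np.zeros(3)], [1.9])
        res, atom = model.chains[0].residues[0], model.chains[0].residues[0].atoms[0]
        sasa = SASAResult(entries=[(res, atom)], per_atom_area=np.array([0.0]), probe_radius=1.4, n_points=960)
        atom_e, _ = solvation_free_energy(sasa, asp)
        assert atom_e[0] == 0.0


class TestStabilization:
    def test_middle_layer_selection(self):
        assert middle_index(5) == 2  # layers 1..5 -> middle is 3
        assert middle_index(9) == 4  # layers 1..9 -> middle is 5
        with pytest.raises(ValueError):
            middle_index(4)

    def test_single_chain_reference_equals_state(self):
        model = io.assign_radii(syn.make_beta_stack(syn.StackSpec(n_layers=1, chains_per_layer=1)))
        profile = stabilization_energy(model, context=1, reference_mode="isolated_conformer")
        assert all(abs(e) < 1e-12 for e in profile.per_residue_energy.values())
        assert profile.mean_per_residue == pytest.approx(0.0, abs=1e-12)

    def test_even_context_rejected(self, default_stack):
        with pytest.raises(ValueError, match="odd"):
            stabilization_energy(io.assign_radii(default_stack), context=4)

    def test_too_few_layers_rejected(self):
        model = io.assign_radii(syn.make_beta_stack(syn.StackSpec(n_layers=3)))
        with pytest.raises(ValueError, match="< context"):
            stabilization_energy(model, context=5)

    def test_two_chain_contact_matches_mc_oracle(self, two_chain_contact):
        """ΔΔG must equal the ASP-weighted buried area from the MC oracle."""
        from fgtools.fibril_geometry import detect_layers

        asp = load_asp_set()
        # both chains form one layer; a huge gap threshold pins that down
        layers = detect_layers(two_chain_contact, gap_threshold=1e9)
        profile = stabilization_energy(two_chain_contact, layers, context=1, n_points=960)
        mid_chain = profile.middle_chain_ids

        def heavy(model):
            return [(r, a) for r, a in model.iter_atoms() if not a.is_hydrogen]

        def mc_res_energy(model, seed):
            entries = heavy(model)
            coords = np.array([a.coord for _, a in entries])
            radii = np.array([a.vdw_radius for _, a in entries])
            areas = mc_sasa(coords, radii, n_per_atom=40_000, seed=seed)
            out = {}
            for (r, a), area in zip(entries, areas):
                p = asp.parameter(r.res_name, a.name, a.element)
                out[(r.chain_id, r.seq_id)] = out.get((r.chain_id, r.seq_id), 0.0) + p * area / 1000.0
            return out

        assembly_e = mc_res_energy(two_chain_contact, seed=10)
        for cid in mid_chain:
            alone = io.subset_chains(two_chain_contact, [cid])
            alone_e = mc_res_energy(alone, seed=11)
            for res in two_chain_contact.get_chain(cid).residues:
                key = (cid, res.seq_id)
                oracle = assembly_e[key] - alone_e[key]
                assert profile.per_residue_energy[key] == pytest.approx(oracle, abs=0.05)

    def test_buried_carbon_contributions_are_stabilizing(self, two_chain_contact):
        """Positive-ASP atoms whose area shrinks on assembly contribute ≤ 0."""
        asp = load_asp_set()
        assembly = compute_sasa(two_chain_contact)
        keyed_assembly = {
            (r.chain_id, r.seq_id, a.name): ar
            for (r, a), ar in zip(assembly.entries, assembly.per_atom_area)
        }
        cid = two_chain_contact.chains[0].chain_id
        alone = compute_sasa(io.subset_chains(two_chain_contact, [cid]))
        any_buried = False
        for (r, a), ar in zip(alone.entries, alone.per_atom_area):
            if a.element != "C":
                continue
            delta_area = keyed_assembly[(r.chain_id, r.seq_id, a.name)] - ar
            if delta_area < -1.0:
                any_buried = True
                assert asp.mapping["carbon"] * delta_area <= 0
        assert any_buried  # the fixture must actually bury carbon surface

    def test_tripeptide_reference_mode_runs(self):
        model = io.assign_radii(syn.make_beta_stack(syn.StackSpec(n_layers=3, chains_per_layer=2)))
        profile = stabilization_energy(model, context=3, reference_mode="tripeptide", n_points=240)
        assert profile.reference_mode == "tripeptide"
        assert profile.mean_per_residue < 0  # assembly buries surface vs exposed reference

    def test_fibril_middle_layer_is_stabilized(self, default_stack):
        profile = stabilization_energy(io.assign_radii(default_stack), context=5)
        assert set(c for c, _ in profile.per_residue_energy) == set(profile.middle_chain_ids)
        assert len(profile.middle_chain_ids) == 5
        assert profile.mean_per_residue < 0


class TestPatches:
    def test_flat_profile_above_threshold_empty(self):
        means = {i: -0.1 for i in range(1, 11)}
        assert identify_stabilizing_patches(means, threshold=-0.5) == []

    def test_planted_two_dip_profile(self):
        means = {i: -0.1 for i in range(299, 325)}
        for i in (300, 301, 302, 303):
            means[i] = -1.2
        for i in (317, 318, 319, 320):
            means[i] = -0.9
        assert identify_stabilizing_patches(means, threshold=-0.5) == [(300, 303), (317, 320)]

    def test_single_gap_merged(self):
        means = {1: -1.0, 2: -0.1, 3: -1.0, 4: -0.1, 5: -0.1, 6: -1.0}
        assert identify_stabilizing_patches(means, threshold=-0.5) == [(1, 3), (6, 6)]

    def test_position_means_average_over_chains(self, default_stack):
        profile = stabilization_energy(io.assign_radii(default_stack), context=5, n_points=240)
        means = position_means(profile)
        assert len(means) == 30
        some_pos = next(iter(means))
        per_chain = [e for (c, s), e in profile.per_residue_energy.items() if s == some_pos]
        assert means[some_pos] == pytest.approx(np.mean(per_chain))
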