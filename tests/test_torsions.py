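"""Dihedral geometry, torsion series, population maps and Boltzmann weighting."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.spatial.transform import Rotation
from scipy.stats import chisquare

from glycoflow.torsions import (assign_rotamer_states, boltzmann_energy_map,
                                dihedral_angle, population_map2d,
                                torsion_series)
from glycoflow.units import KB

finite3 = st.tuples(*[st.floats(-5, 5) for _ in range(3)]).map(np.array)


def _oracle_dihedral(p1, p2, p3, p4):
    """Independent construction: angle between plane normals, signed by
    the triple product."""
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    cosang = np.dot(n1, n2) / (np.linalg.norm(n1) * np.linalg.norm(n2))
    ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
    if np.dot(np.cross(n1, n2), b2) < 0:
        ang = -ang
    return ang


class TestDihedralAngle:
    def test_planar_cis_is_zero(self):
        p = [np.array([1.0, 1, 0]), np.array([0.0, 0, 0]),
             np.array([0.0, 0, 1]), np.array([1.0, 1, 1])]
        assert dihedral_angle(*p) == pytest.approx(0.0, abs=1e-10)

    def test_planar_trans_is_180(self):
        p = [np.array([1.0, 1, 0]), np.array([0.0, 0, 0]),
             np.array([0.0, 0, 1]), np.array([-1.0, -1, 1])]
        assert dihedral_angle(*p) == pytest.approx(180.0)

    def test_matches_normal_vector_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            pts = rng.normal(size=(4, 3)) * 3
            got = dihedral_angle(*pts)
            want = _oracle_dihedral(*pts)
            assert got == pytest.approx(want, abs=1e-8) or \
                abs(abs(got) - 180) < 1e-8 and abs(abs(want) - 180) < 1e-8

    @given(st.integers(0, 10_000))
    def test_rotation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(4, 3)) * 2
        rot = Rotation.random(random_state=seed)
        shifted = rot.apply(pts) + rng.normal(size=3)
        assert dihedral_angle(*pts) == pytest.approx(
            dihedral_angle(*shifted), abs=1e-8)

    def test_minimum_image_across_boundary(self):
        box = np.array([10.0, 10.0, 10.0])
        p = [np.array([9.5, 1.0, 0.0]), np.array([0.2, 0.0, 0.0]),
             np.array([0.2, 0.0, 1.0]), np.array([9.6, 1.0, 1.0])]
        wrapped = dihedral_angle(*p, box=box)
        unwrapped = dihedral_angle(p[0] - [10, 0, 0], p[1], p[2],
                                   p[3] - [10, 0, 0])
        assert wrapped == pytest.approx(unwrapped, abs=1e-9)

    def test_degenerate_central_bond_rejected(self):
        a = np.zeros(3)
        with pytest.raises(ValueError, match="degenerate"):
            dihedral_angle(np.ones(3), a, a, np.ones(3))


class TestTorsionSeries:
    def test_rigid_structure_gives_constant_series(self, solute_trajectory,
                                                   topology):
        s = torsion_series(solute_trajectory, topology, "8-4", "phi")
        assert len(s) == solute_trajectory.n_frames
        assert np.allclose(s.values, s.values[0])

    def test_single_frame(self, solute_trajectory, topology):
        truncated = solute_trajectory
        import copy
        t1 = copy.copy(truncated)
        t1.frames = truncated.frames[:1]
        s = torsion_series(t1, topology, "5-4", "omega")
        assert len(s) == 1

    def test_values_in_wrap_range(self, pair_runs, topology):
        for lid, ang in [("5-4", "psi"), ("aglycon", "chi2"), ("9-8", "phi")]:
            s = torsion_series(pair_runs["flow"], topology, lid, ang)
            assert np.all(s.values > -180.0) and np.all(s.values <= 180.0)

    def test_unknown_angle_rejected(self, solute_trajectory, topology):
        with pytest.raises(KeyError, match="no angle"):
            torsion_series(solute_trajectory, topology, "8-4", "omega")


class TestPopulationMap:
    def test_identical_samples_one_bin(self):
        a = np.full(50, 42.0)
        pmap = population_map2d(a, a, 5.0)
        assert pmap.counts.sum() == 50
        assert pmap.counts.max() == 50

    def test_uniform_angles_uniform_counts(self):
        rng = np.random.default_rng(1)
        n = 40_000
        a = rng.uniform(-180, 180, n)
        b = rng.uniform(-180, 180, n)
        pmap = population_map2d(a, b, 45.0)  # 8x8 grid
        stat, p = chisquare(pmap.counts.ravel())
        assert p > 1e-4

    def test_sample_at_exactly_180_in_last_bin(self):
        pmap = population_map2d(np.array([180.0]), np.array([180.0]), 5.0)
        assert pmap.counts[-1, -1] == 1

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            population_map2d(np.zeros(3), np.zeros(4), 5.0)

    def test_bin_width_must_divide_360(self):
        with pytest.raises(ValueError, match="divide"):
            population_map2d(np.zeros(3), np.zeros(3), 7.0)


class TestBoltzmannEnergyMap:
    def test_equal_counts_both_zero(self):
        pmap = population_map2d(np.array([-90.0, 90.0]), np.array([0.0, 0.0]),
                                90.0)
        emap = boltzmann_energy_map(pmap, 300.0)
        populated = emap.energies[~emap.energies.mask]
        assert np.allclose(populated, 0.0)

    def test_ten_to_one_ratio_closed_form(self):
        a = np.concatenate([np.full(100, -90.0), np.full(10, 90.0)])
        b = np.zeros(110)
        emap = boltzmann_energy_map(population_map2d(a, b, 90.0), 300.0)
        vals = np.sort(emap.energies.compressed())
        # dE = kT ln(10) = 0.596 * 2.3026 ≈ 1.372 kcal/mol at 300 K
        assert vals[0] == pytest.approx(0.0)
        assert vals[1] == pytest.approx(KB * 300 * np.log(10), abs=1e-9)
        assert vals[1] == pytest.approx(1.372, abs=5e-3)

    def test_population_inversion_identity(self):
        rng = np.random.default_rng(2)
        a = rng.choice([-120.0, 0.0, 120.0], size=500, p=[0.6, 0.3, 0.1])
        pmap = population_map2d(a, np.zeros_like(a), 120.0)
        emap = boltzmann_energy_map(pmap, 300.0)
        back = np.exp(-emap.energies.filled(np.inf) / (KB * 300))
        ratio = pmap.counts / pmap.counts.max()
        assert np.allclose(back, ratio, atol=1e-12)

    def test_empty_map_rejected(self):
        pmap = population_map2d(np.zeros(0), np.zeros(0), 90.0)
        with pytest.raises(ValueError, match="empty"):
            boltzmann_energy_map(pmap)


class TestRotamerStates:
    def test_constant_near_180(self):
        _, occ = assign_rotamer_states(np.full(20, 175.0))
        assert occ["180"] == 1.0

    def test_constant_at_minus_60(self):
        _, occ = assign_rotamer_states(np.full(20, -60.0))
        assert occ["-60"] == 1.0

    def test_tie_resolves_to_lower_center(self):
        labels, _ = assign_rotamer_states(np.array([0.0]),
                                          state_centers=(-60.0, 60.0),
                                          window_halfwidth=60.0)
        assert labels[0] == "-60"

    def test_occupancies_sum_to_one(self):
        rng = np.random.default_rng(3)
        _, occ = assign_rotamer_states(rng.uniform(-180, 180, 500),
                                       window_halfwidth=40.0)
        assert sum(occ.values()) == pytest.approx(1.0)
        assert occ["unassigned"] > 0

    def test_overlapping_windows_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            assign_rotamer_states(np.zeros(3), state_centers=(-60.0, 0.0),
                                  window_halfwidth=60.0)

    def test_flow_shifts_aglycon_phi_populations(self, pair_runs, topology):
        """Matched-seed flow vs diffusion: the aglycon phi rotamer
        populations shift detectably when the glycan aligns with flow."""
        occ = {}
        for cond in ("diffusion", "flow"):
            s = torsion_series(pair_runs[cond], topology, "aglycon", "phi")
            vals = s.values[len(s.values) // 4:]
            _, occ[cond] = assign_rotamer_states(vals)
        tv = 0.5 * sum(abs(occ["flow"][k] - occ["diffusion"][k])
                       for k in occ["flow"])
        assert tv > 0.2
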