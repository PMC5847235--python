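"""r^-6 NOE averaging, inter-proton distances and the comparison table."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from glycoflow.noe import (NOE_CUTOFF, ProtonPair, default_proton_pairs,
                           distance_torsion_map, interproton_distance_series,
                           minimum_image_distance, noe_average, noe_table)


class TestNOEAverage:
    def test_constant_series_is_identity(self):
        assert noe_average(np.full(10, 3.0)) == pytest.approx(3.0)

    def test_two_frame_closed_form(self):
        # ((2^-6 + 4^-6)/2)^(-1/6) ≈ 2.239 Å
        got = noe_average(np.array([2.0, 4.0]))
        want = ((2.0 ** -6 + 4.0 ** -6) / 2) ** (-1 / 6)
        assert got == pytest.approx(want, abs=1e-12)
        assert got == pytest.approx(2.239, abs=5e-4)

    @given(st.lists(st.floats(0.5, 10.0), min_size=1, max_size=30))
    def test_never_exceeds_arithmetic_mean(self, series):
        r = np.array(series)
        assert noe_average(r) <= r.mean() + 1e-9

    @given(st.lists(st.floats(0.5, 10.0), min_size=1, max_size=20),
           st.floats(0.1, 5.0))
    def test_scales_linearly(self, series, c):
        r = np.array(series)
        assert noe_average(c * r) == pytest.approx(c * noe_average(r), rel=1e-9)

    def test_alternative_exponent(self):
        r = np.array([2.0, 4.0])
        want = ((2.0 ** -3 + 4.0 ** -3) / 2) ** (-1 / 3)
        assert noe_average(r, exponent=-3) == pytest.approx(want)

    def test_nonpositive_distance_rejected(self):
        with pytest.raises(ValueError, match="non-positive"):
            noe_average(np.array([2.0, 0.0]))


class TestDistanceSeries:
    def test_static_pair(self, solute_trajectory, topology):
        pair = ProtonPair("8-4", "H1", "H3")
        series = interproton_distance_series(solute_trajectory, pair, topology)
        assert len(series) == solute_trajectory.n_frames
        assert np.allclose(series, series[0])
        assert series[0] > 0

    def test_minimum_image_against_27_image_scan(self):
        """Oracle: explicit minimum over the 27 periodic images."""
        rng = np.random.default_rng(5)
        box = np.array([8.0, 11.0, 9.0])
        for _ in range(40):
            # wrap into the primary box so the 3x3x3 image scan is exhaustive
            a = np.mod(rng.uniform(-5, 15, 3), box)
            b = np.mod(rng.uniform(-5, 15, 3), box)
            images = [b + box * np.array([i, j, k])
                      for i in (-1, 0, 1) for j in (-1, 0, 1)
                      for k in (-1, 0, 1)]
            oracle = min(np.linalg.norm(a - im) for im in images)
            assert minimum_image_distance(a, b, box) == pytest.approx(
                oracle, abs=1e-10)

    def test_unknown_pair_atom_names_pair(self, solute_trajectory, topology):
        with pytest.raises(KeyError, match="H1/HX"):
            interproton_distance_series(
                solute_trajectory, ProtonPair("8-4", "H1", "HX"), topology)


class TestNOETable:
    def test_long_pair_annotated_no_noe(self, solute_trajectory, topology):
        pair = ProtonPair("8-4", "H1", "H1")  # template separation > 4 Å?
        series = interproton_distance_series(solute_trajectory, pair, topology)
        table = noe_table(solute_trajectory, solute_trajectory, [pair],
                          topology, burn_in=0)
        row = table.iloc[0]
        expect = "No-NOE" if series[0] > NOE_CUTOFF else ""
        assert row["diffusion_annotation"] == expect
        # the numeric value is always kept alongside the annotation
        assert row["diffusion_A"] > 0

    def test_constant_5A_pair_is_no_noe(self, make_random_trajectory):
        # direct check of the annotation rule on a constructed series
        r_eff = noe_average(np.full(10, 5.0))
        assert r_eff > NOE_CUTOFF

    def test_identical_trajectories_identical_columns(self, solute_trajectory,
                                                      topology):
        pairs = default_proton_pairs(topology)[:5]
        table = noe_table(solute_trajectory, solute_trajectory, pairs,
                          topology, burn_in=0)
        assert (table["diffusion_A"] == table["flow_A"]).all()

    def test_empty_pair_list_gives_header_only(self, solute_trajectory,
                                               topology):
        table = noe_table(solute_trajectory, solute_trajectory, [], topology)
        assert len(table) == 0
        assert "diffusion_A" in table.columns

    def test_default_pair_list_spans_linkages(self, topology):
        pairs = default_proton_pairs(topology)
        linkages = {p.linkage_id for p in pairs}
        assert linkages == {"9-8", "8-4", "7-5", "5-4", "6-5"}
        # 1-6 linkages carry the two H6 protons separately
        labels = [p.resolved_label() for p in pairs if p.linkage_id == "5-4"]
        assert "H1/H6'(a)" in labels and "H1/H6'(b)" in labels

    def test_topology_mismatch_rejected(self, solute_trajectory,
                                        make_random_trajectory, topology):
        other = make_random_trajectory(n_atoms=solute_trajectory.n_atoms)
        with pytest.raises(ValueError, match="topolog"):
            noe_table(solute_trajectory, other,
                      default_proton_pairs(topology)[:1], topology)


class TestDistanceTorsionMap:
    def test_constant_distance_uniform_map(self):
        n = 100
        rng = np.random.default_rng(0)
        a = rng.uniform(-180, 180, n)
        b = rng.uniform(-180, 180, n)
        means, counts, _ = distance_torsion_map(np.full(n, 2.5), a, b, 45.0)
        filled = means.compressed()
        assert np.allclose(filled, 2.5)

    def test_two_state_fixture(self):
        """Two visited cells with distinct per-state distances."""
        a = np.array([-90.0] * 5 + [90.0] * 5)
        b = np.array([-90.0] * 5 + [90.0] * 5)
        r = np.array([2.0] * 5 + [3.5] * 5)
        means, counts, edges = distance_torsion_map(r, a, b, 90.0)
        vals = np.sort(means.compressed())
        assert np.allclose(vals, [2.0, 3.5])
        assert counts.sum() == 10

    def test_unvisited_bins_masked_with_count_grid(self):
        means, counts, _ = distance_torsion_map(
            np.array([2.0]), np.array([0.0]), np.array([0.0]), 90.0)
        assert means.mask.sum() == means.size - 1
        assert (counts == 0).sum() == counts.size - 1

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            distance_torsion_map(np.ones(3), np.zeros(4), np.zeros(4), 90.0)


class TestSamplingBiasConsistency:
    def test_noe_average_bounded_below_by_map_minimum(self, pair_runs,
                                                      topology):
        """If every visited (phi, psi) bin has mean distance >= d0, the
        r^-6 average cannot report a conflicting shorter distance by
        more than the within-bin spread."""
        from glycoflow.torsions import torsion_series

        traj = pair_runs["diffusion"]
        pair = ProtonPair("8-4", "H1", "H4")
        r = interproton_distance_series(traj, pair, topology)
        phi = torsion_series(traj, topology, "8-4", "phi").values
        psi = torsion_series(traj, topology, "8-4", "psi").values
        means, counts, _ = distance_torsion_map(r, phi, psi, 15.0)
        d0 = means.min()
        assert noe_average(r) >= d0 - (r.max() - r.min()) * 0.5
        assert noe_average(r) >= r.min()
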