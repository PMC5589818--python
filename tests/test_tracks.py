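"""Radial profiles, DSB separation distributions and intra-track rates."""

import math

import numpy as np
import pytest

import dsbrepair as dr
from dsbrepair.tracks import (combined_correct_probability, dsb_per_track,
                              eta_track, ion_context_for_let, log_bin_edges,
                              radial_dsb_density, read_radial_profile,
                              separation_distribution, synthetic_profile,
                              track_count_average, write_radial_profile)


class TestProfileIO:
    def test_single_bin_table_let_equals_bin_energy(self):
        text = ("# particle=proton\n"
                "radius_nm_low,radius_nm_high,energy_kev_per_um\n"
                "0.0,0.1,12.5\n")
        profile = read_radial_profile(text)
        assert profile.let_kev_um == pytest.approx(12.5)
        assert profile.particle == "proton"

    def test_round_trip_preserves_profile(self):
        original = synthetic_profile("carbon", 80.0)
        recovered = read_radial_profile(write_radial_profile(original))
        assert recovered.particle == original.particle
        assert recovered.energy_mev_u == pytest.approx(original.energy_mev_u)
        np.testing.assert_allclose(recovered.bin_edges_nm, original.bin_edges_nm)
        np.testing.assert_allclose(recovered.energy_kev_per_um,
                                   original.energy_kev_per_um)

    def test_log_binning_width_ratio(self):
        edges = log_bin_edges(1000.0)
        ratios = edges[2:] / edges[1:-1]
        # 100 bins per decade: every bin ~2.33% wider than the previous
        np.testing.assert_allclose(ratios, 10 ** 0.01, rtol=1e-12)
        assert 10 ** 0.01 == pytest.approx(1.0233, abs=2e-4)

    def test_non_monotone_bins_rejected(self):
        text = ("radius_nm_low,radius_nm_high,energy_kev_per_um\n"
                "0.0,0.2,1.0\n0.1,0.3,1.0\n")
        with pytest.raises(ValueError):
            read_radial_profile(text)

    def test_negative_energy_rejected(self):
        text = ("radius_nm_low,radius_nm_high,energy_kev_per_um\n"
                "0.0,0.1,-1.0\n")
        with pytest.raises(ValueError):
            read_radial_profile(text)


class TestSyntheticProfile:
    def test_normalised_to_target_let(self):
        for let in (1.0, 10.0, 150.0):
            assert synthetic_profile("proton", let).let_kev_um == pytest.approx(
                let, rel=1e-12)

    def test_linearity_in_let(self):
        lo = synthetic_profile("proton", 5.0, energy_mev_u=10.0)
        hi = synthetic_profile("proton", 10.0, energy_mev_u=10.0)
        np.testing.assert_allclose(hi.energy_kev_per_um,
                                   2.0 * lo.energy_kev_per_um)

    def test_energetic_track_core_below_quarter_of_energy(self):
        profile = synthetic_profile("proton", 1.0)  # high-energy, wide track
        core = profile.energy_kev_per_um[profile.bin_edges_nm[1:] <= 10.0].sum()
        assert core < 0.25 * profile.let_kev_um

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            synthetic_profile("proton", 10.0, core_radius_nm=100.0,
                              penumbra_radius_nm=50.0)


class TestDsbDensity:
    def test_total_density_is_let_over_edsb(self):
        profile = synthetic_profile("proton", 60.7)
        assert radial_dsb_density(profile, 60.7).sum() == pytest.approx(1.0)

    def test_zero_energy_bins_give_zero_density(self):
        profile = synthetic_profile("proton", 10.0)
        dens = radial_dsb_density(profile, 60.7)
        assert np.all(dens[profile.energy_kev_per_um == 0.0] == 0.0)

    def test_central_traversal_break_count(self, params, geometry):
        # LET numerically equal to e_dsb: one DSB per um, ~8.6 per diameter
        n = dsb_per_track(60.7, params.e_dsb, geometry, chord="diameter")
        assert n == pytest.approx(2.0 * geometry.radius_um, rel=1e-9)
        assert n == pytest.approx(8.65, abs=0.05)

    def test_mean_chord_option(self, params, geometry):
        diam = dsb_per_track(10.0, params.e_dsb, geometry, "diameter")
        mean = dsb_per_track(10.0, params.e_dsb, geometry, "mean")
        assert mean == pytest.approx(diam * 2.0 / 3.0)


class TestSeparationDistribution:
    def test_point_track_limit_matches_1d_spacing_law(self, params):
        # all energy on the axis: neighbours within +/- s follow the uniform
        # line law 2 * s * (DSB per um)
        profile = dr.RadialProfile(particle="proton", energy_mev_u=None,
                                   bin_edges_nm=np.array([0.0, 0.1]),
                                   energy_kev_per_um=np.array([60.7]))
        sep = separation_distribution(profile, params.e_dsb, window_um=5.0)
        cum = sep.cumulative()
        for s_um in (0.5, 1.0, 3.0):
            k = int(s_um * 1e3 / sep.bin_width_nm)
            assert cum[k - 1] == pytest.approx(2.0 * s_um * sep.dsb_per_um,
                                               rel=0.01)

    def test_long_range_density_saturates_at_twice_let_over_edsb(self, params):
        profile = synthetic_profile("proton", 10.0)
        sep = separation_distribution(profile, params.e_dsb)
        grid_um = sep.distance_grid_nm / 1e3
        far = (grid_um > 4.0) & (grid_um < 4.9)
        per_um = sep.expected_neighbours[far].sum() / (
            far.sum() * sep.bin_width_nm * 1e-3)
        assert per_um == pytest.approx(2.0 * sep.dsb_per_um, rel=0.02)

    def test_counts_scale_inversely_with_edsb(self, params):
        profile = synthetic_profile("proton", 10.0)
        a = separation_distribution(profile, params.e_dsb)
        b = separation_distribution(profile, 2.0 * params.e_dsb)
        np.testing.assert_allclose(b.expected_neighbours,
                                   0.5 * a.expected_neighbours, rtol=1e-9)

    def test_cumulative_counts_non_decreasing(self, params):
        sep = separation_distribution(synthetic_profile("carbon", 100.0),
                                      params.e_dsb)
        assert np.all(np.diff(sep.cumulative()) >= -1e-12)


class TestEtaTrack:
    def test_zero_let_gives_zero_rate(self, params, geometry):
        ctx = ion_context_for_let("proton", 0.0, params)
        assert ctx.eta_track == 0.0 and ctx.dsb_per_track == 0.0

    def test_independent_of_dose_by_construction(self, params, geometry):
        # the rate is defined per track; recomputing it never touches dose
        a = ion_context_for_let("proton", 10.0, params).eta_track
        b = ion_context_for_let("proton", 10.0, params).eta_track
        assert a == b > 0.0

    def test_superlinear_growth_with_let(self, params):
        # narrower low-energy tracks make the rate grow faster than LET
        etas = {let: ion_context_for_let("proton", let, params).eta_track
                for let in (5.0, 10.0, 20.0)}
        assert etas[10.0] > 2.0 * etas[5.0]
        assert etas[20.0] > 2.0 * etas[10.0]

    def test_dominated_by_sub_micron_separations(self, params, geometry):
        profile = synthetic_profile("proton", 10.0)
        sep = separation_distribution(profile, params.e_dsb)
        weights = 2.0 * dr.zeta(sep.distance_grid_nm,
                                geometry.sigma_abs_um * 1e3) \
            * sep.expected_neighbours
        below_micron = weights[sep.distance_grid_nm < 1000.0].sum()
        assert below_micron > 0.9 * weights.sum()

    def test_window_too_small_rejected(self, params, geometry):
        profile = synthetic_profile("proton", 10.0)
        sep = separation_distribution(profile, params.e_dsb, window_um=0.2)
        with pytest.raises(ValueError, match="window"):
            eta_track(sep, geometry.sigma_abs_um)

    def test_discretisation_converged(self, params, geometry):
        profile = synthetic_profile("proton", 10.0)
        base = eta_track(separation_distribution(profile, params.e_dsb),
                         geometry.sigma_abs_um)
        fine = eta_track(
            separation_distribution(profile, params.e_dsb, arc_nm=20.0,
                                    radial_step_nm=5.0, grid_step_nm=2.5),
            geometry.sigma_abs_um)
        assert base == pytest.approx(fine, rel=5e-3)


class TestCombinedRepair:
    def test_reduces_to_photon_case_without_track_term(self):
        for eta in (0.0, 0.3, 2.0):
            assert combined_correct_probability(eta, 0.0, 0.985) == \
                pytest.approx(dr.correct_repair_probability(eta, 0.985))

    def test_zero_rates_return_fidelity(self):
        assert combined_correct_probability(0.0, 0.0, 0.445) == pytest.approx(0.445)

    def test_rates_add_in_the_exponent(self):
        combined = combined_correct_probability(0.3, 0.7, 1.0)
        assert combined == pytest.approx(
            dr.correct_repair_probability(1.0, 1.0), rel=1e-12)


class TestTrackCountAverage:
    def test_zero_dose_survives(self):
        assert track_count_average(0.0, 5.0, lambda n: np.exp(-0.1 * n)) == 1.0

    def test_poisson_weights_normalised(self):
        # with a response of 1 the average must return exactly 1
        assert track_count_average(100.0, 5.0, lambda n: np.ones_like(n)) == \
            pytest.approx(1.0, abs=1e-9)

    def test_branches_agree_at_threshold(self):
        # at the switch point the discrete average approaches the
        # expectation-level response for a gently curved response
        response = lambda n: np.exp(-0.02 * n - 1e-4 * n ** 2)
        below = track_count_average(50.0, 0.5, response)
        above = track_count_average(50.0, 0.5 + 1e-9, response)
        assert above == pytest.approx(below, rel=0.01)

    def test_discrete_average_exceeds_expectation_for_convex_response(self):
        # Jensen: averaging a convex survival response over track-number
        # fluctuations increases survival
        response = lambda n: np.exp(-0.5 * n)
        discrete = track_count_average(20.0, 4.0, response)
        expectation = float(response(np.array([20.0]))[0])
        assert discrete > expectation
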