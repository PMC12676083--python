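"""Displacement model, radius fit, internode sampling, population simulator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phyllostat import (
    Chirality,
    RadiusProfile,
    TorsionModelParams,
    apply_torsion,
    fit_radius_profile,
    sample_internode_lengths,
    simulate_population,
    sweep_parameters,
)


class TestApplyTorsion:
    def test_zero_torsion_identity(self):
        for internode, radius in [(0.5, 0.3), (12.0, 1.0), (25.0, 0.4)]:
            assert apply_torsion(137.5, 0.0, internode, radius, Chirality.CW) == 137.5
            assert apply_torsion(137.5, 0.0, internode, radius, Chirality.CCW) == 137.5

    def test_counterclockwise_spiral_gains_angle(self):
        # tan(0.6 deg) * 9.5493 mm / 1.0 mm = 0.1000 rad = 5.7298 deg
        out = apply_torsion(137.5, 0.6, 9.5493, 1.0, Chirality.CCW)
        assert out == pytest.approx(143.2298, abs=1e-3)

    def test_clockwise_spiral_loses_angle(self):
        out = apply_torsion(137.5, 0.6, 9.5493, 1.0, Chirality.CW)
        assert out == pytest.approx(131.7702, abs=1e-3)

    def test_result_wrapped_to_circle(self):
        out = apply_torsion(350.0, 5.0, 30.0, 0.5, Chirality.CCW)
        assert 0 <= out < 360

    def test_nonpositive_radius_refused(self):
        with pytest.raises(ValueError):
            apply_torsion(137.5, 0.6, 1.0, 0.0, Chirality.CW)

    def test_ambiguous_chirality_refused(self):
        with pytest.raises(ValueError):
            apply_torsion(137.5, 0.6, 1.0, 1.0, Chirality.AMBIGUOUS)

    @given(st.floats(min_value=0.01, max_value=20),
           st.floats(min_value=-10, max_value=10),
           st.floats(min_value=0.1, max_value=2))
    @settings(max_examples=100, deadline=None)
    def test_displacement_linear_in_internode(self, internode, alpha, radius):
        d1 = apply_torsion(0.0, alpha, internode, radius, Chirality.CCW)
        d2 = apply_torsion(0.0, alpha, 2 * internode, radius, Chirality.CCW)
        # compare as signed displacements on the circle
        s1 = (d1 + 180) % 360 - 180
        s2 = (d2 + 180) % 360 - 180
        if abs(2 * s1) < 170:  # away from the wrap, doubling is exact
            assert s2 == pytest.approx(2 * s1, abs=1e-9, rel=1e-9)

    @given(st.floats(min_value=0.01, max_value=20),
           st.floats(min_value=0.01, max_value=10))
    @settings(max_examples=100, deadline=None)
    def test_chirality_flip_negates_displacement(self, internode, alpha):
        up = apply_torsion(137.5, alpha, internode, 1.0, Chirality.CCW)
        down = apply_torsion(137.5, alpha, internode, 1.0, Chirality.CW)
        assert (up - 137.5) % 360 == pytest.approx((137.5 - down) % 360, abs=1e-9)
        # flipping the sign of alpha does the same
        neg = apply_torsion(137.5, -alpha, internode, 1.0, Chirality.CCW)
        assert neg == pytest.approx(down, abs=1e-9)


class TestRadiusProfile:
    def test_exact_quadratic_recovered(self):
        pos = np.arange(1, 36, dtype=float)  # max position already 35: no rescale
        rad = 0.0002 * pos**2 - 0.02 * pos + 1.0
        prof = fit_radius_profile(pos, rad)
        assert prof.coefficients == pytest.approx((0.0002, -0.02, 1.0), abs=1e-10)
        assert len(prof.radii()) == 30

    def test_constant_radius(self):
        prof = fit_radius_profile([1, 5, 10, 20, 35], [0.5] * 5)
        assert prof.coefficients == pytest.approx((0.0, 0.0, 0.5), abs=1e-12)
        np.testing.assert_allclose(prof.radii(), 0.5)

    def test_noisy_fit_matches_normal_equations(self, rng):
        pos = np.linspace(1, 35, 40)
        true = 0.0003 * pos**2 - 0.025 * pos + 1.1
        obs = true + rng.normal(0, 0.02, len(pos))
        prof = fit_radius_profile(pos, obs)
        # independent oracle: solve the normal equations directly
        X = np.vander(pos, 3)
        beta = np.linalg.solve(X.T @ X, X.T @ obs)
        assert prof.coefficients == pytest.approx(tuple(beta), abs=1e-8)

    def test_rescaling_maps_max_position_to_35(self):
        # radius linear in rescaled position: coefficients seen in the 35-frame
        pos = np.array([1.0, 5.0, 7.0])       # max 7 -> scale factor 5
        rad = 1.0 - 0.01 * (pos * 5.0)
        prof = fit_radius_profile(pos, rad)
        assert prof.coefficients == pytest.approx((0.0, -0.01, 1.0), abs=1e-9)

    def test_too_few_positions(self):
        with pytest.raises(ValueError):
            fit_radius_profile([1, 2], [0.5, 0.4])

    def test_nonpositive_prediction_rejected(self):
        with pytest.raises(ValueError):
            RadiusProfile(coefficients=(0.0, -0.1, 1.0)).radii()  # negative by p=11


class TestInternodeSampling:
    def test_zero_sd_returns_means(self, rng):
        means = np.array([10.0, 5.0, 1.0])
        out = sample_internode_lengths(means, np.zeros(3), rng)
        np.testing.assert_array_equal(out, means)

    def test_sample_mean_matches_clt(self, rng):
        out = np.array([sample_internode_lengths([10.0], [1.0], rng)[0]
                        for _ in range(10000)])
        assert abs(out.mean() - 10.0) < 3 * 1.0 / np.sqrt(10000)

    def test_rejection_keeps_everything_nonnegative(self, rng):
        out = sample_internode_lengths([0.1] * 200, [5.0] * 200, rng)
        assert (out >= 0).all()

    def test_negative_sd_refused(self, rng):
        with pytest.raises(ValueError):
            sample_internode_lengths([1.0], [-0.1], rng)


class TestSimulatePopulation:
    def test_degenerate_params_give_constant_angles(self):
        params = TorsionModelParams(delta_i_sd=0.0, torsion_mean=0.0, torsion_sd=0.0,
                                    n_inflorescences=5, seed=3)
        pop = simulate_population(params)
        for rec in pop.records:
            np.testing.assert_allclose(rec.series.angles, 137.5)

    def test_population_shape_and_pair_count(self):
        pop = simulate_population(TorsionModelParams(seed=0))
        assert len(pop.records) == 101
        assert all(len(r.series) == 30 for r in pop.records)
        assert all(len(r.internode_lengths) == 30 for r in pop.records)
        assert pop.bin(22.5).n_pairs == 101 * 29

    def test_seed_determinism_bit_identical(self):
        a = simulate_population(TorsionModelParams(seed=42))
        b = simulate_population(TorsionModelParams(seed=42))
        for ra, rb in zip(a.records, b.records):
            np.testing.assert_array_equal(ra.series.angles, rb.series.angles)
            np.testing.assert_array_equal(ra.internode_lengths, rb.internode_lengths)
            assert ra.series.chirality is rb.series.chirality
        for ia, ib in zip(a.initial_angles, b.initial_angles):
            np.testing.assert_array_equal(ia, ib)

    def test_counterclockwise_torsion_splits_modes_by_chirality(self):
        params = TorsionModelParams(delta_i_sd=2.0, torsion_mean=2.0, torsion_sd=0.0,
                                    n_inflorescences=60, seed=7)
        pop = simulate_population(params)
        cw_mode = pop.bin(22.5, chirality=Chirality.CW).modal_bin()[0]
        ccw_mode = pop.bin(22.5, chirality=Chirality.CCW).modal_bin()[0]
        assert cw_mode <= 135.0
        assert ccw_mode >= 135.0

    def test_initial_track_is_pre_torsion(self):
        params = TorsionModelParams(torsion_mean=0.0, torsion_sd=0.0,
                                    n_inflorescences=3, seed=5)
        pop = simulate_population(params)
        for rec, init in zip(pop.records, pop.initial_angles):
            np.testing.assert_allclose(rec.series.angles, init)


class TestSweep:
    def test_unit_scales_reproduce_base(self):
        base = TorsionModelParams(n_inflorescences=20, seed=11)
        grid = sweep_parameters(base, [1.0], [1.0])
        direct = simulate_population(base).bin(22.5)
        np.testing.assert_array_equal(grid[(1.0, 1.0)].counts, direct.counts)

    def test_zero_torsion_maximizes_window_fraction(self):
        base = TorsionModelParams(n_inflorescences=40, seed=13)
        grid = sweep_parameters(base, [1.0], [0.0, 1.0, 3.0])
        fracs = [grid[(1.0, t)].window_fraction() for t in (0.0, 1.0, 3.0)]
        assert fracs[0] == max(fracs)

    def test_doubled_internodes_push_modes_toward_90_and_180(self):
        # under counterclockwise torsion, doubling internode length displaces the
        # clockwise mode toward the 90-containing bin and the counterclockwise
        # mode toward 180
        base = TorsionModelParams(delta_i_sd=5.0, torsion_mean=1.7, torsion_sd=0.3,
                                  n_inflorescences=80, seed=17)
        pop = simulate_population(base)
        doubled = sweep_parameters(base, [2.0], [1.0])[(2.0, 1.0)]
        cw1 = pop.bin(22.5, chirality=Chirality.CW).modal_bin()[0]
        # chirality split of the swept cell needs a fresh simulation at scale 2
        from dataclasses import replace
        pop2 = simulate_population(replace(base,
                                           internode_means=base.internode_means * 2,
                                           internode_sds=base.internode_sds * 2))
        cw2 = pop2.bin(22.5, chirality=Chirality.CW).modal_bin()[0]
        ccw2 = pop2.bin(22.5, chirality=Chirality.CCW).modal_bin()[0]
        assert cw2 <= cw1
        assert abs(cw2 - 90.0) <= abs(cw1 - 90.0)
        assert ccw2 >= 157.5 or abs(ccw2 - 180.0) < 45.0
        assert doubled.n_pairs == 80 * 29

    def test_invalid_scales(self):
        base = TorsionModelParams(n_inflorescences=2, seed=0)
        with pytest.raises(ValueError):
            sweep_parameters(base, [0.0], [1.0])
        with pytest.raises(ValueError):
            sweep_parameters(base, [1.0], [-1.0])
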