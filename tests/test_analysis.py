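"""Tests for the derived-quantity layer: turning points, dominance, phases."""

import numpy as np
import pytest

from efatrans import (
    BoundaryError,
    DominanceCase,
    Phase,
    PhaseBoundaries,
    PhaseLabel,
    PrimaryRateParams,
    RateConstantParams,
    SubRegion,
    acceleration_profile,
    advection_rate_constant,
    classification_table,
    classify_dominance,
    classify_kinetic_phase,
    dominance_crossover,
    find_turning_points,
    primary_advection_rate,
    primary_advection_rate_derivative,
    solve_boundaries,
)


class TestTurningPoints:
    def test_two_turning_points_in_fitted_range(self, primary_params):
        """One flat minimum (rate ≈ 0.0080) and one maximum near 12.5 μg/ml."""
        points = find_turning_points(primary_params)
        assert [tp.kind for tp in points] == ["minimum", "maximum"]
        minimum, maximum = points
        assert 1.1 < minimum.x < 1.5  # extremely flat region around the minimum
        assert 0.0080 <= minimum.rate <= 0.0082
        assert maximum.x == pytest.approx(12.4786605329, rel=1e-6)

    def test_locations_match_dense_grid_scan(self, primary_params):
        """Bracketing roots agree with a 1e−4-step brute-force derivative scan."""
        grid = np.arange(0.01, 15.5, 1e-4)
        deriv = primary_advection_rate_derivative(grid, primary_params)
        changes = np.nonzero(np.sign(deriv[:-1]) != np.sign(deriv[1:]))[0]
        scanned = grid[changes]
        points = find_turning_points(primary_params)
        assert len(points) == len(scanned)
        for tp, x_scan in zip(points, scanned):
            assert tp.x == pytest.approx(x_scan, abs=1e-3)

    def test_derivative_vanishes_at_reported_points(self, primary_params):
        for tp in find_turning_points(primary_params):
            assert primary_advection_rate_derivative(tp.x, primary_params) == (
                pytest.approx(0.0, abs=1e-9)
            )

    def test_ricker_only_maximum_at_inverse_h(self):
        params = PrimaryRateParams(g=0.02, h=0.4, n=1e-300, b=1.0, m=1e-12, p=1e-6)
        points = find_turning_points(params, domain=(0.5, 10.0))
        assert len(points) == 1
        assert points[0].kind == "maximum"
        assert points[0].x == pytest.approx(1 / 0.4, rel=1e-3)

    def test_domain_excluding_roots_yields_empty(self, primary_params):
        assert find_turning_points(primary_params, domain=(3.0, 9.0)) == []


class TestDominance:
    def test_crossover_near_reported_value(self, primary_params):
        """Passive and energy-dependent magnitudes balance near 0.97 μg/ml."""
        assert dominance_crossover(primary_params) == (
            pytest.approx(0.9711318450, rel=1e-8)
        )

    def test_crossover_increases_with_passive_floor(self, primary_params):
        """Scaling m up pushes the balance point to higher concentration."""
        scaled = PrimaryRateParams(
            g=primary_params.g, h=primary_params.h, n=primary_params.n,
            b=primary_params.b, m=4 * primary_params.m, p=primary_params.p,
        )
        assert dominance_crossover(scaled) > dominance_crossover(primary_params)

    def test_crossover_above_b_when_passive_dominates_there(self):
        """With n = 2m and b = p, |II| = m < III = 2m·(…) at x = b, so x̄ > b."""
        params = PrimaryRateParams(g=0.01, h=0.1, n=0.002, b=2.0, m=0.001, p=2.0)
        comp = primary_advection_rate(params.b, params)
        assert abs(comp.energy_dependent) < comp.energy_independent
        assert dominance_crossover(params) > params.b

    def test_classification_on_either_side(self, primary_params):
        assert classify_dominance(0.5, primary_params) is DominanceCase.PASSIVE
        assert classify_dominance(5.0, primary_params) is DominanceCase.ENERGY_DEPENDENT
        x_bar = dominance_crossover(primary_params)
        assert classify_dominance(x_bar, primary_params) is DominanceCase.BALANCED

    @pytest.mark.parametrize("seed", range(10))
    def test_crossover_classifies_balanced_for_random_params(self, seed):
        rng = np.random.default_rng(seed)
        m = float(rng.uniform(1e-3, 0.02))
        params = PrimaryRateParams(
            g=float(rng.uniform(1e-3, 0.1)),
            h=float(rng.uniform(0.01, 0.5)),
            # a crossover only exists when the E_D magnitude cap |n| exceeds
            # the passive floor m
            n=float(rng.choice([-1, 1]) * rng.uniform(3 * m, 0.3)),
            b=float(rng.uniform(1.0, 20.0)),
            m=m,
            p=float(rng.uniform(0.1, 5.0)),
        )
        x_bar = dominance_crossover(params)
        assert classify_dominance(x_bar, params) is DominanceCase.BALANCED

    def test_no_crossover_without_energy_dependent_term(self, primary_params):
        flat = PrimaryRateParams(
            g=primary_params.g, h=primary_params.h, n=1e-12,
            b=primary_params.b, m=primary_params.m, p=primary_params.p,
        )
        with pytest.raises(ValueError, match="no dominance crossover"):
            dominance_crossover(flat)


class TestPhaseBoundaries:
    def test_boundary_near_reported_value(self, rate_constant_params):
        """The advection rate constant crosses zero near 32.8 μg/ml."""
        b = solve_boundaries(rate_constant_params)
        assert b.x_ad == pytest.approx(32.7972286101, rel=1e-8)
        assert advection_rate_constant(b.x_ad, rate_constant_params).a_r == (
            pytest.approx(0.0, abs=1e-10)
        )

    def test_convection_extinction_point(self, rate_constant_params):
        """c_r decays to the 0.01/h tolerance near 126 μg/ml."""
        b = solve_boundaries(rate_constant_params, eps_c=0.01)
        assert b.x_c == pytest.approx(125.8821155102, rel=1e-8)
        assert advection_rate_constant(b.x_c, rate_constant_params).c_r == (
            pytest.approx(0.01, abs=1e-10)
        )
        assert b.x_ad < b.x_c

    def test_boundaries_match_bisection_oracle(self, rate_constant_params):
        """Roots agree with an independent dense-grid + midpoint bisection."""

        def bisect(f, lo, hi, iters=60):
            for _ in range(iters):
                mid = 0.5 * (lo + hi)
                if f(lo) * f(mid) <= 0:
                    hi = mid
                else:
                    lo = mid
            return 0.5 * (lo + hi)

        ar = lambda x: advection_rate_constant(x, rate_constant_params).a_r
        cr = lambda x: advection_rate_constant(x, rate_constant_params).c_r - 0.01
        b = solve_boundaries(rate_constant_params, eps_c=0.01)
        assert b.x_ad == pytest.approx(bisect(ar, 20.0, 50.0), abs=1e-6)
        assert b.x_c == pytest.approx(bisect(cr, 50.0, 500.0), abs=1e-6)

    def test_no_saturable_term_means_no_boundary(self):
        params = RateConstantParams(zeta=0.144, lam=0.0596, alpha=1e-12,
                                    omega=1.1, kappa=6.0)
        with pytest.raises(BoundaryError, match="never leaves"):
            solve_boundaries(params)

    def test_overlapping_neighbourhoods_rejected(self, rate_constant_params):
        with pytest.raises(ValueError, match="overlap"):
            solve_boundaries(rate_constant_params, eps_radii=(20.0, 20.0, 0.5, 0.5))


@pytest.fixture(scope="module")
def boundaries(rate_constant_params):
    return solve_boundaries(rate_constant_params)


class TestPhaseClassification:
    def test_therapeutic_range_is_good_phase(self, rate_constant_params, boundaries):
        """The 1–4 μg/ml therapeutic range lies in the freely-soluble region."""
        for x in (1.0, 2.0, 4.0):
            label = classify_kinetic_phase(x, rate_constant_params, boundaries)
            assert label.phase is Phase.GOOD
            assert label.sub_region is SubRegion.FREELY

    def test_neighbourhood_sub_regions(self, rate_constant_params, boundaries):
        b = boundaries
        cases = [
            (b.eps1 / 2, Phase.GOOD, SubRegion.VERY),
            (b.x_ad - b.eps2 / 2, Phase.GOOD, SubRegion.SOLUBLE),
            (b.x_ad + b.eps3 / 2, Phase.POOR, SubRegion.SPARINGLY),
            ((b.x_ad + b.x_c) / 2, Phase.POOR, SubRegion.SLIGHTLY),
            (b.x_c - b.eps4 / 2, Phase.POOR, SubRegion.VERY_SLIGHTLY),
            (2 * b.x_c, Phase.UNDEFINED, SubRegion.UNDEFINED),
        ]
        for x, phase, sub in cases:
            label = classify_kinetic_phase(x, rate_constant_params, boundaries)
            assert (label.phase, label.sub_region) == (phase, sub), f"x={x}"

    def test_partition_of_domain(self, rate_constant_params, boundaries):
        """Every concentration gets exactly one phase and one sub-region."""
        grid = np.linspace(0.05, 2.2 * boundaries.x_c, 1500)
        seen_subs = set()
        for x in grid:
            label = classify_kinetic_phase(float(x), rate_constant_params, boundaries)
            seen_subs.add(label.sub_region)
            if x <= boundaries.x_ad:
                assert label.phase is Phase.GOOD
            elif x <= boundaries.x_c:
                assert label.phase is Phase.POOR
            else:
                assert label.phase is Phase.UNDEFINED
        assert seen_subs == set(SubRegion)

    def test_saturation_freezes_beyond_extinction(
        self, rate_constant_params, boundaries
    ):
        """In the undefined phase st_r is reported at its x_C value."""
        table = classification_table(
            rate_constant_params, boundaries,
            np.array([2.0, 40.0, boundaries.x_c * 2, boundaries.x_c * 3]),
        )
        st_cap = advection_rate_constant(boundaries.x_c, rate_constant_params).st_r
        beyond = table[table["x"] > boundaries.x_c]
        assert np.allclose(beyond["st_r"], st_cap)
        assert list(table["phase"]) == ["R_I", "R_II", "R_III", "R_III"]

    def test_inconsistent_boundaries_detected(self, rate_constant_params):
        bogus = PhaseBoundaries(x_ad=10.0, x_c=125.88, eps1=0.5, eps2=0.5,
                                eps3=0.5, eps4=0.5, eps_c=0.01)
        with pytest.raises(BoundaryError, match="inconsistent"):
            classify_kinetic_phase(20.0, rate_constant_params, bogus)

    def test_invalid_label_combination_rejected(self):
        with pytest.raises(ValueError):
            PhaseLabel(phase=Phase.GOOD, sub_region=SubRegion.SPARINGLY)

    def test_saturable_dominates_advection_beyond_crossover(
        self, rate_constant_params, boundaries
    ):
        """st_r exceeds a_r throughout (0, 60] — the rate-constant ordering."""
        grid = np.linspace(0.05, 60.0, 1200)
        rc = advection_rate_constant(grid, rate_constant_params)
        assert np.all(rc.st_r > rc.a_r - 1e-12)
        assert np.all(rc.a_r[grid > boundaries.x_ad] < 0)


class TestAccelerationProfile:
    def test_sign_change_between_seven_and_eight_hours(self, convection_params):
        frame = acceleration_profile(convection_params, np.arange(0.0, 25.0, 1.0))
        acc = frame["acceleration"].to_numpy()
        assert acc[7] > 0 > acc[8]
        tz = frame.attrs["zero_crossing"]
        assert 7.0 < tz < 8.0

    def test_crossing_matches_profile_argmax(self, convection_params):
        times = np.arange(0.0, 24.01, 0.01)
        frame = acceleration_profile(convection_params, times)
        i = int(frame["c_r"].idxmax())
        assert frame["t"][i] == pytest.approx(frame.attrs["zero_crossing"], abs=0.01)
        before = frame["acceleration"][frame["t"] < frame.attrs["zero_crossing"]]
        after = frame["acceleration"][frame["t"] > frame.attrs["zero_crossing"]]
        assert (before > 0).all() and (after < 0).all()

    def test_amplitude_scales_acceleration_but_not_crossing(self, convection_params):
        from efatrans import ConvectionTimeParams

        doubled = ConvectionTimeParams(
            j=2 * convection_params.j, w=convection_params.w, l=convection_params.l
        )
        times = np.arange(0.0, 25.0, 1.0)
        base = acceleration_profile(convection_params, times)
        scaled = acceleration_profile(doubled, times)
        np.testing.assert_allclose(
            scaled["acceleration"], 2 * base["acceleration"], rtol=1e-12
        )
        assert scaled.attrs["zero_crossing"] == base.attrs["zero_crossing"]

    def test_times_outside_dosing_interval_rejected(self, convection_params):
        with pytest.raises(ValueError):
            acceleration_profile(convection_params, np.array([0.0, 25.0]))
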