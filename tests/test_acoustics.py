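"""Acoustic primitives: weighting curves, ISO propagation terms, dB algebra."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from soundscapes import acoustics as ac

# ---------------------------------------------------------------------------
# A-weighting
# ---------------------------------------------------------------------------

# IEC 61672 tabulated A-weights (dB) at nominal band frequencies, printed to
# 0.1 dB; the exact mid-band frequency of nominal band n is 1000*10^(n/10)
IEC_A_WEIGHTS = {
    -12: -26.2, -9: -16.1, -6: -8.6, -3: -3.2,
    0: 0.0, 3: 1.2, 6: 1.0, 9: -1.1,
}


class TestAWeighting:
    def test_zero_at_1khz(self):
        assert ac.a_weighting_offset(1000.0) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("band_n,expected", sorted(IEC_A_WEIGHTS.items()))
    def test_matches_standard_table(self, band_n, expected):
        freq = 1000.0 * 10.0 ** (band_n / 10.0)
        assert ac.a_weighting_offset(freq) == pytest.approx(expected, abs=0.05)

    def test_monotone_below_1khz(self):
        vals = [ac.a_weighting_offset(f) for f in (50, 500, 1000)]
        assert vals[0] < vals[1] < vals[2]

    def test_rejects_nonpositive_frequency(self):
        with pytest.raises(ValueError):
            ac.a_weighting_offset(0.0)


# ---------------------------------------------------------------------------
# ISO 9613-1 atmospheric absorption
# ---------------------------------------------------------------------------


def _absorption_oracle(f, t_c, rh, p_kpa):
    """Straight re-transcription of the standard's equations, scalar-only."""
    import math

    T = t_c + 273.15
    psat = 101.325 * 10.0 ** (-6.8346 * (273.16 / T) ** 1.261 + 4.6151)
    h = rh * psat / p_kpa
    pr = p_kpa / 101.325
    tr = T / 293.15
    f_ro = pr * (24.0 + 4.04e4 * h * (0.02 + h) / (0.391 + h))
    f_rn = pr / math.sqrt(tr) * (9.0 + 280.0 * h * math.exp(-4.170 * (tr ** (-1.0 / 3.0) - 1.0)))
    a = 8.686 * f * f * (
        1.84e-11 / pr * math.sqrt(tr)
        + tr ** -2.5 * (
            0.01275 * math.exp(-2239.1 / T) / (f_ro + f * f / f_ro)
            + 0.1068 * math.exp(-3352.0 / T) / (f_rn + f * f / f_rn)
        )
    )
    return a * 1000.0  # dB/km


class TestAtmosphericAbsorption:
    def test_increases_with_frequency(self, std_conditions):
        assert ac.atm_absorption_coeff(4000.0, std_conditions) > ac.atm_absorption_coeff(
            500.0, std_conditions
        )

    @pytest.mark.parametrize("freq", [125.0, 1000.0, 4000.0, 8000.0])
    @pytest.mark.parametrize("t_c,rh", [(20.0, 60.0), (0.0, 30.0), (30.0, 90.0)])
    def test_matches_independent_transcription(self, freq, t_c, rh):
        cond = ac.AtmosphericConditions(t_c, rh, 1.01325)
        got = ac.atm_absorption_coeff(freq, cond)
        want = _absorption_oracle(freq, t_c, rh, 101.325)
        assert got == pytest.approx(want, rel=1e-4)

    def test_plausible_magnitude_at_1khz(self, std_conditions):
        # sea-level temperate air absorbs a few dB/km at 1 kHz
        assert 2.0 < ac.atm_absorption_coeff(1000.0, std_conditions) < 8.0

    def test_nonnegative_over_random_conditions(self, rng):
        for _ in range(1000):
            cond = ac.AtmosphericConditions(
                rng.uniform(-20, 40), rng.uniform(0, 100), rng.uniform(0.8, 1.1)
            )
            assert ac.atm_absorption_coeff(rng.uniform(50, 10000), cond) >= 0.0

    def test_rejects_bad_humidity(self):
        with pytest.raises(ValueError):
            ac.AtmosphericConditions(20.0, 150.0, 1.0)


# ---------------------------------------------------------------------------
# Band power laws
# ---------------------------------------------------------------------------


class TestBandPowerLaw:
    def test_constant_levels(self):
        pl = ac.fit_band_powerlaw([5.0, 10.0, 20.0], [[60.0, 60.0, 60.0]], [1000.0])
        assert pl.intercepts[0] == pytest.approx(60.0)
        assert pl.slopes[0] == pytest.approx(0.0, abs=1e-10)

    def test_exact_recovery_at_reference_speeds(self):
        v = np.array([6.7, 11.2, 24.6])
        levels = 55.0 + 30.0 * np.log10(v)
        pl = ac.fit_band_powerlaw(v, levels[None, :], [1000.0])
        assert pl.intercepts[0] == pytest.approx(55.0)
        assert pl.slopes[0] == pytest.approx(30.0)

    def test_matches_normal_equation_oracle(self, rng):
        v = rng.uniform(3.0, 30.0, size=5)
        levels = rng.uniform(40.0, 90.0, size=(3, 5))
        pl = ac.fit_band_powerlaw(v, levels, [250.0, 1000.0, 4000.0])
        x = np.log10(v)
        for b in range(3):
            A = np.array([[len(v), x.sum()], [x.sum(), (x * x).sum()]])
            rhs = np.array([levels[b].sum(), (x * levels[b]).sum()])
            a0, b0 = np.linalg.solve(A, rhs)
            assert pl.intercepts[b] == pytest.approx(a0)
            assert pl.slopes[b] == pytest.approx(b0)

    def test_rejects_single_speed(self):
        with pytest.raises(ValueError):
            ac.fit_band_powerlaw([10.0, 10.0], [[60.0, 61.0]], [1000.0])

    def test_spectrum_at_reference_speed_reproduces_input(self):
        v = np.array([6.7, 11.2, 24.6])
        levels = np.vstack([50 + 20 * np.log10(v), 60 + 35 * np.log10(v)])
        pl = ac.fit_band_powerlaw(v, levels, [500.0, 1000.0])
        spec = ac.source_spectrum_at_speed(pl, 11.2)
        np.testing.assert_allclose(spec.levels, levels[:, 1])

    def test_geometric_mean_speed_gives_arithmetic_mean_level(self):
        v = np.array([6.7, 24.6])
        levels = (48.0 + 27.0 * np.log10(v))[None, :]
        pl = ac.fit_band_powerlaw(v, levels, [1000.0])
        mid = ac.source_spectrum_at_speed(pl, float(np.sqrt(6.7 * 24.6)))
        assert mid.levels[0] == pytest.approx(levels.mean())

    def test_positive_slope_bands_increase_with_speed(self, sedan_laws):
        lo = ac.source_spectrum_at_speed(sedan_laws, 8.0)
        hi = ac.source_spectrum_at_speed(sedan_laws, 20.0)
        grows = sedan_laws.slopes > 0
        assert np.all(hi.levels[grows] > lo.levels[grows])

    def test_speed_clamped_to_fit_range(self, sedan_laws):
        slow = ac.source_spectrum_at_speed(sedan_laws, 0.5)
        floor = ac.source_spectrum_at_speed(sedan_laws, sedan_laws.speed_min)
        np.testing.assert_array_equal(slow.levels, floor.levels)


# ---------------------------------------------------------------------------
# Received levels
# ---------------------------------------------------------------------------


def _received_oracle(src_levels, bands, d, cond, ground, hs, hr):
    """Independent plain-loop stack of divergence + absorption + ground."""
    out = []
    for L, f in zip(src_levels, bands):
        a_div = 20.0 * np.log10(max(d, 1.0))
        a_atm = _absorption_oracle(f, cond.temperature_c, cond.relative_humidity,
                                   cond.pressure_kpa) * max(d, 1.0) / 1000.0
        a_gr = 0.0
        if ground is not None:
            a_gr = float(
                ac.ground_attenuation(
                    [f], ac.PropagationGeometry(hs, hr, max(d, 1.0)), ground
                )[0]
            )
        out.append(L - a_div - a_atm - a_gr)
    return np.array(out)


class TestReceivedLevels:
    def test_reference_distance_identity(self, std_conditions):
        spec = ac.ThirdOctaveSpectrum([250.0, 1000.0, 4000.0], [70.0, 75.0, 65.0])
        geom = ac.PropagationGeometry(0.5, 1.5, 1.0)
        rec = ac.received_band_levels(spec, geom, std_conditions, ground=None)
        # only the (tiny) 1 m atmospheric term separates them
        np.testing.assert_allclose(rec.levels, spec.levels, atol=0.15)

    def test_doubling_distance_is_inverse_square_plus_absorption(self, std_conditions):
        bands = np.array([250.0, 1000.0, 4000.0])
        spec = ac.ThirdOctaveSpectrum(bands, [80.0, 80.0, 80.0])
        alpha = ac.atm_absorption_coeff(bands, std_conditions)
        r1 = ac.received_band_levels(
            spec, ac.PropagationGeometry(0.5, 1.5, 50.0), std_conditions, None
        )
        r2 = ac.received_band_levels(
            spec, ac.PropagationGeometry(0.5, 1.5, 100.0), std_conditions, None
        )
        expected_drop = 20.0 * np.log10(2.0) + alpha * 50.0 / 1000.0
        np.testing.assert_allclose(r1.levels - r2.levels, expected_drop, rtol=1e-10)

    def test_hard_ground_constant_offset_when_regions_overlap(self, std_conditions):
        # tall source/receiver keep q = 0, so hard ground contributes a fixed
        # -3 dB (low/mid bands) and doubling distance still costs 6.02 dB + atm
        ground = ac.GroundProfile(hardness=1.0)  # G = 0
        bands = np.array([250.0, 1000.0])
        spec = ac.ThirdOctaveSpectrum(bands, [80.0, 80.0])
        alpha = ac.atm_absorption_coeff(bands, std_conditions)
        r1 = ac.received_band_levels(spec, ac.PropagationGeometry(2.0, 2.0, 20.0), std_conditions, ground)
        r2 = ac.received_band_levels(spec, ac.PropagationGeometry(2.0, 2.0, 40.0), std_conditions, ground)
        np.testing.assert_allclose(
            r1.levels - r2.levels, 20.0 * np.log10(2.0) + alpha * 20.0 / 1000.0, rtol=1e-10
        )
        # and the ground term itself is -3 dB at these bands
        agr = ac.ground_attenuation(bands, ac.PropagationGeometry(2.0, 2.0, 20.0), ground)
        np.testing.assert_allclose(agr, -3.0)

    def test_matches_plain_loop_oracle(self, rng, std_ground):
        bands = ac.third_octave_centers()
        for _ in range(20):
            cond = ac.AtmosphericConditions(rng.uniform(0, 30), rng.uniform(10, 90), 1.01325)
            levels = rng.uniform(40, 90, size=len(bands))
            spec = ac.ThirdOctaveSpectrum(bands, levels)
            hs, hr = rng.uniform(0.2, 3.0, size=2)
            d = rng.uniform(1.0, 5000.0)
            rec = ac.received_band_levels(
                spec, ac.PropagationGeometry(hs, hr, d), cond, std_ground
            )
            want = _received_oracle(levels, bands, d, cond, std_ground, hs, hr)
            np.testing.assert_allclose(rec.levels, want, rtol=1e-8)

    def test_subunit_distance_clamps_to_reference(self, std_conditions):
        spec = ac.ThirdOctaveSpectrum([1000.0], [70.0])
        r_a = ac.received_band_levels(spec, ac.PropagationGeometry(0.5, 1.5, 0.2), std_conditions, None)
        r_b = ac.received_band_levels(spec, ac.PropagationGeometry(0.5, 1.5, 1.0), std_conditions, None)
        np.testing.assert_array_equal(r_a.levels, r_b.levels)

    def test_iso_divergence_adds_11db(self, std_conditions):
        spec = ac.ThirdOctaveSpectrum([1000.0], [70.0])
        geom = ac.PropagationGeometry(0.5, 1.5, 100.0)
        a = ac.received_band_levels(spec, geom, std_conditions, None, divergence="source-ref")
        b = ac.received_band_levels(spec, geom, std_conditions, None, divergence="iso")
        assert a.levels[0] - b.levels[0] == pytest.approx(11.0)


# ---------------------------------------------------------------------------
# Energy arithmetic
# ---------------------------------------------------------------------------


class TestEnergySum:
    @pytest.mark.parametrize(
        "levels,expected",
        [([60.0, 60.0], 63.0103), ([60.0], 60.0), ([50.0] * 10, 60.0)],
    )
    def test_examples(self, levels, expected):
        assert ac.energy_sum(levels) == pytest.approx(expected, abs=1e-3)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ac.energy_sum([])

    @given(st.lists(st.floats(-20, 120), min_size=1, max_size=12), st.randoms())
    def test_permutation_invariant_and_bounded(self, levels, pyrandom):
        total = ac.energy_sum(levels)
        shuffled = list(levels)
        pyrandom.shuffle(shuffled)
        assert ac.energy_sum(shuffled) == pytest.approx(total, abs=1e-9)
        assert total >= max(levels) - 1e-9
        assert total <= max(levels) + 10.0 * np.log10(len(levels)) + 1e-9


class TestOverallALevel:
    def test_single_band_at_1khz_passes_through(self):
        spec = ac.ThirdOctaveSpectrum([1000.0], [70.0])
        assert ac.overall_a_level(spec) == pytest.approx(70.0, abs=1e-9)

    def test_dominant_band_energy(self):
        base = ac.ThirdOctaveSpectrum([1000.0], [80.0])
        with_quiet = ac.ThirdOctaveSpectrum([800.0, 1000.0], [40.0 - ac.a_weighting_offset(800.0), 80.0])
        assert abs(ac.overall_a_level(with_quiet) - ac.overall_a_level(base)) < 0.05

    def test_matches_bruteforce_weighted_sum(self, rng):
        bands = ac.third_octave_centers()
        levels = rng.uniform(30, 80, size=len(bands))
        spec = ac.ThirdOctaveSpectrum(bands, levels)
        powers = sum(10.0 ** ((L + ac.a_weighting_offset(f)) / 10.0) for L, f in zip(levels, bands))
        assert ac.overall_a_level(spec) == pytest.approx(10.0 * np.log10(powers))


# ---------------------------------------------------------------------------
# Detection radius
# ---------------------------------------------------------------------------


class TestDetectionRadius:
    def test_reference_level_returns_reference_radius(self):
        assert ac.detection_radius(25.0, 50.0, 25.0) == pytest.approx(50.0)

    @pytest.mark.parametrize("level,expected", [(30.0, 28.1), (35.0, 15.8)])
    def test_published_calibration_triple(self, level, expected):
        got = ac.detection_radius(level, 50.0, 25.0)
        assert float(f"{got:.3g}") == pytest.approx(expected)

    def test_plus_3db_halves_listening_area(self):
        r0 = ac.detection_radius(40.0, 50.0, 25.0)
        r1 = ac.detection_radius(43.0, 50.0, 25.0)
        ratio = ac.listening_area(r1) / ac.listening_area(r0)
        assert ratio == pytest.approx(0.5, abs=0.01)

    def test_capped_below_ambient(self):
        assert ac.detection_radius(10.0, 50.0, 25.0) == pytest.approx(50.0)

    @given(st.floats(0, 60), st.floats(0, 60))
    def test_scaling_law(self, l1, l2):
        r1 = ac.detection_radius(25.0 + l1, 50.0, 25.0)
        r2 = ac.detection_radius(25.0 + l2, 50.0, 25.0)
        if l1 > 0 and l2 > 0:
            assert r1 / r2 == pytest.approx(10.0 ** ((l2 - l1) / 20.0), rel=1e-9)


# ---------------------------------------------------------------------------
# Propagation tables
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def small_table(sedan_laws, std_conditions, std_ground, std_geometry):
    return ac.build_propagation_table(
        sedan_laws, std_conditions, std_ground, std_geometry,
        distance_grid=np.logspace(0, 4, 201),
    )


class TestPropagationTable:
    def test_node_lookup_is_exact(self, small_table):
        for i in (0, 17, 100, 200):
            for j in (0, 5, len(small_table.speeds) - 1):
                got = small_table.lookup(small_table.distances[i], small_table.speeds[j])
                assert got == small_table.levels[i, j]

    def test_between_nodes_is_bounded(self, small_table):
        d0, d1 = small_table.distances[50], small_table.distances[51]
        v = small_table.speeds[3]
        mid = small_table.lookup(np.sqrt(d0 * d1), v)
        lo, hi = sorted([small_table.levels[50, 3], small_table.levels[51, 3]])
        assert lo - 1e-9 <= mid <= hi + 1e-9

    def test_offnode_queries_match_direct_computation(
        self, small_table, sedan_laws, std_conditions, std_ground, std_geometry, rng
    ):
        for _ in range(100):
            d = 10.0 ** rng.uniform(0.0, 4.0)
            v = rng.uniform(6.7, 24.6)
            direct = ac.overall_a_level(
                ac.received_band_levels(
                    ac.source_spectrum_at_speed(sedan_laws, v),
                    ac.PropagationGeometry(
                        std_geometry.source_height, std_geometry.receiver_height, d
                    ),
                    std_conditions,
                    std_ground,
                )
            )
            assert small_table.lookup(d, v) == pytest.approx(direct, abs=0.1)

    def test_received_level_nonincreasing_in_distance(self, sedan_laws, rng):
        for _ in range(10):
            cond = ac.AtmosphericConditions(rng.uniform(0, 30), rng.uniform(10, 90), 1.01325)
            ground = ac.GroundProfile(rng.uniform(0, 1))
            geom = ac.PropagationGeometry(rng.uniform(0.2, 2), rng.uniform(0.5, 2), 1.0)
            table = ac.build_propagation_table(
                sedan_laws, cond, ground, geom, distance_grid=np.logspace(0, 4.5, 100)
            )
            assert np.all(np.diff(table.levels, axis=0) <= 1e-9)

    def test_queries_outside_grid_clamp(self, small_table):
        assert small_table.lookup(0.1, 10.0) == small_table.lookup(1.0, 10.0)
        assert small_table.lookup(1e6, 10.0) == small_table.lookup(small_table.distances[-1], 10.0)
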