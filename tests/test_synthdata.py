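"""Generator correctness: photon bookkeeping, cohort sampling, forward model,
trajectory construction and toy spectra."""

import math

import numpy as np
import pytest

from cnetvna import synthdata
from cnetvna.synthdata import (
    GroundTruth,
    SpectrumTable,
    geometry_forward_model,
    make_toy_spectra,
    simulate_cohort,
    simulate_photon_stream,
    simulate_trajectory,
)


class TestPhotonStream:
    def test_post_bleach_segment_is_background_only(self):
        stream, truth = simulate_photon_stream(
            true_tau=3.5, irf_sigma=0.1, brightness=2e4, background_rate=200.0,
            bleach_rate=0.2, duration=30.0, seed=1,
        )
        tb = truth.bleach_time
        assert tb < 30.0
        post = stream.macro_times >= tb
        post_rate = post.sum() / (30.0 - tb)
        # post-bleach photons are pure background: Poisson rate ~200/s
        se = math.sqrt(200.0 * (30.0 - tb)) / (30.0 - tb)
        assert abs(post_rate - 200.0) < 4 * se

    def test_no_sources_gives_empty_stream(self):
        stream, _ = simulate_photon_stream(
            true_tau=1.0, brightness=0.0, background_rate=0.0, seed=0
        )
        assert stream.n_photons == 0

    def test_microtime_mle_converges_to_true_tau(self):
        # irf_sigma=0, no background, no bleach: delays are iid exponential
        # shifted by the (deterministic) IRF centre; the closed-form MLE is
        # the mean excess delay
        tau = 1.3
        stream, _ = simulate_photon_stream(
            true_tau=tau, irf_sigma=0.0, irf_center=2.0, brightness=1e5,
            background_rate=0.0, bleach_rate=0.0, duration=2.0,
            excitation_period=200.0, seed=5,
        )
        tau_hat = stream.micro_times.mean() - 2.0
        assert tau_hat == pytest.approx(tau, rel=3.0 / math.sqrt(stream.n_photons))

    def test_expected_signal_count_matches_bleach_clock(self):
        # expected signal photons = brightness * E[min(bleach, duration)]
        rate, bleach, dur, n_rep = 5e3, 0.5, 10.0, 120
        counts = []
        for seed in range(n_rep):
            s, t = simulate_photon_stream(
                true_tau=2.0, brightness=rate, background_rate=0.0,
                bleach_rate=bleach, duration=dur, seed=seed,
            )
            counts.append(s.n_photons)
        expected = rate * (1.0 - math.exp(-bleach * dur)) / bleach
        se = np.std(counts, ddof=1) / math.sqrt(n_rep)
        assert abs(np.mean(counts) - expected) < 4 * se

    def test_determinism(self):
        a, _ = simulate_photon_stream(true_tau=2.0, seed=7)
        b, _ = simulate_photon_stream(true_tau=2.0, seed=7)
        np.testing.assert_array_equal(a.macro_times, b.macro_times)
        np.testing.assert_array_equal(a.micro_times, b.micro_times)

    @pytest.mark.parametrize("kwargs,msg", [
        (dict(true_tau=-1.0), "true_tau"),
        (dict(true_tau=1.0, duration=0.0), "duration"),
        (dict(true_tau=1.0, irf_sigma=-0.1), "irf_sigma"),
    ])
    def test_invalid_parameters_are_named(self, kwargs, msg):
        with pytest.raises(ValueError, match=msg):
            simulate_photon_stream(**kwargs)

    def test_microtimes_respect_window(self):
        stream, _ = simulate_photon_stream(
            true_tau=3.0, excitation_period=25.0, tcspc_window=20.0, seed=2
        )
        assert stream.micro_times.max() < 20.0


class TestCohort:
    def test_single_population_labels(self):
        _, truths = simulate_cohort(
            [(3.5, 0.1, 1.0)], 50,
            dict(brightness=1e3, duration=1.0, background_rate=0.0), seed=0,
        )
        assert {t.population_label for t in truths} == {"component0"}

    def test_two_population_fractions(self):
        _, truths = simulate_cohort(
            [(1.0, 0.15, 0.5), (3.5, 0.15, 0.5)], 400,
            dict(brightness=100.0, duration=0.5, background_rate=0.0), seed=7,
        )
        frac = np.mean([t.population_label == "component0" for t in truths])
        assert abs(frac - 0.5) < 3 * math.sqrt(0.25 / 400)

    def test_weight_normalization_invariance(self):
        pp = dict(brightness=100.0, duration=0.5, background_rate=0.0)
        _, ta = simulate_cohort([(1.0, 0.15, 2.0), (3.5, 0.15, 2.0)], 30, pp, seed=3)
        _, tb = simulate_cohort([(1.0, 0.15, 1.0), (3.5, 0.15, 1.0)], 30, pp, seed=3)
        assert [t.true_tau for t in ta] == [t.true_tau for t in tb]

    def test_rejects_empty_and_near_zero_components(self):
        with pytest.raises(ValueError):
            simulate_cohort([], 10)
        with pytest.raises(ValueError, match="3\\*sd"):
            simulate_cohort([(0.2, 0.1, 1.0)], 10)


class TestForwardModel:
    def test_perpendicular_distance_arithmetic(self):
        # 12 bp at 0.34 nm/bp plus the 1.1 nm linker: d = 5.18 nm
        truths = geometry_forward_model(
            12, rise=0.34, linker_offset=1.1, tilt_distribution=(90.0, 0.0),
            n_molecules=3, seed=0,
        )
        for t in truths:
            assert t.true_distance == pytest.approx(12 * 0.34 + 1.1, abs=1e-12)

    def test_half_quenching_at_characteristic_distance(self):
        # choose geometry so that d == d0 exactly: tau = tau0/2
        d0 = 12 * 0.34 + 1.1
        truths = geometry_forward_model(
            12, tilt_distribution=(90.0, 0.0), d0=d0, tau0=3.5,
            n_molecules=2, seed=0,
        )
        for t in truths:
            assert t.true_tau == pytest.approx(3.5 / 2, abs=1e-12)

    def test_tilt_jitter_lowers_mean_distance(self):
        # sin is concave around 90 deg, so angle jitter only lowers the height
        fixed = geometry_forward_model(
            12, tilt_distribution=(90.0, 0.0), n_molecules=1, seed=0
        )[0].true_distance
        jittered = geometry_forward_model(
            12, tilt_distribution=(90.0, 10.0), n_molecules=10_000, seed=1
        )
        assert np.mean([t.true_distance for t in jittered]) < fixed

    def test_deterministic_chain_at_zero_spread(self):
        truths = geometry_forward_model(
            15, tilt_distribution=(75.0, 0.0), d0=7.4, exponent=5, tau0=3.5,
            n_molecules=4, seed=9,
        )
        d = 15 * 0.34 * math.sin(math.radians(75.0)) + 1.1
        eta = 1.0 / (1.0 + (d / 7.4) ** 5)
        for t in truths:
            assert t.true_distance == pytest.approx(d, abs=1e-12)
            assert t.true_tau == pytest.approx(3.5 * (1 - eta), abs=1e-12)

    def test_rejects_bad_d0_and_exponent(self):
        with pytest.raises(ValueError, match="d0"):
            geometry_forward_model(12, d0=-1.0)
        with pytest.raises(ValueError, match="exponent"):
            geometry_forward_model(12, exponent=7)


class TestTrajectory:
    def test_perpendicular_tip_distance_is_duplex_length(self):
        traj = simulate_trajectory(12, 4, tilt_distribution=(90.0, 0.0), seed=0)
        from cnetvna.geometry import analyze_trajectory

        geo = analyze_trajectory(traj)
        assert np.allclose(geo.tip_distance_nm, 12 * 0.34, atol=1e-9)

    def test_swcnt_atoms_lie_on_cylinder(self):
        traj = simulate_trajectory(12, 2, seed=0)
        sw = traj.frames[0][traj.groups == "SWCNT"]
        radii = np.hypot(sw[:, 0], sw[:, 1])
        assert np.allclose(radii, traj.cylinder_radius, atol=1e-9)

    def test_duplex_is_rigid_rod_of_nominal_length(self):
        traj = simulate_trajectory(15, 3, tilt_distribution=(70.0, 20.0), seed=4)
        comp = traj.groups == "complement"
        for frame in traj.frames:
            # complement atoms sit at rise, 2*rise, ..., n_bp*rise along the rod
            span = np.linalg.norm(frame[comp][-1] - frame[comp][0])
            assert span == pytest.approx(14 * 0.34, abs=1e-9)

    def test_seed_reproducibility(self):
        a = simulate_trajectory(12, 3, tilt_distribution=(90.0, 15.0), seed=11)
        b = simulate_trajectory(12, 3, tilt_distribution=(90.0, 15.0), seed=11)
        for fa, fb in zip(a.frames, b.frames):
            np.testing.assert_array_equal(fa, fb)

    def test_tip_flag_is_last_complement_atom(self):
        traj = simulate_trajectory(12, 1, seed=0)
        assert traj.is_tip.sum() == 1
        assert traj.groups[np.argmax(traj.is_tip)] == "complement"
        assert traj.bp_index[np.argmax(traj.is_tip)] == 11


class TestToySpectra:
    def test_emission_area_normalized(self):
        em, _ = make_toy_spectra(560, 40, 990, 60)
        assert np.trapezoid(em.value, em.wavelength) == pytest.approx(1.0, abs=1e-9)

    def test_identical_bands_maximize_overlap_over_shifts(self):
        from cnetvna.cnet_model import overlap_integral

        grid = np.linspace(300, 900, 1200)
        js = []
        for shift in (-80, -40, 0, 40, 80):
            em, ab = make_toy_spectra(560, 40, 560 + shift, 40, grid=grid)
            js.append(overlap_integral(em, ab))
        assert np.argmax(js) == 2

    def test_disjoint_bands_give_zero_overlap(self):
        from cnetvna.cnet_model import overlap_integral

        em, _ = make_toy_spectra(400, 10, 400, 10, grid=np.linspace(350, 450, 100))
        _, ab = make_toy_spectra(800, 10, 800, 10, grid=np.linspace(750, 850, 100))
        with pytest.warns(UserWarning, match="do not overlap"):
            assert overlap_integral(em, ab) == 0.0

    def test_narrow_grid_warns(self):
        with pytest.warns(UserWarning, match="FWHM"):
            make_toy_spectra(560, 40, 560, 40, grid=np.linspace(540, 580, 50))

    def test_spectrum_table_validation(self):
        with pytest.raises(ValueError, match="increasing"):
            SpectrumTable(np.zeros(12), np.ones(12))
        with pytest.raises(ValueError, match="non-negative"):
            SpectrumTable(np.arange(12.0), -np.ones(12))


def test_ground_truth_validation():
    with pytest.raises(ValueError):
        GroundTruth("m", true_tau=0.0, true_background_fraction=0.0,
                    bleach_time=1.0, population_label="")
    with pytest.raises(ValueError):
        GroundTruth("m", true_tau=1.0, true_background_fraction=0.0,
                    bleach_time=-1.0, population_label="")
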