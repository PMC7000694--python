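"""Decay kernel, mixture model, fitting, and binding-fraction inversion."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import quad

import flimspine as fs
from flimspine.model import (
    InsufficientPhotonsError,
    InvalidParameterError,
    truncated_component_moments,
)
from conftest import kernel_convolution_oracle


# ---------------------------------------------------------------------------
# IRF-convolved kernel
# ---------------------------------------------------------------------------


class TestKernel:
    def test_vanishing_irf_limit_reduces_to_bare_exponential(self):
        # with tau_G -> 0 the convolution degenerates to exp(-(t-t0)/tau)
        for dt in (0.1, 1.0, 2.6, 8.0):
            h = fs.irf_decay_kernel(1.0 + dt, 1.0, 2.6, 1e-6)
            assert h == pytest.approx(math.exp(-dt / 2.6), rel=1e-6)
        assert fs.irf_decay_kernel(2.6, 0.0, 2.6, 1e-6) == pytest.approx(math.exp(-1.0), rel=1e-6)

    @pytest.mark.parametrize("tau", [1.1, 2.6])
    @pytest.mark.parametrize("tau_g", [0.05, 0.2, 0.5])
    def test_matches_numerical_convolution(self, tau, tau_g):
        dts = np.arange(-1.0, 15.01, 0.5)
        h = fs.irf_decay_kernel(dts + 2.0, 2.0, tau, tau_g)
        for dt, val in zip(dts, h):
            oracle = kernel_convolution_oracle(float(dt), tau, tau_g)
            assert val == pytest.approx(oracle, rel=1e-6)

    def test_area_equals_lifetime_and_mean_is_offset_plus_lifetime(self):
        # H is exp(-t/tau) (x) unit-area Gaussian, so its area is tau and
        # the mean of the normalized kernel is t0 + tau
        for tau, tau_g in [(1.1, 0.05), (1.1, 0.5), (2.6, 0.2), (2.6, 0.5)]:
            t0 = 1.5
            f = lambda t: fs.irf_decay_kernel(t, t0, tau, tau_g)  # noqa: E731
            lo, hi = t0 - 10 * tau_g, t0 + 60 * tau
            area, _ = quad(f, lo, hi, limit=500, epsabs=0, epsrel=1e-10)
            mean, _ = quad(lambda t: t * f(t), lo, hi, limit=500, epsabs=0, epsrel=1e-10)
            assert area == pytest.approx(tau, rel=1e-6)
            assert mean / area == pytest.approx(t0 + tau, rel=1e-6)

    @given(
        tau=st.floats(0.3, 5.0),
        tau_g=st.floats(0.01, 1.0),
        dt=st.floats(-5.0, 30.0),
    )
    def test_finite_and_nonnegative_everywhere(self, tau, tau_g, dt):
        h = fs.irf_decay_kernel(dt, 0.0, tau, tau_g)
        assert np.isfinite(h)
        assert h >= 0.0

    def test_invalid_parameters_raise(self):
        with pytest.raises(InvalidParameterError):
            fs.irf_decay_kernel(1.0, 0.0, -2.6, 0.2)
        with pytest.raises(InvalidParameterError):
            fs.irf_decay_kernel(1.0, 0.0, 2.6, 0.0)


class TestMixture:
    def test_pure_component_limits(self, calibration):
        t = np.linspace(0, 12.5, 64)
        for p_ad, tau in [(0.0, 2.6), (1.0, 1.1)]:
            params = fs.DecayModelParams(F0=100.0, P_AD=p_ad, t0=1.0, tau_G=0.2)
            np.testing.assert_allclose(
                fs.mixture_decay(t, params),
                100.0 * fs.irf_decay_kernel(t, 1.0, tau, 0.2),
                rtol=1e-12,
            )

    def test_linearity_in_the_two_components(self):
        t = np.linspace(0, 12.5, 64)
        mix = fs.mixture_decay(t, fs.DecayModelParams(F0=1000.0, P_AD=0.5, t0=1.0, tau_G=0.2))
        pure_d = fs.irf_decay_kernel(t, 1.0, 2.6, 0.2)
        pure_ad = fs.irf_decay_kernel(t, 1.0, 1.1, 0.2)
        np.testing.assert_allclose(mix, 1000.0 * 0.5 * (pure_d + pure_ad), rtol=1e-12)


class TestExpectedBinCounts:
    def test_single_wide_bin_recovers_curve_area(self):
        # F0 chosen so the full curve area is 1
        f0 = 1.0 / (0.7 * 2.6 + 0.3 * 1.1)
        params = fs.DecayModelParams(F0=f0, P_AD=0.3, t0=2.0, tau_G=0.2)
        counts = fs.expected_bin_counts(params, np.array([0.0, 60.0]))
        assert counts[0] == pytest.approx(1.0, abs=1e-6)

    def test_refinement_consistency(self):
        params = fs.DecayModelParams(F0=1e4, P_AD=0.3, t0=2.0, tau_G=0.2)
        coarse = fs.expected_bin_counts(params, fs.default_bin_edges(32))
        fine = fs.expected_bin_counts(params, fs.default_bin_edges(64))
        np.testing.assert_allclose(fine.reshape(32, 2).sum(axis=1), coarse, rtol=1e-6)

    def test_matches_per_bin_quadrature(self):
        params = fs.DecayModelParams(F0=1e4, P_AD=0.3, t0=2.0, tau_G=0.2)
        edges = fs.default_bin_edges()
        counts = fs.expected_bin_counts(params, edges)
        total = counts.sum()
        for i in range(0, edges.size - 1, 7):
            ref, _ = quad(lambda t: fs.mixture_decay(t, params), edges[i], edges[i + 1], epsabs=0, epsrel=1e-10)
            if ref > 1e-4 * total:
                assert counts[i] == pytest.approx(ref, rel=5e-3)

    def test_empty_binning_rejected(self):
        params = fs.DecayModelParams(F0=1.0, P_AD=0.3, t0=2.0, tau_G=0.2)
        with pytest.raises(InvalidParameterError):
            fs.expected_bin_counts(params, np.array([1.0]))


# ---------------------------------------------------------------------------
# Mean arrival time
# ---------------------------------------------------------------------------


class TestMeanArrivalTime:
    def test_single_occupied_bin_gives_its_center(self):
        edges = np.linspace(0.0, 6.0, 7)
        counts = np.zeros(6)
        counts[2] = 17  # bin [2, 3] has centre 2.5
        hist = fs.TCSPCHistogram(edges, counts)
        assert fs.mean_arrival_time(hist) == pytest.approx(2.5)

    def test_symmetric_counts_give_centre_of_symmetry(self):
        edges = np.linspace(0.0, 4.0, 9)
        counts = np.array([1, 2, 5, 9, 9, 5, 2, 1])
        assert fs.mean_arrival_time(fs.TCSPCHistogram(edges, counts)) == pytest.approx(2.0)

    def test_empty_histogram_yields_nan_sentinel(self):
        hist = fs.TCSPCHistogram(np.linspace(0, 1, 5), np.zeros(4))
        assert math.isnan(fs.mean_arrival_time(hist))

    def test_sampled_exponential_mean_with_long_window(self):
        # exGaussian mean is t0 + tau; a long window makes truncation moot
        edges = fs.default_bin_edges(n_bins=512, window_ns=60.0)
        hist = fs.sample_decay_histogram(
            10**6, 0.0, edges, t0=5.0, tau_G=1e-3, rng=np.random.default_rng(4)
        )
        assert fs.mean_arrival_time(hist) == pytest.approx(5.0 + 2.6, abs=0.02)


# ---------------------------------------------------------------------------
# Binding fraction
# ---------------------------------------------------------------------------


class TestBindingFraction:
    def test_endpoints(self, calibration):
        assert fs.binding_fraction(2.6, calibration).raw == pytest.approx(0.0, abs=1e-12)
        assert fs.binding_fraction(1.1, calibration).raw == pytest.approx(1.0, abs=1e-12)

    def test_round_trip_through_mixture_mean(self, calibration):
        p = np.arange(0.0, 1.0001, 0.1)
        back = fs.binding_fraction(fs.mixture_mean_lifetime(p, calibration), calibration)
        np.testing.assert_allclose(back.raw, p, atol=1e-12)

    def test_half_mixture_worked_value(self, calibration):
        mean_tau = (0.5 * 2.6**2 + 0.5 * 1.1**2) / (0.5 * 2.6 + 0.5 * 1.1)
        assert fs.binding_fraction(mean_tau, calibration).raw == pytest.approx(0.5, abs=1e-12)

    def test_strictly_decreasing_in_mean_lifetime(self, calibration):
        taus = np.linspace(1.1, 2.6, 101)
        vals = fs.binding_fraction(taus, calibration).raw
        assert np.all(np.diff(vals) < 0)

    def test_noisy_values_are_clamped_but_raw_preserved(self, calibration):
        bf = fs.binding_fraction(2.75, calibration)  # longer than tau_D
        assert bf.raw < 0 and bf.clamped == 0.0

    def test_pole_raises(self, calibration):
        with pytest.raises(InvalidParameterError):
            fs.binding_fraction(3.7, calibration)

    def test_finite_window_inversion_reduces_to_closed_form_for_long_window(self, calibration):
        edges = np.array([0.0, 4000.0])
        m = truncated_component_moments(calibration, 1.0, edges)
        assert m["w_D"] == pytest.approx(2.6, rel=1e-9)
        assert m["mu_D"] == pytest.approx(2.6, rel=1e-9)
        assert m["w_AD"] == pytest.approx(1.1, rel=1e-9)
        assert m["mu_AD"] == pytest.approx(1.1, rel=1e-9)


# ---------------------------------------------------------------------------
# Population fit
# ---------------------------------------------------------------------------


class TestFitPopulation:
    def test_recovers_generating_parameters_from_noiseless_curve(self, calibration):
        edges = fs.default_bin_edges()
        true = fs.DecayModelParams(F0=5e4, P_AD=0.3, t0=2.0, tau_G=0.2)
        hist = fs.TCSPCHistogram(edges, fs.expected_bin_counts(true, edges))
        res = fs.fit_population(hist, calibration)
        assert res.success
        assert res.params.P_AD == pytest.approx(0.3, abs=1e-3)
        assert res.params.t0 == pytest.approx(2.0, abs=5e-3)
        assert res.params.tau_G == pytest.approx(0.2, abs=5e-3)
        assert res.params.F0 == pytest.approx(5e4, rel=1e-2)

    def test_zero_binding_truth_stays_near_zero(self, calibration):
        edges = fs.default_bin_edges()
        hist = fs.sample_decay_histogram(10**6, 0.0, edges, rng=np.random.default_rng(7))
        res = fs.fit_population(hist, calibration)
        assert res.params.P_AD <= 0.02

    def test_neyman_objective_agrees_at_high_counts(self, calibration):
        edges = fs.default_bin_edges()
        hist = fs.sample_decay_histogram(10**6, 0.25, edges, rng=np.random.default_rng(8))
        p_pois = fs.fit_population(hist, calibration).params.P_AD
        p_ney = fs.fit_population(hist, calibration, objective="neyman").params.P_AD
        assert p_ney == pytest.approx(p_pois, abs=0.01)

    def test_deterministic_given_same_histogram(self, calibration):
        edges = fs.default_bin_edges()
        hist = fs.sample_decay_histogram(10**5, 0.3, edges, rng=np.random.default_rng(9))
        a = fs.fit_population(hist, calibration)
        b = fs.fit_population(hist, calibration)
        assert a.params == b.params

    def test_insufficient_photons_raise(self, calibration):
        edges = fs.default_bin_edges()
        hist = fs.TCSPCHistogram(edges, np.ones(64))
        with pytest.raises(InsufficientPhotonsError, match="1000"):
            fs.fit_population(hist, calibration)

    def test_fixed_subset_keeps_other_parameters(self, calibration):
        edges = fs.default_bin_edges()
        hist = fs.sample_decay_histogram(10**5, 0.3, edges, rng=np.random.default_rng(10))
        res = fs.fit_population(hist, calibration, free=("F0", "P_AD"), init={"t0": 1.2, "tau_G": 0.2})
        assert res.params.t0 == 1.2 and res.params.tau_G == 0.2
        assert res.free_names == ("F0", "P_AD")


# ---------------------------------------------------------------------------
# Lifetime maps and ROI estimates
# ---------------------------------------------------------------------------


def _uniform_frame(p_ad, shape=(12, 12), photons_per_px=400, seed=0):
    edges = fs.default_bin_edges()
    rng = np.random.default_rng(seed)
    counts = np.empty(shape + (64,), dtype=np.int64)
    for r in range(shape[0]):
        for c in range(shape[1]):
            n = rng.poisson(photons_per_px)
            counts[r, c] = fs.sample_decay_histogram(n, p_ad, edges, rng=rng).counts
    return counts, edges


class TestLifetimeMap:
    def test_free_donor_frame_maps_to_donor_lifetime(self, calibration):
        counts, edges = _uniform_frame(0.0)
        hist = fs.TCSPCHistogram(edges, counts.sum(axis=(0, 1)))
        fit = fs.fit_population(hist, calibration)
        img = fs.lifetime_map(counts, edges, fit.t0_effective, min_photons=50)
        assert img.defined.all()
        assert float(np.nanmean(img.mean_tau)) == pytest.approx(2.6, abs=0.05)

    def test_single_bin_pixel_reads_offset_from_t0(self):
        edges = np.linspace(0.0, 8.0, 17)  # width 0.5
        counts = np.zeros((1, 1, 16))
        counts[0, 0, 6] = 25  # bin centre 3.25
        img = fs.lifetime_map(counts, edges, t0=1.75, min_photons=10)
        assert img.mean_tau[0, 0] == pytest.approx(1.5)

    def test_threshold_above_all_counts_gives_undefined_image(self):
        counts, edges = _uniform_frame(0.0, shape=(4, 4), photons_per_px=20)
        img = fs.lifetime_map(counts, edges, t0=1.2, min_photons=10**6)
        assert not img.defined.any()
        assert np.all(img.photon_count >= 0)


class TestRoiBindingFraction:
    def test_uniform_region_recovery(self, calibration):
        counts, edges = _uniform_frame(0.25, shape=(16, 16), photons_per_px=500, seed=3)
        mask = np.ones((16, 16), dtype=bool)  # >= 1e5 pooled photons
        bf = fs.roi_binding_fraction(counts, mask, edges, 1.2, calibration)
        assert bf.raw == pytest.approx(0.25, abs=0.02)

    def test_free_donor_region_reads_zero(self, calibration):
        counts, edges = _uniform_frame(0.0, shape=(16, 16), photons_per_px=500, seed=4)
        bf = fs.roi_binding_fraction(counts, np.ones((16, 16), bool), edges, 1.2, calibration)
        assert bf.raw == pytest.approx(0.0, abs=0.02)

    def test_disjoint_rois_of_same_scene_agree(self, calibration):
        counts, edges = _uniform_frame(0.25, shape=(16, 16), photons_per_px=500, seed=5)
        left = np.zeros((16, 16), bool)
        right = np.zeros((16, 16), bool)
        left[:, :8] = True
        right[:, 8:] = True
        a = fs.roi_binding_fraction(counts, left, edges, 1.2, calibration).raw
        b = fs.roi_binding_fraction(counts, right, edges, 1.2, calibration).raw
        assert a == pytest.approx(b, abs=0.03)

    def test_empty_or_sparse_roi_yields_nan_sentinel(self, calibration):
        counts, edges = _uniform_frame(0.25, shape=(4, 4), photons_per_px=3, seed=6)
        empty = np.zeros((4, 4), bool)
        assert math.isnan(fs.roi_binding_fraction(counts, empty, edges, 1.2, calibration).raw)
        sparse = np.zeros((4, 4), bool)
        sparse[0, 0] = True
        assert math.isnan(fs.roi_binding_fraction(counts, sparse, edges, 1.2, calibration).raw)

    def test_estimator_sd_shrinks_with_photon_count(self, calibration):
        # SD should scale roughly as 1/sqrt(N): factor ~10 from 1e4 to 1e6
        edges = fs.default_bin_edges()
        mask = np.ones((1, 1), bool)
        sds = []
        for n in (10**4, 10**6):
            vals = [
                fs.roi_binding_fraction(
                    fs.sample_decay_histogram(n, 0.25, edges, rng=np.random.default_rng(100 + s)).counts[None, None],
                    mask, edges, 1.2, calibration,
                ).raw
                for s in range(12)
            ]
            sds.append(np.std(vals))
        ratio = sds[0] / sds[1]
        assert 4.0 < ratio < 25.0
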