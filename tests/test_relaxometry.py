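"""CPMG inversion, log-Gaussian deconvolution, and pore mapping."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from limnodigest import relaxometry as rx
from limnodigest import synth

SQRT_2PI = math.sqrt(2 * math.pi)


class TestKernel:
    def test_diagonal_value(self):
        k = rx.build_kernel(np.array([0.1]), np.array([0.1]))
        assert k[0, 0] == pytest.approx(math.exp(-1.0))

    def test_short_time_limit(self):
        k = rx.build_kernel(np.array([1e-12]), np.array([1.0]))
        assert k[0, 0] == pytest.approx(1.0, abs=1e-9)

    def test_hand_computed_3x2(self):
        times = np.array([0.001, 0.01, 0.1])
        grid = np.array([0.005, 0.05])
        k = rx.build_kernel(times, grid)
        expected = np.exp(-times[:, None] / grid[None, :])
        assert np.allclose(k, expected, atol=1e-12)
        assert k[2, 0] == pytest.approx(math.exp(-20.0), abs=1e-12)

    def test_rejects_nonpositive_and_nonincreasing(self):
        with pytest.raises(ValueError):
            rx.build_kernel(np.array([0.0, 1.0]), np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            rx.build_kernel(np.array([1.0, 2.0]), np.array([2.0, 1.0]))


class TestEstimateSnr:
    def test_control_preset_recovered_within_15pct(self):
        rel_errs = []
        for seed in range(20):
            decay = synth.gen_cpmg_decay(
                synth.pore_population_preset("control"),
                synth.acquisition_preset("control", full_length=True, seed=seed),
            )
            est = rx.estimate_snr(decay)
            rel_errs.append(abs(est.snr - 199.0) / 199.0)
        assert np.mean(rel_errs) < 0.15
        assert max(rel_errs) < 0.15

    def test_noiseless_decay_flagged(self):
        # full acquisition: the tail has fully decayed, leaving zero variance
        acq = synth.AcquisitionParams(n_echoes=50_000, echo_time=70e-6, snr=None)
        decay = synth.gen_cpmg_decay(synth.pore_population_preset("control"), acq)
        est = rx.estimate_snr(decay)
        assert est.noiseless
        assert est.snr is None

    def test_all_zero_signal_degenerate(self):
        decay = rx.CPMGDecay(
            time=np.linspace(1e-5, 1.0, 200), signal=np.zeros(200)
        )
        assert rx.estimate_snr(decay).degenerate

    def test_doubling_noise_halves_estimate(self):
        ratios = []
        for seed in range(10):
            d1 = synth.gen_cpmg_decay(
                synth.pore_population_preset("control"),
                synth.AcquisitionParams(50_000, 70e-6, snr=200.0, seed=seed),
            )
            d2 = synth.gen_cpmg_decay(
                synth.pore_population_preset("control"),
                synth.AcquisitionParams(50_000, 70e-6, snr=100.0, seed=seed),
            )
            ratios.append(rx.estimate_snr(d1).snr / rx.estimate_snr(d2).snr)
        assert np.mean(ratios) == pytest.approx(2.0, rel=0.15)


class TestIltNnls:
    def test_single_exponential_mass_concentrates_near_truth(self):
        t2_true = 0.1
        times = 70e-6 * np.arange(1, 4097)
        decay = rx.CPMGDecay(time=times, signal=np.exp(-times / t2_true))
        dist = rx.ilt_nnls(decay, regularization=0.0)
        masses = dist.point_masses()
        window = (dist.t2 >= 0.05) & (dist.t2 <= 0.2)
        assert masses[window].sum() / masses.sum() >= 0.95

    def test_zero_signal_degenerate(self):
        times = 70e-6 * np.arange(1, 1025)
        dist = rx.ilt_nnls(rx.CPMGDecay(time=times, signal=np.zeros(1024)))
        assert dist.degenerate
        assert np.all(dist.amplitude == 0)

    def test_unit_area_normalization(self, control_decay):
        dist = rx.ilt_nnls(control_decay)
        assert dist.area() == pytest.approx(1.0, abs=1e-9)

    def test_forward_consistency_on_noiseless_input(self):
        comps = synth.pore_population_preset("control")
        acq = synth.AcquisitionParams(n_echoes=4096, echo_time=70e-6, snr=None)
        decay = synth.gen_cpmg_decay(comps, acq)
        dist = rx.ilt_nnls(decay)
        sub = rx.subsample_log(decay)
        zero_resid = float(np.linalg.norm(sub.signal))
        assert dist.residual_norm <= 1e-3 * zero_resid

    def test_two_equal_components_areas_half_half(self):
        truth = [
            rx.LogGaussianComponent(a=0.5 / (SQRT_2PI * 0.08), b=-3.0, c=0.08),
            rx.LogGaussianComponent(a=0.5 / (SQRT_2PI * 0.08), b=-1.0, c=0.08),
        ]
        areas = []
        for seed in range(20):
            acq = synth.AcquisitionParams(4096, 70e-6, snr=400.0, seed=seed)
            dist = rx.ilt_nnls(synth.gen_cpmg_decay(truth, acq))
            fit = rx.fit_log_gaussians(dist, 2)
            areas.append(fit.relative_areas)
        mean_areas = np.mean(areas, axis=0)
        assert mean_areas[0] == pytest.approx(0.5, abs=0.05)
        assert mean_areas[1] == pytest.approx(0.5, abs=0.05)

    def test_small_instance_matches_exhaustive_search(self):
        # 5-point time grid, 3-point T2 grid: NNLS objective vs brute force
        times = np.array([0.001, 0.003, 0.01, 0.03, 0.1])
        grid = np.array([0.002, 0.02, 0.2])
        truth = np.array([0.5, 0.3, 0.2])
        kern = rx.build_kernel(times, grid)
        signal = kern @ truth
        lam = 0.01
        decay = rx.CPMGDecay(time=times, signal=signal)
        dist = rx.ilt_nnls(decay, t2_grid=grid, regularization=lam, subsample=None)
        f_hat = dist.nnls_masses

        def objective(f):
            return np.sum((kern @ f - signal) ** 2) + lam * np.sum(f**2)

        # exhaustive search over the non-negative grid [0, 1]^3, step 0.01
        axis = np.linspace(0.0, 1.0, 101)
        fa, fb, fc = np.meshgrid(axis, axis, axis, indexing="ij")
        cand = np.stack([fa.ravel(), fb.ravel(), fc.ravel()], axis=1)
        objs = (
            np.sum((cand @ kern.T - signal) ** 2, axis=1) + lam * np.sum(cand**2, axis=1)
        )
        assert objective(f_hat) <= objs.min() + 1e-3

    def test_deconvolution_recovery_invariant(self):
        # 3-component truth at SNR 199: areas within 0.05 in >= 90% of 50 seeds
        truth = synth.pore_population_preset("control")
        true_areas = np.array([c.area for c in truth])
        true_areas = true_areas / true_areas.sum()
        hits = 0
        for seed in range(50):
            decay = synth.gen_cpmg_decay(
                truth, synth.acquisition_preset("control", seed=seed)
            )
            fit = rx.fit_log_gaussians(rx.ilt_nnls(decay), 3)
            hits += bool(np.all(np.abs(fit.relative_areas - true_areas) <= 0.05))
        assert hits >= 45


class TestLogGaussianFit:
    def test_exact_three_gaussian_input_recovered(self):
        truth = synth.pore_population_preset("control")
        dist = rx.T2Distribution.from_components(truth, rx.default_t2_grid())
        fit = rx.fit_log_gaussians(dist, 3)
        for comp, true_comp in zip(fit.components, truth):
            assert comp.b == pytest.approx(true_comp.b, abs=0.05)
        # residual tiny when the model contains the truth
        assert fit.rss < 1e-6

    def test_bic_selects_three_from_exact_input(self):
        truth = synth.pore_population_preset("control")
        dist = rx.T2Distribution.from_components(truth, rx.default_t2_grid())
        sel = rx.fit_log_gaussians(dist, "auto", k_max=5)
        assert sel.n_components == 3

    def test_bic_selects_one_for_single_gaussian(self):
        one = [rx.LogGaussianComponent(a=1.0, b=-2.0, c=0.25)]
        dist = rx.T2Distribution.from_components(one, rx.default_t2_grid())
        sel = rx.fit_log_gaussians(dist, "auto", k_max=4)
        assert sel.n_components == 1

    def test_components_sorted_by_center(self, control_decay):
        fit = rx.fit_log_gaussians(rx.ilt_nnls(control_decay), 3)
        centers = [c.b for c in fit.components]
        assert centers == sorted(centers)

    def test_too_few_points_is_an_error(self):
        grid = rx.default_t2_grid(n=8)
        dist = rx.T2Distribution.from_components(
            [rx.LogGaussianComponent(a=1.0, b=-2.0, c=0.3)], grid
        )
        with pytest.raises(rx.DeconvolutionError):
            rx.fit_log_gaussians(dist, 3)


class TestComponentArea:
    def test_unit_parameters(self):
        a, sd = rx.component_area(rx.LogGaussianComponent(a=1.0, b=0.0, c=1.0))
        assert a == pytest.approx(SQRT_2PI, abs=1e-9)
        assert sd == 0.0

    def test_zero_amplitude(self):
        a, _ = rx.component_area(rx.LogGaussianComponent(a=0.0, b=0.0, c=1.0))
        assert a == 0.0

    def test_hand_propagated_error(self):
        comp = rx.LogGaussianComponent(a=2.0, b=0.0, c=0.5, sd_a=0.1, sd_c=0.05)
        a, sd = rx.component_area(comp)
        assert a == pytest.approx(2.50663, abs=1e-5)
        # sqrt(2*pi) * sqrt(0.0025 + 0.01)
        assert sd == pytest.approx(0.280250, abs=1e-5)

    @given(
        a=st.floats(0.0, 100.0),
        c=st.floats(1e-3, 10.0),
        sd_a=st.floats(0.0, 5.0),
        sd_c=st.floats(0.0, 5.0),
    )
    @settings(max_examples=300, derandomize=True)
    def test_identity_to_machine_precision(self, a, c, sd_a, sd_c):
        comp = rx.LogGaussianComponent(a=a, b=0.0, c=c, sd_a=sd_a, sd_c=sd_c)
        area, sd = rx.component_area(comp)
        assert area == pytest.approx(SQRT_2PI * a * c, rel=1e-12, abs=1e-300)
        expected_sd = SQRT_2PI * math.hypot(c * sd_a, a * sd_c)
        assert sd == pytest.approx(expected_sd, rel=1e-12, abs=1e-300)


class TestPoreMapping:
    def test_reference_point(self):
        assert rx.pore_size(1.0, rho=1.0) == pytest.approx(2.0)

    def test_linearity(self):
        assert rx.pore_size(0.2, rho=3.0) == pytest.approx(2 * rx.pore_size(0.1, rho=3.0))

    def test_four_decades_of_t2_span_four_decades_of_size(self):
        # T2 of 1e-4..1 s maps to nm..um pore scales for a cellulose-like
        # surface relaxivity of a few um/s
        sizes = rx.pore_size(np.array([1e-4, 1.0]), rho=5e3)
        assert sizes[1] / sizes[0] == pytest.approx(1e4)
        assert 0.5 <= sizes[0] <= 5.0  # nanometer scale
        assert 5e3 <= sizes[1] <= 5e4  # micrometer scale (in nm)

    def test_inverse_round_trip(self):
        assert rx.t2_from_pore_size(rx.pore_size(0.05, 7.0), 7.0) == pytest.approx(0.05)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            rx.pore_size(0.0, 1.0)
        with pytest.raises(ValueError):
            rx.pore_size(1.0, -1.0)

    @given(t2=st.floats(1e-6, 1e2), rho=st.floats(1e-3, 1e3))
    @settings(max_examples=300, derandomize=True)
    def test_identity_to_machine_precision(self, t2, rho):
        r = rx.pore_size(t2, rho)
        assert r == pytest.approx(2.0 * rho * t2, rel=1e-14)
        assert 2.0 / r == pytest.approx(1.0 / (rho * t2), rel=1e-12)


class TestComparePopulations:
    def _comps(self, areas, centers=(-3.0, -2.0, -1.0), sds=0.0):
        return [
            rx.LogGaussianComponent(
                a=a / (SQRT_2PI * 0.2), b=b, c=0.2, sd_a=sds, sd_c=0.0
            )
            for a, b in zip(areas, centers)
        ]

    def test_identical_samples_zero_deltas(self):
        comps = self._comps([0.2, 0.3, 0.5])
        out = rx.compare_pore_populations(comps, comps)
        assert all(row["delta"] == pytest.approx(0.0) for row in out)

    def test_shift_into_lower_populations_gives_positive_deltas(self):
        treated = self._comps([0.32, 0.38, 0.30])
        control = self._comps([0.20, 0.30, 0.50])
        out = rx.compare_pore_populations(treated, control)
        assert out[0]["delta"] > 0
        assert out[1]["delta"] > 0
        assert out[2]["delta"] < 0

    def test_quadrature_error_of_toy_values(self):
        # area SDs 0.3 and 0.4 combine in quadrature to 0.5
        c = 1.0 / SQRT_2PI  # unit area for a = 1, and sd_A = sd_a exactly
        a = [rx.LogGaussianComponent(a=1.0, b=-2.0, c=c, sd_a=0.3, sd_c=0.0)]
        b = [rx.LogGaussianComponent(a=1.0, b=-2.0, c=c, sd_a=0.4, sd_c=0.0)]
        out = rx.compare_pore_populations(a, b)
        assert out[0]["delta_sd"] == pytest.approx(0.5, abs=1e-12)

    def test_mismatched_counts_instruct_refit(self):
        with pytest.raises(ValueError, match="re-fit"):
            rx.compare_pore_populations(
                self._comps([0.5, 0.5], centers=(-3.0, -1.0)),
                self._comps([0.2, 0.3, 0.5]),
            )
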