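import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pbsdose import (
    DoseMap,
    DoseRateModel,
    SpotMap,
    detector_averaged_rate,
    fit_spot_centroid,
    homogeneity_index,
    plan_uniform_field,
    spot_peak_dose_rate,
    synthesize_dose_map,
)
from pbsdose.dose_calibration import cyclotron_current_for_nozzle
from pbsdose.field_delivery import (
    calibrated_spot_integrals,
    delivery_schedule,
    delivery_time,
    field_average_dose_rate,
)
from pbsdose.measurement_sim import simulate_lynx_image


class TestPlanUniformField:
    def test_grid_arithmetic_inclusive_endpoints(self, calibration):
        plan = plan_uniform_field(100, 100, 2.5, 2.0, 160.0, 200.0)
        assert plan.n_spots == 41 * 41 == 1681
        assert plan.x_mm.min() == -50.0 and plan.x_mm.max() == 50.0

    def test_fluence_scaling_with_spacing(self, calibration):
        base = plan_uniform_field(100, 100, 2.5, 2.0, 160.0, 200.0)
        coarse = plan_uniform_field(100, 100, 5.0, 2.0, 160.0, 200.0)
        assert coarse.mu[0] == pytest.approx(4.0 * base.mu[0], rel=1e-12)

    def test_spacing_bound_warning_at_245(self, spot_model):
        # 5/3 of the smaller 245 MeV sigma is ~7.4 mm (quoted guidance: 7.3 mm
        # from the measured 4.35 mm sigma); an 8 mm spacing must warn
        bound = (5.0 / 3.0) * spot_model.sigma(245.0, "h")
        assert bound == pytest.approx(7.3, abs=0.25)
        with pytest.warns(UserWarning, match="5/3"):
            plan_uniform_field(100, 100, 8.0, 4.0, 245.0, 30.0)

    def test_oversized_field_rejected(self):
        with pytest.raises(ValueError, match="maximum"):
            plan_uniform_field(450, 100, 2.5, 2.0, 160.0, 200.0)

    def test_spot_map_validation(self):
        with pytest.raises(ValueError, match="maximum field"):
            SpotMap(x_mm=[250.0], y_mm=[0.0], mu=[1.0], energy_MeV=160.0)
        with pytest.raises(ValueError):
            SpotMap(x_mm=[0.0], y_mm=[0.0], mu=[-1.0], energy_MeV=160.0)


class TestSynthesizeDoseMap:
    def test_single_spot_peak_and_sigma(self, spot_model):
        spot = SpotMap(x_mm=[3.0], y_mm=[-2.0], mu=[100.0], energy_MeV=160.0)
        image = synthesize_dose_map(spot, spot_model, 0.5)
        fit = fit_spot_centroid(image)
        assert fit.x_mm == pytest.approx(3.0, abs=1e-6)
        assert fit.y_mm == pytest.approx(-2.0, abs=1e-6)
        assert fit.sigma_h_mm == pytest.approx(spot_model.sigma(160.0, "h"), rel=1e-6)
        assert fit.sigma_v_mm == pytest.approx(spot_model.sigma(160.0, "v"), rel=1e-6)

    def test_dose_integral_conservation(self, spot_model):
        spots = SpotMap(
            x_mm=[0.0, 10.0, -5.0],
            y_mm=[0.0, 5.0, -8.0],
            mu=[100.0, 50.0, 75.0],
            energy_MeV=160.0,
        )
        image = synthesize_dose_map(spots, spot_model, 0.5, margin_mm=40.0)
        assert image.integral() == pytest.approx(225.0, rel=1e-3)

    def test_dense_comb_is_flat(self, calibration):
        ic = cyclotron_current_for_nozzle(2.0, 160.0, calibration)
        plan = plan_uniform_field(100, 100, 2.5, 1.0, 160.0, ic)
        image = synthesize_dose_map(plan, pixel_pitch_mm=0.5)
        # spacing << sigma: central region flat well below 1%
        assert homogeneity_index(image) < 1.0

    def test_planned_field_dose_reached_at_centre(self, calibration):
        # absolute closure: synthesized central dose equals the request (<2%)
        for energy, spacing in ((160.0, 2.5), (160.0, 4.0), (70.0, 2.5)):
            ic = cyclotron_current_for_nozzle(2.0, energy, calibration)
            plan = plan_uniform_field(100, 100, spacing, 2.0, energy, ic)
            image = synthesize_dose_map(
                plan,
                pixel_pitch_mm=1.0,
                spot_integrals=calibrated_spot_integrals(plan, calibration),
            )
            centre = image.grid[image.grid.shape[0] // 2, image.grid.shape[1] // 2]
            assert centre == pytest.approx(2.0, rel=0.02)


class TestHomogeneityIndex:
    def test_uniform_map_is_zero(self):
        dm = DoseMap(grid=np.full((50, 50), 3.3), pixel_pitch_mm=1.0)
        assert homogeneity_index(dm) == 0.0

    def test_direct_arithmetic(self):
        grid = np.full((40, 40), 1.0)
        grid[20, 20] = 1.03
        grid[20, 21] = 0.97
        dm = DoseMap(grid=grid, pixel_pitch_mm=1.0)
        assert homogeneity_index(dm, central_fraction=1.0) == pytest.approx(3.0)

    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=30, deadline=None)
    def test_scale_invariance(self, scale):
        rng = np.random.default_rng(7)
        grid = 1.0 + 0.05 * rng.random((30, 30))
        dm = DoseMap(grid=grid, pixel_pitch_mm=1.0)
        dm_scaled = DoseMap(grid=scale * grid, pixel_pitch_mm=1.0)
        assert homogeneity_index(dm_scaled) == pytest.approx(
            homogeneity_index(dm), rel=1e-9
        )

    def test_zero_map_rejected(self):
        dm = DoseMap(grid=np.zeros((20, 20)), pixel_pitch_mm=1.0)
        with pytest.raises(ValueError):
            homogeneity_index(dm)

    def test_synthetic_fields_meet_tolerance_across_grid(self, config, calibration):
        # 200 x 200 mm, 2.5 mm spacing, noiseless: HI below 3% at every energy
        for energy in config.energy_grid():
            ic = cyclotron_current_for_nozzle(2.0, energy, calibration)
            plan = plan_uniform_field(200, 200, 2.5, 0.5, energy, ic)
            image = synthesize_dose_map(plan, pixel_pitch_mm=1.0)
            assert homogeneity_index(image) < 3.0


class TestFitSpotCentroid:
    def test_noisy_centroid_within_bound(self):
        image = simulate_lynx_image(
            [(3.0, -2.0, 100.0)], 160.0, noise_rel=0.01, seed=0
        )
        fit = fit_spot_centroid(image)
        assert abs(fit.x_mm - 3.0) < 0.05
        assert abs(fit.y_mm + 2.0) < 0.05

    def test_repeatability_under_jitter(self):
        # three repeat deliveries with 0.03 mm positional jitter
        fits = [
            fit_spot_centroid(
                simulate_lynx_image([(0.0, 0.0, 100.0)], 245.0, jitter_mm=0.03, seed=s)
            )
            for s in (11, 12, 13)
        ]
        centroids = np.array([(f.x_mm, f.y_mm) for f in fits])
        assert np.mean(centroids.std(axis=0, ddof=1)) < 0.1

    def test_blank_image_rejected(self):
        with pytest.raises(ValueError):
            fit_spot_centroid(DoseMap(grid=np.zeros((20, 20)), pixel_pitch_mm=1.0))


class TestDeliveryTiming:
    def test_zero_mu_plan_is_transit_only(self, calibration, config):
        # serpentine transit for an n x m grid: within-row hops at v_h,
        # row changes at v_v
        n = 5
        xs, ys = np.meshgrid(
            np.arange(n) * 10.0 - 20.0, np.arange(n) * 10.0 - 20.0
        )
        plan = SpotMap(
            x_mm=xs.ravel(),
            y_mm=ys.ravel(),
            mu=np.zeros(n * n),
            energy_MeV=245.0,
            cyclotron_current_nA=800.0,
        )
        total = delivery_time(plan, calibration=calibration, config=config)
        v_h = 10.64e3  # mm/s at 245 MeV
        v_v = 2.75e3
        expected = n * (n - 1) * 10.0 / v_h + (n - 1) * 10.0 / v_v
        assert total == pytest.approx(expected, rel=1e-9)

    def test_beam_on_component_linear_in_mu(self, calibration, config):
        plan = plan_uniform_field(20, 20, 5.0, 2.0, 160.0, 200.0)
        doubled = SpotMap(
            x_mm=plan.x_mm,
            y_mm=plan.y_mm,
            mu=2 * plan.mu,
            energy_MeV=plan.energy_MeV,
            cyclotron_current_nA=plan.cyclotron_current_nA,
            spacing_mm=plan.spacing_mm,
            field_size_mm=plan.field_size_mm,
        )
        zero = SpotMap(
            x_mm=plan.x_mm,
            y_mm=plan.y_mm,
            mu=0 * plan.mu,
            energy_MeV=plan.energy_MeV,
            cyclotron_current_nA=plan.cyclotron_current_nA,
        )
        t1 = delivery_time(plan, calibration=calibration, config=config)
        t2 = delivery_time(doubled, calibration=calibration, config=config)
        t0 = delivery_time(zero, calibration=calibration, config=config)
        assert t2 - t0 == pytest.approx(2.0 * (t1 - t0), rel=1e-9)


class TestSpotPeakDoseRate:
    def test_reference_identity(self):
        assert spot_peak_dose_rate(245.0, 800.0) == pytest.approx(171.93, rel=1e-12)

    def test_printed_scaled_values(self):
        # scaling by transmission and power-law spot area
        assert spot_peak_dose_rate(240.0, 800.0) == pytest.approx(112.65, abs=0.005)
        assert spot_peak_dose_rate(70.0, 800.0) == pytest.approx(0.05, abs=0.005)

    @given(current=st.floats(min_value=1.0, max_value=800.0))
    @settings(max_examples=30, deadline=None)
    def test_linear_in_current(self, current):
        base = spot_peak_dose_rate(200.0, 100.0)
        assert spot_peak_dose_rate(200.0, current) == pytest.approx(
            base * current / 100.0, rel=1e-12
        )


class TestDetectorAveragedRate:
    def test_point_detector_limit(self):
        assert detector_averaged_rate(100.0, 4.0, 4.0, 0.0) == 100.0
        tiny = detector_averaged_rate(100.0, 4.0, 4.0, 1e-8)
        assert tiny == pytest.approx(100.0, rel=1e-6)

    def test_closed_form_circular_case(self):
        peak, sigma, area = 100.0, 4.4867, 3.8
        r2 = area / math.pi
        expected = peak * (2 * sigma**2 / r2) * (1 - math.exp(-r2 / (2 * sigma**2)))
        assert detector_averaged_rate(peak, sigma, sigma, area) == pytest.approx(
            expected, rel=1e-12
        )

    def test_quadrature_matches_closed_form(self):
        peak, sigma, area = 171.93, 4.4867, 3.8
        closed = detector_averaged_rate(peak, sigma, sigma, area, method="closed")
        quad = detector_averaged_rate(peak, sigma, sigma, area, method="quadrature")
        assert abs(quad / closed - 1) < 1e-4  # < 0.01%

    def test_elliptical_below_peak(self):
        out = detector_averaged_rate(100.0, 4.4867, 5.848, 3.8)
        assert 0 < out < 100.0


class TestFieldAverageDoseRate:
    def test_single_spot_equals_instantaneous(self, calibration, config, spot_model):
        plan = SpotMap(
            x_mm=[0.0],
            y_mm=[0.0],
            mu=[100.0],
            energy_MeV=160.0,
            cyclotron_current_nA=200.0,
            spacing_mm=2.5,
        )
        _, rates, _ = field_average_dose_rate(
            plan,
            calibration=calibration,
            config=config,
            points_mm=np.array([[0.0, 0.0]]),
        )
        _, t0, t1 = delivery_schedule(plan, calibration=calibration, config=config)
        sh = spot_model.sigma(160.0, "h")
        sv = spot_model.sigma(160.0, "v")
        inst = (
            calibrated_spot_integrals(plan, calibration)[0]
            / (2 * math.pi * sh * sv)
            / (t1[0] - t0[0])
        )
        assert rates[0] == pytest.approx(inst, rel=1e-12)

    def test_two_pulse_definition_arithmetic(self, calibration, config):
        # two equal-MU spots: dose / (2*pulse + gap) at any point
        plan = SpotMap(
            x_mm=[-10.0, 10.0],
            y_mm=[0.0, 0.0],
            mu=[50.0, 50.0],
            energy_MeV=160.0,
            cyclotron_current_nA=200.0,
            spacing_mm=2.5,
        )
        point = np.array([[0.0, 0.0]])
        _, rates, _ = field_average_dose_rate(
            plan, calibration=calibration, config=config, points_mm=point
        )
        _, t0, t1 = delivery_schedule(plan, calibration=calibration, config=config)
        pulse = t1[0] - t0[0]
        gap = t0[1] - t1[0]
        sh = 6.10542485177108  # power-law sigmas at 160 MeV
        sv = 7.651856758027787
        dose = sum(
            integral
            / (2 * math.pi * sh * sv)
            * math.exp(-(x**2) / (2 * sh**2))
            for integral, x in zip(
                calibrated_spot_integrals(plan, calibration), (-10.0, 10.0)
            )
        )
        assert rates[0] == pytest.approx(dose / (2 * pulse + gap), rel=1e-6)

    def test_brute_force_time_trace_oracle(self, calibration, config, spot_model):
        plan = plan_uniform_field(20, 20, 5.0, 2.0, 160.0, 200.0)  # 5x5 toy plan
        points = np.array([[0.0, 0.0], [5.0, 5.0], [-7.5, 2.5]])
        _, rates, _ = field_average_dose_rate(
            plan, calibration=calibration, config=config, points_mm=points
        )
        order, t0, t1 = delivery_schedule(plan, calibration=calibration, config=config)
        sh = spot_model.sigma(160.0, "h")
        sv = spot_model.sigma(160.0, "v")
        integrals = calibrated_spot_integrals(plan, calibration)[order]
        xs, ys = plan.x_mm[order], plan.y_mm[order]
        amps = integrals / (2 * math.pi * sh * sv)
        tgrid = np.linspace(0.0, t1[-1], 400_001)
        dt = tgrid[1] - tgrid[0]
        for (px, py), analytic in zip(points, rates):
            contrib = amps * np.exp(
                -((xs - px) ** 2) / (2 * sh**2) - ((ys - py) ** 2) / (2 * sv**2)
            )
            rate_t = np.zeros_like(tgrid)
            for c, a, b in zip(contrib, t0, t1):
                rate_t[(tgrid >= a) & (tgrid < b)] += c / (b - a)
            nz = np.flatnonzero(rate_t > 0)
            window = tgrid[nz[-1]] + dt - tgrid[nz[0]]
            brute = np.sum(rate_t) * dt / window
            assert analytic == pytest.approx(brute, rel=1e-3)

    def test_average_never_exceeds_instantaneous_maximum(
        self, calibration, config, spot_model
    ):
        plan = plan_uniform_field(20, 20, 5.0, 2.0, 160.0, 200.0)
        points = np.array([[0.0, 0.0], [10.0, -10.0]])
        _, rates, _ = field_average_dose_rate(
            plan, calibration=calibration, config=config, points_mm=points
        )
        order, t0, t1 = delivery_schedule(plan, calibration=calibration, config=config)
        sh = spot_model.sigma(160.0, "h")
        sv = spot_model.sigma(160.0, "v")
        amps = calibrated_spot_integrals(plan, calibration)[order] / (
            2 * math.pi * sh * sv
        )
        xs, ys = plan.x_mm[order], plan.y_mm[order]
        for (px, py), avg in zip(points, rates):
            contrib = amps * np.exp(
                -((xs - px) ** 2) / (2 * sh**2) - ((ys - py) ** 2) / (2 * sv**2)
            )
            inst_max = np.max(contrib / (t1 - t0))
            assert avg <= inst_max * (1 + 1e-12)

    def test_dose_rate_model_validation(self):
        with pytest.raises(ValueError):
            DoseRateModel(ref_peak_rate_Gy_per_s=-1.0)
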