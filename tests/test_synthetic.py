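"""Unit and property tests for the synthetic-data generators."""

import math

import numpy as np
import pytest
from scipy.special import ive

import guvfrap as g
from guvfrap import InvalidParameterError, SimConfig
from guvfrap.synthetic import CompositionSimConfig


class TestSoumpasisFractional:
    def test_full_recovery_limit(self):
        tau = 1.0  # w=2, D=1
        assert g.soumpasis_fractional(1e6 * tau, 2.0, 1.0) == pytest.approx(1.0, abs=1e-3)

    def test_zero_time_is_zero(self):
        assert g.soumpasis_fractional(0.0, 2.0, 1.0) == 0.0

    @pytest.mark.parametrize(
        "t_over_tau, expected",
        [
            # Bessel-series oracle: f = e^-x (I0(x)+I1(x)) at x = 2 tau/t
            (2.0, float(ive(0, 1.0) + ive(1, 1.0))),  # ~0.6737
            (1.0, float(ive(0, 2.0) + ive(1, 2.0))),  # ~0.5238
        ],
    )
    def test_bessel_checkpoints(self, t_over_tau, expected):
        tau = 2.0**2 / 4.0
        assert g.soumpasis_fractional(t_over_tau * tau, 2.0, 1.0) == pytest.approx(
            expected, abs=1e-12
        )
        # frozen decimal values from summing the Bessel series independently
        assert {2.0: 0.6737, 1.0: 0.5238}[t_over_tau] == pytest.approx(expected, abs=1e-4)

    def test_monotone_in_t_and_D(self):
        t = np.linspace(0.0, 50.0, 400)
        f = g.soumpasis_fractional(t, 2.0, 1.0)
        assert np.all(np.diff(f) >= -1e-12)
        f_fast = g.soumpasis_fractional(t[1:], 2.0, 2.0)
        assert np.all(f_fast > g.soumpasis_fractional(t[1:], 2.0, 1.0))

    @pytest.mark.parametrize("w,D", [(0.0, 1.0), (-1.0, 1.0), (2.0, 0.0), (2.0, -3.0)])
    def test_invalid_parameters(self, w, D):
        with pytest.raises(InvalidParameterError):
            g.soumpasis_fractional(1.0, w, D)


class TestHalfTimeConstant:
    def test_value_matches_convention(self):
        c = g.solve_half_time_constant()
        assert round(c, 3) == 0.224
        assert c == pytest.approx(0.2236, abs=5e-5)

    def test_independent_of_w_and_D(self):
        c1 = g.solve_half_time_constant(w=2.0, D=1.0)
        c2 = g.solve_half_time_constant(w=5.0, D=0.3)
        assert c1 == pytest.approx(c2, abs=1e-5)

    def test_against_dense_grid_argmin(self):
        # brute-force oracle: argmin |f - 1/2| on a dense time grid
        w, D = 2.0, 1.0
        t = np.linspace(1e-4, 10.0, 200_001)
        f = g.soumpasis_fractional(t, w, D)
        t_half_grid = t[np.argmin(np.abs(f - 0.5))]
        c = g.solve_half_time_constant(w, D)
        assert c * w**2 / D == pytest.approx(t_half_grid, abs=(t[1] - t[0]))


class TestGenerateTrace:
    def test_noise_free_construction(self):
        cfg = SimConfig(D_true=1.0, beta=0.8, M_true=1.0, F_pre=100.0,
                        sigma_noise=0.0, curve_model="closed_form")
        tr = g.generate_trace(cfg)
        assert np.all(tr.pre_intensities == 100.0)
        assert tr.recovery_intensities[0] == pytest.approx(20.0)
        # the closed-form tail approaches F_pre as ~1 - tau/t; check at long t
        long = g.FrameSchedule(n_pre=8, t_bleach=0.1, n_post=100, dt=10.0)
        tr_long = g.generate_trace(
            g.SimConfig(D_true=1.0, beta=0.8, M_true=1.0, F_pre=100.0,
                        sigma_noise=0.0, curve_model="closed_form", schedule=long)
        )
        assert tr_long.recovery_intensities[-1] == pytest.approx(100.0, rel=0.01)
        assert np.all(np.diff(tr.recovery_intensities) >= -1e-9)

    def test_immobile_limit_is_flat(self):
        cfg = SimConfig(D_true=1.0, M_true=0.0, sigma_noise=0.0)
        tr = g.generate_trace(cfg)
        assert np.allclose(tr.recovery_intensities, tr.recovery_intensities[0])

    def test_half_recovery_at_predicted_time(self):
        # t_half = c w^2 / D lands on a frame when dt divides it
        c = g.solve_half_time_constant()
        D, w = 1.0, 2.0
        t_half = c * w**2 / D
        sched = g.FrameSchedule(n_pre=8, t_bleach=0.1, n_post=40, dt=t_half / 4)
        cfg = SimConfig(D_true=D, w=w, beta=0.8, M_true=1.0, F_pre=100.0,
                        sigma_noise=0.0, curve_model="closed_form", schedule=sched)
        tr = g.generate_trace(cfg)
        midpoint = (20.0 + 100.0) / 2
        assert tr.recovery_intensities[4] == pytest.approx(midpoint, abs=1e-3 * 100)

    def test_deterministic_under_seed(self):
        cfg = SimConfig(D_true=1.2, sigma_noise=5.0, seed=42)
        a = g.generate_trace(cfg)
        b = g.generate_trace(cfg)
        assert np.array_equal(a.intensities, b.intensities)

    def test_invalid_config_raises(self):
        with pytest.raises(InvalidParameterError):
            SimConfig(D_true=-1.0)
        with pytest.raises(InvalidParameterError):
            SimConfig(beta=0.0)
        with pytest.raises(InvalidParameterError):
            SimConfig(reservoir_radius=1.0, w=2.0)


class TestLatticeOracle:
    def test_frozen_particles_no_recovery(self):
        cfg = SimConfig(D_true=1e-12, curve_model="lattice", M_true=1.0,
                        reservoir_radius=40.0, seed=3)
        tr = g.simulate_lattice_frap(cfg, n_particles=5_000)
        assert np.ptp(tr.recovery_intensities) < 1.0  # flat up to shot noise

    def test_finite_reservoir_caps_plateau(self):
        cfg = SimConfig(D_true=1.0, curve_model="lattice", M_true=1.0,
                        reservoir_radius=4.0, seed=3)
        tr = g.simulate_lattice_frap(cfg, n_particles=20_000)
        f = (tr.recovery_intensities - tr.recovery_intensities[0]) / (
            100.0 - tr.recovery_intensities[0]
        )
        plateau = f[-8:].mean()
        assert plateau < 0.9
        assert plateau == pytest.approx(1 - (2.0 / 4.0) ** 2, abs=0.05)

    def test_matches_closed_form_quick(self):
        # small-n version; the full N=1e5 check lives in the acceptance suite
        cfg = SimConfig(D_true=1.0, curve_model="lattice", M_true=1.0,
                        reservoir_radius=40.0, seed=7)
        tr = g.simulate_lattice_frap(cfg, n_particles=30_000)
        f = (tr.recovery_intensities - tr.recovery_intensities[0]) / (
            100.0 - tr.recovery_intensities[0]
        )
        f_cf = g.soumpasis_fractional(tr.recovery_times, 2.0, 1.0)
        assert np.max(np.abs(f - f_cf)) < 0.05

    def test_requires_finite_reservoir_and_lattice_model(self):
        with pytest.raises(InvalidParameterError):
            g.simulate_lattice_frap(SimConfig(curve_model="lattice", reservoir_radius=None))
        with pytest.raises(InvalidParameterError):
            g.simulate_lattice_frap(SimConfig(curve_model="closed_form"))
        with pytest.raises(InvalidParameterError):
            g.simulate_lattice_frap(
                SimConfig(curve_model="lattice"), n_particles=10
            )


@pytest.fixture(scope="module")
def rendered():
    cfg = SimConfig(D_true=1.0, beta=1.0, M_true=1.0, sigma_noise=0.0,
                    curve_model="closed_form", reservoir_radius=20.0, seed=1)
    return cfg, g.render_frap_stack(cfg, pixel_size=0.2)


class TestRenderFrapStack:
    def test_full_bleach_first_recovery_frame(self, rendered):
        cfg, stack = rendered
        c = stack.metadata["spot_center_y_um"]
        tr = g.extract_trace(stack, (c, c), cfg.w)
        assert tr.recovery_intensities[0] < 0.05 * cfg.F_pre

    def test_pre_bleach_spot_equals_disc_mean(self, rendered):
        cfg, stack = rendered
        frame = stack.frames[0]
        c = stack.metadata["spot_center_y_um"]
        tr = g.extract_trace(stack, (c, c), cfg.w)
        disc_mean = frame[frame > 0].mean()
        assert tr.intensities[0] == pytest.approx(disc_mean, rel=1e-6)

    def test_invalid_pixel_size(self):
        with pytest.raises(InvalidParameterError):
            g.render_frap_stack(SimConfig(), pixel_size=0.0)


class TestCompositionGenerator:
    def test_noise_free_exact_proportionality(self):
        cfg = CompositionSimConfig(sigma_noise=0.0, brightness_per_unit=10.0,
                                   n_vesicles_per_group=4)
        ds = g.generate_composition_dataset(cfg)
        means = ds.records.groupby("x_rel")["intensity"].mean()
        assert means.loc[1.0] == 10.0 and means.loc[2.0] == 20.0 and means.loc[3.0] == 30.0

    def test_deterministic_under_seed(self):
        cfg = CompositionSimConfig(sigma_noise=1.0, seed=5)
        a = g.generate_composition_dataset(cfg)
        b = g.generate_composition_dataset(cfg)
        assert a.records.equals(b.records)

    def test_group_means_within_clt_bound(self):
        cfg = CompositionSimConfig(sigma_noise=1.0, brightness_per_unit=10.0,
                                   n_vesicles_per_group=50, seed=11)
        ds = g.generate_composition_dataset(cfg)
        sem = 1.0 / math.sqrt(50)
        for x, sub in ds.records.groupby("x_rel"):
            assert abs(sub["intensity"].mean() - 10.0 * x) < 3 * sem

    def test_empty_groups_rejected(self):
        with pytest.raises(InvalidParameterError):
            CompositionSimConfig(groups=())


class TestCohorts:
    def test_counts_and_labels(self):
        presets = {"a": SimConfig(D_true=1.0), "b": SimConfig(D_true=2.0)}
        traces = g.generate_cohort(presets, 5, seed=1)
        assert len(traces) == 10
        assert sorted({t.condition for t in traces}) == ["a", "b"]

    def test_zero_count_rejected(self):
        with pytest.raises(InvalidParameterError):
            g.generate_cohort({"a": SimConfig()}, 0)

    def test_presets_carry_reported_condition_means(self):
        p = g.CONDITION_PRESETS["electro_DOPC"]
        assert (p.D, p.n) == (1.0, 17)
        assert g.CONDITION_PRESETS["ola_DOPC"].D == 1.1
        assert g.CONDITION_PRESETS["electro_DOPC_37C_0gly"].n == 7
        cfg = g.preset_config("electro_DOPC", sigma_noise=0.0)
        assert cfg.D_true == 1.0 and cfg.curve_model == "exponential_model"
        with pytest.raises(InvalidParameterError):
            g.preset_config("no_such_condition")
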