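"""Tests for the synthetic pulsatile stenotic-flow generator."""

import dataclasses

import numpy as np
import pytest
from scipy.special import i0e, i1e

from turflow import (
    CardiacWaveform,
    ConfigurationError,
    FlowConfig,
    compute_tur,
    frames_per_cycle,
    generate_laminar,
    generate_noise_field,
    generate_stenotic,
    tur_series,
)
from turflow.cine import cycle_mean_tur


def expected_tur(kappa: float) -> float:
    """Closed-form expected Tur of von Mises angles: (1 - I1/I0) * 100."""
    return (1.0 - i1e(kappa) / i0e(kappa)) * 100.0


class TestConfig:
    def test_default_loop_has_570_frames(self):
        """1.5 s at 380 Hz gives 570 frames, inside the 500-600 frame regime."""
        config = FlowConfig()
        assert config.n_frames == 570
        assert 500 <= config.n_frames <= 600

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(vessel_diameter=20.0),            # lumen outside image depth
            dict(stenosis_position=30.0),          # stenosis outside image
            dict(stenosis_severity=1.0),
            dict(stenosis_severity=-0.1),
            dict(kappa=-1.0),
            dict(grid_spacing=0.0),
            dict(duration=-1.0),
        ],
    )
    def test_invalid_geometry_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            FlowConfig(**kwargs)

    def test_stenotic_requires_severity(self, small_config):
        with pytest.raises(ConfigurationError):
            generate_stenotic(small_config)


class TestWaveform:
    def test_periodic_and_bounded(self):
        wf = CardiacWaveform()
        t = np.linspace(0.0, 2.0, 1001)
        w = wf(t, heart_rate=120.0)
        assert np.all(w >= wf.diastolic_floor - 1e-12)
        assert np.all(w <= 1.0 + 1e-12)
        # exact systolic peak at phase = systolic_fraction / 2
        t_peak = wf.systolic_fraction / 2.0 * 60.0 / 120.0
        assert wf(t_peak, 120.0) == pytest.approx(1.0, abs=1e-12)
        period = 60.0 / 120.0
        assert wf(0.123, 120.0) == pytest.approx(wf(0.123 + period, 120.0), abs=1e-12)

    def test_constant_shape(self):
        wf = CardiacWaveform(shape="constant")
        assert np.all(wf(np.linspace(0, 1, 50), 120.0) == 1.0)


class TestLaminar:
    def test_deterministic_for_fixed_seed(self, small_config):
        a = generate_laminar(small_config)
        b = generate_laminar(small_config)
        assert np.array_equal(a.vx, b.vx) and np.array_equal(a.vy, b.vy)
        c = generate_laminar(dataclasses.replace(small_config, seed=124))
        assert not np.array_equal(a.vx, c.vx)

    def test_infinite_kappa_gives_exactly_axial_flow(self, small_config):
        """kappa -> infinity: no jitter, every in-lumen angle exactly 0 and
        any in-lumen ROI has Tur = 0."""
        loop = generate_laminar(dataclasses.replace(small_config, kappa=np.inf))
        assert np.all(loop.vy == 0.0)
        series = tur_series(loop, loop.lumen_roi(center_x=10.0))
        assert np.all(series.values == pytest.approx(0.0, abs=1e-10))

    @pytest.mark.parametrize("kappa", [2000.0, 5000.0])
    def test_high_concentration_keeps_cycle_mean_below_one_percent(
        self, small_config, kappa
    ):
        """The laminar regime: kappa >= 2000 keeps cycle-mean Tur of any
        in-lumen ROI under the 1% turbulence threshold."""
        loop = generate_laminar(dataclasses.replace(small_config, kappa=kappa))
        n = frames_per_cycle(loop.frame_rate, loop.heart_rate)
        for center in (4.0, 11.0, 19.0):
            series = tur_series(loop, loop.lumen_roi(center_x=center))
            assert cycle_mean_tur(series, n) < 1.0

    def test_parabolic_profile_at_systole(self, small_config):
        """Within the lumen the speed follows u_peak * w(t) * (1-(2y/D)^2)."""
        loop = generate_laminar(dataclasses.replace(small_config, kappa=np.inf))
        w = CardiacWaveform()(loop.times(), loop.heart_rate)
        i = int(np.argmax(w))
        rel = 2.0 * (loop.y - loop.lumen_center_y) / loop.vessel_diameter
        inside = np.abs(rel) < 1.0
        profile = loop.vx[i][inside, 50]
        expected = small_config.peak_velocity * w[i] * (1.0 - rel[inside] ** 2)
        np.testing.assert_allclose(profile, expected, atol=1e-9)
        outside = np.abs(rel) > 1.0 + 1e-9
        assert np.all(loop.vx[i][outside, :] == 0.0)


class TestStenotic:
    def test_zero_vortex_strength_identical_to_laminar(self, small_config):
        config = dataclasses.replace(
            small_config, stenosis_severity=0.5, vortex_strength=0.0
        )
        stenotic = generate_stenotic(config)
        laminar = generate_laminar(config)
        assert np.array_equal(stenotic.vx, laminar.vx)
        assert np.array_equal(stenotic.vy, laminar.vy)

    def test_deterministic_for_fixed_seed(self, small_config):
        config = dataclasses.replace(small_config, stenosis_severity=0.5)
        a = generate_stenotic(config)
        b = generate_stenotic(config)
        assert np.array_equal(a.vx, b.vx) and np.array_equal(a.vy, b.vy)

    def test_throat_centerline_velocity_raised_by_flux_conservation(self, small_config):
        """At the narrowest point the centreline velocity rises by
        1/(1-severity)^2."""
        # 0.1 mm grid so the throat centre and lumen centreline are on-grid
        config = FlowConfig(
            frame_rate=100.0, duration=0.1, grid_spacing=0.1,
            stenosis_severity=0.5, vortex_strength=0.0, kappa=np.inf,
        )
        loop = generate_stenotic(config)
        w = CardiacWaveform()(loop.times(), loop.heart_rate)
        i = int(np.argmax(w))
        iy = int(np.argmin(np.abs(loop.y - loop.lumen_center_y)))
        throat_x = config.stenosis_position - config.vessel_diameter / 2.0
        ix = int(np.argmin(np.abs(loop.x - throat_x)))
        expected = config.peak_velocity * w[i] / (1.0 - 0.5) ** 2
        assert loop.vx[i, iy, ix] == pytest.approx(expected, rel=1e-6)

    def test_upstream_of_stenosis_matches_laminar(self, small_config):
        """Upstream of the stenotic taper the field is the laminar base."""
        config = dataclasses.replace(small_config, stenosis_severity=0.5)
        stenotic = generate_stenotic(config)
        laminar = generate_laminar(dataclasses.replace(config, stenosis_severity=0.0))
        upstream = stenotic.x < config.stenosis_position - config.vessel_diameter - 1e-9
        assert np.array_equal(stenotic.vx[:, :, upstream], laminar.vx[:, :, upstream])

    def test_severity_monotonicity(self, small_config):
        """With a fixed seed, raising severity 0.5 -> 0.7 does not lower the
        cycle-mean Tur at any measured distance."""
        from turflow import build_profile

        lo = build_profile(
            generate_stenotic(dataclasses.replace(small_config, stenosis_severity=0.5))
        )
        hi = build_profile(
            generate_stenotic(dataclasses.replace(small_config, stenosis_severity=0.7))
        )
        assert np.all(hi.cycle_mean_tur >= lo.cycle_mean_tur)


class TestNoiseField:
    def test_closed_form_oracle_at_moderate_concentration(self):
        """kappa = 2, n = 1e5: empirical Tur within Monte-Carlo error of
        (1 - I1(2)/I0(2)) * 100 ~ 30.2%."""
        sample = generate_noise_field(100_000, kappa=2.0, seed=11)
        assert compute_tur(sample).tur == pytest.approx(expected_tur(2.0), abs=0.5)

    def test_high_concentration_tur_tiny(self):
        """kappa = 5000: Tur ~ 100/(2 kappa) = 0.01% < 0.02%."""
        for seed in (0, 1, 2):
            sample = generate_noise_field(50_000, kappa=5000.0, seed=seed)
            assert compute_tur(sample).tur < 0.02

    def test_uniform_angles_approach_full_turbulence(self):
        """kappa = 0 is the circular uniform law: expected Tur -> 100% as n
        grows (the resultant shrinks like 1/sqrt(n))."""
        sample = generate_noise_field(200_000, kappa=0.0, seed=3)
        assert compute_tur(sample).tur > 99.0

    def test_convergence_rate_consistent_with_sqrt_n(self):
        """|empirical - closed form| shrinks roughly like 1/sqrt(n)."""
        kappa = 2.0
        errors = {}
        for n in (1_000, 100_000):
            errs = [
                abs(compute_tur(generate_noise_field(n, kappa, seed)).tur - expected_tur(kappa))
                for seed in range(8)
            ]
            errors[n] = np.mean(errs)
        # a factor-100 increase in n should shrink the error about tenfold
        assert errors[100_000] < errors[1_000] / 3.0

    def test_preconditions(self):
        with pytest.raises(ValueError):
            generate_noise_field(0, kappa=1.0, seed=0)
        with pytest.raises(ValueError):
            generate_noise_field(10, kappa=-1.0, seed=0)
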