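"""Tests of the analytic Arnold-tongue theory against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ditherstim import (NoLockingError, TheoryConfig, TongueSpec,
                        boundary_2pm1_2, boundary_p1, fixed_points_2pm1_2,
                        fixed_points_numeric, fixed_points_p1,
                        relative_width_2pm1_2, relative_width_p1,
                        width_2pm1_2, width_p1)

FS = 130.0


def _circ(a, b):
    d = abs(a - b) % (2 * np.pi)
    return min(d, 2 * np.pi - d)


class TestFixedPointsP1:
    def test_resonant_center(self):
        fp = fixed_points_p1(130.0, FS, 1.0, 1)
        assert fp.theta_stable == pytest.approx(np.pi, abs=1e-12)
        assert fp.theta_unstable == pytest.approx(0.0, abs=1e-12)
        assert fp.trap_size == pytest.approx(np.pi, abs=1e-12)

    def test_detuned_trap_size(self):
        # h = pi + 2*asin(2*pi*(f0/fs - 1)/I) below the tongue centre
        fp = fixed_points_p1(125.0, FS, 1.0, 1)
        expect = np.pi + 2 * np.arcsin(2 * np.pi * (125 / 130 - 1))
        assert fp.trap_size == pytest.approx(expect, abs=1e-12)
        assert fp.trap_size == pytest.approx(2.6534, abs=1e-4)

    def test_superharmonic_trap_size(self):
        # f0/fs < p, so h = pi + 2*asin(2*pi*(f0/fs - p)/I) with a
        # negative argument
        fp = fixed_points_p1(255.0, FS, 1.0, 2)
        expect = np.pi + 2 * np.arcsin(2 * np.pi * (255 / 130 - 2))
        assert fp.trap_size == pytest.approx(expect, abs=1e-12)

    def test_no_locking_signalled(self):
        with pytest.raises(NoLockingError):
            fixed_points_p1(100.0, FS, 0.5, 1)


class TestFixedPoints2pm1_2:
    def test_tongue_center_half_pi(self):
        fp = fixed_points_2pm1_2(65.0, FS, 1.0, 1)
        assert fp.trap_size == pytest.approx(np.pi / 2, abs=1e-12)

    def test_detuned_1_2_trap(self):
        fp = fixed_points_2pm1_2(63.0, FS, 1.5, 1)
        expect = np.pi / 2 - abs(np.arcsin(
            8 * np.pi * (63 / 130 - 0.5) / 1.5 ** 2))
        assert fp.trap_size == pytest.approx(expect, abs=1e-12)

    def test_3_2_trap_finite(self):
        fp = fixed_points_2pm1_2(193.0, FS, 1.5, 2)
        assert 0 < fp.trap_size < np.pi

    def test_no_locking_signalled(self):
        with pytest.raises(NoLockingError):
            fixed_points_2pm1_2(70.0, FS, 0.3, 1)


class TestNumericAgreement:
    """Analytic fixed points match brute-force root finding to 1e-8."""

    def test_p1_random_draws(self):
        rng = np.random.default_rng(101)
        n_ok = 0
        while n_ok < 50:
            p = int(rng.integers(1, 4))
            I = rng.uniform(0.1, 1.8)
            f0 = FS * (p + rng.uniform(-0.9, 0.9) * I / (2 * np.pi))
            ana = fixed_points_p1(f0, FS, I, p)
            num = fixed_points_numeric(f0, FS, I, p, 1)
            assert _circ(ana.theta_stable, num.theta_stable) < 1e-8
            assert _circ(ana.theta_unstable, num.theta_unstable) < 1e-8
            assert abs(ana.trap_size - num.trap_size) < 1e-8
            n_ok += 1

    def test_2pm1_2_random_draws(self):
        rng = np.random.default_rng(202)
        n_ok = 0
        while n_ok < 50:
            p = int(rng.integers(1, 3))
            I = rng.uniform(0.3, 1.8)
            centre = (2 * p - 1) / 2
            f0 = FS * (centre + rng.uniform(-0.9, 0.9) * I * I / (8 * np.pi))
            ana = fixed_points_2pm1_2(f0, FS, I, p)
            num = fixed_points_numeric(f0, FS, I, p, 2, approximate=True)
            # the approximate map has two equivalent stable points pi apart
            d = _circ(ana.theta_stable, num.theta_stable)
            assert min(d, abs(d - np.pi)) < 1e-8
            du = _circ(ana.theta_unstable, num.theta_unstable)
            assert min(du, abs(du - np.pi)) < 1e-8
            assert abs(ana.trap_size - num.trap_size) < 1e-8
            n_ok += 1

    def test_exact_composed_map_oracle_at_small_amplitude(self):
        # the one-harmonic approximation converges (linearly in I) to the
        # exact twice-composed map as I -> 0
        errs = []
        for I in (0.6, 0.3, 0.15):
            ana = fixed_points_2pm1_2(65.0, FS, I, 1)
            num = fixed_points_numeric(65.0, FS, I, 1, 2,
                                       approximate=False)
            errs.append(abs(ana.trap_size - num.trap_size) /
                        num.trap_size)
        assert errs[0] > errs[1] > errs[2]
        assert errs[2] < 0.07


class TestBoundaries:
    def test_p1_periodic_limit(self):
        cfg = TheoryConfig(zeta=0.0, fs=FS)
        assert boundary_p1(135.0, 1, cfg) == pytest.approx(
            2 * np.pi * (135 / 130 - 1), rel=1e-12)
        assert boundary_p1(135.0, 1, cfg) == pytest.approx(0.2417, abs=1e-4)

    def test_tongue_tip_at_center(self):
        cfg = TheoryConfig(zeta=0.0, fs=FS)
        assert boundary_p1(130.0, 1, cfg) == pytest.approx(0.0, abs=1e-12)
        assert boundary_2pm1_2(65.0, 1, cfg) == pytest.approx(0.0, abs=1e-12)

    def test_2pm1_2_periodic_limit(self):
        cfg = TheoryConfig(zeta=0.0, fs=FS)
        assert boundary_2pm1_2(67.0, 1, cfg) == pytest.approx(
            np.sqrt(8 * np.pi * (67 / 130 - 0.5)), rel=1e-12)
        assert boundary_2pm1_2(67.0, 1, cfg) == pytest.approx(0.6218,
                                                             abs=1e-4)

    @pytest.mark.parametrize("zeta", [0.003, 0.009])
    def test_boundary_and_width_are_mutually_consistent(self, zeta):
        # the two f0 roots of boundary(f0) = I bracket the tongue and their
        # separation matches the Taylor width up to O(zeta^4)
        from scipy.optimize import brentq
        cfg = TheoryConfig(zeta=zeta, fs=FS)
        I = 1.0
        left = brentq(lambda f: boundary_p1(f, 1, cfg) - I, 100.0, 130.0)
        right = brentq(lambda f: boundary_p1(f, 1, cfg) - I, 130.0, 160.0)
        assert right - left == pytest.approx(width_p1(I, 1, cfg),
                                             rel=5e-3)


class TestWidths:
    def test_periodic_limits_independent_of_p(self):
        cfg = TheoryConfig(zeta=0.0, fs=FS)
        for p in (1, 2, 3):
            assert width_p1(1.0, p, cfg) == pytest.approx(FS / np.pi)
            assert width_2pm1_2(1.0, p, cfg) == pytest.approx(
                FS / (4 * np.pi))

    def test_dithered_width_value(self):
        cfg = TheoryConfig(zeta=0.09, fs=FS, n_sigma=4)
        assert width_p1(1.0, 1, cfg) == pytest.approx(14.245, abs=5e-3)

    def test_width_clamped_at_zero(self):
        cfg = TheoryConfig(zeta=0.5, fs=FS)
        assert width_p1(1.0, 3, cfg) == 0.0
        assert width_2pm1_2(1.0, 2, cfg) == 0.0

    def test_1_2_width_shrinks_with_dithering(self):
        w0 = width_2pm1_2(1.0, 1, TheoryConfig(zeta=0.0, fs=FS))
        w = width_2pm1_2(1.0, 1, TheoryConfig(zeta=0.009, fs=FS))
        assert 0 < w < w0

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(p=st.integers(1, 3), I=st.floats(0.1, 1.5))
    def test_widths_decrease_in_zeta_until_clamped(self, p, I):
        zetas = np.linspace(0.0, 0.2, 30)
        for width in (width_p1, width_2pm1_2):
            vals = [width(I, p, TheoryConfig(zeta=z, fs=FS)) for z in zetas]
            assert all(a >= b for a, b in zip(vals[:-1], vals[1:]))

    def test_higher_order_tongues_die_first(self):
        # the zeta at which a higher-order width reaches zero is strictly
        # smaller than for the 1:1 width at equal amplitude
        def zeta_kill(width, p, I):
            zetas = np.linspace(0.0, 1.0, 4000)
            for z in zetas:
                if width(I, p, TheoryConfig(zeta=z, fs=FS)) == 0.0:
                    return z
            raise AssertionError("width never clamped")

        for I in (0.3, 1.0):
            z11 = zeta_kill(width_p1, 1, I)
            assert zeta_kill(width_p1, 2, I) < z11       # 2:1
            assert zeta_kill(width_2pm1_2, 1, I) < z11   # 1:2
            assert zeta_kill(width_2pm1_2, 2, I) < z11   # 3:2


class TestRelativeWidths:
    def test_no_dithering_gives_unity(self):
        for p in (1, 2, 5):
            assert relative_width_p1(p, 0.0) == 1.0
            assert relative_width_2pm1_2(p, 0.0) == 1.0

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(zeta=st.floats(1e-4, 0.05))
    def test_core_selectivity_ordering(self, zeta):
        assert relative_width_p1(2, zeta) < relative_width_p1(1, zeta)
        assert relative_width_2pm1_2(1, zeta) < relative_width_p1(1, zeta)

    def test_matches_full_width_ratio_at_small_amplitude(self):
        zeta = 0.01
        for p in (1, 2):
            ratio = width_p1(1e-3, p, TheoryConfig(zeta=zeta, fs=FS)) / \
                width_p1(1e-3, p, TheoryConfig(zeta=0.0, fs=FS))
            assert ratio == pytest.approx(relative_width_p1(p, zeta),
                                          abs=1e-6)
        ratio = width_2pm1_2(1e-3, 1, TheoryConfig(zeta=zeta, fs=FS)) / \
            width_2pm1_2(1e-3, 1, TheoryConfig(zeta=0.0, fs=FS))
        assert ratio == pytest.approx(relative_width_2pm1_2(1, zeta),
                                      abs=1e-6)

    def test_clamped_to_unit_interval(self):
        assert relative_width_2pm1_2(3, 0.5) == 0.0


class TestSpecsAndConfigs:
    def test_tongue_spec_requires_coprime(self):
        with pytest.raises(ValueError):
            TongueSpec(2, 4)
        assert TongueSpec(3, 2).analytic
        assert not TongueSpec(2, 3).analytic

    def test_theory_config_validates_n_sigma(self):
        with pytest.raises(ValueError):
            TheoryConfig(zeta=0.0, fs=FS, n_sigma=2.0)
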