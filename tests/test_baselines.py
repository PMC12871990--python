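"""Aspect-ratio, Fourier-descriptor and elastic (SRVF) contour distances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cellph as cp
from cellph.baselines import resample_closed
from cellph.errors import GeometryError, ParameterError

from .conftest import polygon_contour, rigid


def ellipse(a=2.0, b=1.0, n=64, phase=0.0, power=1.0):
    """Ellipse sampled at n parameter values t^power (power!=1 reparameterizes)."""
    t = 2 * np.pi * (np.arange(n) / n) ** power + phase
    return cp.Contour(np.column_stack([a * np.cos(t), b * np.sin(t)]), id="ellipse")


class TestAspectRatio:
    def test_regular_polygon_is_isotropic(self, circle64):
        assert cp.aspect_ratio(circle64).value == pytest.approx(1.0, abs=1e-6)

    def test_ellipse_variance_ratio(self):
        # var(2 cos t) = 2, var(sin t) = 1/2 under uniform t sampling
        assert cp.aspect_ratio(ellipse(2, 1, 256)).value == pytest.approx(4.0, abs=1e-3)

    def test_rotation_invariance(self):
        c = ellipse(3, 1, 128)
        rot = cp.Contour(rigid(c.points, np.deg2rad(37), (5, -2)), id="rot")
        assert cp.aspect_ratio(rot).value == pytest.approx(cp.aspect_ratio(c).value, rel=1e-9)

    def test_sqrt_variant_halves_log(self):
        c = ellipse(2, 1, 256)
        a = cp.aspect_ratio(c).value
        assert cp.aspect_ratio(c, sqrt=True).value == pytest.approx(np.sqrt(a), rel=1e-12)

    def test_collinear_points_degenerate(self):
        # a "contour" object can't be built collinear, so call on a thin sliver
        thin = cp.Contour([[0, 0], [10, 1e-9], [20, 0], [10, -1e-9]], id="thin")
        with pytest.raises(GeometryError):
            cp.aspect_ratio(thin)


class TestAspectDistance:
    def test_zero_iff_equal_elongation(self):
        a = cp.AspectRatio(3.7)
        assert cp.aspect_distance(a, a) == 0.0

    def test_multiplicative_symmetry(self):
        d24 = cp.aspect_distance(cp.AspectRatio(2), cp.AspectRatio(4))
        d48 = cp.aspect_distance(cp.AspectRatio(4), cp.AspectRatio(8))
        assert d24 == pytest.approx(d48) == pytest.approx(np.log(2))

    def test_unit_distance(self):
        assert cp.aspect_distance(cp.AspectRatio(1.0), cp.AspectRatio(np.e)) == pytest.approx(1.0)

    def test_triangle_inequality_random(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            a, b, c = (cp.AspectRatio(v) for v in rng.uniform(1, 20, 3))
            assert cp.aspect_distance(a, c) <= cp.aspect_distance(a, b) + cp.aspect_distance(b, c) + 1e-12

    @given(st.floats(min_value=1, max_value=1e6), st.floats(min_value=1, max_value=1e6))
    @settings(derandomize=True, deadline=None)
    def test_symmetry_and_nonnegativity_property(self, a, b):
        d = cp.aspect_distance(cp.AspectRatio(a), cp.AspectRatio(b))
        assert d >= 0
        assert d == cp.aspect_distance(cp.AspectRatio(b), cp.AspectRatio(a))


class TestFourierDescriptor:
    def test_centering_zeroes_f0(self):
        c, _ = cp.lobed_contour(3, 2, 5, n_points=100, noise_sd=0.3, seed=1)
        pts = resample_closed(c.points, 256)
        z = pts[:, 0] + 1j * pts[:, 1]
        z = z - z.mean()
        assert abs(np.fft.fft(z)[0] / 256) < 1e-12

    def test_circle_energy_in_first_harmonic(self, circle64):
        fd = cp.fourier_descriptor(circle64, M=8)
        assert fd.magnitudes[0] == pytest.approx(10.0, rel=1e-2)
        assert np.all(fd.magnitudes[1:] < 0.05)

    def test_rotation_and_start_point_invariance(self):
        c = polygon_contour([5, 3, 6, 2, 7, 3.5, 4, 2.5], id="blob")
        base = cp.fourier_descriptor(c, M=3, n_resample=256).magnitudes
        rot = cp.Contour(rigid(c.points, 1.1, (4, 4)), id="rot")
        np.testing.assert_allclose(cp.fourier_descriptor(rot, M=3, n_resample=256).magnitudes, base, atol=1e-9)
        # starting-point shifts: exact on a regular polygon (start-invariant
        # resampling); within resampling tolerance on an irregular one
        shifted = cp.Contour(np.roll(c.points, 3, axis=0), id="shift")
        np.testing.assert_allclose(
            cp.fourier_descriptor(shifted, M=3, n_resample=256).magnitudes, base, atol=1e-4
        )
        t = 2 * np.pi * np.arange(64) / 64
        reg = cp.Contour(np.column_stack([7 * np.cos(t), 7 * np.sin(t)]), id="reg")
        reg_shift = cp.Contour(np.roll(reg.points, 17, axis=0), id="regshift")
        np.testing.assert_allclose(
            cp.fourier_descriptor(reg_shift, M=3).magnitudes,
            cp.fourier_descriptor(reg, M=3).magnitudes,
            atol=1e-12,
        )

    def test_invalid_harmonic_count(self):
        with pytest.raises(ParameterError):
            cp.fourier_descriptor(polygon_contour([1, 2, 1.5, 2.5]), M=200, n_resample=256)


class TestFourierDistance:
    def test_self_distance_zero(self, circle64):
        fd = cp.fourier_descriptor(circle64, M=10)
        assert cp.fourier_distance(fd, fd) == 0.0

    def test_circles_differ_by_radius(self):
        t = 2 * np.pi * np.arange(128) / 128
        c1 = cp.Contour(np.column_stack([np.cos(t), np.sin(t)]), id="r1")
        c2 = cp.Contour(np.column_stack([2 * np.cos(t), 2 * np.sin(t)]), id="r2")
        d = cp.fourier_distance(cp.fourier_descriptor(c1, M=10), cp.fourier_descriptor(c2, M=10))
        assert d == pytest.approx(1.0, abs=1e-2)

    def test_symmetry_and_length_check(self):
        rng = np.random.default_rng(5)
        f1 = cp.FourierDescriptor(rng.uniform(0, 3, 6), 6)
        f2 = cp.FourierDescriptor(rng.uniform(0, 3, 6), 6)
        assert cp.fourier_distance(f1, f2) == cp.fourier_distance(f2, f1)
        with pytest.raises(ParameterError):
            cp.fourier_distance(f1, cp.FourierDescriptor(np.ones(4), 4))


class TestElasticDistance:
    def test_self_distance_zero(self):
        c = polygon_contour([5, 3, 6, 2, 7, 3.5], id="blob")
        assert cp.elastic_distance(c, c, n=64) == pytest.approx(0.0, abs=1e-8)

    def test_rotation_invariance(self, circle64):
        star, _ = cp.lobed_contour(4, 5, 12, n_points=96)
        rot = cp.Contour(rigid(star.points, 0.7, (0, 0)), id="rot")
        assert cp.elastic_distance(star, rot, n=64) == pytest.approx(0.0, abs=1e-6)

    def test_reparameterization_near_invariance(self):
        # the same polygon traced at a strongly non-uniform speed
        c1 = ellipse(2, 1, 64)
        closed = np.vstack([c1.points, c1.points[:1]])
        seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        u = (np.arange(512) / 512) ** 1.5 * s[-1]
        pts2 = np.column_stack([np.interp(u, s, closed[:, 0]), np.interp(u, s, closed[:, 1])])
        c2 = cp.Contour(pts2, id="reparam")
        assert cp.elastic_distance(c1, c2, n=128) <= 1e-2

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        for seed in range(3):
            c1, _ = cp.lobed_contour(3, 4, 9, n_points=72, noise_sd=0.5, seed=seed)
            c2, _ = cp.lobed_contour(5, 3, 8, n_points=72, noise_sd=0.5, seed=seed + 10)
            d12 = cp.elastic_distance(c1, c2, n=64)
            d21 = cp.elastic_distance(c2, c1, n=64)
            assert d12 == pytest.approx(d21, abs=1e-6)  # symmetrized by construction
            assert d12 > 0


class TestRigidMotionInvarianceOfAllDistances:
    def test_all_four_distances_invariant(self):
        c1, ctr1 = cp.lobed_contour(4, 3, 7, n_points=80, noise_sd=0.4, seed=21)
        c2, ctr2 = cp.lobed_contour(2, 4, 6, n_points=80, noise_sd=0.4, seed=22)
        angle, shift = 0.9, (11.0, -4.0)
        m1 = cp.Contour(rigid(c1.points, angle, shift), id="m1")
        mc1 = cp.NucleusCenter(*rigid(ctr1.xy[None, :], angle, shift)[0])

        d_ph = cp.wasserstein(cp.diagram_for_cell(c1, ctr1), cp.diagram_for_cell(c2, ctr2))[0]
        d_ph_m = cp.wasserstein(cp.diagram_for_cell(m1, mc1), cp.diagram_for_cell(c2, ctr2))[0]
        assert d_ph_m == pytest.approx(d_ph, abs=1e-9)

        d_a = cp.aspect_distance(cp.aspect_ratio(c1), cp.aspect_ratio(c2))
        d_a_m = cp.aspect_distance(cp.aspect_ratio(m1), cp.aspect_ratio(c2))
        assert d_a_m == pytest.approx(d_a, abs=1e-9)

        d_f = cp.fourier_distance(cp.fourier_descriptor(c1), cp.fourier_descriptor(c2))
        d_f_m = cp.fourier_distance(cp.fourier_descriptor(m1), cp.fourier_descriptor(c2))
        assert d_f_m == pytest.approx(d_f, abs=1e-9)

        d_e = cp.elastic_distance(c1, c2, n=64)
        d_e_m = cp.elastic_distance(m1, c2, n=64)
        assert d_e_m == pytest.approx(d_e, abs=1e-5)
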