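"""Spectral core vs. literal double-sum DFT oracles and algebraic identities."""

import numpy as np
import pytest

from peppersort.spectral import (ComplexSpectrum, PolarSpectrum, RealGrid,
                                 fft2d, from_polar, ifft2d, to_polar)


def dft2_oracle(x: np.ndarray) -> np.ndarray:
    """O(N²M²) double-sum forward DFT, written straight from the definition."""
    n, m = x.shape
    out = np.zeros((n, m), dtype=complex)
    for k in range(n):
        for l in range(m):
            acc = 0.0j
            for xi in range(n):
                for yi in range(m):
                    acc += x[xi, yi] * np.exp(-2j * np.pi * (k * xi / n + l * yi / m))
            out[k, l] = acc
    return out


def idft2_oracle(z: np.ndarray) -> np.ndarray:
    n, m = z.shape
    out = np.zeros((n, m), dtype=complex)
    for xi in range(n):
        for yi in range(m):
            acc = 0.0j
            for k in range(n):
                for l in range(m):
                    acc += z[k, l] * np.exp(2j * np.pi * (k * xi / n + l * yi / m))
            out[xi, yi] = acc / (n * m)
    return out


class TestForwardTransform:
    def test_constant_grid_is_dc_only(self):
        spec = fft2d(RealGrid(np.full((2, 2), 3.0)))
        assert spec.re[0, 0] == pytest.approx(12.0, abs=1e-12)
        z = spec.as_complex()
        z[0, 0] = 0
        assert np.abs(z).max() < 1e-12

    def test_impulse_has_flat_spectrum(self):
        x = np.zeros((4, 4))
        x[0, 0] = 1.0
        spec = fft2d(RealGrid(x))
        np.testing.assert_allclose(spec.re, 1.0, atol=1e-12)
        np.testing.assert_allclose(spec.im, 0.0, atol=1e-12)

    @pytest.mark.parametrize("shape", [(2, 2), (3, 5), (8, 8), (1, 7)])
    def test_matches_double_sum_oracle(self, rng, shape):
        x = rng.normal(size=shape)
        got = fft2d(RealGrid(x)).as_complex()
        np.testing.assert_allclose(got, dft2_oracle(x), atol=1e-9)

    def test_batched_channels_transform_independently(self, rng):
        x = rng.normal(size=(2, 3, 4, 4))
        got = fft2d(RealGrid(x))
        for b in range(2):
            for c in range(3):
                single = fft2d(RealGrid(x[b, c]))
                np.testing.assert_allclose(got.re[b, c], single.re, atol=1e-12)

    def test_rejects_non_finite(self):
        x = np.ones((3, 3))
        x[1, 2] = np.nan
        with pytest.raises(ValueError, match=r"\(1, 2\)"):
            fft2d(RealGrid(x))


class TestInverseTransform:
    def test_dc_spectrum_inverts_to_constant(self):
        n = m = 4
        re = np.zeros((n, m))
        re[0, 0] = n * m * 2.5
        grid = ifft2d(ComplexSpectrum(re, np.zeros_like(re)))
        np.testing.assert_allclose(grid.values, 2.5, atol=1e-12)

    @pytest.mark.filterwarnings("ignore::RuntimeWarning")
    def test_matches_double_sum_oracle(self, rng):
        # an arbitrary complex spectrum is not conjugate-symmetric, so the
        # real-part comparison is exactly what the contract specifies
        z = rng.normal(size=(8, 8)) + 1j * rng.normal(size=(8, 8))
        got = ifft2d(ComplexSpectrum(z.real, z.imag))
        np.testing.assert_allclose(got.values, idft2_oracle(z).real, atol=1e-9)

    @pytest.mark.parametrize("shape", [(4, 4), (16, 16), (64, 64), (5, 9)])
    def test_round_trip(self, rng, shape):
        x = rng.normal(size=shape)
        back = ifft2d(fft2d(RealGrid(x)))
        np.testing.assert_allclose(back.values, x, rtol=1e-6, atol=1e-9)
        assert back.imag_residue < 1e-9

    def test_parseval(self, rng):
        x = rng.normal(size=(16, 16))
        spec = fft2d(RealGrid(x))
        lhs = (x ** 2).sum()
        rhs = (np.abs(spec.as_complex()) ** 2).sum() / x.size
        assert abs(lhs - rhs) / lhs < 1e-5

    def test_warns_on_large_imaginary_residue(self, rng):
        z = rng.normal(size=(4, 4)) + 1j * rng.normal(size=(4, 4))
        with pytest.warns(RuntimeWarning, match="residue"):
            ifft2d(ComplexSpectrum(z.real, z.imag))

    def test_rejects_empty_spectrum(self):
        with pytest.raises(ValueError):
            ComplexSpectrum(np.zeros((0, 4)), np.zeros((0, 4)))


class TestPolarConversion:
    def test_three_four_five(self):
        p = to_polar(ComplexSpectrum(np.array([[3.0]]), np.array([[4.0]])))
        assert p.magnitude[0, 0] == pytest.approx(5.0)
        assert p.phase[0, 0] == pytest.approx(0.9272952180016122)

    def test_negative_real_axis_quadrant(self):
        p = to_polar(ComplexSpectrum(np.array([[-2.0]]), np.array([[0.0]])))
        assert p.magnitude[0, 0] == pytest.approx(2.0)
        assert p.phase[0, 0] == pytest.approx(np.pi)

    def test_pythagorean_identity(self, rng):
        z = rng.normal(size=(8, 8)) + 1j * rng.normal(size=(8, 8))
        p = to_polar(ComplexSpectrum(z.real, z.imag))
        np.testing.assert_allclose(p.magnitude ** 2, z.real ** 2 + z.imag ** 2,
                                   atol=1e-9)
        assert np.all(p.magnitude >= 0)
        assert np.all(p.phase > -np.pi) and np.all(p.phase <= np.pi)

    def test_from_polar_inverse_345(self):
        spec = from_polar(PolarSpectrum(np.array([[5.0]]),
                                        np.array([[0.92729522]])))
        assert spec.re[0, 0] == pytest.approx(3.0, abs=1e-6)
        assert spec.im[0, 0] == pytest.approx(4.0, abs=1e-6)

    def test_zero_magnitude_annihilates_phase(self, rng):
        phase = rng.uniform(-np.pi, np.pi, size=(4, 4))
        spec = from_polar(PolarSpectrum(np.zeros((4, 4)), phase))
        np.testing.assert_array_equal(spec.re, 0.0)
        np.testing.assert_array_equal(spec.im, 0.0)

    def test_polar_round_trip_lossless(self, rng):
        for _ in range(100):
            z = rng.normal(size=(5, 5)) + 1j * rng.normal(size=(5, 5))
            spec = ComplexSpectrum(z.real, z.imag)
            back = from_polar(to_polar(spec))
            np.testing.assert_allclose(back.as_complex(), z, atol=1e-9)

    def test_negative_magnitude_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            from_polar(PolarSpectrum(np.array([[-1.0]]), np.array([[0.0]])))
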