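"""Oracle tests for the circulant/Fourier ridge-regression machinery.

The central property: on small instances, the FFT pathway (elementwise
divisions in the Fourier domain) agrees with explicit matrix solves over the
full set of cyclic shifts, for all three kernels.
"""

import numpy as np
import pytest
from numpy.fft import fft, fft2, ifft, ifft2

from kcfbs.kcf_core import (Detection, KernelSpec, build_circulant, detect,
                            gaussian_response_target, kernel_correlation,
                            train, train_linear, update_model)

KERNELS = [
    KernelSpec("linear"),
    KernelSpec("polynomial", poly_offset=0.7, poly_degree=2),
    KernelSpec("gaussian", gauss_sigma=0.5),
]


def kappa(u: np.ndarray, v: np.ndarray, ks: KernelSpec) -> float:
    """Direct pointwise kernel evaluation (the brute-force reference)."""
    ip = float((u * v).sum())
    if ks.kind == "linear":
        return ip
    if ks.kind == "polynomial":
        return (ip + ks.poly_offset) ** ks.poly_degree
    d2 = float(((u - v) ** 2).sum())
    return float(np.exp(-d2 / (ks.gauss_sigma ** 2 * u.size)))


def all_shifts(a: np.ndarray):
    h, w = a.shape
    return [np.roll(a, (i, j), axis=(0, 1)) for i in range(h)
            for j in range(w)]


class TestResponseTarget:
    def test_degenerate_single_cell(self):
        np.testing.assert_allclose(gaussian_response_target(1, 1), [[1.0]])

    def test_peak_at_origin_with_unit_max(self):
        g = gaussian_response_target(8, 6)
        assert np.unravel_index(g.argmax(), g.shape) == (0, 0)
        assert g.max() == 1.0

    def test_circular_shift_moves_the_peak(self):
        g = gaussian_response_target(8, 8)
        shifted = np.roll(g, (3, 5), axis=(0, 1))
        assert np.unravel_index(shifted.argmax(), shifted.shape) == (3, 5)


class TestBuildCirculant:
    def test_matches_the_definition_in_1d(self):
        A = build_circulant(np.array([1.0, 2.0, 3.0]))
        np.testing.assert_array_equal(
            A, [[1, 2, 3], [3, 1, 2], [2, 3, 1]]
        )

    def test_circulant_matrices_are_normal(self, rng):
        A = build_circulant(rng.normal(size=(4, 4)))
        np.testing.assert_allclose(A.conj().T @ A, A @ A.conj().T,
                                   atol=1e-9)

    @pytest.mark.parametrize("shape", [(8,), (4, 4)])
    def test_eigenvalues_are_the_dft_of_the_sample(self, rng, shape):
        """Diagonalisation by the DFT, irrespective of sample values."""
        a = rng.normal(size=shape)
        A = build_circulant(a)
        ev = np.linalg.eigvals(A)
        dft = (fft(a) if a.ndim == 1 else fft2(a)).ravel()
        assert len(ev) == len(dft)
        # multiset comparison: every DFT value is an eigenvalue and vice versa
        d1 = np.abs(ev[:, None] - dft[None, :]).min(axis=1)
        d2 = np.abs(dft[:, None] - ev[None, :]).min(axis=1)
        assert d1.max() < 1e-9 and d2.max() < 1e-9

    def test_size_guard(self):
        with pytest.raises(ValueError):
            build_circulant(np.zeros(100))


class TestTrainLinear:
    def test_scalar_arithmetic(self):
        a_hat = np.ones((2, 2), dtype=complex)
        b_hat = np.ones((2, 2), dtype=complex)
        np.testing.assert_allclose(train_linear(a_hat, b_hat, 1.0), 0.5)

    @pytest.mark.parametrize("n", [4, 8])
    def test_matches_explicit_primal_solve(self, rng, n):
        """inverse-DFT of the Fourier solution equals the direct ridge
        solve (A^H A + lam I) w = A^H b over the circulant sample matrix."""
        a, b = rng.normal(size=n), rng.normal(size=n)
        lam = 0.37
        A = build_circulant(a)
        w_explicit = np.linalg.solve(
            A.conj().T @ A + lam * np.eye(n), A.conj().T @ b
        )
        w = ifft(train_linear(fft(a), fft(b), lam))
        np.testing.assert_allclose(w, w_explicit, atol=1e-8)

    def test_infinite_regularisation_shrinks_to_zero(self, rng):
        a_hat, b_hat = fft(rng.normal(size=8)), fft(rng.normal(size=8))
        w = train_linear(a_hat, b_hat, 1e12)
        assert np.abs(w).max() < 1e-9

    def test_singular_unregularised_system_raises(self):
        a_hat = np.array([1.0, 0.0, 1.0, 0.0], dtype=complex)
        with pytest.raises(ZeroDivisionError):
            train_linear(a_hat, np.ones(4, dtype=complex), 0.0)


class TestKernelCorrelation:
    def test_impulse_autocorrelation_is_an_impulse(self):
        delta = np.zeros((6, 6))
        delta[0, 0] = 1.0
        k = kernel_correlation(delta, delta, KernelSpec("linear"))
        np.testing.assert_allclose(k, delta, atol=1e-12)

    @pytest.mark.parametrize("ks", KERNELS, ids=lambda k: k.kind)
    def test_matches_shift_enumeration_oracle(self, rng, ks):
        """k[p, q] equals the kernel applied to an explicitly rolled copy."""
        x = rng.normal(size=(6, 6)) * 0.4
        z = rng.normal(size=(6, 6)) * 0.4
        k = kernel_correlation(x, z, ks)
        oracle = np.array(
            [[kappa(np.roll(z, (p, q), axis=(0, 1)), x, ks)
              for q in range(6)] for p in range(6)]
        )
        np.testing.assert_allclose(k, oracle, atol=1e-8)

    def test_gaussian_kernel_bounds(self, rng):
        x = rng.normal(size=(6, 6))
        z = np.roll(x, (2, 1), axis=(0, 1))
        k = kernel_correlation(x, z, KernelSpec("gaussian", gauss_sigma=0.3))
        assert np.all(k > 0) and np.all(k <= 1.0 + 1e-12)
        # k[p, q] applies a further roll of (p, q) to z, so rolling by the
        # complement (-2, -1 mod 6) reproduces x exactly
        assert k[4, 5] == pytest.approx(1.0, abs=1e-9)
        assert np.sum(k > 1.0 - 1e-9) == 1

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            kernel_correlation(np.zeros((4, 4)), np.zeros((5, 4)),
                               KernelSpec("linear"))


class TestTrain:
    @pytest.mark.parametrize("ks", KERNELS, ids=lambda k: k.kind)
    def test_matches_explicit_dual_solve(self, rng, ks):
        """inverse-DFT of alpha_hat equals (K + lam I)^{-1} b with K
        assembled row-by-row from all cyclic shifts."""
        x = rng.normal(size=(6, 6)) * 0.4
        b = gaussian_response_target(6, 6, 0.3, 1.0)
        lam = 1e-2
        shifts = all_shifts(x)
        K = np.array([[kappa(ci, aj, ks) for aj in shifts] for ci in shifts])
        alpha_explicit = np.linalg.solve(K + lam * np.eye(36), b.ravel())
        model = train(x, b, lam, ks)
        alpha = ifft2(model.alpha_hat).ravel()
        np.testing.assert_allclose(alpha.imag, 0, atol=1e-8)
        np.testing.assert_allclose(alpha.real, alpha_explicit, atol=1e-8)

    def test_linear_kernel_agrees_with_primal_regression(self, rng):
        """Primal-dual equivalence: the dual detection response equals the
        explicit primal regression f(c) = w^T c over candidate shifts
        (up to the candidate enumeration direction)."""
        x = rng.normal(size=(6, 6)) * 0.5
        z = rng.normal(size=(6, 6)) * 0.5
        b = gaussian_response_target(6, 6, 0.3, 1.0)
        lam = 0.05
        model = train(x, b, lam, KernelSpec("linear"))
        resp = detect(model, z).response
        w = ifft2(train_linear(fft2(x), fft2(b), lam)).real
        primal = np.array(
            [[float((w * np.roll(z, (-p, -q), axis=(0, 1))).sum())
              for q in range(6)] for p in range(6)]
        )
        np.testing.assert_allclose(resp, primal, atol=1e-8)

    def test_zero_target_gives_zero_coefficients(self, rng):
        model = train(rng.normal(size=(4, 4)), np.zeros((4, 4)), 1e-3,
                      KernelSpec("gaussian"))
        np.testing.assert_allclose(model.alpha_hat, 0.0)


class TestDetect:
    def test_self_match_has_zero_offset(self, rng):
        x = rng.normal(size=(12, 12))
        model = train(x, gaussian_response_target(12, 12), 1e-4,
                      KernelSpec("gaussian", gauss_sigma=0.5))
        assert detect(model, x).peak_offset == (0.0, 0.0)

    def test_recovers_circular_shifts_exactly(self, rng):
        """Shift recovery: unwindowed gray features, the offset equals the
        applied cyclic shift (wrapped to signed form)."""
        x = rng.normal(size=(16, 16))
        model = train(x, gaussian_response_target(16, 16), 1e-4,
                      KernelSpec("gaussian", gauss_sigma=0.5))
        for dr, dc in [(3, 2), (0, 5), (13, 7), (15, 15)]:
            det = detect(model, np.roll(x, (dr, dc), axis=(0, 1)))
            want = (dc if dc <= 8 else dc - 16, dr if dr <= 8 else dr - 16)
            assert det.peak_offset == want

    @pytest.mark.parametrize("ks", KERNELS, ids=lambda k: k.kind)
    def test_response_maximum_matches_classifier_oracle(self, rng, ks):
        """max response equals max over f(c_i) = sum_j alpha_j kappa(c_i, a_j)
        with alpha from the explicit dual solve."""
        x = rng.normal(size=(5, 5)) * 0.4
        z = rng.normal(size=(5, 5)) * 0.4
        b = gaussian_response_target(5, 5, 0.3, 1.0)
        lam = 1e-2
        shifts = all_shifts(x)
        K = np.array([[kappa(ci, aj, ks) for aj in shifts] for ci in shifts])
        alpha = np.linalg.solve(K + lam * np.eye(25), b.ravel())
        f = [
            sum(alpha[j] * kappa(c, shifts[j], ks) for j in range(25))
            for c in all_shifts(z)
        ]
        det = detect(train(x, b, lam, ks), z)
        assert det.response.max() == pytest.approx(max(f), abs=1e-8)

    def test_max_shift_restricts_the_peak(self, rng):
        x = rng.normal(size=(16, 16))
        model = train(x, gaussian_response_target(16, 16), 1e-4,
                      KernelSpec("gaussian", gauss_sigma=0.5))
        z = np.roll(x, (6, 6), axis=(0, 1))
        unrestricted = detect(model, z)
        capped = detect(model, z, max_shift=3)
        assert unrestricted.peak_offset == (6.0, 6.0)
        assert max(abs(o) for o in capped.peak_offset) <= 3


class TestUpdateModel:
    def _model(self, rng):
        x = rng.normal(size=(8, 8))
        return train(x, gaussian_response_target(8, 8), 1e-3,
                     KernelSpec("gaussian"))

    def test_eta_zero_keeps_and_eta_one_replaces(self, rng):
        m1, m2 = self._model(rng), self._model(rng)
        kept = update_model(m1, m2, 0.0)
        np.testing.assert_array_equal(kept.alpha_hat, m1.alpha_hat)
        swapped = update_model(m1, m2, 1.0)
        np.testing.assert_array_equal(swapped.alpha_hat, m2.alpha_hat)

    def test_midpoint_interpolation(self, rng):
        m1, m2 = self._model(rng), self._model(rng)
        mid = update_model(m1, m2, 0.5)
        np.testing.assert_allclose(
            mid.alpha_hat, 0.5 * (m1.alpha_hat + m2.alpha_hat)
        )
        np.testing.assert_allclose(
            mid.template.values,
            0.5 * (m1.template.values + m2.template.values),
        )


def test_fft_round_trip_consistency(rng):
    """The DFT conventions used throughout invert to 1e-10."""
    x = rng.normal(size=(16, 16))
    np.testing.assert_allclose(ifft2(fft2(x)).real, x, atol=1e-10)


try:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        h=st.integers(2, 6),
        w=st.integers(2, 6),
        seed=st.integers(0, 2 ** 16),
        kind=st.sampled_from(["linear", "polynomial", "gaussian"]),
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_kernel_correlation_oracle_property(h, w, seed, kind):
        """Property form of the shift-enumeration oracle: for arbitrary
        small shapes and samples, the FFT kernel correlation equals the
        kernel applied to explicitly rolled copies."""
        ks = KernelSpec(kind, gauss_sigma=0.6, poly_degree=2)
        r = np.random.default_rng(seed)
        x = r.normal(size=(h, w)) * 0.5
        z = r.normal(size=(h, w)) * 0.5
        k = kernel_correlation(x, z, ks)
        oracle = np.array(
            [[kappa(np.roll(z, (p, q), axis=(0, 1)), x, ks)
              for q in range(w)] for p in range(h)]
        )
        np.testing.assert_allclose(k, oracle, atol=1e-8)
except ImportError:  # pragma: no cover - hypothesis is an optional extra
    pass
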