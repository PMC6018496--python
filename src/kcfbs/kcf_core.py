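"""Ridge regression over cyclic shifts — the correlation-filter machinery.

A target patch ``a`` and all of its 2-D cyclic shifts form a circulant sample
matrix ``A`` whose rows are ``D^j R^i a``.  Circulant matrices are diagonal in
the discrete Fourier basis, so both the primal ridge-regression solution

    w = (A^H A + lambda I)^{-1} A^H b      <=>   w_hat = a_hat .* b_hat
                                                         / (conj(a_hat) .* a_hat + lambda)

and the dual (kernel) solution

    alpha = (K + lambda I)^{-1} b          <=>   alpha_hat = b_hat / (k_hat + lambda)

reduce to elementwise divisions, where ``k`` is the first column of the kernel
matrix ``K`` (the kernel correlation of the patch with itself over all cyclic
shifts).  ``build_circulant`` exists as the brute-force oracle against which
the FFT pathway is verified on small instances; it is never the fast path.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np
from numpy.fft import fft2, ifft2

from .errors import NumericError
from .features import FeatureMap


@dataclass
class KernelSpec:
    """Kernel used for the dual (nonlinear) regression.

    ``gauss_sigma`` is the Gaussian bandwidth on per-element feature scale;
    the polynomial kernel is ``(<x, z> + poly_offset) ** poly_degree``.
    """

    kind: str = "gaussian"  # {"linear", "polynomial", "gaussian"}
    poly_offset: float = 1.0
    poly_degree: int = 3
    gauss_sigma: float = 0.2

    def __post_init__(self):
        if self.kind not in ("linear", "polynomial", "gaussian"):
            raise ValueError(f"unknown kernel {self.kind!r}")
        if self.gauss_sigma <= 0:
            raise ValueError("gauss_sigma must be positive")
        if self.poly_degree < 1:
            raise ValueError("poly_degree must be >= 1")


@dataclass
class KCFModel:
    """Learned dual coefficients (Fourier domain) plus the appearance template."""

    alpha_hat: np.ndarray
    template: FeatureMap
    lam: float
    kernel: KernelSpec
    response_target_hat: np.ndarray = field(repr=False, default=None)

    def __post_init__(self):
        if not np.all(np.isfinite(self.alpha_hat)):
            raise NumericError("alpha_hat contains non-finite entries")
        if self.alpha_hat.shape != self.template.spatial_shape:
            raise ValueError("alpha_hat dims must match the template")


def gaussian_response_target(h: int, w: int, sigma_factor: float = 0.1,
                             padding: float = 2.0) -> np.ndarray:
    """Periodic 2-D Gaussian regression target peaked at index (0, 0).

    The bandwidth is ``sigma_factor * sqrt(h * w) / padding`` — i.e. a fixed
    fraction of the un-padded target size, so that the desired response decays
    within the target footprint rather than the whole search window.
    """
    if h < 1 or w < 1:
        raise ValueError("target dims must be >= 1")
    sigma = sigma_factor * np.sqrt(h * w) / padding
    ri = np.arange(h)
    ci = np.arange(w)
    # wrapped (periodic) distances from index 0
    dr = np.minimum(ri, h - ri)[:, None]
    dc = np.minimum(ci, w - ci)[None, :]
    if sigma == 0:
        g = np.zeros((h, w))
        g[0, 0] = 1.0
        return g
    return np.exp(-(dr ** 2 + dc ** 2) / (2.0 * sigma ** 2))


def build_circulant(a: np.ndarray, max_elements: int = 4096) -> np.ndarray:
    """Explicit matrix of all cyclic shifts of ``a`` (brute-force oracle only).

    For a 1-D sample, row ``i`` is ``a`` shifted right by ``i``.  For a 2-D
    sample of shape (h, w), row ``i * w + j`` is ``roll(a, (i, j))`` flattened
    row-major, i.e. shifts enumerated down-then-right.
    """
    a = np.asarray(a)
    if a.size ** 2 > max_elements:
        raise ValueError(
            f"sample of {a.size} elements exceeds the oracle size guard"
        )
    if a.ndim == 1:
        n = a.size
        return np.stack([np.roll(a, i) for i in range(n)])
    if a.ndim == 2:
        h, w = a.shape
        rows = [
            np.roll(a, (i, j), axis=(0, 1)).ravel()
            for i in range(h)
            for j in range(w)
        ]
        return np.stack(rows)
    raise ValueError("sample must be 1-D or 2-D")


def train_linear(a_hat: np.ndarray, b_hat: np.ndarray,
                 lam: float) -> np.ndarray:
    """Fourier-domain primal ridge solution w_hat = a_hat b_hat / (|a_hat|^2 + lam)."""
    a_hat = np.asarray(a_hat)
    b_hat = np.asarray(b_hat)
    if a_hat.shape != b_hat.shape:
        raise ValueError("a_hat and b_hat must share a shape")
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    denom = np.conj(a_hat) * a_hat + lam
    if lam == 0 and np.any(np.abs(denom) < 1e-12 * (np.abs(a_hat).max() + 1)):
        raise ZeroDivisionError(
            "zero Fourier coefficient with lambda = 0; the ridge is singular"
        )
    return a_hat * b_hat / denom


def _as_values(x) -> np.ndarray:
    if isinstance(x, FeatureMap):
        return x.values
    x = np.asarray(x, dtype=float)
    return x[:, :, None] if x.ndim == 2 else x


def _cross_correlation(x: np.ndarray, z: np.ndarray) -> np.ndarray:
    """sum_c ifft2(fft2(x_c) * conj(fft2(z_c))): cc[p, q] = <x, roll(z, (p, q))>."""
    cc = np.zeros(x.shape[:2])
    for c in range(x.shape[2]):
        cc += np.real(ifft2(fft2(x[:, :, c]) * np.conj(fft2(z[:, :, c]))))
    return cc


def kernel_correlation(x, z, kernel: KernelSpec) -> np.ndarray:
    """Kernel evaluated against every cyclic shift: k[p, q] = kappa(roll(z, (p, q)), x).

    Computed with FFT cross-correlation; multi-channel features sum their
    per-channel correlations before the kernel nonlinearity.
    """
    xv, zv = _as_values(x), _as_values(z)
    if xv.shape != zv.shape:
        raise ValueError(f"shape mismatch: {xv.shape} vs {zv.shape}")
    cc = _cross_correlation(xv, zv)
    if kernel.kind == "linear":
        return cc
    if kernel.kind == "polynomial":
        return (cc + kernel.poly_offset) ** kernel.poly_degree
    # gaussian: ||x - roll(z)||^2 = ||x||^2 + ||z||^2 - 2 cc, clipped at 0
    # against FFT round-off
    sq = float((xv ** 2).sum() + (zv ** 2).sum())
    d2 = np.maximum(sq - 2.0 * cc, 0.0)
    n = xv.size
    return np.exp(-d2 / (kernel.gauss_sigma ** 2 * n))


def train(x, b: np.ndarray, lam: float, kernel: KernelSpec) -> KCFModel:
    """Fit dual coefficients alpha_hat = b_hat / (k_hat_xx + lambda)."""
    xm = x if isinstance(x, FeatureMap) else FeatureMap(x)
    b = np.asarray(b, dtype=float)
    if b.shape != xm.spatial_shape:
        raise ValueError("target shape must match the feature map")
    k_xx = kernel_correlation(xm, xm, kernel)
    b_hat = fft2(b)
    alpha_hat = b_hat / (fft2(k_xx) + lam)
    return KCFModel(alpha_hat=alpha_hat, template=xm, lam=lam, kernel=kernel,
                    response_target_hat=b_hat)


def _wrap_shift(i: int, n: int) -> int:
    """Map an FFT index to the signed cyclic shift it represents."""
    return i - n if i > n // 2 else i


@dataclass
class Detection:
    response: np.ndarray
    peak_offset: Tuple[float, float]  # (du, dv) in pixels
    peak_value: float


def detect(model: KCFModel, z, max_shift: Optional[float] = None) -> Detection:
    """Evaluate the classifier over all cyclic shifts of the search patch.

    The response is ``ifft2(fft2(k_z,template) * alpha_hat)``; its argmax is
    the displacement of the target within the search window relative to the
    template, returned as a signed (du, dv) in pixels (feature cells scaled
    by ``cell_size``).

    ``max_shift`` (pixels) restricts the admissible displacement: shifts for
    which the target would have left the search window entirely are not
    physically meaningful detections, so the tracking loop caps the peak
    search at (window - target)/2.  ``None`` searches all cyclic shifts.
    """
    zm = z if isinstance(z, FeatureMap) else FeatureMap(z)
    if zm.spatial_shape != model.template.spatial_shape:
        raise ValueError("search patch dims must match the template")
    k = kernel_correlation(zm, model.template, model.kernel)
    resp_c = ifft2(fft2(k) * model.alpha_hat)
    scale = np.abs(resp_c).max()
    if not np.all(np.isfinite(resp_c)):
        raise NumericError("non-finite detection response")
    if scale > 0 and np.abs(resp_c.imag).max() > 1e-6 * scale:
        raise NumericError("detection response is not numerically real")
    response = resp_c.real
    h, w = response.shape
    if max_shift is None:
        r, c = np.unravel_index(int(np.argmax(response)), response.shape)
    else:
        cells = max(int(max_shift / zm.cell_size), 0)
        sr = np.array([_wrap_shift(i, h) for i in range(h)])
        sc = np.array([_wrap_shift(j, w) for j in range(w)])
        admissible = ((np.abs(sr)[:, None] <= cells)
                      & (np.abs(sc)[None, :] <= cells))
        masked = np.where(admissible, response, -np.inf)
        r, c = np.unravel_index(int(np.argmax(masked)), response.shape)
    du = _wrap_shift(c, w) * zm.cell_size
    dv = _wrap_shift(r, h) * zm.cell_size
    return Detection(response=response, peak_offset=(float(du), float(dv)),
                     peak_value=float(response[r, c]))


def update_model(model: KCFModel, new_model: KCFModel,
                 eta: float) -> KCFModel:
    """Linear interpolation of dual coefficients and template (adaptation).

    ``eta = 0`` keeps the first-frame model unchanged (the literal no-update
    reading of the tracking loop); ``eta = 1`` replaces it outright.
    """
    if not 0.0 <= eta <= 1.0:
        raise ValueError("eta must lie in [0, 1]")
    if model.alpha_hat.shape != new_model.alpha_hat.shape:
        raise ValueError("model shapes do not match")
    alpha_hat = (1.0 - eta) * model.alpha_hat + eta * new_model.alpha_hat
    template = FeatureMap(
        (1.0 - eta) * model.template.values + eta * new_model.template.values,
        cell_size=model.template.cell_size,
    )
    return replace(model, alpha_hat=alpha_hat, template=template)
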