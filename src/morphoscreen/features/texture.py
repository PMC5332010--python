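"""Texture features: Gaussian-derivative (SER), co-occurrence (Haralick),
and Gabor.

SER responses follow the scale-space derivative taxonomy: with L the image
smoothed at sigma = sigma0 + scale and (l1 >= l2) the eigenvalues of the
scale-normalised Hessian,

    spot   = relu(-(l1 + l2)) where the blob is compact (l1 < alpha*l2 < 0)
    hole   = relu(l1 + l2)    where l2 > alpha*l1 > 0
    ridge  = relu(-l2)        where the dark eigenvalue dominates
    valley = relu(l1)         where the bright eigenvalue dominates
    saddle = sqrt(-l1*l2)     where l1 > 0 > l2
    edge   = sigma * |grad L|
    bright = relu(I - L), dark = relu(L - I)

Derivatives are gamma-normalised (multiplied by sigma^order), which is the
"normalised to within the kernel" convention keeping responses comparable
across scales; each feature is the mean response over the region pixels.

Haralick features come from a region-restricted grey-level co-occurrence
matrix: intensities are quantised to a fixed number of levels over the
region's range and pairs are accumulated symmetrically over the four
distance-1 directions with both pixels inside the mask.

Gabor features use one wavelength at 8 orientations; kernels are zero-mean
and unit-L2 so a constant image responds zero.  The per-pixel response
magnitude is reduced across orientations by mean/min/max and averaged over
the region.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import gabor_kernel

#: relative dominance threshold separating blob-like from line-like Hessians
_ALPHA = 0.5


def _gaussian_derivative_kernels(sigma: float) -> tuple[np.ndarray, ...]:
    """Sampled 1-D Gaussian kernels of order 0/1/2, moment-corrected.

    At sub-pixel sigmas the naively sampled derivative kernels do not
    annihilate constants; each kernel is therefore re-normalised to have
    exact vanishing moments (order 1: zero sum, unit first moment; order 2:
    zero sum, zero first moment, second moment 2) so that flat and linear
    ramps respond exactly zero.
    """
    radius = max(2, int(4.0 * sigma + 0.5))
    n = np.arange(-radius, radius + 1, dtype=np.float64)
    g = np.exp(-(n**2) / (2 * sigma**2))
    g /= g.sum()
    g1 = -n / sigma**2 * g
    g1 -= g1.mean()
    g1 /= -(n * g1).sum()  # d/dx of a unit ramp = 1
    g2 = (n**2 / sigma**4 - 1 / sigma**2) * g
    g2 -= g2.mean()
    g2 -= n * (n * g2).sum() / (n**2).sum()  # kill first moment
    g2 /= 0.5 * (n**2 * g2).sum()  # d2/dx2 of x^2/2 = 1
    return g, g1, g2


def ser_derivative_stack(
    img: np.ndarray, scale: int, sigma0: float = 0.5
) -> tuple[float, tuple[np.ndarray, ...]]:
    """(sigma, (I, L, Lx, Ly, Lxx, Lyy, Lxy)) of one channel at one scale.

    Derivatives are gamma-normalised (multiplied by sigma^order).
    """
    if scale not in (0, 1):
        raise ValueError("scale must be 0 or 1")
    sigma = sigma0 + scale
    x = np.ascontiguousarray(img, dtype=np.float32)
    g, g1, g2 = _gaussian_derivative_kernels(sigma)

    def sep(krow, kcol):
        out = ndi.correlate1d(x, kcol[::-1], axis=1, mode="nearest")
        return ndi.correlate1d(out, krow[::-1], axis=0, mode="nearest")

    L = sep(g, g)
    Lx = sep(g, g1) * sigma
    Ly = sep(g1, g) * sigma
    Lxx = sep(g, g2) * sigma**2
    Lyy = sep(g2, g) * sigma**2
    Lxy = sep(g1, g1) * sigma**2
    return sigma, (x, L, Lx, Ly, Lxx, Lyy, Lxy)


_SER_STRUCTURAL = ("spot", "hole", "ridge", "valley", "saddle", "edge")

_SER_CALIBRATION_CACHE: dict[float, dict[str, float]] = {}


def _raw_ser_candidates(stack, sigma: float) -> dict[str, np.ndarray]:
    """Gated, rectified detector strengths (before noise calibration)."""
    x, L, Lx, Ly, Lxx, Lyy, Lxy = [a.astype(np.float64) for a in stack]
    # Hessian eigenvalues, l1 >= l2
    tr = Lxx + Lyy
    det_part = np.sqrt(np.clip(((Lxx - Lyy) / 2) ** 2 + Lxy**2, 0, None))
    l1 = tr / 2 + det_part
    l2 = tr / 2 - det_part

    relu = lambda a: np.clip(a, 0, None)  # noqa: E731
    blob_neg = (l1 < _ALPHA * l2) & (l2 < 0)  # compact bright blob
    blob_pos = (l2 > _ALPHA * l1) & (l1 > 0)  # compact dark blob
    return {
        "spot": np.where(blob_neg, relu(-(l1 + l2)), 0.0),
        "hole": np.where(blob_pos, relu(l1 + l2), 0.0),
        "ridge": np.where((l2 < 0) & ~blob_neg, relu(-l2), 0.0),
        "valley": np.where((l1 > 0) & ~blob_pos, relu(l1), 0.0),
        "saddle": np.where((l1 > 0) & (l2 < 0), np.sqrt(relu(-l1 * l2)), 0.0),
        "edge": np.hypot(Lx, Ly),
        "bright": relu(x - L),
        "dark": relu(L - x),
    }


def _ser_noise_calibration(sigma: float) -> dict[str, float]:
    """Per-detector normalisation: RMS of each strength on unit white noise.

    Dividing by these puts the eight detectors in comparable (SNR-like)
    units -- the "normalised to within the kernel" convention.
    Deterministic: computed once per sigma from a fixed-seed noise patch.
    """
    key = round(sigma, 6)
    if key not in _SER_CALIBRATION_CACHE:
        rng = np.random.default_rng(12345)
        noise = rng.standard_normal((256, 256))
        _, stack = ser_derivative_stack(noise, 0, sigma0=sigma)
        resp = _raw_ser_candidates(stack, sigma)
        _SER_CALIBRATION_CACHE[key] = {
            k: float(max(np.sqrt((v**2).mean()), 1e-12)) for k, v in resp.items()
        }
    return _SER_CALIBRATION_CACHE[key]


def ser_responses(stack, sigma: float) -> dict[str, np.ndarray]:
    """The eight SER responses from a derivative stack (any array shape).

    The six structural detectors (spot, hole, ridge, valley, saddle, edge)
    are mutually exclusive per pixel: each pixel contributes only to the
    detector for which its noise-calibrated strength is largest, so a blob
    centre scores as spot while its flanks score as edge.  bright/dark are
    residual (I - L) detectors and stay non-exclusive.
    """
    raw = _raw_ser_candidates(stack, sigma)
    cal = _ser_noise_calibration(sigma)
    calibrated = {k: raw[k] / cal[k] for k in raw}
    strengths = np.stack([calibrated[k] for k in _SER_STRUCTURAL])
    winner = np.argmax(strengths, axis=0)
    out = {
        k: np.where(winner == i, calibrated[k], 0.0)
        for i, k in enumerate(_SER_STRUCTURAL)
    }
    out["bright"] = calibrated["bright"]
    out["dark"] = calibrated["dark"]
    return out


def ser_response_maps(
    img: np.ndarray, scale: int, sigma0: float = 0.5
) -> dict[str, np.ndarray]:
    """The eight SER response maps of one channel at one scale."""
    sigma, stack = ser_derivative_stack(img, scale, sigma0)
    return ser_responses(stack, sigma)


# ---------------------------------------------------------------- Haralick

_GLCM_OFFSETS = ((0, 1), (1, 0), (1, 1), (1, -1))


def masked_glcm(
    img: np.ndarray, mask: np.ndarray, levels: int = 64, distance: int = 1
) -> np.ndarray | None:
    """Symmetric, direction-averaged GLCM restricted to mask-internal pairs.

    Quantisation is min-max over the region's intensity range.  Returns the
    normalised ``levels x levels`` matrix, or None when the region has no
    valid pair or is constant (the constant case is handled by the caller:
    contrast 0, homogeneity 1, variance 0, correlation missing).
    """
    vals = img[mask]
    if vals.size < 2:
        return None
    vmin, vmax = float(vals.min()), float(vals.max())
    if vmax <= vmin:
        return None
    q = np.zeros(img.shape, dtype=np.int64)
    q[mask] = np.minimum(
        ((img[mask] - vmin) / (vmax - vmin) * levels).astype(np.int64), levels - 1
    )
    glcm = np.zeros((levels, levels), dtype=np.float64)
    for dr, dc in _GLCM_OFFSETS:
        dr, dc = dr * distance, dc * distance
        H, W = img.shape
        r0a, r1a = max(0, -dr), min(H, H - dr)
        c0a, c1a = max(0, -dc), min(W, W - dc)
        a_sl = (slice(r0a, r1a), slice(c0a, c1a))
        b_sl = (slice(r0a + dr, r1a + dr), slice(c0a + dc, c1a + dc))
        valid = mask[a_sl] & mask[b_sl]
        i = q[a_sl][valid]
        j = q[b_sl][valid]
        np.add.at(glcm, (i, j), 1.0)
        np.add.at(glcm, (j, i), 1.0)
    total = glcm.sum()
    if total == 0:
        return None
    return glcm / total


def haralick_features(
    img: np.ndarray, mask: np.ndarray, levels: int = 64, distance: int = 1
) -> dict[str, float]:
    """Correlation, contrast, variance, homogeneity of the region GLCM."""
    if mask.sum() < 2:
        return {k: np.nan for k in ("correlation", "contrast", "variance", "homogeneity")}
    glcm = masked_glcm(img, mask, levels=levels, distance=distance)
    if glcm is None:
        # constant region: all co-occurrences on the diagonal
        return {
            "correlation": np.nan,
            "contrast": 0.0,
            "variance": 0.0,
            "homogeneity": 1.0,
        }
    i = np.arange(glcm.shape[0], dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    mu_x = float((ii * glcm).sum())
    mu_y = float((jj * glcm).sum())
    var_x = float(((ii - mu_x) ** 2 * glcm).sum())
    var_y = float(((jj - mu_y) ** 2 * glcm).sum())
    contrast = float(((ii - jj) ** 2 * glcm).sum())
    homogeneity = float((glcm / (1.0 + (ii - jj) ** 2)).sum())
    # symmetric GLCM: mu_x == mu_y; variance is the standard Haralick
    # sum-of-squares variance about the matrix mean
    variance = var_x
    if var_x <= 0 or var_y <= 0:
        correlation = np.nan
    else:
        correlation = float(
            (((ii - mu_x) * (jj - mu_y) * glcm).sum()) / np.sqrt(var_x * var_y)
        )
    return {
        "correlation": correlation,
        "contrast": contrast,
        "variance": variance,
        "homogeneity": homogeneity,
    }


# ------------------------------------------------------------------ Gabor


def gabor_bank(
    wavelength: float = 4.0, n_orientations: int = 8
) -> list[np.ndarray]:
    """Zero-mean, unit-L2 complex Gabor kernels at evenly spaced angles."""
    kernels = []
    for k in range(n_orientations):
        theta = np.pi * k / n_orientations
        kern = gabor_kernel(frequency=1.0 / wavelength, theta=theta)
        kern = kern - kern.mean()
        kern = kern / np.sqrt((np.abs(kern) ** 2).sum())
        kernels.append(kern)
    # zero-pad to a common (odd) shape so the bank convolves as one batch
    kh = max(k.shape[0] for k in kernels)
    kw = max(k.shape[1] for k in kernels)
    padded = []
    for k in kernels:
        ph, pw = (kh - k.shape[0]) // 2, (kw - k.shape[1]) // 2
        out = np.zeros((kh, kw), dtype=complex)
        out[ph : ph + k.shape[0], pw : pw + k.shape[1]] = k
        padded.append(out)
    return padded


_GABOR_FFT_CACHE: dict[tuple, tuple] = {}


def _gabor_kernel_ffts(kernels: list[np.ndarray], shape: tuple[int, int]):
    """FFTs of the padded kernels, cached per image shape."""
    from scipy.fft import fft2, next_fast_len

    key = (shape, len(kernels), kernels[0].shape, complex(kernels[0][0, 0]))
    if key in _GABOR_FFT_CACHE:
        return _GABOR_FFT_CACHE[key]
    kh, kw = kernels[0].shape
    fshape = (next_fast_len(shape[0] + kh - 1), next_fast_len(shape[1] + kw - 1))
    ffts = [fft2(k.astype(np.complex64), fshape) for k in kernels]
    _GABOR_FFT_CACHE[key] = (fshape, ffts)
    if len(_GABOR_FFT_CACHE) > 8:
        _GABOR_FFT_CACHE.pop(next(iter(_GABOR_FFT_CACHE)))
    return fshape, ffts


def gabor_response_maps(
    img: np.ndarray, kernels: list[np.ndarray]
) -> dict[str, np.ndarray]:
    """Per-pixel magnitude reduced across orientations by mean/min/max."""
    from scipy.fft import fft2, ifft2

    x = img.astype(np.complex64)
    fshape, kffts = _gabor_kernel_ffts(kernels, img.shape)
    Fx = fft2(x, fshape)
    kh, kw = kernels[0].shape
    r0, c0 = (kh - 1) // 2, (kw - 1) // 2
    H, W = img.shape
    mags = np.empty((len(kernels), H, W), dtype=np.float32)
    for i, kf in enumerate(kffts):
        full = ifft2(Fx * kf)
        mags[i] = np.abs(full[r0 : r0 + H, c0 : c0 + W])
    return {
        "mean": mags.mean(axis=0).astype(np.float64),
        "min": mags.min(axis=0).astype(np.float64),
        "max": mags.max(axis=0).astype(np.float64),
    }


def gabor_features(
    img: np.ndarray,
    mask: np.ndarray,
    wavelength: float = 4.0,
    n_orientations: int = 8,
) -> dict[str, float]:
    """Region means of the orientation-reduced Gabor magnitude maps."""
    if not mask.any():
        return {"mean": np.nan, "min": np.nan, "max": np.nan}
    maps = gabor_response_maps(img, gabor_bank(wavelength, n_orientations))
    return {k: float(v[mask].mean()) for k, v in maps.items()}


def ser_features(
    img: np.ndarray, mask: np.ndarray, scale: int, sigma0: float = 0.5
) -> dict[str, float]:
    """Region means of the eight SER response maps at one scale."""
    if not mask.any():
        from .registry import SER_RESPONSES

        return {k: np.nan for k in SER_RESPONSES}
    maps = ser_response_maps(img, scale, sigma0=sigma0)
    return {k: float(v[mask].mean()) for k, v in maps.items()}
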