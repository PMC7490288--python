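"""Independent brute-force oracles for the ROI-based corrections.

These rebuild the spill-over systems from first principles — explicit
sampled-Gaussian kernel, FFT convolution, dense linear algebra — sharing no
code with the package's RSF/GTM machinery beyond numpy itself.
"""

import numpy as np
from scipy.signal import fftconvolve

_FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


def _kernel_1d(sigma_vox: float) -> np.ndarray:
    radius = int(4.0 * sigma_vox + 0.5)
    x = np.arange(-radius, radius + 1, dtype=float)
    k = np.exp(-0.5 * (x / sigma_vox) ** 2)
    return k / k.sum()


def brute_blur(volume: np.ndarray, fwhm_mm: float, voxel_mm) -> np.ndarray:
    """Zero-padded Gaussian convolution via explicit kernel + FFT."""
    out = np.asarray(volume, dtype=float)
    for axis, v in enumerate(voxel_mm):
        sigma = (fwhm_mm / _FWHM_PER_SIGMA) / v
        k = _kernel_1d(sigma)
        shape = [1, 1, 1]
        shape[axis] = k.size
        out = fftconvolve(out, k.reshape(shape), mode="same")
    return out


def brute_gtm(image, labels, region_ids, fwhm_mm, voxel_mm):
    """Assemble the transfer matrix by direct convolution and invert it."""
    n = len(region_ids)
    rsf = [brute_blur((labels == rid).astype(float), fwhm_mm, voxel_mm) for rid in region_ids]
    omega = np.empty((n, n))
    b = np.empty(n)
    for i, rid in enumerate(region_ids):
        m = labels == rid
        b[i] = image[m].mean()
        for j in range(n):
            omega[i, j] = rsf[j][m].mean()
    return np.linalg.inv(omega) @ b


def brute_labbe(image, labels, region_ids, fwhm_mm, voxel_mm, mask):
    """Normal-equation least squares of the image on brute-force RSFs."""
    cols = [
        brute_blur((labels == rid).astype(float), fwhm_mm, voxel_mm)[mask]
        for rid in region_ids
    ]
    A = np.stack(cols, axis=1)
    y = image[mask]
    return np.linalg.solve(A.T @ A, A.T @ y)
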