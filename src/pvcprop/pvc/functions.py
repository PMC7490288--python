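"""Functional front-end to the PVC estimators.

Thin wrappers for one-shot use; the estimator classes are the primary API
when several algorithms share a parcellation and PSF.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..phantom import Parcellation
from ..simulate import PSFModel
from .estimators import (
    GTM,
    SFSRR,
    RBV,
    IterativeYang,
    Labbe,
    MullerGartner,
    paint_regions,
    yang_ratio,
)

__all__ = [
    "gtm_solve",
    "labbe_solve",
    "mg_correct",
    "synthetic_image",
    "yang_correct",
    "rbv_correct",
    "iy_correct",
    "sfsrr_correct",
]


def gtm_solve(image, parc: Parcellation, psf: PSFModel, **kw) -> pd.Series:
    """Geometric-transfer-matrix regional means of ``image``."""
    return GTM(psf.fwhm_mm, **kw).fit(parc).transform(image)


def labbe_solve(image, parc: Parcellation, psf: PSFModel, **kw) -> pd.Series:
    """Labbé least-squares regional means of ``image``."""
    return Labbe(psf.fwhm_mm, **kw).fit(parc).transform(image)


def mg_correct(image, parc: Parcellation, psf: PSFModel, gm_threshold: float = 0.5,
               **kw) -> np.ndarray:
    """Müller-Gärtner grey-matter corrected volume (NaN outside GM domain)."""
    return MullerGartner(psf.fwhm_mm, gm_threshold=gm_threshold, **kw).fit(parc).transform(image)


def synthetic_image(parc: Parcellation, means) -> np.ndarray:
    """Paint-by-number volume from regional means."""
    return paint_regions(parc, means)


def yang_correct(image, synthetic, psf: PSFModel, grid) -> np.ndarray:
    """Single Yang multiplicative correction against a synthetic image."""
    return yang_ratio(np.asarray(image, dtype=float), synthetic, psf, grid)


def rbv_correct(image, parc: Parcellation, psf: PSFModel, **kw) -> np.ndarray:
    """Region-based voxel-wise corrected volume."""
    return RBV(psf.fwhm_mm, **kw).fit(parc).transform(image)


def iy_correct(image, parc: Parcellation, psf: PSFModel, n_iter: int = 10) -> np.ndarray:
    """Iterative-Yang corrected volume (ten iterations by default)."""
    return IterativeYang(psf.fwhm_mm, n_iter=n_iter).fit(parc).transform(image)


def sfsrr_correct(image, parc: Parcellation, psf: PSFModel,
                  structural_source: str = "roi_means", **kw) -> np.ndarray:
    """SFS-RR (or, with ``structural_source='gtm_means'``, modified SFS-RR)."""
    return SFSRR(psf.fwhm_mm, structural_source=structural_source, **kw).fit(parc).transform(image)
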