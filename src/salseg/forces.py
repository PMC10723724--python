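"""Per-pixel driving forces of the hybrid active contour.

Three forces are blended into the single scalar field that drives the
level-set evolution:

* a Difference-of-Gaussians (DoG) edge force whose zero-crossings track
  rapid intensity change,
* a global signed-pressure-force (SPF) region term whose sign at a pixel
  says whether the intensity exceeds the midpoint of the two region
  means ``(j1 + j2) / 2``,
* an adaptive saliency force of the same signed-pressure form, driven by
  the saliency map ``S = |mean(I) - G_sigma * I|`` and its region means
  ``s1, s2``.

Each component is normalized to [-1, 1] so that the blend weights ``s``
and ``w`` are meaningful on a common scale.  The default blend groups
the two intensity terms under ``s``::

    F = s * (w * F_DoG + (1 - w) * F_SPF) + (1 - s) * F_SAL

an un-grouped variant ``s*w*F_DoG + (1-w)*F_SPF + (1-s)*F_SAL`` is
available behind the ``literal_eq2`` flag.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

#: guard added to denominators; constant inputs produce zero force fields
DENOM_GUARD = 1e-10

#: a region whose Heaviside weight mass falls below this fraction of the
#: pixel count is considered degenerate (warning logged)
DEGENERATE_MASS_FRACTION = 1e-6

__all__ = [
    "RegionMeans", "gaussian_blur", "compute_dog", "region_means",
    "compute_spf", "compute_saliency_map", "saliency_means",
    "compute_sal_force", "combine_forces", "DENOM_GUARD",
]


@dataclass(frozen=True)
class RegionMeans:
    """Heaviside-weighted means inside/outside the contour.

    ``j1``/``j2`` are intensity means of the interior/exterior regions
    (the Chan-Vese constants); ``s1``/``s2`` are the analogous means of
    the saliency map.  Only the pair relevant to a force needs to be set.
    """

    j1: float | None = None
    j2: float | None = None
    s1: float | None = None
    s2: float | None = None

    def merged_with(self, other: "RegionMeans") -> "RegionMeans":
        return RegionMeans(
            j1=self.j1 if self.j1 is not None else other.j1,
            j2=self.j2 if self.j2 is not None else other.j2,
            s1=self.s1 if self.s1 is not None else other.s1,
            s2=self.s2 if self.s2 is not None else other.s2,
        )


def gaussian_blur(img: np.ndarray, sigma: float) -> np.ndarray:
    """Separable Gaussian blur, kernel truncated at radius ceil(3*sigma),
    reflect (half-sample symmetric) boundary handling."""
    if not sigma > 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    radius = math.ceil(3.0 * sigma)
    return ndimage.gaussian_filter(
        np.asarray(img, dtype=np.float64), sigma,
        mode="reflect", radius=radius)


def _normalize_max_abs(field: np.ndarray) -> np.ndarray:
    peak = np.abs(field).max() if field.size else 0.0
    if peak < DENOM_GUARD:
        return np.zeros_like(field)
    return field / peak


def compute_dog(img: np.ndarray, sigma1: float, sigma2: float) -> np.ndarray:
    """Difference-of-Gaussians edge force, normalized to [-1, 1].

    ``blur(img, sigma1) - blur(img, sigma2)`` with ``sigma1 < sigma2``;
    positive on the bright side of an edge, negative on the dark side,
    zero-crossing on the edge itself.
    """
    if not 0 < sigma1 < sigma2:
        raise ValueError(
            f"require 0 < sigma1 < sigma2, got sigma1={sigma1}, "
            f"sigma2={sigma2}")
    return _normalize_max_abs(
        gaussian_blur(img, sigma1) - gaussian_blur(img, sigma2))


def _weighted_means(field: np.ndarray, phi: np.ndarray, eps: float,
                    labels: tuple[str, str]) -> tuple[float, float]:
    # local import: levelset also imports this module
    from .levelset import heaviside

    field = np.asarray(field, dtype=np.float64)
    phi = np.asarray(phi, dtype=np.float64)
    if field.shape != phi.shape:
        raise ValueError(
            f"field shape {field.shape} != phi shape {phi.shape}")
    h = heaviside(phi, eps)
    mass_in = h.sum()
    mass_out = (1.0 - h).sum()
    degenerate_cut = DEGENERATE_MASS_FRACTION * field.size
    for mass, label in ((mass_in, labels[0]), (mass_out, labels[1])):
        if mass < degenerate_cut:
            logger.warning(
                "degenerate region: weight mass for %s is %.3g "
                "(< %.3g of pixel count)", label, mass, degenerate_cut)
    mean_in = float((field * h).sum() / (mass_in + DENOM_GUARD))
    mean_out = float((field * (1.0 - h)).sum() / (mass_out + DENOM_GUARD))
    return mean_in, mean_out


def region_means(img: np.ndarray, phi: np.ndarray, eps: float) -> RegionMeans:
    """Chan-Vese intensity means j1 (interior) and j2 (exterior),
    weighted by the regularized Heaviside of phi."""
    j1, j2 = _weighted_means(img, phi, eps, ("j1 (interior)",
                                             "j2 (exterior)"))
    return RegionMeans(j1=j1, j2=j2)


def _signed_pressure(field: np.ndarray, mean_in: float, mean_out: float
                     ) -> np.ndarray:
    deviation = np.asarray(field, dtype=np.float64) - 0.5 * (mean_in + mean_out)
    return _normalize_max_abs(deviation)


def compute_spf(img: np.ndarray, means: RegionMeans) -> np.ndarray:
    """Signed pressure force: (I - (j1+j2)/2) / max|I - (j1+j2)/2|.

    Positive exactly where the intensity exceeds the mid-mean, so the
    contour expands in bright regions and shrinks in dark ones (for
    j1 > j2).  Constant images give a zero field.
    """
    if means.j1 is None or means.j2 is None:
        raise ValueError("SPF requires intensity means j1 and j2")
    if not (np.isfinite(means.j1) and np.isfinite(means.j2)):
        raise ValueError("region means must be finite")
    return _signed_pressure(img, means.j1, means.j2)


def compute_saliency_map(img: np.ndarray, sigma_sal: float) -> np.ndarray:
    """Saliency map S(x) = |mean(I) - (G_sigma * I)(x)|; non-negative."""
    img = np.asarray(img, dtype=np.float64)
    return np.abs(img.mean() - gaussian_blur(img, sigma_sal))


def saliency_means(sal: np.ndarray, phi: np.ndarray, eps: float
                   ) -> RegionMeans:
    """Heaviside-weighted saliency means s1 (interior), s2 (exterior)."""
    s1, s2 = _weighted_means(sal, phi, eps, ("s1 (interior)",
                                             "s2 (exterior)"))
    return RegionMeans(s1=s1, s2=s2)


def compute_sal_force(sal: np.ndarray, means: RegionMeans) -> np.ndarray:
    """Adaptive saliency force: (S - (s1+s2)/2) / max|S - (s1+s2)/2|."""
    if means.s1 is None or means.s2 is None:
        raise ValueError("saliency force requires means s1 and s2")
    if not (np.isfinite(means.s1) and np.isfinite(means.s2)):
        raise ValueError("saliency means must be finite")
    return _signed_pressure(sal, means.s1, means.s2)


def combine_forces(dog: np.ndarray, spf: np.ndarray, sal: np.ndarray,
                   s: float, w: float, literal_eq2: bool = False
                   ) -> np.ndarray:
    """Blend the three component forces into the driving force field."""
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"s must lie in [0, 1], got {s}")
    if not 0.0 <= w <= 1.0:
        raise ValueError(f"w must lie in [0, 1], got {w}")
    dog = np.asarray(dog, dtype=np.float64)
    spf = np.asarray(spf, dtype=np.float64)
    sal = np.asarray(sal, dtype=np.float64)
    if not (dog.shape == spf.shape == sal.shape):
        raise ValueError("force fields must share a shape")
    if literal_eq2:
        return s * w * dog + (1.0 - w) * spf + (1.0 - s) * sal
    return s * (w * dog + (1.0 - w) * spf) + (1.0 - s) * sal
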