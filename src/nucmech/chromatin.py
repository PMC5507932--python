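"""Chromatin-condensation scoring from band-pass-filtered DAPI images.

Condensed chromatin shows up in widefield DAPI images as ~1.5 µm bright
speckles and similarly sized dim spots.  They are isolated with a band-pass
filter passing 0.75–2.5 µm features, realized as a difference of Gaussians
whose sigmas map the cut-offs through the FWHM relation
sigma = cut / (2·sqrt(2 ln 2)).  The condensation score CC sums |band-passed
intensity| over the optically thick part of the nucleus (where the local
ellipsoid thickness exceeds the depth of focus, so the speckle contrast is
not diluted by partial sampling) and normalizes by the integrated nuclear
fluorescence, making the score invariant to staining brightness.  A
peripheral variant restricts the sum to the outermost 25% of the projected
nuclear area, where heterochromatin preferentially sits.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import ndimage

from .core import CalibratedImage, DomainError
from .morphology import NucleusGeometry, NucleusMask

FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclasses.dataclass(frozen=True)
class BandpassSpec:
    low_cut: float = 0.75   # µm
    high_cut: float = 2.5   # µm

    def __post_init__(self) -> None:
        if not 0 < self.low_cut < self.high_cut:
            raise DomainError("need 0 < low_cut < high_cut")

    def sigmas_um(self) -> tuple[float, float]:
        return self.low_cut * FWHM_TO_SIGMA, self.high_cut * FWHM_TO_SIGMA


@dataclasses.dataclass(frozen=True)
class ChromatinMetrics:
    cc: float
    cc_peripheral: float
    thick_region_area: float  # µm²
    flags: tuple[str, ...] = ()


def bandpass(image: CalibratedImage, mask: np.ndarray,
             spec: BandpassSpec = BandpassSpec()) -> np.ndarray:
    """Difference-of-Gaussians band-pass inside the mask, zero outside."""
    if spec.high_cut < 3.0 * image.pixel_size:
        raise DomainError("band-pass cut-offs unresolvable at this pixel size")
    s_small, s_large = (s / image.pixel_size for s in spec.sigmas_um())
    masked = np.where(mask, image.pixels, 0.0).astype(float)
    support = mask.astype(float)
    # normalized convolution so the mask edge does not ring into the score
    def _blur(arr, sigma):
        num = ndimage.gaussian_filter(arr, sigma)
        den = ndimage.gaussian_filter(support, sigma)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(den > 1e-9, num / den, 0.0)
    out = _blur(masked, s_small) - _blur(masked, s_large)
    out[~mask] = 0.0
    return out


def thickness_map_from_geometry(geometry: NucleusGeometry,
                                shape: tuple[int, int],
                                pixel_size: float) -> np.ndarray:
    """Ellipsoid thickness model evaluated from the fitted geometry."""
    from .core import ellipsoid_thickness_map
    return ellipsoid_thickness_map(shape, geometry.centroid_rc, geometry.a,
                                   geometry.b, geometry.c, geometry.theta_nuc,
                                   pixel_size)


def peripheral_ring(mask: np.ndarray, fraction: float = 0.25
                    ) -> tuple[np.ndarray, bool]:
    """Outermost ``fraction`` of the projected area, by iterative erosion.

    Erodes one step at a time until the removed ring first reaches the
    target pixel count, then keeps whichever of the last two rings is
    closer (within one erosion step by construction).  Returns
    ``(ring_mask, flagged)``; a mask too small to erode comes back whole
    and flagged.
    """
    if not 0 < fraction < 1:
        raise DomainError("fraction must be in (0, 1)")
    total = int(mask.sum())
    if total == 0:
        raise DomainError("empty mask")
    target = fraction * total
    structure = ndimage.generate_binary_structure(2, 2)
    eroded = mask
    prev_ring = None
    while True:
        nxt = ndimage.binary_erosion(eroded, structure=structure)
        ring = mask & ~nxt
        removed = int(ring.sum())
        if nxt.sum() == 0 and removed < target:
            return mask.copy(), True  # cannot erode far enough
        if removed >= target:
            if prev_ring is not None and abs(prev_ring.sum() - target) < abs(removed - target):
                return prev_ring, False
            return ring, removed == total  # whole mask gone in one step
        prev_ring = ring
        eroded = nxt


def chromatin_condensation(image: CalibratedImage, nucleus: NucleusMask,
                           thickness_map: np.ndarray,
                           depth_of_focus: float = 3.0,
                           spec: BandpassSpec = BandpassSpec(),
                           peripheral_fraction: float = 0.25
                           ) -> ChromatinMetrics:
    """CC = Σ|band-passed| over the optically thick region, divided by the
    integrated nuclear fluorescence I_T.

    The peripheral score uses the outer-ring mask with the same I_T
    denominator (and no thickness gate — the rim is thin by construction),
    so global and peripheral scores share a scale.
    """
    if nucleus.i_total <= 0:
        raise DomainError("non-positive integrated nuclear intensity")
    filtered = bandpass(image, nucleus.mask, spec)
    flags: list[str] = []
    thick = nucleus.mask & (thickness_map > depth_of_focus)
    if not thick.any():
        thick = nucleus.mask
        flags.append("no_pixels_above_depth_of_focus")
    cc = float(np.abs(filtered[thick]).sum()) / nucleus.i_total

    ring, ring_flag = peripheral_ring(nucleus.mask, peripheral_fraction)
    if ring_flag:
        flags.append("peripheral_ring_is_whole_mask")
    cc_peri = float(np.abs(filtered[ring]).sum()) / nucleus.i_total
    return ChromatinMetrics(cc=cc, cc_peripheral=cc_peri,
                            thick_region_area=float(thick.sum())
                            * image.pixel_area,
                            flags=tuple(flags))
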