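"""Nucleus segmentation and 3D gross morphology from a single DAPI image.

The axial dimension of the nucleus is not imaged directly: in a widefield
image of a thick, uniformly stained nucleus the pixel intensity acts as a
readout of the local axial thickness.  The radial fluorescence-intensity
profile I(r) of an ellipsoidal nucleus therefore follows
I(r) = I0·sqrt(1 − r²) outside the central plateau caused by the finite
depth of focus, and the fitted central intensity I0 divided by a
calibration factor k (fluorescence per µm of thickness) gives the nuclear
height.  In-plane semi-axes and orientation come from the moment-equivalent
ellipse of the segmented projection.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy import ndimage, optimize
from skimage.filters import median as median_filter
from skimage.filters import threshold_otsu
from skimage.morphology import disk

from .core import (
    CalibratedImage,
    DomainError,
    FitError,
    NoNucleusError,
    moment_ellipse,
    physical_coords,
    rotate_into_frame,
)

log = logging.getLogger("nucmech")

MIN_NUCLEUS_AREA_UM2 = 20.0


@dataclasses.dataclass(frozen=True)
class NucleusMask:
    """Binary nucleus mask plus summary quantities of the segmentation."""

    mask: np.ndarray
    centroid_rc: tuple[float, float]
    projected_area: float  # µm²
    background: float      # fluorescence units
    i_total: float         # background-subtracted integrated intensity


@dataclasses.dataclass(frozen=True)
class RadialProfile:
    """Mean background-subtracted intensity binned by normalized elliptical
    radius (0 at the centroid, 1 at the fitted outline)."""

    r: np.ndarray
    intensity: np.ndarray
    plateau_level: float
    plateau_extent: float


@dataclasses.dataclass(frozen=True)
class NucleusGeometry:
    """Semi-axes (a ≥ b in-plane, c axial), orientation and total intensity."""

    a: float
    b: float
    c: float
    height: float
    theta_nuc: float  # degrees in [0, 180)
    i_total: float
    aspect_ratio_xy: float
    centroid_rc: tuple[float, float]
    degenerate_orientation: bool = False


def segment_nucleus(image: CalibratedImage,
                    min_area_um2: float = MIN_NUCLEUS_AREA_UM2,
                    k_sigma: float = 3.0,
                    edge_fraction: float = 0.02) -> NucleusMask:
    """Segment the nucleus in a DAPI image.

    Detection is an Otsu threshold on a median-filtered image; because the
    widefield intensity of an ellipsoidal nucleus tapers continuously to
    background at the projected rim, the boundary is then refined down to
    background + max(k·σ_bg, ``edge_fraction`` of the peak range) so the
    mask covers the full projection rather than only its bright core.
    Background is the median intensity outside the detected object;
    ``i_total`` is the sum of (intensity − background) over the mask.
    Multiple nuclei in the field keep the largest with a warning.
    """
    px = image.pixels
    smoothed = median_filter(px, footprint=disk(2))
    thresh = threshold_otsu(smoothed)
    rough = ndimage.binary_fill_holes(smoothed > thresh)
    outside = ~ndimage.binary_dilation(rough, iterations=3)
    if not outside.any():
        outside = ~rough
    bg_est = float(np.median(px[outside]))
    sigma_bg = float(px[outside].std())
    refined_thresh = bg_est + max(k_sigma * sigma_bg,
                                  edge_fraction * (smoothed.max() - bg_est))
    binary = ndimage.binary_fill_holes(smoothed > refined_thresh)
    labels, n_comp = ndimage.label(binary)
    if n_comp == 0:
        raise NoNucleusError("no nucleus found")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                               index=np.arange(1, n_comp + 1))
    min_px = min_area_um2 / image.pixel_area
    big = np.nonzero(sizes >= min_px)[0]
    if big.size == 0:
        raise NoNucleusError("no nucleus found above minimum area")
    if big.size > 1:
        log.warning("multiple nuclei in field; keeping the largest")
    mask = labels == (1 + int(np.argmax(sizes)))
    background = float(np.median(px[~mask]))
    i_total = float((px[mask] - background).sum())
    rr, cc = np.nonzero(mask)
    return NucleusMask(mask=mask,
                       centroid_rc=(float(rr.mean()), float(cc.mean())),
                       projected_area=float(mask.sum()) * image.pixel_area,
                       background=background,
                       i_total=i_total)


def radial_profile(image: CalibratedImage, nucleus: NucleusMask,
                   n_bins: int = 50, plateau_tol: float = 0.05
                   ) -> RadialProfile:
    """Bin pixels by normalized elliptical radius and average their
    background-subtracted intensity.

    The elliptical radius comes from the moment-equivalent ellipse of the
    mask, so elongated nuclei are profiled along self-similar ellipses
    rather than circles.  The plateau level is the median of bins within
    ``plateau_tol`` of the profile maximum; the plateau extent is the
    largest radius still within that tolerance.
    """
    centre, a, b, theta = moment_ellipse(nucleus.mask, image.pixel_size)
    if 2.0 * b / image.pixel_size < 5.0:
        raise DomainError("nucleus too small to profile")
    x, y = physical_coords(image.shape, centre, image.pixel_size)
    xp, yp = rotate_into_frame(x, y, theta)
    r = np.sqrt((xp / a) ** 2 + (yp / b) ** 2)

    inside = nucleus.mask & (r <= 1.0)
    vals = image.pixels[inside] - nucleus.background
    radii = r[inside]
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(radii, edges) - 1, 0, n_bins - 1)
    sums = np.bincount(idx, weights=vals, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    nonempty = counts > 0
    centres = 0.5 * (edges[:-1] + edges[1:])[nonempty]
    means = sums[nonempty] / counts[nonempty]

    peak = means.max()
    near_peak = means >= (1.0 - plateau_tol) * peak
    plateau_level = float(np.median(means[near_peak]))
    plateau_extent = float(centres[near_peak].max())
    return RadialProfile(r=centres, intensity=means,
                         plateau_level=plateau_level,
                         plateau_extent=plateau_extent)


def _quarter_ellipse(r, i0, radius):
    return i0 * np.sqrt(np.clip(1.0 - (r / radius) ** 2, 0.0, None))


def fit_height(profile: RadialProfile, calibration_k: float,
               depth_of_focus: float = 3.0) -> float:
    """Nuclear height from a quarter-ellipse fit of the radial profile.

    Fits I(r) = I0·sqrt(1 − (r/R)²) over the bins outside the plateau (the
    outermost pixels, where intensity genuinely tracks thickness); height =
    I0 / k.  If the plateau intensity corresponds to a thickness below the
    depth of focus the nucleus never saturates the focal depth and all bins
    are used.
    """
    if calibration_k <= 0:
        raise DomainError("calibration_k must be positive")
    has_plateau = profile.plateau_level / calibration_k > depth_of_focus
    use = profile.r > profile.plateau_extent if has_plateau else slice(None)
    r = profile.r[use]
    i = profile.intensity[use]
    if r.size < 5:
        raise FitError("too few non-plateau bins for the height fit")
    try:
        popt, _ = optimize.curve_fit(
            _quarter_ellipse, r, i,
            p0=(max(i.max(), profile.plateau_level), 1.02),
            bounds=([0.0, 0.3], [np.inf, 3.0]), maxfev=10000)
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"height fit failed: {exc}") from exc
    i0 = float(popt[0])
    if i0 <= 0:
        raise FitError("height fit failed: non-positive central intensity")
    return i0 / calibration_k


def measure_geometry(image: CalibratedImage, nucleus: NucleusMask,
                     height: float,
                     degenerate_tol: float = 1e-3) -> NucleusGeometry:
    """Full 3D gross morphology: in-plane semi-axes and orientation from the
    moment-equivalent ellipse of the mask, axial semi-axis c = height/2."""
    if height <= 0:
        raise DomainError("height must be positive")
    centre, a, b, theta = moment_ellipse(nucleus.mask, image.pixel_size)
    degenerate = (a - b) / a < degenerate_tol
    if degenerate:
        theta = 0.0
    return NucleusGeometry(a=a, b=b, c=height / 2.0, height=height,
                           theta_nuc=theta, i_total=nucleus.i_total,
                           aspect_ratio_xy=a / b, centroid_rc=centre,
                           degenerate_orientation=degenerate)
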