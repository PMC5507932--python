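"""Shared primitives for the pipeline.

Conventions used throughout the package:

* images are 2D float arrays indexed ``[row, col]``; physical coordinates are
  ``x = col * pixel_size`` and ``y = -row * pixel_size`` so that angles are
  measured counter-clockwise from the image x-axis in the usual mathematical
  sense;
* every length downstream of an image is in µm, every area in µm²;
* orientations are axial (period 180°), reported in degrees in [0, 180); all
  comparisons between orientations go through doubled-angle circular
  arithmetic.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from pathlib import Path

import numpy as np
import tifffile

log = logging.getLogger("nucmech")


class NucmechError(Exception):
    """Base class for pipeline failures."""


class NoNucleusError(NucmechError):
    """No nucleus-sized object found in the DAPI channel."""


class NoCellError(NucmechError):
    """No cell-sized object found in a cytoskeletal channel."""


class FitError(NucmechError):
    """A model fit failed to converge or returned an unusable optimum."""


class DomainError(NucmechError):
    """Input values outside the domain of an operation."""


# --------------------------------------------------------------------------
# Calibrated images
# --------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class CalibratedImage:
    """A grey-scale fluorescence image with a known pixel size (µm/px)."""

    pixels: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise DomainError("pixel_size must be positive")
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise DomainError("expected a single-channel 2D image")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def pixel_area(self) -> float:
        """Area of one pixel in µm²."""
        return self.pixel_size ** 2


def write_tiff(path: str | Path, image: CalibratedImage,
               ground_truth: dict | None = None) -> None:
    """Write a 16-bit TIFF with the pixel size in ImageJ metadata.

    A sidecar ``<stem>.json`` carries the pixel size (and the ground-truth
    record for synthetic images) so calibration survives tools that strip
    TIFF tags.
    """
    path = Path(path)
    px = np.clip(np.round(image.pixels), 0, 65535).astype(np.uint16)
    tifffile.imwrite(
        path, px, imagej=True,
        resolution=(1.0 / image.pixel_size, 1.0 / image.pixel_size),
        metadata={"unit": "um"},
    )
    sidecar = {"pixel_size_um": image.pixel_size}
    if ground_truth is not None:
        sidecar["ground_truth"] = ground_truth
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_tiff(path: str | Path, pixel_size: float | None = None) -> CalibratedImage:
    """Read a single-channel TIFF; pixel size from sidecar JSON, ImageJ
    resolution tags, or the explicit argument (in that order of preference)."""
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        px = tf.asarray().astype(float)
        if pixel_size is None:
            sidecar = path.with_suffix(".json")
            if sidecar.exists():
                pixel_size = json.loads(sidecar.read_text()).get("pixel_size_um")
        if pixel_size is None:
            page = tf.pages[0]
            res = page.tags.get("XResolution")
            if res is not None:
                num, den = res.value
                if num:
                    pixel_size = den / num
    if pixel_size is None:
        raise DomainError(f"no pixel size available for {path}")
    if px.ndim == 3:  # single-channel stored with a unit axis
        px = np.squeeze(px)
    return CalibratedImage(px, float(pixel_size))


# --------------------------------------------------------------------------
# Axial (period-180°) angle arithmetic
# --------------------------------------------------------------------------

def wrap_axial(theta_deg):
    """Map an orientation to [0, 180)."""
    return np.mod(theta_deg, 180.0)


def axial_resultant(theta_deg, weights=None) -> tuple[float, float]:
    """Resultant length and mean of axial angles via angle doubling.

    Returns ``(R, mean_deg)`` where ``R`` is the length of the (weighted)
    mean resultant vector of the doubled angles (0 = uniform, 1 = parallel)
    and ``mean_deg`` the axial circular mean in [0, 180).
    """
    theta = np.deg2rad(np.asarray(theta_deg, dtype=float)) * 2.0
    if theta.size == 0:
        raise DomainError("no angles supplied")
    if weights is None:
        z = np.exp(1j * theta).mean()
    else:
        w = np.asarray(weights, dtype=float)
        tot = w.sum()
        if tot <= 0:
            raise DomainError("weights sum to zero")
        z = (w * np.exp(1j * theta)).sum() / tot
    mean = wrap_axial(np.rad2deg(np.angle(z)) / 2.0)
    return float(abs(z)), float(mean)


def axial_sd_deg(resultant_length: float) -> float:
    """Circular standard deviation of axial data, degrees.

    ``sqrt(-2 ln R)`` on the doubled angles, halved back to the axial scale.
    """
    r = min(max(resultant_length, 1e-300), 1.0)
    return math.degrees(math.sqrt(-2.0 * math.log(r)) / 2.0)


def axial_difference(theta1_deg, theta2_deg):
    """Signed axial difference theta1 − theta2, mapped to (−90, 90]."""
    d = np.mod(np.asarray(theta1_deg, dtype=float)
               - np.asarray(theta2_deg, dtype=float), 180.0)
    return np.where(d > 90.0, d - 180.0, d)


# --------------------------------------------------------------------------
# Ellipse / ellipsoid geometry helpers
# --------------------------------------------------------------------------

def physical_coords(shape: tuple[int, int], centre_rc: tuple[float, float],
                    pixel_size: float) -> tuple[np.ndarray, np.ndarray]:
    """(x, y) in µm for every pixel, centred on ``centre_rc``, y pointing up."""
    rows, cols = np.mgrid[0:shape[0], 0:shape[1]]
    x = (cols - centre_rc[1]) * pixel_size
    y = -(rows - centre_rc[0]) * pixel_size
    return x, y


def rotate_into_frame(x, y, theta_deg):
    """Rotate coordinates into the frame whose x-axis lies along theta."""
    th = math.radians(theta_deg)
    xp = x * math.cos(th) + y * math.sin(th)
    yp = -x * math.sin(th) + y * math.cos(th)
    return xp, yp


def ellipsoid_thickness_map(shape, centre_rc, a, b, c, theta_deg,
                            pixel_size) -> np.ndarray:
    """Axial thickness t(x, y) = 2c·sqrt(1 − (x'/a)² − (y'/b)²) of an
    ellipsoid with in-plane semi-axes a, b (a along theta) and axial
    semi-axis c, evaluated at pixel centres; zero outside the projection."""
    x, y = physical_coords(shape, centre_rc, pixel_size)
    xp, yp = rotate_into_frame(x, y, theta_deg)
    arg = 1.0 - (xp / a) ** 2 - (yp / b) ** 2
    return 2.0 * c * np.sqrt(np.clip(arg, 0.0, None))


def moment_ellipse(mask: np.ndarray, pixel_size: float
                   ) -> tuple[tuple[float, float], float, float, float]:
    """Moment-equivalent ellipse of a binary mask.

    Returns ``(centre_rc, a_um, b_um, theta_deg)`` with a ≥ b the semi-axes
    in µm and theta the major-axis orientation in [0, 180).  For a filled
    ellipse the second central moments give exactly a²/4 and b²/4 along the
    principal axes, so semi-axes are 2·sqrt(eigenvalue).
    """
    rr, cc = np.nonzero(mask)
    if rr.size == 0:
        raise DomainError("empty mask")
    r0, c0 = rr.mean(), cc.mean()
    x = (cc - c0) * pixel_size
    y = -(rr - r0) * pixel_size
    m20 = np.mean(x * x)
    m02 = np.mean(y * y)
    m11 = np.mean(x * y)
    common = math.hypot(m20 - m02, 2.0 * m11)
    lam1 = 0.5 * (m20 + m02 + common)
    lam2 = 0.5 * (m20 + m02 - common)
    a = 2.0 * math.sqrt(max(lam1, 0.0))
    b = 2.0 * math.sqrt(max(lam2, 0.0))
    theta = wrap_axial(math.degrees(0.5 * math.atan2(2.0 * m11, m20 - m02)))
    return (float(r0), float(c0)), float(a), float(b), float(theta)
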