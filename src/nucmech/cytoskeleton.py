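"""Stress-fibre segmentation and per-cell cytoskeletal descriptors.

The quantification runs in three steps: (1) initial fibre segmentation by
ridge enhancement — the maximum response over a bank of elongated,
zero-mean oriented kernels (12 orientations, 15° apart); (2) refinement —
segmented components shorter than a minimum length or insufficiently
elongated are discarded; (3) background determination and subtraction — a
large-kernel median background is removed from the fibre brightness.

Per-cell descriptors are the cell spread area (CSA), the summed
background-subtracted fibre brightness ("CSK amount", later median
normalized per protein so channels with different dye brightness are
comparable), the fibre anisotropy (brightness-weighted resultant length of
the doubled orientation angles: 0 random, 1 parallel) and the main fibre
orientation (axial circular mean).
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .core import CalibratedImage, DomainError, NoCellError, axial_resultant

log = logging.getLogger("nucmech")

N_ORIENTATIONS = 12
KERNEL_LENGTH_UM = 3.0
KERNEL_WIDTH_UM = 0.6
MIN_FIBRE_LENGTH_UM = 2.0
MIN_FIBRE_ASPECT = 2.0
MIN_CELL_AREA_UM2 = 200.0


@dataclasses.dataclass(frozen=True)
class FibreMaps:
    """Per-pixel fibre brightness and local orientation inside the cell."""

    brightness_map: np.ndarray   # background-subtracted, 0 off fibres
    orientation_map: np.ndarray  # degrees [0, 180), NaN off fibres
    cell_mask: np.ndarray
    pixel_size: float


@dataclasses.dataclass(frozen=True)
class CytoskeletonMetrics:
    csa: float
    csk_amount_raw: float
    anisotropy: float
    theta_fib: float  # NaN when no fibre pixels
    flags: tuple[str, ...] = ()


def segment_cell(image: CalibratedImage, k_sigma: float = 2.0,
                 min_area_um2: float = MIN_CELL_AREA_UM2,
                 border_px: int = 5) -> tuple[np.ndarray, float]:
    """Cell mask and spread area.

    Background level and noise come from the image border frame; the
    smoothed image is thresholded at background + k·σ (σ floored at 1% of
    the dynamic range so noise-free synthetic images threshold sensibly),
    the largest component kept and holes filled.
    """
    px = image.pixels
    border = np.concatenate([px[:border_px].ravel(), px[-border_px:].ravel(),
                             px[:, :border_px].ravel(),
                             px[:, -border_px:].ravel()])
    bg = float(np.median(border))
    sigma = max(float(border.std()),
                0.01 * max(float(np.percentile(px, 99.5)) - bg, 1e-12))
    smoothed = ndimage.gaussian_filter(px, 1.0)
    binary = smoothed > bg + k_sigma * sigma
    labels, n_comp = ndimage.label(binary)
    if n_comp == 0:
        raise NoCellError("no cell found")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                               index=np.arange(1, n_comp + 1))
    if sizes.max() * image.pixel_area < min_area_um2:
        raise NoCellError("no cell found above minimum area")
    if (sizes * image.pixel_area >= min_area_um2).sum() > 1:
        log.warning("multiple cells in field; keeping the largest")
    mask = ndimage.binary_fill_holes(labels == (1 + int(np.argmax(sizes))))
    return mask, float(mask.sum()) * image.pixel_area


def _oriented_kernel(theta_deg: float, pixel_size: float) -> np.ndarray:
    """Zero-mean elongated Gaussian ridge kernel along theta."""
    sig_l = 0.5 * KERNEL_LENGTH_UM / pixel_size
    sig_w = 0.5 * KERNEL_WIDTH_UM / pixel_size
    half = int(math.ceil(2.5 * sig_l))
    rows, cols = np.mgrid[-half:half + 1, -half:half + 1]
    x, y = cols.astype(float), -rows.astype(float)
    th = math.radians(theta_deg)
    u = x * math.cos(th) + y * math.sin(th)
    v = -x * math.sin(th) + y * math.cos(th)
    kern = np.exp(-(u ** 2) / (2 * sig_l ** 2) - (v ** 2) / (2 * sig_w ** 2))
    kern -= kern.mean()  # flat and linear-gradient backgrounds respond with 0
    return kern / np.abs(kern).sum()


def segment_fibres(image: CalibratedImage, cell_mask: np.ndarray,
                   rel_threshold: float = 0.25,
                   bg_kernel_um: float = 10.0) -> FibreMaps:
    """Three-step fibre segmentation; an empty fibre set is a valid result."""
    px = image.pixels.astype(float)
    angles = np.arange(N_ORIENTATIONS) * (180.0 / N_ORIENTATIONS)
    best = np.full(px.shape, -np.inf)
    argbest = np.zeros(px.shape)
    for theta in angles:
        resp = signal.fftconvolve(px, _oriented_kernel(theta, image.pixel_size),
                                  mode="same")
        better = resp > best
        best[better] = resp[better]
        argbest[better] = theta

    candidates = cell_mask & (best > rel_threshold * max(best.max(), 1e-12))
    # refinement: drop components too short or too round to be fibres
    labels, n_comp = ndimage.label(candidates,
                                   structure=ndimage.generate_binary_structure(2, 2))
    fibre_mask = np.zeros_like(candidates)
    if n_comp:
        from .core import moment_ellipse
        for lab in range(1, n_comp + 1):
            comp = labels == lab
            try:
                _, major, minor, _ = moment_ellipse(comp, image.pixel_size)
            except DomainError:
                continue
            if 2.0 * major < MIN_FIBRE_LENGTH_UM:
                continue
            if major / max(minor, 0.25 * image.pixel_size) < MIN_FIBRE_ASPECT:
                continue
            fibre_mask |= comp

    size_px = max(3, int(round(bg_kernel_um / image.pixel_size)) | 1)
    local_bg = ndimage.median_filter(px, size=size_px)
    brightness = np.where(fibre_mask, np.clip(px - local_bg, 0.0, None), 0.0)
    orientation = np.where(brightness > 0, argbest, np.nan)
    return FibreMaps(brightness_map=brightness, orientation_map=orientation,
                     cell_mask=cell_mask, pixel_size=image.pixel_size)


def fibre_descriptors(maps: FibreMaps, csa: float) -> CytoskeletonMetrics:
    """Brightness-weighted doubled-angle statistics over the fibre pixels."""
    sel = maps.brightness_map > 0
    amount = float(maps.brightness_map[sel].sum())
    if not sel.any() or amount <= 0:
        return CytoskeletonMetrics(csa=csa, csk_amount_raw=0.0, anisotropy=0.0,
                                   theta_fib=float("nan"),
                                   flags=("no_fibres",))
    resultant, mean_theta = axial_resultant(maps.orientation_map[sel],
                                            weights=maps.brightness_map[sel])
    return CytoskeletonMetrics(csa=csa, csk_amount_raw=amount,
                               anisotropy=resultant, theta_fib=mean_theta)


def normalize_amounts(table: pd.DataFrame, protein_col: str = "protein",
                      amount_col: str = "csk_amount_raw",
                      out_col: str = "csk_amount") -> pd.DataFrame:
    """Median-normalize CSK amounts within each protein so channels with
    different dye brightness share a scale (the median cell sits at 1)."""
    if table.empty:
        raise DomainError("empty table")
    out = table.copy()
    for protein, group in table.groupby(protein_col):
        if len(group) < 2:
            raise DomainError(f"fewer than 2 cells for protein {protein!r}")
        med = group[amount_col].median()
        if med <= 0:
            raise DomainError(f"non-positive median amount for {protein!r}")
        out.loc[group.index, out_col] = group[amount_col] / med
    return out
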