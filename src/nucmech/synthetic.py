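"""Synthetic ground-truth data for every pipeline stage.

Two kinds of fixtures are produced:

* rendered widefield-like fluorescence images — ellipsoidal nuclei whose
  pixel intensity is proportional to the local axial thickness of the
  ellipsoid (the imaging model behind the radial-profile height estimate),
  optionally decorated with ~1.5 µm chromatin speckles, and "cells" filled
  with oriented fibrillar structures;
* tabular single-cell populations whose cytoskeletal amounts follow
  [X] ∝ CSA^γ and whose nuclear responses follow the multiplicative
  power-law models, with multiplicative log-normal noise.

Every generator is fully reproducible from its seed and returns the
ground-truth record alongside the data, so each downstream estimator can be
tested for parameter recovery without external data.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import line_aa

from .core import (
    CalibratedImage,
    DomainError,
    axial_resultant,
    ellipsoid_thickness_map,
    physical_coords,
    wrap_axial,
)

FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))

#: Power-law exponents of filamentous assembly versus cell spread area,
#: one per cytoskeletal protein (actin, myosin, tubulin, vimentin).
DEFAULT_GAMMA = {"actin": 0.56, "myosin": 0.37, "tubulin": 1.05, "vimentin": 0.76}

#: Multiplicative global-fit models of nuclear responses on median-centred
#: cytoskeletal amounts: Y = Y0 · Π_X (X/⟨X⟩)^α_X.
DEFAULT_MODEL_EXPONENTS = {
    "volume": {"myosin": 0.094, "tubulin": 0.073, "vimentin": 0.125},
    "nu": {"actin": -0.152, "vimentin": -0.102},
    "e_mod": {"myosin": 0.192, "tubulin": 0.225, "vimentin": 0.443},
    "cc": {"actin": 0.081, "vimentin": -0.072},
    "height_model": {"actin": -0.064, "vimentin": -0.078},
}

DEFAULT_MODEL_PREFACTORS = {
    "volume": 1.4323,
    "nu": -0.440,
    "e_mod": 58.39,
    "cc": 0.0491,
    "height_model": 7.80,
}

#: Rational height law h = a + b/(c + CSA): bounds h(0) = 12.9 µm and
#: h(∞) = 5.7 µm with the cross-over scale c = 2000 µm².
DEFAULT_RATIONAL = (5.7, 14400.0, 2000.0)

DEFAULT_CSA_RANGE = (843.0, 18000.0)

PROTEINS = ("actin", "myosin", "tubulin", "vimentin")


# --------------------------------------------------------------------------
# Nucleus image rendering
# --------------------------------------------------------------------------

@dataclasses.dataclass
class SyntheticNucleusSpec:
    """Parameters of one rendered nucleus.

    ``intensity_per_um`` is the calibration factor k (fluorescence units per
    µm of axial thickness); ``speckle_amplitude`` is a signed fraction of
    the local noise-free intensity, with half the speckles bright and half
    dim.  ``blur_sigma`` (µm) optionally applies a Gaussian blur to the
    noise-free signal; the default renders intensity strictly proportional
    to thickness so ground truth stays analytic.
    """

    semi_axis_a: float = 8.0
    semi_axis_b: float = 5.0
    semi_axis_c: float = 3.0
    orientation_deg: float = 0.0
    intensity_per_um: float = 100.0
    speckle_count: int = 0
    speckle_diameter: float = 1.5
    speckle_amplitude: float = 0.0
    background_level: float = 50.0
    noise_sd: float = 0.0
    pixel_size: float = 0.32
    image_shape: tuple[int, int] = (160, 160)
    blur_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.semi_axis_a, self.semi_axis_b, self.semi_axis_c) <= 0:
            raise DomainError("semi-axes must be positive")
        if self.speckle_diameter <= 0:
            raise DomainError("speckle_diameter must be positive")
        if self.pixel_size <= 0:
            raise DomainError("pixel_size must be positive")
        if self.speckle_count < 0:
            raise DomainError("speckle_count must be >= 0")


def render_nucleus_image(spec: SyntheticNucleusSpec
                         ) -> tuple[CalibratedImage, dict]:
    """Render one nucleus and return the image plus its ground truth.

    Pixel model: background + k·t(x, y) + speckle field + Gaussian noise,
    where t is the axial thickness of the ellipsoid.  The ground-truth
    ``I_T`` is the noise-free integrated intensity above background
    (thickness signal plus speckle field).
    """
    h, w = spec.image_shape
    centre = ((h - 1) / 2.0, (w - 1) / 2.0)
    a, b = spec.semi_axis_a, spec.semi_axis_b
    th = math.radians(spec.orientation_deg)
    # bounding half-extents of the rotated projected ellipse
    wx = math.hypot(a * math.cos(th), b * math.sin(th))
    wy = math.hypot(a * math.sin(th), b * math.cos(th))
    margin = 2.0 * spec.pixel_size
    if (wx + margin > centre[1] * spec.pixel_size
            or wy + margin > centre[0] * spec.pixel_size):
        raise DomainError("ellipsoid projection exceeds the field of view")

    thickness = ellipsoid_thickness_map(
        (h, w), centre, a, b, spec.semi_axis_c,
        spec.orientation_deg, spec.pixel_size)
    signal = spec.intensity_per_um * thickness

    rng = np.random.default_rng(spec.seed)
    if spec.speckle_count:
        x, y = physical_coords((h, w), centre, spec.pixel_size)
        sigma = spec.speckle_diameter * FWHM_TO_SIGMA
        # uniform positions inside the projected ellipse (kept off the rim)
        u = rng.uniform(0.0, 1.0, spec.speckle_count)
        phi = rng.uniform(0.0, 2.0 * math.pi, spec.speckle_count)
        xe = 0.85 * a * np.sqrt(u) * np.cos(phi)
        ye = 0.85 * b * np.sqrt(u) * np.sin(phi)
        cx = xe * math.cos(th) - ye * math.sin(th)
        cy = xe * math.sin(th) + ye * math.cos(th)
        signs = np.where(np.arange(spec.speckle_count) % 2 == 0, 1.0, -1.0)
        for k in range(spec.speckle_count):
            rr = centre[0] - cy[k] / spec.pixel_size
            cc = centre[1] + cx[k] / spec.pixel_size
            local = signal[int(round(rr)), int(round(cc))]
            amp = signs[k] * spec.speckle_amplitude * local
            signal = signal + amp * np.exp(
                -((x - cx[k]) ** 2 + (y - cy[k]) ** 2) / (2.0 * sigma ** 2))

    if spec.blur_sigma > 0:
        signal = ndimage.gaussian_filter(
            signal, spec.blur_sigma / spec.pixel_size)

    i_total = float(signal.sum())
    pixels = spec.background_level + signal
    if spec.noise_sd > 0:
        pixels = pixels + rng.normal(0.0, spec.noise_sd, size=pixels.shape)

    truth = {
        "a": a, "b": b, "c": spec.semi_axis_c,
        "theta_deg": wrap_axial(spec.orientation_deg),
        "height": 2.0 * spec.semi_axis_c,
        "I_T": i_total,
        "volume": 4.0 / 3.0 * math.pi * a * b * spec.semi_axis_c,
        "centre_rc": centre,
    }
    return CalibratedImage(pixels, spec.pixel_size), truth


# --------------------------------------------------------------------------
# Fibre image rendering
# --------------------------------------------------------------------------

def render_fibre_image(n_fibres: int,
                       orientation_kappa: float,
                       mean_orientation_deg: float,
                       fibre_intensity: float = 200.0,
                       background: float = 30.0,
                       noise_sd: float = 0.0,
                       pixel_size: float = 0.32,
                       image_shape: tuple[int, int] = (256, 256),
                       seed: int = 0,
                       cell_semi_axes: tuple[float, float] | None = None,
                       cytoplasm_level: float = 25.0,
                       fibre_length_um: tuple[float, float] = (6.0, 14.0),
                       ) -> tuple[CalibratedImage, dict]:
    """Render a cell filled with straight fibres of a set axial orientation
    distribution.

    Fibre orientations are drawn from an axial von Mises: the doubled angle
    2θ follows a von Mises with concentration ``orientation_kappa`` around
    2·mean; ``kappa = inf`` puts every fibre exactly at the mean, ``kappa =
    0`` is uniform.  Fibres are anti-aliased line segments ~2–3 px wide,
    clipped to an elliptical cell body that also carries a diffuse
    cytoplasmic level so cell segmentation sees the body.
    """
    if n_fibres < 0:
        raise DomainError("n_fibres must be >= 0")
    if orientation_kappa < 0:
        raise DomainError("orientation_kappa must be >= 0")
    h, w = image_shape
    centre = ((h - 1) / 2.0, (w - 1) / 2.0)
    if cell_semi_axes is None:
        cell_semi_axes = (0.42 * w * pixel_size, 0.38 * h * pixel_size)
    ca, cb = cell_semi_axes

    x, y = physical_coords((h, w), centre, pixel_size)
    cell_mask = (x / ca) ** 2 + (y / cb) ** 2 <= 1.0

    rng = np.random.default_rng(seed)
    mu2 = 2.0 * math.radians(mean_orientation_deg)
    if n_fibres == 0:
        thetas = np.empty(0)
    elif math.isinf(orientation_kappa):
        thetas = np.full(n_fibres, wrap_axial(mean_orientation_deg))
    elif orientation_kappa == 0:
        thetas = rng.uniform(0.0, 180.0, n_fibres)
    else:
        doubled = rng.vonmises(mu2, orientation_kappa, n_fibres)
        thetas = wrap_axial(np.rad2deg(doubled) / 2.0)

    canvas = np.zeros((h, w))
    for k in range(n_fibres):
        u, phi = rng.uniform(), rng.uniform(0.0, 2.0 * math.pi)
        cx = 0.9 * ca * math.sqrt(u) * math.cos(phi)
        cy = 0.9 * cb * math.sqrt(u) * math.sin(phi)
        length = rng.uniform(*fibre_length_um)
        t = math.radians(thetas[k])
        dx, dy = 0.5 * length * math.cos(t), 0.5 * length * math.sin(t)
        r0 = int(round(centre[0] - (cy - dy) / pixel_size))
        c0 = int(round(centre[1] + (cx - dx) / pixel_size))
        r1 = int(round(centre[0] - (cy + dy) / pixel_size))
        c1 = int(round(centre[1] + (cx + dx) / pixel_size))
        r0, r1 = np.clip([r0, r1], 0, h - 1)
        c0, c1 = np.clip([c0, c1], 0, w - 1)
        rr, cc, val = line_aa(r0, c0, r1, c1)
        canvas[rr, cc] += val * fibre_intensity
    if n_fibres:
        canvas = ndimage.gaussian_filter(canvas, 0.6)  # widen to ~2-3 px
    canvas[~cell_mask] = 0.0

    pixels = background + cytoplasm_level * cell_mask + canvas
    if noise_sd > 0:
        pixels = pixels + rng.normal(0.0, noise_sd, size=pixels.shape)

    if n_fibres:
        anisotropy, mean_theta = axial_resultant(thetas)
    else:
        anisotropy, mean_theta = 0.0, float("nan")
    truth = {
        "n_fibres": n_fibres,
        "theta_fib": mean_theta,
        "anisotropy": anisotropy,
        "fibre_intensity_sum": float(canvas.sum()),
        "cell_area": float(cell_mask.sum()) * pixel_size ** 2,
        "cell_mask": cell_mask,
        "orientations": thetas,
    }
    return CalibratedImage(pixels, pixel_size), truth


# --------------------------------------------------------------------------
# Tabular populations
# --------------------------------------------------------------------------

@dataclasses.dataclass
class SyntheticPopulationSpec:
    """Parameters of a synthetic single-cell population.

    Cell spread area is log-uniform on ``csa_range`` so log–log fits have
    balanced leverage.  Cytoskeletal amounts either follow the power laws
    X = CSA^γ·ε (``amount_distribution="csa-power"``, the default) or are
    independent log-normals with log-sd ``amount_sigma_log``
    (``"lognormal"``), matching the design of the global-fit recovery
    experiments.  Responses follow the multiplicative models on
    median-centred amounts; all noise ε is i.i.d. log-normal with
    coefficient of variation ``noise_cv``.
    """

    n_cells: int = 600
    csa_range: tuple[float, float] = DEFAULT_CSA_RANGE
    gamma_by_protein: dict = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_GAMMA))
    model_exponents: dict = dataclasses.field(
        default_factory=lambda: {k: dict(v) for k, v in
                                 DEFAULT_MODEL_EXPONENTS.items()})
    model_prefactors: dict = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_MODEL_PREFACTORS))
    rational_params: tuple[float, float, float] = DEFAULT_RATIONAL
    noise_cv: float = 0.1
    amount_distribution: str = "csa-power"
    amount_sigma_log: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 2:
            raise DomainError("n_cells must be >= 2")
        if not self.csa_range[0] < self.csa_range[1]:
            raise DomainError("csa_range must be increasing")
        if self.noise_cv < 0:
            raise DomainError("noise_cv must be >= 0")
        if self.amount_distribution not in ("csa-power", "lognormal"):
            raise DomainError("unknown amount_distribution")


def _lognormal_noise(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Unit-median multiplicative noise with the requested CV."""
    if cv == 0:
        return np.ones(n)
    sigma = math.sqrt(math.log(1.0 + cv ** 2))
    return np.exp(rng.normal(0.0, sigma, n))


def generate_population(spec: SyntheticPopulationSpec
                        ) -> tuple[pd.DataFrame, dict]:
    """Draw a cell population; returns the table and the generative truth.

    Columns: ``cell_id, csa, height`` plus one normalized amount per protein
    and one column per modelled response (``volume, nu, e_mod, cc,
    height_model``).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_cells
    lo, hi = spec.csa_range
    csa = np.exp(rng.uniform(math.log(lo), math.log(hi), n))

    amounts: dict[str, np.ndarray] = {}
    for prot in PROTEINS:
        if spec.amount_distribution == "csa-power":
            gamma = spec.gamma_by_protein.get(prot, 0.0)
            raw = csa ** gamma * _lognormal_noise(rng, spec.noise_cv, n)
        else:
            raw = np.exp(rng.normal(0.0, spec.amount_sigma_log, n))
        amounts[prot] = raw / np.median(raw)

    responses: dict[str, np.ndarray] = {}
    for resp, exps in spec.model_exponents.items():
        y0 = spec.model_prefactors[resp]
        y = np.full(n, abs(y0))
        for prot, alpha in exps.items():
            y = y * amounts[prot] ** alpha
        y = y * _lognormal_noise(rng, spec.noise_cv, n)
        responses[resp] = math.copysign(1.0, y0) * y

    ra, rb, rc = spec.rational_params
    height = (ra + rb / (rc + csa)) * _lognormal_noise(rng, spec.noise_cv, n)

    table = pd.DataFrame({"cell_id": np.arange(n), "csa": csa,
                          "height": height, **amounts, **responses})
    truth = {
        "gamma_by_protein": dict(spec.gamma_by_protein),
        "model_exponents": {k: dict(v) for k, v in spec.model_exponents.items()},
        "model_prefactors": dict(spec.model_prefactors),
        "rational_params": spec.rational_params,
        "h_isolated": ra + rb / rc,
        "h_min": ra,
        "noise_cv": spec.noise_cv,
        "seed": spec.seed,
    }
    return table, truth


def generate_cc_volume_population(n_cells: int = 600,
                                  beta: float = -0.013,
                                  cc_intercept: float = 0.068,
                                  noise_sd: float = 0.02,
                                  seed: int = 0) -> tuple[pd.DataFrame, dict]:
    """Population with a linear chromatin-condensation / volume coupling
    CC = CC0 + β·V + ε, ε Gaussian.

    Volume comes from the multiplicative volume model so its spread matches
    the rest of the synthetic study; the default noise sd gives the slope
    fit a standard error of about 0.003, the scale of the reported fit.
    ``beta = 0`` produces the decoupled (drug-treated-like) null.
    """
    pop_spec = SyntheticPopulationSpec(n_cells=n_cells, seed=seed)
    table, _ = generate_population(pop_spec)
    rng = np.random.default_rng(seed + 1)
    volume = table["volume"].to_numpy()
    cc = cc_intercept + beta * volume + rng.normal(0.0, noise_sd, n_cells)
    out = pd.DataFrame({"cell_id": np.arange(n_cells),
                        "volume": volume, "cc": cc})
    truth = {"beta": beta, "cc_intercept": cc_intercept, "noise_sd": noise_sd}
    return out, truth
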