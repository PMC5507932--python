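"""Nuclear mechanical parameters from gross morphology.

The model assumes an isolated, undeformed nucleus is a sphere whose volume
is proportional to its integrated DAPI fluorescence.  Intracellular forces
flatten it axially and stretch it in-plane into the measured ellipsoid:

* undeformed radius      r = r̄ · (I_T / ⟨I_T⟩)^(1/3)
* undeformed volume      V0 = (4/3)πr³
* measured volume        V  = (4/3)πabc
* Poisson's ratio ν from ΔV/V = (1 + ΔL/L)^(1−2ν) − 1, with ΔL/L the mean
  in-plane stretch (√(ab) − r)/r
* apparent elastic modulus E_A = (R0/A)·(CSA/ΔR), where the unmeasured
  compressive force is proxied by cell spread area, A is the ellipsoid
  surface area (Thomsen approximation) and ΔR = r − c the axial flattening.

E_A is in arbitrary units by construction (force ∝ CSA); ν < 0 marks an
auxetic nucleus, one that loses volume under compression.
"""

from __future__ import annotations

import dataclasses
import math

from .core import DomainError
from .morphology import NucleusGeometry

THOMSEN_P = 1.6075


@dataclasses.dataclass(frozen=True)
class MechanicsParams:
    """Population-level constants: mean undeformed radius r̄ (µm) and the
    population median integrated DAPI intensity."""

    r_bar: float = 12.9
    i_total_median: float = 1.0

    def __post_init__(self) -> None:
        if self.r_bar <= 0 or self.i_total_median <= 0:
            raise DomainError("r_bar and i_total_median must be positive")


@dataclasses.dataclass(frozen=True)
class NuclearMechanics:
    r: float
    v0_undeformed: float
    v: float
    delta_v_over_v: float
    delta_l_over_l: float
    nu: float | None
    a_surf: float
    e_mod: float | None
    flags: tuple[str, ...] = ()


def undeformed_radius(i_total: float, params: MechanicsParams) -> float:
    """r = r̄·(I_T/⟨I_T⟩)^(1/3): intensity as a readout of undeformed volume."""
    if i_total <= 0:
        raise DomainError("I_T must be positive")
    return params.r_bar * (i_total / params.i_total_median) ** (1.0 / 3.0)


def volumes(geometry: NucleusGeometry, r: float
            ) -> tuple[float, float, float]:
    """(V0, V, ΔV/V) with ΔV = V − V0 and the undeformed volume as the
    denominator."""
    if min(geometry.a, geometry.b, geometry.c) <= 0 or r <= 0:
        raise DomainError("semi-axes and radius must be positive")
    v0 = 4.0 / 3.0 * math.pi * r ** 3
    v = 4.0 / 3.0 * math.pi * geometry.a * geometry.b * geometry.c
    return v0, v, (v - v0) / v0


def poisson_ratio(delta_v_over_v: float, delta_l_over_l: float,
                  stretch_tol: float = 1e-6) -> float:
    """Closed-form inversion of ΔV/V = (1 + ΔL/L)^(1−2ν) − 1."""
    if 1.0 + delta_v_over_v <= 0 or 1.0 + delta_l_over_l <= 0:
        raise DomainError("relative changes must exceed -1")
    log_stretch = math.log1p(delta_l_over_l)
    if abs(log_stretch) <= stretch_tol:
        raise DomainError("indeterminate Poisson ratio: no in-plane stretch")
    return 0.5 * (1.0 - math.log1p(delta_v_over_v) / log_stretch)


def ellipsoid_surface_area(a: float, b: float, c: float) -> float:
    """Thomsen approximation (p = 1.6075), accurate to ~1.1% worst case."""
    if min(a, b, c) <= 0:
        raise DomainError("semi-axes must be positive")
    p = THOMSEN_P
    return 4.0 * math.pi * (((a * b) ** p + (a * c) ** p + (b * c) ** p)
                            / 3.0) ** (1.0 / p)


def apparent_modulus(geometry: NucleusGeometry, r: float, csa: float) -> float:
    """E_A = (r/A)·(CSA/(r − c)); requires the nucleus to be axially
    flattened relative to its undeformed radius."""
    if csa <= 0:
        raise DomainError("CSA must be positive")
    delta_r = r - geometry.c
    if delta_r <= 0:
        raise DomainError("nucleus not compressed (r <= c)")
    a_surf = ellipsoid_surface_area(geometry.a, geometry.b, geometry.c)
    return (r / a_surf) * (csa / delta_r)


def compute_mechanics(geometry: NucleusGeometry, csa: float | None,
                      params: MechanicsParams) -> NuclearMechanics:
    """Full per-nucleus mechanics record; indeterminate quantities are
    withheld (None) and flagged rather than raising."""
    flags: list[str] = []
    r = undeformed_radius(geometry.i_total, params)
    v0, v, dvv = volumes(geometry, r)
    dll = (math.sqrt(geometry.a * geometry.b) - r) / r
    try:
        nu = poisson_ratio(dvv, dll)
    except DomainError:
        nu = None
        flags.append("indeterminate_poisson_ratio")
    a_surf = ellipsoid_surface_area(geometry.a, geometry.b, geometry.c)
    e_mod: float | None = None
    if csa is None:
        flags.append("no_csa")
    else:
        try:
            e_mod = apparent_modulus(geometry, r, csa)
        except DomainError:
            flags.append("nucleus_not_compressed")
    return NuclearMechanics(r=r, v0_undeformed=v0, v=v, delta_v_over_v=dvv,
                            delta_l_over_l=dll, nu=nu, a_surf=a_surf,
                            e_mod=e_mod, flags=tuple(flags))
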