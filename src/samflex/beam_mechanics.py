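"""Closed-form mechanics of a coated rectangular microcantilever.

The measurement principle: a thin adsorbate film on a resonating
clamped-free beam shifts the fundamental flexural frequency through two
competing channels — added inertial mass (downshift) and added bending
stiffness (upshift). For a film whose thickness ``t_f`` is small against
the beam thickness ``t_c`` the relative shift admits a power-series
expansion in the thickness ratio τ = t_f/t_c,

    Δω/ω₀ ≈ ½(3E_r − ρ_r)τ
            + (3/8)[ρ_r² + 2E_r(4 − ρ_r) − 7E_r²]τ²,

with E_r = E_f/E_c and ρ_r = ρ_f/ρ_c the modulus and density ratios.
This module provides the expansion forward and inverted (a quadratic in
E_r), Euler–Bernoulli resonance and spring-constant relations, and the
two-layer composite-beam effective modulus with its decoupling inverse.

All quantities are SI.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .errors import DegenerateInputError, InfeasibleShiftError, InvalidInputError
from .units import GPA, UM

__all__ = [
    "LAMBDA1_SQ",
    "CantileverGeometry",
    "LayerProperties",
    "BilayerSpec",
    "InversionResult",
    "resonance_frequency",
    "spring_constant_from_modulus",
    "modulus_from_spring_constant",
    "frequency_shift_second_order",
    "invert_frequency_shift",
    "bilayer_effective_modulus",
    "decouple_layer_modulus",
]

#: Squared eigenvalue of the fundamental clamped-free flexural mode
#: (λ₁ = 1.8751). Overridable per call for non-standard boundary conditions.
LAMBDA1_SQ = 3.5160

#: Aspect ratio below which the slender-beam assumption gets questionable.
_MIN_ASPECT_RATIO = 50.0

#: Film/beam thickness ratio above which the second-order expansion is dubious.
_MAX_THICKNESS_RATIO = 0.05


@dataclass(frozen=True)
class CantileverGeometry:
    """Rectangular cantilever dimensions and substrate material constants.

    Parameters
    ----------
    length, width, thickness : float
        Beam dimensions in m.
    modulus : float
        Substrate Young's modulus in Pa (169 GPa for silicon).
    density : float
        Substrate mass density in kg/m³ (2330 for silicon).
    """

    length: float
    width: float
    thickness: float
    modulus: float
    density: float

    def __post_init__(self):
        for name in ("length", "width", "thickness", "modulus", "density"):
            if not getattr(self, name) > 0:
                raise InvalidInputError(f"{name} must be strictly positive")
        if self.length / self.thickness < _MIN_ASPECT_RATIO:
            warnings.warn(
                f"aspect ratio L/t = {self.length / self.thickness:.1f} < "
                f"{_MIN_ASPECT_RATIO:.0f}; slender-beam theory may be inaccurate",
                stacklevel=3,
            )

    @classmethod
    def from_practical(
        cls,
        length_um: float,
        width_um: float,
        thickness_um: float,
        modulus_gpa: float,
        density: float,
    ) -> "CantileverGeometry":
        """Build from μm dimensions and a GPa modulus."""
        return cls(
            length=length_um * UM,
            width=width_um * UM,
            thickness=thickness_um * UM,
            modulus=modulus_gpa * GPA,
            density=density,
        )


@dataclass(frozen=True)
class LayerProperties:
    """Adsorbate film state at one measurement condition (SI units).

    ``modulus`` may be ``nan`` for the inversion input (the unknown).
    """

    thickness: float
    mass_density: float
    modulus: float = float("nan")
    grafting_density: float | None = None  # molecules/cm²
    relative_humidity: float | None = None  # %

    def __post_init__(self):
        if self.thickness < 0:
            raise InvalidInputError("layer thickness must be non-negative")
        if not self.mass_density > 0:
            raise InvalidInputError("layer mass density must be strictly positive")
        if not math.isnan(self.modulus) and self.modulus < 0:
            raise InvalidInputError("layer modulus must be non-negative")
        if self.relative_humidity is not None and not (
            0 <= self.relative_humidity <= 100
        ):
            raise InvalidInputError("relative humidity must lie in [0, 100]")


@dataclass(frozen=True)
class BilayerSpec:
    """Two stacked layers of a composite beam cross-section (SI units)."""

    substrate_modulus: float
    substrate_thickness: float
    layer_modulus: float
    layer_thickness: float

    def __post_init__(self):
        if not self.substrate_thickness > 0:
            raise InvalidInputError("substrate thickness must be strictly positive")
        for name in ("substrate_modulus", "layer_modulus", "layer_thickness"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be non-negative")


@dataclass(frozen=True)
class InversionResult:
    """Outcome of one frequency-shift inversion.

    ``clipped`` marks a mathematically negative modulus clipped to zero
    (expected for noisy low-coverage points where the shift is more negative
    than pure mass loading permits).
    """

    modulus: float
    clipped: bool = False


def resonance_frequency(
    geometry: CantileverGeometry, mode_constant: float = LAMBDA1_SQ
) -> float:
    """Fundamental flexural resonance frequency (Hz) of the bare beam.

    Euler–Bernoulli closed form
    f₁ = (λ₁²/2π)·(t/L²)·sqrt(E/(12ρ)).
    """
    g = geometry
    return (
        (mode_constant / (2.0 * math.pi))
        * (g.thickness / g.length**2)
        * math.sqrt(g.modulus / (12.0 * g.density))
    )


def spring_constant_from_modulus(modulus: float, geometry: CantileverGeometry) -> float:
    """End-load static spring constant k = E·w·t³/(4L³) in N/m."""
    if modulus < 0:
        raise InvalidInputError("modulus must be non-negative")
    g = geometry
    return modulus * g.width * g.thickness**3 / (4.0 * g.length**3)


def modulus_from_spring_constant(k: float, geometry: CantileverGeometry) -> float:
    """Invert the cantilever spring constant to a Young's modulus.

    E = 4L³k/(w·t³); the route by which a spring constant obtained as the
    second derivative of a simulated bending-energy curve is expressed as
    an effective modulus of the beam device.
    """
    if k < 0:
        raise InvalidInputError("spring constant must be non-negative")
    g = geometry
    return 4.0 * g.length**3 * k / (g.width * g.thickness**3)


def _ratios(layer: LayerProperties, geometry: CantileverGeometry):
    tau = layer.thickness / geometry.thickness
    rho_r = layer.mass_density / geometry.density
    return tau, rho_r


def frequency_shift_second_order(
    layer: LayerProperties,
    geometry: CantileverGeometry,
    order: int = 2,
) -> float:
    """Relative resonance-frequency shift Δω/ω₀ of the coated beam.

    Second-order expansion in the thickness ratio τ (``order=1`` truncates
    to the leading mass/stiffness balance). Warns when τ exceeds the
    thin-film regime the expansion assumes.
    """
    if order not in (1, 2):
        raise InvalidInputError("expansion order must be 1 or 2")
    if math.isnan(layer.modulus):
        raise InvalidInputError("layer modulus is required for the forward model")
    tau, rho_r = _ratios(layer, geometry)
    if tau > _MAX_THICKNESS_RATIO:
        warnings.warn(
            f"thickness ratio τ = {tau:.3g} exceeds the thin-film regime "
            f"(≤ {_MAX_THICKNESS_RATIO})",
            stacklevel=2,
        )
    e_r = layer.modulus / geometry.modulus
    shift = 0.5 * (3.0 * e_r - rho_r) * tau
    if order == 2:
        shift += (
            0.375 * (rho_r**2 + 2.0 * e_r * (4.0 - rho_r) - 7.0 * e_r**2) * tau**2
        )
    return shift


def invert_frequency_shift(
    shift: float,
    layer: LayerProperties,
    geometry: CantileverGeometry,
    order: int = 2,
) -> InversionResult:
    """Solve the thickness-ratio expansion for the film Young's modulus.

    With τ and ρ_r known, the second-order expansion is a quadratic in
    E_r = E_f/E_c:

        a·E_r² + b·E_r + c = 0,
        a = −(21/8)τ²,
        b = (3/2)τ + (3/4)(4 − ρ_r)τ²,
        c = −½ρ_r·τ + (3/8)ρ_r²τ² − shift.

    Of the two roots the physical one is continuous with the first-order
    solution (shift + ½ρ_rτ)/((3/2)τ); the spurious root is O(1/τ²) and is
    rejected by distance to that first-order value. A mathematically
    negative modulus (shift below the pure mass-loading value) is clipped
    to zero and flagged rather than raised.

    Raises
    ------
    InfeasibleShiftError
        When the quadratic has no real root (the shift exceeds the maximum
        the expansion can map), or when τ = 0 with a nonzero shift.
    """
    if order not in (1, 2):
        raise InvalidInputError("expansion order must be 1 or 2")
    tau, rho_r = _ratios(layer, geometry)
    if tau == 0.0:
        if shift == 0.0:
            return InversionResult(modulus=0.0)
        raise InfeasibleShiftError("zero-thickness layer cannot produce a shift")

    first_order = (shift + 0.5 * rho_r * tau) / (1.5 * tau)
    if order == 1:
        e_r = first_order
    else:
        a = -(21.0 / 8.0) * tau**2
        b = 1.5 * tau + 0.75 * (4.0 - rho_r) * tau**2
        c = -0.5 * rho_r * tau + 0.375 * rho_r**2 * tau**2 - shift
        disc = b * b - 4.0 * a * c
        if disc < 0.0:
            raise InfeasibleShiftError(
                f"no real modulus produces relative shift {shift:.3e}",
                discriminant=disc,
            )
        sq = math.sqrt(disc)
        roots = ((-b + sq) / (2.0 * a), (-b - sq) / (2.0 * a))
        e_r = min(roots, key=lambda r: abs(r - first_order))
    modulus = e_r * geometry.modulus
    if modulus < 0.0:
        return InversionResult(modulus=0.0, clipped=True)
    return InversionResult(modulus=modulus)


def bilayer_effective_modulus(spec: BilayerSpec, variant: str = "normalized") -> float:
    """Effective modulus of a two-layer composite beam.

    With N = E_g²t_g⁴ + E_d²t_d⁴ + 2E_gE_dt_gt_d(2t_g² + 2t_d² + 3t_gt_d),
    the ``normalized`` variant returns N/[(E_gt_g + E_dt_d)(t_g + t_d)³] —
    the standard composite-beam result (N/(E_gt_g+E_dt_d) is 12× the
    bending stiffness per unit width, renormalized by the total-thickness
    cube so a homogeneous stack returns its own modulus exactly). The
    ``as_printed`` variant omits the (t_g+t_d)³ normalization and has units
    Pa·m³; it is retained only for traceability and is not used by any
    pipeline path.
    """
    e_g, t_g = spec.substrate_modulus, spec.substrate_thickness
    e_d, t_d = spec.layer_modulus, spec.layer_thickness
    n = (
        e_g**2 * t_g**4
        + e_d**2 * t_d**4
        + 2.0 * e_g * e_d * t_g * t_d * (2.0 * t_g**2 + 2.0 * t_d**2 + 3.0 * t_g * t_d)
    )
    denom_et = e_g * t_g + e_d * t_d
    if denom_et == 0.0:
        raise InvalidInputError("E·t of both layers is zero")
    if variant == "as_printed":
        return n / denom_et
    if variant == "normalized":
        return n / (denom_et * (t_g + t_d) ** 3)
    raise InvalidInputError(f"unknown variant {variant!r}")


def decouple_layer_modulus(
    composite_modulus: float,
    substrate: tuple[float, float],
    layer_thickness: float,
    bracket_factor: float = 10.0,
) -> float:
    """Extract the film modulus from a composite-beam effective modulus.

    Numerically inverts the normalized two-layer relation for the film
    modulus on [0, ``bracket_factor``·E_substrate]; the normalized map is
    strictly increasing in the film modulus, so the root is unique.
    """
    e_g, t_g = substrate
    if layer_thickness <= 0.0:
        raise DegenerateInputError(
            "film modulus is indeterminate for a zero-thickness layer"
        )

    def residual(e_d: float) -> float:
        spec = BilayerSpec(e_g, t_g, e_d, layer_thickness)
        return bilayer_effective_modulus(spec, "normalized") - composite_modulus

    lo, hi = 0.0, bracket_factor * e_g
    r_lo, r_hi = residual(lo), residual(hi)
    if r_lo == 0.0:
        return 0.0
    if r_lo > 0.0 or r_hi < 0.0:
        raise InfeasibleShiftError(
            "composite modulus outside the range attainable for "
            f"film modulus in [0, {hi:.3g}] Pa"
        )
    return float(brentq(residual, lo, hi, xtol=1e-6, rtol=1e-12))
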