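"""XPS-based layer-thickness and grafting-density quantification.

A uniform organic overlayer of thickness t attenuates the substrate Au4f
photoelectron signal as I_Au = I_Au⁰·exp(−t/L_Au), with L_Au the practical
effective attenuation length (PEAL) of the photoelectrons in the film.
Inverting the attenuation gives the film thickness; the same exponential
model corrects measured overlayer/substrate peak ratios (P, N vs Au) for
finite-thickness emission, after which the phosphorus signal counts
backbone atoms and hence tethered molecules.

This module consumes already-integrated peak intensities — background
subtraction, line-shape deconvolution and sensitivity factors are upstream
instrument processing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError

__all__ = [
    "XPSRecord",
    "overlayer_thickness",
    "peal_from_reference",
    "attenuation_corrected_ratio",
    "density_from_phosphorus",
    "DEFAULT_INSTRUMENT_CONSTANT",
]

#: t/L beyond which the exponential correction overflows any useful scale.
_MAX_T_OVER_L = 50.0

#: Free calibration mapping a thickness-weighted corrected ratio to a P
#: areal density, atoms·cm⁻²·m⁻¹ per unit ratio. The published analysis
#: does not state its sensitivity/geometry calibration; this constant is
#: the corresponding free parameter (the generator uses the same value, so
#: round trips are calibration-independent).
DEFAULT_INSTRUMENT_CONSTANT = 1e20


@dataclass(frozen=True)
class XPSRecord:
    """Integrated peak intensities of one sample.

    ``peak_ratios`` maps element symbol → raw intensity ratio vs the Au4f
    substrate peak. A record with I_Au > I_Au⁰ (possible with noise) is
    accepted with a warning.
    """

    i_au: float
    i_au0: float
    l_au: float
    peak_ratios: dict[str, float] = field(default_factory=dict)
    sample_id: str = ""

    def __post_init__(self):
        if not self.i_au > 0 or not self.i_au0 > 0:
            raise InvalidInputError("Au4f intensities must be strictly positive")
        if not self.l_au > 0:
            raise InvalidInputError("attenuation length must be strictly positive")
        if self.i_au > self.i_au0:
            warnings.warn(
                f"sample {self.sample_id or '<unnamed>'}: attenuated intensity "
                "exceeds the clean reference (noise?)",
                stacklevel=3,
            )


def overlayer_thickness(rec: XPSRecord) -> float:
    """Overlayer thickness t = −L_Au·ln(I_Au/I_Au⁰) in m.

    A negative result (I_Au above the reference, i.e. noise) is clipped
    to 0.
    """
    t = -rec.l_au * np.log(rec.i_au / rec.i_au0)
    return max(t, 0.0)


def peal_from_reference(i: float, i0: float, t_ref: float) -> float:
    """Practical effective attenuation length from a reference film.

    L = t_ref/ln(I⁰/I) for a film of independently measured (AFM)
    thickness ``t_ref``.
    """
    if not t_ref > 0:
        raise InvalidInputError("reference thickness must be strictly positive")
    if not 0 < i < i0:
        raise InvalidInputError(
            "reference film must attenuate the substrate signal (0 < I < I0)"
        )
    return t_ref / np.log(i0 / i)


def attenuation_corrected_ratio(
    raw_ratio: float,
    t: float,
    l_overlayer: float,
    l_substrate: float,
) -> float:
    """Correct a measured overlayer/substrate peak ratio for attenuation.

    Uniform-overlayer emission model: the overlayer element emits with a
    finite-thickness factor (1 − e^(−t/L_overlayer)) while the substrate
    signal is attenuated by e^(−t/L_substrate). Dividing the measured
    ratio by both restores the thickness-independent composition ratio.
    """
    if t < 0:
        raise InvalidInputError("thickness must be non-negative")
    if not l_overlayer > 0 or not l_substrate > 0:
        raise InvalidInputError("attenuation lengths must be strictly positive")
    if t / l_overlayer > _MAX_T_OVER_L or t / l_substrate > _MAX_T_OVER_L:
        raise InvalidInputError(
            f"t/L exceeds the overflow guard ({_MAX_T_OVER_L})"
        )
    if t == 0.0:
        raise InvalidInputError(
            "zero thickness: the overlayer emission factor vanishes"
        )
    emission = 1.0 - np.exp(-t / l_overlayer)
    return raw_ratio * np.exp(-t / l_substrate) / emission


def forward_ratio(
    corrected_ratio: float,
    t: float,
    l_overlayer: float,
    l_substrate: float,
) -> float:
    """Forward emission model: the raw ratio a spectrometer would measure.

    Exact algebraic inverse of :func:`attenuation_corrected_ratio`; used by
    the synthetic-data generator.
    """
    emission = 1.0 - np.exp(-t / l_overlayer)
    return corrected_ratio * emission * np.exp(t / l_substrate)


def density_from_phosphorus(
    corrected_ratio: float,
    t: float,
    strand_length: int = 20,
    instrument_constant: float = DEFAULT_INSTRUMENT_CONSTANT,
) -> float:
    """Grafting density (molecules/cm²) from the corrected P/Au ratio.

    The corrected ratio is proportional to the volumetric phosphorus
    concentration; multiplying by the film thickness and the instrument
    calibration gives the P areal density (atoms/cm²), and dividing by the
    backbone phosphorus count per strand (default 20 for the 20-mer,
    19 internucleotide + 1 linker-associated; configurable) gives
    molecules/cm².
    """
    if not corrected_ratio > 0:
        raise InvalidInputError("corrected ratio must be strictly positive")
    if not strand_length > 0:
        raise InvalidInputError("strand length must be strictly positive")
    atoms_per_cm2 = instrument_constant * corrected_ratio * t
    return atoms_per_cm2 / strand_length
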