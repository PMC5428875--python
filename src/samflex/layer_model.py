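"""Physical property models of the tethered-DNA layer.

The layer is parameterized by its grafting density n (molecules/cm²), its
hydration state (relative humidity, %), and its hybridization state. Three
property surfaces feed the beam-mechanics forward model:

* thickness t(n, RH) — anchored to molecular-dynamics outcomes: 0.3 nm at
  3.1×10¹² cm⁻² (strands lying flat, one base diameter) rising to 1.5 nm
  at 2.5×10¹³ cm⁻² as the strands stand up, approaching a cap beyond the
  last anchor; dry layers contract by a fixed factor;
* mass density ρ(n, RH) — deposited strand mass plus adsorbed water,
  spread over the layer volume;
* modulus E(n, RH) — near zero at low coverage (strands too far apart to
  interact), rising with density to a saturating plateau, and linear in RH
  between the dry and fully hydrated states.

The effective *dynamic* strand mass carried by the default presets is a
calibration, not the chemical strand mass — see docs/methods.md; the
chemical mass is available from :func:`strand_mass`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DegenerateInputError, InvalidInputError, ParseError
from .units import DALTON, GPA, NM, PER_CM2, WATER_MOLECULE_MASS

__all__ = [
    "StrandModel",
    "LayerConfig",
    "ModulusFitParams",
    "SS_STRAND",
    "DS_STRAND",
    "PUBLISHED_SS_FIT",
    "PUBLISHED_DS_FIT",
    "PROBE_SEQUENCE",
    "LINKER_C3H6S_MASS_DA",
    "thickness_vs_density",
    "layer_thickness",
    "layer_mass_density",
    "effective_strand_mass",
    "waters_per_strand",
    "modulus_vs_density",
    "modulus_rh_linear",
    "layer_modulus",
    "strand_mass",
    "complement",
]

#: RH (%) at which the layer is taken as fully hydrated; the hydration
#: interpolations below are pinned between 0 and this value.
FULL_HYDRATION_RH = 70.0


@dataclass(frozen=True)
class StrandModel:
    """Property tables for one strand species (ss or ds).

    ``strand_mass`` is the effective dynamic mass per tethered molecule
    (kg) entering the resonator mass loading. ``waters_per_strand`` maps
    RH (%) to adsorbed water molecules per strand (linear in between).
    ``thickness_anchors`` are (n in cm⁻², t in m) knots of the hydrated
    thickness curve: flat below the first knot, linear between knots, and
    above the last knot an exponential approach to ``thickness_cap`` with
    density scale ``thickness_saturation`` (cm⁻²). ``modulus_dry`` /
    ``modulus_hydrated`` tabulate E(n) (Pa) at RH 0 and RH 70.
    """

    strand_mass: float
    waters_per_strand: tuple[tuple[float, float], ...]
    thickness_anchors: tuple[tuple[float, float], ...]
    thickness_cap: float
    thickness_saturation: float
    dry_contraction: float
    modulus_dry: tuple[tuple[float, float], ...]
    modulus_hydrated: tuple[tuple[float, float], ...]

    def __post_init__(self):
        if not self.strand_mass > 0:
            raise InvalidInputError("strand mass must be strictly positive")
        if not 0 < self.dry_contraction <= 1:
            raise InvalidInputError("dry contraction factor must lie in (0, 1]")
        anchors = self.thickness_anchors
        if any(t <= 0 for _, t in anchors):
            raise InvalidInputError("thickness anchors must be strictly positive")
        if any(
            n2 <= n1 or t2 < t1
            for (n1, t1), (n2, t2) in zip(anchors, anchors[1:])
        ):
            raise InvalidInputError(
                "thickness anchors must be strictly increasing in density "
                "and non-decreasing in thickness"
            )
        if self.thickness_cap < anchors[-1][1]:
            raise InvalidInputError("thickness cap below the last anchor")


# --- Default presets -------------------------------------------------------
#
# Thickness anchors: MD outcomes (0.3 nm at 3.1e12, 1.5 nm at 2.5e13 cm⁻²).
# Modulus tables: calibration reproducing the measured behavior — ss
# saturating toward ~15 GPa fully hydrated (dry point near 10 GPa at high
# coverage, ~0 at low coverage, 5→15 GPa tuning at 3.7e13); ds an order of
# magnitude softer with weak RH dependence.
#
# strand_mass values are the calibrated effective dynamic masses: the ss
# value is fixed by requiring the noiseless fully hydrated shift-vs-density
# curve to cross zero at 2.5e13 cm⁻² (see docs/methods.md); the ds strand
# carries twice the ss value (complement of equal length).

SS_STRAND = StrandModel(
    strand_mass=2.3797e-24,
    waters_per_strand=((0.0, 0.0), (70.0, 20.0)),
    thickness_anchors=((3.1e12, 0.3 * NM), (2.5e13, 1.5 * NM)),
    thickness_cap=2.2 * NM,
    thickness_saturation=1.5e13,
    dry_contraction=0.8,
    modulus_dry=(
        (1e12, 0.0),
        (1e13, 1.0 * GPA),
        (2.5e13, 4.0 * GPA),
        (3.7e13, 5.0 * GPA),
        (6.5e13, 10.0 * GPA),
    ),
    modulus_hydrated=(
        (1e12, 0.6 * GPA),
        (1e13, 5.0 * GPA),
        (2.5e13, 12.0 * GPA),
        (3.7e13, 15.0 * GPA),
        (6.5e13, 15.0 * GPA),
    ),
)

DS_STRAND = StrandModel(
    strand_mass=2 * 2.3797e-24,
    waters_per_strand=((0.0, 0.0), (70.0, 40.0)),
    thickness_anchors=((3.1e12, 2.0 * NM), (2.5e13, 2.2 * NM)),
    thickness_cap=2.6 * NM,
    thickness_saturation=1.5e13,
    dry_contraction=0.9,
    modulus_dry=((1e12, 0.4 * GPA), (6.5e13, 1.6 * GPA)),
    modulus_hydrated=((1e12, 0.5 * GPA), (6.5e13, 2.0 * GPA)),
)


@dataclass(frozen=True)
class LayerConfig:
    """One layer condition: species mix, grafting density, adjustments.

    ``kind`` is ``"ssDNA"`` (h pinned to 0), ``"dsDNA"`` (h pinned to 1)
    or ``"mixed"`` (h = ``hybridization_fraction``). ``excess_mass_fraction``
    multiplies the strand mass by (1 + m), modelling nonspecifically
    adsorbed material.
    """

    kind: str
    grafting_density: float  # molecules/cm²
    hybridization_fraction: float = 0.0
    excess_mass_fraction: float = 0.0
    ss: StrandModel = SS_STRAND
    ds: StrandModel = DS_STRAND

    def __post_init__(self):
        if self.kind not in ("ssDNA", "dsDNA", "mixed"):
            raise InvalidInputError(f"unknown layer kind {self.kind!r}")
        if self.grafting_density < 0:
            raise InvalidInputError("grafting density must be non-negative")
        if not 0 <= self.hybridization_fraction <= 1:
            raise InvalidInputError("hybridization fraction must lie in [0, 1]")
        if self.excess_mass_fraction < 0:
            raise InvalidInputError("excess mass fraction must be non-negative")

    @property
    def effective_hybridization(self) -> float:
        if self.kind == "ssDNA":
            return 0.0
        if self.kind == "dsDNA":
            return 1.0
        return self.hybridization_fraction

    def with_density(self, n: float) -> "LayerConfig":
        return replace(self, grafting_density=n)


@dataclass(frozen=True)
class ModulusFitParams:
    """Parameters of one E(n) fit family.

    ``saturating_growth`` evaluates A/(B + C·exp(−n/n0)) — monotone
    increasing toward the asymptote A/B; ``linear`` evaluates
    intercept + slope·n. Densities n in molecules/cm², moduli in Pa.
    """

    family: str
    a: float = 1.0
    b: float = 1.0
    c: float = 0.0
    n0: float = 1.0
    slope: float = 0.0
    intercept: float = 0.0

    def __post_init__(self):
        if self.family not in ("saturating_growth", "linear"):
            raise InvalidInputError(f"unknown fit family {self.family!r}")
        if self.family == "saturating_growth":
            if not self.b > 0 or self.c < 0 or not self.n0 > 0:
                raise InvalidInputError(
                    "saturating_growth requires B > 0, C >= 0, n0 > 0"
                )

    @property
    def asymptote(self) -> float:
        if self.family != "saturating_growth":
            raise InvalidInputError("asymptote defined for saturating_growth only")
        return self.a / self.b


#: The published fit constants, verbatim, as documented presets. Their unit
#: labels are inconsistent as printed; the readings below (moduli in Pa,
#: densities scaled by 10¹³ cm⁻² in the exponent) are the only ones that do
#: not overflow. They are NOT the defaults of any pipeline path.
PUBLISHED_SS_FIT = ModulusFitParams(
    family="saturating_growth", a=1.5, b=1.22e-10, c=2.29e-9, n0=1e13 / 1.42
)
PUBLISHED_DS_FIT = ModulusFitParams(family="linear", intercept=4.59e6, slope=1.35e-6)

#: The immobilized 20-mer probe sequence (5'→3', thiol linker at the 3' end).
PROBE_SEQUENCE = "CAATGCAGATACACTTTTTT"

#: Average mass of the C₃H₆S thiol linker, Da.
LINKER_C3H6S_MASS_DA = 74.141


# --- Thickness -------------------------------------------------------------

def thickness_vs_density(
    n, hydration: str = "hydrated", model: StrandModel = SS_STRAND
):
    """Layer thickness (m) at grafting density ``n`` (molecules/cm²).

    Piecewise: flat below the first anchor, linear between anchors, and an
    exponential approach to the cap above the last anchor. The ``dry``
    state is the hydrated curve scaled by the model's contraction factor.
    Accepts scalars or arrays.
    """
    if hydration not in ("dry", "hydrated"):
        raise InvalidInputError(f"unknown hydration state {hydration!r}")
    n_arr = np.asarray(n, dtype=float)
    if np.any(n_arr < 0):
        raise InvalidInputError("grafting density must be non-negative")
    knots_n = np.array([a[0] for a in model.thickness_anchors])
    knots_t = np.array([a[1] for a in model.thickness_anchors])
    t = np.interp(n_arr, knots_n, knots_t)
    above = n_arr > knots_n[-1]
    if np.any(above):
        cap, t_last = model.thickness_cap, knots_t[-1]
        t = np.where(
            above,
            cap
            - (cap - t_last)
            * np.exp(-(n_arr - knots_n[-1]) / model.thickness_saturation),
            t,
        )
    if hydration == "dry":
        t = t * model.dry_contraction
    return float(t) if np.isscalar(n) else t


def _blend(h: float, ss_value, ds_value):
    return (1.0 - h) * ss_value + h * ds_value


def layer_thickness(config: LayerConfig, rh):
    """Thickness (m) of the configured layer at relative humidity ``rh``.

    Linear between the dry and fully hydrated states over [0, 70] % RH,
    constant above; ss/ds blended by the hybridization fraction.
    """
    rh_arr = np.asarray(rh, dtype=float)
    if np.any((rh_arr < 0) | (rh_arr > 100)):
        raise InvalidInputError("relative humidity must lie in [0, 100]")
    frac = np.minimum(rh_arr, FULL_HYDRATION_RH) / FULL_HYDRATION_RH
    h = config.effective_hybridization
    n = config.grafting_density
    out = 0.0
    for weight, model in ((1.0 - h, config.ss), (h, config.ds)):
        if weight == 0.0:
            continue
        t_dry = thickness_vs_density(n, "dry", model)
        t_wet = thickness_vs_density(n, "hydrated", model)
        out = out + weight * (t_dry + (t_wet - t_dry) * frac)
    return float(out) if np.isscalar(rh) else out


# --- Mass ------------------------------------------------------------------

def waters_per_strand(model: StrandModel, rh):
    """Adsorbed water molecules per strand at ``rh``, from the model table."""
    knots = np.array(model.waters_per_strand)
    return np.interp(np.asarray(rh, dtype=float), knots[:, 0], knots[:, 1])


def effective_strand_mass(config: LayerConfig, rh) -> float:
    """Mass per tethered molecule (kg): blended strands, excess mass, water."""
    h = config.effective_hybridization
    strand = _blend(h, config.ss.strand_mass, config.ds.strand_mass)
    waters = _blend(
        h, waters_per_strand(config.ss, rh), waters_per_strand(config.ds, rh)
    )
    return strand * (1.0 + config.excess_mass_fraction) + waters * WATER_MOLECULE_MASS


def layer_mass_density(config: LayerConfig, rh):
    """Layer mass density ρ (kg/m³) at relative humidity ``rh`` (%).

    Deposited molecular mass (strands, blended ss/ds by the hybridization
    fraction, times 1 + excess-mass fraction) plus adsorbed water, spread
    over the layer envelope volume n·t(n, RH).
    """
    t = layer_thickness(config, rh)
    if np.any(np.asarray(t) == 0.0):
        raise DegenerateInputError("zero layer thickness: density undefined")
    n_areal = config.grafting_density * PER_CM2  # molecules/m²
    rho = n_areal * effective_strand_mass(config, rh) / t
    return float(rho) if np.isscalar(rh) else rho


# --- Modulus ---------------------------------------------------------------

def modulus_vs_density(n, params: ModulusFitParams):
    """Evaluate an E(n) fit family at density ``n`` (molecules/cm²) → Pa."""
    n_arr = np.asarray(n, dtype=float)
    if np.any(n_arr < 0):
        raise InvalidInputError("grafting density must be non-negative")
    if params.family == "linear":
        out = params.intercept + params.slope * n_arr
    else:
        out = params.a / (params.b + params.c * np.exp(-n_arr / params.n0))
    return float(out) if np.isscalar(n) else out


def modulus_rh_linear(e_dry: float, e_at_70: float, rh):
    """Modulus linear in RH, pinned at RH 0 and RH 70 (extrapolated above)."""
    rh_arr = np.asarray(rh, dtype=float)
    if np.any((rh_arr < 0) | (rh_arr > 100)):
        raise InvalidInputError("relative humidity must lie in [0, 100]")
    out = e_dry + (e_at_70 - e_dry) * rh_arr / FULL_HYDRATION_RH
    return float(out) if np.isscalar(rh) else out


def _table_modulus(model: StrandModel, n, table: tuple[tuple[float, float], ...]):
    knots = np.array(table)
    return np.interp(np.asarray(n, dtype=float), knots[:, 0], knots[:, 1])


def layer_modulus(config: LayerConfig, rh):
    """Effective Young's modulus E (Pa) of the configured layer at ``rh``.

    Tabulated E(n) at the dry and fully hydrated states, linear in RH
    between them, ss/ds blended by the hybridization fraction.
    """
    h = config.effective_hybridization
    n = config.grafting_density
    out = 0.0
    for weight, model in ((1.0 - h, config.ss), (h, config.ds)):
        if weight == 0.0:
            continue
        e_dry = _table_modulus(model, n, model.modulus_dry)
        e_wet = _table_modulus(model, n, model.modulus_hydrated)
        out = out + weight * modulus_rh_linear(e_dry, e_wet, rh)
    return float(out) if np.isscalar(rh) else out


# --- Composition -----------------------------------------------------------

#: Average residue masses (Da) of the four deoxynucleotide monophosphates
#: as incorporated in a strand.
_RESIDUE_MASS_DA = {"A": 313.21, "C": 289.18, "G": 329.21, "T": 304.20}
#: Terminal correction (Da): removes one HPO₃ and adds H + OH for the free ends.
_TERMINAL_CORRECTION_DA = -61.96
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def complement(sequence: str) -> str:
    """Watson–Crick complement (5'→3') of a DNA sequence."""
    return sequence.upper().translate(_COMPLEMENT)[::-1]


def strand_mass(
    sequence: str,
    linker_mass_da: float = 0.0,
    double_stranded: bool = False,
) -> float:
    """Average chemical mass (kg) of a DNA strand, optionally hybridized.

    Sums published average residue masses with an end-group correction;
    ``linker_mass_da`` adds a covalent modification (e.g. the C₃H₆-SH
    tether, :data:`LINKER_C3H6S_MASS_DA`). The double-stranded variant adds
    the full complement strand mass.
    """
    seq = sequence.upper()
    if not seq:
        return linker_mass_da * DALTON
    for i, base in enumerate(seq):
        if base not in _RESIDUE_MASS_DA:
            raise ParseError(f"non-ACGT character {base!r} in sequence", line=None)
    total = sum(_RESIDUE_MASS_DA[b] for b in seq) + _TERMINAL_CORRECTION_DA
    total += linker_mass_da
    if double_stranded:
        comp = complement(seq)
        total += sum(_RESIDUE_MASS_DA[b] for b in comp) + _TERMINAL_CORRECTION_DA
    return total * DALTON


#: Atoms per strand of the two XPS marker elements for the default 20-mer:
#: one backbone phosphorus per nucleotide (incl. the linker-associated
#: phosphate) and the summed base nitrogens (A:5, C:3, G:5, T:2).
def marker_atoms_per_strand(sequence: str = PROBE_SEQUENCE) -> dict[str, int]:
    n_per_base = {"A": 5, "C": 3, "G": 5, "T": 2}
    seq = sequence.upper()
    return {"P": len(seq), "N": sum(n_per_base[b] for b in seq)}
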