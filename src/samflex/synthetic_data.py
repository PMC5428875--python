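"""Seeded synthetic instrument data with the statistical structure the
analysis assumes.

The generator emulates the lab chain end to end: triangular RH ramps at a
fixed rate, a resonance-frequency branch computed from the forward layer
model plus white PLL noise (no hysteresis — the real frequency branch
shows almost none), a phenomenological static-deflection branch (monotone
in RH, growing with immobilization time, with a hysteretic loop), shift
tables over grafting-density grids referenced to the bare-gold beam, and
XPS records from the exponential attenuation model. Every dataset carries
a truth sidecar for recovery tests, and a fixed seed reproduces output
byte for byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import beam_mechanics as bm
from . import layer_model as lm
from . import xps_quant as xq
from .errors import InvalidInputError
from .inversion_pipeline import RHSweep, model_relative_shift

__all__ = [
    "GeneratorConfig",
    "DEFAULT_GEOMETRY",
    "DensitySeries",
    "XPSSeries",
    "generate_rh_sweep",
    "generate_density_series",
    "generate_hybridization_series",
    "generate_xps_series",
    "density_from_immobilization_time",
    "immobilization_time_from_density",
]

#: The measurement cantilever: 500 × 100 × 1 μm silicon (E = 169 GPa,
#: ρ = 2330 kg/m³); fundamental resonance ≈ 5.5 kHz.
DEFAULT_GEOMETRY = bm.CantileverGeometry.from_practical(
    length_um=500.0, width_um=100.0, thickness_um=1.0,
    modulus_gpa=169.0, density=2330.0,
)

_DEFAULT_DENSITY_GRID = (
    1e12, 5e12, 1e13, 1.5e13, 2e13, 2.5e13, 3e13, 3.7e13, 4.5e13, 5.5e13, 6.5e13
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions of the emulated experiment.

    Defaults: RH ramp 10 %/min over [0, 70] %, frequency noise 50 mHz
    (the PLL noise floor), deflection noise 5 nm with a hysteretic loop,
    immobilization times 5 min – 24 h, hybridization truth
    (efficiency 0.40, excess mass 0.15). ``deflection_scale`` and
    ``deflection_exponent`` calibrate the RH-70 deflection to −180 nm at
    5 min and −1550 nm at 24 h immobilization.
    """

    seed: int = 0
    ramp_rate: float = 10.0          # % RH / min
    rh_max: float = 70.0             # %
    sample_dt: float = 1.0           # s
    frequency_noise_sd: float = 0.05  # Hz
    deflection_noise_sd: float = 5.0  # nm
    deflection_hysteresis_scale: float = 0.08  # fraction of full-RH deflection
    deflection_scale: float = 648.0   # nm at 1e13 molecules/cm²
    deflection_exponent: float = 0.4655
    deflection_shape_exponent: float = 1.5
    density_grid: tuple[float, ...] = _DEFAULT_DENSITY_GRID
    immobilization_times: tuple[float, ...] = (5, 120, 360, 540, 720, 1200, 1440)
    langmuir_n_max: float = 7e13      # molecules/cm²
    langmuir_tau: float = 545.6       # min; 1440 min → 6.5e13 molecules/cm²
    hybridization_truth: tuple[float, float] = (0.40, 0.15)
    xps_noise: float = 0.01           # lognormal sd on intensities
    xps_i0: float = 1e5               # clean-reference Au4f counts
    xps_l_au: float = 2.0e-9          # PEAL, m
    xps_instrument_constant: float = xq.DEFAULT_INSTRUMENT_CONSTANT
    noise: bool = True

    def __post_init__(self):
        for name in ("frequency_noise_sd", "deflection_noise_sd", "xps_noise"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be non-negative")
        if not self.ramp_rate > 0 or not self.sample_dt > 0:
            raise InvalidInputError("ramp rate and sample spacing must be positive")

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(stream,))
        )


@dataclass
class DensitySeries:
    """Shift table over a grafting-density grid plus the generating truth."""

    table: pd.DataFrame  # columns: density_per_cm2, rel_shift, delta_f_hz
    truth: dict
    sweeps: list[RHSweep] = field(default_factory=list)


@dataclass
class XPSSeries:
    records: list[xq.XPSRecord]
    truth: pd.DataFrame  # columns: sample_id, density_per_cm2, thickness_m


def density_from_immobilization_time(
    minutes: float, cfg: GeneratorConfig | None = None
) -> float:
    """Langmuir-type adsorption kinetics n(t) = n_max(1 − e^(−t/τ)).

    A modeling convenience mapping incubation time to grafting density
    (calibrated so 24 h → 6.5×10¹³ cm⁻²); the experimental densities come
    from XPS, not from kinetics.
    """
    cfg = cfg or GeneratorConfig()
    return cfg.langmuir_n_max * (1.0 - math.exp(-minutes / cfg.langmuir_tau))


def immobilization_time_from_density(
    n: float, cfg: GeneratorConfig | None = None
) -> float:
    cfg = cfg or GeneratorConfig()
    if not 0 <= n < cfg.langmuir_n_max:
        raise InvalidInputError("density outside the Langmuir range")
    return -cfg.langmuir_tau * math.log(1.0 - n / cfg.langmuir_n_max)


def _triangular_ramp(cfg: GeneratorConfig):
    """Time (s), RH (%) and branch labels of one hydration/dehydration loop."""
    ramp_per_s = cfg.ramp_rate / 60.0
    t_half = cfg.rh_max / ramp_per_s
    time = np.arange(0.0, 2.0 * t_half + cfg.sample_dt / 2, cfg.sample_dt)
    rh = np.where(
        time <= t_half, ramp_per_s * time, cfg.rh_max - ramp_per_s * (time - t_half)
    )
    rh = np.clip(rh, 0.0, cfg.rh_max)
    branch = np.where(time <= t_half, "hydration", "dehydration")
    return time, rh, branch


def generate_rh_sweep(
    cfg: GeneratorConfig,
    layer: lm.LayerConfig,
    geometry: bm.CantileverGeometry = DEFAULT_GEOMETRY,
    stream: int = 0,
) -> RHSweep:
    """One hydration/dehydration cycle for one functionalized cantilever.

    The frequency branch is the forward layer model (no hysteresis) plus
    white noise; the deflection branch is a monotone power law in RH
    scaled with grafting density, with a hysteretic loop of configured
    width. ``stream`` decorrelates several sweeps drawn from one seed.
    """
    rng = cfg.rng(stream)
    time, rh, branch = _triangular_ramp(cfg)
    f_bare = bm.resonance_frequency(geometry)

    shift = model_relative_shift(layer, rh, geometry)
    shift0 = model_relative_shift(layer, 0.0, geometry)
    f = f_bare * (1.0 + shift)
    f0 = f_bare * (1.0 + shift0)
    delta_f = f - f0
    if cfg.noise:
        delta_f = delta_f + rng.normal(0.0, cfg.frequency_noise_sd, delta_f.shape)

    n = layer.grafting_density
    d_full = cfg.deflection_scale * (n / 1e13) ** cfg.deflection_exponent if n > 0 else 0.0
    u = rh / cfg.rh_max
    deflection = -d_full * u**cfg.deflection_shape_exponent
    loop = cfg.deflection_hysteresis_scale * d_full * 4.0 * u * (1.0 - u)
    deflection = deflection - np.where(branch == "dehydration", loop, 0.0)
    if cfg.noise:
        deflection = deflection + rng.normal(
            0.0, cfg.deflection_noise_sd, deflection.shape
        )

    data = pd.DataFrame(
        {
            "time_s": time,
            "rh_percent": rh,
            "deflection_nm": deflection,
            "delta_f_hz": delta_f,
            "branch": branch,
        }
    )
    try:
        imm_time = immobilization_time_from_density(n, cfg)
    except InvalidInputError:
        imm_time = float("nan")
    metadata = {
        "f0_hz": float(f0),
        "f_bare_hz": float(f_bare),
        "grafting_density_per_cm2": float(n),
        "kind": layer.kind,
        "immobilization_time_min": float(imm_time),
        "seed": cfg.seed,
    }
    return RHSweep(data=data, metadata=metadata)


def _series(
    cfg: GeneratorConfig,
    base_layer: lm.LayerConfig,
    geometry: bm.CantileverGeometry,
    rh: float,
    stream: int,
    include_sweeps: bool,
) -> DensitySeries:
    rng = cfg.rng(stream)
    f_bare = bm.resonance_frequency(geometry)
    densities = np.asarray(cfg.density_grid, dtype=float)
    rel = np.array(
        [
            model_relative_shift(base_layer.with_density(n), rh, geometry)
            for n in densities
        ]
    )
    if cfg.noise:
        rel = rel + rng.normal(0.0, cfg.frequency_noise_sd / f_bare, rel.shape)
    table = pd.DataFrame(
        {
            "density_per_cm2": densities,
            "rel_shift": rel,
            "delta_f_hz": rel * f_bare,
        }
    )
    truth = {
        "kind": base_layer.kind,
        "rh_percent": rh,
        "hybridization_fraction": base_layer.effective_hybridization,
        "excess_mass_fraction": base_layer.excess_mass_fraction,
        "rel_shift_noiseless": np.array(
            [
                model_relative_shift(base_layer.with_density(n), rh, geometry)
                for n in densities
            ]
        ),
        "modulus_pa": np.array(
            [
                lm.layer_modulus(base_layer.with_density(n), rh)
                for n in densities
            ]
        ),
        "rel_shift_noise_sd": cfg.frequency_noise_sd / f_bare,
    }
    sweeps = []
    if include_sweeps:
        sweeps = [
            generate_rh_sweep(
                cfg, base_layer.with_density(n), geometry, stream=stream + 1 + i
            )
            for i, n in enumerate(densities)
        ]
    return DensitySeries(table=table, truth=truth, sweeps=sweeps)


def generate_density_series(
    cfg: GeneratorConfig,
    geometry: bm.CantileverGeometry = DEFAULT_GEOMETRY,
    kind: str = "ssDNA",
    rh: float = 70.0,
    include_sweeps: bool = False,
) -> DensitySeries:
    """Relative shifts vs bare gold over the density grid, one species.

    With ``include_sweeps`` a full RH sweep is generated per density (the
    per-cantilever raw data behind the table).
    """
    layer = lm.LayerConfig(kind=kind, grafting_density=0.0)
    return _series(cfg, layer, geometry, rh, stream=0, include_sweeps=include_sweeps)


def generate_hybridization_series(
    cfg: GeneratorConfig,
    geometry: bm.CantileverGeometry = DEFAULT_GEOMETRY,
    rh: float = 70.0,
) -> DensitySeries:
    """Shift table of the partially hybridized layer with (h, m) truth."""
    h, m = cfg.hybridization_truth
    layer = lm.LayerConfig(
        kind="mixed",
        grafting_density=0.0,
        hybridization_fraction=h,
        excess_mass_fraction=m,
    )
    return _series(cfg, layer, geometry, rh, stream=0, include_sweeps=False)


def generate_xps_series(
    cfg: GeneratorConfig,
    strand_length: int = 20,
) -> XPSSeries:
    """XPS records over the density grid with thickness/density truth.

    Ex-situ spectra: the dry-state ss thickness attenuates the Au4f
    reference, and the raw P/Au and N/Au ratios follow the uniform-
    overlayer emission model with multiplicative lognormal noise.
    """
    rng = cfg.rng(stream=7)
    markers = lm.marker_atoms_per_strand()
    records, truth_rows = [], []
    for i, n in enumerate(cfg.density_grid):
        t = lm.thickness_vs_density(n, "dry", lm.SS_STRAND)
        i_au = cfg.xps_i0 * math.exp(-t / cfg.xps_l_au)
        ratios = {}
        for element, atoms in markers.items():
            areal = n * atoms  # atoms/cm²
            corrected = areal / (cfg.xps_instrument_constant * t)
            raw = xq.forward_ratio(corrected, t, cfg.xps_l_au, cfg.xps_l_au)
            if cfg.noise:
                raw *= math.exp(rng.normal(0.0, cfg.xps_noise))
            ratios[element] = float(raw)
        if cfg.noise:
            i_au *= math.exp(rng.normal(0.0, cfg.xps_noise))
        sample_id = f"xps-{i:02d}"
        records.append(
            xq.XPSRecord(
                i_au=float(i_au),
                i_au0=cfg.xps_i0,
                l_au=cfg.xps_l_au,
                peak_ratios=ratios,
                sample_id=sample_id,
            )
        )
        truth_rows.append((sample_id, n, t))
    truth = pd.DataFrame(
        truth_rows, columns=["sample_id", "density_per_cm2", "thickness_m"]
    )
    return XPSSeries(records=records, truth=truth)
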