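"""End-to-end analysis: RH sweeps → E_eff(RH); density series → fits.

The measurement chain this module implements:

1. an RH sweep of a coated cantilever yields Δf(RH); each record is
   converted to an absolute relative shift, the layer thickness and mass
   density at that RH are resolved from the layer model, and the
   thickness-ratio expansion is inverted for the effective Young's
   modulus, with a thickness-uncertainty error bar;
2. hydration/dehydration loops are characterized by their hysteresis
   (area between branches, maximum branch gap);
3. modulus-vs-density series are fit with the saturating-growth or linear
   family; the composed forward model locates the critical grafting
   density where layer stiffening cancels mass loading; and a
   two-parameter fit of (hybridization efficiency, excess mass) matches
   the forward model to hybridized-layer shift data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq, curve_fit, least_squares

from . import beam_mechanics as bm
from . import layer_model as lm
from .errors import (
    InfeasibleShiftError,
    InvalidInputError,
    MissingBranchError,
    NoCrossoverError,
)
from .units import GPA

__all__ = [
    "RHSweep",
    "FitResult",
    "HybridizationFit",
    "HysteresisMetrics",
    "model_relative_shift",
    "sweep_to_modulus_curve",
    "hysteresis_metrics",
    "propagate_thickness_uncertainty",
    "relative_uncertainty_percent",
    "fit_density_curves",
    "frequency_shift_vs_density",
    "critical_crossover_density",
    "fit_hybridization",
]

SWEEP_COLUMNS = ("time_s", "rh_percent", "deflection_nm", "delta_f_hz", "branch")
BRANCHES = ("hydration", "dehydration")


@dataclass
class RHSweep:
    """One hydration/dehydration cycle of one cantilever.

    ``data`` columns: time_s, rh_percent, deflection_nm, delta_f_hz,
    branch (hydration|dehydration). Δf is referenced to the sweep's own
    RH = 0 % resonance, f0. ``metadata`` must carry ``f0_hz``; the bare
    (uncoated) cantilever frequency ``f_bare_hz``, when present, anchors
    absolute shifts.
    """

    data: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = [c for c in SWEEP_COLUMNS if c not in self.data.columns]
        if missing:
            raise InvalidInputError(f"sweep is missing columns {missing}")
        t = self.data["time_s"].to_numpy()
        if len(t) and not np.all(np.diff(t) > 0):
            raise InvalidInputError("sweep time must be strictly increasing")
        rh = self.data["rh_percent"].to_numpy()
        if np.any((rh < 0) | (rh > 100)):
            raise InvalidInputError("sweep RH must lie in [0, 100]")
        branches = set(self.data["branch"].unique())
        if not branches <= set(BRANCHES):
            raise InvalidInputError(f"unknown branch labels {branches - set(BRANCHES)}")
        f0 = self.metadata.get("f0_hz")
        if f0 is None or not f0 > 0:
            raise InvalidInputError("sweep metadata must carry f0_hz > 0")

    @property
    def f0(self) -> float:
        return float(self.metadata["f0_hz"])


@dataclass
class FitResult:
    """Fitted parameters with 1σ standard errors from the local curvature."""

    params: dict[str, float]
    stderr: dict[str, float]
    residual_sum: float
    n_points: int
    converged: bool
    family: str = ""
    seed: int | None = None

    def __post_init__(self):
        if any(v < 0 for v in self.stderr.values() if not math.isnan(v)):
            raise InvalidInputError("standard errors must be non-negative")


@dataclass
class HybridizationFit:
    """Two-parameter hybridization fit outcome.

    ``efficiency`` is the hybridized fraction h ∈ [0, 1]; ``excess_mass``
    the nonspecifically adsorbed mass fraction m ≥ 0. ``boundary_pinned``
    flags a solution stuck at a bound (treat as non-identified).
    """

    efficiency: float
    excess_mass: float
    fit: FitResult
    boundary_pinned: bool = False

    def __post_init__(self):
        if not 0 <= self.efficiency <= 1:
            raise InvalidInputError("efficiency must lie in [0, 1]")
        if self.excess_mass < 0:
            raise InvalidInputError("excess mass must be non-negative")


@dataclass(frozen=True)
class HysteresisMetrics:
    loop_area: float
    max_branch_gap: float


# --- Forward model ---------------------------------------------------------

def model_relative_shift(
    config: lm.LayerConfig,
    rh,
    geometry: bm.CantileverGeometry,
    order: int = 2,
):
    """Modeled relative frequency shift of the coated vs bare cantilever.

    Composes the layer property models (thickness, mass density, modulus
    at the given RH) with the thickness-ratio expansion. Vectorized
    over ``rh``.
    """
    rh_arr = np.atleast_1d(np.asarray(rh, dtype=float))
    t = np.atleast_1d(lm.layer_thickness(config, rh_arr))
    rho = np.atleast_1d(lm.layer_mass_density(config, rh_arr))
    e = np.atleast_1d(lm.layer_modulus(config, rh_arr))
    tau = t / geometry.thickness
    e_r = e / geometry.modulus
    rho_r = rho / geometry.density
    shift = 0.5 * (3.0 * e_r - rho_r) * tau
    if order == 2:
        shift = shift + 0.375 * (
            rho_r**2 + 2.0 * e_r * (4.0 - rho_r) - 7.0 * e_r**2
        ) * tau**2
    return float(shift[0]) if np.isscalar(rh) else shift


# --- Sweep inversion -------------------------------------------------------

def sweep_to_modulus_curve(
    sweep: RHSweep,
    config: lm.LayerConfig,
    geometry: bm.CantileverGeometry,
    order: int = 2,
    rel_thickness_uncertainty: float = 0.0,
) -> pd.DataFrame:
    """Invert every sweep record to an effective layer Young's modulus.

    Sweep shifts are self-referenced (Δf = f(RH) − f(0%)); the absolute
    shift needed by the inversion is reconstructed from the bare-beam
    frequency in the metadata (``f_bare_hz``) or, absent that, anchored at
    the layer model's own dry-state forward shift.

    Returns a frame with columns rh_percent, branch, modulus_pa,
    modulus_err_pa, clipped, infeasible. Infeasible inversions are flagged
    per point, never fatal.
    """
    f0 = sweep.f0
    f_bare = sweep.metadata.get("f_bare_hz")
    if f_bare is not None:
        baseline = (f0 - float(f_bare)) / float(f_bare)
        ref = float(f_bare)
    else:
        baseline = model_relative_shift(config, 0.0, geometry, order=order)
        ref = f0
    rows = []
    for rec in sweep.data.itertuples(index=False):
        shift = rec.delta_f_hz / ref + baseline
        t = lm.layer_thickness(config, rec.rh_percent)
        rho = lm.layer_mass_density(config, rec.rh_percent)
        layer = bm.LayerProperties(thickness=t, mass_density=rho)
        try:
            res = bm.invert_frequency_shift(shift, layer, geometry, order=order)
            err = (
                propagate_thickness_uncertainty(
                    shift, layer, geometry, rel_thickness_uncertainty, order=order
                )
                if rel_thickness_uncertainty > 0
                else 0.0
            )
            rows.append(
                (rec.rh_percent, rec.branch, res.modulus, err, res.clipped, False)
            )
        except InfeasibleShiftError:
            rows.append((rec.rh_percent, rec.branch, np.nan, np.nan, False, True))
    return pd.DataFrame(
        rows,
        columns=[
            "rh_percent",
            "branch",
            "modulus_pa",
            "modulus_err_pa",
            "clipped",
            "infeasible",
        ],
    )


def hysteresis_metrics(
    curve: pd.DataFrame,
    value_column: str,
    rh_column: str = "rh_percent",
    branch_column: str = "branch",
) -> HysteresisMetrics:
    """Loop area and maximum gap between hydration and dehydration branches.

    Both branches are interpolated to their common RH grid (the union of
    the two branch grids restricted to the overlapping RH range);
    ``loop_area`` is the trapezoidal integral of |hydration − dehydration|
    over RH, ``max_branch_gap`` the maximum absolute difference.
    """
    branches = {}
    for name in BRANCHES:
        sel = curve[curve[branch_column] == name]
        if len(sel) < 2:
            raise MissingBranchError(f"branch {name!r} absent or too short")
        rh = sel[rh_column].to_numpy(dtype=float)
        val = sel[value_column].to_numpy(dtype=float)
        idx = np.argsort(rh)
        branches[name] = (rh[idx], val[idx])
    lo = max(branches[b][0].min() for b in BRANCHES)
    hi = min(branches[b][0].max() for b in BRANCHES)
    if hi <= lo:
        raise MissingBranchError("branches do not overlap in RH")
    grid = np.unique(
        np.concatenate([rh[(rh >= lo) & (rh <= hi)] for rh, _ in branches.values()])
    )
    interp = {
        name: np.interp(grid, rh, val) for name, (rh, val) in branches.items()
    }
    diff = np.abs(interp["hydration"] - interp["dehydration"])
    return HysteresisMetrics(
        loop_area=float(np.trapezoid(diff, grid)),
        max_branch_gap=float(diff.max()) if len(diff) else 0.0,
    )


def propagate_thickness_uncertainty(
    shift: float,
    layer: bm.LayerProperties,
    geometry: bm.CantileverGeometry,
    rel_thickness_uncertainty: float,
    order: int = 2,
) -> float:
    """Modulus error ΔE (Pa) from a relative layer-thickness uncertainty.

    The layer thickness is the dominant error source of the inversion.
    Re-runs the inversion at t(1±u) with the mass density co-varied as 1/t
    (deposited areal mass conserved) and returns half the spread; if one
    perturbed inversion is infeasible the one-sided difference is
    returned.
    """
    if rel_thickness_uncertainty < 0:
        raise InvalidInputError("relative thickness uncertainty must be >= 0")
    if rel_thickness_uncertainty == 0.0:
        return 0.0
    u = rel_thickness_uncertainty
    center = bm.invert_frequency_shift(shift, layer, geometry, order=order).modulus
    results = []
    for s in (1.0 + u, 1.0 - u):
        perturbed = replace(
            layer, thickness=layer.thickness * s, mass_density=layer.mass_density / s
        )
        try:
            results.append(
                bm.invert_frequency_shift(shift, perturbed, geometry, order=order).modulus
            )
        except InfeasibleShiftError:
            results.append(None)
    hi, lo = results
    if hi is not None and lo is not None:
        return abs(hi - lo) / 2.0
    one_sided = hi if hi is not None else lo
    if one_sided is None:
        raise InfeasibleShiftError("inversion infeasible at both perturbed thicknesses")
    return abs(one_sided - center)


def relative_uncertainty_percent(modulus: float, modulus_err: float) -> float:
    """Relative modulus uncertainty ΔE/E as a percentage."""
    if not modulus > 0:
        raise InvalidInputError("modulus must be strictly positive")
    if modulus_err < 0:
        raise InvalidInputError("modulus error must be non-negative")
    return 100.0 * modulus_err / modulus


# --- Density-series fits ---------------------------------------------------

def _stderr_from_covariance(cov: np.ndarray) -> np.ndarray:
    diag = np.diag(cov)
    return np.where(diag >= 0, np.sqrt(np.abs(diag)), np.nan)


def fit_density_curves(
    densities,
    moduli,
    family: str,
    weights=None,
) -> FitResult:
    """Weighted least-squares fit of an E(n) family to (n, E) points.

    ``saturating_growth`` is fit in the non-redundant parameterization
    E(n) = E_max/(1 + R·e^(−n/n0)) (the A/(B + C·e^(−n/n0)) family is
    scale-invariant in (A, B, C); E_max = A/B, R = C/B) and reports
    e_max (the asymptote A/B), r and n0. ``linear`` reports slope and
    intercept. ``weights`` are per-point standard deviations (inverse-
    variance weighting); uniform when omitted.
    """
    n = np.asarray(densities, dtype=float)
    e = np.asarray(moduli, dtype=float)
    if family == "saturating_growth" and len(n) < 4:
        raise InvalidInputError("saturating_growth needs at least 4 points")
    if family == "linear" and len(n) < 2:
        raise InvalidInputError("linear needs at least 2 points")
    sigma = None if weights is None else np.asarray(weights, dtype=float)

    if family == "linear":
        def f(x, slope, intercept):
            return intercept + slope * x

        p0 = [(e[-1] - e[0]) / (n[-1] - n[0] + 1e-300), float(e[0])]
        names = ["slope", "intercept"]
        bounds = (-np.inf, np.inf)
    elif family == "saturating_growth":
        def f(x, e_max, log_r, n0):
            return e_max / (1.0 + np.exp(log_r) * np.exp(-x / n0))

        p0 = [float(max(e.max(), 1.0)), math.log(10.0), float(np.median(n))]
        names = ["e_max", "log_r", "n0"]
        bounds = ([0.0, -10.0, n.max() * 1e-3], [np.inf, 30.0, n.max() * 10.0])
    else:
        raise InvalidInputError(f"unknown fit family {family!r}")

    try:
        popt, pcov = curve_fit(
            f, n, e, p0=p0, sigma=sigma, absolute_sigma=sigma is not None,
            bounds=bounds, maxfev=20000,
        )
        converged = bool(np.all(np.isfinite(popt)))
    except RuntimeError:
        popt = np.full(len(p0), np.nan)
        pcov = np.full((len(p0), len(p0)), np.nan)
        converged = False
    resid = e - f(n, *popt) if converged else np.full_like(e, np.nan)
    stderr = _stderr_from_covariance(pcov) if converged else np.full(len(p0), np.nan)
    params = dict(zip(names, (float(v) for v in popt)))
    errs = dict(zip(names, (float(v) for v in stderr)))
    if family == "saturating_growth" and converged:
        params["asymptote"] = params["e_max"]
        errs["asymptote"] = errs["e_max"]
    return FitResult(
        params=params,
        stderr=errs,
        residual_sum=float(np.nansum(resid**2)),
        n_points=len(n),
        converged=converged,
        family=family,
    )


def frequency_shift_vs_density(
    densities,
    base_config: lm.LayerConfig,
    geometry: bm.CantileverGeometry,
    rh: float,
    order: int = 2,
) -> np.ndarray:
    """Modeled relative shift (vs bare beam) over a grafting-density grid."""
    return np.array(
        [
            model_relative_shift(base_config.with_density(n), rh, geometry, order)
            for n in np.asarray(densities, dtype=float)
        ]
    )


def critical_crossover_density(
    base_config: lm.LayerConfig,
    geometry: bm.CantileverGeometry,
    rh: float = 70.0,
    interval: tuple[float, float] = (1e12, 1e14),
    order: int = 2,
    scan_points: int = 600,
) -> float:
    """Grafting density (molecules/cm²) where the modeled shift crosses zero.

    The critical coverage at which layer stiffening cancels the added-mass
    downshift. A log-spaced scan over ``interval`` locates sign changes;
    the smallest bracketed one is refined by Brent's method.

    Raises
    ------
    NoCrossoverError
        When the modeled curve does not change sign on the interval (the
        expected outcome for the soft, mass-dominated dsDNA layer).
    """

    def shift_at(n: float) -> float:
        return model_relative_shift(base_config.with_density(n), rh, geometry, order)

    grid = np.geomspace(interval[0], interval[1], scan_points)
    values = np.array([shift_at(n) for n in grid])
    sign = np.sign(values)
    change = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    exact = np.nonzero(values == 0.0)[0]
    if len(exact) and (not len(change) or exact[0] <= change[0]):
        return float(grid[exact[0]])
    if not len(change):
        raise NoCrossoverError(
            f"modeled shift does not change sign on [{interval[0]:.2g}, "
            f"{interval[1]:.2g}] molecules/cm²"
        )
    i = change[0]
    return float(brentq(shift_at, grid[i], grid[i + 1], xtol=1e6, rtol=1e-12))


# --- Hybridization fit -----------------------------------------------------

def fit_hybridization(
    densities,
    shifts,
    geometry: bm.CantileverGeometry,
    rh: float,
    base_config: lm.LayerConfig | None = None,
    order: int = 2,
) -> HybridizationFit:
    """Fit (hybridization efficiency, excess mass) to hybridized-layer shifts.

    Bounded least squares of the full forward model — the mixed ss/ds
    layer with hybridized fraction h and excess mass fraction m — against
    measured relative shifts (vs bare beam) over a grafting-density grid.
    h ∈ [0, 1], m ∈ [0, 1].
    """
    n = np.asarray(densities, dtype=float)
    y = np.asarray(shifts, dtype=float)
    if len(n) < 3:
        raise InvalidInputError("hybridization fit needs at least 3 density points")
    if base_config is None:
        base_config = lm.LayerConfig(kind="mixed", grafting_density=0.0)

    def predict(h: float, m: float) -> np.ndarray:
        cfg = replace(
            base_config,
            kind="mixed",
            hybridization_fraction=h,
            excess_mass_fraction=m,
        )
        return frequency_shift_vs_density(n, cfg, geometry, rh, order)

    def residuals(p):
        return predict(p[0], p[1]) - y

    sol = least_squares(
        residuals, x0=[0.5, 0.1], bounds=([0.0, 0.0], [1.0, 1.0]),
        method="dogbox", xtol=1e-12, ftol=1e-12, gtol=1e-12,
    )
    h_hat, m_hat = sol.x
    # 1σ from the Gauss-Newton curvature at the solution
    dof = max(len(n) - 2, 1)
    s2 = 2.0 * sol.cost / dof
    jtj = sol.jac.T @ sol.jac
    try:
        cov = s2 * np.linalg.inv(jtj)
        stderr = _stderr_from_covariance(cov)
    except np.linalg.LinAlgError:
        stderr = np.array([np.nan, np.nan])
    eps = 1e-6
    pinned = bool(
        h_hat < eps or h_hat > 1 - eps or m_hat < eps or m_hat > 1 - eps
    )
    fit = FitResult(
        params={"efficiency": float(h_hat), "excess_mass": float(m_hat)},
        stderr={"efficiency": float(stderr[0]), "excess_mass": float(stderr[1])},
        residual_sum=float(2.0 * sol.cost),
        n_points=len(n),
        converged=bool(sol.success),
        family="hybridization",
    )
    return HybridizationFit(
        efficiency=float(h_hat),
        excess_mass=float(m_hat),
        fit=fit,
        boundary_pinned=pinned,
    )
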