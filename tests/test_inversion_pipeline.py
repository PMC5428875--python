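"""Sweep inversion, hysteresis metrics, uncertainty propagation and the
density-series / hybridization fitting chain."""

import numpy as np
import pandas as pd
import pytest

import samflex as sf
from samflex import beam_mechanics as bm
from samflex import inversion_pipeline as ip
from samflex import layer_model as lm
from samflex import synthetic_data as sd
from samflex.errors import (
    InvalidInputError,
    MissingBranchError,
    NoCrossoverError,
)

GPA = 1e9


@pytest.fixture(scope="module")
def noiseless_sweep(geometry):
    cfg = sd.GeneratorConfig(seed=5, noise=False)
    layer = lm.LayerConfig(kind="ssDNA", grafting_density=3.7e13)
    return sd.generate_rh_sweep(cfg, layer, geometry), layer


class TestSweepInversion:
    def test_noiseless_sweep_recovers_model_modulus_curve(self, noiseless_sweep, geometry):
        sweep, layer = noiseless_sweep
        curve = ip.sweep_to_modulus_curve(sweep, layer, geometry)
        assert not curve["infeasible"].any()
        truth = np.array(
            [lm.layer_modulus(layer, rh) for rh in curve["rh_percent"]]
        )
        assert np.allclose(curve["modulus_pa"], truth, rtol=1e-6)

    def test_recovered_tuning_range_is_ten_gigapascal(self, noiseless_sweep, geometry):
        sweep, layer = noiseless_sweep
        curve = ip.sweep_to_modulus_curve(sweep, layer, geometry)
        e70 = curve.loc[curve["rh_percent"].idxmax(), "modulus_pa"]
        e0 = curve.loc[curve["rh_percent"].idxmin(), "modulus_pa"]
        assert (e70 - e0) / GPA == pytest.approx(10.0, rel=1e-6)

    def test_zero_shift_zero_modulus_layer_flags_all_points(self, geometry):
        # a soft layer with no shift inverts to 0 everywhere
        layer = lm.LayerConfig(kind="ssDNA", grafting_density=5e12)
        n_pts = 20
        data = pd.DataFrame(
            {
                "time_s": np.arange(n_pts, dtype=float),
                "rh_percent": np.linspace(0, 70, n_pts),
                "deflection_nm": np.zeros(n_pts),
                "delta_f_hz": np.zeros(n_pts),
                "branch": ["hydration"] * n_pts,
            }
        )
        f0 = bm.resonance_frequency(geometry)
        sweep = ip.RHSweep(data=data, metadata={"f0_hz": f0, "f_bare_hz": f0})
        curve = ip.sweep_to_modulus_curve(sweep, layer, geometry)
        # zero total shift at finite mass loading → stiffness compensates;
        # all inversions feasible, none negative
        assert not curve["infeasible"].any()
        assert (curve["modulus_pa"] >= 0).all()

    def test_modulus_curve_is_hysteresis_free_at_noise_floor(self, geometry):
        cfg = sd.GeneratorConfig(seed=6)
        layer = lm.LayerConfig(kind="ssDNA", grafting_density=3.7e13)
        sweep = sd.generate_rh_sweep(cfg, layer, geometry)
        curve = ip.sweep_to_modulus_curve(sweep, layer, geometry)
        metrics = ip.hysteresis_metrics(curve, "modulus_pa")
        # expected branch separation from the frequency noise floor alone:
        # σ_E(rh) ≈ σ_shift · E_c / (1.5 τ(rh)); the loop area of pure noise
        # is below ~√2·mean σ_E per unit RH
        f_bare = bm.resonance_frequency(geometry)
        sigma_shift = cfg.frequency_noise_sd / f_bare
        taus = lm.layer_thickness(layer, np.linspace(0, 70, 50)) / geometry.thickness
        sigma_e = sigma_shift * geometry.modulus / (1.5 * taus)
        bound = 3.0 * np.sqrt(2.0) * sigma_e.mean() * 70.0
        assert metrics.loop_area < bound


class TestHysteresisMetrics:
    @staticmethod
    def _loop(up, down, rh=None):
        rh = np.linspace(0, 70, len(up)) if rh is None else rh
        return pd.DataFrame(
            {
                "rh_percent": np.concatenate([rh, rh]),
                "value": np.concatenate([up, down]),
                "branch": ["hydration"] * len(up) + ["dehydration"] * len(up),
            }
        )

    def test_identical_branches_give_zero(self):
        rh = np.linspace(0, 70, 30)
        m = ip.hysteresis_metrics(self._loop(rh**1.3, rh**1.3), "value")
        assert m.loop_area == 0.0
        assert m.max_branch_gap == 0.0

    def test_constant_offset_matches_closed_form(self):
        # branches y = RH and y = RH + c: area 70c, gap c by the trapezoid rule
        rh = np.linspace(0, 70, 71)
        c = 2.5
        m = ip.hysteresis_metrics(self._loop(rh, rh + c), "value")
        assert m.loop_area == pytest.approx(70 * c, rel=1e-12)
        assert m.max_branch_gap == pytest.approx(c, rel=1e-12)

    def test_single_branch_raises(self):
        rh = np.linspace(0, 70, 30)
        df = pd.DataFrame(
            {"rh_percent": rh, "value": rh, "branch": ["hydration"] * 30}
        )
        with pytest.raises(MissingBranchError):
            ip.hysteresis_metrics(df, "value")

    def test_generator_contract_deflection_loops_frequency_does_not(self, geometry):
        cfg = sd.GeneratorConfig(seed=7)
        layer = lm.LayerConfig(kind="ssDNA", grafting_density=3.7e13)
        sweep = sd.generate_rh_sweep(cfg, layer, geometry)
        defl = ip.hysteresis_metrics(sweep.data, "deflection_nm")
        freq = ip.hysteresis_metrics(sweep.data, "delta_f_hz")
        # deflection: a real loop, far above its 5 nm noise; frequency:
        # consistent with the 50 mHz noise floor
        assert defl.loop_area > 10 * cfg.deflection_noise_sd * 70.0
        assert freq.loop_area < 3 * np.sqrt(2) * cfg.frequency_noise_sd * 70.0


class TestThicknessUncertainty:
    @pytest.fixture()
    def operating_point(self, geometry):
        layer_in = bm.LayerProperties(
            thickness=1.88546972512e-9, mass_density=584.395487937, modulus=12.3e9
        )
        shift = bm.frequency_shift_second_order(layer_in, geometry)
        bare = bm.LayerProperties(
            thickness=layer_in.thickness, mass_density=layer_in.mass_density
        )
        return shift, bare

    def test_zero_uncertainty_zero_error(self, operating_point, geometry):
        shift, layer = operating_point
        assert ip.propagate_thickness_uncertainty(shift, layer, geometry, 0.0) == 0.0

    def test_small_u_linearity(self, operating_point, geometry):
        shift, layer = operating_point
        e1 = ip.propagate_thickness_uncertainty(shift, layer, geometry, 0.025)
        e2 = ip.propagate_thickness_uncertainty(shift, layer, geometry, 0.05)
        assert e2 == pytest.approx(2 * e1, rel=0.05)

    def test_printed_33_percent_needs_plausible_thickness_uncertainty(
        self, operating_point, geometry
    ):
        # scan u until ΔE/E reaches the published 33 % relative error;
        # the implied thickness uncertainty must be physically plausible
        shift, layer = operating_point
        e = bm.invert_frequency_shift(shift, layer, geometry).modulus
        us = np.linspace(0.02, 0.6, 200)
        rel = np.array(
            [
                ip.propagate_thickness_uncertainty(shift, layer, geometry, u) / e
                for u in us
            ]
        )
        crossing = us[np.argmin(np.abs(rel - 0.33))]
        assert 0.1 <= crossing <= 0.5

    def test_relative_uncertainty_helper(self):
        assert ip.relative_uncertainty_percent(12.3, 4.1) == pytest.approx(
            100 * 4.1 / 12.3
        )
        with pytest.raises(InvalidInputError):
            ip.relative_uncertainty_percent(0.0, 1.0)


class TestDensityFits:
    def test_noiseless_saturating_growth_recovered_exactly(self):
        n = np.linspace(1e12, 6.5e13, 9)
        e = 15e9 / (1.0 + 8.0 * np.exp(-n / 9e12))
        fit = ip.fit_density_curves(n, e, "saturating_growth")
        assert fit.converged
        assert fit.params["e_max"] == pytest.approx(15e9, rel=1e-6)
        assert fit.params["n0"] == pytest.approx(9e12, rel=1e-6)
        assert fit.params["asymptote"] == pytest.approx(15e9, rel=1e-6)

    def test_noiseless_linear_recovered_exactly(self):
        n = np.linspace(1e12, 6.5e13, 5)
        e = 4.6e8 + 2.4e-5 * n
        fit = ip.fit_density_curves(n, e, "linear")
        assert fit.params["slope"] == pytest.approx(2.4e-5, rel=1e-9)
        assert fit.params["intercept"] == pytest.approx(4.6e8, rel=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(InvalidInputError):
            ip.fit_density_curves([1e12, 1e13, 2e13], [1, 2, 3], "saturating_growth")


class TestShiftVsDensityCurve:
    def test_zero_modulus_layer_is_pure_mass_loading(self, geometry):
        # E(n) ≡ 0: strictly negative and decreasing shift
        soft = lm.StrandModel(
            strand_mass=lm.SS_STRAND.strand_mass,
            waters_per_strand=lm.SS_STRAND.waters_per_strand,
            thickness_anchors=lm.SS_STRAND.thickness_anchors,
            thickness_cap=lm.SS_STRAND.thickness_cap,
            thickness_saturation=lm.SS_STRAND.thickness_saturation,
            dry_contraction=lm.SS_STRAND.dry_contraction,
            modulus_dry=((1e12, 0.0),),
            modulus_hydrated=((1e12, 0.0),),
        )
        cfg = lm.LayerConfig(kind="ssDNA", grafting_density=0.0, ss=soft)
        grid = np.geomspace(1e12, 1e14, 40)
        shifts = ip.frequency_shift_vs_density(grid, cfg, geometry, 70.0)
        assert np.all(shifts < 0)
        assert np.all(np.diff(shifts) < 0)

    def test_ss_curve_dips_then_recovers_through_zero(self, geometry):
        cfg = lm.LayerConfig(kind="ssDNA", grafting_density=0.0)
        grid = np.geomspace(1e12, 4e13, 60)
        shifts = ip.frequency_shift_vs_density(grid, cfg, geometry, 70.0)
        assert shifts[0] < 0  # mass-dominated at low coverage
        assert np.any(shifts > 0)  # stiffness wins past the critical coverage
        # non-monotonic: a dip precedes the recovery
        assert np.argmin(shifts) > 0

    def test_ds_curve_is_monotonically_negative(self, geometry):
        cfg = lm.LayerConfig(kind="dsDNA", grafting_density=0.0)
        grid = np.geomspace(1e12, 1e14, 40)
        shifts = ip.frequency_shift_vs_density(grid, cfg, geometry, 70.0)
        assert np.all(shifts < 0)
        assert np.all(np.diff(shifts) < 0)


class TestCrossover:
    def test_ss_crossover_near_published_value(self, geometry):
        cfg = lm.LayerConfig(kind="ssDNA", grafting_density=0.0)
        n_star = ip.critical_crossover_density(cfg, geometry, rh=70.0)
        assert 2.5e13 / 1.3 <= n_star <= 2.5e13 * 1.3

    def test_ds_has_no_crossover(self, geometry):
        cfg = lm.LayerConfig(kind="dsDNA", grafting_density=0.0)
        with pytest.raises(NoCrossoverError):
            ip.critical_crossover_density(cfg, geometry, rh=70.0)

    def test_root_agrees_with_dense_scan_oracle(self, geometry):
        # independent bracket location on a fine grid, bisected by hand
        cfg = lm.LayerConfig(kind="ssDNA", grafting_density=0.0)
        grid = np.linspace(1e12, 1e14, 20001)
        shifts = ip.frequency_shift_vs_density(grid, cfg, geometry, 70.0)
        sign_change = np.nonzero(np.sign(shifts[:-1]) * np.sign(shifts[1:]) < 0)[0][0]
        lo, hi = grid[sign_change], grid[sign_change + 1]
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            s = ip.model_relative_shift(cfg.with_density(mid), 70.0, geometry)
            if s * shifts[sign_change] > 0:
                lo = mid
            else:
                hi = mid
        oracle = 0.5 * (lo + hi)
        n_star = ip.critical_crossover_density(cfg, geometry, rh=70.0)
        assert n_star == pytest.approx(oracle, rel=1e-6)

    def test_invariant_to_noise_rescaling(self, geometry):
        # the crossover is a zero of the noiseless model: generating the
        # series with different noise levels cannot move it
        cfg = lm.LayerConfig(kind="ssDNA", grafting_density=0.0)
        n_star = ip.critical_crossover_density(cfg, geometry, rh=70.0)
        for noise_sd in (0.0, 0.05, 0.5):
            gen = sd.GeneratorConfig(seed=3, frequency_noise_sd=noise_sd,
                                     noise=noise_sd > 0)
            series = sd.generate_density_series(gen, geometry)
            # noiseless truth shift rises through zero on the 2e13–3.7e13 leg
            zero = np.interp(
                0.0,
                series.truth["rel_shift_noiseless"][4:8],
                series.table["density_per_cm2"][4:8],
            )
            assert ip.critical_crossover_density(cfg, geometry, rh=70.0) == n_star
            assert zero == pytest.approx(n_star, rel=0.05)


class TestHybridizationFit:
    def test_noise_free_recovery_of_generator_truth(self, geometry):
        cfg = sd.GeneratorConfig(seed=9, noise=False)
        series = sd.generate_hybridization_series(cfg, geometry)
        fit = ip.fit_hybridization(
            series.table["density_per_cm2"], series.table["rel_shift"],
            geometry, 70.0,
        )
        assert fit.efficiency == pytest.approx(0.40, abs=1e-4)
        assert fit.excess_mass == pytest.approx(0.15, abs=1e-4)
        assert fit.fit.converged

    def test_fully_hybridized_clean_reference_recovers_one_zero(self, geometry):
        cfg = sd.GeneratorConfig(seed=9, noise=False, hybridization_truth=(1.0, 0.0))
        series = sd.generate_hybridization_series(cfg, geometry)
        fit = ip.fit_hybridization(
            series.table["density_per_cm2"], series.table["rel_shift"],
            geometry, 70.0,
        )
        # truth sits exactly on the parameter bounds; the solution is
        # flagged as boundary-pinned
        assert fit.efficiency == pytest.approx(1.0, abs=1e-4)
        assert fit.excess_mass == pytest.approx(0.0, abs=1e-4)
        assert fit.boundary_pinned

    def test_estimator_bias_shrinks_with_noise(self, geometry):
        # consistency: mean recovered (h, m) approaches truth as noise → 0
        biases = []
        for noise_scale in (1.0, 0.3, 0.03):
            hs, ms = [], []
            for rep in range(12):
                cfg = sd.GeneratorConfig(
                    seed=100 + rep, frequency_noise_sd=0.05 * noise_scale
                )
                series = sd.generate_hybridization_series(cfg, geometry)
                fit = ip.fit_hybridization(
                    series.table["density_per_cm2"], series.table["rel_shift"],
                    geometry, 70.0,
                )
                hs.append(fit.efficiency)
                ms.append(fit.excess_mass)
            biases.append(abs(np.mean(hs) - 0.40) + abs(np.mean(ms) - 0.15))
        assert biases[2] < biases[0]
        assert biases[2] < 0.01

    def test_too_few_points_rejected(self, geometry):
        with pytest.raises(InvalidInputError):
            ip.fit_hybridization([1e13, 2e13], [0.0, 0.0], geometry, 70.0)
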