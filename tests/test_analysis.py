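"""Hill fitting, total charge curves, pI, calibration and benchmarking."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from stochtit.analysis import (
    PENTAPEPTIDE_PKA,
    AmbiguousCrossingError,
    ExtrapolatedFitError,
    NoCrossingError,
    benchmark,
    calibrate_pkmod,
    hill_curve,
    hill_fit,
    isoelectric_point,
    load_benchmark_table,
    total_titration_curve,
)
from stochtit.fixtures import make_titration_replicates
from stochtit.mc import MCConfig, titration_scan
from stochtit.records import TitrationRecord
from stochtit.sites import Site, SiteSystem


GRID = np.arange(1.0, 13.0)


class TestHillFit:
    def test_noiseless_recovery_to_machine_precision(self):
        fit = hill_fit(GRID, hill_curve(GRID, 6.2, 1.0))
        assert fit.pka == pytest.approx(6.2, abs=1e-6)
        assert fit.hill_n == pytest.approx(1.0, abs=1e-6)
        assert not fit.extrapolated

    @pytest.mark.parametrize("pka,n", [(4.0, 0.8), (7.5, 1.6), (9.9, 1.0)])
    def test_noiseless_recovery_general(self, pka, n):
        fit = hill_fit(GRID, hill_curve(GRID, pka, n))
        assert fit.pka == pytest.approx(pka, abs=1e-6)
        assert fit.hill_n == pytest.approx(n, abs=1e-6)

    def test_identical_replicates_have_zero_jackknife_se(self):
        curve = hill_curve(GRID, 5.0)
        fit = hill_fit(GRID, replicates=np.tile(curve, (3, 1)))
        assert fit.se_pka == 0.0
        assert fit.se_hill == 0.0

    def test_noisy_replicates_recover_truth_within_bias_bound(self):
        errs = []
        for seed in range(100):
            ph, reps = make_titration_replicates(
                4.0, 1.0, n_replicates=3, noise_sd=0.02, seed=seed
            )
            errs.append(hill_fit(ph, replicates=reps).pka - 4.0)
        assert abs(np.mean(errs)) < 0.1

    def test_flat_curves_flagged_with_direction(self):
        lo = hill_fit(GRID, np.zeros_like(GRID))
        hi = hill_fit(GRID, np.ones_like(GRID))
        assert lo.extrapolated and hi.extrapolated
        assert math.isnan(lo.pka) and math.isnan(hi.pka)
        assert lo.direction == "below_range"
        assert hi.direction == "above_range"

    def test_offgrid_transition_flagged_extrapolated(self):
        fit = hill_fit(GRID, hill_curve(GRID, 13.5, 1.0))
        assert fit.extrapolated
        assert fit.direction == "above_range"

    def test_fix_n_mode(self):
        fit = hill_fit(GRID, hill_curve(GRID, 6.2, 1.0), fix_n=True)
        assert fit.hill_n == 1.0
        assert fit.pka == pytest.approx(6.2, abs=1e-8)

    @settings(max_examples=30, deadline=None)
    @given(delta=hst.floats(-3.0, 3.0), pka=hst.floats(4.0, 9.0))
    def test_ph_shift_equivariance(self, delta, pka):
        base = hill_fit(GRID, hill_curve(GRID, pka, 1.2))
        shifted = hill_fit(GRID + delta, hill_curve(GRID, pka, 1.2))
        assert shifted.pka - base.pka == pytest.approx(delta, abs=1e-6)
        assert shifted.hill_n == pytest.approx(base.hill_n, abs=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            hill_fit(np.array([6.0, 7.0]), np.array([0.7, 0.3]))


def _hh(ph, pk):
    return 1.0 / (1.0 + 10.0 ** (ph - pk))


def _record_from_closed_form(sites, ph_grid):
    """TitrationRecord with exact Henderson-Hasselbalch occupancies."""
    rows = []
    for ph in ph_grid:
        for s in sites:
            n = _hh(ph, s.pk_int)
            rows.append((ph, 0, s.id, n, 0.0, n + s.charge_offset))
    return TitrationRecord.from_rows(rows)


class TestTotalChargeAndPI:
    def test_matched_acid_base_pair_is_neutral_at_midpoint(self):
        sites = [Site(id="a", residue_type="Asp", pk_int=7.0),
                 Site(id="b", residue_type="Lys", pk_int=7.0)]
        curve = total_titration_curve(_record_from_closed_form(sites, GRID))
        assert curve.loc[7.0] == pytest.approx(0.0, abs=1e-12)

    def test_fully_protonated_charge_counts_bases(self):
        sites = [Site(id="a", residue_type="Asp", pk_int=20.0),
                 Site(id="b", residue_type="Lys", pk_int=20.0),
                 Site(id="c", residue_type="His", pk_int=20.0)]
        curve = total_titration_curve(_record_from_closed_form(sites, [1.0]))
        assert curve.loc[1.0] == pytest.approx(2.0, abs=1e-10)

    def test_uncoupled_system_matches_sum_of_closed_forms(self):
        rng = np.random.default_rng(0)
        sites = [
            Site(id=f"s{k}",
                 residue_type=("Asp" if k % 2 else "Lys"),
                 pk_int=float(rng.uniform(3, 10)))
            for k in range(6)
        ]
        system = SiteSystem(sites, np.zeros((6, 6)))
        record, _ = titration_scan(system, GRID, MCConfig(n_cycles=30_000, seed=2))
        curve = total_titration_curve(record)
        for ph in GRID:
            expected = sum(_hh(ph, s.pk_int) + s.charge_offset for s in sites)
            assert curve.loc[ph] == pytest.approx(expected, abs=0.05)

    def test_pi_linear_interpolation(self):
        assert isoelectric_point([4.0, 6.0], [2.0, -2.0]) == pytest.approx(5.0)

    def test_pi_errors(self):
        with pytest.raises(NoCrossingError, match="below"):
            isoelectric_point([4.0, 6.0], [-1.0, -2.0])
        with pytest.raises(AmbiguousCrossingError):
            isoelectric_point([4.0, 5.0, 6.0, 7.0], [1.0, -1.0, 1.0, -1.0])

    def test_pi_against_bisection_oracle(self):
        from scipy.optimize import brentq

        sites = [Site(id="a", residue_type="Glu", pk_int=4.2),
                 Site(id="b", residue_type="Lys", pk_int=10.1),
                 Site(id="c", residue_type="His", pk_int=6.3)]

        def charge(ph):
            return sum(_hh(ph, s.pk_int) + s.charge_offset for s in sites)

        grid = np.arange(1.0, 12.01, 0.25)
        curve = total_titration_curve(_record_from_closed_form(sites, grid))
        pi = isoelectric_point(grid, curve.to_numpy())
        oracle = brentq(charge, 1.0, 12.0)
        assert pi == pytest.approx(oracle, abs=0.01)  # linear vs exact root


class TestCalibration:
    def test_additive_shift_and_fixed_point(self):
        assert calibrate_pkmod(3.8, 4.0, 4.0) == pytest.approx(4.2)
        assert calibrate_pkmod(4.0, 4.0, 4.0) == 4.0

    def test_refuses_extrapolated_fit(self):
        with pytest.raises(ExtrapolatedFitError):
            calibrate_pkmod(math.nan, 4.0, 4.0)

    def test_closed_loop_converges_on_isolated_site(self):
        # two calibration iterations against simulated titrations of a
        # single model compound drive the fitted pKa to the target value
        target = 4.25
        pkmod = 3.0  # poor initial guess
        grid = np.arange(1.0, 13.0)
        fitted = None
        for it in range(2):
            system = SiteSystem(
                [Site(id="m", residue_type="Glu", pk_int=pkmod)], np.zeros((1, 1))
            )
            record, _ = titration_scan(
                system, grid, MCConfig(n_cycles=30_000, seed=100 + it),
                n_replicates=3,
            )
            ph, _, reps = record.site_curve("m")
            fitted = hill_fit(ph, replicates=reps)
            pkmod = calibrate_pkmod(fitted.pka, target, pkmod)
        assert abs(fitted.pka - target) < max(5 * fitted.se_pka, 0.05) + abs(
            pkmod - target
        )
        # after convergence the model pKa tracks the experimental target
        assert abs(pkmod - target) < 0.05


class TestBenchmark:
    def _table(self, rows):
        return pd.DataFrame(
            rows, columns=["residue", "residue_type", "pka_pred", "pka_exp"]
        ).assign(pka_null=lambda d: d["residue_type"].map(PENTAPEPTIDE_PKA))

    def test_perfect_predictions_have_zero_rmse(self):
        t = self._table([("E1", "Glu", 4.4, 4.4), ("K2", "Lys", 10.0, 10.0)])
        res = benchmark(t)
        assert res.rmse == 0.0

    def test_symmetric_errors(self):
        t = self._table([("E1", "Glu", 5.0, 4.0), ("E2", "Glu", 3.0, 4.0)])
        res = benchmark(t)
        assert res.rmse == pytest.approx(1.0)
        assert res.mean_error_by_type["Glu"] == pytest.approx(0.0)

    def test_missing_experimental_rows_skipped(self):
        t = self._table([("E1", "Glu", 5.0, 4.0), ("E2", "Glu", 3.0, math.nan)])
        res = benchmark(t)
        assert res.n_used == 1 and res.n_skipped == 1

    def test_tyrosine_exclusion_flag(self):
        t = self._table([("Y1", "Tyr", 12.0, 10.0), ("E1", "Glu", 4.0, 4.0)])
        assert benchmark(t, exclude_tyr=True).n_used == 1
        assert benchmark(t, exclude_tyr=False).n_used == 2

    @settings(max_examples=25, deadline=None)
    @given(errs=hst.lists(hst.floats(-3, 3), min_size=2, max_size=10))
    def test_rmse_dominates_mean_error(self, errs):
        rows = [(f"E{i}", "Glu", 4.0 + e, 4.0) for i, e in enumerate(errs)]
        res = benchmark(self._table(rows))
        assert res.rmse >= abs(res.mean_error_by_type["Glu"]) - 1e-12

    def test_bundled_tables_load_with_null_column(self):
        for protein, n in [("hewl", 18), ("snase", 17)]:
            df = load_benchmark_table(protein)
            assert len(df) == n
            assert df["pka_null"].notna().all()
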