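"""ddCt, TBARS, FAME quantification and replicate statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from screenstat.assay_quant import (
    AssayError,
    CtTable,
    ddct_fold_change,
    fame_profile,
    fit_calibration,
    replicate_test,
    tbars_mda,
)
from screenstat.screen_sim import gen_ct_table, gen_gc_peaks, gen_tbars


class TestDdct:
    def test_zero_ddct_is_unit_fold(self):
        table = CtTable(gen_ct_table({"GPH1": 1.0}, seed=0))
        r = ddct_fold_change(table, "GPH1", "treatment")
        assert r.fold == pytest.approx(1.0, abs=1e-12)
        assert r.direction == "up"
        assert r.reported_fold == pytest.approx(1.0, abs=1e-12)

    def test_round_trip_strong_upregulation(self):
        table = CtTable(gen_ct_table({"ANB1": 21.37}, seed=0))
        r = ddct_fold_change(table, "ANB1", "treatment")
        assert r.reported_fold == pytest.approx(21.37, rel=1e-12)
        assert r.direction == "up"

    def test_round_trip_downregulation_reciprocal_convention(self):
        table = CtTable(gen_ct_table({"OLE1": 1 / 7.39}, seed=0))
        r = ddct_fold_change(table, "OLE1", "treatment")
        assert r.direction == "down"
        assert r.reported_fold == pytest.approx(7.39, rel=1e-12)

    @given(fold=st.floats(min_value=1e-3, max_value=1e3))
    @settings(deadline=None, max_examples=60)
    def test_zero_noise_recovery_is_exact_for_any_fold(self, fold):
        table = CtTable(gen_ct_table({"G": fold}, seed=0))
        r = ddct_fold_change(table, "G", "treatment")
        assert r.fold == pytest.approx(fold, rel=1e-9)
        assert r.reported_fold >= 1.0 - 1e-12
        assert r.reported_fold == pytest.approx(max(fold, 1 / fold), rel=1e-9)

    def test_noisy_recovery_within_propagated_error(self):
        table = CtTable(gen_ct_table({"G": 2.0}, replicate_sd=0.1, n_replicates=3, seed=4))
        r = ddct_fold_change(table, "G", "treatment")
        # 4-sigma band on ddCt translated to fold space
        lo, hi = 2 ** (-(r.ddct + 4 * r.ddct_sd)), 2 ** (-(r.ddct - 4 * r.ddct_sd))
        assert lo <= 2.0 <= hi or abs(r.fold - 2.0) < 0.5

    def test_missing_reference_named_in_error(self):
        df = pd.DataFrame(
            {"sample": ["a"], "gene": ["G"], "replicate": [1], "ct": [20.0]}
        )
        with pytest.raises(AssayError, match="TAF10"):
            CtTable(df)

    def test_missing_control_records_named(self):
        table = CtTable(gen_ct_table({"G": 2.0}, seed=0))
        with pytest.raises(AssayError, match="ZZZ"):
            ddct_fold_change(table, "ZZZ", "treatment")


class TestCalibrationAndTbars:
    def test_exact_line_recovered(self):
        std = pd.DataFrame({"concentration": [0, 10, 20, 30], "od535": [0.1, 0.3, 0.5, 0.7]})
        cal = fit_calibration(std)
        assert cal.slope == pytest.approx(0.02, rel=1e-12)
        assert cal.intercept == pytest.approx(0.1, rel=1e-9)
        assert cal.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_standard_order_irrelevant(self):
        std = pd.DataFrame({"concentration": [0, 10, 20, 30], "od535": [0.11, 0.28, 0.52, 0.69]})
        cal1 = fit_calibration(std)
        cal2 = fit_calibration(std.iloc[::-1].reset_index(drop=True))
        assert cal1.slope == pytest.approx(cal2.slope, rel=1e-12)

    def test_noisy_slope_within_analytic_se(self):
        # OLS slope sampling distribution: SE = sigma / sqrt(Sxx)
        rng = np.random.default_rng(0)
        x = np.linspace(0, 50, 8)
        sigma, true_slope = 0.01, 0.02
        sxx = ((x - x.mean()) ** 2).sum()
        se = sigma / math.sqrt(sxx)
        slopes = []
        for _ in range(100):
            y = true_slope * x + rng.normal(0, sigma, size=x.size)
            slopes.append(fit_calibration(pd.DataFrame({"concentration": x, "od535": y})).slope)
        assert abs(np.mean(slopes) - true_slope) < 4 * se / math.sqrt(100)
        assert np.std(slopes) == pytest.approx(se, rel=0.35)

    def test_degenerate_standards_rejected(self):
        std = pd.DataFrame({"concentration": [5, 5, 5], "od535": [0.1, 0.2, 0.3]})
        with pytest.raises(AssayError, match="degenerate"):
            fit_calibration(std)

    def test_linear_arithmetic_example(self):
        std = pd.DataFrame({"concentration": [0, 25, 50], "od535": [0.0, 0.5, 1.0]})
        cal = fit_calibration(std)  # slope 0.02 OD/uM, intercept 0
        res = tbars_mda(cal, od535=0.5, cells=1e7, assay_volume=1.0)
        assert res.per_1e7_cells == pytest.approx(25.0, rel=1e-9)  # nmol / 1e7 cells

    def test_blank_reading_gives_zero(self):
        std = pd.DataFrame({"concentration": [0, 25, 50], "od535": [0.05, 0.55, 1.05]})
        cal = fit_calibration(std)
        assert tbars_mda(cal, 0.05, 1e7, 1.0).per_1e7_cells == pytest.approx(0.0, abs=1e-9)

    def test_negative_concentration_floored_and_flagged(self):
        std = pd.DataFrame({"concentration": [0, 25, 50], "od535": [0.05, 0.55, 1.05]})
        cal = fit_calibration(std)
        res = tbars_mda(cal, 0.01, 1e7, 1.0)
        assert res.per_1e7_cells == 0.0
        assert res.clipped

    def test_pipeline_linear_in_od(self):
        std = pd.DataFrame({"concentration": [0, 25, 50], "od535": [0.1, 0.6, 1.1]})
        cal = fit_calibration(std)
        one = tbars_mda(cal, 0.1 + 0.2, 1e7, 1.0).per_1e7_cells
        two = tbars_mda(cal, 0.1 + 0.4, 1e7, 1.0).per_1e7_cells
        assert two == pytest.approx(2 * one, rel=1e-9)

    def test_round_trip_with_generator(self):
        truth = {"30C": 10.0, "42C": 25.0}
        samples, standards = gen_tbars(truth, slope=0.02, intercept=0.05, seed=0)
        cal = fit_calibration(standards)
        for r in samples.itertuples(index=False):
            res = tbars_mda(cal, r.od535, cells=1e7, assay_volume=1.0)
            assert res.per_1e7_cells == pytest.approx(truth[r.sample], rel=1e-9)

    def test_zero_cells_rejected(self):
        std = pd.DataFrame({"concentration": [0, 25, 50], "od535": [0.0, 0.5, 1.0]})
        with pytest.raises(AssayError):
            tbars_mda(fit_calibration(std), 0.5, cells=0, assay_volume=1.0)


class TestFameProfile:
    PEAKS = pd.DataFrame(
        {"species": ["IS", "16:0", "16:1", "18:0", "18:1"], "area": [100, 20, 30, 10, 40]}
    )

    def test_fractions_and_ufa_arithmetic(self):
        prof = fame_profile(self.PEAKS, is_conc=10.0)
        assert prof.fractions == pytest.approx(
            {"16:0": 0.2, "16:1": 0.3, "18:0": 0.1, "18:1": 0.4}
        )
        assert prof.ufa_fraction == pytest.approx(0.7)
        assert prof.mono_ufa_fraction == pytest.approx(0.7)  # all UFAs are mono here

    def test_scale_invariance_of_fractions(self):
        doubled = self.PEAKS.assign(area=self.PEAKS["area"] * 2)
        a = fame_profile(self.PEAKS, is_conc=10.0)
        b = fame_profile(doubled, is_conc=10.0)
        assert a.fractions == pytest.approx(b.fractions)

    def test_round_trip_with_generator(self):
        comp = {"16:0": 0.25, "16:1": 0.15, "18:0": 0.2, "18:1": 0.4}
        peaks = gen_gc_peaks(comp, total_conc=40.0, is_conc=10.0)
        prof = fame_profile(peaks, is_conc=10.0)
        assert prof.fractions == pytest.approx(comp, rel=1e-9)
        assert prof.ufa_fraction == pytest.approx(0.55, rel=1e-9)

    def test_randomized_compositions_round_trip(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            raw = rng.dirichlet(np.ones(4))
            comp = dict(zip(["16:0", "16:1", "18:0", "18:1"], raw))
            total = sum(comp.values())
            comp = {k: v / total for k, v in comp.items()}
            prof = fame_profile(gen_gc_peaks(comp, seed=0), is_conc=10.0)
            assert prof.fractions == pytest.approx(comp, rel=1e-6)

    def test_missing_internal_standard(self):
        with pytest.raises(AssayError, match="internal standard"):
            fame_profile(self.PEAKS[self.PEAKS["species"] != "IS"], is_conc=10.0)

    def test_unknown_species_needs_annotation(self):
        peaks = pd.concat(
            [self.PEAKS, pd.DataFrame({"species": ["20:4"], "area": [5.0]})]
        )
        with pytest.raises(AssayError, match="20:4"):
            fame_profile(peaks, is_conc=10.0)


def t_density(x: float, df: int) -> float:
    """Student's t density from first principles (gamma functions)."""
    c = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))
    return c * (1 + x * x / df) ** (-(df + 1) / 2)


class TestReplicateTest:
    def test_identical_groups_not_significant(self):
        r = replicate_test([1.0, 1.1, 0.9], [1.0, 1.1, 0.9])
        assert r.t_statistic == pytest.approx(0.0, abs=1e-12)
        assert not r.significant

    def test_textbook_instance_against_quadrature_oracle(self):
        a = [6.1, 5.8, 6.4, 6.0]
        b = [5.2, 5.5, 5.0, 5.4]
        r = replicate_test(a, b)
        # pooled t statistic from first principles
        na, nb = len(a), len(b)
        va = np.var(a, ddof=1)
        vb = np.var(b, ddof=1)
        sp = math.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
        t_expect = (np.mean(a) - np.mean(b)) / (sp * math.sqrt(1 / na + 1 / nb))
        assert r.t_statistic == pytest.approx(t_expect, rel=1e-10)
        tail, _ = quad(t_density, abs(t_expect), np.inf, args=(na + nb - 2,))
        assert r.p_value == pytest.approx(2 * tail, rel=1e-6)
        assert r.significant

    def test_type_one_error_near_alpha_under_null(self):
        rng = np.random.default_rng(8)
        reps, n = 10_000, 3
        a = rng.normal(0, 1, size=(reps, n))
        b = rng.normal(0, 1, size=(reps, n))
        rejections = sum(
            replicate_test(a[i], b[i]).significant for i in range(0, reps, 5)
        )
        rate = rejections / (reps / 5)
        se = math.sqrt(0.05 * 0.95 / (reps / 5))
        assert abs(rate - 0.05) < 4 * se

    def test_zero_variance_equal_means_defined_as_one(self):
        r = replicate_test([2.0, 2.0], [2.0, 2.0])
        assert r.p_value == 1.0
        assert not r.significant

    def test_welch_flag_changes_unequal_variance_case(self):
        a = [10.0, 10.1, 9.9, 10.2]
        b = [7.0, 10.0, 6.0, 9.5]
        student = replicate_test(a, b, welch=False)
        welch = replicate_test(a, b, welch=True)
        assert student.p_value != pytest.approx(welch.p_value, rel=1e-3)

    def test_single_replicate_rejected(self):
        with pytest.raises(AssayError):
            replicate_test([1.0], [1.0, 2.0])
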