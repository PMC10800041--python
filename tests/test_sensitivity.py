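import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cortmr import (SimulationConfig, simulate_pair, build_instruments,
                    SelectionConfig)
from cortmr.errors import PressoNotApplicableError
from cortmr.estimators import ivw, MRResult
from cortmr.sensitivity import (cochran_q, mr_presso, steiger, leave_one_out,
                                confounder_screen, apply_verdict,
                                SensitivityReport, run_sensitivity)
from conftest import make_harmonized


@pytest.fixture(scope="module")
def harmonized_sim():
    cfg = SimulationConfig(theta=0.1, seed=13, n_null_snps=0,
                           palindrome_frac=0.0)
    expo, outc, ld, truth = simulate_pair(cfg)
    table = build_instruments(expo, outc, ld, SelectionConfig()).table
    return cfg, table


class TestCochranQ:
    def test_identical_ratios_q_zero_p_one(self):
        res = cochran_q(make_harmonized([2.0, 2.0, 2.0]))
        assert res.q == pytest.approx(0.0, abs=1e-20)
        assert res.pval == pytest.approx(1.0)

    def test_two_ratios_chi_square_tail(self):
        res = cochran_q(make_harmonized([1.0, 3.0]))
        assert res.q == pytest.approx(2.0)
        assert res.df == 1
        assert res.pval == pytest.approx(stats.chi2.sf(2.0, 1), abs=1e-10)
        assert res.pval == pytest.approx(0.1573, abs=1e-4)

    def test_duplicating_instruments_doubles_q(self):
        t = make_harmonized([1.0, 2.5, 3.0])
        t2 = pd.concat([t, t.assign(variant_id=t["variant_id"] + "b")],
                       ignore_index=True)
        assert cochran_q(t2).q == pytest.approx(2 * cochran_q(t).q, abs=1e-10)


class TestPresso:
    def test_too_few_instruments_typed_signal(self):
        with pytest.raises(PressoNotApplicableError):
            mr_presso(make_harmonized([1.0, 2.0, 3.0]), n_sim=100, seed=0)

    def test_determinism_under_seed(self, harmonized_sim):
        _, table = harmonized_sim
        a = mr_presso(table, n_sim=100, seed=3)
        b = mr_presso(table, n_sim=100, seed=3)
        assert a.global_pval == b.global_pval
        pd.testing.assert_series_equal(a.outlier_pvals, b.outlier_pvals)

    def test_order_invariance(self, harmonized_sim):
        _, table = harmonized_sim
        a = mr_presso(table, n_sim=100, seed=3)
        shuffled = table.sample(frac=1, random_state=1).reset_index(drop=True)
        b = mr_presso(shuffled, n_sim=100, seed=3)
        assert a.global_pval == pytest.approx(b.global_pval)
        pd.testing.assert_series_equal(a.outlier_pvals.sort_index(),
                                       b.outlier_pvals.sort_index())

    def test_clean_data_rarely_flags(self):
        hits = 0
        for s in range(20):
            cfg = SimulationConfig(theta=0.1, seed=300 + s, n_null_snps=0,
                                   palindrome_frac=0.0, n_instruments=30)
            expo, outc, ld, _ = simulate_pair(cfg)
            t = build_instruments(expo, outc, ld, SelectionConfig()).table
            res = mr_presso(t, n_sim=200, seed=s)
            hits += res.global_pval <= 0.05
        assert hits <= 2  # global test holds its size on clean data

    def test_planted_outlier_detected_and_corrected(self, harmonized_sim):
        cfg, table = harmonized_sim
        t = table.copy().reset_index(drop=True)
        t.loc[0, "beta_out"] = 50 * 0.1 * t.loc[0, "beta_exp"]
        res = mr_presso(t, n_sim=1000, seed=5)
        vid = t.loc[0, "variant_id"]
        assert res.outlier_pvals.idxmin() == vid
        assert res.outlier_pvals[vid] < 0.05
        assert vid in res.outliers
        assert res.outliers_identified
        uncorrected = ivw(t)
        assert abs(res.corrected.beta - 0.1) < abs(uncorrected.beta - 0.1)
        assert res.global_pval < 0.05


class TestSteiger:
    def test_strong_exposure_direction_true(self):
        t = make_harmonized(beta_exp=[0.1, 0.12], beta_out=[0.01, 0.01],
                            se_exp=[0.01, 0.01])
        res = steiger(t, 40_000, 50_000)
        assert res.correct_direction

    def test_symmetric_inputs_p_one(self):
        t = make_harmonized(beta_exp=[0.1, 0.12], beta_out=[0.1, 0.12])
        res = steiger(t, 40_000, 40_000)
        assert not res.correct_direction
        assert res.pval == pytest.approx(1.0)

    def test_r2_sums_formula(self):
        t = make_harmonized(beta_exp=[0.1], beta_out=[0.02], eaf=[0.25])
        res = steiger(t, 40_000, 50_000)
        assert res.r2_exposure == pytest.approx(2 * 0.01 * 0.25 * 0.75)
        assert res.r2_outcome == pytest.approx(2 * 0.0004 * 0.25 * 0.75)


class TestLeaveOneOut:
    def test_identical_ratios_flag_false(self):
        t = make_harmonized([2.0] * 5, se_out=[0.1] * 5)
        res = leave_one_out(t)
        assert not res.driven_by_single_snp
        assert np.allclose(res.results["beta"], 2.0)

    def test_cardinality(self, harmonized_sim):
        _, table = harmonized_sim
        res = leave_one_out(table)
        assert len(res.results) == len(table)

    def test_each_row_matches_independent_subset_ivw(self, harmonized_sim):
        _, table = harmonized_sim
        res = leave_one_out(table)
        for i in range(len(table)):
            sub = table.drop(table.index[i])
            expect = ivw(sub)
            assert res.results["beta"].iloc[i] == pytest.approx(
                expect.beta, abs=1e-12)

    def test_q_decomposition_nonnegative(self, harmonized_sim):
        _, table = harmonized_sim
        q_full = cochran_q(table).q
        for i in range(len(table)):
            q_sub = cochran_q(table.drop(table.index[i])).q
            assert q_full - q_sub >= -1e-9


class TestConfounderScreen:
    def test_listed_trait_removes_variant(self):
        t = make_harmonized([1.0, 2.0], ids=["rs1", "rs2"])
        ann = {"rs1": ["body mass index"]}
        filtered, removed = confounder_screen(
            t, ann, ["body mass index", "smoking"])
        assert list(filtered["variant_id"]) == ["rs2"]
        assert removed == {"rs1": ["body mass index"]}

    def test_unlisted_trait_retained(self):
        t = make_harmonized([1.0], ids=["rs2"])
        filtered, removed = confounder_screen(
            t, {"rs2": ["height"]}, ["body mass index"])
        assert len(filtered) == 1 and not removed

    def test_empty_confounder_list_noop(self):
        t = make_harmonized([1.0, 2.0])
        filtered, removed = confounder_screen(t, {"rs1": ["smoking"]}, [])
        assert len(filtered) == 2 and not removed

    def test_case_insensitive_substring(self):
        t = make_harmonized([1.0], ids=["rs9"])
        _, removed = confounder_screen(
            t, {"rs9": ["Body Mass Index (adult)"]}, ["body mass index"])
        assert "rs9" in removed


class TestVerdict:
    def _mr(self, p):
        return MRResult("ivw_re", 10, 0.1, 0.02, p)

    def test_pleiotropy_fails(self):
        rep = SensitivityReport(egger_intercept_pval=0.04)
        assert apply_verdict(self._mr(0.01), rep)[0] == "fail_pleiotropy"

    def test_heterogeneity_alone_survives(self):
        from cortmr.sensitivity import CochranQ, SteigerResult
        rep = SensitivityReport(
            cochran=CochranQ(68.52, 44, 0.01),
            egger_intercept_pval=0.5,
            steiger=SteigerResult(0.02, 0.001, True, 1e-10))
        assert apply_verdict(self._mr(0.01), rep)[0] == "survive"

    def test_confounder_reversal_fails(self):
        rep = SensitivityReport(
            egger_intercept_pval=0.5,
            post_screen_ivw=MRResult("ivw_re", 8, 0.05, 0.05, 0.21))
        assert apply_verdict(self._mr(0.03), rep)[0] == "fail_confounder"

    def test_wrong_direction_fails(self):
        from cortmr.sensitivity import SteigerResult
        rep = SensitivityReport(
            egger_intercept_pval=0.5,
            steiger=SteigerResult(0.001, 0.02, False, 1e-4))
        assert apply_verdict(self._mr(0.01), rep)[0] == "fail_other"


class TestRunSensitivity:
    def test_clean_effect_usually_survives(self):
        survived = 0
        for s in range(20):
            cfg = SimulationConfig(theta=0.1, seed=600 + s, n_null_snps=0,
                                   palindrome_frac=0.0, n_instruments=30)
            expo, outc, ld, _ = simulate_pair(cfg)
            t = build_instruments(expo, outc, ld, SelectionConfig()).table
            rep = run_sensitivity(t, cfg.n_exposure, cfg.n_outcome,
                                  mr_result=ivw(t), n_sim=150, seed=s)
            survived += rep.verdict == "survive"
        assert survived >= 18

    def test_steiger_direction_true_with_strong_instruments(self):
        for s in range(10):
            cfg = SimulationConfig(theta=0.1, seed=700 + s, n_null_snps=0,
                                   palindrome_frac=0.0)
            expo, outc, ld, _ = simulate_pair(cfg)
            t = build_instruments(expo, outc, ld, SelectionConfig()).table
            assert steiger(t, cfg.n_exposure, cfg.n_outcome).correct_direction
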