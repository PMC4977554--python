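import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nucmorph.errors import NucmorphError
from nucmorph.phantoms import make_qpcr_table
from nucmorph.stats_report import (
    analyze_qpcr,
    bonferroni_adjust,
    compare_groups,
    export_boxplots,
    export_histograms,
    normality,
    pfaffl_ratio,
    summarize,
)
from nucmorph.volume import FeatureTable


def _table(values_by_condition, feature="nuclear_volume"):
    rows = []
    for cond, vals in values_by_condition.items():
        for i, v in enumerate(vals):
            rows.append({"cell_id": f"{cond}_{i}", "condition": cond,
                         "feature": feature, "value": float(v), "unit": "um3"})
    return FeatureTable(pd.DataFrame(rows))


class TestSummarize:
    def test_mean_and_sem(self):
        t = _table({"DMSO": [1, 2, 3]})
        mean, sem, n = summarize(t, "nuclear_volume", "DMSO")
        assert mean == pytest.approx(2.0)
        assert sem == pytest.approx(0.5774, abs=1e-4)
        assert n == 3

    def test_constant_values_have_zero_sem(self):
        _, sem, _ = summarize(_table({"DMSO": [5, 5, 5, 5]}), "nuclear_volume", "DMSO")
        assert sem == 0.0

    def test_single_value_is_an_error(self):
        with pytest.raises(NucmorphError):
            summarize(_table({"DMSO": [1]}), "nuclear_volume", "DMSO")


class TestCompareGroups:
    def test_complete_separation_gives_zero_u_for_first_group(self):
        res = compare_groups([1, 2, 3], [10, 20, 30], test="mann-whitney")
        assert res.statistic == 0.0

    def test_identical_samples_give_p_one(self):
        res = compare_groups([1.0, 2.0, 3.0], [3.0, 1.0, 2.0], test="mann-whitney")
        assert res.p_value >= 0.99
        res_ks = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], test="ks")
        assert res_ks.p_value >= 0.99

    @pytest.mark.parametrize("test", ["mann-whitney", "ks"])
    def test_type_one_error_calibrated_at_n200(self, test):
        rng = np.random.default_rng(2024)
        n_rep, rejections = 1000, 0
        for _ in range(n_rep):
            a = rng.normal(size=200)
            b = rng.normal(size=200)
            if compare_groups(a, b, test=test).p_value < 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_rep <= 0.07

    @pytest.mark.parametrize("test", ["mann-whitney", "ks"])
    def test_invariance_under_monotone_transform(self, test):
        rng = np.random.default_rng(5)
        a = rng.normal(2.0, 1.0, size=40)
        b = rng.normal(2.5, 1.0, size=40)
        base = compare_groups(a, b, test=test)
        trans = compare_groups(np.exp(a), np.exp(b), test=test)
        assert trans.p_value == pytest.approx(base.p_value, rel=1e-9)

    def test_bonferroni_adjustment(self):
        family = [compare_groups([1, 2, 3, 4], [2, 3, 4, 5], test="mann-whitney")
                  for _ in range(4)]
        bonferroni_adjust(family)
        for r in family:
            assert r.adjusted_p == pytest.approx(min(1.0, 4 * r.p_value))

    def test_tiny_groups_rejected(self):
        with pytest.raises(NucmorphError):
            compare_groups([1, 2], [3, 4, 5])


class TestNormality:
    def test_matches_r_nortest_reference_values(self):
        # reference values computed with R nortest::ad.test (case-3 AD with
        # the small-sample correction and piecewise-exponential p)
        x = [0.1, 0.5, 0.2, 0.8, 1.5, -0.3, 0.9, 1.1, -1.2, 0.4, 2.2, 0.05,
             -0.7, 1.9, 0.33, 0.21]
        a2, p = normality(x)
        assert a2 == pytest.approx(0.2244141971, abs=1e-9)
        assert p == pytest.approx(0.7863376331, abs=1e-9)
        a2u, pu = normality(np.linspace(-2, 2, 50))
        assert a2u == pytest.approx(0.5345002393, abs=1e-9)
        assert pu == pytest.approx(0.1632158621, abs=1e-9)

    def test_null_acceptance_rate_at_least_90pct(self):
        accepted = 0
        for i in range(100):
            x = np.random.default_rng(500 + i).normal(size=100)
            accepted += normality(x)[1] > 0.05
        assert accepted >= 90

    def test_bimodal_alternative_rejected(self):
        rng = np.random.default_rng(9)
        x = np.concatenate([rng.normal(-3, 0.5, 50), rng.normal(3, 0.5, 50)])
        a2, p = normality(x)
        assert p < 0.01

    def test_bimodal_statistic_exceeds_normal_statistic(self):
        # non-Gaussian data should score a larger A than matched normal draws
        for i in range(5):
            rng = np.random.default_rng(40 + i)
            a_norm = normality(rng.normal(size=100))[0]
            bim = np.concatenate([rng.normal(-3, 0.5, 50), rng.normal(3, 0.5, 50)])
            assert normality(bim)[0] > a_norm

    def test_small_or_constant_samples_rejected(self):
        with pytest.raises(NucmorphError):
            normality([1.0] * 20)
        with pytest.raises(NucmorphError):
            normality([1, 2, 3])


class TestPfaffl:
    def test_zero_delta_cts_give_unity(self):
        assert pfaffl_ratio(2.0, 2.0, 0.0, 0.0) == pytest.approx(1.0)

    def test_one_doubling(self):
        assert pfaffl_ratio(2.0, 2.0, 1.0, 0.0) == pytest.approx(2.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(e=st.floats(1.05, 2.0), d=st.floats(-5.0, 5.0))
    def test_equal_efficiency_and_delta_is_identity(self, e, d):
        assert pfaffl_ratio(e, e, d, d) == pytest.approx(1.0, rel=1e-12)

    def test_bad_efficiency_rejected(self):
        with pytest.raises(NucmorphError):
            pfaffl_ratio(1.0, 2.0, 1.0, 0.0)

    def test_recovers_planted_12_fold_change(self):
        table = make_qpcr_table({"MGMT": 2.0, "ACTB": 2.0}, {"MGMT": 12.0},
                                noise_sd=0.05, seed=6)
        res = analyze_qpcr(table, {"MGMT": 2.0, "ACTB": 2.0})
        assert len(res) == 1
        assert res[0].ratio == pytest.approx(12.0, rel=0.10)


class TestExports:
    def test_histogram_counts_conserve_n(self, tmp_path):
        rng = np.random.default_rng(1)
        t = _table({"DMSO": rng.normal(600, 50, 200), "vstat": rng.normal(550, 50, 200)})
        binned = export_histograms(t, tmp_path, bins=20)
        for cond in ("DMSO", "vstat"):
            assert binned[binned.condition == cond]["count"].sum() == 200
        assert (tmp_path / "hist_nuclear_volume.png").exists()

    def test_binned_csv_round_trip(self, tmp_path):
        t = _table({"DMSO": np.arange(50.0)})
        binned = export_histograms(t, tmp_path, bins=10)
        back = pd.read_csv(tmp_path / "histograms.csv")
        assert back["count"].tolist() == binned["count"].tolist()

    def test_boxplot_stats(self, tmp_path):
        vals = np.arange(1.0, 101.0)
        stats = export_boxplots(_table({"DMSO": vals}), tmp_path)
        row = stats.iloc[0]
        assert row["median"] == pytest.approx(np.median(vals))
        assert row["q1"] == pytest.approx(np.percentile(vals, 25))
        assert (tmp_path / "box_nuclear_volume.png").exists()
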