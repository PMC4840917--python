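"""Association scans, effect transforms, and the descriptive cohort table."""

import numpy as np
import pandas as pd
import pytest

from vkproteome import (AnalysisConfig, AssociationScan, CohortDataset,
                        GroupDifferenceScan, generate_cohort, percent_change)
from vkproteome.association import build_cohort_table, percent_change_interval
from vkproteome.preprocess import dichotomize_vk, log2_median_normalize

from conftest import make_observations, make_subjects, small_sim_config


class TestPercentChange:
    @pytest.mark.parametrize("beta,expected", [
        (0.0, 0.0),      # no slope, no change
        (1.0, 100.0),    # doubling of protein doubles PIVKA-II
        (-1.0, -50.0),
        (np.log2(2.375), 137.5),
    ])
    def test_exact_transform(self, beta, expected):
        assert percent_change(beta) == pytest.approx(expected, abs=1e-9)

    def test_interval_is_monotone_transform(self):
        pc, lo, hi = percent_change_interval(0.5, 0.2)
        assert lo < pc < hi
        assert pc == pytest.approx(percent_change(0.5))
        z = 1.959963984540054
        assert lo == pytest.approx(percent_change(0.5 - z * 0.2))

    def test_bounded_below_by_minus_100(self):
        assert percent_change(-30.0) > -100.0


@pytest.fixture(scope="module")
def small_scan():
    """Small simulated cohort with one driver among nulls, scanned end to end."""
    cfg = small_sim_config(seed=21, driver_slopes=(1.0,))
    dataset, truth = generate_cohort(cfg)
    normalized, _ = log2_median_normalize(dataset)
    analysis = AnalysisConfig(min_children=cfg.min_children)
    assoc = AssociationScan(normalized, analysis).fit()
    return cfg, truth, normalized, analysis, assoc


class TestAssociationScan:
    def test_driver_recovered_with_smallest_p(self, small_scan):
        cfg, truth, _, _, assoc = small_scan
        top_gi = truth.drivers.sort_values(
            "true_slope", key=np.abs, ascending=False).gi_accession.iloc[0]
        assert assoc.results[0].gi_accession == top_gi
        r = assoc.results[0]
        true_beta = float(truth.drivers.set_index("gi_accession")
                          .loc[top_gi, "true_slope"])
        assert abs(r.beta - true_beta) < 3 * r.se_beta

    def test_direction_consistency(self, small_scan):
        _, truth, _, _, assoc = small_scan
        slopes = truth.drivers.set_index("gi_accession")["true_slope"]
        for r in assoc.results:
            if r.gi_accession in slopes.index and r.q_value < 0.05:
                assert np.sign(r.percent_change) == \
                    np.sign(slopes[r.gi_accession])

    def test_coverage_rule_respected(self, small_scan):
        _, _, _, analysis, assoc = small_scan
        assert all(r.n_obs > analysis.min_children for r in assoc.results)

    def test_results_sorted_by_p_with_qvalues(self, small_scan):
        _, _, _, _, assoc = small_scan
        p = [r.p_value for r in assoc.results]
        assert p == sorted(p)
        assert all(0 <= r.q_value <= 1 for r in assoc.results)

    def test_requires_normalized_dataset(self, small_scan):
        cfg, _, _, _, _ = small_scan
        dataset, _ = generate_cohort(cfg)
        with pytest.raises(ValueError, match="normalized"):
            AssociationScan(dataset)


def group_shift_cohort(shift_log2, n_per_group=100, n_experiments=25,
                       noise_sd=0.2, seed=4):
    """One protein, abundance shifted by `shift_log2` in the deficient group."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    assert n <= 8 * n_experiments
    exp = np.array([f"e{i % n_experiments}" for i in range(n)])
    deficient = np.arange(n) < n_per_group
    pivka = np.where(deficient, 3.0, 1.0)
    subjects = make_subjects([
        (f"c{i}", exp[i], 1 + i // n_experiments, float(pivka[i]))
        for i in range(n)])
    u = rng.normal(0, 0.1, n_experiments)
    value = shift_log2 * deficient + u[np.arange(n) % n_experiments] \
        + rng.normal(0, noise_sd, n)
    obs = make_observations([("PX", "9", f"c{i}", exp[i], float(value[i]))
                             for i in range(n)])
    return CohortDataset(subjects, obs, normalized=True)


class TestGroupDifferenceScan:
    def test_recovers_plus_10_percent_shift(self):
        true = float(np.log2(1.10))
        dataset = group_shift_cohort(true)
        res = GroupDifferenceScan(dataset,
                                  AnalysisConfig(min_children=10)).fit()
        assert len(res.results) == 1
        r = res.results[0]
        assert r.beta_group == pytest.approx(true, abs=3 * r.se_beta)
        assert r.percent_difference == pytest.approx(10.0, abs=12.0)

    def test_null_centered_at_zero(self):
        cfg = small_sim_config(driver_slopes=(), seed=33)
        dataset, _ = generate_cohort(cfg)
        normalized, _ = log2_median_normalize(dataset)
        res = GroupDifferenceScan(
            normalized, AnalysisConfig(min_children=cfg.min_children)).fit()
        pds = np.array([r.percent_difference for r in res.results])
        assert len(pds) > 10
        assert abs(np.mean(pds)) < 3.0

    def test_small_group_skipped(self):
        # only one deficient child quantified -> protein skipped with warning
        dataset = group_shift_cohort(0.0, n_per_group=30)
        subj = dataset.subjects.copy()
        subj.loc[1:29, "pivka2_ugL"] = 1.0  # leaves one deficient child
        dataset = dataset.replace(subjects=subj)
        res = GroupDifferenceScan(dataset,
                                  AnalysisConfig(min_children=10)).fit()
        assert not res.results
        assert res.skipped and "group" in res.skipped[0][1]


class TestCohortTable:
    @staticmethod
    def subjects_with_status(n_def=100, n_suf=400, seed=0):
        rng = np.random.default_rng(seed)
        df = make_subjects(
            [(f"d{i}", f"e{i % 50}", 1 + i % 8, 3.0) for i in range(n_def)]
            + [(f"s{i}", f"f{i % 50}", 1 + i % 8, 1.0) for i in range(n_suf)])
        return dichotomize_vk(df), rng

    def test_chi_square_near_identical_proportions(self):
        subj, _ = self.subjects_with_status()
        male = np.zeros(500, dtype=int)
        male[:50] = 1                     # 50 / 100 deficient
        male[100:299] = 1                 # 199 / 400 sufficient
        subj["male"] = male
        table = build_cohort_table(subj, {"male": "categorical"})
        assert table.loc[0, "test"] == "chi-square"
        assert table.loc[0, "p_value"] > 0.95

    def test_identical_continuous_distributions_t_test_p_one(self):
        subj, _ = self.subjects_with_status(n_def=4, n_suf=4)
        subj["age_y"] = [6.0, 7.0, 8.0, 9.0] * 2
        table = build_cohort_table(subj, {"age_y": "normal"})
        assert table.loc[0, "p_value"] == pytest.approx(1.0)

    def test_skew_flag_routes_to_mann_whitney(self):
        subj, rng = self.subjects_with_status(n_def=30, n_suf=30)
        subj["triglyceride"] = rng.lognormal(0, 0.4, 60)
        table = build_cohort_table(subj, {"triglyceride": "skewed"})
        assert table.loc[0, "test"] == "Mann-Whitney"
        assert 0 <= table.loc[0, "p_value"] <= 1

    def test_all_missing_covariate_gets_blank_p(self):
        subj, _ = self.subjects_with_status(n_def=5, n_suf=5)
        subj["crp"] = np.nan
        table = build_cohort_table(subj, {"crp": "normal"})
        assert np.isnan(table.loc[0, "p_value"])
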