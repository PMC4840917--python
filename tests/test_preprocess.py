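"""Normalization, coverage filtering, and outcome derivation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vkproteome import CohortDataset
from vkproteome.preprocess import (continuous_outcome_subset, dichotomize_vk,
                                   filter_proteins_by_coverage,
                                   log2_median_normalize)

from conftest import make_observations, make_subjects


def one_channel_cohort(values, pivka=1.0):
    """One child, one channel, len(values) proteins with raw intensities."""
    subjects = make_subjects([("c1", "e1", 1, pivka)])
    obs = make_observations([(f"P{i}", str(i), "c1", "e1", v)
                             for i, v in enumerate(values)])
    return CohortDataset(subjects, obs, normalized=False)


class TestLog2MedianNormalize:
    def test_median_subtraction(self):
        # raw {2, 4, 8} -> log2 {1, 2, 3} -> centered {-1, 0, 1}
        out, _ = log2_median_normalize(one_channel_cohort([2.0, 4.0, 8.0]))
        assert sorted(out.observations["value"]) == [-1.0, 0.0, 1.0]
        assert out.normalized

    def test_single_observation_maps_to_zero(self):
        out, _ = log2_median_normalize(one_channel_cohort([37.5]))
        assert out.observations["value"].iloc[0] == 0.0

    def test_per_channel_median_is_zero_after_transform(self, tiny_raw_cohort):
        out, report = log2_median_normalize(tiny_raw_cohort)
        med = out.observations.groupby(["experiment_id", "child_id"])["value"] \
            .median()
        np.testing.assert_allclose(med, 0.0, atol=1e-9)
        assert report.n_observations == len(tiny_raw_cohort.observations)

    def test_idempotent_on_zero_median_data(self):
        # already centered in log2 <=> raw values whose log2 median is 0
        dataset = one_channel_cohort([0.5, 1.0, 2.0])
        out, _ = log2_median_normalize(dataset)
        again = CohortDataset(dataset.subjects,
                              out.observations.assign(
                                  value=2.0 ** out.observations["value"]),
                              normalized=False)
        out2, _ = log2_median_normalize(again)
        np.testing.assert_allclose(out2.observations["value"],
                                   out.observations["value"], atol=1e-12)

    def test_non_positive_intensity_names_observation(self):
        with pytest.raises(ValueError, match="c1"):
            log2_median_normalize(one_channel_cohort([1.0, -2.0]))

    def test_double_normalization_rejected(self, tiny_raw_cohort):
        out, _ = log2_median_normalize(tiny_raw_cohort)
        with pytest.raises(ValueError, match="already"):
            log2_median_normalize(out)

    @settings(max_examples=25, deadline=None)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3),
           seed=st.integers(0, 10_000))
    def test_invariant_to_per_channel_scaling(self, scale, seed):
        # multiplying one channel's raw intensities by c > 0 changes nothing
        rng = np.random.default_rng(seed)
        values = rng.lognormal(10, 1, size=5)
        base, _ = log2_median_normalize(one_channel_cohort(values))
        scaled, _ = log2_median_normalize(one_channel_cohort(values * scale))
        np.testing.assert_allclose(scaled.observations["value"],
                                   base.observations["value"], atol=1e-9)


class TestCoverageFilter:
    @staticmethod
    def cohort_with_counts(counts):
        """One protein per entry, observed in `count` distinct children."""
        n = max(counts)
        exp_of = [f"e{i // 8}" for i in range(n)]
        subjects = make_subjects([(f"c{i}", exp_of[i], 1 + i % 8, 1.0)
                                  for i in range(n)])
        rows = []
        for p, count in enumerate(counts):
            rows += [(f"P{p}", str(p), f"c{i}", exp_of[i], 0.1)
                     for i in range(count)]
        return CohortDataset(subjects, make_observations(rows),
                             normalized=True)

    def test_boundary_is_strict(self):
        # quantified in exactly 50 children -> excluded; 51 -> retained
        dataset = self.cohort_with_counts([50, 51])
        kept = filter_proteins_by_coverage(dataset, min_children=50)
        assert set(kept.observations["gi_accession"]) == {"1"}

    def test_zero_threshold_keeps_everything_observed(self):
        dataset = self.cohort_with_counts([1, 3])
        kept = filter_proteins_by_coverage(dataset, min_children=0)
        assert set(kept.observations["gi_accession"]) == {"0", "1"}

    @settings(max_examples=20, deadline=None)
    @given(st.lists(st.integers(1, 30), min_size=1, max_size=6),
           st.integers(0, 15), st.integers(0, 15))
    def test_monotone_in_threshold(self, counts, t1, t2):
        lo, hi = min(t1, t2), max(t1, t2)
        dataset = self.cohort_with_counts(counts)
        keep = [set(filter_proteins_by_coverage(dataset, t)
                    .observations["gi_accession"]) for t in (lo, hi)]
        assert keep[1] <= keep[0]


class TestVkStatus:
    @pytest.mark.parametrize("pivka,status", [
        (2.0, "sufficient"),       # cutoff inclusive on the sufficient side
        (2.01, "deficient"),
        (0.0005, "sufficient"),    # below-detection counts as sufficient
        (13.0, "deficient"),
    ])
    def test_dichotomization_boundary(self, pivka, status):
        subj = dichotomize_vk(make_subjects([("c1", "e1", 1, pivka)]))
        assert subj["vk_status"].iloc[0] == status

    def test_missing_pivka_leaves_status_missing(self):
        df = make_subjects([("c1", "e1", 1, 1.0)])
        df.loc[0, "pivka2_ugL"] = np.nan
        assert dichotomize_vk(df)["vk_status"].isna().iloc[0]


class TestContinuousSubset:
    def test_below_detection_dropped_and_log2_defined(self):
        rows = [(f"c{i}", "e1", 1 + i % 8, 1.5) for i in range(6)]
        df = make_subjects(rows)
        df.loc[[0, 3], "pivka2_ugL"] = 0.0
        df["below_detection"] = df["pivka2_ugL"] < 0.001
        kept = continuous_outcome_subset(df)
        assert len(kept) == 4
        assert np.isfinite(kept["log2_pivka"]).all()

    def test_identity_without_censoring(self):
        df = make_subjects([("c1", "e1", 1, 1.31), ("c2", "e1", 2, 2.5)])
        kept = continuous_outcome_subset(df)
        assert len(kept) == 2
        np.testing.assert_allclose(kept["log2_pivka"],
                                   np.log2([1.31, 2.5]))

    def test_study_scale_counts(self, default_cohort):
        dataset, _ = default_cohort
        kept = continuous_outcome_subset(dataset.subjects)
        assert len(dataset.subjects) == 500
        assert len(kept) == 474  # 26 undetectable children excluded
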