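"""Tests for the parturition-date simulator and study runner."""

import numpy as np
import pandas as pd
import pytest

from psindex import (
    DesignCell,
    DistributionSpec,
    StudyDesign,
    draw_group,
    enforce_span,
    default_design,
    run_study,
    sample_pool,
    simulate_group,
)


def rng(seed=0):
    return np.random.default_rng(seed)


class TestSpecsAndCells:
    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            DistributionSpec("weibull")
        with pytest.raises(ValueError, match="unknown"):
            DesignCell("weibull", 10, 5)

    def test_defaults_merged_and_overridable(self):
        spec = DistributionSpec("lognormal", {"sigma_log": 0.9})
        assert spec.params["sigma_log"] == 0.9
        assert spec.params["median_frac"] == 0.15

    def test_nonpositive_parameter_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            DistributionSpec("normal", {"sd_frac": 0.0})

    def test_cell_invariants(self):
        with pytest.raises(ValueError, match="1-day"):
            DesignCell("synchronous", 10, 5)
        with pytest.raises(ValueError, match=">= 2 days"):
            DesignCell("uniform", 1, 5)
        with pytest.raises(ValueError, match=">= 2 mothers"):
            DesignCell("uniform", 10, 1)

    def test_design_pool_must_cover_largest_group(self):
        with pytest.raises(ValueError, match="pool_size"):
            StudyDesign(cells=(DesignCell("uniform", 10, 500),), pool_size=100)


class TestSamplePool:
    def test_synchronous_all_day_one(self):
        pool = sample_pool(DistributionSpec("synchronous"), 1, 1000, rng())
        assert np.all(pool == 1)

    @pytest.mark.parametrize(
        "family", ["uniform", "normal", "lognormal", "bimodal"]
    )
    def test_support_is_season(self, family):
        pool = sample_pool(DistributionSpec(family), 50, 20_000, rng())
        assert pool.dtype.kind == "i"
        assert pool.min() >= 1 and pool.max() <= 50

    def test_uniform_frequencies_balanced(self):
        # each of 10 days expects 10000 draws; allow 5 binomial SDs
        pool = sample_pool(DistributionSpec("uniform"), 10, 100_000, rng())
        counts = np.bincount(pool, minlength=11)[1:]
        sd = np.sqrt(100_000 * 0.1 * 0.9)
        assert np.all(np.abs(counts - 10_000) < 5 * sd)

    def test_bimodal_peaks_at_30_and_70_percent(self):
        # 200-day season: modes on/adjacent to days 60 and 140; smooth the
        # daily histogram (7-day window) before locating the modes
        pool = sample_pool(DistributionSpec("bimodal"), 200, 100_000, rng())
        counts = np.bincount(pool, minlength=201).astype(float)
        smooth = np.convolve(counts, np.ones(7) / 7, mode="same")
        assert abs(int(np.argmax(smooth[:101])) - 60) <= 2
        assert abs(int(np.argmax(smooth[101:])) + 101 - 140) <= 2

    def test_lognormal_right_skewed_early_peak(self):
        pool = sample_pool(DistributionSpec("lognormal"), 100, 100_000, rng())
        assert np.median(pool) < 25  # mass concentrated early in season
        assert pool.mean() > np.median(pool)  # right skew


class TestDrawGroup:
    def test_full_draw_is_permutation(self):
        pool = np.arange(1, 21)
        g = draw_group(pool, 20, rng())
        assert sorted(g) == list(pool)

    def test_subset_of_pool_and_deterministic(self):
        pool = sample_pool(DistributionSpec("uniform"), 100, 1000, rng(3))
        g1 = draw_group(pool, 5, rng(7))
        g2 = draw_group(pool, 5, rng(7))
        np.testing.assert_array_equal(g1, g2)
        assert np.isin(g1, pool).all()

    def test_oversized_group_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            draw_group(np.arange(3), 5, rng())


class TestEnforceSpan:
    @pytest.mark.parametrize(
        "dates, duration, expected",
        [
            ([1, 4, 10], 10, [1, 4, 10]),  # already spans: untouched
            ([3, 4, 7], 10, [1, 4, 10]),  # min -> 1, max -> 10
            ([5, 5], 10, [1, 10]),  # both endpoints injected
            ([1, 1], 10, [10, 1]),  # only the final day missing
        ],
    )
    def test_endpoint_injection(self, dates, duration, expected):
        out = enforce_span(np.array(dates), duration)
        assert list(out) == expected

    def test_changes_at_most_two_positions(self):
        r = rng(5)
        for _ in range(50):
            d = r.integers(2, 50, size=r.integers(2, 20))
            out = enforce_span(d, 50)
            assert (out != d).sum() <= 2
            assert out.min() == 1 and out.max() == 50

    def test_one_day_season_rejected(self):
        with pytest.raises(ValueError):
            enforce_span(np.array([1, 1]), 1)


class TestSimulateGroup:
    def test_synchronous_bypasses_pool(self):
        g = simulate_group(DesignCell("synchronous", 1, 25))
        assert np.all(g == 1) and g.size == 25

    @pytest.mark.parametrize("family", ["normal", "lognormal", "bimodal", "uniform"])
    def test_span_invariant(self, family):
        g = simulate_group(DesignCell(family, 10, 5), pool_size=1000)
        assert g.size == 5
        assert g.min() == 1 and g.max() == 10
        assert np.all((g >= 1) & (g <= 10))

    def test_rejection_mode_spans_naturally(self):
        g = simulate_group(
            DesignCell("uniform", 10, 100), pool_size=10_000, span_mode="reject"
        )
        assert g.min() == 1 and g.max() == 10


class TestRunStudy:
    def test_default_design_counts(self, study_mothers, study_groups):
        assert len(study_groups) == 168
        assert len(study_mothers) == 140_490
        fam_counts = study_mothers["family"].value_counts()
        assert fam_counts["synchronous"] == 6690
        for fam in ("lognormal", "normal", "bimodal", "uniform"):
            assert fam_counts[fam] == 33_450

    def test_synchronous_only_subdesign(self):
        design = default_design(seed=1, families=("synchronous",))
        mothers, groups = run_study(design)
        assert len(groups) == 8 and len(mothers) == 6690
        assert (groups["mean_psi"] == 1.0).all()

    def test_single_cell_design(self):
        design = StudyDesign(
            cells=(DesignCell("uniform", 10, 5),), seed=2, pool_size=1000
        )
        mothers, groups = run_study(design)
        assert len(groups) == 1 and len(mothers) == 5

    def test_count_conservation(self, study_mothers, study_groups):
        per_group = study_mothers.groupby("group_id").size()
        merged = study_groups.set_index("group_id")["size"]
        pd.testing.assert_series_equal(
            per_group.sort_index(),
            merged.sort_index(),
            check_names=False,
            check_dtype=False,
        )

    def test_determinism(self):
        design = default_design(
            seed=9, durations=(10, 50), sizes=(5, 100), pool_size=2000
        )
        m1, g1 = run_study(design)
        m2, g2 = run_study(design)
        pd.testing.assert_frame_equal(m1, m2)
        pd.testing.assert_frame_equal(g1, g2)

    def test_seed_changes_output(self):
        kw = dict(durations=(50,), sizes=(25,), pool_size=2000,
                  families=("uniform",))
        _, g1 = run_study(default_design(seed=1, **kw))
        _, g2 = run_study(default_design(seed=2, **kw))
        assert g1["mean_psi"].iloc[0] != g2["mean_psi"].iloc[0]

    def test_uniform_large_groups_near_continuous_limit(self, study_groups):
        # mean pairwise |diff| of a uniform season is D/3, so mean PSI
        # approaches 1/(D/3 + 1) for large groups
        big = study_groups.query("family == 'uniform' and size >= 1000")
        assert len(big) == 10
        limit = 1.0 / (big["duration"] / 3.0 + 1.0)
        assert (np.abs(big["mean_psi"] - limit) / limit < 0.15).all()

    def test_lognormal_more_synchronous_than_uniform(self, study_groups):
        ns = study_groups[study_groups["family"] != "synchronous"]
        means = ns.groupby("family")["mean_psi"].mean()
        assert means["lognormal"] > means["uniform"]
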