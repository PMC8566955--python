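import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ddft3d.cohort_stats import (
    TransitionRecord,
    build_transitions,
    compare_groups,
    concordance_counts,
    correlate_scores,
    example_cohort,
    normality,
    odds_ratio,
    parse_time_months,
    pathologic_row_count,
    pearson_correlation,
    summarize_outcome_groups,
    thickness_change_table,
)


def transition(mri=0, clin=0, dthick=0.0, dvol=0.0, **kw):
    return TransitionRecord(
        horse=1, limb="LF", interval=("0", "5 M"), mri_score=mri,
        clinical_score=clin, delta_median_thickness_mm=dthick,
        delta_volume_pct=dvol, **kw,
    )


class TestTransitions:
    def test_time_label_parsing(self):
        assert parse_time_months("0") == 0
        assert parse_time_months("2 W") == 0.5
        assert parse_time_months("10 M") == 10
        assert parse_time_months("0 M") == 0

    def test_example_cohort_transition_count(self):
        # 3 tendons with three scans (2 transitions each) + 7 with two
        trans = build_transitions(example_cohort())
        assert len(trans) == 13

    def test_normal_tendon_volume_change(self):
        """Horse 3 RF volumes give the 2.3% reduction at one decimal."""
        trans = build_transitions(example_cohort())
        rec = next(t for t in trans if t.horse == 3 and t.limb == "RF")
        assert round(rec.delta_volume_pct, 1) == -2.3

    def test_identical_consecutive_rows_give_zero_deltas(self):
        import pandas as pd

        df = pd.DataFrame(
            {
                "horse": [1, 1],
                "limb": ["LF", "LF"],
                "time": ["0", "5 M"],
                "median_thickness_mm": [3.0, 3.0],
                "volume_mm3": [9000.0, 9000.0],
                "field_T": [1.5, 1.5],
                "mri_score": [pd.NA, 0],
                "clinical_score": [pd.NA, 0],
            }
        )
        rec = build_transitions(df)[0]
        assert rec.delta_median_thickness_mm == 0.0
        assert rec.delta_volume_pct == 0.0

    def test_pathologic_rows_exclude_flagged_normal_tendon(self):
        assert pathologic_row_count(example_cohort()) == 21


class TestConcordance:
    def test_example_cohort_counts(self):
        counts = concordance_counts(build_transitions(example_cohort()))
        assert counts["both_unchanged"] == 4
        assert counts["both_improved"] == 3
        assert counts["both_worse"] == 2

    def test_all_zero_table(self):
        trans = [transition(0, 0) for _ in range(5)]
        counts = concordance_counts(trans)
        assert counts == {
            "both_improved": 0,
            "both_unchanged": 5,
            "both_worse": 0,
            "discordant": 0,
        }

    @given(
        st.lists(
            st.tuples(st.sampled_from([-1, 0, 1]), st.sampled_from([-1, 0, 1])),
            min_size=1,
            max_size=30,
        )
    )
    @settings(max_examples=60, deadline=None)
    def test_partition_sums_to_total(self, pairs):
        trans = [transition(m, c) for m, c in pairs]
        counts = concordance_counts(trans)
        assert sum(counts.values()) == len(pairs)


class TestPearson:
    def test_collinear_data(self):
        x = [1, 2, 3, 4, 5]
        res = pearson_correlation(x, [2 * v + 1 for v in x])
        assert res.r == pytest.approx(1.0, abs=1e-12)
        res = pearson_correlation(x, [-v for v in x])
        assert res.r == pytest.approx(-1.0, abs=1e-12)

    def test_hand_computed_example(self):
        """r = 0.8 with p from t = r sqrt(n-2)/sqrt(1-r^2) on 3 d.f."""
        from scipy import stats

        res = pearson_correlation([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert res.r == pytest.approx(0.8, abs=1e-12)
        t = 0.8 * np.sqrt(3) / np.sqrt(1 - 0.64)
        assert t == pytest.approx(2.3094, abs=1e-4)
        assert res.p == pytest.approx(2 * stats.t.sf(t, 3), abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            pearson_correlation([1, 1, 1], [1, 2, 3])

    def test_three_point_grid_matches_closed_form(self):
        """Brute-force closed form over a small grid of 3-point data sets."""
        vals = [0.0, 1.0, 2.0]
        for y1 in vals:
            for y2 in vals:
                for y3 in vals:
                    y = np.array([y1, y2, y3])
                    if np.ptp(y) == 0:
                        continue
                    x = np.array([0.0, 1.0, 2.0])
                    r_closed = float(
                        np.sum((x - 1) * (y - y.mean()))
                        / np.sqrt(np.sum((x - 1) ** 2) * np.sum((y - y.mean()) ** 2))
                    )
                    res = pearson_correlation(x, y)
                    assert res.r == pytest.approx(r_closed, abs=1e-12)


class TestOddsRatio:
    def test_unit_table(self):
        assert odds_ratio((1, 1, 1, 1)).odds_ratio == 1.0

    def test_woolf_interval_closed_form(self):
        res = odds_ratio((8, 2, 2, 8))
        assert res.odds_ratio == 16.0
        se = np.sqrt(1 / 8 + 1 / 2 + 1 / 2 + 1 / 8)
        lo = np.exp(np.log(16) - 1.96 * se)
        hi = np.exp(np.log(16) + 1.96 * se)
        assert res.ci95 == (pytest.approx(lo), pytest.approx(hi))
        assert not res.correction_applied

    def test_haldane_correction_with_zero_cell(self):
        res = odds_ratio((4, 0, 1, 6))
        assert res.correction_applied
        assert res.odds_ratio == pytest.approx((4.5 * 6.5) / (0.5 * 1.5))

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            odds_ratio((0, 0, 3, 4))

    @given(st.tuples(*[st.integers(1, 30)] * 4))
    @settings(max_examples=60, deadline=None)
    def test_row_column_swap_invariances(self, table):
        a, b, c, d = table
        base = odds_ratio((a, b, c, d)).odds_ratio
        swapped = odds_ratio((d, c, b, a)).odds_ratio  # both rows and columns
        assert swapped == pytest.approx(base, rel=1e-12)
        recip = odds_ratio((b, a, d, c)).odds_ratio  # outcome columns only
        assert recip == pytest.approx(1.0 / base, rel=1e-12)


class TestRankSumAndNormality:
    def test_identical_groups_exact_p_is_one(self):
        res = compare_groups([1.0, 2.0, 5.0], [1.5, 2.5, 4.0])
        assert res.method == "exact"
        # symmetric configurations: p must be large; identical rank sums
        res2 = compare_groups([1, 3, 5], [2, 4, 6])
        assert res2.p > 0.5

    def test_fully_separated_groups_exact_p(self):
        """Rank sum 6 is minimal; exact two-sided p = 2/20 = 0.1."""
        res = compare_groups([1, 2, 3], [10, 11, 12])
        assert res.rank_sum == 6.0
        assert res.method == "exact"
        assert res.p == pytest.approx(0.1, abs=1e-12)

    def test_degenerate_pooled_values_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1, 1, 1], [1, 1, 1])

    def test_skewed_construction_fails_normality(self):
        """Squared normals (n=50) are flagged non-normal almost always."""
        rng = np.random.default_rng(0)
        rejected = 0
        for _ in range(200):
            sample = rng.normal(size=50) ** 2
            if normality(sample).p < 0.05:
                rejected += 1
        assert rejected >= 190

    def test_normal_sample_usually_passes(self):
        rng = np.random.default_rng(1)
        res = normality(rng.normal(size=200))
        assert res.p > 0.01


class TestGroupSummaries:
    def test_group_medians_match_hand_computation(self):
        trans = [
            transition(1, 1, dvol=5.2),
            transition(1, 1, dvol=8.5),
            transition(1, 1, dvol=22.3),
            transition(0, 0, dvol=-2.3),
            transition(-1, -1, dvol=14.2),
        ]
        out = summarize_outcome_groups(trans)
        assert out["improved"]["delta_volume_pct"]["median"] == 8.5
        assert out["improved"]["delta_volume_pct"]["range"] == (5.2, 22.3)
        assert out["worse"]["delta_volume_pct"]["median"] == 14.2

    def test_single_member_group_median_equals_endpoints(self):
        out = summarize_outcome_groups([transition(1, 1, dvol=7.0)])
        assert out["improved"]["delta_volume_pct"] == {
            "median": 7.0,
            "range": (7.0, 7.0),
            "n": 1,
        }

    def test_row_order_invariance(self):
        t = [transition(1, 1, dvol=v) for v in (3.0, 9.0, 5.0)]
        a = summarize_outcome_groups(t)
        b = summarize_outcome_groups(t[::-1])
        assert a == b

    def test_thickness_change_table_construction(self):
        trans = [
            transition(1, 1, exceeds_threshold=True),
            transition(-1, -1, exceeds_threshold=True),
            transition(1, 0, exceeds_threshold=False),
            transition(0, 0, exceeds_threshold=False),
            transition(0, 0, exceeds_threshold=True),
        ]
        assert thickness_change_table(trans) == (2, 1, 1, 1)


class TestSyntheticRecovery:
    def test_imposed_score_effect_recovered(self):
        """Cohorts with a monotone score-thickness effect yield r > 0,
        p < 0.05 in at least 90% of seeded replicates."""
        from ddft3d.synthetic_phantom import CohortConfig, generate_cohort

        hits = 0
        for seed in range(100):
            df = generate_cohort(CohortConfig(), seed=seed)
            res = correlate_scores(build_transitions(df))
            if res.r > 0 and res.p < 0.05:
                hits += 1
        assert hits >= 90
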