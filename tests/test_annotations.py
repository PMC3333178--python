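"""Disorder quantification, interaction typing, group comparisons, landscapes."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from coexstab.annotations import (
    AnnotationError,
    build_landscape,
    disease_class_summary,
    disorder_fraction,
    group_compare,
    interaction_type,
    wilcoxon_rank_sum,
)
from coexstab.network import ProteinSummary


class TestDisorderFraction:
    def test_single_long_run(self):
        s = "0" * 30 + "1" * 40 + "0" * 30
        assert disorder_fraction(s) == pytest.approx(0.40)

    def test_run_below_the_rule_counts_zero(self):
        s = "0" * 40 + "1" * 29 + "0" * 31
        assert disorder_fraction(s) == 0.0

    def test_mixed_runs_scan(self):
        s = "1" * 35 + "0" + "1" * 29 + "0" * 24 + "1" * 31
        assert len(s) == 120
        assert disorder_fraction(s) == pytest.approx((35 + 31) / 120)

    def test_min_run_parameter(self):
        s = "1" * 10 + "0" * 10
        assert disorder_fraction(s, min_run=10) == pytest.approx(0.5)
        assert disorder_fraction(s, min_run=11) == 0.0

    def test_invalid_characters_rejected(self):
        with pytest.raises(AnnotationError):
            disorder_fraction("0102")
        with pytest.raises(AnnotationError):
            disorder_fraction("")

    @settings(max_examples=100, deadline=None)
    @given(st.text(alphabet="01", min_size=1, max_size=200))
    def test_invariant_under_reversal(self, s):
        assert disorder_fraction(s) == pytest.approx(disorder_fraction(s[::-1]))


class TestInteractionType:
    @pytest.mark.parametrize(
        "fa, fb, expected",
        [
            (0.35, 0.40, "disordered_pair"),
            (0.10, 0.50, "mixed"),
            (0.0, 0.0, "ordered_pair"),
            (0.30, 0.30, "disordered_pair"),  # boundary counts as disordered
            (0.30, 0.29, "mixed"),
        ],
    )
    def test_typing_rules(self, fa, fb, expected):
        assert interaction_type(fa, fb) == expected

    @settings(max_examples=100, deadline=None)
    @given(st.floats(0, 1), st.floats(0, 1))
    def test_symmetric(self, fa, fb):
        assert interaction_type(fa, fb) == interaction_type(fb, fa)

    def test_fraction_range_validated(self):
        with pytest.raises(AnnotationError):
            interaction_type(1.2, 0.1)


def exact_ranksum_p(x, y):
    """Enumeration oracle: two-sided p over all group assignments."""
    pooled = sorted(x) + sorted(y)
    ranks = {v: r + 1 for r, v in enumerate(sorted(pooled))}
    observed = sum(ranks[v] for v in x)
    n = len(x)
    sums = [
        sum(combo) for combo in itertools.combinations(
            [ranks[v] for v in pooled], n
        )
    ]
    mean = np.mean(sums)
    extreme = sum(1 for s in sums if abs(s - mean) >= abs(observed - mean) - 1e-12)
    return extreme / len(sums)


class TestWilcoxonRankSum:
    def test_identical_groups(self):
        assert wilcoxon_rank_sum([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_extreme_small_groups_match_enumeration(self):
        x, y = [1, 2, 3], [4, 5, 6]
        assert wilcoxon_rank_sum(x, y) == pytest.approx(0.1, abs=1e-12)
        assert wilcoxon_rank_sum(x, y) == pytest.approx(exact_ranksum_p(x, y), abs=1e-12)

    def test_large_groups_use_tie_corrected_approximation(self):
        rng = np.random.default_rng(3)
        x = np.round(rng.normal(0, 1, 40), 1)
        y = np.round(rng.normal(0.8, 1, 40), 1)
        p = wilcoxon_rank_sum(x, y)
        assert 0 < p < 0.01

    def test_empty_group_rejected(self):
        with pytest.raises(AnnotationError):
            wilcoxon_rank_sum([], [1.0])


def make_summaries(stabs, cors=None, prefix="p"):
    cors = cors if cors is not None else [0.5] * len(stabs)
    return [
        ProteinSummary(f"{prefix}{i}", degree=5, avg_cor=c, avg_stab=s)
        for i, (c, s) in enumerate(zip(cors, stabs))
    ]


class TestGroupCompare:
    def test_planted_stability_shift_detected(self):
        rng = np.random.default_rng(11)
        base = rng.normal(0.5, 0.1, 100)
        stabs = base.copy()
        stabs[:50] += 0.2  # planted shift in the "disease" half
        summaries = make_summaries(stabs)
        labels = pd.DataFrame(
            {
                "disease": [True] * 50 + [False] * 50,
                "essential": [False] * 100,
            },
            index=[f"p{i}" for i in range(100)],
        )
        cmp_res = group_compare(summaries, labels, "disease")
        assert cmp_res.groups["disease"].mean_stab > cmp_res.groups["non-disease"].mean_stab
        assert cmp_res.pairwise_p[("disease", "non-disease")]["avg_stab"] < 0.001

    def test_four_way_grouping_and_missing_labels(self):
        summaries = make_summaries([0.1, 0.2, 0.3, 0.4], prefix="q")
        labels = pd.DataFrame(
            {"disease": [True, True, False], "essential": [True, False, False]},
            index=["q0", "q1", "q2"],  # q3 unlabeled
        )
        cmp_res = group_compare(summaries, labels, "disease_essential")
        assert set(cmp_res.groups) == {
            "disease_essential", "disease_non-essential", "non-disease_non-essential"
        }
        assert sum(g.n for g in cmp_res.groups.values()) == 3

    def test_invalid_grouping(self):
        with pytest.raises(AnnotationError):
            group_compare([], pd.DataFrame(), "banana")


class TestLandscape:
    def test_single_occupied_bin(self):
        l2d = build_landscape([(0.55, 0.75)] * 10, bin_width=0.1)
        assert l2d.counts.sum() == 10
        assert l2d.counts.max() == 10
        assert l2d.mask.sum() == l2d.mask.size - 1

    def test_counts_conserved_and_final_bin_closed(self):
        rng = np.random.default_rng(5)
        items = list(zip(rng.uniform(-1, 1, 500), rng.uniform(-1, 1, 500)))
        items.append((1.0, 1.0))  # exactly on the closing edge
        l2d = build_landscape(items, bin_width=0.1)
        assert l2d.counts.sum() == len(items)
        assert l2d.counts[-1, -1] >= 1

    def test_overlay_mean_matches_groupby_oracle(self):
        rng = np.random.default_rng(6)
        cor = rng.uniform(0, 1, 200)
        stab = rng.uniform(0, 1, 200)
        val = rng.uniform(0, 1, 200)
        l2d = build_landscape(zip(cor, stab, val), bin_width=0.25)
        df = pd.DataFrame({"c": cor, "s": stab, "v": val})
        df["ci"] = np.minimum(((df.c + 1) / 0.25).astype(int), 7)
        df["si"] = np.minimum(((df.s + 1) / 0.25).astype(int), 7)
        for (ci, si), grp in df.groupby(["ci", "si"]):
            assert l2d.overlay_mean[ci, si] == pytest.approx(grp.v.mean())
        assert np.isnan(l2d.overlay_mean[l2d.mask]).all()

    def test_bad_bin_width(self):
        with pytest.raises(AnnotationError):
            build_landscape([(0, 0)], bin_width=0.0)
        with pytest.raises(AnnotationError):
            build_landscape([(0, 0)], bin_width=0.3)


class TestDiseaseClassSummary:
    def test_hand_arithmetic(self):
        summaries = make_summaries([0.4, 0.6], cors=[0.2, 0.4])
        labels = pd.DataFrame(
            {"disease": [True, True], "essential": [False, False],
             "disease_class": ["hematological", "hematological"]},
            index=["p0", "p1"],
        )
        df = disease_class_summary(summaries, labels)
        row = df.iloc[0]
        assert row["n"] == 2
        assert row["mean_avg_stab"] == pytest.approx(0.5)
        assert row["se_avg_stab"] == pytest.approx(0.1)
        assert row["mean_avg_cor"] == pytest.approx(0.3)

    def test_unclassed_proteins_excluded(self):
        summaries = make_summaries([0.4, 0.6])
        labels = pd.DataFrame(
            {"disease": [True, False], "essential": [False, False],
             "disease_class": ["metabolic", ""]},
            index=["p0", "p1"],
        )
        df = disease_class_summary(summaries, labels)
        assert list(df["disease_class"]) == ["metabolic"]
        assert df.iloc[0]["n"] == 1
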