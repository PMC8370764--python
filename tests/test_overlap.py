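"""Similarity, sharing and rank-test statistics between repertoires."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tcroverlap import (InsufficientDataError, UndefinedSimilarityError,
                        aggregate, mhi_group_summary, morisita_horn,
                        overlap_regression, overlap_table,
                        relative_intersection, sharing_counts, top_n,
                        venn3_counts)
from tcroverlap.overlap import compute_pair_overlap
from tcroverlap.processing import KeyMode

from .conftest import random_rep, rep_from_counts


def brute_force_mhi(rep_a, rep_b):
    """Naive double-loop evaluation of the similarity formula."""
    a = {tuple(r): f for *r, f in
         rep_a.clonotypes[rep_a.key_columns + ["frequency"]].itertuples(index=False)}
    b = {tuple(r): f for *r, f in
         rep_b.clonotypes[rep_b.key_columns + ["frequency"]].itertuples(index=False)}
    num = 0.0
    for ka, pa in a.items():
        for kb, qb in b.items():
            if ka == kb:
                num += pa * qb
    den = sum(p * p for p in a.values()) + sum(q * q for q in b.values())
    return 2.0 * num / den


class TestMorisitaHorn:
    def test_hand_computed_example(self):
        a = rep_from_counts({"c1": 2, "c2": 2})
        b = rep_from_counts({"c1": 1, "c2": 1, "c3": 2})
        assert morisita_horn(a, b) == pytest.approx(4.0 / 7.0, abs=1e-15)

    def test_identity_is_exactly_one(self):
        rep = rep_from_counts({"a": 5, "b": 3, "c": 1})
        assert morisita_horn(rep, rep) == 1.0

    def test_disjoint_is_exactly_zero(self):
        a = rep_from_counts({"a": 5, "b": 3})
        b = rep_from_counts({"x": 2, "y": 7})
        assert morisita_horn(a, b) == 0.0

    def test_empty_repertoire_is_an_error(self):
        a = rep_from_counts({"a": 5})
        with pytest.raises(UndefinedSimilarityError):
            morisita_horn(a, rep_from_counts({}))

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(0, 10 ** 6))
    def test_symmetric_bounded_and_matches_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = random_rep(rng, int(rng.integers(2, 40)))
        b = random_rep(rng, int(rng.integers(2, 40)))
        m = morisita_horn(a, b)
        assert 0.0 <= m <= 1.0
        assert m == pytest.approx(morisita_horn(b, a), abs=1e-15)
        assert m == pytest.approx(brute_force_mhi(a, b), abs=1e-12)

    def test_subsampling_error_shrinks_with_depth(self, rng):
        # multinomial downsampling to 50% perturbs the index less when the
        # starting depth is higher
        def downsample(rep, gen):
            counts = rep.clonotypes["read_count"].to_numpy()
            half = gen.multinomial(counts.sum() // 2, counts / counts.sum())
            df = rep.clonotypes.loc[half > 0, ["cdr3_nt", "cdr3_aa", "v_call",
                                               "j_call", "productive"]].copy()
            df["read_count"] = half[half > 0]
            return aggregate(df, rep.key_mode)

        deltas = {}
        for depth in (2000, 200_000):
            errs = []
            for rep_seed in range(4):
                g = np.random.default_rng(1000 * depth + rep_seed)
                shared = {f"s{i}": 1 + int(c) for i, c in
                          enumerate(g.multinomial(depth // 2, np.ones(30) / 30))}
                a = rep_from_counts({**shared, **{f"a{i}": 1 + int(c) for i, c in
                    enumerate(g.multinomial(depth // 2, np.ones(50) / 50))}})
                b = rep_from_counts({**shared, **{f"b{i}": 1 + int(c) for i, c in
                    enumerate(g.multinomial(depth // 2, np.ones(50) / 50))}})
                full = morisita_horn(a, b)
                sub = morisita_horn(downsample(a, g), downsample(b, g))
                errs.append(abs(full - sub))
            deltas[depth] = np.mean(errs)
        assert deltas[200_000] < deltas[2000]


class TestOverlapTable:
    def test_disjoint_is_empty(self):
        t = overlap_table(rep_from_counts({"a": 1}), rep_from_counts({"b": 1}))
        assert len(t) == 0

    def test_identical_repertoires(self):
        rep = rep_from_counts({"a": 3, "b": 1})
        t = overlap_table(rep, rep)
        assert len(t) == 2
        np.testing.assert_allclose(t["freq_a_pct"], t["freq_b_pct"])

    def test_percent_frequencies(self):
        a = rep_from_counts({"c1": 2, "c2": 2})
        b = rep_from_counts({"c1": 1, "c2": 1, "c3": 2})
        t = overlap_table(a, b)
        row = t[t["cdr3_nt"] == "c1"].iloc[0]
        assert row["freq_a_pct"] == pytest.approx(50.0)
        assert row["freq_b_pct"] == pytest.approx(25.0)


class TestRegression:
    def test_proportional_frequencies_give_r2_one(self):
        a = rep_from_counts({"a": 10, "b": 20, "c": 40})
        b = rep_from_counts({"a": 5, "b": 10, "c": 20})
        fit = overlap_regression(overlap_table(a, b))
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_two_points_determine_a_line(self):
        a = rep_from_counts({"a": 1, "b": 3})
        b = rep_from_counts({"a": 2, "b": 1})
        fit = overlap_regression(overlap_table(a, b))
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_independent_frequencies_give_low_r2(self):
        rng = np.random.default_rng(7)
        a = rep_from_counts({f"c{i}": int(c) for i, c in
                             enumerate(rng.integers(1, 1000, size=100))})
        b = rep_from_counts({f"c{i}": int(c) for i, c in
                             enumerate(rng.integers(1, 1000, size=100))})
        fit = overlap_regression(overlap_table(a, b), transform="log10")
        assert fit.r_squared < 0.1

    def test_insufficient_points(self):
        a = rep_from_counts({"a": 1})
        with pytest.raises(InsufficientDataError):
            overlap_regression(overlap_table(a, a))


class TestTopN:
    def test_single_most_frequent(self):
        rep = rep_from_counts({"a": 1, "b": 9})
        assert top_n(rep, 1)["cdr3_nt"].tolist() == ["b"]

    def test_n_larger_than_repertoire(self):
        rep = rep_from_counts({"a": 1, "b": 9})
        assert len(top_n(rep, 20)) == 2

    def test_tie_break_is_lexicographic(self):
        rep = rep_from_counts({"e": 5, "d": 4, "c": 3, "b": 3, "a": 1})
        assert top_n(rep, 4)["cdr3_nt"].tolist() == ["e", "d", "b", "c"]


class TestRelativeIntersection:
    def test_superset_and_disjoint(self):
        rep = rep_from_counts({f"c{i}": i + 1 for i in range(20)})
        other_sup = rep_from_counts({f"c{i}": 1 for i in range(25)})
        other_dis = rep_from_counts({f"x{i}": 1 for i in range(5)})
        top = top_n(rep, 20)
        assert relative_intersection(top, other_sup) == 100.0
        assert relative_intersection(top, other_dis) == 0.0

    def test_eleven_of_twenty(self):
        rep = rep_from_counts({f"c{i}": 21 - i for i in range(20)})
        other = rep_from_counts({f"c{i}": 1 for i in range(11)})
        assert relative_intersection(top_n(rep, 20), other) == pytest.approx(55.0)

    def test_monotone_in_other_repertoire(self, rng):
        rep = random_rep(rng, 30)
        top = top_n(rep, 10)
        small = rep_from_counts({"c0": 1, "c1": 1})
        big = rep_from_counts({f"c{i}": 1 for i in range(40)})
        assert (relative_intersection(top, big)
                >= relative_intersection(top, small))


def brute_force_sharing(sets):
    union = set().union(*sets.values())
    counts = {k: 0 for k in range(1, len(sets) + 1)}
    for clone in union:
        k = sum(clone in s for s in sets.values())
        counts[k] += 1
    return counts


class TestSharing:
    def test_hand_example(self):
        sets = {"m1": {"a", "b"}, "m2": {"b", "c"}, "m3": {"b", "d"}}
        table = sharing_counts(sets)
        assert table.counts == {1: 3, 2: 0, 3: 1}
        assert table.members[3] == ["b"]

    def test_identical_and_disjoint_sets(self):
        same = {f"m{i}": {"a", "b", "c"} for i in range(3)}
        assert sharing_counts(same).counts == {1: 0, 2: 0, 3: 3}
        disjoint = {"m1": {"a"}, "m2": {"b"}, "m3": {"c"}}
        assert sharing_counts(disjoint).counts == {1: 3, 2: 0, 3: 0}

    def test_conservation_against_brute_force(self, rng):
        for _ in range(25):
            sets = {f"m{i}": set(rng.choice(30, size=rng.integers(1, 20),
                                            replace=False).tolist())
                    for i in range(3)}
            table = sharing_counts(sets)
            assert table.counts == brute_force_sharing(sets)
            assert sum(table.counts.values()) == len(set().union(*sets.values()))

    def test_segment_breakdown_sums_match(self):
        sets = {"m1": {("x", "TRBV3", "TRBJ1-1"), ("y", "TRBV2", "TRBJ1-1")},
                "m2": {("x", "TRBV3", "TRBJ1-1")}}
        table = sharing_counts(sets)
        for k, count in table.counts.items():
            assert sum(table.segment_breakdown[k].values()) == count
        assert table.segment_breakdown[2] == {"TRBV3": 1}

    def test_venn_three_sets(self):
        sets = {"m1": {"a", "b"}, "m2": {"b", "c"}, "m3": {"b", "d"}}
        regions = venn3_counts(sets)
        assert regions == {"100": 1, "010": 1, "001": 1, "110": 0,
                           "101": 0, "011": 0, "111": 1}
        assert sum(regions.values()) == 4


class TestGroupSummary:
    def test_exact_mann_whitney_maximal_separation(self):
        groups = {"hi": [0.4, 0.5, 0.45], "lo": [0.1, 0.15, 0.12]}
        res = mhi_group_summary(groups, alternative="greater")
        assert res["test"]["statistic"] == 9.0
        assert res["test"]["p_value"] == pytest.approx(0.05)
        assert res["test"]["method"] == "exact"

    def test_identical_groups_p_one(self):
        groups = {"a": [0.4, 0.5, 0.45], "b": [0.4, 0.5, 0.45]}
        res = mhi_group_summary(groups)
        assert res["test"]["p_value"] == pytest.approx(1.0)

    def test_three_identical_groups_h_zero(self):
        groups = {g: [0.4, 0.5, 0.45] for g in "abc"}
        res = mhi_group_summary(groups)
        assert res["test"]["name"] == "kruskal-wallis"
        assert res["test"]["statistic"] == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_group_is_an_error(self):
        with pytest.raises(InsufficientDataError):
            mhi_group_summary({"a": [0.4], "b": [0.1, 0.2]})


class TestPairOverlapResult:
    def test_invariants_on_random_pair(self, rng):
        a = random_rep(rng, 30)
        b = random_rep(rng, 30)
        res = compute_pair_overlap(a, b, n_top=10)
        assert 0.0 <= res.mhi <= 1.0
        assert res.top_n_shared <= res.top_n
        assert res.n_shared >= res.top_n_shared
        assert 0.0 <= res.relative_intersection_pct <= 100.0

    def test_key_mode_mismatch_rejected(self):
        from tcroverlap import ConfigurationError
        a = rep_from_counts({"a": 1})
        b = rep_from_counts({"a": 1}, key_mode=KeyMode.NT_ONLY)
        with pytest.raises(ConfigurationError):
            morisita_horn(a, b)
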