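"""Clonotype aggregation and the two-stage filter chain."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tcroverlap import (ClonotypeRecord, DataInconsistencyError, KeyMode,
                        aggregate, annotation_filter, median_abundance_filter,
                        merge_repertoires)

from .conftest import make_records, rep_from_counts


class TestAggregate:
    def test_equal_keys_merge_counts(self):
        recs = make_records({"X": 2}) + make_records({"X": 3})
        rep = aggregate(recs)
        assert rep.n_unique == 1
        assert rep.clonotypes["read_count"].iloc[0] == 5
        assert rep.clonotypes["frequency"].iloc[0] == 1.0

    def test_key_mode_semantics(self):
        recs = (make_records({"X": 2}, v_call="TRBV3")
                + make_records({"X": 3}, v_call="TRBV2"))
        assert aggregate(recs, KeyMode.NT_VJ).n_unique == 2
        assert aggregate(recs, KeyMode.NT_ONLY).n_unique == 1

    def test_empty_input_gives_empty_repertoire(self):
        rep = aggregate([])
        assert rep.is_empty and rep.n_total_reads == 0

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.permutations(list(range(8))))
    def test_order_invariance(self, order):
        base = (make_records({"A": 3, "B": 1, "C": 7}, v_call="TRBV3")
                + make_records({"A": 2, "D": 5}, v_call="TRBV2")
                + make_records({"B": 4, "E": 1, "C": 2}, v_call="TRBV3"))
        shuffled = [base[i] for i in order]
        ref = aggregate(base).clonotypes
        got = aggregate(shuffled).clonotypes
        assert got.equals(ref)

    def test_split_merge_equals_whole(self, rng):
        labels = [f"c{i}" for i in range(40)]
        recs = []
        for _ in range(120):
            lab = labels[rng.integers(len(labels))]
            recs.append(ClonotypeRecord(lab, "", "TRBV3", "TRBJ2-5",
                                        int(rng.integers(1, 50)), True))
        whole = aggregate(recs).clonotypes
        cut = sorted(rng.choice(len(recs), size=2, replace=False))
        parts = [aggregate(recs[:cut[0]]), aggregate(recs[cut[0]:cut[1]]),
                 aggregate(recs[cut[1]:])]
        merged = merge_repertoires(parts).clonotypes
        assert merged.equals(whole)


class TestAnnotationFilter:
    def test_keeps_productive_with_copy_ge_2(self):
        rep = rep_from_counts({"A": 5, "B": 1, "C": 4},
                              productive={"A": True, "B": True, "C": False})
        out = annotation_filter(rep)
        assert set(out.clonotypes["cdr3_nt"]) == {"A"}
        assert out.clonotypes["frequency"].iloc[0] == 1.0
        assert out.filter_log[-1].rule == "annotation_filter"
        assert (out.filter_log[-1].n_before, out.filter_log[-1].n_after) == (3, 1)

    def test_identity_when_all_pass(self):
        rep = rep_from_counts({"A": 5, "B": 3})
        out = annotation_filter(rep)
        assert out.clonotypes[["cdr3_nt", "read_count", "frequency"]].equals(
            rep.clonotypes[["cdr3_nt", "read_count", "frequency"]])

    def test_idempotent(self):
        rep = rep_from_counts({"A": 5, "B": 1, "C": 2})
        once = annotation_filter(rep)
        twice = annotation_filter(once)
        assert twice.clonotypes.equals(once.clonotypes)

    def test_empty_survivor_set_logged_not_error(self):
        rep = rep_from_counts({"A": 1, "B": 1})
        out = annotation_filter(rep)
        assert out.is_empty
        assert out.filter_log[-1].n_after == 0

    def test_mixed_productive_flags_rejected(self):
        recs = (make_records({"X": 2}, productive=True)
                + make_records({"X": 3}, productive=False))
        with pytest.raises(DataInconsistencyError):
            annotation_filter(aggregate(recs))


class TestMedianFilter:
    @pytest.mark.parametrize("counts,survivors", [
        ({"a": 5, "b": 4, "c": 3, "d": 2, "e": 2}, {"a", "b"}),  # median 3, strict
        ({"a": 2, "b": 2, "c": 2}, set()),                       # all at the median
        ({"a": 10}, set()),                                      # singleton boundary
        ({"a": 9, "b": 5, "c": 3, "d": 1}, {"a", "b"}),          # even n, midpoint 4
    ])
    def test_strictly_above_median(self, counts, survivors):
        out = median_abundance_filter(rep_from_counts(counts))
        assert set(out.clonotypes["cdr3_nt"]) == survivors
        assert out.filter_log[-1].n_after == len(survivors)

    def test_not_idempotent(self):
        rep = rep_from_counts({"a": 5, "b": 4, "c": 3, "d": 2, "e": 1})
        once = median_abundance_filter(rep)
        twice = median_abundance_filter(once)
        assert set(once.clonotypes["cdr3_nt"]) == {"a", "b"}
        assert set(twice.clonotypes["cdr3_nt"]) == {"a"}

    def test_empty_input_passes_through(self):
        out = median_abundance_filter(rep_from_counts({}))
        assert out.is_empty
        assert out.filter_log[-1].rule == "median_abundance_filter"


class TestFilterInvariants:
    def test_filters_only_remove_and_preserve_proportions(self, rng):
        counts = {f"c{i}": int(c) for i, c in enumerate(rng.integers(1, 60, size=40))}
        rep = rep_from_counts(counts)
        for out in (annotation_filter(rep), median_abundance_filter(rep)):
            kept = set(out.clonotypes["cdr3_nt"])
            assert kept <= set(rep.clonotypes["cdr3_nt"])
            if not out.is_empty:
                np.testing.assert_allclose(out.clonotypes["frequency"].sum(), 1.0,
                                           atol=1e-9)
                merged = out.clonotypes.merge(rep.clonotypes, on="cdr3_nt",
                                              suffixes=("_f", "_r"))
                ratio = merged["frequency_f"] / merged["frequency_r"]
                np.testing.assert_allclose(ratio, ratio.iloc[0])
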