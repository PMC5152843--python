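import math
import random

import pytest

from glyccomp import (
    SampleTable,
    all_presence_filter,
    compare,
    compare_tables,
    merge_adduct_groups,
    read_comparison,
    write_comparison,
)
from glyccomp.comparator import sort_key

from conftest import make_record, random_instance, rows_to_tables, write_tsv
from oracles import naive_compare, table1_simulator


def results_as_dict(results):
    return {
        r.key: {l: (s.score, s.total_volume) for l, s in r.per_sample.items()}
        for r in results
    }


class TestAllPresenceFilter:
    LABELS = {"a", "b", "c"}

    def test_key_in_all_labels_survives_key_in_two_deleted(self):
        records = [
            make_record("a", "[1,1,2,0,1]"),
            make_record("b", "[1,1,2,0,1]"),
            make_record("c", "[1,1,2,0,1]"),
            make_record("a", "[0,1,2,0,3]"),
            make_record("b", "[0,1,2,0,3]"),
        ]
        kept = all_presence_filter(records, self.LABELS)
        assert [r.sample_label for r in kept] == ["a", "b", "c"]

    def test_four_rows_over_three_labels_all_retained(self):
        # >=3 rows AND from 3 distinct samples: every adduct row survives
        records = [
            make_record("a", "[1,1,2,0,1] 0NH3"),
            make_record("a", "[1,1,2,0,1] 2NH3"),
            make_record("b", "[1,1,2,0,1]"),
            make_record("c", "[1,1,2,0,1] 1NH3"),
        ]
        assert len(all_presence_filter(records, self.LABELS)) == 4

    def test_three_rows_in_two_labels_deleted(self):
        # row count alone is not enough: distinct sample labels are required
        records = [
            make_record("a", "[1,1,2,0,1]"),
            make_record("a", "[1,1,2,0,1] 1NH3"),
            make_record("b", "[1,1,2,0,1]"),
        ]
        assert all_presence_filter(records, self.LABELS) == []

    def test_empty_input(self):
        assert all_presence_filter([], self.LABELS) == []

    def test_record_outside_label_set_is_an_error(self):
        with pytest.raises(ValueError, match="outside"):
            all_presence_filter([make_record("z", "[1,1,2,0,1]")], self.LABELS)

    def test_order_preserved(self):
        records = [
            make_record(l, k)
            for k in ("[1,1,2,0,1]", "[0,1,2,0,3]")
            for l in ("c", "a", "b")
        ]
        kept = all_presence_filter(records, self.LABELS)
        assert [id(r) for r in kept] == [id(r) for r in records]

    def test_monotone_in_sample_count(self, rng):
        # removing one sample can only grow or preserve the retained key set
        for _ in range(50):
            rows, labels = random_instance(rng)
            if len(labels) < 3:
                continue
            from glyccomp import extract_key

            records = [make_record(l, c, s, v) for l, c, s, v in rows]
            full = {
                extract_key(r.compound_key_raw)
                for r in all_presence_filter(records, set(labels))
            }
            dropped = set(labels[:-1])
            fewer = {
                extract_key(r.compound_key_raw)
                for r in all_presence_filter(
                    [r for r in records if r.sample_label in dropped], dropped
                )
            }
            assert full <= fewer


class TestMergeAdductGroups:
    def test_max_score_sum_volume(self):
        records = [
            make_record("L1", "[1,4,5,2,7] 0NH3", 0.3, 100.0),
            make_record("L1", "[1,4,5,2,7] 2NH3", 0.5, 200.0),
        ]
        (result,) = merge_adduct_groups(records)
        assert result.key == "[1,4,5,2,7]"
        assert result.per_sample["L1"].score == 0.5
        assert result.per_sample["L1"].total_volume == 300.0

    def test_single_row_identity(self):
        records = [make_record("L1", "[1,4,5,2,7]", 0.42, 77.0, {"rt": "3.2"})]
        (result,) = merge_adduct_groups(records)
        assert result.per_sample["L1"] .score == 0.42
        assert result.per_sample["L1"].total_volume == 77.0
        assert result.per_sample["L1"].extras == {"rt": "3.2"}

    def test_extras_come_from_max_score_row(self):
        records = [
            make_record("L1", "[1,4,5,2,7]", 0.3, 1.0, {"rt": "low"}),
            make_record("L1", "[1,4,5,2,7]", 0.9, 2.0, {"rt": "high"}),
            make_record("L1", "[1,4,5,2,7]", 0.5, 3.0, {"rt": "mid"}),
        ]
        (result,) = merge_adduct_groups(records)
        assert result.per_sample["L1"].extras == {"rt": "high"}

    def test_permutation_invariant(self, rng):
        base = [
            make_record("L1", "[1,4,5,2,7]", round(rng.random(), 3), float(i + 1))
            for i in range(6)
        ] + [
            make_record("L2", "[1,4,5,2,7]", round(rng.random(), 3), float(i + 1))
            for i in range(4)
        ]
        want = results_as_dict(merge_adduct_groups(base))
        for _ in range(10):
            shuffled = base[:]
            rng.shuffle(shuffled)
            assert results_as_dict(merge_adduct_groups(shuffled)) == want

    def test_inconsistent_coverage_is_internal_error(self):
        records = [
            make_record("a", "[1,1,2,0,1]"),
            make_record("b", "[1,1,2,0,1]"),
            make_record("a", "[0,1,2,0,3]"),
        ]
        with pytest.raises(RuntimeError, match="all-presence"):
            merge_adduct_groups(records)

    def test_results_sorted_by_dp_then_tuple(self):
        records = [
            make_record(l, k)
            for l in ("a", "b")
            for k in ("[1,4,5,2,7]", "[1,2,3,1,4]", "[0,2,3,0,2]")
        ]
        merged = merge_adduct_groups(records)
        assert [r.key for r in merged] == [
            "[0,2,3,0,2]", "[1,2,3,1,4]", "[1,4,5,2,7]",
        ]
        assert [r.dp for r in merged] == [5, 6, 10]


class TestOracleEquivalence:
    def test_matches_naive_and_literal_simulator(self, rng):
        for _ in range(300):
            rows, labels = random_instance(rng)
            tables = rows_to_tables(rows, labels)
            got = results_as_dict(compare_tables(tables))

            want = naive_compare(rows, labels)
            assert {k: {l: v for l, v in d.items()} for k, d in got.items()} == want

            # literal spreadsheet loop on the filtered, key-extracted rows;
            # pooled order is label-blocked, as copying sheet after sheet
            # into one total sheet produces
            from glyccomp import extract_key

            retained = [
                (l, extract_key(c), s, v)
                for label in labels
                for l, c, s, v in rows
                if l == label and extract_key(c) in want
            ]
            sim = table1_simulator(retained)
            flat_got = {
                (k, l): v for k, d in got.items() for l, v in d.items()
            }
            assert flat_got == sim

    def test_conservation_exact(self, rng):
        for _ in range(100):
            rows, labels = random_instance(rng)
            got = results_as_dict(compare_tables(rows_to_tables(rows, labels)))
            from glyccomp import extract_key

            for key, by_label in got.items():
                for label, (_, volume) in by_label.items():
                    brute = sum(
                        v for l, c, _, v in rows
                        if l == label and extract_key(c) == key
                    )
                    assert volume == brute  # integer volumes: exact


class TestCompare:
    def _write_replicates(self, tmp_path, per_label_rows):
        paths = []
        for label, rows in per_label_rows.items():
            paths.append(write_tsv(tmp_path / f"{label}.txt", rows))
        return paths

    def test_two_identical_files_distinct_labels(self, tmp_path):
        rows = [("[1,2,3,0,4] 1NH3", 0.5, 100), ("[1,2,3,0,4]", 0.9, 50),
                ("[0,1,2,0,1]", 0.2, 10), ("", 0.0, 5)]
        paths = self._write_replicates(tmp_path, {"l1": rows, "l2": rows})
        results = compare(paths)
        assert {r.key for r in results} == {"[1,2,3,0,4]", "[0,1,2,0,1]"}
        for r in results:
            assert (
                r.per_sample["l1"].total_volume == r.per_sample["l2"].total_volume
            )

    def test_fewer_than_two_paths_rejected(self, tmp_path):
        path = write_tsv(tmp_path / "only.txt", [("[1,2,3,0,4]", 0.5, 1)])
        with pytest.raises(ValueError, match="at least 2"):
            compare([path])

    def test_min_score_prefilter(self, tmp_path):
        rows_hi = [("[1,2,3,0,4]", 0.5, 100)]
        rows_lo = [("[1,2,3,0,4]", 0.05, 100)]
        paths = self._write_replicates(tmp_path, {"l1": rows_hi, "l2": rows_lo})
        assert compare(paths, min_score=0.1) == []
        assert len(compare(paths)) == 1

    def test_mismatched_label_count_rejected(self, tmp_path):
        rows = [("[1,2,3,0,4]", 0.5, 100)]
        paths = self._write_replicates(tmp_path, {"l1": rows, "l2": rows})
        with pytest.raises(ValueError, match="labels"):
            compare(paths, labels=["only_one"])


class TestComparisonRoundTrip:
    def test_write_read_round_trip(self, tmp_path):
        records = [
            make_record(l, k, s, v)
            for l in ("a", "b")
            for k, s, v in [("[1,2,3,0,4]", 0.25, 10.5), ("[1,4,5,2,7]", 0.5, 3.0)]
        ]
        results = merge_adduct_groups(records)
        path = tmp_path / "merged.tsv"
        write_comparison(results, path)
        back = read_comparison(path)
        assert results_as_dict(back) == results_as_dict(results)
        assert [r.key for r in back] == [r.key for r in results]

    def test_sort_key_orders_by_dp_first(self):
        keys = ["[1,4,5,2,7]", "[0,1,2,0,1]", "[1,2,3,1,4]"]
        assert sorted(keys, key=sort_key) == [
            "[0,1,2,0,1]", "[1,2,3,1,4]", "[1,4,5,2,7]",
        ]
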