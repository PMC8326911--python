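"""Count-table I/O, validation and transform contracts."""

import numpy as np
import pytest

from metaneutral import (
    GroupDesign,
    OtuTable,
    OtuTableError,
    filter_singletons,
    read_biom_json,
    read_group_metadata,
    read_otu_tsv,
    relative_abundance,
    split_by_group,
    write_table,
)
from conftest import random_table


class TestOtuTable:
    def test_shape_and_ids(self, tiny_table):
        assert tiny_table.counts.shape == (3, 2)
        assert tiny_table.n_taxa == 3 and tiny_table.n_samples == 2

    def test_duplicate_taxon_id_rejected(self):
        with pytest.raises(OtuTableError, match="duplicate taxon"):
            OtuTable(np.ones((2, 1), dtype=int), ("a", "a"), ("s",))

    def test_duplicate_sample_id_rejected(self):
        with pytest.raises(OtuTableError, match="duplicate sample"):
            OtuTable(np.ones((1, 2), dtype=int), ("a",), ("s", "s"))

    def test_negative_count_rejected(self):
        with pytest.raises(OtuTableError, match="negative"):
            OtuTable(np.array([[1, -2]]), ("a",), ("s1", "s2"))

    def test_fractional_count_rejected(self):
        with pytest.raises(OtuTableError, match="non-integer"):
            OtuTable(np.array([[1.5, 2.0]]), ("a",), ("s1", "s2"))

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(OtuTableError, match="does not match"):
            OtuTable(np.ones((2, 2), dtype=int), ("a",), ("s1", "s2"))


class TestTsvRoundTrip:
    def test_identity_round_trip(self, tiny_table, tmp_path):
        path = tmp_path / "t.tsv"
        write_table(tiny_table, path)
        assert path.read_text().splitlines()[0].startswith("#OTU_ID")
        assert read_otu_tsv(path) == tiny_table

    def test_random_round_trips(self, rng, tmp_path):
        for k in range(5):
            table = random_table(rng)
            path = tmp_path / f"r{k}.tsv"
            write_table(table, path)
            assert read_otu_tsv(path) == table

    def test_orientation_transpose(self, tiny_table, tmp_path):
        path = tmp_path / "t.tsv"
        write_table(tiny_table, path)
        flipped = read_otu_tsv(path, orientation="samples-rows")
        assert flipped.counts.shape == (2, 3)
        assert flipped.taxon_ids == tiny_table.sample_ids

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_otu_tsv(tmp_path / "absent.tsv")

    def test_fractional_count_in_file(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("#OTU_ID\ts1\nA\t1.5\n")
        with pytest.raises(OtuTableError, match="fractional"):
            read_otu_tsv(path)

    def test_non_numeric_count_named_with_location(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("#OTU_ID\ts1\nA\t3\nB\txyz\n")
        with pytest.raises(OtuTableError, match="line 3"):
            read_otu_tsv(path)


def test_biom_json_reader(tmp_path, tiny_table):
    import json

    doc = {
        "format": "Biological Observation Matrix 1.0.0",
        "matrix_type": "sparse",
        "shape": [3, 2],
        "rows": [{"id": t} for t in tiny_table.taxon_ids],
        "columns": [{"id": s} for s in tiny_table.sample_ids],
        "data": [
            [i, j, int(v)]
            for (i, j), v in np.ndenumerate(tiny_table.counts)
            if v
        ],
    }
    path = tmp_path / "t.biom"
    path.write_text(json.dumps(doc))
    assert read_biom_json(path) == tiny_table


class TestFilterSingletons:
    def test_direct_rule(self):
        # taxon totals {1, 2, 1, 7} -> keep {2, 7}
        counts = np.array([[1, 0], [1, 1], [0, 1], [3, 4]])
        table = OtuTable(counts, ("a", "b", "c", "d"), ("s1", "s2"))
        out = filter_singletons(table)
        assert out.taxon_ids == ("b", "d")
        assert list(out.taxon_totals) == [2, 7]

    def test_no_singletons_identity(self, tiny_table):
        # tiny_table totals are 2, 4, 9: nothing removed
        assert filter_singletons(tiny_table) == tiny_table

    def test_planted_singletons_removed_exactly(self, rng):
        for _ in range(5):
            table = random_table(rng, n_taxa=40)
            expected_removed = int((table.taxon_totals == 1).sum())
            out = filter_singletons(table)
            assert table.n_taxa - out.n_taxa == expected_removed
            assert np.all(out.taxon_totals != 1)

    def test_all_singletons_warns(self):
        table = OtuTable(np.array([[1], [1]]), ("a", "b"), ("s",))
        with pytest.warns(UserWarning, match="singleton"):
            out = filter_singletons(table)
        assert out.n_taxa == 0


class TestRelativeAbundance:
    def test_arithmetic(self):
        table = OtuTable(np.array([[2], [3], [5]]), ("a", "b", "c"), ("s",))
        assert np.allclose(relative_abundance(table)[:, 0], [0.2, 0.3, 0.5])

    def test_one_taxon_normalizes_to_one(self):
        table = OtuTable(np.array([[7, 2]]), ("a",), ("s1", "s2"))
        assert np.allclose(relative_abundance(table), 1.0)

    def test_columns_sum_to_one(self, rng):
        for _ in range(5):
            rel = relative_abundance(random_table(rng))
            assert np.allclose(rel.sum(axis=0), 1.0, atol=1e-12)

    def test_zero_column_names_sample(self):
        table = OtuTable(np.array([[1, 0]]), ("a",), ("s1", "empty"))
        with pytest.raises(OtuTableError, match="empty"):
            relative_abundance(table)


class TestGroupDesign:
    def test_sizes_derived(self):
        design = GroupDesign({"a": "X", "b": "X", "c": "Y"})
        assert design.group_sizes == {"X": 2, "Y": 1}
        assert design.samples_in("X") == ("a", "b")

    def test_inconsistent_sizes_rejected(self):
        with pytest.raises(OtuTableError, match="inconsistent"):
            GroupDesign({"a": "X"}, {"X": 2})

    def test_empty_group_label_rejected(self):
        with pytest.raises(OtuTableError, match="empty group"):
            GroupDesign({"a": ""})


class TestSplitByGroup:
    def test_partition_sizes(self):
        counts = np.arange(10).reshape(2, 5)
        table = OtuTable(counts, ("a", "b"), tuple(f"s{i}" for i in range(5)))
        design = GroupDesign({"s0": "A", "s1": "A", "s2": "A", "s3": "B", "s4": "B"})
        parts = split_by_group(table, design)
        assert parts["A"].n_samples == 3 and parts["B"].n_samples == 2
        assert parts["A"].taxon_ids == table.taxon_ids

    def test_unassigned_sample_rejected(self, tiny_table):
        with pytest.raises(OtuTableError, match="without group"):
            split_by_group(tiny_table, GroupDesign({"s1": "A"}))

    def test_reassembly_recovers_table(self, rng):
        table = random_table(rng, n_samples=6)
        labels = ["A", "A", "B", "B", "B", "C"]
        design = GroupDesign(dict(zip(table.sample_ids, labels)))
        parts = split_by_group(table, design)
        rebuilt = {}
        for part in parts.values():
            for j, s in enumerate(part.sample_ids):
                rebuilt[s] = part.counts[:, j]
        assert set(rebuilt) == set(table.sample_ids)
        for j, s in enumerate(table.sample_ids):
            assert np.array_equal(rebuilt[s], table.counts[:, j])


def test_cross_group_singleton_filter_order():
    """A taxon with one read in each of two groups (total 2) survives
    global-first filtering but would be dropped by per-part filtering —
    the pipeline always filters on the full table first."""
    counts = np.array([[1, 1, 0], [0, 3, 2], [5, 5, 5]])
    table = OtuTable(counts, ("cross", "b", "c"), ("s1", "s2", "s3"))
    design = GroupDesign({"s1": "A", "s2": "B", "s3": "B"})
    global_first = split_by_group(filter_singletons(table), design)
    assert "cross" in global_first["A"].taxon_ids
    per_part = {
        g: filter_singletons(t) for g, t in split_by_group(table, design).items()
    }
    assert "cross" not in per_part["A"].taxon_ids
    assert "cross" not in per_part["B"].taxon_ids


def test_group_metadata_reader(tmp_path):
    path = tmp_path / "meta.tsv"
    path.write_text("sample_id\tgroup\ns1\tnormal\ns2\tbenign\n")
    design = read_group_metadata(path)
    assert design.assignment == {"s1": "normal", "s2": "benign"}
    bad = tmp_path / "bad.tsv"
    bad.write_text("sample\tgroup\ns1\tnormal\n")
    with pytest.raises(OtuTableError, match="sample_id"):
        read_group_metadata(bad)
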