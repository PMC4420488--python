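"""Reference-pool loading, zero-mismatch annotation and normalization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ligbias import (
    annotate_reads,
    average_replicates,
    load_reference_pool,
    normalize,
    pool_from_sequences,
)
from ligbias.annotate import CountTable
from ligbias.pool import load_concentrations


def _write_fasta(path, records):
    path.write_text("".join(f">{i}\n{s}\n" for i, s in records))


class TestLoadReferencePool:
    def test_loads_unique_records_with_default_concentration(self, tmp_path):
        fa = tmp_path / "pool.fasta"
        _write_fasta(fa, [("a", "ACGT"), ("b", "GGGC"), ("c", "UUUA")])
        pool = load_reference_pool(fa)
        assert len(pool) == 3
        assert pool.sequences["a"] == "ACGU"  # T->U applied
        assert all(c == 1.0 for c in pool.concentrations.values())

    def test_duplicate_sequences_rejected_naming_both_ids(self, tmp_path):
        fa = tmp_path / "pool.fasta"
        _write_fasta(fa, [("a", "ACGU"), ("b", "ACGU")])
        with pytest.raises(ValueError, match="a and b"):
            load_reference_pool(fa)

    def test_concentrations_read_from_tsv(self, tmp_path):
        fa = tmp_path / "pool.fasta"
        _write_fasta(fa, [("a", "ACGU"), ("b", "GGGC"), ("c", "UUUA")])
        tsv = tmp_path / "conc.tsv"
        tsv.write_text("a\t1\nb\t1\nc\t2\n")
        pool = load_reference_pool(fa, tsv)
        assert pool.concentrations == {"a": 1.0, "b": 1.0, "c": 2.0}

    def test_unknown_tsv_id_and_empty_fasta_and_bad_alphabet(self, tmp_path):
        fa = tmp_path / "pool.fasta"
        _write_fasta(fa, [("a", "ACGU")])
        with pytest.raises(ValueError, match="not in FASTA"):
            load_reference_pool(fa, {"zzz": 1.0})
        empty = tmp_path / "empty.fasta"
        empty.write_text("")
        with pytest.raises(ValueError, match="no FASTA records"):
            load_reference_pool(empty)
        bad = tmp_path / "bad.fasta"
        _write_fasta(bad, [("a", "ACXU")])
        with pytest.raises(ValueError, match="non-ACGU"):
            load_reference_pool(bad)

    def test_concentration_tsv_parser_skips_header(self, tmp_path):
        tsv = tmp_path / "c.tsv"
        tsv.write_text("id\tconcentration\nm1\t2.5\n")
        assert load_concentrations(tsv) == {"m1": 2.5}


class TestAnnotate:
    def test_exact_full_length_matches_only(self):
        pool = pool_from_sequences({"m1": "ACGU"})
        ct = annotate_reads(["ACGU", "GGGG", "ACGU"], pool)
        assert ct.counts == {"m1": 2}
        assert ct.unannotated == 1

    def test_trailing_extra_base_is_unannotated(self):
        pool = pool_from_sequences({"m1": "ACGU"})
        ct = annotate_reads(["ACGUA"], pool)
        assert ct.counts["m1"] == 0 and ct.unannotated == 1

    def test_empty_read_set_gives_zero_counts(self, small_pool):
        ct = annotate_reads([], small_pool)
        assert ct.total_reads == 0
        assert all(v == 0 for v in ct.counts.values())

    def test_dna_alphabet_reads_match_after_mapping(self):
        pool = pool_from_sequences({"m1": "ACGU"})
        assert annotate_reads(["ACGT"], pool).counts["m1"] == 1


class TestNormalize:
    def test_factor_is_annotated_reads_per_unique_sequence(self):
        # the defined-pool study floor: 143,900 annotated reads over 962
        # unique sequences is a ~149.6x factor (at least 149-fold coverage)
        assert 143_900 / 962 == pytest.approx(149.58, abs=0.01)
        pool = pool_from_sequences({"m1": "ACGU", "m2": "GGGC"})
        nt = normalize(CountTable({"m1": 300, "m2": 100}), pool)
        assert nt.normalization_factor == 200
        assert nt.normalized_reads.tolist() == [1.5, 0.5]

    def test_non_equimolar_expected_values_have_mean_one(self):
        pool = pool_from_sequences(
            {"a": "ACGU", "b": "GGGC", "c": "UUUA"},
            concentrations={"a": 1, "b": 1, "c": 2},
        )
        nt = normalize(CountTable({"a": 1, "b": 1, "c": 2}), pool)
        assert nt.expected.tolist() == [0.75, 0.75, 1.5]
        assert nt.expected.mean() == pytest.approx(1.0)

    def test_zero_annotated_reads_is_an_error(self, small_pool):
        with pytest.raises(ValueError, match="no annotated reads"):
            normalize(CountTable({i: 0 for i in small_pool.ids}), small_pool)

    @given(
        counts=st.lists(st.integers(min_value=0, max_value=10_000), min_size=2, max_size=30)
    )
    @settings(max_examples=50, deadline=None)
    def test_normalization_closure(self, counts):
        """Mean normalized reads over the pool is exactly 1 for any counts."""
        if sum(counts) == 0:
            counts[0] = 1
        pool = pool_from_sequences(
            {f"s{i}": "ACGU" + "A" * (i + 1) for i in range(len(counts))}
        )
        ct = CountTable(dict(zip(pool.ids, counts)), unannotated=3)
        assert ct.total_reads == sum(counts) + 3  # conservation
        nt = normalize(ct, pool)
        assert nt.normalized_reads.mean() == pytest.approx(1.0, abs=1e-9)
        assert nt.expected.mean() == pytest.approx(1.0, abs=1e-9)


class TestAverageReplicates:
    def test_mean_of_normalized_reads(self):
        pool = pool_from_sequences({"m1": "ACGU", "m2": "GGGC"})
        t1 = normalize(CountTable({"m1": 100, "m2": 100}), pool)
        t2 = normalize(CountTable({"m1": 300, "m2": 100}), pool)
        avg = average_replicates([t1, t2])
        assert avg.normalized_reads["m1"] == pytest.approx((1.0 + 1.5) / 2)
        assert avg.normalized_reads["m2"] == pytest.approx((1.0 + 0.5) / 2)

    def test_identical_tables_unchanged(self):
        pool = pool_from_sequences({"m1": "ACGU", "m2": "GGGC"})
        t = normalize(CountTable({"m1": 10, "m2": 30}), pool)
        avg = average_replicates([t, t])
        assert (avg.normalized_reads == t.normalized_reads).all()

    def test_mismatched_id_sets_error(self):
        p1 = pool_from_sequences({"m1": "ACGU", "m2": "GGGC"})
        p2 = pool_from_sequences({"m1": "ACGU", "mX": "GGGC"})
        t1 = normalize(CountTable({"m1": 1, "m2": 1}), p1)
        t2 = normalize(CountTable({"m1": 1, "mX": 1}), p2)
        with pytest.raises(ValueError, match="different id sets"):
            average_replicates([t1, t2])

    def test_mismatched_expected_values_error(self):
        seqs = {"m1": "ACGU", "m2": "GGGC"}
        p1 = pool_from_sequences(seqs)
        p2 = pool_from_sequences(seqs, concentrations={"m1": 2, "m2": 1})
        t1 = normalize(CountTable({"m1": 1, "m2": 1}), p1)
        t2 = normalize(CountTable({"m1": 1, "m2": 1}), p2)
        with pytest.raises(ValueError, match="expected values"):
            average_replicates([t1, t2])
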