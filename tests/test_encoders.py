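"""One-hot and structural-profile encodings against independent lookup oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hmpi.encoders import (
    DINUCLEOTIDES,
    EncodingError,
    StructuralPropertyTable,
    load_property_table,
    one_hot_encode,
    positional_profile,
    sp_encode,
    standardize_table,
)
from hmpi.sequence_io import SequenceRecord

from conftest import random_records

dna = st.text(alphabet="ACGT", min_size=2, max_size=60)


def rec(seq):
    return SequenceRecord(id="t", sequence=seq, label="x")


class TestOneHot:
    def test_acgt_is_identity(self):
        assert np.array_equal(one_hot_encode(rec("ACGT")).onehot, np.eye(4))

    def test_homopolymer(self):
        m = one_hot_encode(rec("AAAA")).onehot
        assert m[0].sum() == 4 and m[1:].sum() == 0

    @given(dna)
    @settings(max_examples=50, deadline=None)
    def test_matches_dictionary_oracle(self, seq):
        # independent per-position oracle: a plain dict lookup per base
        lut = {"A": [1, 0, 0, 0], "C": [0, 1, 0, 0], "G": [0, 0, 1, 0], "T": [0, 0, 0, 1]}
        expected = np.array([lut[b] for b in seq]).T
        assert np.array_equal(one_hot_encode(rec(seq)).onehot, expected)

    def test_column_sums_and_row_counts(self):
        for r in random_records(5, 251, seed=3):
            m = one_hot_encode(r).onehot
            assert np.array_equal(m.sum(axis=0), np.ones(251))
            counts = [r.sequence.count(b) for b in "ACGT"]
            assert m.sum(axis=1).tolist() == counts

    def test_non_acgt_names_position(self):
        with pytest.raises(EncodingError, match="position 3"):
            one_hot_encode(rec("ACNT"))


class TestStandardize:
    def test_arithmetic_oracle(self):
        # row 1..16 standardized by hand: mean 8.5, population sd of 1..16
        row = np.arange(1.0, 17.0)
        raw = np.vstack([row, row**2])  # second row breaks ties, keeps variance
        tab = StructuralPropertyTable(("p1", "p2"), raw)
        std = standardize_table(tab).std_values
        expected = (row - row.mean()) / row.std(ddof=0)
        assert np.allclose(std[0], expected)
        assert np.all(np.diff(std[0]) > 0)

    def test_rows_mean0_sd1(self, table):
        assert np.allclose(table.std_values.mean(axis=1), 0.0, atol=1e-9)
        assert np.allclose(table.std_values.std(axis=1, ddof=0), 1.0, atol=1e-9)

    def test_constant_row_errors(self):
        raw = np.vstack([np.ones(16), np.arange(16.0)])
        with pytest.raises(ValueError, match="flat"):
            standardize_table(StructuralPropertyTable(("flat", "ok"), raw))

    def test_idempotent_on_standardized_rows(self, table):
        again = standardize_table(
            StructuralPropertyTable(table.property_names, table.std_values)
        )
        assert np.allclose(again.std_values, table.std_values, atol=1e-12)


class TestSpEncode:
    def test_lookup_oracle_small(self, table):
        m = sp_encode(rec("AAT"), table).sp_matrix
        aa = table.std_values[:, DINUCLEOTIDES.index("AA")]
        at = table.std_values[:, DINUCLEOTIDES.index("AT")]
        assert np.allclose(m[:, 0], aa) and np.allclose(m[:, 1], at)

    def test_single_window(self, table):
        m = sp_encode(rec("AA"), table).sp_matrix
        assert m.shape == (12, 1)
        assert np.allclose(m[:, 0], table.std_values[:, 0])

    @given(seq=dna)
    @settings(max_examples=50, deadline=None)
    def test_matches_dictionary_oracle(self, seq, table):
        lut = {d: table.std_values[:, i] for i, d in enumerate(DINUCLEOTIDES)}
        expected = np.column_stack([lut[seq[j : j + 2]] for j in range(len(seq) - 1)])
        assert np.allclose(sp_encode(rec(seq), table).sp_matrix, expected)

    def test_entries_within_property_range(self, table):
        for r in random_records(10, 81, seed=9):
            m = sp_encode(r, table).sp_matrix
            lo = table.std_values.min(axis=1, keepdims=True)
            hi = table.std_values.max(axis=1, keepdims=True)
            assert np.all(m >= lo - 1e-12) and np.all(m <= hi + 1e-12)

    def test_reversal_is_not_columnwise_reversal(self, table):
        # dinucleotides are direction-sensitive: TG is not GT
        found_counterexample = False
        for r in random_records(20, 10, seed=13):
            fwd = sp_encode(r, table).sp_matrix
            rev = sp_encode(rec(r.sequence[::-1]), table).sp_matrix
            if not np.allclose(fwd, rev[:, ::-1]):
                found_counterexample = True
                break
        assert found_counterexample

    def test_requires_standardized_table(self, raw_table):
        with pytest.raises(ValueError, match="standardiz"):
            sp_encode(rec("ACGT"), raw_table)


class TestPositionalProfile:
    def test_single_sequence_is_own_matrix(self, table):
        r = rec("ACGTACGT")
        prof = positional_profile([r], table)
        assert np.allclose(prof.per_position_mean, sp_encode(r, table).sp_matrix)
        assert prof.n == 1

    def test_identical_sequences(self, table):
        prof = positional_profile([rec("AA"), rec("AA")], table)
        assert np.allclose(prof.per_position_mean[:, 0], table.std_values[:, 0])

    def test_uniform_background_centres_on_zero(self, table):
        # Monte-Carlo: mean of std values over the 16 dinucleotides is 0, so
        # uniform sequences give profile entries ~ N(0, sd/sqrt(n))
        recs = random_records(1000, 81, seed=21)
        prof = positional_profile(recs, table)
        se = 1.0 / np.sqrt(1000)  # each property row has population sd 1
        # union bound over the 12 x 80 entries: 5 SE keeps the false-alarm
        # probability of the max below 1e-3
        assert np.all(np.abs(prof.per_position_mean) < 5 * se)
        assert abs(prof.per_position_mean.mean()) < 3 * se

    def test_mixed_lengths_error(self, table):
        with pytest.raises(ValueError, match="mixed"):
            positional_profile([rec("ACGT"), rec("ACG")], table)


def test_bundled_table_shape_and_order(raw_table):
    assert raw_table.raw_values.shape == (12, 16)
    assert raw_table.n_properties == 12
    assert "bendability" in raw_table.property_names
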