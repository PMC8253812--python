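"""Demultiplexing, Tag filtering and trimming semantics."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from breaktag.preprocess import (
    FilterParams,
    ReadPair,
    demultiplex,
    filter_tag_reads,
    read_pairs,
    trim_and_length_filter,
    write_pairs,
)

TAG = "GTTGACATCG"


def _pair(read_id="r", seq2="", seq1=None, qual=None, barcode=""):
    seq1 = seq1 if seq1 is not None else "A" * max(len(seq2), 60)
    p = ReadPair(
        read_id,
        seq1,
        qual or "I" * len(seq1),
        seq2,
        qual or "I" * len(seq2),
    )
    p.barcode = barcode
    return p


class TestDemultiplex:
    TABLE = {"AAAA": "s1", "CCCC": "s2"}

    def test_exact_matches_route_to_samples(self):
        pairs = [_pair(f"r{i}", "ACGT" * 20, barcode="AAAA") for i in range(10)]
        pairs += [_pair(f"q{i}", "ACGT" * 20, barcode="CCCC") for i in range(10)]
        out, counts = demultiplex(pairs, self.TABLE)
        assert len(out["s1"]) == len(out["s2"]) == 10
        assert not out["undetermined"]
        assert counts.kept == 20 and counts.dropped == 0

    def test_unknown_barcode_goes_to_undetermined(self):
        out, counts = demultiplex([_pair(barcode="GGGG")], self.TABLE)
        assert len(out["undetermined"]) == 1 and counts.dropped == 1

    def test_one_mismatch_rescue_only_when_enabled(self):
        pair = [_pair(barcode="AAAT")]
        out, _ = demultiplex(pair, self.TABLE)
        assert out["undetermined"]
        out, _ = demultiplex(pair, self.TABLE, allow_one_mismatch=True)
        assert len(out["s1"]) == 1

    def test_empty_input_gives_empty_outputs(self):
        out, counts = demultiplex([], self.TABLE)
        assert all(not v for v in out.values()) and counts.total == 0

    def test_duplicate_barcode_rejected_at_load(self):
        with pytest.raises(ValueError):
            demultiplex([], {"AAAA": "s1", "AAA": "s2"})

    def test_counts_are_conserved(self):
        pairs = [_pair(barcode=b) for b in ("AAAA", "CCCC", "GGGG", "TTTT")]
        out, counts = demultiplex(pairs, self.TABLE)
        assert sum(len(v) for v in out.values()) == len(pairs) == counts.total


class TestTagFilter:
    PARAMS = FilterParams(tag_prefix=TAG, max_prefix_mismatches=1)

    def test_exact_prefix_kept_and_stripped(self):
        genomic = "ACGTACGTACGT"
        kept, counts = filter_tag_reads([_pair(seq2=TAG + genomic)], self.PARAMS)
        assert len(kept) == 1 and kept[0].seq2 == genomic
        assert len(kept[0].qual2) == len(genomic)
        assert counts.kept == 1

    def test_missing_prefix_dropped(self):
        kept, counts = filter_tag_reads([_pair(seq2="T" * 40)], self.PARAMS)
        assert not kept and counts.dropped == 1

    @given(st.integers(0, 3), st.data())
    @settings(max_examples=60, deadline=None)
    def test_mismatch_tolerance_matches_hamming_oracle(self, n_subs, data):
        positions = data.draw(
            st.lists(st.integers(0, len(TAG) - 1), min_size=n_subs,
                     max_size=n_subs, unique=True)
        )
        prefix = list(TAG)
        for pos in positions:
            prefix[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[prefix[pos]]
        pair = _pair(seq2="".join(prefix) + "ACGT" * 10)
        kept, _ = filter_tag_reads([pair], self.PARAMS)
        assert bool(kept) == (n_subs <= self.PARAMS.max_prefix_mismatches)

    def test_empty_prefix_is_an_error(self):
        with pytest.raises(ValueError):
            filter_tag_reads([], FilterParams(tag_prefix=""))


class TestTrimAndLengthFilter:
    PARAMS = FilterParams(tag_prefix=TAG, adapter_sequences=("AGATCGGAAGAGC",))

    @pytest.mark.parametrize(
        "length,kept", [(49, False), (50, True), (51, True)]
    )
    def test_fifty_bp_boundary(self, length, kept):
        """Mates shorter than 50 bp after trimming are discarded; a
        50 bp mate survives."""
        pair = _pair(seq2="A" * length)
        out, _ = trim_and_length_filter([pair], self.PARAMS)
        assert bool(out) == kept

    def test_adapter_and_following_bases_removed(self):
        seq = "C" * 60 + "AGATCGGAAGAGC" + "T" * 10
        out, _ = trim_and_length_filter([_pair(seq2=seq)], self.PARAMS)
        assert out[0].seq2 == "C" * 60

    def test_partial_terminal_adapter_removed(self):
        seq = "C" * 60 + "AGATCGG"  # first 7 bases of the adapter at the 3' end
        out, _ = trim_and_length_filter([_pair(seq2=seq)], self.PARAMS)
        assert out[0].seq2 == "C" * 60

    def test_no_adapter_leaves_sequence_unchanged(self):
        out, _ = trim_and_length_filter([_pair(seq2="C" * 60)], self.PARAMS)
        assert out[0].seq2 == "C" * 60

    def test_low_quality_ends_trimmed(self):
        seq = "A" * 70
        qual = "#" * 5 + "I" * 60 + "#" * 5  # Phred 2 tails
        pair = ReadPair("r", "A" * 70, "I" * 70, seq, qual)
        out, _ = trim_and_length_filter([pair], self.PARAMS)
        assert out[0].seq2 == "A" * 60

    @given(
        st.text(alphabet="ACGT", min_size=45, max_size=80),
        st.text(alphabet="#5I", min_size=80, max_size=80),
    )
    @settings(max_examples=50, deadline=None)
    def test_idempotence(self, seq, qual):
        pair = ReadPair("r", "G" * 60, "I" * 60, seq, qual[: len(seq)])
        once, _ = trim_and_length_filter([pair], self.PARAMS)
        twice, _ = trim_and_length_filter(list(once), self.PARAMS)
        assert [(p.seq2, p.qual2) for p in once] == [(p.seq2, p.qual2) for p in twice]

    def test_partition_property(self):
        pairs = [_pair(f"r{i}", seq2="A" * n) for i, n in enumerate((30, 50, 80))]
        out, counts = trim_and_length_filter(pairs, self.PARAMS)
        assert counts.kept == len(out) and counts.total == len(pairs)


class TestFastqRoundTrip:
    def test_write_then_read_preserves_pairs(self, tmp_path):
        pairs = [
            ReadPair(f"read{i}", "ACGT" * 20, "I" * 80, "TGCA" * 20, "J" * 80)
            for i in range(5)
        ]
        r1, r2 = tmp_path / "a_R1.fastq", tmp_path / "a_R2.fastq"
        write_pairs(pairs, str(r1), str(r2))
        back = list(read_pairs(str(r1), str(r2)))
        assert [(p.read_id, p.seq1, p.seq2) for p in back] == [
            (p.read_id, p.seq1, p.seq2) for p in pairs
        ]

    def test_desynced_files_raise(self, tmp_path):
        r1, r2 = tmp_path / "R1.fastq", tmp_path / "R2.fastq"
        r1.write_text("@a/1\nACGT\n+\nIIII\n")
        r2.write_text("@b/2\nACGT\n+\nIIII\n")
        with pytest.raises(ValueError, match="mismatch"):
            list(read_pairs(str(r1), str(r2)))
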