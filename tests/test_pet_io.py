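"""PET table I/O, concordance classification and library statistics."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_pet
from petsv.errors import InputError
from petsv.pet_io import (
    LibraryConfig,
    classify_library,
    classify_pet,
    deduplicate,
    downsample,
    from_alignments,
    from_browser_frame,
    physical_coverage,
    read_pet_table,
    records_to_frame,
    span_stats,
    to_browser_frame,
    write_pet_table,
)


class TestReadPetTable:
    def test_empty_file_gives_empty_collection(self, tmp_path):
        path = tmp_path / "pets.tsv"
        path.write_text("# header only\n")
        pets, errors = read_pet_table(path)
        assert len(pets) == 0 and errors == []

    def test_single_line_identity_parse(self, tmp_path):
        path = tmp_path / "pets.tsv"
        path.write_text("r1\tchr1\t100\t125\t+\tchr2\t900\t925\t-\n")
        pets, errors = read_pet_table(path)
        assert errors == []
        row = pets.iloc[0]
        assert (row.read_id, row.chrom5, row.start5, row.end5, row.strand5) == \
            ("r1", "chr1", 100, 125, "+")
        assert (row.chrom3, row.start3, row.end3, row.strand3) == ("chr2", 900, 925, "-")

    def test_malformed_lines_rejected_with_line_numbers(self, tmp_path):
        path = tmp_path / "pets.tsv"
        path.write_text(
            "# comment\n"
            "r1\tchr1\t100\t125\t+\tchr1\t900\t925\t+\n"
            "r2\tchr1\t200\t150\t+\tchr1\t900\t925\t+\n"   # end < start
            "r3\tchr1\t100\t125\t*\tchr1\t900\t925\t+\n"   # bad strand
            "r4\tchr1\t100\n"                                # truncated
            "r5\tchr1\t300\t325\t+\tchr1\t950\t975\t+\n"
        )
        pets, errors = read_pet_table(path)
        assert len(pets) == 2
        assert [lineno for lineno, _ in errors] == [3, 4, 5]

    def test_unreadable_file_raises(self, tmp_path):
        with pytest.raises(InputError):
            read_pet_table(tmp_path / "absent.tsv")

    def test_roundtrip_including_bedpe_order(self, tmp_path):
        frame = records_to_frame([
            make_pet("a", s5=10, s3=500), make_pet("b", s5=20, s3=600, st5="-", st3="-"),
        ])
        for bedpe in (False, True):
            path = tmp_path / f"out_{bedpe}.tsv"
            write_pet_table(frame, path, bedpe=bedpe)
            back, errors = read_pet_table(path, bedpe=bedpe)
            assert errors == []
            pd.testing.assert_frame_equal(
                back[["read_id", "chrom5", "start5", "strand5", "start3", "strand3"]],
                frame[["read_id", "chrom5", "start5", "strand5", "start3", "strand3"]],
            )


class TestClassify:
    def test_1kb_same_chrom_strand_order_span_800_concordant(self, config_1kb):
        pet = make_pet(s5=1_000, s3=1_800 - 25)  # outer span exactly 800
        assert classify_pet(pet, config_1kb) == "concordant"

    def test_different_chromosomes_discordant(self, config_1kb):
        pet = make_pet(c5="chr1", c3="chr2")
        assert classify_pet(pet, config_1kb) == "discordant"

    @pytest.mark.parametrize("offset,expected", [
        (-1, "concordant"), (0, "concordant"), (1, "discordant"),
    ])
    def test_span_bound_is_inclusive(self, config_1kb, offset, expected):
        span = config_1kb.concordant_span_max + offset
        pet = make_pet(s5=10_000, s3=10_000 + span - 25)
        assert classify_pet(pet, config_1kb) == expected

    def test_minus_strand_order_reversed(self, config_1kb):
        # on the minus strand the 5' tag must lie downstream of the 3' tag
        good = make_pet(s5=2_000, st5="-", s3=1_000, st3="-")
        bad = make_pet(s5=1_000, st5="-", s3=2_000, st3="-")
        assert classify_pet(good, config_1kb) == "concordant"
        assert classify_pet(bad, config_1kb) == "discordant"

    def test_wrong_order_on_plus_discordant(self, config_1kb):
        pet = make_pet(s5=2_000, s3=1_000)
        assert classify_pet(pet, config_1kb) == "discordant"

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        s5=st.integers(0, 50_000), s3=st.integers(0, 50_000),
        st5=st.sampled_from("+-"), st3=st.sampled_from("+-"),
        same_chrom=st.booleans(),
    )
    def test_total_partition(self, s5, s3, st5, st3, same_chrom):
        """Every PET is exactly one of concordant / discordant."""
        config = LibraryConfig.preset("10kb")
        pet = make_pet(s5=s5, st5=st5, c3="chr1" if same_chrom else "chr2",
                       s3=s3, st3=st3)
        assert classify_pet(pet, config) in ("concordant", "discordant")

    def test_span_min_excludes_short_pets(self):
        config = LibraryConfig.preset("1kb", concordant_span_min=500)
        assert classify_pet(make_pet(s5=1_000, s3=1_100), config) == "discordant"
        assert classify_pet(make_pet(s5=1_000, s3=1_600), config) == "concordant"


class TestDeduplicate:
    def test_identical_coordinates_collapse(self):
        frame = records_to_frame([make_pet("a"), make_pet("b")])
        out = deduplicate(frame)
        assert len(out) == 1 and out.iloc[0].read_id == "a"  # first kept

    def test_one_bp_difference_retained(self):
        frame = records_to_frame([make_pet("a", s5=100), make_pet("b", s5=101)])
        assert len(deduplicate(frame)) == 2

    def test_empty_and_idempotent(self):
        assert len(deduplicate(records_to_frame([]))) == 0
        frame = records_to_frame([make_pet("a"), make_pet("b"), make_pet("c", s5=5)])
        once = deduplicate(frame)
        pd.testing.assert_frame_equal(once, deduplicate(once))
        assert len(once) <= len(frame)


class TestDownsample:
    def test_required_equals_total_keeps_all(self):
        frame = records_to_frame([make_pet(f"r{i}", s5=i * 100) for i in range(50)])
        assert len(downsample(frame, 50, seed=0)) == 50

    def test_required_zero_keeps_none(self):
        frame = records_to_frame([make_pet(f"r{i}", s5=i * 100) for i in range(50)])
        assert len(downsample(frame, 0, seed=0)) == 0

    def test_binomial_concentration(self):
        total, required = 100_000, 50_000
        frame = pd.DataFrame({
            "read_id": [f"r{i}" for i in range(total)],
            "chrom5": "chr1", "start5": np.arange(total), "end5": np.arange(total) + 25,
            "strand5": "+", "chrom3": "chr1", "start3": np.arange(total) + 500,
            "end3": np.arange(total) + 525, "strand3": "+", "status": "unclassified",
        })
        kept = len(downsample(frame, required, seed=7))
        p = required / total
        assert abs(kept - required) <= 3 * np.sqrt(total * p * (1 - p))

    def test_reproducible_and_bounds_checked(self):
        frame = records_to_frame([make_pet(f"r{i}", s5=i * 100) for i in range(100)])
        a = downsample(frame, 40, seed=3)
        b = downsample(frame, 40, seed=3)
        pd.testing.assert_frame_equal(a, b)
        with pytest.raises(InputError):
            downsample(frame, 101, seed=0)


class TestSpanStats:
    def _frame_with_spans(self, spans):
        return records_to_frame([
            make_pet(f"r{i}", s5=1_000, s3=1_000 + s - 25, status="concordant")
            for i, s in enumerate(spans)
        ])

    def test_median_of_three(self, config_1kb):
        stats = span_stats(self._frame_with_spans([900, 1_000, 1_100]), config_1kb)
        assert stats.median == 1_000

    def test_single_pet_degenerate(self, config_1kb):
        stats = span_stats(self._frame_with_spans([987]), config_1kb)
        assert stats.median == stats.mean == 987 and stats.sd == 0

    def test_requires_concordant_pets(self, config_1kb):
        frame = records_to_frame([make_pet(status="discordant")])
        with pytest.raises(InputError):
            span_stats(frame, config_1kb)


class TestPhysicalCoverage:
    def test_ten_10kb_spans_on_100kb_genome(self):
        frame = records_to_frame([
            make_pet(f"r{i}", s5=i * 10, s3=i * 10 + 10_000 - 25, status="concordant")
            for i in range(10)
        ])
        assert physical_coverage(frame, 100_000) == pytest.approx(1.0)

    def test_empty_is_zero_and_bad_genome_rejected(self):
        assert physical_coverage(records_to_frame([]), 1_000) == 0.0
        with pytest.raises(InputError):
            physical_coverage(records_to_frame([]), 0)


def test_browser_coordinate_roundtrip():
    frame = records_to_frame([make_pet("a", s5=99, s3=499)])
    browser = to_browser_frame(frame)
    assert browser.iloc[0].start5 == 100  # 1-based inclusive
    pd.testing.assert_frame_equal(from_browser_frame(browser), frame)


def test_preset_bounds_and_validation():
    assert LibraryConfig.preset("1kb").concordant_span_max == 3_000
    assert LibraryConfig.preset("10kb").concordant_span_max == 20_000
    assert LibraryConfig.preset("20kb").concordant_span_max == 40_000
    with pytest.raises(InputError):
        LibraryConfig.preset("5kb")
    with pytest.raises(InputError):
        LibraryConfig(name="x", nominal_insert=1_000, concordant_span_max=500,
                      concordant_span_min=600)


def test_sam_importer_pairs_mates(tmp_path):
    sam = tmp_path / "tiny.sam"
    sam.write_text(
        "@HD\tVN:1.6\tSO:unsorted\n"
        "@SQ\tSN:chr1\tLN:100000\n"
        "p1\t65\tchr1\t101\t60\t25M\t=\t10101\t10025\t" + "A" * 25 + "\t*\n"
        "p1\t129\tchr1\t10101\t60\t25M\t=\t101\t-10025\t" + "A" * 25 + "\t*\n"
    )
    frame = from_alignments(sam)
    assert len(frame) == 1
    row = frame.iloc[0]
    assert row.start5 == 100 and row.start3 == 10_100 and row.strand5 == "+"
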