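import numpy as np
import pytest

from tescope.core_io import (
    HSPLoadStats,
    TescopeError,
    align_reads,
    load_hsps,
    quality_filter,
    read_library,
)
from tescope.sim import random_dna


def write_fasta(path, entries):
    with open(path, "w") as fh:
        for name, seq in entries.items():
            fh.write(f">{name}\n{seq}\n")
    return path


class TestReadLibrary:
    def test_roles_assigned_explicitly(self, tmp_path):
        fa = write_fasta(tmp_path / "lib.fa", {"PPI251": "ACGT" * 10, "rpl32": "TTGC" * 8})
        lib = read_library(fa, gene_names=["rpl32"])
        assert lib.families == ["PPI251"]
        assert lib.genes == ["rpl32"]

    def test_default_role_is_family(self, tmp_path):
        fa = write_fasta(tmp_path / "lib.fa", {"a": "ACGT", "b": "GGCC"})
        lib = read_library(fa)
        assert set(lib.families) == {"a", "b"} and lib.genes == []

    def test_missing_gene_named_in_error(self, tmp_path):
        fa = write_fasta(tmp_path / "lib.fa", {"a": "ACGT"})
        with pytest.raises(TescopeError, match="bogus"):
            read_library(fa, gene_names=["bogus"])

    def test_duplicate_names_fatal(self, tmp_path):
        path = tmp_path / "dup.fa"
        path.write_text(">a\nACGT\n>a\nGGGG\n")
        with pytest.raises(TescopeError, match="duplicate"):
            read_library(path)

    def test_missing_file(self, tmp_path):
        with pytest.raises(TescopeError, match="not found"):
            read_library(tmp_path / "absent.fa")


class TestReadAnnotation:
    def test_gff3_features_parsed(self, tmp_path):
        from tescope.core_io import read_annotation

        gff = tmp_path / "ann.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "TE\tsrc\tterminal_inverted_repeat\t1\t31\t.\t+\t.\tID=TIR5\n"
            "TE\tsrc\tCDS\t153\t2409\t.\t+\t.\tName=transposase\n"
        )
        track = read_annotation(gff)
        feats = track.for_contig("TE")
        assert (1, 31, "terminal_inverted_repeat", "TIR5") in feats
        assert (153, 2409, "CDS", "transposase") in feats
        assert track.for_contig("other") == []


def fastq_record(name, seq, quals):
    return f"@{name}\n{seq}\n+\n{quals}\n"


class TestQualityFilter:
    def test_good_read_retained(self, tmp_path):
        src = tmp_path / "in.fastq"
        src.write_text(fastq_record("r1", "A" * 100, "I" * 100))  # Q40
        out = tmp_path / "out.fastq"
        counters = quality_filter(src, out, min_mean_q=15, min_len=50)
        assert counters == {"input": 1, "trimmed": 0, "dropped": 0, "retained": 1}
        assert "r1" in out.read_text()

    def test_low_mean_quality_dropped(self, tmp_path):
        src = tmp_path / "in.fastq"
        src.write_text(fastq_record("r1", "A" * 100, "&" * 100))  # Q5
        out = tmp_path / "out.fastq"
        counters = quality_filter(src, out, min_mean_q=15, min_len=50)
        assert counters["dropped"] == 1 and out.read_text() == ""

    def test_three_prime_trim_then_length_check(self, tmp_path):
        # 60 bp read whose last 20 bases are Q2: trimmed to 40 bp, then dropped
        # because 40 < min_len=50
        src = tmp_path / "in.fastq"
        src.write_text(fastq_record("r1", "A" * 60, "I" * 40 + "#" * 20))
        out = tmp_path / "out.fastq"
        counters = quality_filter(src, out, min_mean_q=15, min_len=50)
        assert counters["trimmed"] == 1 and counters["dropped"] == 1

    def test_trimmed_read_surviving_length_kept_shorter(self, tmp_path):
        src = tmp_path / "in.fastq"
        src.write_text(fastq_record("r1", "A" * 80, "I" * 70 + "#" * 10))
        out = tmp_path / "out.fastq"
        quality_filter(src, out, min_mean_q=15, min_len=50)
        lines = out.read_text().splitlines()
        assert len(lines[1]) == 70

    def test_malformed_fastq_fatal_with_record_number(self, tmp_path):
        src = tmp_path / "in.fastq"
        src.write_text("@r1\nACGT\n+\nII\n")  # quality length mismatch
        with pytest.raises(TescopeError, match="record #1"):
            quality_filter(src, tmp_path / "out.fastq", 15, 2)


class TestLoadHsps:
    def test_mapq_zero_is_ambiguous(self, tmp_path, sam_writer):
        sam = sam_writer(
            tmp_path / "a.sam",
            [{"name": "r1", "contig": "TE", "pos": 0, "mapq": 0,
              "cigar": "50M", "seq": "A" * 50}],
            {"TE": 200},
        )
        (read_id, hsps), = load_hsps(sam)
        assert hsps[0].ambiguous

    def test_cigar_arithmetic_soft_clip(self, tmp_path, sam_writer):
        # 30S70M at SAM position 11 (1-based) -> ref [10,80), read [30,100)
        sam = sam_writer(
            tmp_path / "a.sam",
            [{"name": "r1", "contig": "TE", "pos": 10, "cigar": "30S70M",
              "seq": "C" * 100}],
            {"TE": 200},
        )
        (_, hsps), = load_hsps(sam)
        h = hsps[0]
        assert (h.ref_start, h.ref_end) == (10, 80)
        assert (h.read_start, h.read_end) == (30, 100)
        assert h.read_length == 100

    def test_reverse_strand_read_coordinates(self, tmp_path, sam_writer):
        # reverse record 30S70M: aligned SEQ[30:100] maps to original read [0,70)
        sam = sam_writer(
            tmp_path / "a.sam",
            [{"name": "r1", "contig": "TE", "pos": 10, "flag": 16,
              "cigar": "30S70M", "seq": "C" * 100}],
            {"TE": 200},
        )
        (_, hsps), = load_hsps(sam)
        h = hsps[0]
        assert h.strand == "-"
        assert (h.read_start, h.read_end) == (0, 70)

    def test_records_grouped_by_read(self, tmp_path, sam_writer):
        sam = sam_writer(
            tmp_path / "a.sam",
            [
                {"name": "r1", "contig": "TE", "pos": 0, "cigar": "50M", "seq": "A" * 50},
                {"name": "r1", "contig": "other", "pos": 10, "cigar": "50M", "seq": "A" * 50},
            ],
            {"TE": 200, "other": 200},
        )
        groups = list(load_hsps(sam))
        assert len(groups) == 1 and len(groups[0][1]) == 2

    def test_long_deletion_split_into_two_hsps(self, tmp_path, sam_writer):
        sam = sam_writer(
            tmp_path / "a.sam",
            [{"name": "r1", "contig": "TE", "pos": 0, "cigar": "40M100D40M",
              "seq": "G" * 80}],
            {"TE": 400},
        )
        (_, hsps), = load_hsps(sam, min_internal_deletion=30)
        assert len(hsps) == 2
        assert hsps[0].ref_end == 40 and hsps[1].ref_start == 140
        # read coordinates contiguous across the split
        assert hsps[0].read_end == hsps[1].read_start == 40

    def test_short_deletion_not_split(self, tmp_path, sam_writer):
        sam = sam_writer(
            tmp_path / "a.sam",
            [{"name": "r1", "contig": "TE", "pos": 0, "cigar": "40M10D40M",
              "seq": "G" * 80}],
            {"TE": 400},
        )
        (_, hsps), = load_hsps(sam, min_internal_deletion=30)
        assert len(hsps) == 1 and hsps[0].del_pos.size == 10

    def test_accounting_emitted_equals_mapped_minus_skipped(self, tmp_path, sam_writer):
        recs = [
            {"name": f"r{i}", "contig": "TE", "pos": 0, "cigar": "50M", "seq": "A" * 50}
            for i in range(5)
        ]
        recs.append({"name": "u", "flag": 4, "seq": "A" * 50, "contig": "TE",
                     "pos": 0, "cigar": "50M"})
        sam = sam_writer(tmp_path / "a.sam", recs, {"TE": 200})
        stats = HSPLoadStats()
        groups = list(load_hsps(sam, stats=stats))
        emitted = sum(len(h) for _, h in groups)
        assert stats.mapped_records == 5
        assert emitted == stats.hsps_emitted == stats.mapped_records - stats.skipped_records


class TestAlignReads:
    """Contract tests for the wrapped local aligner (bwa bwasw)."""

    def test_error_free_reads_align_fully(self, tmp_path):
        rng = np.random.default_rng(3)
        cons = random_dna(1200, rng)
        lib_fa = write_fasta(tmp_path / "lib.fa", {"TE": cons})
        lib = read_library(lib_fa)
        reads = tmp_path / "r.fastq"
        with open(reads, "w") as fh:
            for i in range(20):
                s = rng.integers(0, 1100)
                fh.write(fastq_record(f"r{i}", cons[s : s + 100], "I" * 100))
        sam = align_reads(reads, lib, tmp_path / "aln")
        groups = list(load_hsps(sam))
        assert len(groups) == 20
        for _, hsps in groups:
            assert any(h.read_span == 100 for h in hsps)

    def test_empty_read_file_gives_valid_empty_alignment(self, tmp_path):
        cons = random_dna(500, np.random.default_rng(0))
        lib = read_library(write_fasta(tmp_path / "lib.fa", {"TE": cons}))
        reads = tmp_path / "r.fastq"
        reads.write_text("")
        sam = align_reads(reads, lib, tmp_path / "aln")
        assert list(load_hsps(sam)) == []

    def test_read_spanning_deletion_yields_split_hsps(self, tmp_path):
        rng = np.random.default_rng(5)
        cons = random_dna(2000, rng)
        lib = read_library(write_fasta(tmp_path / "lib.fa", {"TE": cons}))
        # read = 100 bp before a 500 bp deletion + 100 bp after it
        read = cons[700:800] + cons[1300:1400]
        reads = tmp_path / "r.fastq"
        reads.write_text(fastq_record("split", read, "I" * 200))
        sam = align_reads(reads, lib, tmp_path / "aln")
        (_, hsps), = load_hsps(sam)
        assert len(hsps) >= 2

    def test_missing_aligner_is_fatal_with_hint(self, tmp_path):
        lib = read_library(write_fasta(tmp_path / "lib.fa", {"TE": "ACGT" * 50}))
        reads = tmp_path / "r.fastq"
        reads.write_text("")
        with pytest.raises(TescopeError, match="not found on PATH"):
            align_reads(reads, lib, tmp_path / "aln", aligner="no-such-aligner")
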