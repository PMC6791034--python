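import numpy as np
import pandas as pd
import pytest

from tescope.chain import ChainParams, chain_read
from tescope.core_io import BASE_CODE, TescopeError
from tescope.profile import (
    ProfileParams,
    build_pileup,
    call_internal_deletions,
    call_snps,
    call_terminal_deletions,
    detection_probability,
    estimate_divergence,
    profile_to_table,
    read_table,
    write_table,
)

from conftest import make_hsp


def chains_from(hsp_groups, params=None):
    out = []
    for hsps in hsp_groups:
        c = chain_read(hsps, params or ChainParams())
        assert c is not None
        out.append(c)
    return out


@pytest.fixture
def te_seq(small_library):
    return small_library.sequence("TE")


class TestBuildPileup:
    def test_full_coverage_reads(self, small_library, te_seq):
        n = len(te_seq)
        groups = [
            [make_hsp(read_id=f"r{i}", ref_start=0, ref_end=n, read_end=n,
                      read_length=n, ref_seq=te_seq)]
            for i in range(3)
        ]
        prof = build_pileup(chains_from(groups), small_library, "s1")
        fam = prof["TE"]
        assert (fam.base_cov == 3).all()
        assert (fam.phys_cov == 0).all()

    def test_junction_physical_coverage(self, small_library, te_seq):
        hsps = [
            make_hsp(read_id="r", ref_start=100, ref_end=170, read_start=0,
                     read_end=70, read_length=150, ref_seq=te_seq),
            make_hsp(read_id="r", ref_start=500, ref_end=580, read_start=70,
                     read_end=150, read_length=150, ref_seq=te_seq),
        ]
        prof = build_pileup(chains_from([hsps]), small_library, "s1")
        fam = prof["TE"]
        # 1-based rows 171..500 get physical coverage (0-based [170,500))
        assert (fam.phys_cov[170:500] == 1).all()
        assert fam.phys_cov[169] == 0 and fam.phys_cov[500] == 0

    def test_base_counts_accumulate(self, small_library, te_seq):
        # ref base at position 10, two matching reads and one G mismatch
        ref_b = te_seq[10]
        groups = [
            [make_hsp(read_id="r1", ref_start=10, ref_end=11, read_end=1,
                      read_length=1, read_bases=ref_b)],
            [make_hsp(read_id="r2", ref_start=10, ref_end=11, read_end=1,
                      read_length=1, read_bases=ref_b)],
            [make_hsp(read_id="r3", ref_start=10, ref_end=11, read_end=1,
                      read_length=1, read_bases="G" if ref_b != "G" else "T")],
        ]
        prof = build_pileup(chains_from(groups), small_library, "s1")
        fam = prof["TE"]
        assert fam.base_cov[10] == 3
        assert fam.counts[10, BASE_CODE[ref_b]] == 2

    def test_unknown_contig_fatal(self, small_library):
        hsps = [make_hsp(contig="nope")]
        with pytest.raises(TescopeError, match="nope"):
            build_pileup(chains_from([hsps]), small_library, "s1")

    def test_conservation_of_aligned_bases(self, small_library, te_seq):
        rng = np.random.default_rng(4)
        groups = []
        for i in range(40):
            s = int(rng.integers(0, 500))
            e = s + int(rng.integers(20, 100))
            e = min(e, 600)
            groups.append(
                [make_hsp(read_id=f"r{i}", ref_start=s, ref_end=e, read_end=e - s,
                          read_length=e - s, ref_seq=te_seq)]
            )
        chains = chains_from(groups)
        prof = build_pileup(chains, small_library, "s1")
        total_counts = sum(p.counts.sum() for p in prof.families.values())
        total_aligned = sum(h.match_ref_pos.size for c in chains for h in c.hsps)
        assert total_counts == total_aligned


class TestCallSnps:
    def _profile_with_counts(self, small_library, pos, counts):
        prof = build_pileup([], small_library, "s1")
        fam = prof["TE"]
        for b, n in counts.items():
            fam.counts[pos, BASE_CODE[b]] = n
            fam.hq_counts[pos, BASE_CODE[b]] = n
        return prof

    def test_fixed_difference(self, small_library, te_seq):
        pos = next(i for i, b in enumerate(te_seq) if b == "A")
        prof = self._profile_with_counts(small_library, pos, {"G": 10})
        call_snps(prof)
        assert prof["TE"].snp[pos] == "fixed"

    def test_segregating_site(self, small_library, te_seq):
        pos = next(i for i, b in enumerate(te_seq) if b == "A")
        prof = self._profile_with_counts(small_library, pos, {"A": 7, "G": 3})
        call_snps(prof, min_count=2, min_freq=0.1)
        fam = prof["TE"]
        assert fam.snp[pos] == "seg"
        assert fam.refsnp[pos] == pytest.approx(0.7)

    def test_below_count_threshold_not_called(self, small_library, te_seq):
        pos = next(i for i, b in enumerate(te_seq) if b == "A")
        prof = self._profile_with_counts(small_library, pos, {"A": 9, "G": 1})
        call_snps(prof, min_count=2)
        assert prof["TE"].snp[pos] == "."

    def test_zero_coverage_is_none(self, small_library):
        prof = build_pileup([], small_library, "s1")
        call_snps(prof)
        assert (prof["TE"].snp == ".").all()


class TestDetectionProbability:
    @pytest.mark.parametrize("L,m", [(100, 30), (1000, 30), (80, 25), (201, 30)])
    def test_matches_enumeration_oracle(self, L, m):
        # enumerate all L spanning placements; count those with both flanks >= m
        visible = sum(1 for k in range(L) if k >= m and L - k >= m)
        assert detection_probability(L, m) == pytest.approx(visible / L)

    def test_known_values(self):
        assert detection_probability(100, 30) == pytest.approx(0.41)
        assert detection_probability(1000, 30) == pytest.approx(0.941)

    def test_too_short_reads_error(self):
        with pytest.raises(TescopeError, match="too short"):
            detection_probability(60, 30)


class TestInternalDeletions:
    def _junction_profile(self, small_library, te_seq, n_junction, read_length,
                          gap=(170, 500), cov_reads=0):
        groups = []
        for i in range(n_junction):
            flank = (read_length - 0) // 2
            groups.append([
                make_hsp(read_id=f"j{i}", ref_start=gap[0] - flank, ref_end=gap[0],
                         read_start=0, read_end=flank, read_length=read_length,
                         ref_seq=te_seq),
                make_hsp(read_id=f"j{i}", ref_start=gap[1], ref_end=gap[1] + flank,
                         read_start=flank, read_end=2 * flank,
                         read_length=read_length, ref_seq=te_seq),
            ])
        for i in range(cov_reads):
            groups.append([
                make_hsp(read_id=f"c{i}", ref_start=gap[0], ref_end=gap[1],
                         read_end=gap[1] - gap[0], read_length=gap[1] - gap[0],
                         ref_seq=te_seq)
            ])
        chains = chains_from(groups)
        prof = build_pileup(chains, small_library, "s1")
        call_internal_deletions(prof)
        return prof["TE"]

    def test_correction_factor_applied(self, small_library, te_seq):
        fam = self._junction_profile(small_library, te_seq, 10, 100)
        (call,) = fam.deletion_calls
        assert call.raw_count == 10
        assert call.corrected_count == pytest.approx(10 / 0.41, rel=1e-9)

    def test_frequency_definition(self, small_library, te_seq):
        # corrected 24.39 junction reads against ~75.61 mean gap coverage
        fam = self._junction_profile(small_library, te_seq, 10, 100, cov_reads=76)
        (call,) = fam.deletion_calls
        corrected = 10 / 0.41
        assert call.frequency == pytest.approx(corrected / (corrected + 76))
        assert call.raw_frequency == pytest.approx(10 / 76)

    def test_nearby_breakpoints_cluster(self, small_library, te_seq):
        groups = []
        for i, (a, b) in enumerate([(170, 500), (172, 501)]):
            groups.append([
                make_hsp(read_id=f"j{i}", ref_start=a - 50, ref_end=a, read_start=0,
                         read_end=50, read_length=100, ref_seq=te_seq),
                make_hsp(read_id=f"j{i}", ref_start=b, ref_end=b + 50, read_start=50,
                         read_end=100, read_length=100, ref_seq=te_seq),
            ])
        prof = build_pileup(chains_from(groups), small_library, "s1")
        call_internal_deletions(prof)
        calls = prof["TE"].deletion_calls
        assert len(calls) == 1 and calls[0].raw_count == 2

    def test_uncorrectable_short_reads_flagged(self, small_library, te_seq):
        fam = self._junction_profile(small_library, te_seq, 4, 60)
        (call,) = fam.deletion_calls
        assert not call.corrected and call.corrected_count == 4


class TestTerminalDeletions:
    def _clip_profile(self, small_library, te_seq, ref_start, left_clip,
                      read_length=145, min_clip=30):
        span = read_length - left_clip
        hsps = [make_hsp(read_id="t", ref_start=ref_start,
                         ref_end=ref_start + span, read_start=left_clip,
                         read_end=read_length, read_length=read_length,
                         ref_seq=te_seq)]
        prof = build_pileup(chains_from([hsps]), small_library, "s1")
        call_terminal_deletions(prof, ProfileParams(min_clip=min_clip))
        return prof["TE"]

    def test_internal_clip_yields_left_truncation(self, small_library, te_seq):
        # 45 bp unaligned at the read start, anchored at 1-based position 293
        fam = self._clip_profile(small_library, te_seq, ref_start=292, left_clip=45)
        (call,) = fam.truncation_calls
        assert call.side == "left" and call.ref_pos == 293 and call.count == 1

    def test_clip_at_consensus_edge_ignored(self, small_library, te_seq):
        fam = self._clip_profile(small_library, te_seq, ref_start=3, left_clip=45)
        assert fam.truncation_calls == []

    def test_short_clip_ignored(self, small_library, te_seq):
        fam = self._clip_profile(small_library, te_seq, ref_start=292, left_clip=10)
        assert fam.truncation_calls == []

    def test_explained_clip_excluded(self, small_library, te_seq):
        # second HSP on another contig explains the clipped prefix
        hsps = [
            make_hsp(read_id="t", contig="gene1", ref_start=0, ref_end=45,
                     read_start=0, read_end=45, read_length=145, ref_seq=None,
                     read_bases="A" * 45),
            make_hsp(read_id="t", ref_start=292, ref_end=392, read_start=45,
                     read_end=145, read_length=145, ref_seq=te_seq),
        ]
        prof = build_pileup(chains_from([hsps]), small_library, "s1")
        call_terminal_deletions(prof)
        assert prof["TE"].truncation_calls == []


class TestDivergence:
    def test_identical_reads_zero_divergence(self, small_library, te_seq):
        groups = [[make_hsp(read_id=f"r{i}", ref_start=0, ref_end=600, read_end=600,
                            read_length=600, ref_seq=te_seq)] for i in range(3)]
        prof = build_pileup(chains_from(groups), small_library, "s1")
        d, per_pos = estimate_divergence(prof["TE"])
        assert d == 0.0

    def test_uniform_mismatch_rate(self, small_library, te_seq):
        # 9 matching reads + 1 read mismatching everywhere -> divergence 0.1
        alt = "".join("A" if b != "A" else "C" for b in te_seq)
        groups = [[make_hsp(read_id=f"r{i}", ref_start=0, ref_end=600, read_end=600,
                            read_length=600, ref_seq=te_seq)] for i in range(9)]
        groups.append([make_hsp(read_id="alt", ref_start=0, ref_end=600, read_end=600,
                                read_length=600, read_bases=alt)])
        prof = build_pileup(chains_from(groups), small_library, "s1")
        d, _ = estimate_divergence(prof["TE"])
        assert d == pytest.approx(0.1)

    def test_zero_coverage_is_undefined(self, small_library):
        prof = build_pileup([], small_library, "s1")
        d, per_pos = estimate_divergence(prof["TE"])
        assert d is None and np.isnan(per_pos).all()


class TestTableRoundTrip:
    def _full_profile(self, small_library, te_seq):
        groups = [[make_hsp(read_id=f"r{i}", ref_start=0, ref_end=600, read_end=600,
                            read_length=600, ref_seq=te_seq)] for i in range(3)]
        hsps = [
            make_hsp(read_id="j", ref_start=100, ref_end=170, read_start=0,
                     read_end=70, read_length=150, ref_seq=te_seq),
            make_hsp(read_id="j", ref_start=500, ref_end=580, read_start=70,
                     read_end=150, read_length=150, ref_seq=te_seq),
        ]
        groups.append(hsps)
        prof = build_pileup(chains_from(groups), small_library, "s1")
        call_snps(prof)
        call_internal_deletions(prof)
        call_terminal_deletions(prof)
        return prof

    def test_bit_exact_round_trip(self, small_library, te_seq, tmp_path):
        prof = self._full_profile(small_library, te_seq)
        df = profile_to_table(prof)
        path = write_table(df, tmp_path / "t.tsv", {"sample": "s1"})
        back, meta = read_table(path)
        pd.testing.assert_frame_equal(df, back)
        assert meta["sample"] == "s1"

    def test_round_trip_after_per_million_scaling(self, small_library, te_seq, tmp_path):
        from tescope.abundance import normalize_per_million

        prof = self._full_profile(small_library, te_seq)
        normalize_per_million(prof, total_mapped_reads=1234567)
        df = profile_to_table(prof)
        path = write_table(df, tmp_path / "t.tsv")
        back, _ = read_table(path)
        pd.testing.assert_frame_equal(df, back)

    def test_int_del_cell_encoding(self, small_library, te_seq):
        prof = self._full_profile(small_library, te_seq)
        df = profile_to_table(prof)
        cell = df.loc[(df["family"] == "TE") & (df["pos"] == 171), "int_del"].iloc[0]
        start, end, count = cell.split(":")
        assert (int(start), int(end)) == (171, 500)
        # one junction read of length 150: corrected count = 1/p = 150/91
        assert float(count) == pytest.approx(150 / 91)
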