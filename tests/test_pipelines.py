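"""End-to-end behaviour of the Illumina and 454 QC pipelines on
generated datasets with planted, manifest-recorded artifacts."""

from collections import Counter

import pytest

from ngsqc.fixtures import DEFAULT_LINKER, FixtureSpec, generate_reads
from ngsqc.illumina_pipeline import (
    IlluminaQCParams,
    qc_paired_end,
    qc_single_end,
    qc_single_end_chunked,
)
from ngsqc.roche454_pipeline import (
    Roche454QCParams,
    qc_454,
    qc_454_chunked,
    qc_454_pe,
    split_by_linker,
)
from ngsqc.seqio import FormatError, SequenceRead


def _ids(reads):
    return Counter(r.id for r in reads)


class TestIlluminaSingleEnd:
    def test_planted_low_quality_reads_are_discarded(self):
        spec = FixtureSpec(n_reads=1000, frac_low_quality=0.1, seed=7)
        res = generate_reads(spec)
        kept, stats = qc_single_end(res.reads, IlluminaQCParams())
        assert len(kept) == 900
        assert stats.low_quality_discarded == 100
        assert stats.input_reads == stats.hq_reads + stats.total_discarded

    def test_planted_adaptor_reads_are_discarded(self):
        spec = FixtureSpec(n_reads=500, frac_adaptor=0.1, seed=8)
        res = generate_reads(spec)
        params = IlluminaQCParams(adaptors=[("a", spec.adaptor)])
        kept, stats = qc_single_end(res.reads, params)
        assert stats.adaptor_discarded == 50
        assert len(kept) == 450

    def test_empty_input(self):
        kept, stats = qc_single_end([], IlluminaQCParams())
        assert kept == [] and stats.input_reads == 0
        assert stats.total_discarded == 0

    def test_order_preserved(self):
        spec = FixtureSpec(n_reads=100, frac_low_quality=0.2, seed=9)
        res = generate_reads(spec)
        kept, _ = qc_single_end(res.reads, IlluminaQCParams())
        wanted = [r.id for r in res.reads
                  if dict((e.read_id, e.expected_fate) for e in res.manifest)[r.id] == "kept"]
        assert [r.id for r in kept] == wanted

    def test_every_fate_matches_manifest(self):
        spec = FixtureSpec(
            n_reads=400, frac_low_quality=0.15, frac_adaptor=0.15,
            adaptor_mismatches=(0, 1, 2), seed=10,
        )
        res = generate_reads(spec)
        params = IlluminaQCParams(adaptors=[("a", spec.adaptor)])
        kept, stats = qc_single_end(res.reads, params)
        kept_ids = {r.id for r in kept}
        for entry in res.manifest:
            actual = "kept" if entry.read_id in kept_ids else None
            if entry.expected_fate == "kept":
                assert actual == "kept", entry
            else:
                assert actual is None, entry

    @pytest.mark.parametrize("k", [2, 3, 7])
    def test_chunked_equals_single_pass(self, k):
        spec = FixtureSpec(n_reads=333, frac_low_quality=0.1, frac_adaptor=0.1, seed=11)
        res = generate_reads(spec)
        params = IlluminaQCParams(adaptors=[("a", spec.adaptor)])
        kept1, stats1 = qc_single_end(res.reads, params)
        keptk, statsk = qc_single_end_chunked(res.reads, params, k)
        assert keptk == kept1
        assert statsk.stage_counts == stats1.stage_counts
        assert statsk.input_stats == stats1.input_stats
        assert statsk.output_stats == stats1.output_stats


class TestIlluminaPairedEnd:
    def _run(self, spec):
        res = generate_reads(spec)
        fwd, rev = res.mates
        return res, qc_paired_end(fwd, rev, IlluminaQCParams())

    def test_failing_forward_mates_divert_reverse_to_unpaired(self):
        spec = FixtureSpec(n_reads=100, paired=True, frac_fwd_fail=0.1, seed=12)
        res, (pf, pr, up, stats) = self._run(spec)
        assert len(pf) == len(pr) == 90
        assert len(up) == 10
        assert all(r.id.endswith("/2") for r in up)

    def test_all_pairs_pass(self):
        spec = FixtureSpec(n_reads=50, paired=True, seed=13)
        res, (pf, pr, up, stats) = self._run(spec)
        assert up == []
        assert [f.pairing_key for f in pf] == [r.pairing_key for r in pr]

    def test_conservation_multiset_identity(self):
        spec = FixtureSpec(
            n_reads=200, paired=True, frac_fwd_fail=0.1, frac_rev_fail=0.1,
            frac_both_fail=0.05, seed=14,
        )
        res, (pf, pr, up, stats) = self._run(spec)
        fwd, rev = res.mates
        survivors = _ids(pf) + _ids(pr) + _ids(up)
        everything = _ids(fwd) + _ids(rev)
        # every input read lands in exactly one of: paired out, unpaired out, discarded
        assert survivors | Counter() == Counter(
            {k: v for k, v in survivors.items()}
        )
        assert all(everything[k] >= v for k, v in survivors.items())
        n_discarded = sum(stats.stage_counts.values())
        assert sum(everything.values()) == sum(survivors.values()) + n_discarded
        assert 2 * stats.pairs_in == (
            2 * stats.paired_surviving + stats.unpaired_surviving + n_discarded
        )

    def test_pair_fates_match_manifest(self):
        spec = FixtureSpec(
            n_reads=150, paired=True, frac_fwd_fail=0.1, frac_rev_fail=0.1,
            frac_both_fail=0.1, seed=15,
        )
        res, (pf, pr, up, stats) = self._run(spec)
        paired_keys = {r.pairing_key for r in pf}
        unpaired_ids = {r.id for r in up}
        for entry in res.manifest:
            if entry.expected_fate == "pair":
                assert entry.read_id in paired_keys
            elif entry.expected_fate == "unpaired_reverse":
                assert entry.read_id + "/2" in unpaired_ids
            elif entry.expected_fate == "unpaired_forward":
                assert entry.read_id + "/1" in unpaired_ids
            else:
                assert entry.read_id not in paired_keys

    def test_mate_key_mismatch_cites_ordinal(self):
        fwd = [SequenceRead(f"p{i}/1", "ACGT", [30] * 4) for i in range(10)]
        rev = [SequenceRead(f"p{i}/2", "ACGT", [30] * 4) for i in range(10)]
        rev[6] = SequenceRead("pX/2", "ACGT", [30] * 4)
        with pytest.raises(FormatError, match="ordinal 7"):
            qc_paired_end(fwd, rev, IlluminaQCParams())

    def test_unequal_file_lengths_error(self):
        fwd = [SequenceRead(f"p{i}/1", "ACGT", [30] * 4) for i in range(3)]
        rev = fwd[:2]
        rev = [SequenceRead(r.id.replace("/1", "/2"), r.seq, r.quals) for r in rev]
        with pytest.raises(FormatError, match="ordinal 3"):
            qc_paired_end(fwd, rev, IlluminaQCParams())


class TestRoche454:
    def test_mean_quality_stage_counts(self):
        spec = FixtureSpec(platform="454", n_reads=500, read_length=(80, 150),
                           frac_low_quality=0.1, low_quality_q=5, seed=16)
        res = generate_reads(spec)
        kept, stats = qc_454(res.reads, Roche454QCParams())
        assert len(kept) == 450
        assert stats.stage_counts["low_quality"] == 50

    def test_homopolymer_shortening_counted_in_its_own_stage(self):
        # a planted run before the length cutoff leaves a too-short read:
        # it must be charged to the homopolymer stage, not the quality stage
        read_ok = SequenceRead("ok", "ACGT" * 30, [30] * 120)
        seq = "ACGTACGTAC" + "G" * 8 + "ACGT" * 30
        read_short = SequenceRead("short", seq[:120], [30] * 120)
        params = Roche454QCParams(min_len=50, homopolymer_len=8)
        kept, stats = qc_454([read_ok, read_short], params)
        assert [r.id for r in kept] == ["ok"]
        assert stats.stage_counts["homopolymer_trim_short"] == 1
        assert stats.stage_counts["low_quality"] == 0

    def test_homopolymer_off_leaves_runs_untouched(self):
        seq = "ACGT" * 10 + "A" * 20 + "ACGT" * 10
        read = SequenceRead("r", seq, [30] * len(seq))
        kept, _ = qc_454([read], Roche454QCParams(homopolymer_len=None))
        assert kept == [read]

    def test_all_fates_match_manifest(self):
        spec = FixtureSpec(
            platform="454", n_reads=400, read_length=(80, 150),
            frac_low_quality=0.1, frac_homopolymer=0.1, frac_adaptor=0.1,
            adaptor_mismatches=(0, 1, 2), low_quality_q=5, seed=17,
        )
        res = generate_reads(spec)
        params = Roche454QCParams(homopolymer_len=spec.homopolymer_run,
                                  adaptors=[("a", spec.adaptor)])
        kept, stats = qc_454(res.reads, params)
        kept_by_id = {r.id: r for r in kept}
        for entry in res.manifest:
            if entry.expected_fate == "kept":
                assert entry.read_id in kept_by_id, entry
                if entry.expected_length is not None:
                    assert len(kept_by_id[entry.read_id]) == entry.expected_length, entry
            else:
                assert entry.read_id not in kept_by_id, entry

    def test_identity_with_all_filters_disabled(self):
        spec = FixtureSpec(platform="454", n_reads=100, read_length=(60, 140), seed=18)
        res = generate_reads(spec)
        params = Roche454QCParams(min_len=1, homopolymer_len=None,
                                  quality_cutoff=0, adaptors=())
        kept, stats = qc_454(res.reads, params)
        assert kept == res.reads
        assert stats.total_discarded == 0

    @pytest.mark.parametrize("k", [2, 3, 7])
    def test_chunked_equals_single_pass(self, k):
        spec = FixtureSpec(platform="454", n_reads=211, read_length=(80, 150),
                           frac_low_quality=0.1, low_quality_q=5, seed=19)
        res = generate_reads(spec)
        params = Roche454QCParams()
        kept1, stats1 = qc_454(res.reads, params)
        keptk, statsk = qc_454_chunked(res.reads, params, k)
        assert keptk == kept1
        assert statsk.stage_counts == stats1.stage_counts
        assert statsk.output_stats == stats1.output_stats


class TestLinkerSplit:
    def _parent(self, flen, rlen, linker=DEFAULT_LINKER):
        seq = "A" * flen + linker + "C" * rlen
        return SequenceRead("p1", seq, list(range(len(seq))))

    def test_exact_split_arithmetic(self):
        read = self._parent(90, 66)
        split = split_by_linker(read, DEFAULT_LINKER)
        assert split.linker_span == (90, 90 + 44)
        assert len(split.forward) == 90 and len(split.reverse) == 66
        assert split.forward.id == "p1/1" and split.reverse.id == "p1/2"
        # base and qual conservation around the span
        assert split.forward.quals == read.quals[:90]
        assert split.reverse.quals == read.quals[134:]

    def test_no_linker_is_unpaired(self):
        read = SequenceRead("p1", "ACGT" * 40, [30] * 160)
        split = split_by_linker(read, DEFAULT_LINKER)
        assert split.unpaired == read and split.forward is None

    def test_linker_at_start_demotes_to_unpaired_reverse(self):
        read = self._parent(0, 70)
        split = split_by_linker(read, DEFAULT_LINKER)
        assert split.forward is None
        assert split.unpaired is not None and len(split.unpaired) == 70

    def test_mismatched_linker_within_allowance(self):
        linker = list(DEFAULT_LINKER)
        linker[10] = "A" if linker[10] != "A" else "C"
        read = SequenceRead("p1", "G" * 80 + "".join(linker) + "T" * 60,
                            [30] * (80 + 44 + 60))
        assert split_by_linker(read, DEFAULT_LINKER, allowance=2).forward is not None
        assert split_by_linker(read, DEFAULT_LINKER, allowance=0).forward is None


class TestRoche454PairedEnd:
    def test_all_hq_linkered_reads_become_pairs(self):
        spec = FixtureSpec(platform="454", n_reads=100, read_length=200,
                           frac_linker=1.0, seed=20)
        res = generate_reads(spec)
        pf, pr, up, stats = qc_454_pe(res.reads, Roche454QCParams(linker=spec.linker))
        assert len(pf) == len(pr) == 100
        assert up == []
        assert stats.paired_surviving == 100

    def test_failing_forward_mates_go_unpaired(self):
        spec = FixtureSpec(platform="454", n_reads=100, read_length=200,
                           frac_linker=0.9, frac_linker_fwd_fail=0.1,
                           low_quality_q=5, seed=21)
        res = generate_reads(spec)
        pf, pr, up, stats = qc_454_pe(res.reads, Roche454QCParams(linker=spec.linker))
        assert len(pf) == 90
        assert len(up) == 10
        assert all(r.id.endswith("/2") for r in up)

    def test_no_linker_input_processed_as_single_end(self):
        spec = FixtureSpec(platform="454", n_reads=60, read_length=(80, 140), seed=22)
        res = generate_reads(spec)
        pf, pr, up, stats = qc_454_pe(res.reads, Roche454QCParams(linker=DEFAULT_LINKER))
        assert pf == [] and pr == []
        assert len(up) == 60
        assert stats.pairs_in == 0

    def test_base_conservation_under_splitting(self):
        spec = FixtureSpec(platform="454", n_reads=50, read_length=200,
                           frac_linker=1.0, seed=23)
        res = generate_reads(spec)
        for read in res.reads:
            split = split_by_linker(read, spec.linker)
            span = split.linker_span
            assert len(split.forward) + (span[1] - span[0]) + len(split.reverse) == len(read)
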