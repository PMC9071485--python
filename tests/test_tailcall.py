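"""Unit and property tests for poly(A) tail calling."""

import math
import re

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from paika.tailcall import (
    AlignedRead,
    GeneAnnotation,
    GeneInterval,
    HardClippedTailError,
    TailStatus,
    assign_to_gene,
    call_tail,
    classify_tail,
    compare_conditions,
    extend_a_tract,
    extract_soft_clip_tail,
    reverse_complement,
    summarize_gene_tails,
)

BODY20 = "ACGTACGTACGTACGTACGT"


def fwd_read(tail: str, body: str = BODY20, passes=10, read_id="r", gene_id=None):
    cigar = f"{len(body)}M" + (f"{len(tail)}S" if tail else "")
    return AlignedRead(read_id, body + tail, cigar, False, "chr1", 0, passes, gene_id)


def rev_read(tail: str, body: str = BODY20, passes=10, read_id="r", gene_id=None):
    cigar = (f"{len(tail)}S" if tail else "") + f"{len(body)}M"
    return AlignedRead(
        read_id, reverse_complement(body + tail), cigar, True, "chr1", 0, passes, gene_id
    )


# ---------------------------------------------------------------------------
# soft-clip extraction


class TestExtractSoftClip:
    def test_trailing_clip_forward(self):
        read = AlignedRead("r1", BODY20 + "AAAAA", "20M5S", False, "chr1", 0)
        assert extract_soft_clip_tail(read) == "AAAAA"

    def test_no_clip_is_empty(self):
        read = AlignedRead("r1", "A" * 25, "25M", False, "chr1", 0)
        assert extract_soft_clip_tail(read) == ""

    def test_reverse_strand_reverse_complements_leading_clip(self):
        # stored leading clip TTTTT -> transcript-orientation tail AAAAA
        read = AlignedRead("r1", "TTTTT" + BODY20, "5S20M", True, "chr1", 0)
        assert extract_soft_clip_tail(read) == "AAAAA"

    def test_hard_clip_at_3prime_is_unusable(self):
        read = AlignedRead("r1", BODY20, "20M5H", False, "chr1", 0)
        with pytest.raises(HardClippedTailError):
            extract_soft_clip_tail(read)

    def test_malformed_cigar_rejected(self):
        with pytest.raises(ValueError):
            AlignedRead("r1", "ACGT", "4Q", False, "chr1", 0)

    def test_seq_cigar_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            AlignedRead("r1", "ACGT", "5M", False, "chr1", 0)

    def test_leading_clip_on_forward_read_is_not_a_tail(self):
        read = AlignedRead("r1", "GGG" + BODY20, "3S20M", False, "chr1", 0)
        assert extract_soft_clip_tail(read) == ""


# ---------------------------------------------------------------------------
# A-tract extension


class TestExtendATract:
    @pytest.mark.parametrize(
        "suffix,tail,expected",
        [
            ("GCGAAA", "AAAAA", "AAAAAAAA"),  # 3-A run moved, 8 nt total
            ("GACT", "AAAA", "AAAA"),  # suffix does not end in A
            ("AAAA", "AA", "AAAAAA"),  # whole suffix is the run
            ("GCGN", "AAA", "AAA"),  # N is not A
            ("GCANA", "AA", "AAA"),  # run stops at N
        ],
    )
    def test_examples(self, suffix, tail, expected):
        assert extend_a_tract(suffix, tail) == expected

    @given(
        suffix=st.text(alphabet="ACGTN", max_size=30),
        tail=st.text(alphabet="ACGTN", max_size=30),
    )
    def test_idempotent(self, suffix, tail):
        once = extend_a_tract(suffix, tail)
        # after extension the suffix's terminal A-run is exhausted
        trimmed = suffix[: len(suffix) - (len(once) - len(tail))]
        assert extend_a_tract(trimmed, once) == once

    @given(
        suffix=st.text(alphabet="ACGT", max_size=30),
        tail=st.text(alphabet="ACGT", max_size=30),
    )
    def test_conserves_bases(self, suffix, tail):
        out = extend_a_tract(suffix, tail)
        moved = len(out) - len(tail)
        assert out.endswith(tail)
        assert set(out[:moved]) <= {"A"}
        assert moved == 0 or suffix[-moved:] == "A" * moved


# ---------------------------------------------------------------------------
# classification


class TestClassifyTail:
    def test_long_a_run_accepted(self):
        call = classify_tail("A" * 10, passes=10, min_passes=7)
        assert call.status is TailStatus.ACCEPTED
        assert call.tail_len == 10

    def test_three_as_in_first_eight_rejected(self):
        call = classify_tail("AACGTGCT" + "AAAA", passes=10)
        assert call.status is TailStatus.REJECTED_LOW_A

    def test_exactly_four_as_accepted(self):
        # the filter removes tails with *less than* 4 As; 4 is not less than 4
        call = classify_tail("AAAATTTT", passes=10)
        assert call.status is TailStatus.ACCEPTED

    def test_empty_tail_is_no_clip(self):
        assert classify_tail("", passes=10).status is TailStatus.REJECTED_NO_CLIP

    def test_low_pass_filtered(self):
        call = classify_tail("A" * 20, passes=6, min_passes=7)
        assert call.status is TailStatus.FILTERED_LOW_PASS

    def test_pass_seven_is_kept(self):
        assert classify_tail("A" * 20, passes=7, min_passes=7).status is TailStatus.ACCEPTED

    def test_absent_passes_not_filtered(self):
        assert classify_tail("A" * 20, passes=None).status is TailStatus.ACCEPTED

    def test_pass_filter_can_be_disabled(self):
        call = classify_tail("A" * 20, passes=1, enforce_pass_filter=False)
        assert call.status is TailStatus.ACCEPTED

    def test_non_nucleotide_characters_rejected(self):
        with pytest.raises(ValueError):
            classify_tail("AAAXAAA")

    @given(tail=st.text(alphabet="ACGTN", max_size=40), passes=st.integers(0, 30))
    def test_accepted_implies_at_least_four_as(self, tail, passes):
        call = classify_tail(tail, passes=passes, min_passes=7)
        if call.status is TailStatus.ACCEPTED:
            assert call.tail_len >= 4
            head = tail[: min(8, len(tail))].upper()
            assert head.count("A") >= 4
        if call.status is TailStatus.REJECTED_NO_CLIP:
            assert call.tail_len == 0

    @given(tail=st.text(alphabet="ACGTN", min_size=1, max_size=3))
    def test_tails_shorter_than_four_always_fail(self, tail):
        assert classify_tail(tail, passes=10).status is TailStatus.REJECTED_LOW_A


class TestCallTailDeterminismAndStrand:
    def test_identical_input_identical_call(self):
        read = fwd_read("AAAAAAAAAA")
        assert call_tail(read) == call_tail(read)

    @given(tail_len=st.integers(0, 50), seed=st.integers(0, 1000))
    def test_strand_consistency(self, tail_len, seed):
        # a forward read and its exact reverse-complement stored as a
        # reverse-strand alignment must yield identical tail calls
        rng = np.random.default_rng(seed)
        body = "".join(rng.choice(list("ACGT"), 20))
        tail = "A" * tail_len
        fwd = call_tail(fwd_read(tail, body))
        rev = call_tail(rev_read(tail, body))
        assert (fwd.status, fwd.tail_seq) == (rev.status, rev.tail_seq)

    def test_a_tract_extension_applied_in_pipeline(self):
        # aligned body ends in GAAA: the 3-A run belongs to the tail
        body = "ACGTACGTACGTACGT" + "GAAA"
        call = call_tail(fwd_read("AAAAA", body))
        assert call.status is TailStatus.ACCEPTED
        assert call.tail_len == 8


# ---------------------------------------------------------------------------
# brute-force oracle equivalence


def oracle_tail_length(seq: str, cigar: str, is_reverse: bool) -> int:
    """Independent clip arithmetic: re-derive the extended tail length
    directly from (sequence, CIGAR) by position bookkeeping."""
    ops = [(int(n), op) for n, op in re.findall(r"(\d+)([MIDNSHP=X])", cigar)]
    lead = ops[0][0] if ops[0][1] == "S" else 0
    trail = ops[-1][0] if ops[-1][1] == "S" else 0
    if is_reverse:
        clip = reverse_complement(seq[:lead]) if lead else ""
        aligned = reverse_complement(seq[lead: len(seq) - trail if trail else len(seq)])
    else:
        clip = seq[len(seq) - trail:] if trail else ""
        aligned = seq[lead: len(seq) - trail if trail else len(seq)]
    if not clip:
        return 0
    run = len(aligned) - len(aligned.rstrip("A"))
    return run + len(clip)


def test_oracle_equivalence_on_small_fixture(small_sim):
    reads, truth, _ = small_sim
    subset = reads[:50]
    for read in subset:
        call = call_tail(read, enforce_pass_filter=False)
        assert call.tail_len == oracle_tail_length(read.seq, read.cigar, read.is_reverse)


# ---------------------------------------------------------------------------
# gene assignment


@pytest.fixture
def annotation():
    ann = GeneAnnotation()
    ann.add(GeneInterval("G1", "chr1", 0, 1000, "+"))
    ann.add(GeneInterval("G2", "chr1", 250, 2000, "+"))
    ann.add(GeneInterval("G3", "chr1", 0, 1000, "-"))
    return ann


class TestAssignToGene:
    def test_simple_overlap(self, annotation):
        read = AlignedRead("r", "A" * 200, "200M", False, "chr1", 100)
        assert assign_to_gene(read, annotation) == "G1"

    def test_largest_overlap_wins(self, annotation):
        # spans [850, 1050): overlaps G1 by 150 nt, G2 by 200 nt
        read = AlignedRead("r", "A" * 200, "200M", False, "chr1", 850)
        assert assign_to_gene(read, annotation) == "G2"

    def test_tie_broken_lexicographically(self):
        ann = GeneAnnotation()
        ann.add(GeneInterval("GB", "chr1", 0, 500, "+"))
        ann.add(GeneInterval("GA", "chr1", 0, 500, "+"))
        read = AlignedRead("r", "A" * 100, "100M", False, "chr1", 50)
        assert assign_to_gene(read, ann) == "GA"

    def test_strand_aware(self, annotation):
        read = AlignedRead("r", "A" * 200, "200M", True, "chr1", 100)
        assert assign_to_gene(read, annotation) == "G3"

    def test_unknown_reference_unassigned(self, annotation):
        read = AlignedRead("r", "A" * 200, "200M", False, "chr9", 100)
        assert assign_to_gene(read, annotation) is None


# ---------------------------------------------------------------------------
# per-gene summaries


def accepted(gene_id, length, read_id="r"):
    return classify_tail("A" * length, passes=10, read_id=read_id, gene_id=gene_id)


class TestSummaries:
    def test_identical_lengths(self):
        calls = [accepted("G1", 100, f"r{i}") for i in range(10)]
        (summary,) = summarize_gene_tails(calls)
        assert summary.geom_mean_len == pytest.approx(100.0)
        assert summary.n_transcripts == 10

    def test_geometric_mean_is_exp_mean_log(self):
        calls = [accepted("G1", L, f"r{i}") for i, L in enumerate([10] * 5 + [1000] * 5)]
        (summary,) = summarize_gene_tails(calls)
        assert summary.geom_mean_len == pytest.approx(100.0)

    def test_nine_transcripts_filtered(self):
        calls = [accepted("G1", 100, f"r{i}") for i in range(9)]
        assert summarize_gene_tails(calls, min_transcripts=10) == []

    def test_rejected_calls_do_not_count(self):
        calls = [accepted("G1", 100, f"r{i}") for i in range(10)]
        calls += [classify_tail("", read_id="x", gene_id="G1") for _ in range(5)]
        (summary,) = summarize_gene_tails(calls)
        assert summary.n_transcripts == 10

    def test_geom_mean_between_min_and_max(self, rng):
        lengths = rng.integers(5, 300, size=25)
        calls = [accepted("G1", int(L), f"r{i}") for i, L in enumerate(lengths)]
        (summary,) = summarize_gene_tails(calls)
        assert lengths.min() <= summary.geom_mean_len <= lengths.max()

    @pytest.mark.parametrize("min_transcripts", [1, 5, 10, 20])
    def test_filter_monotone_in_min_transcripts(self, rng, min_transcripts):
        calls = []
        for g in range(8):
            for i in range(int(rng.integers(1, 25))):
                calls.append(accepted(f"G{g}", 50, f"r{g}_{i}"))
        n_low = len(summarize_gene_tails(calls, min_transcripts=min_transcripts))
        n_high = len(summarize_gene_tails(calls, min_transcripts=min_transcripts + 5))
        assert n_high <= n_low


def test_raising_min_passes_never_accepts_more(small_sim):
    reads, _, _ = small_sim
    counts = []
    for min_passes in (0, 7, 12, 20):
        calls = [call_tail(r, min_passes=min_passes) for r in reads]
        counts.append(sum(c.status is TailStatus.ACCEPTED for c in calls))
    assert counts == sorted(counts, reverse=True)


# ---------------------------------------------------------------------------
# condition comparison


def make_summaries_and_calls(lengths_by_gene):
    calls = []
    for gene, lengths in lengths_by_gene.items():
        for i, L in enumerate(lengths):
            calls.append(accepted(gene, L, f"{gene}_{i}"))
    return summarize_gene_tails(calls, min_transcripts=1), calls


class TestCompareConditions:
    def test_identity(self):
        data = {"G1": [80, 90, 100], "G2": [50, 60, 70]}
        s, c = make_summaries_and_calls(data)
        cmp = compare_conditions(s, s, c, c, bins=(5, 90, 200))
        assert cmp.median_a == cmp.median_b
        assert (cmp.per_gene["geom_mean_a"] == cmp.per_gene["geom_mean_b"]).all()
        assert (cmp.bin_fractions["a"] == cmp.bin_fractions["b"]).all()

    def test_doubling_scales_median(self):
        data = {"G1": [80, 90, 100], "G2": [50, 60, 70]}
        s_a, c_a = make_summaries_and_calls(data)
        s_b, c_b = make_summaries_and_calls({g: [2 * L for L in ls] for g, ls in data.items()})
        cmp = compare_conditions(s_a, s_b, c_a, c_b, bins=(5, 90, 400))
        assert cmp.median_b == pytest.approx(2 * cmp.median_a)

    def test_bin_fractions_sum_to_one_over_covered_bins(self):
        data = {"G1": [10, 50, 95, 150, 180]}
        s, c = make_summaries_and_calls(data)
        cmp = compare_conditions(s, s, c, c, bins=(5, 90, 200))
        assert cmp.bin_fractions["a"].sum() == pytest.approx(1.0)

    def test_no_shared_genes_warns(self):
        s_a, c_a = make_summaries_and_calls({"G1": [100] * 3})
        s_b, c_b = make_summaries_and_calls({"G2": [100] * 3})
        with pytest.warns(UserWarning):
            cmp = compare_conditions(s_a, s_b, c_a, c_b)
        assert cmp.per_gene.empty
        assert math.isnan(cmp.median_a)
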