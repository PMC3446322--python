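"""The closing core: trimming, voting extension, merging, rewriting."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gapclose.extension import (
    apply_closure,
    build_kmer_store,
    extend_edge,
    extend_step,
    fill_gap,
    trim_gap_edges,
    try_close,
)
from gapclose.model import (
    ClosureResult,
    GapRecord,
    GapStatus,
    KmerStore,
    Parameters,
    Reason,
    Scaffold,
    find_gaps,
    revcomp,
)


def _record(expected_len, start=0, end=0):
    return GapRecord("s", start, end or expected_len, expected_len)


class TestTrimGapEdges:
    def test_interior_gap_enlarged_both_sides(self):
        sc = Scaffold("s", "A" * 10 + "N" * 5 + "C" * 10)
        trimmed, recs = trim_gap_edges(sc, find_gaps(sc), t=2)
        assert len(recs) == 1
        rec = recs[0]
        assert (rec.start, rec.end) == (8, 17)
        assert rec.expected_len == 5 + 2 + 2
        assert trimmed.seq == "A" * 8 + "N" * 9 + "C" * 8
        assert len(trimmed.seq) == len(sc.seq)

    def test_t_zero_is_identity(self):
        sc = Scaffold("s", "A" * 10 + "N" * 5 + "C" * 10)
        trimmed, recs = trim_gap_edges(sc, find_gaps(sc), t=0)
        assert trimmed.seq == sc.seq
        assert (recs[0].start, recs[0].end, recs[0].expected_len) == (10, 15, 5)

    def test_short_flanks_fully_consumed_at_scaffold_ends(self):
        sc = Scaffold("s", "ANNNA")
        trimmed, recs = trim_gap_edges(sc, find_gaps(sc), t=2)
        assert (recs[0].start, recs[0].end) == (0, 5)
        assert recs[0].expected_len == 5
        assert trimmed.seq == "NNNNN"

    def test_terminal_runs_flagged_and_untrimmed(self):
        sc = Scaffold("s", "NNACGTACGTNN")
        trimmed, recs = trim_gap_edges(sc, find_gaps(sc), t=3)
        assert all(r.terminal for r in recs)
        assert trimmed.seq == sc.seq

    def test_adjacent_gaps_keep_a_separator(self):
        sc = Scaffold("s", "ACGTACGT" + "N" * 3 + "ACG" + "N" * 3 + "ACGTACGT")
        trimmed, recs = trim_gap_edges(sc, find_gaps(sc), t=10)
        assert len(find_gaps(trimmed)) == 2, "gaps must never merge"
        assert sum(r.expected_len for r in recs) == trimmed.seq.count("N")


class TestExtendStep:
    def test_majority_base_incorporated_and_kmers_consumed(self):
        store = KmerStore(4)
        store.counts = {"ACGT": 3, "ACGA": 1}
        base, reason = extend_step("ACG", store, o=2, r=0.7)
        assert (base, reason) == ("T", Reason.OK)
        assert store.counts == {"ACGA": 1}

    def test_insufficient_coverage(self):
        store = KmerStore(4)
        store.counts = {"ACGT": 1}
        assert extend_step("ACG", store, o=2, r=0.7) == (None, Reason.NO_COVERAGE)

    def test_tie_is_ambiguous(self):
        store = KmerStore(4)
        store.counts = {"ACGT": 2, "ACGA": 2}
        assert extend_step("ACG", store, o=2, r=0.7) == (None, Reason.AMBIGUOUS)

    def test_ratio_failure_is_ambiguous(self):
        store = KmerStore(4)
        store.counts = {"ACGT": 3, "ACGA": 2}
        assert extend_step("ACG", store, o=2, r=0.7) == (None, Reason.AMBIGUOUS)

    @given(
        st.lists(
            st.tuples(st.sampled_from("ACGT"), st.integers(1, 6)),
            min_size=0,
            max_size=4,
        ),
        st.integers(1, 3),
        st.floats(0.51, 1.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_oracle(self, support, o, r):
        """Voting agrees with direct enumeration of the four candidates."""
        edge = "GGT"
        store = KmerStore(4)
        for b, c in support:
            store.counts[edge + b] = store.counts.get(edge + b, 0) + c
        counts = {b: store.count(edge + b) for b in "ACGT"}
        total = sum(counts.values())
        best = max(counts.values())
        winners = [b for b in "ACGT" if counts[b] == best]
        base, reason = extend_step(edge, store, o, r)
        if best < o:
            assert (base, reason) == (None, Reason.NO_COVERAGE)
        elif len(winners) > 1 or best / total < r:
            assert (base, reason) == (None, Reason.AMBIGUOUS)
        else:
            assert base == winners[0] and reason == Reason.OK
            assert store.count(edge + base) == 0


class TestExtendEdge:
    def test_recovers_true_continuation_from_clean_reads(self):
        rng = random.Random(5)
        context = "".join(rng.choice("ACGT") for _ in range(60))
        params = Parameters(m=9)  # k = 10
        flank, truth = context[:20], context[20:40]
        reads = [context[j : j + 25] for j in range(0, 36, 2)] * 3
        store = build_kmer_store(reads, params.k)
        ext, reason = extend_edge(flank, store, params, cap=20)
        assert ext == truth

    def test_empty_store(self):
        params = Parameters(m=3)
        ext, reason = extend_edge("ACGTA", KmerStore(4), params, cap=10)
        assert (ext, reason) == ("", Reason.NO_COVERAGE)

    def test_short_or_gapped_flank(self):
        params = Parameters(m=5)
        store = KmerStore(6)
        assert extend_edge("ACG", store, params, cap=5) == ("", Reason.NO_COVERAGE)
        assert extend_edge("ACGTNACGT"[-5:], store, params, cap=5)[0] == ""

    def test_cap_bounds_growth(self):
        """Extension stops exactly at the growth cap on a long clean path."""
        rng = random.Random(8)
        context = "".join(rng.choice("ACGT") for _ in range(200))
        params = Parameters(m=9, o=1, r=0.7)
        store = build_kmer_store([context], params.k)
        ext, reason = extend_edge(context[:20], store, params, cap=37)
        assert len(ext) == 37
        assert reason is Reason.OK

    def test_cyclic_store_terminates(self):
        """A periodic k-mer set cannot loop: removal-on-use exhausts it.

        Every incorporation deletes the supporting k-mer, so extension
        length is bounded by the number of distinct k-mers in the store.
        """
        params = Parameters(m=3, o=1, r=0.7)
        store = KmerStore(4)
        # ACGA -> CGAC -> GACG -> ACGA ... a cycle regenerating its edge
        store.counts = {"ACGA": 1000, "CGAC": 1000, "GACG": 1000}
        ext, reason = extend_edge("TACG", store, params, cap=10_000)
        assert len(ext) <= 3
        assert reason is Reason.NO_COVERAGE


class TestTryClose:
    def test_merge_at_expected_length(self):
        res = try_close("ACGTGATTAAGG", "TTAAGGCCAGTA", expected_len=18, n=3, d=5)
        assert res.status is GapStatus.CLOSED
        assert res.overlap_len == 6
        assert res.inserted_seq == "ACGTGATTAAGGCCAGTA"
        assert len(res.inserted_seq) == 18

    def test_overlap_below_minimum(self):
        res = try_close("ACGTGATTAAGG", "TTAAGGCCAGTA", expected_len=18, n=10, d=5)
        assert res.status is not GapStatus.CLOSED
        assert res.reason is Reason.NO_OVERLAP

    def test_size_mismatch(self):
        res = try_close("ACGTGATTAAGG", "TTAAGGCCAGTA", expected_len=100, n=3, d=50)
        assert res.status is not GapStatus.CLOSED
        assert res.reason is Reason.SIZE_MISMATCH

    def _oracle(self, L, R, expected_len, n, d):
        candidates = []
        for x in range(n, min(len(L), len(R)) + 1):
            if L[len(L) - x :] == R[:x]:
                ins = L + R[x:]
                candidates.append((abs(len(ins) - expected_len), -x, ins, x))
        ok = [c for c in candidates if c[0] <= d]
        if ok:
            diff, negx, ins, x = min(ok)
            return ("CLOSED", ins, x)
        return ("SIZE_MISMATCH" if candidates else "NO_OVERLAP", "", 0)

    @given(st.data())
    @settings(max_examples=300, deadline=None)
    def test_matches_brute_force_oracle(self, data):
        # binary alphabet raises the accidental-overlap rate
        L = data.draw(st.text(alphabet="AC", min_size=0, max_size=30))
        R = data.draw(st.text(alphabet="AC", min_size=0, max_size=30))
        n = data.draw(st.integers(1, 6))
        d = data.draw(st.integers(0, 12))
        expected = data.draw(st.integers(0, 60))
        res = try_close(L, R, expected, n, d)
        status, ins, x = self._oracle(L, R, expected, n, d)
        if status == "CLOSED":
            assert res.status is GapStatus.CLOSED
            assert (res.inserted_seq, res.overlap_len) == (ins, x)
            assert res.overlap_len >= n
            assert abs(len(res.inserted_seq) - expected) <= d
        else:
            assert res.status is not GapStatus.CLOSED
            assert res.reason.value == status


def _gap_scenario(rng, gap_len, read_len=36, insert=150, coverage=40, m=15):
    """Build a true context, a gap record and clean reads spanning it."""
    context = "".join(rng.choice("ACGT") for _ in range(gap_len + 400))
    gs = 200
    truth = context[gs : gs + gap_len]
    left_flank = context[gs - m :gs]
    right_flank = context[gs + gap_len : gs + gap_len + m]
    n_reads = max(10, coverage * (gap_len + 200) // read_len)
    reads = []
    for _ in range(n_reads):
        p = rng.randrange(gs - 100, gs + gap_len + 100 - read_len)
        reads.append(context[p : p + read_len])
    rec = GapRecord("s", gs, gs + gap_len, gap_len)
    return truth, left_flank, right_flank, reads, rec


class TestFillGap:
    def test_clean_reads_close_gap_exactly(self):
        rng = random.Random(77)
        params = Parameters(m=15, d=50)
        truth, lf, rf, reads, rec = _gap_scenario(rng, gap_len=30)
        res = fill_gap(rec, reads, params, lf, rf)
        assert res.status is GapStatus.CLOSED
        assert res.inserted_seq == truth
        assert res.overlap_len >= params.n

    def test_no_reads(self):
        res = fill_gap(_record(20), [], Parameters(), "A" * 30, "C" * 30)
        assert (res.status, res.reason) == (GapStatus.OPEN, Reason.NO_READS)

    def test_one_sided_coverage_gives_partial(self):
        rng = random.Random(3)
        params = Parameters(m=15, d=50)
        truth, lf, rf, _, rec = _gap_scenario(rng, gap_len=200)
        # reads only over the left half of the gap neighbourhood
        context = lf + truth + rf
        reads = [context[j : j + 36] for j in range(0, 60)] * 3
        res = fill_gap(rec, reads, params, lf, rf)
        assert res.status is GapStatus.PARTIAL
        assert len(res.left_ext) > 0
        assert len(res.left_ext) > len(res.right_ext)

    def test_strand_symmetry(self):
        """Reverse complementing every recruited read changes nothing."""
        rng = random.Random(12)
        params = Parameters(m=15, d=50)
        truth, lf, rf, reads, rec = _gap_scenario(rng, gap_len=40)
        res_fwd = fill_gap(rec, reads, params, lf, rf)
        res_rc = fill_gap(rec, [revcomp(r) for r in reads], params, lf, rf)
        assert res_fwd == res_rc
        assert res_fwd.status is GapStatus.CLOSED

    def test_closed_results_respect_invariants(self):
        rng = random.Random(9)
        params = Parameters(m=15)
        for gap_len in (20, 50, 90):
            truth, lf, rf, reads, rec = _gap_scenario(rng, gap_len=gap_len)
            res = fill_gap(rec, reads, params, lf, rf)
            if res.status is GapStatus.CLOSED:
                assert res.overlap_len >= params.n
                assert abs(len(res.inserted_seq) - rec.expected_len) <= params.d


class TestApplyClosure:
    def test_closed_replaces_interval(self):
        sc = Scaffold("s", "AAAA" + "N" * 9 + "CCCC")
        rec = GapRecord("s", 4, 13, 9)
        res = ClosureResult(GapStatus.CLOSED, inserted_seq="GGGGGGGGG", overlap_len=3)
        out = apply_closure(sc, rec, res)
        assert out.seq == "AAAA" + "G" * 9 + "CCCC"
        assert len(out.seq) == len(sc.seq)

    def test_partial_keeps_expected_n_budget(self):
        sc = Scaffold("s", "AAAA" + "N" * 20 + "CCCC")
        rec = GapRecord("s", 4, 24, 20)
        res = ClosureResult(GapStatus.PARTIAL, left_ext="GGGGG", right_ext="TTT")
        out = apply_closure(sc, rec, res)
        assert out.seq == "AAAA" + "GGGGG" + "N" * 12 + "TTT" + "CCCC"

    def test_partial_always_keeps_one_n(self):
        sc = Scaffold("s", "AAAA" + "N" * 6 + "CCCC")
        rec = GapRecord("s", 4, 10, 6)
        res = ClosureResult(GapStatus.PARTIAL, left_ext="GGGG", right_ext="TTTT")
        out = apply_closure(sc, rec, res)
        assert out.seq.count("N") == 1

    def test_open_is_identity(self):
        sc = Scaffold("s", "AAAANNNNCCCC")
        rec = GapRecord("s", 4, 8, 4)
        assert apply_closure(sc, rec, ClosureResult(GapStatus.OPEN)).seq == sc.seq
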