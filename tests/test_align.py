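"""Alignment engine: exhaustive-oracle optimality, MSA invariants,
conservation statistics, blocks, indel events and length stretches."""

import itertools

import numpy as np
import pytest

from spacertyper.align import (
    Alignment,
    AlignParams,
    conservation_summary,
    count_indel_events,
    find_conserved_blocks,
    locate_length_stretches,
    needleman_wunsch,
    percent_identity,
    progressive_msa,
)
from spacertyper.seqcore import NucleotideSequence

P = AlignParams()


# ---------------------------------------------------------------------------
# Independent oracle: enumerate every global alignment, score gap runs
# ---------------------------------------------------------------------------

def _score_alignment(ga: str, gb: str, params: AlignParams) -> float:
    score = 0.0
    in_gap_a = in_gap_b = False
    for x, y in zip(ga, gb):
        if x == "-":
            score += params.gap_extend + (0 if in_gap_a else params.gap_open)
            in_gap_a, in_gap_b = True, False
        elif y == "-":
            score += params.gap_extend + (0 if in_gap_b else params.gap_open)
            in_gap_b, in_gap_a = True, False
        else:
            score += params.match if x == y else params.mismatch
            in_gap_a = in_gap_b = False
    return score


def _enumerate_alignments(a: str, b: str):
    """Every monotone global alignment of a and b (exponential)."""
    if not a and not b:
        yield "", ""
        return
    if a:
        for ga, gb in _enumerate_alignments(a[1:], b):
            yield a[0] + ga, "-" + gb
    if b:
        for ga, gb in _enumerate_alignments(a, b[1:]):
            yield "-" + ga, b[0] + gb
    if a and b:
        for ga, gb in _enumerate_alignments(a[1:], b[1:]):
            yield a[0] + ga, b[0] + gb


def _brute_force_best(a: str, b: str, params: AlignParams) -> float:
    return max(
        _score_alignment(ga, gb, params)
        for ga, gb in _enumerate_alignments(a, b)
    )


class TestNeedlemanWunsch:
    def test_identical_sequences_align_gapless(self):
        a = NucleotideSequence("a", "ACGTACGTACGTACGTACGT")
        b = NucleotideSequence("b", "ACGTACGTACGTACGTACGT")
        aln, score = needleman_wunsch(a, b)
        assert score == 20 * P.match
        assert "-" not in aln.rows[0][1] + aln.rows[1][1]

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            NucleotideSequence("b", "")

    def test_score_equals_exhaustive_oracle_on_random_pairs(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            la, lb = rng.integers(1, 7, size=2)
            a = "".join(rng.choice(list("ACGT"), size=la))
            b = "".join(rng.choice(list("ACGT"), size=lb))
            _aln, score = needleman_wunsch(
                NucleotideSequence("a", a), NucleotideSequence("b", b)
            )
            assert score == pytest.approx(_brute_force_best(a, b, P)), (a, b)

    def test_oracle_agreement_on_eight_mers(self):
        rng = np.random.default_rng(77)
        for _ in range(5):
            a = "".join(rng.choice(list("ACGT"), size=8))
            b = "".join(rng.choice(list("ACGT"), size=8))
            _aln, score = needleman_wunsch(
                NucleotideSequence("a", a), NucleotideSequence("b", b)
            )
            assert score == pytest.approx(_brute_force_best(a, b, P))

    def test_gap_strip_round_trip(self, rng):
        for _ in range(10):
            a = "".join(rng.choice(list("ACGT"), size=int(rng.integers(5, 40))))
            b = "".join(rng.choice(list("ACGT"), size=int(rng.integers(5, 40))))
            aln, _ = needleman_wunsch(
                NucleotideSequence("a", a), NucleotideSequence("b", b)
            )
            assert aln.ungapped("a") == a
            assert aln.ungapped("b") == b


class TestProgressiveMsa:
    def test_identical_sequences_stay_gapless(self):
        seqs = [NucleotideSequence(f"s{i}", "ACGTACGTAA") for i in range(3)]
        aln = progressive_msa(seqs)
        assert aln.ncols == 10
        assert all("-" not in g for _id, g in aln.rows)

    def test_two_sequences_reduce_to_pairwise(self, rng):
        a = NucleotideSequence("a", "".join(rng.choice(list("ACGT"), size=30)))
        b = NucleotideSequence("b", "".join(rng.choice(list("ACGT"), size=25)))
        msa = progressive_msa([a, b])
        pair, _ = needleman_wunsch(a, b)
        assert msa.rows == pair.rows

    def test_planted_motif_columns_align(self, rng):
        motif = "CCAACCATTGGT"
        seqs = []
        for i in range(5):
            left = "".join(rng.choice(list("ACGT"), size=int(rng.integers(10, 30))))
            right = "".join(rng.choice(list("ACGT"), size=int(rng.integers(10, 30))))
            seqs.append(NucleotideSequence(f"s{i}", left + motif + right))
        aln = progressive_msa(seqs)
        starts = set()
        for s in seqs:
            row = aln.row(s.id)
            # column of the motif start: map sequence position to column
            pos = s.residues.index(motif)
            col = [j for j, ch in enumerate(row) if ch != "-"][pos]
            starts.add(col)
        assert len(starts) == 1

    def test_gap_strip_round_trip(self, rng):
        seqs = [
            NucleotideSequence(f"s{i}", "".join(
                rng.choice(list("ACGT"), size=int(rng.integers(20, 60)))))
            for i in range(6)
        ]
        aln = progressive_msa(seqs)
        for s in seqs:
            assert aln.ungapped(s.id) == s.residues
        assert aln.ncols >= max(len(s) for s in seqs)


class TestPercentIdentity:
    def test_identical_rows(self):
        assert percent_identity("ACGT", "ACGT") == 100.0

    def test_gap_column_in_both_rows_excluded(self):
        assert percent_identity("AC-T", "AG-T") == pytest.approx(200 / 3)

    def test_no_matching_positions(self):
        assert percent_identity("ACGT", "TGCA") == 0.0

    def test_symmetric_and_column_permutation_invariant(self, rng):
        a = "AC-GTAC--GT"
        b = "ACCG-ACGT-T"
        assert percent_identity(a, b) == percent_identity(b, a)
        perm = rng.permutation(len(a))
        ap = "".join(a[i] for i in perm)
        bp = "".join(b[i] for i in perm)
        assert percent_identity(ap, bp) == pytest.approx(percent_identity(a, b))


class TestConservationSummary:
    def test_two_rows_sd_zero_by_convention(self):
        aln = Alignment([("a", "ACGTA"), ("b", "ACGTT")])
        cs = conservation_summary(aln)
        assert cs.mean_pid == 80.0
        assert cs.sd_pid == 0.0

    def test_identical_rows_mean_100_sd_0(self):
        aln = Alignment([(f"s{i}", "ACGTACGT") for i in range(4)])
        cs = conservation_summary(aln)
        assert cs.mean_pid == 100.0 and cs.sd_pid == 0.0

    def test_matches_brute_force_recomputation(self, rng):
        rows = [
            (f"s{i}", "".join(rng.choice(list("ACGT-"), size=30)))
            for i in range(5)
        ]
        rows = [(i, r) for i, r in rows]
        aln = Alignment(rows)
        cs = conservation_summary(aln)
        vals = [
            percent_identity(rows[i][1], rows[j][1])
            for i, j in itertools.combinations(range(5), 2)
        ]
        assert cs.mean_pid == pytest.approx(np.mean(vals))
        assert cs.sd_pid == pytest.approx(np.std(vals, ddof=1))
        assert cs.min_pid <= cs.mean_pid <= cs.max_pid
        assert np.allclose(cs.pid_matrix, cs.pid_matrix.T)
        assert np.all(np.diag(cs.pid_matrix) == 100.0)


class TestConservedBlocks:
    def test_shared_head_motif_is_first_block(self, rng):
        rows = [
            ("s%d" % i, "CCAACCAT" + "".join(rng.choice(list("ACGT"), size=20)))
            for i in range(5)
        ]
        blocks = find_conserved_blocks(Alignment(rows), min_len=4, min_col_identity=90)
        assert blocks[0][0][0] == 0
        assert blocks[0][1].startswith("CCAACCAT")

    def test_shared_terminal_block(self, rng):
        rows = [
            ("s%d" % i, "".join(rng.choice(list("ACGT"), size=20)) + "TGGT")
            for i in range(5)
        ]
        blocks = find_conserved_blocks(Alignment(rows), min_len=4, min_col_identity=90)
        assert blocks[-1][0][1] == 24
        assert blocks[-1][1].endswith("TGGT")

    def test_random_alignments_rarely_hold_long_blocks(self):
        rng = np.random.default_rng(5)
        hits = 0
        for _ in range(20):
            rows = [
                ("s%d" % i, "".join(rng.choice(list("ACGT"), size=60)))
                for i in range(8)
            ]
            blocks = find_conserved_blocks(
                Alignment(rows), min_len=6, min_col_identity=90
            )
            hits += bool(blocks)
        assert hits <= 1  # >= 95% of replicates clean

    def test_tie_becomes_iupac_union(self):
        rows = [("a", "AAAA"), ("b", "AAGA")]
        blocks = find_conserved_blocks(Alignment(rows), min_len=4, min_col_identity=50)
        assert blocks[0][1] == "AARA"


class TestIndelEvents:
    def test_ten_bp_deletion_at_position_672(self, rng):
        base = "".join(rng.choice(list("ACGT"), size=700))
        focus = base[:671] + "-" * 10 + base[681:]
        aln = Alignment([("ref", base), ("bn", focus)])
        events = count_indel_events(aln, "bn")
        assert len(events) == 1
        ev = events[0]
        assert ev["kind"] == "deletion"
        assert ev["columns"] == (672, 681)
        assert ev["length"] == 10

    def test_gapless_alignment_has_no_events(self):
        aln = Alignment([("a", "ACGTACGT"), ("b", "ACCTACGA")])
        assert count_indel_events(aln, "a") == []

    def test_three_separated_runs_are_three_events(self):
        a = "ACGTACGTACGTACGTACGT"
        b = "AC--ACGTA--TACGTAC-T"
        aln = Alignment([("a", a), ("b", b)])
        events = count_indel_events(aln, "b")
        assert len(events) == 3
        assert all(e["kind"] == "deletion" for e in events)

    def test_insertion_unique_to_focus(self):
        aln = Alignment([
            ("a", "ACGTAAAACGT"),
            ("b", "ACGT----CGT"),
            ("c", "ACGT----CGT"),
        ])
        events = count_indel_events(aln, "a")
        assert [e["kind"] for e in events] == ["insertion"]
        assert events[0]["length"] == 4


class TestLengthStretches:
    def _panel(self):
        # group_a carries three extra stretches of 21, 51 and 43 columns.
        blocks = [(22, 43), (50, 101), (110, 153)]
        ncols = 180
        row_a = ["A"] * ncols
        row_b = ["A"] * ncols
        for s, e in blocks:
            for j in range(s, e):
                row_b[j] = "-"
        return Alignment([
            ("a1", "".join(row_a)), ("a2", "".join(row_a)),
            ("b1", "".join(row_b)), ("b2", "".join(row_b)),
        ]), blocks

    def test_planted_stretches_recovered(self):
        aln, blocks = self._panel()
        out = locate_length_stretches(aln, ["a1", "a2"], ["b1", "b2"], min_len=20)
        assert [iv for iv, _len in out] == blocks
        assert [ln for _iv, ln in out] == [21, 51, 43]

    def test_identical_groups_have_no_stretches(self):
        aln = Alignment([("a", "ACGT" * 10), ("b", "ACGT" * 10)])
        assert locate_length_stretches(aln, ["a"], ["b"], min_len=5) == []

    def test_short_stretch_excluded_by_min_len(self):
        aln, _ = self._panel()
        out = locate_length_stretches(aln, ["a1", "a2"], ["b1", "b2"], min_len=44)
        assert [ln for _iv, ln in out] == [51]
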