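"""Shared exhaustive oracles, independent of the package's DP code."""

from spacertyper.align import AlignParams
from spacertyper.structure import DEFAULT_FOLD_PARAMS


def _score_alignment(ga, gb, params):
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


def _enumerate_alignments(a, b):
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


def brute_force_nw(a, b, params=AlignParams()):
    return max(
        _score_alignment(ga, gb, params) for ga, gb in _enumerate_alignments(a, b)
    )


_PAIRS = {("G", "C"), ("C", "G"), ("A", "T"), ("T", "A"), ("G", "T"), ("T", "G")}


def _enumerate_structures(seq, i, j, min_loop):
    if j - i <= min_loop + 1:
        yield frozenset()
        return
    for s in _enumerate_structures(seq, i + 1, j, min_loop):
        yield s
    for k in range(i + min_loop + 1, j):
        if (seq[i], seq[k]) not in _PAIRS:
            continue
        for inner in _enumerate_structures(seq, i + 1, k, min_loop):
            for outer in _enumerate_structures(seq, k + 1, j, min_loop):
                yield inner | outer | {(i, k)}


def brute_force_fold(seq, params=DEFAULT_FOLD_PARAMS):
    best = 0.0
    for pairs in _enumerate_structures(seq, 0, len(seq), params.min_loop):
        score = 0.0
        for i, j in pairs:
            score += params.weight(seq[i], seq[j])
            if (i + 1, j - 1) in pairs:
                score += params.stack_bonus
        best = min(best, score)
    return best
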