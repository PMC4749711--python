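"""ITS-2 hairpin secondary-structure prediction by dynamic programming.

A Nussinov-style DP over nested base pairs with simple integer weights
(GC -3, AT -2, GT wobble -1) and a -1 stacking bonus for each pair
stacked directly on another.  The resulting "stability" is explicitly
unitless and only ordering-comparable (more negative = more stable): the
point is to separate long-stem forms from short hairpins, the putative
RNase III processing substrates, not to estimate free energies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seqcore import NucleotideSequence

_PAIR_WEIGHT = {
    ("G", "C"): -3.0, ("C", "G"): -3.0,
    ("A", "T"): -2.0, ("T", "A"): -2.0,
    ("G", "T"): -1.0, ("T", "G"): -1.0,
}

_INF = float("inf")


@dataclass(frozen=True)
class FoldParams:
    gc: float = -3.0
    at: float = -2.0
    gt: float = -1.0
    stack_bonus: float = -1.0
    min_loop: int = 3
    # GT (= GU in the transcript) wobble pairing.  Note that with wobble
    # enabled the fold score is not exactly invariant under reverse
    # complement: a G:T pair complements to A:C, which cannot pair.
    allow_wobble: bool = True

    def weight(self, a: str, b: str) -> float:
        w = _PAIR_WEIGHT.get((a, b))
        if w is None:
            return _INF
        if w == -1.0 and not self.allow_wobble:
            return _INF
        return {-3.0: self.gc, -2.0: self.at, -1.0: self.gt}[w]


DEFAULT_FOLD_PARAMS = FoldParams()
LONG_STEM_BP = 8


@dataclass
class SecondaryStructure:
    pairs: set[tuple[int, int]]
    dot_bracket: str
    stem_len: int
    loop_len: int
    stability: float

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for i, j in self.pairs:
            if i >= j:
                raise ValueError("pair indices must satisfy i < j")
            if i in seen or j in seen:
                raise ValueError("index participates in more than one pair")
            seen.update((i, j))


def _pair_matrix(seq: str, params: FoldParams) -> np.ndarray:
    n = len(seq)
    W = np.full((n, n), _INF)
    for i in range(n):
        for j in range(i + params.min_loop + 1, n):
            w = params.weight(seq[i], seq[j])
            if w != _INF:
                W[i, j] = w
    return W


def _fill(seq: str, params: FoldParams):
    """DP tables.

    ``P[i][j]`` (j inclusive): best energy of s[i..j] given (i, j)
    paired; the stacking bonus is claimed by an outer pair when the
    immediately inner ends also pair.  ``E[i][j]`` (j exclusive): best
    energy of the segment s[i:j].
    """
    n = len(seq)
    W = _pair_matrix(seq, params)
    E = np.zeros((n + 1, n + 1))
    P = np.full((n, n), _INF)
    for span in range(params.min_loop + 2, n + 1):  # segment length
        for i in range(0, n - span + 1):
            j_excl = i + span
            j = j_excl - 1
            if W[i, j] != _INF:
                inner_val = E[i + 1, j]  # s[i+1 .. j-1], no bonus
                stack_val = (
                    P[i + 1, j - 1] + params.stack_bonus
                    if (j - 1) - (i + 1) > params.min_loop
                    and P[i + 1, j - 1] != _INF
                    else _INF
                )
                P[i, j] = W[i, j] + min(inner_val, stack_val)
            best = E[i + 1, j_excl]  # i unpaired
            ks = np.arange(i + params.min_loop + 1, j_excl)
            if len(ks):
                cand = P[i, ks] + E[ks + 1, j_excl]
                kmin = cand.min()
                if kmin < best:
                    best = kmin
            E[i, j_excl] = best
    return W, E, P


def fold_its2(
    its2: NucleotideSequence | str, params: FoldParams = DEFAULT_FOLD_PARAMS
) -> SecondaryStructure:
    """Minimum-"energy" nested structure of a spacer segment.

    Deterministic traceback: prefer pairing i, and among ties the
    leftmost pairing partner; inside a pair prefer the stacked
    continuation.
    """
    seq = its2.residues if isinstance(its2, NucleotideSequence) else its2
    n = len(seq)
    if n < 8:
        raise ValueError("sequence shorter than 8 nt")
    W, E, P = _fill(seq, params)

    pairs: set[tuple[int, int]] = set()

    def trace_E(i: int, j: int) -> None:
        """Structure of s[i..j-1] achieving E[i][j]."""
        while i < j:
            target = E[i, j]
            if target == 0 and j - i <= params.min_loop + 1:
                return
            found = False
            for k in range(i + params.min_loop + 1, j):
                if P[i, k] != _INF and P[i, k] + E[k + 1, j] == target:
                    trace_P(i, k)
                    i = k + 1
                    found = True
                    break
            if not found:
                i += 1  # E[i+1, j] == target

    def trace_P(i: int, j: int) -> None:
        """Structure of s[i..j] with (i, j) paired."""
        while True:
            pairs.add((i, j))
            stack_val = (
                P[i + 1, j - 1] + params.stack_bonus
                if i + 1 < j - 1 and P[i + 1, j - 1] != _INF
                else _INF
            )
            if stack_val != _INF and W[i, j] + stack_val == P[i, j]:
                i, j = i + 1, j - 1
                continue
            trace_E(i + 1, j)  # inner segment s[i+1 .. j-1]
            return

    trace_E(0, n)
    stability = float(E[0, n])
    return _build_structure(n, pairs, stability)


def _build_structure(
    n: int, pairs: set[tuple[int, int]], stability: float
) -> SecondaryStructure:
    db = ["."] * n
    for i, j in pairs:
        db[i], db[j] = "(", ")"
    stem_len, loop_len = _longest_helix(pairs)
    return SecondaryStructure(
        pairs=pairs,
        dot_bracket="".join(db),
        stem_len=stem_len,
        loop_len=loop_len,
        stability=stability,
    )


def _longest_helix(pairs: set[tuple[int, int]]) -> tuple[int, int]:
    """Length of the longest run of stacked pairs, and the unpaired span
    enclosed by that helix's innermost pair."""
    if not pairs:
        return 0, 0
    best_len, best_inner = 0, None
    by_outer = sorted(pairs)
    pairset = pairs
    seen = set()
    for i, j in by_outer:
        if (i, j) in seen:
            continue
        run = 0
        a, b = i, j
        while (a, b) in pairset:
            seen.add((a, b))
            run += 1
            a, b = a + 1, b - 1
        innermost = (a - 1, b + 1)
        if run > best_len:
            best_len = run
            best_inner = innermost
    loop = best_inner[1] - best_inner[0] - 1 if best_inner else 0
    return best_len, loop


def classify_hairpin(
    s: SecondaryStructure, long_stem_bp: int = LONG_STEM_BP
) -> dict:
    """long_stem / short_hairpin / unstructured, with the short hairpins
    flagged as putative RNase III processing targets."""
    if s.stem_len >= long_stem_bp:
        label = "long_stem"
    elif s.stem_len >= 3:
        label = "short_hairpin"
    else:
        label = "unstructured"
    return {
        "class": label,
        "stem_len": s.stem_len,
        "loop_len": s.loop_len,
        "stability": s.stability,
        "putative_rnase3_target": label == "short_hairpin",
    }


def stability_compare(a: SecondaryStructure, b: SecondaryStructure) -> int:
    """-1 if a is more stable, +1 if b is, 0 on ties (lower = stabler)."""
    if a.stability < b.stability:
        return -1
    if a.stability > b.stability:
        return 1
    return 0
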