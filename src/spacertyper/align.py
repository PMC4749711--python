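"""Pairwise and progressive multiple alignment plus per-region
conservation statistics, conserved-block discovery and indel-event
counting.

The aligner is a global (Needleman-Wunsch) affine-gap aligner, extended
to profile-profile alignment for the progressive stage.  The guide tree
comes from a 3-mer distance and UPGMA.  Emulating a production MSA tool
in role only: column-for-column agreement with external aligners is a
non-goal, but the invariants (gap-strip round trip, optimality on small
inputs) are tested against exhaustive oracles.

Scoring convention: a gap run of length k costs ``gap_open + k *
gap_extend`` (so a single-residue gap costs -6 at the defaults).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .seqcore import NucleotideSequence, IUPAC_EXPANSION

GAP = "-"

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}

#: IUPAC symbol encoding ambiguity-code column consensus (set of bases -> symbol)
_SET_TO_IUPAC = {frozenset(v): k for k, v in IUPAC_EXPANSION.items()}


@dataclass(frozen=True)
class AlignParams:
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -5.0
    gap_extend: float = -1.0


DEFAULT_PARAMS = AlignParams()


@dataclass
class Alignment:
    """A multiple alignment: rows of (seq_id, gapped string)."""

    rows: list[tuple[str, str]]
    params: AlignParams = field(default_factory=AlignParams)

    def __post_init__(self) -> None:
        lengths = {len(r[1]) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("alignment rows have unequal lengths")

    @property
    def ncols(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0

    @property
    def ids(self) -> list[str]:
        return [r[0] for r in self.rows]

    def row(self, seq_id: str) -> str:
        for rid, gapped in self.rows:
            if rid == seq_id:
                return gapped
        raise KeyError(seq_id)

    def ungapped(self, seq_id: str) -> str:
        return self.row(seq_id).replace(GAP, "")

    def column(self, j: int) -> list[str]:
        return [r[1][j] for r in self.rows]

    def to_fasta(self, path) -> None:
        from .seqcore import write_fasta

        write_fasta(
            [NucleotideSequenceGapped(rid, g) for rid, g in self.rows], path
        )


class NucleotideSequenceGapped:
    """Minimal record shim so gapped rows can reuse the FASTA writer."""

    def __init__(self, seq_id: str, residues: str):
        self.id = seq_id
        self.residues = residues
        self.description = ""


@dataclass
class ConservationSummary:
    labels: list[str]
    pid_matrix: np.ndarray  # symmetric, diagonal 100
    mean_pid: float
    sd_pid: float
    min_pid: float
    max_pid: float

    def to_dict(self) -> dict:
        return {
            "labels": self.labels,
            "mean_pid": self.mean_pid,
            "sd_pid": self.sd_pid,
            "min_pid": self.min_pid,
            "max_pid": self.max_pid,
            "pid_matrix": self.pid_matrix.tolist(),
        }


# ---------------------------------------------------------------------------
# Profile representation and the affine-gap DP engine
# ---------------------------------------------------------------------------

class _Profile:
    """Columns of residue frequencies over A,C,G,T plus gap fraction."""

    def __init__(self, rows: list[tuple[str, str]]):
        self.rows = rows
        n = len(rows[0][1])
        freqs = np.zeros((n, 4))
        gaps = np.zeros(n)
        for _rid, gapped in rows:
            enc = np.frombuffer(gapped.encode(), dtype=np.uint8)
            for b, i in _BASE_INDEX.items():
                freqs[enc == ord(b), i] += 1.0
            gaps[enc == ord(GAP)] += 1.0
            # Ambiguity symbols spread uniformly over their expansion.
            for sym, expansion in IUPAC_EXPANSION.items():
                if sym in _BASES:
                    continue
                mask = enc == ord(sym)
                if mask.any():
                    for b in expansion:
                        freqs[mask, _BASE_INDEX[b]] += 1.0 / len(expansion)
        total = len(rows)
        self.freqs = freqs / total
        self.gap_frac = gaps / total
        self.ncols = n


def _column_scores(pa: _Profile, pb: _Profile, params: AlignParams) -> np.ndarray:
    """Expected residue-pair score between every column pair.

    Gap characters already inside a profile contribute a flat
    half-gap-extend term so previously opened gaps are not re-penalised
    at the open rate.
    """
    match, mismatch = params.match, params.mismatch
    # E[score] = mismatch + (match - mismatch) * P(same base)
    psame = pa.freqs @ pb.freqs.T
    pa_res = pa.freqs.sum(axis=1)
    pb_res = pb.freqs.sum(axis=1)
    both = np.outer(pa_res, pb_res)
    s = mismatch * both + (match - mismatch) * psame
    gap_pair = (
        np.outer(pa.gap_frac, pb_res) + np.outer(pa_res, pb.gap_frac)
    )
    s += params.gap_extend * gap_pair
    return s


_DIAG, _UP, _LEFT = 0, 1, 2
_NEG = -1e30


def _gotoh(S: np.ndarray, params: AlignParams):
    """Global affine-gap DP over a precomputed column-score matrix.

    Returns (score, ops) where ops is the traceback path as a list of
    (_DIAG | _UP | _LEFT).  Tie-breaking prefers diagonal, then up
    (gap in the second profile), then left.
    """
    n, m = S.shape
    go, ge = params.gap_open, params.gap_extend
    M = np.full((n + 1, m + 1), _NEG)
    Ix = np.full((n + 1, m + 1), _NEG)  # gap in B (consume A rows)
    Iy = np.full((n + 1, m + 1), _NEG)  # gap in A (consume B cols)
    M[0, 0] = 0.0
    Ix[1:, 0] = go + ge * np.arange(1, n + 1)
    Iy[0, 1:] = go + ge * np.arange(1, m + 1)
    ptr_m = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptr_x = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0: open from M, 1: extend
    ptr_y = np.zeros((n + 1, m + 1), dtype=np.int8)

    for i in range(1, n + 1):
        prev_best = np.maximum(M[i - 1], np.maximum(Ix[i - 1], Iy[i - 1]))
        # M row: depends on previous row only.
        M[i, 1:] = S[i - 1] + prev_best[:-1]
        # Preference order encoded for traceback of the 'best' at i-1,j-1.
        ptr_m[i, 1:] = np.where(
            M[i - 1, :-1] >= np.maximum(Ix[i - 1, :-1], Iy[i - 1, :-1]),
            _DIAG,
            np.where(Ix[i - 1, :-1] >= Iy[i - 1, :-1], _UP, _LEFT),
        )
        # Ix: vertical gaps, previous row.
        open_x = M[i - 1] + go + ge
        ext_x = Ix[i - 1] + ge
        Ix[i] = np.maximum(open_x, ext_x)
        ptr_x[i] = (ext_x > open_x).astype(np.int8)
        # Iy: horizontal gaps within this row; running-max trick:
        # Iy[i, j] = max_{k<j} M[i, k] + go + (j - k) * ge
        #          = (max_{k<j} (M[i, k] - k * ge)) + go + j * ge
        base = M[i, :-1] - np.arange(m) * ge
        run = np.maximum.accumulate(base)
        Iy[i, 1:] = run + go + np.arange(1, m + 1) * ge
        # extend-vs-open pointer: extension iff the running max came from
        # an earlier k than j-1.
        ptr_y[i, 1:] = (run > base).astype(np.int8)
    end_scores = (M[n, m], Ix[n, m], Iy[n, m])
    state = int(np.argmax([end_scores[_DIAG], end_scores[_UP], end_scores[_LEFT]]))
    score = end_scores[state]

    ops: list[int] = []
    i, j = n, m
    while i > 0 or j > 0:
        if i == 0:
            ops.append(_LEFT)
            j -= 1
            continue
        if j == 0:
            ops.append(_UP)
            i -= 1
            continue
        if state == _DIAG:
            ops.append(_DIAG)
            state = int(ptr_m[i, j])
            i -= 1
            j -= 1
        elif state == _UP:
            ops.append(_UP)
            state = _UP if ptr_x[i, j] else _DIAG
            i -= 1
        else:
            ops.append(_LEFT)
            if ptr_y[i, j]:
                # extension: stay in Iy
                state = _LEFT
            else:
                state = _DIAG
            j -= 1
    ops.reverse()
    return float(score), ops


def _merge(pa: _Profile, pb: _Profile, params: AlignParams):
    S = _column_scores(pa, pb, params)
    score, ops = _gotoh(S, params)
    rows = []
    for rid, gapped in pa.rows:
        out = []
        k = 0
        for op in ops:
            if op in (_DIAG, _UP):
                out.append(gapped[k])
                k += 1
            else:
                out.append(GAP)
        rows.append((rid, "".join(out)))
    for rid, gapped in pb.rows:
        out = []
        k = 0
        for op in ops:
            if op in (_DIAG, _LEFT):
                out.append(gapped[k])
                k += 1
            else:
                out.append(GAP)
        rows.append((rid, "".join(out)))
    return _Profile(rows), score


# ---------------------------------------------------------------------------
# Public alignment operations
# ---------------------------------------------------------------------------

def needleman_wunsch(
    a: NucleotideSequence,
    b: NucleotideSequence,
    params: AlignParams = DEFAULT_PARAMS,
) -> tuple[Alignment, float]:
    """Optimal global pairwise alignment under affine gap scoring."""
    if len(a) == 0 or len(b) == 0:
        raise ValueError("cannot align empty sequences")
    pa = _Profile([(a.id, a.residues)])
    pb = _Profile([(b.id, b.residues)])
    merged, score = _merge(pa, pb, params)
    return Alignment(merged.rows, params), score


def _kmer_distance(seqs: list[NucleotideSequence], k: int = 3) -> np.ndarray:
    """1 - fractional shared k-mer count; crude but fine for a guide tree."""
    from collections import Counter

    counters = [Counter(s.residues[i: i + k] for i in range(len(s) - k + 1))
                for s in seqs]
    n = len(seqs)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = sum((counters[i] & counters[j]).values())
            denom = min(
                sum(counters[i].values()), sum(counters[j].values())
            ) or 1
            D[i, j] = D[j, i] = 1.0 - shared / denom
    return D


def progressive_msa(
    seqs: list[NucleotideSequence],
    params: AlignParams = DEFAULT_PARAMS,
) -> Alignment:
    """Progressive multiple alignment: k-mer distance, UPGMA guide tree,
    profile-profile Needleman-Wunsch merges."""
    if len(seqs) < 2:
        raise ValueError("need >= 2 sequences")
    ids = [s.id for s in seqs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    if len(seqs) == 2:
        aln, _ = needleman_wunsch(seqs[0], seqs[1], params)
        return aln
    D = _kmer_distance(seqs)
    Z = linkage(squareform(D, checks=False), method="average")
    profiles: dict[int, _Profile] = {
        i: _Profile([(s.id, s.residues)]) for i, s in enumerate(seqs)
    }
    n = len(seqs)
    for step, (left, right, _dist, _count) in enumerate(Z):
        pa, pb = profiles.pop(int(left)), profiles.pop(int(right))
        merged, _score = _merge(pa, pb, params)
        profiles[n + step] = merged
    final = profiles[n + len(Z) - 1]
    order = {sid: i for i, sid in enumerate(ids)}
    rows = sorted(final.rows, key=lambda r: order[r[0]])
    return Alignment(rows, params)


def percent_identity(row_a: str, row_b: str) -> float:
    """100 x matches / columns where at least one row is non-gap.

    Treats indels as differences; the alternative denominator (columns
    where both rows are non-gap) is available via
    ``percent_identity_ungapped``.
    """
    if len(row_a) != len(row_b):
        raise ValueError("rows have different lengths")
    matches = 0
    counted = 0
    for x, y in zip(row_a, row_b):
        if x == GAP and y == GAP:
            continue
        counted += 1
        if x == y and x != GAP:
            matches += 1
    if counted == 0:
        raise ValueError("rows are entirely gaps")
    return 100.0 * matches / counted


def percent_identity_ungapped(row_a: str, row_b: str) -> float:
    """100 x matches / columns where both rows are non-gap."""
    if len(row_a) != len(row_b):
        raise ValueError("rows have different lengths")
    matches = 0
    counted = 0
    for x, y in zip(row_a, row_b):
        if x == GAP or y == GAP:
            continue
        counted += 1
        if x == y:
            matches += 1
    if counted == 0:
        raise ValueError("no shared non-gap columns")
    return 100.0 * matches / counted


def conservation_summary(
    aln: Alignment, method: str = "pairwise"
) -> ConservationSummary:
    """Mean/SD (n-1 denominator) over upper-triangle pairwise identities."""
    if len(aln.rows) < 2:
        raise ValueError("need >= 2 rows")
    pid = percent_identity if method == "pairwise" else percent_identity_ungapped
    n = len(aln.rows)
    mat = np.full((n, n), 100.0)
    vals = []
    for i in range(n):
        for j in range(i + 1, n):
            p = pid(aln.rows[i][1], aln.rows[j][1])
            mat[i, j] = mat[j, i] = p
            vals.append(p)
    vals = np.asarray(vals)
    sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    return ConservationSummary(
        labels=aln.ids,
        pid_matrix=mat,
        mean_pid=float(vals.mean()),
        sd_pid=sd,
        min_pid=float(vals.min()),
        max_pid=float(vals.max()),
    )


def _column_majority(column: list[str]) -> tuple[str, float]:
    """(consensus symbol, majority fraction); ties become IUPAC unions."""
    from collections import Counter

    counts = Counter(column)
    top = max(counts.values())
    winners = frozenset(
        itertools.chain.from_iterable(
            IUPAC_EXPANSION.get(sym, frozenset())
            for sym, c in counts.items()
            if c == top and sym != GAP
        )
    )
    if not winners:
        return GAP, 0.0
    symbol = _SET_TO_IUPAC[winners]
    return symbol, top / len(column)


def find_conserved_blocks(
    aln: Alignment, min_len: int = 4, min_col_identity: float = 90.0
) -> list[tuple[tuple[int, int], str]]:
    """Maximal runs of >= min_len gap-free columns whose majority residue
    reaches min_col_identity (%).  Returns 0-based half-open column
    intervals with majority consensus strings (ties as IUPAC unions)."""
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    good = []
    consensus = []
    for j in range(aln.ncols):
        col = aln.column(j)
        sym, frac = _column_majority(col)
        gap_free = GAP not in col
        good.append(gap_free and 100.0 * frac >= min_col_identity)
        consensus.append(sym)
    blocks = []
    j = 0
    while j < aln.ncols:
        if good[j]:
            start = j
            while j < aln.ncols and good[j]:
                j += 1
            if j - start >= min_len:
                blocks.append(((start, j), "".join(consensus[start:j])))
        else:
            j += 1
    return blocks


def _gap_runs(row: str) -> list[tuple[int, int]]:
    runs = []
    j = 0
    while j < len(row):
        if row[j] == GAP:
            start = j
            while j < len(row) and row[j] == GAP:
                j += 1
            runs.append((start, j))
        else:
            j += 1
    return runs


def count_indel_events(
    aln: Alignment, focus_row: str
) -> list[dict]:
    """Indel events of one sequence against the rest of the alignment.

    A deletion is a maximal gap run in the focus row where at least one
    other row has residues; an insertion is a maximal run of columns
    where the focus row has residues but every other row is gapped.
    Events carry 1-based alignment-column and focus-sequence coordinates.
    """
    focus = aln.row(focus_row)
    others = [g for rid, g in aln.rows if rid != focus_row]
    if not others:
        raise ValueError("alignment has no other rows")

    # Map alignment column -> 1-based focus-sequence position (of the
    # nearest focus residue at or before the column).
    events = []
    for start, end in _gap_runs(focus):
        if all(all(o[j] == GAP for o in others) for j in range(start, end)):
            continue  # all-gap columns are not events
        events.append({
            "kind": "deletion",
            "columns": (start + 1, end),
            "length": end - start,
        })
    # Insertion: focus residue columns where all others are gaps.
    j = 0
    while j < aln.ncols:
        if focus[j] != GAP and all(o[j] == GAP for o in others):
            start = j
            while (
                j < aln.ncols
                and focus[j] != GAP
                and all(o[j] == GAP for o in others)
            ):
                j += 1
            events.append({
                "kind": "insertion",
                "columns": (start + 1, j),
                "length": j - start,
            })
        else:
            j += 1
    # Attach focus-sequence coordinates.
    pos = 0
    col_to_seqpos = []
    for ch in focus:
        if ch != GAP:
            pos += 1
        col_to_seqpos.append(pos)
    for ev in events:
        c0, c1 = ev["columns"]
        if ev["kind"] == "insertion":
            ev["seq_positions"] = (col_to_seqpos[c0 - 1], col_to_seqpos[c1 - 1])
        else:
            ev["seq_positions"] = (col_to_seqpos[c0 - 1], col_to_seqpos[c0 - 1])
    events.sort(key=lambda e: e["columns"])
    return events


def locate_length_stretches(
    aln: Alignment,
    group_a: list[str],
    group_b: list[str],
    min_len: int = 20,
) -> list[tuple[tuple[int, int], int]]:
    """Group-level presence/absence stretches.

    Maximal column runs of >= min_len where every group_a row has a
    residue and every group_b row is gapped; 0-based half-open column
    intervals with lengths.
    """
    if not group_a or not group_b or set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint and non-empty")
    rows_a = [aln.row(r) for r in group_a]
    rows_b = [aln.row(r) for r in group_b]
    flags = [
        all(r[j] != GAP for r in rows_a) and all(r[j] == GAP for r in rows_b)
        for j in range(aln.ncols)
    ]
    stretches = []
    j = 0
    while j < aln.ncols:
        if flags[j]:
            start = j
            while j < aln.ncols and flags[j]:
                j += 1
            if j - start >= min_len:
                stretches.append(((start, j), j - start))
        else:
            j += 1
    return stretches
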