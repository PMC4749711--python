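"""Seeded generator of synthetic rRNA-operon panels with known ground
truth.

The generator emulates the statistical structure of a drinking-water
sphingomonad survey: a panel of reference clade templates plus isolate
descendants, spacer (ITS) lengths inside a 415-849 bp envelope, G+C in
42.2-57.9 mol%, the five tRNA arrangements with the Ala+Ile pattern
dominant, ITS-2 size groups (16-19 / 60-61 / 122-138 nt plus an
unbinned remainder), conserved CCAACCAT / TGGT blocks at the ITS-2
boundaries, and JC-style substitution plus small indel events between a
clade template and its isolates.

Every operon is [16S tail carrying the forward primer site] + ITS +
[23S head carrying the reverse primer site], so the in-silico PCR
stage can excise the planted spacer exactly.  Ground truth (gene
positions, type, subregions, size group, clade) is recorded alongside
and is byte-consistent with the emitted FASTA.

Biological features deliberately not modelled: rRNA secondary structure
in the flanking scaffolds, recombination, and within-gene tRNA sequence
divergence (planted genes are mutation-protected, mirroring the strict
length/structure conservation of real spacer tRNAs).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .arrangement import assign_its2_group
from .seqcore import Interval, NucleotideSequence, gc_content, reverse_complement
from .trna import Geometry, _PAIR_SCORE, _BASE_INDEX

_BASES = "ACGT"

# Fixed flanking scaffolds (200 nt each).  The forward primer site sits at
# the very 3' end of the 16S tail and the reverse primer site at the very
# 5' start of the 23S head, so the spacer between the footprints is the ITS.
_FWD_SITE = "AAGTCGTAACAAGGTAACCG"           # 16S-1511f with R -> A
_REV_SITE = reverse_complement("TCGCCAAGGCATCCACC")  # 23S-23r with Y -> T, C

_scaffold_rng = np.random.default_rng(20160211)
SCAFFOLD_16S = (
    "".join(_scaffold_rng.choice(list(_BASES), size=180)) + _FWD_SITE
)
SCAFFOLD_23S = _REV_SITE + "".join(_scaffold_rng.choice(list(_BASES), size=183))

# Panel-conserved boundary blocks inside the ITS (boxA-like leader after
# the 16S terminus, and a conserved run before the 23S start).  These are
# the columns that survive complete deletion across the whole panel.
CONSERVED_LEADER = "TTGAAGGTTAGCGAAGCAAGACCT"
CONSERVED_TAIL = "AAGGTTAAGCCTCACGGTTC"

MOTIF_HEAD = "CCAACCAT"
MOTIF_TAIL = "TGGT"

_CANONICAL_GEOMETRY = {
    "Ala": Geometry(acc=7, d=4, d_loop=8, var=5, t_loop=7),   # 73 nt
    "Ile": Geometry(acc=7, d=4, d_loop=8, var=6, t_loop=7),   # 74 nt
}
_ANTICODON = {"Ala": "TGC", "Ile": "GAT"}

#: Panel-wide ITS-2 divergence scale (JC substitutions/site between a
#: size group's ancestral core and each clade template's core; isolates
#: diverge from their template core at a fixed 0.25x this scale).
#: Calibrated once with scripts/calibrate.py so that the default panel's
#: mean pairwise ITS-2 identity lands on the survey's 22.5% headline.
DEFAULT_ITS2_DIVERGENCE = 3.0


class PanelConfigError(ValueError):
    """Raised for infeasible generator configurations."""


@dataclass
class PanelConfig:
    """Study-scale defaults: 14 reference templates + 23 isolates."""

    n_references: int = 14
    n_isolates: int = 23
    its_len_bounds: tuple[int, int] = (415, 849)
    # Templates are drawn inside an interior margin so that isolate
    # indels cannot push a descendant outside the printed envelope.
    template_len_margin: int = 15
    gc_bounds_molpct: tuple[float, float] = (42.2, 57.9)
    gc_target_margin: float = 1.3
    type_mix: dict[str, float] = field(default_factory=lambda: {
        "ITS_AlaIle": 0.60,
        "ITS_IleAla": 0.10,
        "ITS_IlePseudo": 0.10,
        "ITS_Ala": 0.10,
        "ITS_none": 0.10,
    })
    its2_group_mix: dict[str, float] = field(default_factory=lambda: {
        "short(16-19)": 0.20,
        "mid(60-61)": 0.20,
        "long(122-138)": 0.15,
        "other": 0.45,
    })
    its2_divergence: float = DEFAULT_ITS2_DIVERGENCE
    # ITS-2 is the hypervariable region: isolates diverge from their clade
    # template inside the ITS-2 core at this fixed fraction of the
    # panel-wide ITS-2 scale, much faster than the rest of the spacer.
    within_clade_its2_factor: float = 0.25
    isolate_divergence: float = 0.02
    leader_divergence: float = 0.04
    indel_rate: float = 1.0
    indel_len_p: float = 0.35   # geometric; mean run ~1/p
    max_indel_len: int = 10
    motif_head: str = MOTIF_HEAD
    motif_tail: str = MOTIF_TAIL
    seed: int = 42

    def __post_init__(self) -> None:
        for mix, name in ((self.type_mix, "type_mix"),
                          (self.its2_group_mix, "its2_group_mix")):
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise PanelConfigError(f"{name} frequencies sum to {total}, not 1")
        if self.its_len_bounds[0] >= self.its_len_bounds[1]:
            raise PanelConfigError("its_len_bounds out of order")
        if self.gc_bounds_molpct[0] >= self.gc_bounds_molpct[1]:
            raise PanelConfigError("gc_bounds out of order")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=str)


@dataclass
class OperonTruth:
    """Ground truth for one generated operon."""

    seq_id: str
    clade_id: str
    role: str                       # "reference" | "isolate"
    its_interval: Interval
    its_len: int
    gc_molpct: float
    genes: list[tuple[int, int, str, bool]]   # ITS-local (start, end, isotype, pseudo)
    its_type: str
    its2_interval: tuple[int, int] | None
    its2_group: str | None

    def to_row(self) -> dict:
        return {
            "seq_id": self.seq_id,
            "clade_id": self.clade_id,
            "role": self.role,
            "its_start": self.its_interval.start + 1,
            "its_end": self.its_interval.end,
            "its_len": self.its_len,
            "gc_molpct": round(self.gc_molpct, 2),
            "its_type": self.its_type,
            "genes": ";".join(
                f"{iso}{'(pseudo)' if ps else ''}:{s + 1}-{e}"
                for s, e, iso, ps in self.genes
            ),
            "its2_len": (
                self.its2_interval[1] - self.its2_interval[0]
                if self.its2_interval else ""
            ),
            "its2_group": self.its2_group or "",
        }


# ---------------------------------------------------------------------------
# Canonical and pseudo tRNA genes
# ---------------------------------------------------------------------------

def _draw_stem(rng: np.random.Generator, n_bp: int) -> tuple[str, str]:
    """A perfectly paired, GC-rich stem: (5' side, 3' side)."""
    pairs = [("G", "C"), ("C", "G"), ("A", "T"), ("T", "A")]
    idx = rng.choice(4, size=n_bp, p=[0.5, 0.5, 0.0, 0.0])
    five = "".join(pairs[i][0] for i in idx)
    three = "".join(pairs[i][1] for i in reversed(idx))
    return five, three


def _draw_loop(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(_BASES), size=n))


def make_canonical_trna(isotype: str, seed: int) -> NucleotideSequence:
    """A canonical gene of the isotype's fixed length (Ala 73, Ile 74 nt)
    satisfying every hard constraint of the default cloverleaf model."""
    if isotype not in _CANONICAL_GEOMETRY:
        raise ValueError(f"unknown isotype {isotype!r}")
    geom = _CANONICAL_GEOMETRY[isotype]
    rng = np.random.default_rng([seed, {"Ala": 101, "Ile": 202}[isotype]])
    acc5, acc3 = _draw_stem(rng, geom.acc)
    d5, d3 = _draw_stem(rng, geom.d)
    ac5, ac3 = _draw_stem(rng, 5)
    t5, t3 = _draw_stem(rng, 5)
    sp1 = _draw_loop(rng, 2)
    d_loop = _draw_loop(rng, geom.d_loop)
    sp2 = _draw_loop(rng, 1)
    ac_loop = _draw_loop(rng, 2) + _ANTICODON[isotype] + _draw_loop(rng, 2)
    var = _draw_loop(rng, geom.var)
    t_loop = "TTC" + _draw_loop(rng, geom.t_loop - 3)
    disc = _draw_loop(rng, 1)
    residues = (
        acc5 + sp1 + d5 + d_loop + d3 + sp2
        + ac5 + ac_loop + ac3 + var + t5 + t_loop + t3 + acc3 + disc
    )
    assert len(residues) == geom.length
    return NucleotideSequence(f"trna_{isotype}", residues, f"canonical tRNA-{isotype}")


def make_pseudo_trna(base: NucleotideSequence, seed: int) -> NucleotideSequence:
    """Disrupt exactly one hard constraint of a canonical gene: three
    substitutions breaking the anticodon stem, leaving the score above
    threshold so the detector reports the hit with pseudo=True.

    A disrupted window can occasionally admit an alternative cloverleaf
    reading whose shifted anticodon stem is intact; candidates are
    therefore validated against the detector and redrawn (deterministic
    given the seed) until the window scans as a single pseudo hit.
    """
    from .trna import scan_trnas

    length = len(base)
    geom = next(
        (g for g in _CANONICAL_GEOMETRY.values() if g.length == length), None
    )
    if geom is None:
        raise ValueError("base is not a canonical gene from this generator")
    p = geom.acc + 2 + 2 * geom.d + geom.d_loop + 1  # anticodon 5' stem start
    for attempt in range(100):
        rng = np.random.default_rng([seed, 303, attempt])
        seq = list(base.residues)
        positions = rng.choice(5, size=3, replace=False)
        for k in sorted(positions):
            partner = seq[p + 16 - k]
            old = seq[p + k]
            choices = [
                b for b in _BASES
                if b != old and _PAIR_SCORE[_BASE_INDEX[b], _BASE_INDEX[partner]] == 0
            ]
            seq[p + k] = choices[int(rng.integers(len(choices)))]
        candidate = NucleotideSequence(
            base.id + "_pseudo", "".join(seq), "pseudo tRNA"
        )
        hits = scan_trnas(candidate)
        if (
            len(hits) == 1
            and hits[0].pseudo
            and hits[0].interval.start == 0
            and hits[0].length_nt == length
        ):
            return candidate
    raise RuntimeError("could not construct a cleanly pseudo window")


# ---------------------------------------------------------------------------
# Spacer assembly
# ---------------------------------------------------------------------------

def _exact_gc_dna(rng: np.random.Generator, n: int, n_gc: int) -> str:
    """Random sequence of length n with exactly n_gc G/C residues."""
    n_gc = int(min(max(n_gc, 0), n))
    strong = rng.choice(["G", "C"], size=n_gc)
    weak = rng.choice(["A", "T"], size=n - n_gc)
    seq = np.concatenate([strong, weak])
    rng.shuffle(seq)
    return "".join(seq)


def _count_gc(s: str) -> int:
    return s.count("G") + s.count("C")


def _sub_rate(jc_d: float) -> float:
    """Expected per-site difference fraction for a JC distance."""
    return 0.75 * (1.0 - np.exp(-4.0 * jc_d / 3.0))


def _mutate(rng: np.random.Generator, seq: str, rate: float,
            protected: list[tuple[int, int]] | None = None) -> str:
    """Per-site substitutions at the given rate, sparing protected spans."""
    arr = np.array(list(seq))
    ok = np.ones(len(arr), dtype=bool)
    for s, e in protected or []:
        ok[s:e] = False
    hit = (rng.random(len(arr)) < rate) & ok
    for i in np.nonzero(hit)[0]:
        others = [b for b in _BASES if b != arr[i]]
        arr[i] = others[int(rng.integers(3))]
    return "".join(arr)


_TYPE_GENES = {
    "ITS_none": [],
    "ITS_Ala": [("Ala", False)],
    "ITS_AlaIle": [("Ala", False), ("Ile", False)],
    "ITS_IleAla": [("Ile", False), ("Ala", False)],
    "ITS_IlePseudo": [("Ile", False), ("Ala", True)],
}

_GROUP_SPAN = {
    "short(16-19)": (16, 19),
    "mid(60-61)": (60, 61),
    "long(122-138)": (122, 138),
}
_GROUP_ANCESTOR_LEN = {
    "short(16-19)": 19,
    "mid(60-61)": 61,
    "long(122-138)": 138,
    "other": 121,
}


class _PanelContext:
    """Per-panel shared material: canonical genes, group ancestors."""

    def __init__(self, cfg: PanelConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.genes = {
            "Ala": make_canonical_trna("Ala", cfg.seed).residues,
            "Ile": make_canonical_trna("Ile", cfg.seed).residues,
        }
        # Some canonical draws admit an alternative intact reading under
        # every anticodon-stem disruption; fall back to a fresh base draw
        # for the pseudo relic in that case (still seed-deterministic).
        self.pseudo = None
        for k in range(20):
            try:
                base = make_canonical_trna("Ala", cfg.seed + 7919 * k)
                self.pseudo = make_pseudo_trna(base, cfg.seed).residues
                break
            except RuntimeError:
                continue
        if self.pseudo is None:
            raise PanelConfigError("could not construct a pseudo tRNA relic")
        self.group_ancestors = {
            g: _draw_loop(rng, n) for g, n in _GROUP_ANCESTOR_LEN.items()
        }

    def gene_seq(self, isotype: str, pseudo: bool) -> str:
        return self.pseudo if pseudo else self.genes[isotype]


def _draw_from_mix(rng: np.random.Generator, mix: dict[str, float]) -> str:
    keys = list(mix)
    probs = np.array([mix[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    return keys[int(rng.choice(len(keys), p=probs))]


def _draw_its2_len(rng: np.random.Generator, group: str) -> int:
    if group in _GROUP_SPAN:
        lo, hi = _GROUP_SPAN[group]
        return int(rng.integers(lo, hi + 1))
    # "other": anything outside the printed bins, between the bins.
    pools = list(range(20, 60)) + list(range(62, 122))
    return int(pools[int(rng.integers(len(pools)))])


def generate_operon(
    cfg: PanelConfig,
    rng: np.random.Generator,
    seq_id: str = "operon",
    clade_id: str = "C00",
    ctx: _PanelContext | None = None,
) -> tuple[NucleotideSequence, OperonTruth]:
    """One reference-grade operon: scaffolds + freshly assembled ITS."""
    ctx = ctx or _PanelContext(cfg, rng)
    its_type = _draw_from_mix(rng, cfg.type_mix)
    gene_plan = _TYPE_GENES[its_type]
    gene_seqs = [ctx.gene_seq(iso, ps) for iso, ps in gene_plan]
    genes_len = sum(len(g) for g in gene_seqs)

    its2_group = None
    its2_core = ""
    its2_len = 0
    if len(gene_plan) == 2:
        its2_group = _draw_from_mix(rng, cfg.its2_group_mix)
        its2_len = _draw_its2_len(rng, its2_group)
        core_len = its2_len - len(cfg.motif_head) - len(cfg.motif_tail)
        if core_len < 0:
            raise PanelConfigError(
                f"ITS-2 length {its2_len} cannot hold the boundary motifs"
            )
        ancestor = ctx.group_ancestors[
            its2_group if its2_group in _GROUP_ANCESTOR_LEN else "other"
        ]
        core = ancestor[:core_len]
        core = _mutate(rng, core, _sub_rate(cfg.its2_divergence)) if core else ""
        its2_core = core

    leader = _mutate(rng, CONSERVED_LEADER, cfg.leader_divergence)
    tail = _mutate(rng, CONSERVED_TAIL, cfg.leader_divergence)
    its2_seq = (cfg.motif_head + its2_core + cfg.motif_tail) if len(gene_plan) == 2 else ""

    fixed_len = len(leader) + genes_len + len(its2_seq) + len(tail)
    lo = cfg.its_len_bounds[0] + cfg.template_len_margin
    hi = cfg.its_len_bounds[1] - cfg.template_len_margin
    min_filler = 30
    if fixed_len + min_filler > hi:
        raise PanelConfigError("fixed ITS content exceeds the length budget")
    L = int(rng.integers(max(lo, fixed_len + min_filler), hi + 1))
    filler_total = L - fixed_len

    # Split the filler between the sub-spacers flanking the genes.
    if len(gene_plan) == 2:
        f1 = int(rng.integers(15, filler_total - 14))
        fillers = [f1, filler_total - f1]
    elif len(gene_plan) == 1:
        f1 = int(rng.integers(15, filler_total - 14))
        fillers = [f1, filler_total - f1]
    else:
        fillers = [filler_total]

    gc_lo = cfg.gc_bounds_molpct[0] + cfg.gc_target_margin
    gc_hi = cfg.gc_bounds_molpct[1] - cfg.gc_target_margin
    target = rng.uniform(gc_lo, gc_hi) / 100.0
    fixed_gc = sum(map(_count_gc, [leader, its2_seq, tail] + gene_seqs))
    need = int(round(target * L - fixed_gc))
    filler_seqs = []
    remaining_len = filler_total
    remaining_gc = need
    for fl in fillers:
        share = int(round(remaining_gc * fl / remaining_len)) if remaining_len else 0
        share = min(max(share, 0), fl)
        filler_seqs.append(_exact_gc_dna(rng, fl, share))
        remaining_len -= fl
        remaining_gc -= share

    # Assemble: leader + filler1 [+ gene1 + its2 + gene2 | + gene1] + fillerN + tail
    parts = [leader, filler_seqs[0]]
    genes_truth = []
    cursor = len(leader) + len(filler_seqs[0])
    for k, gseq in enumerate(gene_seqs):
        iso, ps = gene_plan[k]
        genes_truth.append((cursor, cursor + len(gseq), iso, ps))
        parts.append(gseq)
        cursor += len(gseq)
        if k == 0 and len(gene_seqs) == 2:
            parts.append(its2_seq)
            cursor += len(its2_seq)
    if len(gene_plan) >= 1:
        parts.append(filler_seqs[1] if len(fillers) > 1 else "")
        cursor += len(filler_seqs[1]) if len(fillers) > 1 else 0
    parts.append(tail)
    its = "".join(parts)
    assert len(its) == L, (len(its), L)

    operon = SCAFFOLD_16S + its + SCAFFOLD_23S
    truth = _truth_from_state(
        seq_id, clade_id, "reference", its, genes_truth, gene_plan
    )
    seq = NucleotideSequence(seq_id, operon, f"synthetic operon {clade_id}")
    return seq, truth


def _truth_from_state(seq_id, clade_id, role, its, genes_truth, gene_plan):
    its_type = _classify_plan(gene_plan)
    its2_iv = None
    group = None
    if len(genes_truth) == 2:
        its2_iv = (genes_truth[0][1], genes_truth[1][0])
        group = assign_its2_group(its2_iv[1] - its2_iv[0])
    return OperonTruth(
        seq_id=seq_id,
        clade_id=clade_id,
        role=role,
        its_interval=Interval(len(SCAFFOLD_16S), len(SCAFFOLD_16S) + len(its)),
        its_len=len(its),
        gc_molpct=100.0 * gc_content(its),
        genes=genes_truth,
        its_type=its_type,
        its2_interval=its2_iv,
        its2_group=group,
    )


def _classify_plan(gene_plan) -> str:
    sig = [("pseudo" if ps else iso) for iso, ps in gene_plan]
    mapping = {
        (): "ITS_none",
        ("Ala",): "ITS_Ala",
        ("Ala", "Ile"): "ITS_AlaIle",
        ("Ile", "Ala"): "ITS_IleAla",
        ("Ile", "pseudo"): "ITS_IlePseudo",
    }
    return mapping.get(tuple(sig), "ITS_other")


# ---------------------------------------------------------------------------
# Clade evolution
# ---------------------------------------------------------------------------

def evolve_clade(
    ancestor: NucleotideSequence,
    n_desc: int,
    jc_d: float,
    indel_rate: float,
    rng: np.random.Generator,
    protected: list[tuple[int, int]] | None = None,
    len_bounds: tuple[int, int] | None = None,
    indel_len_p: float = 0.35,
    max_indel_len: int = 10,
) -> list[NucleotideSequence]:
    """Descendants of an ancestor under JC substitutions plus indels.

    Substitution count ~ Poisson(L * p(jc_d)) with p inverted from the
    JC distance; indel count ~ Poisson(indel_rate) with geometric
    lengths.  Protected spans receive neither substitutions nor indels.
    """
    if jc_d < 0:
        raise ValueError("jc_d must be >= 0")
    out = []
    for k in range(n_desc):
        seq, _shifted = _evolve_one(
            ancestor.residues, jc_d, indel_rate, rng,
            [list(p) for p in (protected or [])],
            len_bounds, indel_len_p, max_indel_len,
        )
        out.append(NucleotideSequence(f"{ancestor.id}_d{k + 1}", seq))
    return out


def _evolve_one(seq, jc_d, indel_rate, rng, protected, len_bounds,
                indel_len_p, max_indel_len):
    """Returns (sequence, protected-after-edit) with interval tracking."""
    L = len(seq)
    p = _sub_rate(jc_d)
    n_sub = rng.poisson(L * p)
    ok = np.ones(L, dtype=bool)
    for s, e in protected:
        ok[s:e] = False
    free = np.nonzero(ok)[0]
    arr = list(seq)
    if len(free) and n_sub:
        n_sub = min(n_sub, len(free))
        for i in rng.choice(free, size=n_sub, replace=False):
            others = [b for b in _BASES if b != arr[i]]
            arr[i] = others[int(rng.integers(3))]
    seq = "".join(arr)

    n_indels = rng.poisson(indel_rate)
    for _ in range(n_indels):
        length = int(min(rng.geometric(indel_len_p), max_indel_len))
        is_del = bool(rng.integers(2))
        if is_del:
            if len_bounds and len(seq) - length < len_bounds[0]:
                continue
            starts = _free_deletion_starts(len(seq), length, protected)
            if not len(starts):
                continue
            start = int(starts[int(rng.integers(len(starts)))])
            seq = seq[:start] + seq[start + length:]
            protected = [
                [s - length if s >= start + length else s,
                 e - length if e >= start + length else e]
                for s, e in protected
            ]
        else:
            if len_bounds and len(seq) + length > len_bounds[1]:
                continue
            points = _free_insertion_points(len(seq), protected)
            if not len(points):
                continue
            point = int(points[int(rng.integers(len(points)))])
            ins = _draw_loop(rng, length)
            seq = seq[:point] + ins + seq[point:]
            protected = [
                [s + length if s >= point else s,
                 e + length if e > point else e]
                for s, e in protected
            ]
    return seq, protected


def _free_deletion_starts(L, length, protected):
    ok = np.ones(max(L - length + 1, 0), dtype=bool)
    for s, e in protected:
        lo = max(s - length + 1, 0)
        ok[lo: min(e, len(ok))] = False
    return np.nonzero(ok)[0]


def _free_insertion_points(L, protected):
    ok = np.ones(L + 1, dtype=bool)
    for s, e in protected:
        ok[s + 1: e] = False
    return np.nonzero(ok)[0]


def _derive_isolate(cfg, ctx, rng, template_its, template_truth, seq_id):
    """An isolate: template ITS evolved with tracked annotations."""
    gene_ivs = [[s, e] for s, e, _i, _p in template_truth.genes]
    # Protect genes and the ITS-2 boundary motifs from all mutation, and
    # the conserved leader/tail blocks from indels only.
    motif_ivs = []
    if template_truth.its2_interval:
        a, b = template_truth.its2_interval
        motif_ivs = [[a, a + len(cfg.motif_head)], [b - len(cfg.motif_tail), b]]
    sub_protected = [list(iv) for iv in gene_ivs] + [list(iv) for iv in motif_ivs]
    L0 = len(template_its)
    indel_protected = (
        sub_protected
        + [[0, len(CONSERVED_LEADER)], [L0 - len(CONSERVED_TAIL), L0]]
    )

    p = _sub_rate(cfg.isolate_divergence)
    ok = np.ones(L0, dtype=bool)
    for s, e in sub_protected:
        ok[s:e] = False
    arr = list(template_its)
    hit = (rng.random(L0) < p) & ok
    # The ITS-2 core between the boundary motifs evolves much faster:
    # its divergence rides on the panel-wide ITS-2 scale.
    if template_truth.its2_interval:
        a, b = template_truth.its2_interval
        core = slice(a + len(cfg.motif_head), b - len(cfg.motif_tail))
        p_core = _sub_rate(cfg.its2_divergence * cfg.within_clade_its2_factor)
        hit[core] |= (rng.random(L0) < p_core)[core] & ok[core]
    # Replacement bases follow the template's own composition (a
    # stationary-composition substitution model), so the tuned G+C of
    # the spacer is preserved in expectation even under heavy ITS-2
    # divergence.
    comp = np.array([template_its.count(bs) for bs in _BASES], dtype=float)
    comp = comp / comp.sum()
    for i in np.nonzero(hit)[0]:
        weights = comp.copy()
        weights[_BASES.index(arr[i])] = 0.0
        weights = weights / weights.sum()
        arr[i] = _BASES[int(rng.choice(4, p=weights))]
    # Residual drift repair: compensate any G+C shift introduced by the
    # substitutions with flips in the filler regions (never in genes,
    # motifs, or the hypervariable core), keeping the spacer inside the
    # panel's G+C envelope.
    repair_ok = ok.copy()
    if template_truth.its2_interval:
        repair_ok[core] = False
    target_gc = sum(1 for bs in template_its if bs in "GC")
    _repair_gc(arr, target_gc, repair_ok, rng)
    seq = "".join(arr)

    # Indels with interval tracking; gene intervals ride along at the
    # front of the protected list so we can read their new coordinates.
    tracked = [list(iv) for iv in gene_ivs] + [list(iv) for iv in motif_ivs] + [
        [0, len(CONSERVED_LEADER)], [len(seq) - len(CONSERVED_TAIL), len(seq)]
    ]
    seq, tracked = _evolve_one(
        seq, 0.0, cfg.indel_rate, rng, tracked, cfg.its_len_bounds,
        cfg.indel_len_p, cfg.max_indel_len,
    )
    new_gene_ivs = tracked[: len(gene_ivs)]
    gene_plan = [(iso, ps) for _s, _e, iso, ps in template_truth.genes]
    genes_truth = [
        (s, e, iso, ps)
        for (s, e), (iso, ps) in zip(new_gene_ivs, gene_plan)
    ]
    truth = _truth_from_state(
        seq_id, template_truth.clade_id, "isolate", seq, genes_truth, gene_plan
    )
    operon = SCAFFOLD_16S + seq + SCAFFOLD_23S
    return NucleotideSequence(seq_id, operon, f"synthetic isolate {template_truth.clade_id}"), truth


def _repair_gc(arr: list[str], target_gc: int, ok: np.ndarray,
               rng: np.random.Generator, slack: int = 2) -> None:
    """Flip eligible filler bases until the G+C count is within ``slack``
    of the target (in place)."""
    delta = sum(1 for b in arr if b in "GC") - target_gc
    if abs(delta) <= slack:
        return
    if delta > 0:
        donors = [i for i in np.nonzero(ok)[0] if arr[i] in "GC"]
        new_pool = "AT"
    else:
        donors = [i for i in np.nonzero(ok)[0] if arr[i] in "AT"]
        new_pool = "GC"
    rng.shuffle(donors)
    for i in donors[: abs(delta) - slack]:
        arr[i] = new_pool[int(rng.integers(2))]


def generate_panel(
    cfg: PanelConfig | None = None,
) -> tuple[list[NucleotideSequence], list[OperonTruth]]:
    """The full study-scale panel: clade templates plus isolates.

    Deterministic: the single integer seed in the config reproduces the
    panel byte-for-byte.
    """
    cfg = cfg or PanelConfig()
    rng = np.random.default_rng(cfg.seed)
    ctx = _PanelContext(cfg, rng)
    seqs: list[NucleotideSequence] = []
    truths: list[OperonTruth] = []
    templates: list[tuple[str, OperonTruth]] = []
    for i in range(cfg.n_references):
        seq_id = f"REF{i + 1:02d}"
        clade = f"C{i + 1:02d}"
        seq, truth = generate_operon(cfg, rng, seq_id, clade, ctx)
        seqs.append(seq)
        truths.append(truth)
        its = seq.residues[truth.its_interval.start: truth.its_interval.end]
        templates.append((its, truth))
    if cfg.n_isolates and not cfg.n_references:
        raise PanelConfigError("isolates need at least one reference template")
    for k in range(cfg.n_isolates):
        idx = int(rng.integers(cfg.n_references))
        its, truth = templates[idx]
        seq_id = f"ISO{k + 1:02d}"
        seq, iso_truth = _derive_isolate(cfg, ctx, rng, its, truth, seq_id)
        seqs.append(seq)
        truths.append(iso_truth)
    return seqs, truths


def truth_table(truths: list[OperonTruth]):
    """Ground truth as a pandas DataFrame (TSV-ready)."""
    import pandas as pd

    return pd.DataFrame([t.to_row() for t in truths])
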