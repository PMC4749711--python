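"""Sequence and interval primitives shared by the whole pipeline.

Sequences are DNA-alphabet throughout: ``U`` is folded into ``T`` at parse
time and every degenerate IUPAC symbol is accepted.  Coordinates are 0-based
half-open internally; anything written to a report is converted to 1-based
inclusive, which is the convention used in the microbiology literature
("position 672-681").
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Expansion of every IUPAC nucleotide symbol into the set of unambiguous
#: bases it may stand for.
IUPAC_EXPANSION: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

IUPAC_ALPHABET = frozenset(IUPAC_EXPANSION)

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


class FastaParseError(ValueError):
    """Raised when a FASTA file is malformed or carries non-IUPAC symbols."""


class UndefinedContentError(ValueError):
    """Raised when a composition statistic is requested on an entirely
    ambiguous sequence."""


@dataclass(frozen=True)
class Interval:
    """0-based half-open interval on a parent sequence.

    ``to_report()`` yields the 1-based inclusive form used in all
    human-facing output.
    """

    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def to_report(self) -> str:
        return f"{self.start + 1}-{self.end}"

    def shift(self, offset: int) -> "Interval":
        return Interval(self.start + offset, self.end + offset, self.strand)

    def overlaps(self, other: "Interval") -> bool:
        return self.start < other.end and other.start < self.end


def _normalize(residues: str) -> str:
    return residues.upper().replace("U", "T")


@dataclass
class NucleotideSequence:
    """An identified IUPAC nucleotide string.

    Residues are stored uppercase with U mapped to T; any non-IUPAC symbol
    is rejected on construction.
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        self.residues = _normalize(self.residues)
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - IUPAC_ALPHABET
        if bad:
            raise ValueError(
                f"sequence {self.id!r} carries non-IUPAC symbols: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def slice(self, interval: Interval, new_id: str | None = None) -> "NucleotideSequence":
        if interval.end > len(self):
            raise ValueError("interval exceeds sequence length")
        return NucleotideSequence(
            new_id or self.id, self.residues[interval.start: interval.end]
        )

    def reverse_complement(self, new_id: str | None = None) -> "NucleotideSequence":
        return NucleotideSequence(
            new_id or self.id, reverse_complement(self.residues)
        )


def reverse_complement(residues: str) -> str:
    """IUPAC-aware reverse complement (R<->Y, S<->S, ...)."""
    return _normalize(residues).translate(_COMPLEMENT)[::-1]


def read_fasta(path: str | Path) -> list[NucleotideSequence]:
    """Read a (wrapped or unwrapped) FASTA file.

    An empty file yields an empty list.  Non-IUPAC residues raise
    :class:`FastaParseError` naming the offending line.
    """
    path = Path(path)
    seqs: list[NucleotideSequence] = []
    # Manual pass for line-accurate error reporting, then hand records to
    # the same validation as every other construction path.
    current_id: str | None = None
    current_desc = ""
    chunks: list[str] = []
    ids_seen: set[str] = set()

    def _flush(line_no: int) -> None:
        nonlocal current_id, chunks
        if current_id is None:
            return
        residues = "".join(chunks)
        try:
            seqs.append(NucleotideSequence(current_id, residues, current_desc))
        except ValueError as exc:
            raise FastaParseError(f"{path}: record ending at line {line_no}: {exc}") from exc
        current_id, chunks = None, []

    with open(path) as handle:
        line_no = 0
        for line_no, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush(line_no - 1)
                header = line[1:].strip()
                if not header:
                    raise FastaParseError(f"{path}: empty header at line {line_no}")
                parts = header.split(None, 1)
                current_id = parts[0]
                current_desc = parts[1] if len(parts) > 1 else ""
                if current_id in ids_seen:
                    raise FastaParseError(
                        f"{path}: duplicate id {current_id!r} at line {line_no}"
                    )
                ids_seen.add(current_id)
                chunks = []
            else:
                if current_id is None:
                    raise FastaParseError(
                        f"{path}: sequence data before any header at line {line_no}"
                    )
                chunks.append(line)
        _flush(line_no)
    return seqs


def write_fasta(
    seqs: Iterable[NucleotideSequence], path: str | Path, width: int = 70
) -> None:
    """Write sequences as FASTA with the given line width (>= 1)."""
    if width < 1:
        raise ValueError("width must be >= 1")
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description=s.description)
        for s in seqs
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(records)


def gc_content(seq: NucleotideSequence | str) -> float:
    """G+C fraction in [0, 1]; report as mol% via ``100 * gc_content(...)``.

    S (G or C) counts toward G+C and W (A or T) toward A+T; every other
    ambiguity symbol is excluded from both numerator and denominator so an
    unknown base cannot bias the estimate.
    """
    residues = seq.residues if isinstance(seq, NucleotideSequence) else _normalize(seq)
    gc = sum(residues.count(b) for b in "GCS")
    at = sum(residues.count(b) for b in "ATW")
    total = gc + at
    if total == 0:
        raise UndefinedContentError("sequence has no unambiguous A/C/G/T/S/W residues")
    return gc / total


def iupac_matches(symbol_a: str, symbol_b: str) -> bool:
    """True iff the IUPAC expansion sets of the two symbols intersect."""
    try:
        ea = IUPAC_EXPANSION[symbol_a.upper().replace("U", "T")]
        eb = IUPAC_EXPANSION[symbol_b.upper().replace("U", "T")]
    except KeyError as exc:
        raise ValueError(f"non-IUPAC symbol: {exc.args[0]!r}") from exc
    return not ea.isdisjoint(eb)
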