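"""In-silico PCR: degenerate primer matching, amplicon extraction, and
excision of the 16S-23S intergenic spacer (ITS) from an amplicon.

The ITS proper is defined as the stretch strictly between the two primer
footprints: the forward primer sits in the conserved 3' end of the 16S
rRNA gene and the reverse primer in the conserved 5' start of the 23S, so
the excised spacer is directly comparable across strains.

Templates are assumed to be in 16S->23S orientation: forward primers are
scanned on the given strand and reverse primers as reverse complements
(``both_strands=True`` relaxes this for unoriented input).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

from .seqcore import (
    Interval,
    NucleotideSequence,
    iupac_matches,
    reverse_complement,
)

DEFAULT_MAX_MISMATCH = 2
DEFAULT_PRODUCT_LIMITS = (200, 2000)


class DegenerateSpacerError(ValueError):
    """Raised when the two primer footprints abut or overlap, leaving a
    zero-length spacer."""


@dataclass(frozen=True)
class Primer:
    """A PCR primer written 5'->3'.

    Reverse primers are matched against the template as reverse
    complements.
    """

    name: str
    residues: str
    role: str  # "forward" | "reverse"

    def __post_init__(self) -> None:
        if self.role not in ("forward", "reverse"):
            raise ValueError(f"primer role must be forward/reverse, got {self.role!r}")
        if len(self.residues) < 10:
            raise ValueError(f"primer {self.name!r} shorter than 10 nt")
        # Validate alphabet via the sequence type.
        NucleotideSequence(self.name, self.residues)

    def site_pattern(self) -> str:
        """The pattern this primer leaves on the forward template strand."""
        if self.role == "reverse":
            return reverse_complement(self.residues)
        return self.residues.upper().replace("U", "T")


@dataclass(frozen=True)
class Amplicon:
    """A PCR product: template coordinates span both primer footprints."""

    template_id: str
    interval: Interval
    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) != len(self.interval):
            raise ValueError("amplicon residues/interval length mismatch")


def load_primers() -> dict[str, Primer]:
    """The packaged primer panel (two assay sets), keyed by primer name."""
    primers: dict[str, Primer] = {}
    with resources.files("spacertyper.data").joinpath("primers.tsv").open() as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            primers[row["name"]] = Primer(row["name"], row["sequence"], row["role"])
    return primers


def _mismatches(window: str, pattern: str, budget: int) -> int | None:
    count = 0
    for a, b in zip(window, pattern):
        if not iupac_matches(a, b):
            count += 1
            if count > budget:
                return None
    return count


def find_primer_sites(
    template: NucleotideSequence,
    primer: Primer,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
) -> list[Interval]:
    """All ungapped primer sites with <= max_mismatch IUPAC mismatches.

    Returned intervals are on the forward strand, sorted by start; reverse
    primer sites carry strand '-'.
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    pattern = primer.site_pattern()
    strand = "-" if primer.role == "reverse" else "+"
    m = len(pattern)
    seq = template.residues
    hits = []
    for start in range(len(seq) - m + 1):
        if _mismatches(seq[start: start + m], pattern, max_mismatch) is not None:
            hits.append(Interval(start, start + m, strand))
    return hits


def amplify(
    template: NucleotideSequence,
    fwd: Primer,
    rev: Primer,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    min_len: int = DEFAULT_PRODUCT_LIMITS[0],
    max_len: int = DEFAULT_PRODUCT_LIMITS[1],
    both_strands: bool = False,
) -> list[Amplicon]:
    """Every forward/reverse site pair yielding a product in [min_len, max_len].

    Products are sorted by start, then by length.
    """
    if min_len > max_len:
        raise ValueError("min_len > max_len")
    products = _amplify_oriented(template, fwd, rev, max_mismatch, min_len, max_len)
    if both_strands:
        flipped = template.reverse_complement()
        products += _amplify_oriented(flipped, fwd, rev, max_mismatch, min_len, max_len)
    products.sort(key=lambda a: (a.interval.start, len(a.interval)))
    return products


def _amplify_oriented(template, fwd, rev, max_mismatch, min_len, max_len):
    fwd_sites = find_primer_sites(template, fwd, max_mismatch)
    rev_sites = find_primer_sites(template, rev, max_mismatch)
    products = []
    for f in fwd_sites:
        for r in rev_sites:
            if f.start >= r.start:
                continue
            length = r.end - f.start
            if min_len <= length <= max_len:
                interval = Interval(f.start, r.end)
                products.append(
                    Amplicon(
                        template.id,
                        interval,
                        template.residues[interval.start: interval.end],
                    )
                )
    return products


def extract_its(
    amplicon: Amplicon, fwd_anchor: Primer, rev_anchor: Primer
) -> tuple[NucleotideSequence, Interval]:
    """Excise the spacer strictly between the two primer footprints.

    The forward footprint's 3' end is taken as the annotated 16S terminus
    and the reverse footprint's 5' end as the 23S start; the returned
    interval is on the original template.
    """
    f_len = len(fwd_anchor.residues)
    r_len = len(rev_anchor.residues)
    its_len = len(amplicon.residues) - f_len - r_len
    if its_len <= 0:
        raise DegenerateSpacerError(
            f"primer footprints abut or overlap on {amplicon.template_id}"
        )
    residues = amplicon.residues[f_len: f_len + its_len]
    interval = Interval(
        amplicon.interval.start + f_len, amplicon.interval.end - r_len
    )
    seq = NucleotideSequence(f"{amplicon.template_id}", residues, "ITS")
    return seq, interval
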