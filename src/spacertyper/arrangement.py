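"""ITS typing: arrangement classification, ITS-1/2/3 partitioning and
ITS-2 size-group binning.

Spacers are typed by the tRNA genes they carry, in 5'->3' order.  The
five arrangements observed in sphingomonad spacers are ITS_none (no
tRNA), ITS_Ala, ITS_AlaIle, ITS_IleAla and ITS_IlePseudo; anything else
is reported as ITS_other, never silently coerced.  Two gene-like
features (pseudo genes count) divide the spacer into ITS-1, ITS-2 and
ITS-3; a single gene yields spacer-a/spacer-b, which are excluded from
ITS-2 statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .seqcore import Interval, NucleotideSequence, gc_content
from .trna import CloverleafModel, TrnaGene, scan_trnas


class AnnotationConflictError(ValueError):
    """Raised when reported tRNA genes overlap or are out of order."""


class ItsType(str, Enum):
    ITS_none = "ITS_none"
    ITS_Ala = "ITS_Ala"
    ITS_AlaIle = "ITS_AlaIle"
    ITS_IleAla = "ITS_IleAla"
    ITS_IlePseudo = "ITS_IlePseudo"
    ITS_other = "ITS_other"


# ITS-2 size groups reported for the study panel (nt).
SIZE_GROUPS = {
    "short(16-19)": (16, 19),
    "mid(60-61)": (60, 61),
    "long(122-138)": (122, 138),
}


@dataclass
class ItsAnnotation:
    """Complete per-sequence ITS record (Figure-2B-style row)."""

    seq_id: str
    its_interval: Interval | None
    its_len_nt: int
    gc_molpct: float
    trnas: list[TrnaGene]
    its_type: ItsType
    subregions: dict[str, Interval]
    its2_group: str | None = None

    @property
    def its2_len(self) -> int | None:
        iv = self.subregions.get("ITS-2")
        if iv is None:
            return None
        return iv.end - iv.start


def _check_sorted(trnas: list[TrnaGene]) -> None:
    for prev, cur in zip(trnas, trnas[1:]):
        if cur.interval.start < prev.interval.end:
            if cur.interval.start < prev.interval.start:
                raise AnnotationConflictError("tRNA genes out of order")
            raise AnnotationConflictError("tRNA genes overlap")


def classify_its_type(trnas: list[TrnaGene]) -> ItsType:
    """Map an ordered gene list to one of the five arrangements (or other)."""
    _check_sorted(trnas)
    sig = [("pseudo" if g.pseudo else g.isotype) for g in trnas]
    if sig == []:
        return ItsType.ITS_none
    if sig == ["Ala"]:
        return ItsType.ITS_Ala
    if sig == ["Ala", "Ile"]:
        return ItsType.ITS_AlaIle
    if sig == ["Ile", "Ala"]:
        return ItsType.ITS_IleAla
    if len(sig) == 2 and sig[0] == "Ile" and sig[1] == "pseudo":
        return ItsType.ITS_IlePseudo
    return ItsType.ITS_other


def partition_its(
    its: NucleotideSequence, trnas: list[TrnaGene]
) -> dict[str, Interval]:
    """Split the spacer around its gene-like features.

    Two genes -> {ITS-1, ITS-2, ITS-3}; one gene -> {spacer-a, spacer-b};
    no gene -> {spacer-a}.  Zero-length sub-spacers (abutting genes) are
    simply omitted from the map, which keeps the tiling invariant:
    sub-spacers plus genes cover the ITS exactly.
    """
    _check_sorted(trnas)
    L = len(its)
    if not trnas:
        return {"spacer-a": Interval(0, L)}
    if trnas[-1].interval.end > L:
        raise AnnotationConflictError("tRNA gene exceeds spacer length")

    def maybe(start: int, end: int) -> Interval | None:
        return Interval(start, end) if end > start else None

    if len(trnas) == 1:
        g = trnas[0]
        out = {}
        if (iv := maybe(0, g.interval.start)) is not None:
            out["spacer-a"] = iv
        if (iv := maybe(g.interval.end, L)) is not None:
            out["spacer-b"] = iv
        return out

    if len(trnas) == 2:
        g1, g2 = trnas
        out = {}
        if (iv := maybe(0, g1.interval.start)) is not None:
            out["ITS-1"] = iv
        if (iv := maybe(g1.interval.end, g2.interval.start)) is not None:
            out["ITS-2"] = iv
        if (iv := maybe(g2.interval.end, L)) is not None:
            out["ITS-3"] = iv
        return out

    # >2 gene-like features: label sub-spacers generically.
    out = {}
    bounds = [0] + [x for g in trnas for x in (g.interval.start, g.interval.end)] + [L]
    k = 0
    for start, end in zip(bounds[::2], bounds[1::2]):
        if end > start:
            out[f"spacer-{chr(ord('a') + k)}"] = Interval(start, end)
        k += 1
    return out


def assign_its2_group(its2_len: int) -> str:
    """Bin an ITS-2 length into the study's size groups."""
    if its2_len < 0:
        raise ValueError("negative ITS-2 length")
    for label, (lo, hi) in SIZE_GROUPS.items():
        if lo <= its2_len <= hi:
            return label
    return f"other({its2_len})"


def check_arrangement_convention(annotation: ItsAnnotation) -> bool | None:
    """Whether an Ala+Ile spacer follows the common orientation:
    tRNA-Ala just downstream of the 16S gene, tRNA-Ile just upstream of
    the 23S.  Not applicable (None) for other arrangements."""
    if annotation.its_type != ItsType.ITS_AlaIle:
        return None
    return (
        annotation.trnas[0].isotype == "Ala"
        and annotation.trnas[-1].isotype == "Ile"
    )


def annotate_its(
    its: NucleotideSequence,
    its_interval: Interval | None = None,
    model: CloverleafModel | None = None,
) -> ItsAnnotation:
    """Run detection + typing + partitioning on one excised spacer."""
    trnas = scan_trnas(its, model)
    its_type = classify_its_type(trnas)
    subregions = partition_its(its, trnas)
    its2 = subregions.get("ITS-2")
    group = assign_its2_group(its2.end - its2.start) if its2 is not None else None
    return ItsAnnotation(
        seq_id=its.id,
        its_interval=its_interval,
        its_len_nt=len(its),
        gc_molpct=100.0 * gc_content(its),
        trnas=trnas,
        its_type=its_type,
        subregions=subregions,
        its2_group=group,
    )


def annotation_table_row(a: ItsAnnotation) -> dict:
    """Flat dict for the per-sequence annotation TSV."""
    return {
        "seq_id": a.seq_id,
        "its_len": a.its_len_nt,
        "gc_molpct": round(a.gc_molpct, 1),
        "its_type": a.its_type.value,
        "trna_positions": ";".join(
            f"{g.isotype}{'(pseudo)' if g.pseudo else ''}:{g.interval.to_report()}"
            for g in a.trnas
        ),
        "its2_len": a.its2_len if a.its2_len is not None else "",
        "its2_group": a.its2_group or "",
    }
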