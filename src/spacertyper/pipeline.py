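"""End-to-end orchestration: simulate/load -> excise -> detect -> type
-> align -> conserve -> tree -> fold -> report.

Per-sequence failures (e.g. no amplicon) are recorded and skipped, not
fatal: survey panels are heterogeneous and a single refractory sequence
should never abort a run.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict

from . import __version__
from .align import (
    AlignParams,
    conservation_summary,
    find_conserved_blocks,
    progressive_msa,
)
from .arrangement import ItsAnnotation, annotate_its, annotation_table_row
from .pcr import DegenerateSpacerError, amplify, extract_its, load_primers
from .phylo import (
    EmptyAlignmentError,
    bootstrap_consensus,
    complete_deletion,
    leaf_labels,
    to_newick,
)
from .seqcore import Interval, NucleotideSequence, read_fasta
from .structure import classify_hairpin, fold_its2
from .synth import PanelConfig, generate_panel
from .trna import CloverleafModel

logger = logging.getLogger("spacertyper")


class PipelineError(RuntimeError):
    """Raised when no sequence in the run can be analysed."""


@dataclass
class PipelineConfig:
    """Exactly one of input_fasta / simulate must be set."""

    input_fasta: str | None = None
    simulate: PanelConfig | None = None
    primer_pair: tuple[str, str] = ("16S-1511f", "23S-23r")
    max_mismatch: int = 2
    cloverleaf: CloverleafModel = field(default_factory=CloverleafModel)
    align_params: AlignParams = field(default_factory=AlignParams)
    bootstrap_reps: int = 1000
    seed: int = 42
    pre_excised: bool = False   # input FASTA already holds bare spacers

    def __post_init__(self) -> None:
        if (self.input_fasta is None) == (self.simulate is None):
            raise ValueError("set exactly one of input_fasta / simulate")
        if self.bootstrap_reps < 1:
            raise ValueError("bootstrap_reps must be >= 1")


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage and assemble the machine-readable report."""
    if cfg.simulate is not None:
        logger.info("stage=simulate n=%d+%d seed=%d", cfg.simulate.n_references,
                    cfg.simulate.n_isolates, cfg.simulate.seed)
        seqs, _truths = generate_panel(cfg.simulate)
    else:
        seqs = read_fasta(cfg.input_fasta)
        logger.info("stage=load n=%d path=%s", len(seqs), cfg.input_fasta)
    if not seqs:
        raise PipelineError("no input sequences")

    primers = load_primers()
    fwd = primers[cfg.primer_pair[0]]
    rev = primers[cfg.primer_pair[1]]

    annotations: list[ItsAnnotation] = []
    its_seqs: list[NucleotideSequence] = []
    failures: list[dict] = []
    for seq in seqs:
        try:
            if cfg.pre_excised:
                its, its_iv = seq, Interval(0, len(seq))
            else:
                products = amplify(seq, fwd, rev, cfg.max_mismatch)
                if not products:
                    raise DegenerateSpacerError("no amplicon")
                its, its_iv = extract_its(products[0], fwd, rev)
            ann = annotate_its(its, its_iv, cfg.cloverleaf)
            annotations.append(ann)
            its_seqs.append(its)
            logger.info("stage=annotate seq=%s type=%s len=%d",
                        seq.id, ann.its_type.value, ann.its_len_nt)
        except (DegenerateSpacerError, ValueError) as exc:
            failures.append({"seq_id": seq.id, "error": str(exc)})
            logger.warning("stage=annotate seq=%s failed: %s", seq.id, exc)
    if not annotations:
        raise PipelineError("no analyzable sequences")

    report: dict = {
        "metadata": {
            "tool": "spacertyper",
            "version": __version__,
            "seed": cfg.seed,
            "config_hash": _config_hash(cfg),
            "n_input": len(seqs),
            "n_annotated": len(annotations),
            "n_failed": len(failures),
        },
        "annotations": [annotation_table_row(a) for a in annotations],
        "failures": failures,
    }

    # Alignment + conservation of the whole spacer and of ITS-2.
    if len(its_seqs) >= 2:
        logger.info("stage=align n=%d", len(its_seqs))
        aln = progressive_msa(its_seqs, cfg.align_params)
        summary = conservation_summary(aln)
        report["conservation"] = {"ITS": _summary_dict(summary)}
        report["conserved_blocks"] = [
            {"columns": (c0 + 1, c1), "consensus": cons}
            for (c0, c1), cons in find_conserved_blocks(aln)
        ]
        its2 = _its2_sequences(annotations, its_seqs)
        if len(its2) >= 2:
            aln2 = progressive_msa(its2, cfg.align_params)
            report["conservation"]["ITS-2"] = _summary_dict(
                conservation_summary(aln2)
            )
        # Phylogeny on the complete-deleted spacer alignment.
        if len(its_seqs) < 3:
            report["tree"] = {"error": "need >= 3 analyzable sequences"}
            return _finalise(report, annotations, its_seqs)
        try:
            core = complete_deletion(aln)
            logger.info("stage=tree columns=%d reps=%d", core.ncols,
                        cfg.bootstrap_reps)
            consensus, _reps = bootstrap_consensus(
                core, n_reps=cfg.bootstrap_reps, seed=cfg.seed
            )
            report["tree"] = {
                "newick": to_newick(consensus),
                "n_leaves": len(leaf_labels(consensus)),
                "n_informative_columns": core.ncols,
                "bootstrap_reps": cfg.bootstrap_reps,
            }
        except EmptyAlignmentError as exc:
            report["tree"] = {"error": str(exc)}
            logger.warning("stage=tree failed: %s", exc)

    return _finalise(report, annotations, its_seqs)


def _finalise(report, annotations=None, its_seqs=None) -> dict:
    # ITS-2 hairpin folding.
    structures = []
    for ann, its in zip(annotations or [], its_seqs or []):
        iv = ann.subregions.get("ITS-2")
        if iv is None or len(iv) < 8:
            continue
        s = fold_its2(its.slice(iv))
        structures.append({
            "seq_id": ann.seq_id,
            "dot_bracket": s.dot_bracket,
            **classify_hairpin(s),
        })
    report["its2_structures"] = structures
    logger.info("stage=fold n=%d", len(structures))
    report["type_summary"] = summarize_types(report)
    return report


def _summary_dict(summary) -> dict:
    return {
        "mean_pid": round(summary.mean_pid, 2),
        "sd_pid": round(summary.sd_pid, 2),
        "min_pid": round(summary.min_pid, 2),
        "max_pid": round(summary.max_pid, 2),
        "n": len(summary.labels),
    }


def _its2_sequences(annotations, its_seqs) -> list[NucleotideSequence]:
    out = []
    for ann, its in zip(annotations, its_seqs):
        iv = ann.subregions.get("ITS-2")
        if iv is not None and len(iv) >= 2:
            out.append(its.slice(iv, new_id=ann.seq_id))
    return out


def summarize_types(report: dict) -> dict:
    """Frequency table of ITS types and ITS-2 size groups."""
    from .arrangement import ItsType, SIZE_GROUPS

    rows = report["annotations"]
    n = len(rows)
    type_counts = {t.value: 0 for t in ItsType}
    group_counts = {g: 0 for g in SIZE_GROUPS}
    group_counts["other"] = 0
    for row in rows:
        type_counts[row["its_type"]] += 1
        g = row["its2_group"]
        if g:
            if g not in group_counts:
                g = "other"
            group_counts[g] += 1
    mode = max(type_counts, key=type_counts.get) if n else None
    return {
        "n": n,
        "its_types": {
            t: {"count": c, "percent": round(100.0 * c / n, 1) if n else 0.0}
            for t, c in type_counts.items()
        },
        "its2_groups": group_counts,
        "most_common_type": mode,
    }
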