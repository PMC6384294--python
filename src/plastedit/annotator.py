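"""Per-gene orchestration of the editing inference and record annotation.

For each reconciled CDS model the pipeline checks, in order: the start codon
(direct validity, then single-edit rescue, then the +/-5-codon boundary
scan), the final codon (same cascade with stop logic), and finally all
in-frame internal stops of the possibly re-bounded CDS. Any unresolvable
defect — or more internal stops than ``internal_stop_limit`` — flags the
gene for manual checking, in which case none of its annotations change:
genes are edited wholly or not at all, never partially.
"""

from __future__ import annotations

import copy
import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

from . import editing_core as ec
from . import io_formats as iof
from .editing_core import EditEvent, GeneticCode
from .io_formats import Feature, GeneModel, GenomeRecord

logger = logging.getLogger("plastedit")

CLEAN = "clean"
EDITED = "edited"
BOUNDARY_ADJUSTED = "boundary_adjusted"
MANUAL_CHECK = "manual_check"

EXCEPTION_TEXT = "RNA editing"


@dataclass
class Config:
    """Run-time knobs for the editing inference.

    ``internal_stop_limit``: more internal stops than this in one gene is
    treated as a sign of mis-annotation (frameshift, pseudogene) rather than
    editing, and the gene is flagged for manual checking. Genes with more
    genuinely edited stops exist but are rare; raise the limit deliberately.
    """

    internal_stop_limit: int = 5
    boundary_window_codons: int = 5
    valid_start_codons: tuple[str, ...] = ("ATG",)
    seqid_alias: Optional[dict[str, str]] = None
    output_dir: Optional[str] = None

    def __post_init__(self) -> None:
        if self.internal_stop_limit < 0 or self.boundary_window_codons < 0:
            raise ValueError("limits must be >= 0")
        for codon in self.valid_start_codons:
            if len(codon) != 3 or set(codon.upper()) - ec.DNA_BASES:
                raise ValueError(f"malformed start codon {codon!r}")

    def genetic_code(self) -> GeneticCode:
        return GeneticCode.table11(self.valid_start_codons)


@dataclass
class GeneReport:
    """Outcome of processing one gene model."""

    gene_id: str
    status: str
    edits: list[EditEvent] = field(default_factory=list)
    boundary_shift: tuple[int, int] = (0, 0)  # (5' offset, 3' offset), codons
    translation: Optional[str] = None
    messages: list[str] = field(default_factory=list)
    model: Optional[GeneModel] = None  # final (possibly re-bounded) model


@dataclass
class RunReport:
    accession: str
    genes: list[GeneReport] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def totals(self) -> dict:
        by_role = Counter(e.role for g in self.genes for e in g.edits)
        return {
            "genes_processed": len(self.genes),
            "edits_total": sum(len(g.edits) for g in self.genes),
            "edits_by_role": dict(by_role),
            "genes_flagged": sum(1 for g in self.genes if g.status == MANUAL_CHECK),
        }

    def all_edits(self) -> list[EditEvent]:
        return [e for g in self.genes for e in g.edits]


def _manual(gene_id: str, model: GeneModel, messages: list[str]) -> GeneReport:
    return GeneReport(
        gene_id=gene_id,
        status=MANUAL_CHECK,
        edits=[],
        translation=None,
        messages=messages,
        model=model,
    )


def _flank(
    genome: GenomeRecord, model: GeneModel, end: str, n_codons: int
) -> tuple[str, int]:
    """In-frame genomic flank beyond a model boundary, truncated at genome ends.

    Returns (flank sequence in coding sense, codons actually available).
    """
    seq = genome.sequence
    want = 3 * n_codons
    if end == ec.FIVE_PRIME:
        if model.strand == "+":
            s0 = model.intervals[0][0]
            k = min(want, s0) // 3
            return seq[s0 - 3 * k : s0], k
        e0 = model.intervals[0][1]
        k = min(want, len(seq) - e0) // 3
        return iof.revcomp(seq[e0 : e0 + 3 * k]), k
    if model.strand == "+":
        e1 = model.intervals[-1][1]
        k = min(want, len(seq) - e1) // 3
        return seq[e1 : e1 + 3 * k], k
    s1 = model.intervals[-1][0]
    k = min(want, s1) // 3
    return iof.revcomp(seq[s1 - 3 * k : s1]), k


def _shift_boundary(model: GeneModel, end: str, offset_codons: int) -> Optional[GeneModel]:
    """New model with a terminal boundary moved by ``offset_codons``.

    5' offsets are negative upstream (extending the gene); 3' offsets are
    positive downstream (extending). Returns None when the shift would
    invalidate the terminal interval.
    """
    shifted = copy.deepcopy(model)
    delta = 3 * offset_codons
    intervals = shifted.intervals
    if end == ec.FIVE_PRIME:
        start, stop = intervals[0]
        if model.strand == "+":
            new = (start + delta, stop)
        else:
            new = (start, stop - delta)
        intervals[0] = new
    else:
        start, stop = intervals[-1]
        if model.strand == "+":
            new = (start, stop + delta)
        else:
            new = (start - delta, stop)
        intervals[-1] = new
    lo, hi = new
    if lo < 0 or lo >= hi:
        return None
    return shifted


def process_gene(
    model: GeneModel, genome: GenomeRecord, config: Optional[Config] = None
) -> GeneReport:
    """Run the start/stop/internal-stop cascade on one gene model.

    Never raises on biological failure: every unresolvable defect yields
    status ``manual_check`` with explanatory messages and zero edits.
    """
    config = config or Config()
    code = config.genetic_code()
    window = config.boundary_window_codons

    if model.manual or model.frame_suspect:
        return _manual(model.gene_id, model, list(model.messages))
    if model.spliced_length % 3 or model.spliced_length < 6:
        return _manual(
            model.gene_id,
            model,
            [f"spliced length {model.spliced_length} bp unusable for codon inference"],
        )

    current = model
    seq = iof.splice(genome.sequence, current)
    edits: list[EditEvent] = []
    messages: list[str] = []
    five_shift = 0
    three_shift = 0

    # --- start codon
    start_codon = seq[:3]
    if not ec.is_valid_start(start_codon, code):
        if set(start_codon) - ec.DNA_BASES:
            messages.append(f"start codon {start_codon} contains an ambiguous base")
        edit = ec.rescue_start(start_codon, code)
        if edit is not None:
            edits.append(edit.placed(current, 0))
        else:
            flank, k = _flank(genome, current, ec.FIVE_PRIME, window)
            if k < window:
                messages.append(
                    f"5' scan window truncated to {k} codons at the genome end"
                )
            hit = ec.scan_for_boundary(
                flank + seq, ec.FIVE_PRIME, window, code, flank_codons=k
            )
            if hit is None:
                messages.append(
                    f"start codon {start_codon} invalid and no valid or "
                    f"edit-rescuable start within {window} codons"
                )
                return _manual(model.gene_id, model, messages)
            offset, codon, edit = hit
            shifted = _shift_boundary(current, ec.FIVE_PRIME, offset)
            if shifted is None:
                messages.append(
                    f"5' boundary shift of {offset} codons would break the "
                    "first interval"
                )
                return _manual(model.gene_id, model, messages)
            current = shifted
            five_shift = offset
            seq = iof.splice(genome.sequence, current)
            messages.append(f"5' boundary moved {offset} codons to {codon}")
            if edit is not None:
                edits.append(edit.placed(current, 0))

    # --- final codon
    final_codon = seq[-3:]
    if final_codon not in code.stop_codons:
        if set(final_codon) - ec.DNA_BASES:
            messages.append(f"final codon {final_codon} contains an ambiguous base")
        edit = ec.rescue_stop(final_codon)
        if edit is not None:
            edits.append(edit.placed(current, len(seq) // 3 - 1))
        else:
            flank, k = _flank(genome, current, ec.THREE_PRIME, window)
            if k < window:
                messages.append(
                    f"3' scan window truncated to {k} codons at the genome end"
                )
            hit = ec.scan_for_boundary(
                seq + flank, ec.THREE_PRIME, window, code, flank_codons=k
            )
            if hit is None:
                messages.append(
                    f"final codon {final_codon} is not a stop and no valid or "
                    f"edit-rescuable stop within {window} codons"
                )
                return _manual(model.gene_id, model, messages)
            offset, codon, edit = hit
            shifted = _shift_boundary(current, ec.THREE_PRIME, offset)
            if shifted is None:
                messages.append(
                    f"3' boundary shift of {offset} codons would break the "
                    "last interval"
                )
                return _manual(model.gene_id, model, messages)
            current = shifted
            three_shift = offset
            seq = iof.splice(genome.sequence, current)
            messages.append(f"3' boundary moved {offset} codons to {codon}")
            if edit is not None:
                edits.append(edit.placed(current, len(seq) // 3 - 1))

    # --- internal stops (on the re-bounded CDS)
    internal = ec.find_internal_stops(seq, code)
    if len(internal) > config.internal_stop_limit:
        messages.append(
            f"{len(internal)} internal stops exceed the limit of "
            f"{config.internal_stop_limit}; likely mis-annotation — check manually"
        )
        return _manual(model.gene_id, model, messages)
    for codon_index, codon in internal:
        edit = ec.rescue_internal_stop(codon, code)
        if edit is None:
            messages.append(
                f"internal stop {codon} at codon {codon_index} is not rescuable "
                "by a single U-to-C edit"
            )
            return _manual(model.gene_id, model, messages)
        edits.append(edit.placed(current, codon_index))

    translation = ec.conceptual_translation(seq, edits, code)

    if five_shift or three_shift:
        status = BOUNDARY_ADJUSTED
    elif edits:
        status = EDITED
    else:
        status = CLEAN
    return GeneReport(
        gene_id=model.gene_id,
        status=status,
        edits=edits,
        boundary_shift=(five_shift, three_shift),
        translation=translation,
        messages=messages,
        model=current,
    )


def _direction_text(direction: str) -> str:
    return "C to U" if direction == ec.C_TO_U else "U to C"


def _gene_feature_for(record: GenomeRecord, cds_index: int, gene_id: str):
    """Single-interval parent gene feature of a CDS, matched by name/overlap."""
    cds_lo, cds_hi = record.features[cds_index].span()
    for i, feat in enumerate(record.features):
        if feat.kind != "gene" or len(feat.intervals) != 1:
            continue
        name = feat.first_qualifier("gene") or feat.first_qualifier("locus_tag")
        lo, hi = feat.span()
        if name == gene_id and lo < cds_hi and cds_lo < hi:
            return i
    return None


def apply_annotations(
    genome: GenomeRecord, reports: list[GeneReport]
) -> GenomeRecord:
    """Return a copy of ``genome`` carrying the inference results.

    Per edit: one single-base ``misc_feature`` noting the editing direction
    and gene. Per edited CDS: ``exception="RNA editing"`` plus the conceptual
    ``/translation``. Boundary-adjusted genes get updated CDS (and parent
    gene) coordinates. Re-applying identical reports adds nothing
    (idempotence); manual-check genes are left untouched.
    """
    out = copy.deepcopy(genome)
    new_features: list[Feature] = []
    existing_misc = {
        (tuple(f.intervals), f.first_qualifier("note"))
        for f in out.features
        if f.kind == "misc_feature"
    }
    for report in reports:
        if report.status == MANUAL_CHECK or report.model is None:
            continue
        model = report.model
        idx = model.source_feature_index
        if idx is None:
            feat = Feature(
                kind="CDS",
                intervals=list(model.intervals),
                strand=model.strand,
                qualifiers={"gene": [model.gene_id]},
            )
            if model.product:
                feat.qualifiers["product"] = [model.product]
            out.features.append(feat)
            idx = len(out.features) - 1
        feat = out.features[idx]
        if report.boundary_shift != (0, 0):
            gene_idx = _gene_feature_for(out, idx, model.gene_id)
            old_span = feat.span()
            feat.intervals = list(model.intervals)
            new_span = feat.span()
            if gene_idx is not None:
                glo, ghi = out.features[gene_idx].intervals[0]
                if glo == old_span[0]:
                    glo = new_span[0]
                else:
                    glo = min(glo, new_span[0])
                if ghi == old_span[1]:
                    ghi = new_span[1]
                else:
                    ghi = max(ghi, new_span[1])
                out.features[gene_idx].intervals = [(glo, ghi)]
        if report.translation is not None:
            feat.qualifiers["translation"] = [report.translation]
        if report.edits and EXCEPTION_TEXT not in feat.qualifiers.get("exception", []):
            feat.qualifiers.setdefault("exception", []).append(EXCEPTION_TEXT)
        for edit in report.edits:
            intervals = [(edit.genomic_position - 1, edit.genomic_position)]
            note = (
                f"RNA editing ({_direction_text(edit.direction)}) "
                f"in gene {report.gene_id}"
            )
            key = (tuple(intervals), note)
            if key in existing_misc:
                logger.debug("misc_feature already present at %s; skipped", key)
                continue
            existing_misc.add(key)
            new_features.append(
                Feature(
                    kind="misc_feature",
                    intervals=intervals,
                    strand=edit.strand,
                    qualifiers={"note": [note], "gene": [report.gene_id]},
                )
            )
    out.features.extend(new_features)
    return out


_REPORT_COLUMNS = (
    "gene",
    "status",
    "n_edits",
    "five_prime_shift",
    "three_prime_shift",
    "messages",
)


def write_report_tsv(report: RunReport, path) -> None:
    lines = ["\t".join(_REPORT_COLUMNS)]
    for g in report.genes:
        lines.append(
            "\t".join(
                [
                    g.gene_id,
                    g.status,
                    str(len(g.edits)),
                    str(g.boundary_shift[0]),
                    str(g.boundary_shift[1]),
                    "; ".join(g.messages),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def _is_pseudo(genome: GenomeRecord, model: GeneModel) -> bool:
    idx = model.source_feature_index
    if idx is None:
        return False
    quals = genome.features[idx].qualifiers
    return "pseudo" in quals or "pseudogene" in quals


def annotate_record(
    genome: GenomeRecord,
    models: list[GeneModel],
    config: Optional[Config] = None,
) -> tuple[GenomeRecord, RunReport]:
    """Process every reconciled model and return (annotated record, report)."""
    config = config or Config()
    report = RunReport(accession=genome.accession)
    for model in models:
        if _is_pseudo(genome, model):
            report.genes.append(
                GeneReport(
                    gene_id=model.gene_id,
                    status=CLEAN,
                    messages=["pseudo qualifier present; gene skipped"],
                    model=model,
                )
            )
            continue
        gene_report = process_gene(model, genome, config)
        if gene_report.status == MANUAL_CHECK:
            logger.warning(
                "gene %s flagged for manual check: %s",
                gene_report.gene_id,
                "; ".join(gene_report.messages),
            )
        report.genes.append(gene_report)
    annotated = apply_annotations(genome, report.genes)
    return annotated, report


def run(gb_path, gff_path, out_dir, config: Optional[Config] = None) -> RunReport:
    """Full pipeline: read inputs, infer edits, write the four outputs.

    Writes ``<accession>_edited.gb``, ``<accession>.tbl``,
    ``<accession>_proteins.fasta`` and ``<accession>_report.tsv`` into
    ``out_dir``. Manual-check genes are warnings, not failures; only I/O and
    parse errors raise (no partial outputs are written in that case).
    """
    config = config or Config()
    gb_path, gff_path = Path(gb_path), Path(gff_path)
    for p in (gb_path, gff_path):
        if not p.exists():
            raise FileNotFoundError(f"input file not found: {p}")
    genome = iof.read_genbank(gb_path)
    models = iof.read_gff3(gff_path, genome, seqid_alias=config.seqid_alias)
    models, warnings_out = iof.reconcile(models, genome)
    for w in warnings_out:
        logger.warning("%s", w)

    annotated, report = annotate_record(genome, models, config)
    report.warnings.extend(warnings_out)

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    acc = genome.accession
    iof.write_genbank(annotated, out_dir / f"{acc}_edited.gb")
    iof.write_feature_table(annotated, out_dir / f"{acc}.tbl")
    iof.write_protein_fasta(report.genes, acc, out_dir / f"{acc}_proteins.fasta")
    write_report_tsv(report, out_dir / f"{acc}_report.tsv")
    return report
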