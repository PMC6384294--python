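"""Codon-level logic for RNA-editing rescue of nonsense defects.

In plastomes of ferns and hornworts, C-to-U and U-to-C RNA editing routinely
repairs what looks like pseudogenization at the DNA level: genomic ACG read
as an AUG start, genomic CAA/CAG/CGA read as a stop, and genomic in-frame
stops (TAA/TAG/TGA) read as sense codons. This module holds the pure codon
arithmetic: start/stop validity, single-base C<->U rescue of terminal codons,
restoration of internal stops, the +/-5-codon boundary scan, conceptual
translation of the edited mRNA, and the spliced-to-genomic coordinate map.

All directions are expressed in coding-strand sense: ``C-to-U`` means the
coding-strand genomic base is C and is read as U in the mRNA; ``U-to-C``
means the genomic base is T and is read as C. A codon is rescuable only by
exactly one such substitution — multi-site rescue of a single codon is out
of scope, which keeps the false-positive surface minimal.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional

from Bio.Data import CodonTable

from .io_formats import GeneModel

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
DNA_BASES = frozenset("ACGT")

C_TO_U = "C-to-U"
U_TO_C = "U-to-C"

START_RESCUE = "start_rescue"
STOP_RESCUE = "stop_rescue"
INTERNAL_STOP_RESCUE = "internal_stop_rescue"

FIVE_PRIME = "five_prime"
THREE_PRIME = "three_prime"


def _codon_map(table_id: int) -> dict[str, str]:
    table = CodonTable.unambiguous_dna_by_id[table_id]
    mapping = dict(table.forward_table)
    for stop in table.stop_codons:
        mapping[stop] = "*"
    return mapping


@dataclass(frozen=True)
class GeneticCode:
    """A codon table plus the start/stop codon policy used for rescue.

    ``valid_start_codons`` defaults to {ATG} only: accepting the other
    table-11 initiators (GTG/TTG/...) outright would silently suppress the
    edit annotations this tool exists to make. The stop set is the standard
    {TAA, TAG, TGA}.
    """

    codon_to_aa: Mapping[str, str]
    valid_start_codons: frozenset = frozenset({"ATG"})
    stop_codons: frozenset = STOP_CODONS

    @classmethod
    def table11(cls, valid_start_codons: Iterable[str] = ("ATG",)) -> "GeneticCode":
        """The bacterial/archaeal/plant-plastid code (NCBI table 11)."""
        return cls(
            codon_to_aa=_codon_map(11),
            valid_start_codons=frozenset(c.upper() for c in valid_start_codons),
        )

    def translate_codon(self, codon: str) -> str:
        """Single-letter amino acid, '*' for stops, 'X' for ambiguous codons."""
        return self.codon_to_aa.get(codon.upper(), "X")


@dataclass(frozen=True)
class EditEvent:
    """One inferred RNA-editing site.

    ``codon_before`` is the genomic codon on the coding strand;
    ``codon_after`` is the post-editing mRNA codon written in the DNA
    alphabet. They differ at exactly one position, by T<->C.
    ``genomic_position`` is 1-based on the forward genomic strand; rescue
    functions return events with position/strand/codon_index unplaced
    (filled in by the annotator once the gene model is known).
    """

    role: str  # start_rescue | stop_rescue | internal_stop_rescue
    direction: str  # C-to-U | U-to-C (coding-strand sense)
    pos_in_codon: int  # 1 | 2 | 3
    codon_before: str
    codon_after: str
    amino_acid_after: str
    codon_index: int = -1  # 0-based within the spliced CDS
    genomic_position: int = 0  # 1-based, forward strand
    strand: str = "+"
    gene_id: str = ""

    @property
    def key(self) -> tuple:
        """Identity used when comparing emitted edits against a truth set."""
        return (self.genomic_position, self.strand, self.direction, self.role)

    def placed(self, model: GeneModel, codon_index: int) -> "EditEvent":
        pos = spliced_index_to_genomic(model, codon_index, self.pos_in_codon)
        return replace(
            self,
            codon_index=codon_index,
            genomic_position=pos,
            strand=model.strand,
            gene_id=model.gene_id,
        )


def _single_edits(codon: str):
    """All single C<->U substitutions of a codon: (pos0, new_codon, direction)."""
    for i, base in enumerate(codon):
        if base == "C":
            yield i, codon[:i] + "T" + codon[i + 1 :], C_TO_U
        elif base == "T":
            yield i, codon[:i] + "C" + codon[i + 1 :], U_TO_C


def is_valid_start(codon: str, code: GeneticCode) -> bool:
    return codon.upper() in code.valid_start_codons


def rescue_start(codon: str, code: Optional[GeneticCode] = None) -> Optional[EditEvent]:
    """Edit restoring an invalid start codon to a start, if one exists.

    Only genomic C read as U can create the U of AUG, so under the default
    start set the single rescuable codon is ACG (edit at codon position 2).
    """
    code = code or GeneticCode.table11()
    codon = codon.upper()
    if set(codon) - DNA_BASES:
        return None  # ambiguous codons are never edit candidates
    for i, after, direction in _single_edits(codon):
        if direction == C_TO_U and after in code.valid_start_codons:
            return EditEvent(
                role=START_RESCUE,
                direction=direction,
                pos_in_codon=i + 1,
                codon_before=codon,
                codon_after=after,
                amino_acid_after="M",
            )
    return None


def rescue_stop(codon: str) -> Optional[EditEvent]:
    """Edit turning a non-stop final codon into a stop, if one exists.

    Creating the U of UAA/UAG/UGA needs genomic C read as U; the rescuable
    codons are exactly CAA, CAG and CGA (edit at codon position 1).
    """
    codon = codon.upper()
    if set(codon) - DNA_BASES:
        return None
    for i, after, direction in _single_edits(codon):
        if direction == C_TO_U and after in STOP_CODONS:
            return EditEvent(
                role=STOP_RESCUE,
                direction=direction,
                pos_in_codon=i + 1,
                codon_before=codon,
                codon_after=after,
                amino_acid_after="*",
            )
    return None


def rescue_internal_stop(
    codon: str, code: Optional[GeneticCode] = None
) -> Optional[EditEvent]:
    """Edit reading an in-frame genomic stop as a sense codon.

    Removing the U of a genomic stop needs genomic T read as C (U-to-C).
    For each of the three stops the rescue is unique: TAA->CAA (Q),
    TAG->CAG (Q), TGA->CGA (R), always at codon position 1. If several
    sense-restoring substitutions existed, the lowest codon position would
    win (deterministic output).
    """
    code = code or GeneticCode.table11()
    codon = codon.upper()
    if codon not in STOP_CODONS:
        raise ValueError(f"rescue_internal_stop called on non-stop codon {codon!r}")
    for i, after, direction in _single_edits(codon):
        if direction == U_TO_C and code.translate_codon(after) != "*":
            return EditEvent(
                role=INTERNAL_STOP_RESCUE,
                direction=direction,
                pos_in_codon=i + 1,
                codon_before=codon,
                codon_after=after,
                amino_acid_after=code.translate_codon(after),
            )
    return None


def find_internal_stops(
    spliced_cds: str, code: Optional[GeneticCode] = None
) -> list[tuple[int, str]]:
    """In-frame stop codons strictly before the final codon.

    Returns (codon_index, codon) pairs in ascending order; ``spliced_cds``
    length must be divisible by 3.
    """
    code = code or GeneticCode.table11()
    if len(spliced_cds) % 3:
        raise ValueError("spliced CDS length not divisible by 3")
    seq = spliced_cds.upper()
    return [
        (i, seq[3 * i : 3 * i + 3])
        for i in range(len(seq) // 3 - 1)
        if seq[3 * i : 3 * i + 3] in code.stop_codons
    ]


def scan_for_boundary(
    spliced_seq: str,
    end: str,
    window_codons: int = 5,
    code: Optional[GeneticCode] = None,
    flank_codons: Optional[int] = None,
):
    """Look within +/-``window_codons`` of a failed terminal codon for a fix.

    ``spliced_seq`` is the spliced CDS with ``flank_codons`` codons of
    in-frame genomic flank prepended (``end='five_prime'``) or appended
    (``end='three_prime'``); ``flank_codons`` defaults to ``window_codons``
    and may be smaller when the genome end truncated the window.

    Returns ``(offset_codons, codon, edit-or-None)`` for the best candidate,
    or None. Candidates are ranked by smallest |offset|; at equal |offset| a
    directly valid codon beats an edit-rescuable one, and the direction that
    extends the gene (upstream for starts, downstream for stops) beats the
    direction that shrinks it. Offsets that would leave fewer than two
    codons of CDS are not considered.
    """
    code = code or GeneticCode.table11()
    if end not in (FIVE_PRIME, THREE_PRIME):
        raise ValueError(f"unknown end {end!r}")
    if flank_codons is None:
        flank_codons = window_codons
    seq = spliced_seq.upper()
    if len(seq) % 3:
        raise ValueError("scan sequence length not divisible by 3")
    n_codons = len(seq) // 3
    cds_codons = n_codons - flank_codons

    def codon_at(offset: int) -> str:
        if end == FIVE_PRIME:
            idx = flank_codons + offset
        else:
            idx = cds_codons - 1 + offset
        return seq[3 * idx : 3 * idx + 3]

    candidates = []
    for offset in range(-window_codons, window_codons + 1):
        if offset == 0:
            continue
        if end == FIVE_PRIME:
            if offset < -flank_codons or offset > min(window_codons, cds_codons - 2):
                continue
            extends = offset < 0
        else:
            if offset > flank_codons or offset < -min(window_codons, cds_codons - 2):
                continue
            extends = offset > 0
        codon = codon_at(offset)
        if set(codon) - DNA_BASES:
            continue  # ambiguous codons are never candidates
        if end == FIVE_PRIME:
            direct = is_valid_start(codon, code)
            edit = None if direct else rescue_start(codon, code)
        else:
            direct = codon in code.stop_codons
            edit = None if direct else rescue_stop(codon)
        if direct or edit is not None:
            candidates.append(
                ((abs(offset), 0 if direct else 1, 0 if extends else 1), offset, codon, edit)
            )
    if not candidates:
        return None
    _, offset, codon, edit = min(candidates, key=lambda c: c[0])
    return offset, codon, edit


def conceptual_translation(
    spliced_cds: str,
    edits: Iterable[EditEvent] = (),
    code: Optional[GeneticCode] = None,
) -> str:
    """Translate the edited mRNA of a CDS; terminal stop dropped.

    Each edit's ``codon_after`` replaces the genomic codon at its
    ``codon_index`` before translation. A '*' surviving in the interior
    means the caller failed to rescue an internal stop and is an error.
    """
    code = code or GeneticCode.table11()
    if len(spliced_cds) % 3:
        raise ValueError("spliced CDS length not divisible by 3")
    codons = [spliced_cds[i : i + 3].upper() for i in range(0, len(spliced_cds), 3)]
    for edit in edits:
        if not (0 <= edit.codon_index < len(codons)):
            raise ValueError(
                f"edit codon_index {edit.codon_index} outside CDS of "
                f"{len(codons)} codons"
            )
        codons[edit.codon_index] = edit.codon_after
    protein = "".join(code.translate_codon(c) for c in codons)
    if protein.endswith("*"):
        protein = protein[:-1]
    if "*" in protein:
        raise RuntimeError(
            "internal stop remains after applying edits — the annotator must "
            "not translate an unrescued gene"
        )
    return protein


def spliced_index_to_genomic(
    model: GeneModel, codon_index: int, pos_in_codon: int
) -> int:
    """Map a codon-space position to a 1-based forward-strand genome position.

    Walks the model's coding-order intervals; on the minus strand the walk
    descends through genome space, so codon 0 position 1 of a minus-strand
    gene is the interval's highest coordinate.
    """
    if pos_in_codon not in (1, 2, 3):
        raise ValueError("pos_in_codon must be 1, 2 or 3")
    offset = 3 * codon_index + (pos_in_codon - 1)
    if not 0 <= offset < model.spliced_length:
        raise IndexError(
            f"spliced offset {offset} outside CDS of {model.spliced_length} bp"
        )
    for start, end in model.intervals:
        length = end - start
        if offset < length:
            if model.strand == "-":
                return end - offset  # 1-based
            return start + offset + 1
        offset -= length
    raise AssertionError("unreachable")
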