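"""Synthetic toy plastomes with planted RNA-editing defects.

Real validation of an editing annotator needs plastomes whose editing sites
are confirmed by cDNA; those are not shippable test data. Instead this
module builds small artificial plastomes from scratch: random open reading
frames (ATG ... sense codons ... stop) separated by random spacers, on both
strands, optionally split by an intron. Defects are planted by
reverse-applying a legal edit — writing genomic ACG where the edited mRNA
has AUG, genomic CAA/CAG/CGA where the mRNA has a stop, or a genomic stop
where the mRNA has CAA/CAG/CGA — so every planted defect is rescuable by
construction and full recall is a fair expectation. A machine-readable
:class:`TruthSet` records every planted event.

The generator deliberately does not simulate sequencing error, indels or
codon-usage bias; separate knobs plant *unrescuable* defects (e.g. a GTG
start with a scrubbed neighbourhood) to exercise the manual-check paths.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from Bio.Data import CodonTable

from .editing_core import (
    C_TO_U,
    INTERNAL_STOP_RESCUE,
    START_RESCUE,
    STOP_RESCUE,
    U_TO_C,
    EditEvent,
)
from .io_formats import Feature, GenomeRecord, revcomp, write_genbank

_TABLE11 = CodonTable.unambiguous_dna_by_id[11]
STOPS = ("TAA", "TAG", "TGA")
_SENSE_CODONS = sorted(_TABLE11.forward_table)  # 61 sense codons
# stop <-> pre-edit sense codon pairs used for reverse-planting
_STOP_FROM_SENSE = {"CAA": "TAA", "CAG": "TAG", "CGA": "TGA"}
_SENSE_FROM_STOP = {v: k for k, v in _STOP_FROM_SENSE.items()}
# codons free of A/T/G starts and of anything start- or stop-rescuable,
# used to scrub boundary-scan windows
_SCRUB_CODONS = ("CCT", "CCC", "CTC", "TCC")


@dataclass(frozen=True)
class DefectSpec:
    """Per-gene defect distribution for edited genes.

    ``mean_internal_stops`` parameterizes a (capped) Poisson draw; an edited
    gene that draws no defect at all is given one internal stop so that
    "edited" genes always carry at least one planted event.
    """

    p_bad_start: float = 0.5
    p_missing_stop: float = 0.5
    mean_internal_stops: float = 1.0
    max_internal_stops: int = 5


@dataclass
class TruthSet:
    """Ground truth for one synthetic plastome."""

    accession: str
    seed: int
    events: list[EditEvent] = field(default_factory=list)
    expected_status: dict[str, str] = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    n_features: int = 0

    def event_keys(self) -> set[tuple]:
        return {e.key for e in self.events}


@dataclass
class _GeneSpec:
    gene_id: str
    strand: str = "+"
    intron: bool = False
    n_codons: Optional[int] = None
    bad_start: bool = False
    missing_stop: bool = False
    internal_stops: int = 0
    internal_stop_indices: Optional[list[int]] = None
    intron_split_codon: Optional[int] = None
    unrescuable_start: bool = False
    n_in_start: bool = False
    pseudo: bool = False
    frame_break: bool = False
    annotate_skip_start_codons: int = 0


def _poisson(rng: random.Random, mean: float) -> int:
    if mean <= 0:
        return 0
    threshold = math.exp(-mean)
    k, p = 0, 1.0
    while True:
        p *= rng.random()
        if p <= threshold:
            return k
        k += 1


def _random_spacer(rng: random.Random, length: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(length))


def _random_orf_codons(rng: random.Random, n_codons: int) -> list[str]:
    body = [rng.choice(_SENSE_CODONS) for _ in range(n_codons - 2)]
    return ["ATG"] + body + [rng.choice(STOPS)]


def _to_genomic(intervals, strand: str, spliced_offset: int) -> int:
    """Generator-local spliced->genomic walk (1-based), kept independent of
    the annotator's coordinate code so tests can cross-check the two."""
    o = spliced_offset
    for start, end in intervals:
        length = end - start
        if o < length:
            return end - o if strand == "-" else start + o + 1
        o -= length
    raise IndexError(spliced_offset)


def _plant(spec: _GeneSpec, rng: random.Random):
    """Build the gene's codon list, planted events (codon space) and status."""
    n = spec.n_codons or rng.randrange(50, 501)
    n = max(n, 30)
    codons = _random_orf_codons(rng, n)
    events = []  # (codon_index, pos_in_codon, direction, role, before, after, aa)
    status = "clean"

    if spec.annotate_skip_start_codons:
        k = spec.annotate_skip_start_codons
        codons[0] = "ACG"
        for i in range(1, k):
            codons[i] = rng.choice(_SCRUB_CODONS)
        codons[k] = "CTG"  # invalid start, not C-to-U rescuable to ATG
        for i in range(k + 1, min(k + 6, n - 2)):
            codons[i] = rng.choice(_SCRUB_CODONS)
        if k <= 5:
            events.append((0, 2, C_TO_U, START_RESCUE, "ACG", "ATG", "M"))
            status = "boundary_adjusted"
        else:
            status = "manual_check"
    elif spec.unrescuable_start or spec.n_in_start:
        codons[0] = "ANG" if spec.n_in_start else "GTG"
        for i in range(1, min(6, n - 2)):
            codons[i] = rng.choice(_SCRUB_CODONS)
        status = "manual_check"
    elif spec.bad_start:
        codons[0] = "ACG"
        events.append((0, 2, C_TO_U, START_RESCUE, "ACG", "ATG", "M"))
        status = "edited"

    if spec.missing_stop and status != "manual_check":
        pre = rng.choice(sorted(_STOP_FROM_SENSE))
        codons[-1] = pre
        events.append((n - 1, 1, C_TO_U, STOP_RESCUE, pre, _STOP_FROM_SENSE[pre], "*"))
        if status == "clean":
            status = "edited"

    if spec.internal_stops and status != "manual_check":
        lo = (spec.annotate_skip_start_codons or 0) + 7
        lo = max(1, min(lo, n - 2 - spec.internal_stops))
        indices = spec.internal_stop_indices or sorted(
            rng.sample(range(lo, n - 1), spec.internal_stops)
        )
        for idx in indices:
            stop = rng.choice(STOPS)
            codons[idx] = stop
            sense = _SENSE_FROM_STOP[stop]
            aa = _TABLE11.forward_table[sense]
            events.append((idx, 1, U_TO_C, INTERNAL_STOP_RESCUE, stop, sense, aa))
        if status == "clean":
            status = "edited"

    if spec.pseudo:
        status = "skipped"
        events = []
    if spec.frame_break:
        status = "manual_check"
        events = []
    return codons, events, status


def _build_plastome(
    accession: str,
    specs: list[_GeneSpec],
    seed: int,
    out_dir,
    params: Optional[dict] = None,
):
    rng = random.Random(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    segments: list[str] = []
    cursor = 0
    features: list[Feature] = []
    gff_lines: list[str] = []
    truth = TruthSet(accession=accession, seed=seed, params=params or {})
    scrub_next_spacer_start = False  # coding 5' flank of a minus-strand gene

    def append(segment: str) -> None:
        nonlocal cursor
        segments.append(segment)
        cursor += len(segment)

    for spec in specs:
        spacer = _random_spacer(rng, rng.randrange(80, 301))
        wants_scrub = spec.unrescuable_start or spec.n_in_start
        if scrub_next_spacer_start:
            spacer = "G" * 15 + spacer[15:]
            scrub_next_spacer_start = False
        if wants_scrub and spec.strand == "+":
            spacer = spacer[:-15] + "C" * 15
        if wants_scrub and spec.strand == "-":
            scrub_next_spacer_start = True
        append(spacer)

        codons, codon_events, status = _plant(spec, rng)
        cds = "".join(codons)
        gene_start = cursor

        if spec.intron:
            split = spec.intron_split_codon
            p = 3 * split if split is not None else rng.randrange(30, len(cds) - 30)
            intron = _random_spacer(rng, rng.randrange(60, 201))
            if spec.strand == "+":
                block = cds[:p] + intron + cds[p:]
                exon1 = (gene_start, gene_start + p)
                exon2 = (gene_start + p + len(intron), gene_start + len(block))
                intervals = [exon1, exon2]  # coding order
            else:
                block = revcomp(cds[p:]) + intron + revcomp(cds[:p])
                low = (gene_start, gene_start + len(cds) - p)
                high = (gene_start + len(cds) - p + len(intron), gene_start + len(block))
                intervals = [high, low]  # coding order: high block first
            append(block)
        else:
            block = cds if spec.strand == "+" else revcomp(cds)
            intervals = [(gene_start, gene_start + len(block))]
            append(block)

        annotated = [list(iv) for iv in intervals]
        if spec.annotate_skip_start_codons:
            k = 3 * spec.annotate_skip_start_codons
            if spec.strand == "+":
                annotated[0][0] += k
            else:
                annotated[0][1] -= k
        if spec.frame_break:
            if spec.strand == "+":
                annotated[-1][1] += 1
            else:
                annotated[-1][0] -= 1
        annotated = [tuple(iv) for iv in annotated]

        for codon_index, pos, direction, role, before, after, aa in codon_events:
            genomic = _to_genomic(intervals, spec.strand, 3 * codon_index + pos - 1)
            truth.events.append(
                EditEvent(
                    role=role,
                    direction=direction,
                    pos_in_codon=pos,
                    codon_before=before,
                    codon_after=after,
                    amino_acid_after=aa,
                    codon_index=codon_index,
                    genomic_position=genomic,
                    strand=spec.strand,
                    gene_id=spec.gene_id,
                )
            )
        truth.expected_status[spec.gene_id] = status

        span_lo = min(s for s, _ in annotated)
        span_hi = max(e for _, e in annotated)
        gene_quals = {"gene": [spec.gene_id]}
        cds_quals = {
            "gene": [spec.gene_id],
            "product": [f"hypothetical plastid protein {spec.gene_id}"],
            "codon_start": ["1"],
            "transl_table": ["11"],
        }
        if spec.pseudo:
            gene_quals["pseudo"] = [""]
            cds_quals["pseudo"] = [""]
        features.append(
            Feature("gene", [(span_lo, span_hi)], spec.strand, gene_quals)
        )
        features.append(Feature("CDS", list(annotated), spec.strand, cds_quals))

        gff_lines.append(
            "\t".join(
                [
                    accession,
                    "plastedit_sim",
                    "gene",
                    str(span_lo + 1),
                    str(span_hi),
                    ".",
                    spec.strand,
                    ".",
                    f"ID=gene-{spec.gene_id};Name={spec.gene_id}",
                ]
            )
        )
        phases = _phases(annotated, spec.strand)
        for (s, e) in sorted(annotated):
            gff_lines.append(
                "\t".join(
                    [
                        accession,
                        "plastedit_sim",
                        "CDS",
                        str(s + 1),
                        str(e),
                        ".",
                        spec.strand,
                        str(phases[(s, e)]),
                        f"ID=cds-{spec.gene_id};Parent=gene-{spec.gene_id};"
                        f"gene={spec.gene_id}"
                        + (";pseudo=true" if spec.pseudo else ""),
                    ]
                )
            )

    final_spacer = _random_spacer(rng, rng.randrange(80, 301))
    if scrub_next_spacer_start:
        final_spacer = "G" * 15 + final_spacer[15:]
    append(final_spacer)
    sequence = "".join(segments)
    features.insert(
        0,
        Feature(
            "source",
            [(0, len(sequence))],
            "+",
            {"organism": ["synthetic construct"], "mol_type": ["genomic DNA"]},
        ),
    )
    record = GenomeRecord(
        accession=accession,
        sequence=sequence,
        topology="linear",
        features=features,
        header_fields={
            "name": accession,
            "definition": "synthetic plastome fixture with planted RNA-editing defects",
            "organism": "synthetic construct",
        },
    )
    truth.n_features = len(features)

    gb_path = out_dir / f"{accession}.gb"
    gff_path = out_dir / f"{accession}.gff3"
    write_genbank(record, gb_path)
    header = [
        "##gff-version 3",
        f"##sequence-region {accession} 1 {len(sequence)}",
    ]
    gff_path.write_text("\n".join(header + gff_lines) + "\n")
    write_truth_tsv(truth, out_dir / f"{accession}_truth.tsv")
    return gb_path, gff_path, truth


def _phases(intervals, strand: str) -> dict:
    """GFF3 phase per exon: 0 for the coding-first exon, then carried over."""
    coding_order = sorted(intervals, reverse=(strand == "-"))
    phases = {}
    carried = 0
    for s, e in coding_order:
        phases[(s, e)] = carried
        carried = (3 - ((e - s) - carried) % 3) % 3
    return phases


def write_truth_tsv(truth: TruthSet, path) -> None:
    lines = ["gene\tgenomic_position\tstrand\tdirection\trole\tcodon_before\tcodon_after"]
    for e in truth.events:
        lines.append(
            "\t".join(
                [
                    e.gene_id,
                    str(e.genomic_position),
                    e.strand,
                    e.direction,
                    e.role,
                    e.codon_before,
                    e.codon_after,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def make_plastome(
    out_dir,
    n_genes: int = 30,
    fraction_edited: float = 0.78,
    defects_per_gene: DefectSpec = DefectSpec(),
    strand_mix: float = 0.5,
    introns: float = 0.2,
    seed: int = 0,
    unrescuable_fraction: float = 0.0,
):
    """Generate one synthetic plastome trio (GenBank, GFF3, TruthSet).

    ``fraction_edited`` genes carry planted rescuable defects (default 0.78,
    the upper end of editing prevalence reported for fern/hornwort
    plastomes); ``strand_mix`` is the minus-strand proportion and ``introns``
    the proportion of two-exon gene models. Identical parameters and seed
    reproduce byte-identical files.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    for name, p in [
        ("fraction_edited", fraction_edited),
        ("strand_mix", strand_mix),
        ("introns", introns),
        ("unrescuable_fraction", unrescuable_fraction),
    ]:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {p}")

    rng = random.Random(seed ^ 0x5EED)
    specs = []
    for i in range(n_genes):
        gene_id = f"g{i + 1:03d}"
        strand = "-" if rng.random() < strand_mix else "+"
        intron = rng.random() < introns
        spec = _GeneSpec(gene_id=gene_id, strand=strand, intron=intron)
        if rng.random() < unrescuable_fraction:
            spec.unrescuable_start = True
        elif rng.random() < fraction_edited:
            d = defects_per_gene
            spec.bad_start = rng.random() < d.p_bad_start
            spec.missing_stop = rng.random() < d.p_missing_stop
            spec.internal_stops = min(
                _poisson(rng, d.mean_internal_stops), d.max_internal_stops
            )
            if not (spec.bad_start or spec.missing_stop or spec.internal_stops):
                spec.internal_stops = 1
        specs.append(spec)

    accession = f"SYN{seed % 10**6:06d}"
    params = {
        "n_genes": n_genes,
        "fraction_edited": fraction_edited,
        "strand_mix": strand_mix,
        "introns": introns,
        "unrescuable_fraction": unrescuable_fraction,
    }
    return _build_plastome(accession, specs, seed, out_dir, params)


def make_boundary_case(out_dir, offset_codons: int, seed: int = 0):
    """Single-gene plastome whose true (edit-rescuable) start lies
    ``offset_codons`` codons upstream of the annotated start.

    The annotated start codon is CTG (invalid, unrescuable) and the scan
    window is scrubbed of competing candidates, so with |offset| <= 5 the
    boundary scan must find exactly this ACG; with |offset| > 5 the gene
    must come back as manual_check.
    """
    if offset_codons >= 0:
        raise ValueError("offset_codons is the upstream shift; must be negative")
    spec = _GeneSpec(
        gene_id="g001",
        strand="+",
        n_codons=60,
        annotate_skip_start_codons=-offset_codons,
    )
    accession = f"BND{(-offset_codons) % 100:02d}{seed % 10**4:04d}"
    return _build_plastome(
        accession, [spec], seed, out_dir, {"offset_codons": offset_codons}
    )


def make_edge_cases(out_dir, seed: int = 0):
    """Pathological fixture plastome exercising the manual-check paths.

    Genes: five planted internal stops (rescuable, at the limit), six
    internal stops (over the limit), an unrescuable GTG start with a
    scrubbed scan window, a CDS whose length is not divisible by three, an
    N-containing start codon, a minus-strand two-exon gene with one planted
    edit in each exon, a pseudo-flagged gene carrying defects, and one clean
    gene.
    """
    specs = [
        _GeneSpec(gene_id="stop5", n_codons=80, internal_stops=5),
        _GeneSpec(gene_id="stop6", n_codons=80, internal_stops=6),
        _GeneSpec(gene_id="badstart", n_codons=60, unrescuable_start=True),
        _GeneSpec(gene_id="frameoff", n_codons=60, frame_break=True),
        _GeneSpec(gene_id="ambig", n_codons=60, n_in_start=True),
        _GeneSpec(
            gene_id="twoexon",
            strand="-",
            n_codons=100,
            intron=True,
            intron_split_codon=50,
            bad_start=True,
            internal_stops=1,
            internal_stop_indices=[70],
        ),
        _GeneSpec(
            gene_id="pseudo1", n_codons=60, pseudo=True, bad_start=True,
            internal_stops=1,
        ),
        _GeneSpec(gene_id="cleang", n_codons=60),
    ]
    # six internal stops exceed the default limit: expected manual, no events
    truth_gb, truth_gff, truth = _build_plastome(
        f"EDGE{seed % 10**4:04d}", specs, seed, out_dir, {"edge_cases": True}
    )
    truth.expected_status["stop6"] = "manual_check"
    truth.events = [e for e in truth.events if e.gene_id != "stop6"]
    write_truth_tsv(truth, Path(out_dir) / f"{truth.accession}_truth.tsv")
    return truth_gb, truth_gff, truth
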