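"""Reading and writing the annotation formats around a plastome run.

Reads GenBank flat files (sequence + existing features, via Biopython) and
GFF3 gene models (via gffutils), and writes the three submission-oriented
outputs: a regenerated GenBank flat file, an NCBI five-column feature table
(.tbl) for table2asn, and a protein FASTA of conceptual translations.

Coordinate convention: everything in memory is 0-based half-open on the
forward genomic strand; 1-based inclusive coordinates exist only inside the
parsers and serializers. Feature/GeneModel interval lists are kept in coding
order (5'->3' along the coding strand), so minus-strand multi-exon features
store their highest-coordinate interval first.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

IUPAC_NT = frozenset("ACGTNRYSWKMBDHV")

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")


def revcomp(seq: str) -> str:
    """Reverse complement of an IUPAC nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


class GenBankParseError(ValueError):
    """The GenBank flat file could not be parsed."""


class Gff3ParseError(ValueError):
    """The GFF3 file could not be parsed."""


class ValidationError(ValueError):
    """Parsed input violates a structural invariant (bad coordinates etc.)."""


Interval = tuple[int, int]  # 0-based half-open on the forward strand


@dataclass
class Feature:
    """One annotation feature (gene, CDS, tRNA, misc_feature, ...).

    ``intervals`` are 0-based half-open forward-strand spans kept in coding
    order; ``qualifiers`` maps qualifier name -> list of values, preserving
    insertion order and unknown keys verbatim.
    """

    kind: str
    intervals: list[Interval]
    strand: str  # '+' | '-'
    qualifiers: dict[str, list[str]] = field(default_factory=dict)

    def span(self) -> Interval:
        starts = [s for s, _ in self.intervals]
        ends = [e for _, e in self.intervals]
        return min(starts), max(ends)

    def first_qualifier(self, name: str) -> Optional[str]:
        values = self.qualifiers.get(name)
        return values[0] if values else None


@dataclass
class GenomeRecord:
    """A plastome: sequence, topology, ordered features and header metadata."""

    accession: str
    sequence: str
    topology: str = "linear"  # 'circular' | 'linear'
    features: list[Feature] = field(default_factory=list)
    header_fields: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sequence)

    def validate(self) -> None:
        bad = set(self.sequence) - IUPAC_NT
        if bad:
            raise ValidationError(
                f"{self.accession}: sequence contains non-IUPAC letters {sorted(bad)}"
            )
        n = len(self.sequence)
        for feat in self.features:
            for start, end in feat.intervals:
                if not (0 <= start < end <= n):
                    raise ValidationError(
                        f"{self.accession}: {feat.kind} interval "
                        f"{start + 1}..{end} outside sequence 1..{n}"
                    )


@dataclass
class GeneModel:
    """One CDS gene model: the unit the editing inference processes."""

    gene_id: str
    product: str
    intervals: list[Interval]  # coding order
    strand: str
    source_feature_index: Optional[int] = None
    manual: bool = False
    frame_suspect: bool = False
    messages: list[str] = field(default_factory=list)

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.intervals)

    def flag(self, message: str) -> None:
        self.manual = True
        self.messages.append(message)


def splice(sequence: str, model_or_feature) -> str:
    """Spliced coding-strand sequence of a model/feature over ``sequence``."""
    parts = []
    for start, end in model_or_feature.intervals:
        chunk = sequence[start:end]
        parts.append(revcomp(chunk) if model_or_feature.strand == "-" else chunk)
    return "".join(parts)


def _coding_order(intervals: list[Interval], strand: str) -> list[Interval]:
    return sorted(intervals, key=lambda iv: iv[0], reverse=(strand == "-"))


# ---------------------------------------------------------------------------
# GenBank flat file


def _feature_from_seqfeature(feat: SeqFeature, accession: str) -> Feature:
    strand = "-" if feat.location.strand == -1 else "+"
    as_written = [(int(p.start), int(p.end)) for p in feat.location.parts]
    for (s1, e1), (s2, e2) in zip(as_written, as_written[1:]):
        if s2 < e1:
            raise ValidationError(
                f"{accession}: {feat.type} location {as_written} is out of order "
                "or spans the circular origin; flagged for manual handling"
            )
    qualifiers = {k: [str(v) for v in vs] for k, vs in feat.qualifiers.items()}
    return Feature(
        kind=feat.type,
        intervals=_coding_order(as_written, strand),
        strand=strand,
        qualifiers=qualifiers,
    )


def read_genbank(path) -> GenomeRecord:
    """Parse a GenBank flat file into a :class:`GenomeRecord`.

    The file must begin with a LOCUS line; features whose intervals fall
    outside the sequence raise :class:`ValidationError` naming the feature.
    """
    path = Path(path)
    with open(path) as handle:
        first = ""
        for line in handle:
            if line.strip():
                first = line
                break
        if not first.startswith("LOCUS"):
            raise GenBankParseError(
                f"{path}: not a GenBank flat file (first line is not LOCUS): "
                f"{first.strip()!r}"
            )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bio = SeqIO.read(str(path), "genbank")
    except ValueError as exc:
        raise GenBankParseError(f"{path}: {exc}") from exc

    header = {"name": bio.name, "definition": bio.description}
    for key in ("organism", "source", "date", "data_file_division", "accessions"):
        value = bio.annotations.get(key)
        if isinstance(value, list):
            value = value[0] if value else ""
        if value:
            header[key] = str(value)

    record = GenomeRecord(
        accession=bio.id if bio.id != "<unknown id>" else bio.name,
        sequence=str(bio.seq).upper(),
        topology=bio.annotations.get("topology", "linear"),
        features=[_feature_from_seqfeature(f, bio.id) for f in bio.features],
        header_fields=header,
    )
    record.validate()
    return record


def _seqfeature_from_feature(feat: Feature) -> SeqFeature:
    strand = -1 if feat.strand == "-" else 1
    ascending = sorted(feat.intervals, key=lambda iv: iv[0])
    locs = [SimpleLocation(s, e, strand=strand) for s, e in ascending]
    location = locs[0] if len(locs) == 1 else CompoundLocation(locs)
    return SeqFeature(
        location=location,
        type=feat.kind,
        qualifiers={k: list(v) for k, v in feat.qualifiers.items()},
    )


def write_genbank(record: GenomeRecord, path) -> None:
    """Serialize a :class:`GenomeRecord` as a GenBank flat file.

    The file is regenerated (ORIGIN in 60-base lines, qualifier wrapping per
    the flat-file grammar); feature content round-trips through
    :func:`read_genbank` feature- and sequence-equal.
    """
    record.validate()
    annotations = {
        "molecule_type": "DNA",
        "topology": record.topology,
        "data_file_division": record.header_fields.get("data_file_division", "PLN"),
    }
    for key in ("organism", "source", "date"):
        if key in record.header_fields:
            annotations[key] = record.header_fields[key]
    annotations.setdefault("organism", "synthetic construct")
    annotations.setdefault("source", annotations["organism"])
    bio = SeqRecord(
        Seq(record.sequence),
        id=record.accession,
        name=record.header_fields.get("name", record.accession),
        description=record.header_fields.get("definition", ""),
        annotations=annotations,
    )
    bio.features = [_seqfeature_from_feature(f) for f in record.features]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        SeqIO.write(bio, str(path), "genbank")


def features_equal(
    a: Feature, b: Feature, ignore_qualifiers: Sequence[str] = ()
) -> bool:
    qa = {k: v for k, v in a.qualifiers.items() if k not in ignore_qualifiers}
    qb = {k: v for k, v in b.qualifiers.items() if k not in ignore_qualifiers}
    return (
        a.kind == b.kind
        and a.strand == b.strand
        and a.intervals == b.intervals
        and qa == qb
    )


def records_feature_equal(
    a: GenomeRecord, b: GenomeRecord, ignore_qualifiers: Sequence[str] = ()
) -> bool:
    return (
        a.sequence == b.sequence
        and len(a.features) == len(b.features)
        and all(
            features_equal(fa, fb, ignore_qualifiers)
            for fa, fb in zip(a.features, b.features)
        )
    )


# ---------------------------------------------------------------------------
# GFF3


def read_gff3(
    path,
    genome: GenomeRecord,
    seqid_alias: Optional[dict[str, str]] = None,
) -> list[GeneModel]:
    """Parse the CDS gene models of a GFF3 file describing ``genome``.

    Multi-line CDS groups (shared Parent, or shared ID when no Parent is
    present) are joined into a single spliced model. Groups with parts on
    both strands — trans-splicing — are returned flagged for manual check,
    as are models shorter than two codons or with spliced length not
    divisible by three.
    """
    path = Path(path)
    seqid_alias = seqid_alias or {}
    with open(path) as handle:
        first = handle.readline()
    if not first.startswith("##gff-version 3"):
        raise Gff3ParseError(f"{path}: missing '##gff-version 3' pragma")
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # gffutils raises a mix of exception types
        if "No lines parsed" in str(exc):
            return []  # header-only GFF3: zero gene models
        raise Gff3ParseError(f"{path}: {exc}") from exc

    groups: dict[str, list] = {}
    order: list[str] = []
    for cds in db.features_of_type("CDS", order_by=("seqid", "start")):
        seqid = seqid_alias.get(cds.seqid, cds.seqid)
        if seqid != genome.accession:
            raise ValidationError(
                f"{path}: GFF3 seqid {cds.seqid!r} does not match GenBank "
                f"accession {genome.accession!r}"
            )
        parents = cds.attributes.get("Parent") or cds.attributes.get("ID")
        if not parents:
            raise Gff3ParseError(
                f"{path}: CDS line at {cds.start}..{cds.end} has neither "
                "Parent nor ID attribute"
            )
        key = parents[0]
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(cds)

    models: list[GeneModel] = []
    for key in order:
        parts = groups[key]
        strands = {p.strand for p in parts}
        gene_id = _strip_id_prefix(key)
        product = ""
        for p in parts:
            if "product" in p.attributes:
                product = p.attributes["product"][0]
                break
            if "gene" in p.attributes:
                product = p.attributes["gene"][0]
        if strands - {"+", "-"} or len(strands) != 1:
            model = GeneModel(
                gene_id=gene_id,
                product=product,
                intervals=sorted((p.start - 1, p.end) for p in parts),
                strand="+",
            )
            model.flag(
                f"CDS parts of {gene_id} lie on both strands "
                "(trans-splicing is unsupported)"
            )
            models.append(model)
            continue
        strand = strands.pop()
        intervals = _coding_order([(p.start - 1, p.end) for p in parts], strand)
        model = GeneModel(
            gene_id=gene_id, product=product, intervals=intervals, strand=strand
        )
        if model.spliced_length < 6:
            model.flag(
                f"spliced CDS of {gene_id} is {model.spliced_length} bp "
                "(< 6 bp: no room for a start codon plus one codon)"
            )
        elif model.spliced_length % 3 != 0:
            model.frame_suspect = True
            model.flag(
                f"spliced CDS of {gene_id} is {model.spliced_length} bp, "
                "not divisible by 3; frame suspect, editing inference skipped"
            )
        models.append(model)
    return models


def _strip_id_prefix(identifier: str) -> str:
    for prefix in ("gene-", "cds-", "gene:", "cds:"):
        if identifier.startswith(prefix):
            return identifier[len(prefix):]
    return identifier


def reconcile(
    gff_models: list[GeneModel], genome: GenomeRecord
) -> tuple[list[GeneModel], list[str]]:
    """Link GFF3 gene models to the GenBank record's CDS features.

    GFF3 coordinates are authoritative; matching is by exact interval/strand
    identity first, then by gene name. Unmatched models are kept (a CDS
    feature will be created on output) and GenBank CDS features absent from
    the GFF3 pass through untouched; both cases are reported as warnings.
    """
    warnings_out: list[str] = []
    cds_indices = [i for i, f in enumerate(genome.features) if f.kind == "CDS"]
    matched: set[int] = set()

    def name_of(feat: Feature) -> Optional[str]:
        return feat.first_qualifier("gene") or feat.first_qualifier("locus_tag")

    for model in gff_models:
        hit = None
        for i in cds_indices:
            feat = genome.features[i]
            if i not in matched and feat.strand == model.strand and feat.intervals == model.intervals:
                hit = i
                break
        if hit is None:
            for i in cds_indices:
                if i not in matched and name_of(genome.features[i]) == model.gene_id:
                    hit = i
                    break
        if hit is None:
            warnings_out.append(
                f"GFF3 model {model.gene_id} has no matching CDS feature in the "
                "GenBank record; a new CDS feature will be created on output"
            )
        else:
            matched.add(hit)
        model.source_feature_index = hit

    for i in cds_indices:
        if i not in matched:
            feat = genome.features[i]
            warnings_out.append(
                f"GenBank CDS {name_of(feat) or feat.span()} absent from the "
                "GFF3; passed through untouched"
            )
    return gff_models, warnings_out


# ---------------------------------------------------------------------------
# Five-column feature table (.tbl)

# /translation is recomputed by table2asn from the flat file, so it is the
# one qualifier the .tbl omits.
_TBL_SKIP_QUALIFIERS = frozenset({"translation"})


def write_feature_table(record: GenomeRecord, path) -> None:
    """Write the NCBI five-column feature table for ``record``.

    Layout: ``>Feature <accession>`` header, then per feature a
    ``start<TAB>end<TAB>key`` line (minus-strand features with start > end),
    continuation coordinate lines for compound locations, and
    ``<TAB><TAB><TAB>qualifier<TAB>value`` lines. The ``source`` feature is
    omitted (it belongs to the .fsa/.sqn side of a submission).
    """
    record.validate()
    lines = [f">Feature {record.accession}"]
    for feat in record.features:
        if feat.kind == "source":
            continue
        coords = []
        for start, end in feat.intervals:  # coding order
            lo, hi = start + 1, end  # 1-based inclusive
            coords.append((hi, lo) if feat.strand == "-" else (lo, hi))
        first, *rest = coords
        lines.append(f"{first[0]}\t{first[1]}\t{feat.kind}")
        for a, b in rest:
            lines.append(f"{a}\t{b}")
        for name, values in feat.qualifiers.items():
            if name in _TBL_SKIP_QUALIFIERS:
                continue
            for value in values:
                if value in ("", None):
                    lines.append(f"\t\t\t{name}")
                else:
                    lines.append(f"\t\t\t{name}\t{value}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Protein FASTA


def write_protein_fasta(reports, accession: str, path, width: int = 60) -> None:
    """Write conceptual translations for genes where RNA editing occurred.

    One record per GeneReport with at least one edit (genes needing no
    editing are excluded); headers are ``<accession>_<gene_id>``.
    """
    lines: list[str] = []
    for report in reports:
        if not getattr(report, "edits", None) or report.translation is None:
            continue
        lines.append(f">{accession}_{report.gene_id}")
        seq = report.translation
        for i in range(0, len(seq), width):
            lines.append(seq[i : i + width])
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
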