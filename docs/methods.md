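# Methods

## The problem and the model

Plastid transcripts in ferns, hornworts and (to a lesser extent) seed plants
undergo site-specific C-to-U and U-to-C RNA editing. Because editing is at
the mRNA level, genomic gene models in heavily edited lineages often look
broken: an ACG where the start codon belongs, a sense codon where the stop
belongs, or in-frame stop codons inside the CDS. These *nonsense defects*
are usually not pseudogenization — the mRNA is repaired — but they block
database submission and mislead downstream users unless annotated.

plastedit refines an existing annotation (GenBank flat file with sequence +
GFF3 gene models) under two working assumptions:

1. only C&harr;U interconversion occurs (the overwhelmingly dominant editing
   type in plastids), and
2. every nonsense defect in an otherwise plausible CDS is the result of
   editing, because plastome genes are overwhelmingly essential.

Assumption 2 is deliberately aggressive and is bounded by the manual-check
policy below; plastedit is not a substitute for inspecting gene models, and
frameshifted annotations, mis-annotated pseudogenes or assembly errors will
be misread as editing if they are fed in.

## The per-gene cascade

Each CDS model is processed independently, in coding-strand codon space:

1. **Start codon.** If not in the valid start set (default {ATG}), try a
   single C-to-U rescue: the only codon one such edit away from ATG is ACG
   (position 2). Failing that, scan in-frame codons within ±5 codons of the
   annotated start for a directly valid or edit-rescuable codon and move the
   gene boundary there.
2. **Final codon.** Same cascade with stop logic. One C-to-U edit yields a
   stop from exactly CAA&rarr;TAA, CAG&rarr;TAG, CGA&rarr;TGA (position 1);
   these sets are pinned in the test suite by a brute-force enumeration of
   all 64 codons × all single C&harr;T substitutions, written before the
   fast paths.
3. **Internal stops.** All in-frame stops strictly before the final codon of
   the (possibly re-bounded) CDS. Each is rescued by the unique U-to-C edit
   that yields a sense codon: TAA&rarr;CAA (Q), TAG&rarr;CAG (Q),
   TGA&rarr;CGA (R). If the count exceeds `internal_stop_limit` the gene is
   flagged instead (see below).
4. **Conceptual translation** of the edit-applied mRNA under NCBI table 11,
   terminal stop dropped.

Direction falls out of the codon alphabet: *creating* a U (start/stop
rescue) requires genomic C read as U; *destroying* a genomic stop's U
requires genomic T read as C. A codon is rescuable only by exactly one
substitution — two-edit rescues of a single codon are out of scope, as they
would inflate the false-positive surface — and codons containing N are never
candidates.

### Boundary-scan tie-breaking

The scan returns the candidate with the smallest |offset|. At equal
|offset|, a directly valid codon beats an edit-rescuable one, and the
direction that extends the gene (upstream for starts, downstream for stops)
beats the direction that shrinks it. This ordering is this package's
decision — minimal perturbation of the upstream annotation — since "nearby"
alone does not determine a preference. Offsets that would leave fewer than
two codons of CDS are never taken. The cascade order itself (direct validity
&rarr; edit rescue &rarr; boundary scan) mirrors the order the checks are
naturally stated in; a CAA final codon is therefore rescued in place rather
than triggering a scan.

### Manual-check policy

All failures are reported, never raised: unrescuable terminal codons with an
empty scan window, internal stops beyond the limit, spliced lengths not
divisible by three (frame-suspect), models shorter than two codons,
ambiguous bases at decision points, trans-spliced (mixed-strand) CDS groups,
and features spanning the circular origin. A flagged gene is left completely
untouched — no partial edits, no translation — because a half-rescued gene
would emit a misleading protein. Genes with an explicit `/pseudo` qualifier
are skipped outright. `internal_stop_limit` defaults to 5: genes with more
genuinely edited internal stops exist but are rare, and above that count a
frameshift or pseudogene is the likelier explanation; the limit is a
configuration knob for users who know better.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `internal_stop_limit` | 5 | internal stops above this flag the gene (count, per gene) |
| `boundary_window_codons` | 5 | half-width of the terminal-codon scan (codons) |
| `valid_start_codons` | {ATG} | codons accepted as starts without editing |
| `seqid_alias` | none | GFF3 seqid &rarr; GenBank accession map |

GTG/TTG are *not* default starts even though table 11 permits them:
accepting them silently would suppress exactly the edit annotations the tool
exists to make.

## Inputs, precedence and outputs

GFF3 is authoritative for gene coordinates; the GenBank file is
authoritative for sequence and pre-existing qualifiers (upstream annotators
emit GFF3, and the flat file carries the curated metadata). Models are
linked to CDS features by exact coordinate identity, then by gene name;
unmatched models are processed and gain a new CDS feature on output,
unmatched GenBank CDS pass through untouched, and both are reported.
Internally all coordinates are 0-based half-open, converted only at the
parse/serialize boundary; interval lists are kept in coding order.

Outputs per run: `<accession>_edited.gb` (regenerated flat file — original
byte layout is not preserved — with one single-base `misc_feature` per edit
noting the direction and gene, `exception="RNA editing"` plus `/translation`
on edited CDS, and updated coordinates for boundary-adjusted genes),
`<accession>.tbl` (NCBI five-column feature table; minus-strand features
written end&rarr;start, `/translation` omitted since table2asn recomputes
it), `<accession>_proteins.fasta` (conceptual translations of edited genes
only), and `<accession>_report.tsv` (one row per gene: status, edit count,
boundary shifts, messages). Annotation application is idempotent: re-running
on the tool's own output adds nothing.

## The synthetic-data generator

Real validation requires cDNA-confirmed plastomes, which cannot ship as test
data; the generator builds toy plastomes in their place. Genes are random
ORFs (ATG, rejection-sampled sense codons, stop) of 150–1500 bp in multiples
of 3, separated by 80–300 bp random spacers, 50% minus-strand, 20% split by
a 60–200 bp intron by default. Defects are planted by *reverse-applying* a
legal edit (ACG for an edited start, CAA/CAG/CGA for an edited stop, a
genomic stop for an edited internal codon), so every planted defect is
rescuable by construction and exact recovery of the truth set is a fair
expectation. By default 78% of genes carry defects — the upper end of
editing prevalence reported for fern and hornwort plastomes — with
bad-start and missing-stop probabilities of 0.5 each and a Poisson(1)
number of internal stops (capped at 5) per edited gene. Truth positions are
computed by the generator's own interval arithmetic, independent of the
annotator's coordinate code, so the recall tests cross-check the two.

Dedicated fixtures plant *unrescuable* defects (GTG starts with scan windows
scrubbed of competing candidates, frame breaks, N-containing starts,
over-limit internal stops, pseudo-flagged genes, a two-exon minus-strand
gene with one edit per exon) to exercise every manual-check path, and
boundary fixtures place a rescuable ACG at a chosen codon offset from the
annotated start.

The generator does **not** simulate sequencing error, indels, codon-usage
bias, overlapping genes, or trans-splicing. Passing tests therefore
demonstrate the codon logic, coordinate arithmetic and format handling — not
robustness to mis-assembled or sloppily annotated real plastomes, which the
manual-check policy only partially covers.

## Numerical and degenerate-input choices

Everything is exact integer/string computation; there are no tolerances.
Determinism is by construction: single seeded RNG stream in the generator
(identical seed &rarr; byte-identical files), lowest-position tie-break in
codon rescues, and the documented boundary-scan ordering. Scan windows
truncated by a genome end are used at their reduced width and logged.
Features spanning the circular origin are rejected loudly rather than
handled by modular arithmetic — silently mis-splicing a wrapped gene would
be worse than asking for a linearized input.

## Verification scale

The test suite and `scripts/acceptance.py` run the full pipeline over 100
clean and 100 defect-planted plastomes of 10–50 genes each (several thousand
genes and planted edits per pass), plus the exhaustive 64-codon oracle
comparisons and the edge-case fixtures; a pass takes a few seconds on one
CPU. Expected results: zero edit calls on clean genomes and exact
truth-set recovery on every defective genome.
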