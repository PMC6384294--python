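# plastedit

Automatic annotation of the C-to-U / U-to-C RNA editing that rescues
apparent nonsense defects in plastid genome (plastome) coding sequences.

## Why

In ferns, hornworts and other heavily edited lineages, up to ~78% of
plastome protein-coding genes are RNA-edited. Because editing happens on the
mRNA, the genomic annotation of a perfectly functional gene can show an
invalid start codon (genomic ACG read as AUG), a missing stop (genomic
CAA/CAG/CGA read as a stop), or in-frame internal stop codons (genomic
TAA/TAG/TGA read as CAA/CAG/CGA). Annotators do not account for this, so
submitting such plastomes to GenBank normally means hours of manual codon
checking per genome. plastedit automates exactly that final step for people
assembling and submitting plastomes: it refines an existing annotation, it
does not annotate genes de novo, and it is not a general editing-site
predictor (synonymous or non-nonsense editing sites are out of scope).

## What it does

Given a GenBank flat file (with sequence) and a GFF3 of the same gene
models, for each CDS it checks, in order:

1. **start codon** — valid (default {ATG})? else rescuable by one C&rarr;U
   edit (only ACG &rarr; AUG)? else scan ±5 in-frame codons and move the
   boundary to the nearest valid or rescuable start;
2. **final codon** — a stop? else rescuable by one C&rarr;U edit
   (CAA&rarr;UAA, CAG&rarr;UAG, CGA&rarr;UGA)? else the same ±5-codon scan;
3. **internal stops** — each in-frame stop is read through the unique
   U&rarr;C edit giving a sense codon (UAA&rarr;CAA Q, UAG&rarr;CAG Q,
   UGA&rarr;CGA R). More than 5 internal stops (configurable) flags the gene
   for manual checking instead — that many is more likely a frameshift or
   pseudogene than editing.

Unresolvable genes are reported, never half-edited. The run writes a
regenerated GenBank flat file with one `misc_feature` per editing site and
`exception="RNA editing"` + conceptual `/translation` (NCBI table 11) on
edited CDS, an NCBI five-column feature table (`.tbl`) ready for table2asn,
a protein FASTA of the edited genes' conceptual translations, and a per-gene
TSV report.

## Worked example

The package ships a synthetic-plastome generator (random ORFs with defects
planted by reverse-applying legal edits, plus a machine-readable truth set),
so you can try the tool without any downloads:

```
$ plastedit simulate --n-genes 8 --fraction-edited 0.6 --seed 7 --out demo/fix
wrote demo/fix/SYN000007.gb and demo/fix/SYN000007.gff3; 9 planted edits

$ plastedit annotate --genbank demo/fix/SYN000007.gb \
                     --gff3 demo/fix/SYN000007.gff3 --out demo/out
8 genes processed: 9 edits ({'start_rescue': 4, 'stop_rescue': 2,
'internal_stop_rescue': 3}), 0 flagged for manual check
```

The 9 edit calls are exactly the 9 planted sites. Per-gene outcomes land in
`demo/out/SYN000007_report.tsv`:

```
gene    status  n_edits five_prime_shift  three_prime_shift  messages
g001    edited  2       0                 0
g002    clean   0       0                 0
g003    edited  1       0                 0
...
```

`status` is `clean` (nothing to do), `edited` (editing sites annotated),
`boundary_adjusted` (a terminal codon was found within ±5 codons and the
gene coordinates moved), or `manual_check` (left untouched; see
`messages`). In the edited flat file each site becomes a single-base
feature — here on a minus-strand gene, so the edited C sits on the
complement:

```
     misc_feature    complement(588)
                     /note="RNA editing (C to U) in gene g001"
                     /gene="g001"
```

and `SYN000007_proteins.fasta` holds the conceptual translations of edited
genes (no internal `*`, terminal stop dropped). Re-running `annotate` on
`demo/out/SYN000007_edited.gb` adds nothing: annotation is idempotent.

The same functionality is available as a library — `plastedit.run()`,
`plastedit.process_gene()`, `plastedit.make_plastome()` — see the module
docstrings and `docs/methods.md` for the model, tie-breaking rules and the
generator's scope.

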