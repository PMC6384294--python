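"""Brute-force codon oracles used to pin the rescue logic.

These enumerate every single C<->T substitution of a codon directly, with no
knowledge of the package's fast paths, and Biopython's translator serves as
the independent translation reference.
"""

from Bio.Data import CodonTable
from Bio.Seq import Seq

TABLE11 = CodonTable.unambiguous_dna_by_id[11]
STOPS = frozenset(TABLE11.stop_codons)
ALL_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]


def single_tc_substitutions(codon):
    """All (pos0, new_codon, direction) single C<->T changes of a codon."""
    for i, base in enumerate(codon):
        if base == "C":
            yield i, codon[:i] + "T" + codon[i + 1 :], "C-to-U"
        elif base == "T":
            yield i, codon[:i] + "C" + codon[i + 1 :], "U-to-C"


def start_rescues(codon, starts=("ATG",)):
    """C-to-U substitutions that produce a valid start codon."""
    return [
        (i, new)
        for i, new, d in single_tc_substitutions(codon)
        if d == "C-to-U" and new in starts
    ]


def stop_rescues(codon):
    """C-to-U substitutions that produce a stop codon."""
    return [
        (i, new)
        for i, new, d in single_tc_substitutions(codon)
        if d == "C-to-U" and new in STOPS
    ]


def internal_stop_rescues(codon):
    """U-to-C substitutions of a stop codon that yield a sense codon."""
    return [
        (i, new)
        for i, new, d in single_tc_substitutions(codon)
        if d == "U-to-C" and new not in STOPS
    ]


def translate11(seq):
    """Independent table-11 translation (Biopython)."""
    return str(Seq(seq).translate(table=11))
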