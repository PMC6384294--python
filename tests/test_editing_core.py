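"""Codon-level rescue logic against the brute-force oracles."""

import random
from dataclasses import replace

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from plastedit import (
    GeneModel,
    GeneticCode,
    conceptual_translation,
    find_internal_stops,
    is_valid_start,
    rescue_internal_stop,
    rescue_start,
    rescue_stop,
    scan_for_boundary,
    spliced_index_to_genomic,
)
from plastedit.editing_core import C_TO_U, U_TO_C

SENSE_CODONS = sorted(set(oracles.ALL_CODONS) - oracles.STOPS)


class TestStartValidity:
    def test_atg_is_the_only_default_start(self, code):
        assert is_valid_start("ATG", code)
        assert not is_valid_start("ACG", code)  # needs editing, not valid itself
        assert not is_valid_start("GTG", code)

    def test_start_set_is_configurable(self):
        permissive = GeneticCode.table11(valid_start_codons=("ATG", "GTG"))
        assert is_valid_start("GTG", permissive)
        # with GTG valid, GCG becomes rescuable (C-to-U at position 2)
        edit = rescue_start("GCG", permissive)
        assert edit is not None and edit.codon_after == "GTG"


class TestRescueOracleEquivalence:
    @pytest.mark.parametrize("codon", oracles.ALL_CODONS)
    def test_start_rescue_matches_bruteforce(self, codon, code):
        expected = oracles.start_rescues(codon)
        edit = rescue_start(codon, code)
        if not expected:
            assert edit is None
        else:
            pos0, after = expected[0]
            assert edit is not None
            assert (edit.pos_in_codon - 1, edit.codon_after) == (pos0, after)
            assert edit.direction == C_TO_U and edit.role == "start_rescue"

    @pytest.mark.parametrize("codon", oracles.ALL_CODONS)
    def test_stop_rescue_matches_bruteforce(self, codon):
        expected = oracles.stop_rescues(codon)
        edit = rescue_stop(codon)
        if not expected:
            assert edit is None
        else:
            pos0, after = expected[0]
            assert edit is not None
            assert (edit.pos_in_codon - 1, edit.codon_after) == (pos0, after)
            assert edit.direction == C_TO_U and edit.codon_after in oracles.STOPS

    def test_bruteforce_rescuable_sets(self):
        """The exact rescuable codon sets, derived by enumeration."""
        assert {c for c in oracles.ALL_CODONS if oracles.start_rescues(c)} == {"ACG"}
        assert {c for c in oracles.ALL_CODONS if oracles.stop_rescues(c)} - oracles.STOPS == {
            "CAA",
            "CAG",
            "CGA",
        }

    @pytest.mark.parametrize(
        "stop,after,aa", [("TAA", "CAA", "Q"), ("TAG", "CAG", "Q"), ("TGA", "CGA", "R")]
    )
    def test_internal_stop_rescue_is_unique(self, stop, after, aa, code):
        candidates = oracles.internal_stop_rescues(stop)
        assert len(candidates) == 1  # provably unique for all three stops
        edit = rescue_internal_stop(stop, code)
        assert edit.codon_after == after == candidates[0][1]
        assert edit.amino_acid_after == aa == oracles.translate11(after)
        assert edit.direction == U_TO_C

    def test_internal_stop_rescue_rejects_sense_codons(self, code):
        with pytest.raises(ValueError):
            rescue_internal_stop("AAA", code)

    @pytest.mark.parametrize("codon", oracles.ALL_CODONS)
    def test_every_rescue_edit_is_a_single_tc_substitution(self, codon, code):
        for edit in (rescue_start(codon, code), rescue_stop(codon)):
            if edit is None:
                continue
            diffs = [
                (a, b)
                for a, b in zip(edit.codon_before, edit.codon_after)
                if a != b
            ]
            assert diffs in ([("C", "T")], [("T", "C")])

    def test_ambiguous_codons_are_never_candidates(self, code):
        assert rescue_start("ANG", code) is None
        assert rescue_stop("CNA") is None


class TestInternalStops:
    def test_clean_orf_has_none(self, code):
        assert find_internal_stops("ATGAAATAA", code) == []

    def test_reports_index_and_codon(self, code):
        assert find_internal_stops("ATGTGAAAATAA", code) == [(1, "TGA")]

    def test_multiple_in_ascending_order(self, code):
        rng = random.Random(11)
        codons = ["ATG"] + [rng.choice(SENSE_CODONS) for _ in range(40)] + ["TAA"]
        planted = {4, 17, 30}
        for i in planted:
            codons[i] = rng.choice(sorted(oracles.STOPS))
        found = find_internal_stops("".join(codons), code)
        assert [i for i, _ in found] == sorted(planted)


class TestConceptualTranslation:
    def test_plain_orf(self, code):
        assert conceptual_translation("ATGAAATAA", [], code) == "MK"

    def test_internal_stop_rescue_applied(self, code):
        edit = replace(rescue_internal_stop("TAA", code), codon_index=1)
        assert conceptual_translation("ATGTAAAAATAA", [edit], code) == "MQK"
        assert conceptual_translation("ATGTAAAAATAA", [edit], code) == oracles.translate11(
            "ATGCAAAAATAA"
        ).rstrip("*")

    def test_start_rescue_reads_as_methionine(self, code):
        edit = replace(rescue_start("ACG", code), codon_index=0)
        assert conceptual_translation("ACGAAATAA", [edit], code) == "MK"

    def test_unrescued_internal_stop_is_an_error(self, code):
        with pytest.raises(RuntimeError):
            conceptual_translation("ATGTAAAAATAA", [], code)

    @given(st.lists(st.sampled_from(SENSE_CODONS), min_size=2, max_size=60))
    @settings(max_examples=50, derandomize=True)
    def test_matches_biopython_on_sense_orfs(self, body):
        seq = "ATG" + "".join(body) + "TAA"
        expected = oracles.translate11(seq).rstrip("*")
        assert conceptual_translation(seq, []) == expected
        assert len(conceptual_translation(seq, [])) == len(seq) // 3 - 1


class TestSplicedToGenomic:
    def test_plus_strand_single_interval(self):
        model = GeneModel("g", "", [(100, 400)], "+")
        assert spliced_index_to_genomic(model, 0, 1) == 101

    def test_minus_strand_single_interval(self):
        model = GeneModel("g", "", [(100, 400)], "-")
        assert spliced_index_to_genomic(model, 0, 1) == 400

    def test_plus_strand_two_intervals(self):
        model = GeneModel("g", "", [(100, 103), (200, 206)], "+")
        assert spliced_index_to_genomic(model, 1, 1) == 201

    @pytest.mark.parametrize(
        "intervals,strand",
        [
            ([(10, 22), (40, 49)], "+"),
            ([(40, 49), (10, 22)], "-"),
            ([(5, 35)], "-"),
        ],
    )
    def test_enumerates_every_spliced_position(self, intervals, strand):
        """Exhaustive walk: explicit genomic position list vs the mapper."""
        positions = []
        for start, end in intervals:
            block = list(range(start + 1, end + 1))  # 1-based
            positions.extend(reversed(block) if strand == "-" else block)
        model = GeneModel("g", "", intervals, strand)
        for offset, expected in enumerate(positions):
            codon_index, pos = divmod(offset, 3)
            assert spliced_index_to_genomic(model, codon_index, pos + 1) == expected

    def test_out_of_range_raises(self):
        model = GeneModel("g", "", [(0, 9)], "+")
        with pytest.raises(IndexError):
            spliced_index_to_genomic(model, 3, 1)


def _best_by_bruteforce(seq, end, window, flank, code):
    """Independent re-scan: rank every candidate by the documented key."""
    n = len(seq) // 3
    cds = n - flank
    best = None
    for offset in range(-window, window + 1):
        if offset == 0:
            continue
        if end == "five_prime":
            if offset < -flank or offset > min(window, cds - 2):
                continue
            idx = flank + offset
            extends = offset < 0
            codon = seq[3 * idx : 3 * idx + 3]
            direct = is_valid_start(codon, code)
            rescuable = bool(oracles.start_rescues(codon))
        else:
            if offset > flank or offset < -min(window, cds - 2):
                continue
            idx = cds - 1 + offset
            extends = offset > 0
            codon = seq[3 * idx : 3 * idx + 3]
            direct = codon in oracles.STOPS
            rescuable = bool(oracles.stop_rescues(codon))
        if direct or rescuable:
            key = (abs(offset), 0 if direct else 1, 0 if extends else 1)
            if best is None or key < best[0]:
                best = (key, offset)
    return best


class TestBoundaryScan:
    def test_direct_hit_beats_nothing_closer(self, code):
        # annotated start CTG; ATG one codon upstream
        flank = "CCCCCCCCCCCC" + "ATG"
        cds = "CTG" + "AAA" * 5 + "TAA"
        hit = scan_for_boundary(flank + cds, "five_prime", 5, code)
        assert hit == (-1, "ATG", None)

    def test_rescuable_codon_found_with_minimal_offset(self, code):
        # nothing valid until ACG at +2
        cds = "CTG" + "CCT" + "ACG" + "AAA" * 5 + "TAA"
        flank = "CCC" * 5
        offset, codon, edit = scan_for_boundary(flank + cds, "five_prime", 5, code)
        assert (offset, codon) == (2, "ACG")
        assert edit is not None and edit.codon_after == "ATG"

    def test_empty_window_returns_none(self, code):
        cds = "CTG" + "AAA" * 6 + "GGG"
        flank = "CCC" * 5
        assert scan_for_boundary(flank + cds, "five_prime", 5, code) is None
        assert scan_for_boundary(cds + flank, "three_prime", 5, code) is None

    def test_truncated_flank_is_honoured(self, code):
        cds = "CTG" + "AAA" * 5 + "TAA"
        hit = scan_for_boundary("ATG" + cds, "five_prime", 5, code, flank_codons=1)
        assert hit == (-1, "ATG", None)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=60, derandomize=True)
    def test_choice_matches_exhaustive_rescan(self, seed):
        code = GeneticCode.table11()
        rng = random.Random(seed)
        end = rng.choice(["five_prime", "three_prime"])
        window = 5
        flank = rng.randint(0, window)
        cds_codons = rng.randint(2, 12)
        n = flank + cds_codons
        seq = "".join(rng.choice(oracles.ALL_CODONS) for _ in range(n))
        # layout convention: flank+cds for five_prime, cds+flank for three_prime,
        # shared with the brute-force re-scan below
        result = scan_for_boundary(seq, end, window, code, flank_codons=flank)
        best = _best_by_bruteforce(seq, end, window, flank, code)
        if best is None:
            assert result is None
        else:
            assert result is not None
            assert result[0] == best[1]
            assert abs(result[0]) <= window
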