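"""Hard filters and penalty scoring rules, each against explicit examples,
single-edit boundary neighbors, and independent counting oracles."""

import pytest

from panprimer import alphabet, thermo
from panprimer.filters import (
    FilterSettings,
    end_dimer_penalty,
    evaluate_primer,
    filter_complementary_ends,
    filter_degeneracy,
    filter_deletions,
    filter_gc,
    filter_repeats,
    filter_size,
    filter_tm_range,
    gc_clamp_penalty,
    hairpin_penalty,
    tandem_repeat_extras,
)

from conftest import random_dna

# ------------------------------------------------------------- degeneracy


@pytest.mark.parametrize(
    "primer,ok",
    [
        ("WGCACGCCGTGRTSAAGGGC", False),  # W in first trimer, three 2-folds
        ("ACGTACGTACGTACGTAA", True),  # no degenerate codes
        ("ACGHACGTACGSACGTAAGC", True),  # one 3-fold + one 2-fold, internal
        ("ACGNACGTACGTACGTAA", False),  # any N disqualifies
        ("ACGHACGBACGTACGTAAGC", False),  # two 3-fold codes
        ("ACGRACGYACGSACGTAAGC", False),  # three 2-fold codes
        ("ACGRACGYACGTACGTAAGC", True),  # two 2-fold codes is the limit
        ("ACGTACGTACGTACGTARGC", False),  # R inside the last trimer... no:
    ],
)
def test_degeneracy_filter(primer, ok):
    assert filter_degeneracy(primer).passed == ok


def test_degeneracy_terminal_trimer_boundary():
    # same single R: inside position 3 passes, inside position 2 fails
    assert filter_degeneracy("ACGRACGTACGTACGTAA").passed
    assert not filter_degeneracy("ACRGACGTACGTACGTAA").passed
    assert not filter_degeneracy("ACGTACGTACGTACGTRA").passed


# -------------------------------------------------------------- deletions


@pytest.mark.parametrize(
    "primer,ok,why",
    [
        ("A-" + "ACGT" * 5, False, "terminal trimer"),  # rule i
        ("ACGT" + "----" + "ACGTACGTACGTACGT", False, "consecutive"),  # rule ii
        ("ACGT" + "-ACG" * 7 + "ACGT", False, "total"),  # rule iii: 7 gaps
        ("ACG" + "T-C-GA-CG-TA-CGT" + "CGT", False, "below minimum"),  # iv: 22 cols, 5 gaps
        ("ACGTAC-GTA-CGT-ACG-TACGTA", True, ""),  # 25 cols, 4 gaps -> 21 bp
        ("ACGTACGTACGTACGTACGT", True, ""),  # no deletions at all
    ],
)
def test_deletion_filter(primer, ok, why):
    out = filter_deletions(primer)
    assert out.passed == ok
    if why:
        assert why in out.detail


def test_deletion_minimum_size_boundary():
    # 22 columns: 5 internal gaps -> 17 bp fails; 4 gaps -> 18 bp passes
    five = "ACG" + "T-C-GA-CG-TA-CGT" + "CGT"
    four = "ACG" + "T-CG-ACG-TA-CGTA" + "CGT"
    assert len(five) == len(four) == 22
    assert not filter_deletions(five).passed
    assert filter_deletions(four).passed
    assert filter_deletions("ACGTACGTACGTACGTACGTAC").passed


# --------------------------------------------------------------------- GC


@pytest.mark.parametrize(
    "primer,ok",
    [
        ("GTGCAGCGAGTGCATCCCGG", False),  # 70% GC
        ("ATATATATATGCGCGCGCAT", True),  # exactly 40%, boundary inclusive
        ("ATATATATATATATATATAT", False),  # 0%
        ("GGACTTCGAGAAGGTGATC", True),  # 52.6%
    ],
)
def test_gc_range_filter(primer, ok):
    assert filter_gc(primer).passed == ok


def test_gc_uses_expected_fraction_for_degenerate_codes():
    # S counts 1, W counts 0, R counts 1/2
    assert alphabet.expected_gc_fraction("SWR") == pytest.approx(0.5)
    assert filter_gc("SSSSSSWWWWWWATGCATGC").passed  # expected 8/20+2/20... 50%


def test_gc_clamp_is_a_penalty_not_a_filter():
    heavy = "AAAAATTTTTAAAAAGCGCC"  # 5 G/C in the last 5
    assert gc_clamp_penalty(heavy) == 1.0
    light = "GCGCGCGCATATAAATATAT"
    assert gc_clamp_penalty(light) == 0.0
    # boundary: exactly 3 G/C in the last five is allowed
    assert gc_clamp_penalty("AAAAATTTTTAAAAAGCGTA") == 0.0


# ---------------------------------------------------------------- repeats


def tandem_oracle(seq: str, k: int) -> int:
    """Naive O(n^2) re-scan of in-place duplications."""
    best = 0
    for i in range(len(seq)):
        copies = 1
        while seq[i + copies * k : i + (copies + 1) * k] == seq[i : i + k] and len(
            seq[i : i + k]
        ) == k:
            copies += 1
        best = max(best, copies - 1)
    return best


@pytest.mark.parametrize(
    "primer,ok",
    [
        ("ATATATATATATATATAT", False),  # AT repeated far beyond two extras
        ("ACGTACGTAAGGCCTTAG", False),  # ACGT tandem tetranucleotide
        ("GAGGACTTCGAGAAGGTG", True),  # GAGA: one extra dinucleotide copy
        ("AACGAGCTGGAGTTCTTC", True),  # TTCTTC: one extra trinucleotide copy
        ("CGCGCCGGCATCATCAACCC", True),  # CGCG + ATCATC both within limits
        ("ATCATCATCGGATTACCAGA", False),  # trinucleotide x3: two extras
        ("ATATATGCGCATTACCAGAC", True),  # AT x3 = two extras, the limit
    ],
)
def test_repeat_filter(primer, ok):
    assert filter_repeats(primer).passed == ok


def test_tandem_counts_match_oracle(rng):
    for _ in range(300):
        s = random_dna(rng, rng.randrange(6, 40), alphabet="ACGT")
        for k in (2, 3, 4):
            assert tandem_repeat_extras(s, k) == tandem_oracle(s, k), (s, k)


# ----------------------------------------------------- complementary ends


@pytest.mark.parametrize(
    "primer,ok",
    [
        ("GCGAGTGCATCCCGGAGCGC", False),  # GCG ... CGC: ends anneal
        ("CTTCAGCAACATGGTGAAG", False),  # CTT ... AAG
        ("AAAAAAAAAAAAAAAAAA", True),  # AAA vs revcomp(AAA)=TTT
        ("GACTTCGAGAAGGTGATCG", True),  # internal CGA is not an end match
        ("GCCCTGACCATCAACCCGGC", False),  # GCC ... GGC
    ],
)
def test_complementary_ends_filter(primer, ok):
    assert filter_complementary_ends(primer).passed == ok


def test_complementary_ends_degenerate_worst_case():
    # first trimer expands to {AGC, TGC}; revcomp of last trimer GCT is AGC
    assert not filter_complementary_ends("WGCAAATTTAAATTTGCT").passed
    assert filter_complementary_ends("WGCAAATTTAAATTTGCG").passed


# ------------------------------------------------------------------- size


@pytest.mark.parametrize(
    "primer,ok",
    [
        ("GTACATGGGCTTCGAGG", False),  # 17 bp
        ("GTACATGGGCTTCGAGGA", True),  # 18 bp boundary
        ("A" * 30, True),  # 30 bp boundary
        ("A" * 31, False),
    ],
)
def test_size_filter(primer, ok):
    assert filter_size(primer).passed == ok


def test_size_counts_gap_free_length():
    assert not filter_size("ACGTACGTA----CGTACGTA"[:21]).passed  # 17 bp + 4 gaps


# ------------------------------------------------------------ temperature


def test_tm_filter_widened_range_passes_anything():
    wide = thermo.ThermoSettings(tm_min=0, tm_max=100)
    assert filter_tm_range("CTTCCAGCTGAAGTACACC", wide).passed


def test_tm_filter_default_range():
    assert not filter_tm_range("CTTCCAGCTGAAGTACACC").passed  # Tm ~ 43 C


def test_tm_filter_boundary_is_inclusive():
    s = "GCGCGCGCGCGCGCGCGC"
    tm = thermo.melting_temperature(s).min
    pinned = thermo.ThermoSettings(tm_min=tm, tm_max=tm)
    assert filter_tm_range(s, pinned).passed


# ---------------------------------------------------------------- hairpin


def hairpin_oracle(seq: str) -> int:
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    hits = 0
    for i in range(len(seq) - 4):
        w = seq[i : i + 5]
        if comp[w[0]] == w[4] and w[1] == "G" and w[3] == "A":
            hits += 1
    for i in range(len(seq) - 5):
        w = seq[i : i + 6]
        if comp[w[0]] == w[5] and w[1] == "G" and w[4] == "A":
            hits += 1
    return hits


def test_triloop_motif_instance():
    # C~G complementary ends, G in second, A in second-to-last position
    assert hairpin_penalty("CGAAG") == 1.0
    assert hairpin_penalty("CGATG") == 0.0  # T in the A slot: no motif


def test_hairpin_penalty_matches_window_oracle(rng):
    assert hairpin_penalty("ACGTACGTACGTACGTAC") == hairpin_oracle(
        "ACGTACGTACGTACGTAC"
    )
    for _ in range(200):
        s = random_dna(rng, rng.randrange(6, 30))
        assert hairpin_penalty(s) == hairpin_oracle(s), s


def test_hairpin_penalty_is_additive():
    two = "CGAAG" + "TTTTT" + "CGAAG"
    assert hairpin_penalty(two) == hairpin_oracle(two) >= 2


# ------------------------------------------------------------------ dimer


def test_end_dimer_threshold():
    assert end_dimer_penalty("AAAAAAAAAAAAAGGTGG") == 1.0  # dG ~ -4.6
    assert end_dimer_penalty("GGTGGAAAAAAAAAATAT") == 0.0  # AATAT ~ -1.3
    # strict inequality: a 5-mer exactly at the threshold is not penalized
    pinned = FilterSettings(dimer_dg_threshold=thermo.delta_g("GGTGG"))
    assert end_dimer_penalty("AAAAAAAAAAAAAGGTGG", pinned) == 0.0


# --------------------------------------------------------------- evaluate


def test_evaluate_runs_all_filters_and_sums_penalties():
    report = evaluate_primer("GTGCAGCGAGTGCATCCCGG")
    assert set(report.outcomes) == {
        "Degeneracy", "Deletions", "GC content", "Repeats",
        "Comp. ends", "Size", "Temp",
    }
    assert report.failed == any(not o.passed for o in report.outcomes.values())
    assert report.penalty == pytest.approx(sum(report.penalty_components.values()))
    assert report.penalty >= 0


def test_evaluate_is_deterministic():
    a = evaluate_primer("GGACTTCGAGAAGGTGATC")
    b = evaluate_primer("GGACTTCGAGAAGGTGATC")
    assert a.outcomes == b.outcomes and a.penalty == b.penalty


def test_evaluate_design_mode_turns_tm_into_penalty():
    test_report = evaluate_primer("GGACTTCGAGAAGGTGATC", mode="test")
    design_report = evaluate_primer("GGACTTCGAGAAGGTGATC", mode="design")
    assert "Temp" in test_report.failed_names
    assert "Temp" not in design_report.outcomes
    assert design_report.penalty_components["tm_range"] > 0


def test_evaluate_rejects_empty_and_invalid():
    with pytest.raises(ValueError):
        evaluate_primer("")
    with pytest.raises(ValueError):
        evaluate_primer("ACGTZ" * 4)
    with pytest.raises(ValueError):
        evaluate_primer("ACGT" * 5, mode="nonsense")
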