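"""Oligonucleotide average masses, slippage mass ladders and peak assignment."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from slipscan import (
    Cds,
    ConfigError,
    InputError,
    Oligo,
    assign_peaks,
    build_ladder,
    find_runs,
    oligo_average_mass,
    reverse_complement,
)

# independent monomer oracle: residue = nucleoside monophosphate - water
DNA_RESIDUE = {"A": 313.2065, "C": 289.1818, "G": 329.2059, "T": 304.1932}
RNA_RESIDUE = {"A": 329.2059, "C": 305.1812, "G": 345.2053, "U": 306.1692}
WATER = 18.0153
HPO3 = 79.9799

dna = st.text(alphabet="ACGT", min_size=1, max_size=40)


def oracle_mass(seq, residue_table, phosphate=False):
    return sum(residue_table[b] for b in seq) + WATER + (HPO3 if phosphate else 0.0)


def test_single_dA_mass():
    # 313.21 (dA residue) + 18.02 (terminal water)
    assert oligo_average_mass(Oligo("A")) == pytest.approx(331.23, abs=0.02)


def test_empty_oligo_forbidden():
    with pytest.raises(InputError):
        Oligo("")


@given(dna)
def test_dna_mass_matches_monomer_oracle(seq):
    assert oligo_average_mass(Oligo(seq)) == pytest.approx(
        oracle_mass(seq, DNA_RESIDUE), abs=0.01 * len(seq)
    )


@given(st.text(alphabet="ACGU", min_size=1, max_size=40))
def test_rna_mass_matches_monomer_oracle(seq):
    assert oligo_average_mass(Oligo(seq, kind="ssRNA")) == pytest.approx(
        oracle_mass(seq, RNA_RESIDUE), abs=0.01 * len(seq)
    )


def test_phosphate_end_adds_hpo3():
    oh = oligo_average_mass(Oligo("ACGT"))
    p = oligo_average_mass(Oligo("ACGT", five_prime_end="phosphate"))
    assert p - oh == pytest.approx(HPO3, abs=1e-6)


@given(dna, dna)
def test_mass_additive_over_concatenation(x, y):
    mx, my = oligo_average_mass(Oligo(x)), oligo_average_mass(Oligo(y))
    assert oligo_average_mass(Oligo(x + y)) == pytest.approx(mx + my - WATER, abs=1e-6)


@pytest.fixture(scope="module")
def rna_ladder(synthetic_rna):
    run = find_runs(synthetic_rna, "A", 8)[0]
    return synthetic_rna, run, build_ladder(synthetic_rna, run, a_counts=range(10, 16))


def test_ladder_has_both_strands_and_six_rungs(rna_ladder):
    _, _, ladder = rna_ladder
    assert sorted({s for s, _ in ladder.entries}) == ["antisense", "sense"]
    assert sorted({a for _, a in ladder.entries}) == list(range(10, 16))
    assert len(ladder.entries) == 12


def test_ladder_spacing_is_one_residue_mass(rna_ladder):
    _, _, ladder = rna_ladder
    for a in range(10, 15):
        sense = ladder.entries[("sense", a + 1)] - ladder.entries[("sense", a)]
        anti = ladder.entries[("antisense", a + 1)] - ladder.entries[("antisense", a)]
        assert sense == pytest.approx(DNA_RESIDUE["A"], abs=0.01)
        assert anti == pytest.approx(DNA_RESIDUE["T"], abs=0.01)


def test_identity_ladder_is_unedited_amplicon(rna_ladder):
    template, run, _ = rna_ladder
    ladder = build_ladder(template, run, a_counts=[11])
    amplicon = template.dna  # PCR product of the full 56-nt window
    assert ladder.entries[("sense", 11)] == pytest.approx(
        oligo_average_mass(Oligo(amplicon)), abs=1e-9
    )
    assert ladder.entries[("antisense", 11)] == pytest.approx(
        oligo_average_mass(Oligo(reverse_complement(amplicon))), abs=1e-9
    )


def test_ladder_matches_directly_constructed_strings(rna_ladder):
    template, run, ladder = rna_ladder
    s = template.dna
    for a in range(10, 16):
        sense = s[: run.start - 1] + "A" * a + s[run.end :]
        assert ladder.entries[("sense", a)] == pytest.approx(
            oracle_mass(sense, DNA_RESIDUE), abs=0.01 * len(sense)
        )


def test_strands_differ_unless_self_complementary(rna_ladder):
    _, _, ladder = rna_ladder
    for a in range(10, 16):
        assert ladder.entries[("sense", a)] != ladder.entries[("antisense", a)]


def test_amplicon_must_bracket_run(rna_ladder):
    template, run, _ = rna_ladder
    with pytest.raises(InputError):
        build_ladder(template, run, amplicon_start=run.start + 1)


def test_exact_peak_has_zero_error(rna_ladder):
    _, _, ladder = rna_ladder
    pred = ladder.entries[("sense", 12)]
    (a,) = assign_peaks([pred], ladder)
    assert (a.assigned_strand, a.assigned_a_count) == ("sense", 12)
    assert a.pct_error == 0.0
    assert a.within_tolerance


def test_empty_measured_list_and_empty_ladder(rna_ladder):
    _, _, ladder = rna_ladder
    assert assign_peaks([], ladder) == []
    from slipscan.mass_spec import MassLadder

    with pytest.raises(ConfigError):
        assign_peaks([1000.0], MassLadder("x", ladder.run, (), {}))


def test_noisy_peaks_recovered_at_true_a_count(rna_ladder):
    _, _, ladder = rna_ladder
    rng = np.random.default_rng(42)
    truth = [(s, a) for (s, a) in ladder.entries]
    measured = [
        ladder.entries[key] * (1.0 + rng.uniform(-5e-5, 5e-5)) for key in truth
    ]
    assigned = assign_peaks(measured, ladder, tolerance_pct=0.02)
    got = {round(a.measured_mass, 6): (a.assigned_strand, a.assigned_a_count) for a in assigned}
    for key, m in zip(truth, measured):
        assert got[round(m, 6)] == key
    assert all(a.within_tolerance for a in assigned)


def test_assignment_permutation_invariant(rna_ladder):
    _, _, ladder = rna_ladder
    measured = [17527.2, 16600.0, 17215.0]
    a1 = assign_peaks(measured, ladder)
    a2 = assign_peaks(list(reversed(measured)), ladder)
    assert a1 == a2
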