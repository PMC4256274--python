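"""Homopolymer runs, premature stops, slippery-site calls and the family screen."""

import re
import warnings

import pytest
from hypothesis import given
from hypothesis import strategies as st

from slipscan import (
    Cds,
    ConfigError,
    ScanConfig,
    call_slippery_sites,
    find_premature_stop,
    find_runs,
    reverse_complement,
    screen_family,
)
from slipscan.seq_core import translate

from conftest import small_design
from slipscan import design_gene, designed_run

nt = st.text(alphabet="ACGT", min_size=1, max_size=80)


def naive_runs(seq, base, min_length):
    """Position-by-position counter oracle for maximal homopolymer runs."""
    return [
        (m.start() + 1, len(m.group()))
        for m in re.finditer(f"{base}+", seq)
        if len(m.group()) >= min_length
    ]


def test_printed_synthetic_rna_has_one_11A_run(synthetic_rna):
    runs = find_runs(synthetic_rna, base="A", min_length=8)
    assert len(runs) == 1
    assert runs[0].length == 11


def test_no_runs_in_alternating_sequence():
    assert find_runs(Cds("x", "ACGTACGTACGT"), base="A", min_length=2) == []


@given(nt, st.sampled_from("AT"), st.integers(1, 6))
def test_find_runs_matches_naive_counter(seq, base, min_length):
    got = [(r.start, r.length) for r in find_runs(Cds("x", seq), base, min_length)]
    assert got == naive_runs(seq, base, min_length)


@given(nt)
def test_t_runs_map_to_a_runs_on_reverse_complement(seq):
    n = len(seq)
    t_runs = find_runs(Cds("x", seq), "T", 2)
    rc_a_runs = find_runs(Cds("x", reverse_complement(seq)), "A", 2)
    mapped = sorted((n - r.end + 1, r.length) for r in rc_a_runs)
    assert sorted((r.start, r.length) for r in t_runs) == mapped


@pytest.mark.parametrize(
    "seq,expected",
    [
        ("ATGAAATAGAAATAA", 7),  # internal amber stop
        ("ATGAAATAA", None),  # terminal stop only
        ("ATGAAATAATAA", 7),  # first stop precedes the terminal one
    ],
)
def test_find_premature_stop(seq, expected):
    assert find_premature_stop(Cds("x", seq)) == expected


def test_find_premature_stop_warns_when_no_stop():
    with pytest.warns(UserWarning, match="no in-frame stop"):
        assert find_premature_stop(Cds("x", "ATGAAAAAC")) is None


def test_designed_gene_stop_placement():
    d = small_design(seed=3, upstream_codons=794)
    gene = design_gene(d)
    assert find_premature_stop(gene) == 2422


def test_site_called_with_plus1_restoring(fixture_gene):
    sites = call_slippery_sites(fixture_gene)
    assert len(sites) == 1
    site = sites[0]
    assert site.run.length == 11
    assert site.distance == 28
    assert 1 in site.restoring_edits


def test_run_outside_window_is_not_a_site():
    # run ends ~500 nt upstream of the in-frame stop: outside the 60-nt window
    filler = "CAC" * 170
    gene = Cds("far", "ATG" + "A" * 11 + "G" + filler + "TAGCCCTAA")
    assert find_runs(gene, "A", 8)
    assert call_slippery_sites(gene) == []


def oracle_restoring(gene, run, k, stop_start):
    """Exhaustive edit-and-translate oracle: strings edited directly,
    translation delegated to Biopython (independent of the package's)."""
    from Bio.Seq import Seq

    s = gene.seq
    edited = s[: run.end] + "A" * k + s[run.end :] if k >= 0 else s[: run.end + k] + s[run.end :]
    trimmed = edited[: len(edited) // 3 * 3]
    prot_len = len(Seq(trimmed).translate(table=11, to_stop=True))
    return 3 * prot_len + 1 > stop_start + k


@pytest.mark.parametrize("seed", range(12))
def test_restoring_edits_match_exhaustive_oracle(seed):
    d = small_design(seed=seed, plus1_orf_codons=seed % 4 * 6)
    gene = design_gene(d)
    sites = call_slippery_sites(gene)
    assert len(sites) == 1
    site = sites[0]
    expected = {
        k
        for k in (-2, -1, 1, 2)
        if oracle_restoring(gene, site.run, k, site.premature_stop_start)
    }
    assert set(site.restoring_edits) == expected


def test_config_honored_exactly(fixture_gene):
    config = ScanConfig(min_run_length=12)  # stricter than the 11-A run
    assert call_slippery_sites(fixture_gene, config) == []
    config = ScanConfig(max_distance_to_stop=10)  # tighter than the 28-nt spacing
    assert call_slippery_sites(fixture_gene, config) == []


def test_screen_family_flags_short_member():
    members = [
        Cds("m1", "CAC" * 1129 + "TAA"),
        Cds("m2", "CAT" * 1129 + "TAA"),
        Cds("m3", "CAG" * 1129 + "TAA"),
        Cds("m4", "CAC" * 807 + "TAA"),  # 2424 nt vs median 3390: 0.715 < 0.8
    ]
    report = screen_family(members)
    flagged = report.set_index("seq_id").abnormal_length
    assert flagged.to_dict() == {"m1": False, "m2": False, "m3": False, "m4": True}


def test_screen_family_uniform_lengths_and_runs():
    tssm3_like = design_gene(small_design(seed=5, run_length=9, spacer_nt=27))
    members = [
        Cds("u1", "CAC" * 40 + "TAA"),
        Cds("u2", "CAT" * 40 + "TAA"),
        tssm3_like,
    ]
    report = screen_family(members).set_index("seq_id")
    assert not report.loc[["u1", "u2"]].abnormal_length.any()
    assert report.loc[tssm3_like.id, "n_runs"] == 1  # 9-A run found at min length 8


def test_screen_family_needs_three_members():
    with pytest.raises(ConfigError):
        screen_family([Cds("a", "ATGTAA"), Cds("b", "ATGTAA")])
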