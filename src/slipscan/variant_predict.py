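"""Prediction of protein length variants produced by slippage edits.

A slippage event at a homopolymeric run adds (or removes) a net number k of
untemplated As in the transcript. Translating each edited transcript from the
start codon yields a catalog of protein variants: for the tssM1-like geometry
the k=0 transcript gives the truncated product, a +1 edit restores the
downstream frame and yields the full-length protein, and a +2 edit gives a
slightly shorter truncation.

Edits are canonically placed at the run's 3' end; insertions within a
homopolymer are indistinguishable at the sequence level, so this fixes
reproducible coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .errors import InputError
from .seq_core import Cds, ProteinSeq, translate
from .slippage_scan import HomopolymerRun, find_premature_stop, is_restoring_edit

# Expasy average residue masses (Da); a chain of L residues weighs
# sum(residues) + one water.
AVERAGE_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0513, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.01524

FLAG_TAG = "DYKDDDDK"
HIS6_TAG = "HHHHHH"


@dataclass(frozen=True)
class TranscriptEdit:
    """A net-k A edit applied at a run's 3' end.

    ``edit_position`` is the 1-based parent coordinate of the last run base;
    all bases outside the run are unchanged and the edited length is the
    parent length plus k.
    """

    parent_id: str
    k: int
    edit_position: int
    edited_seq: str


@dataclass(frozen=True)
class ProteinVariant:
    """One entry of the slippage variant catalog (produced by edit k)."""

    name: str
    produced_by_k: int
    length_aa: int
    mw_kda: float
    full_length_restored: bool


def apply_slippage_edit(cds: Cds, run: HomopolymerRun, k: int) -> TranscriptEdit:
    """Insert (k > 0) or delete (k < 0) ``|k|`` copies of the run base at the
    run's 3' end; k = 0 is the identity."""
    if run.seq_id != cds.id:
        raise InputError(f"run belongs to {run.seq_id!r}, not {cds.id!r}")
    if run.end > len(cds):
        raise InputError(f"{cds.id}: run extends beyond sequence end")
    base = run.base if cds.alphabet == "DNA" or run.base == "A" else "U"
    run_slice = cds.dna[run.start - 1 : run.end]
    if set(run_slice) != {run.base}:
        raise InputError(f"{cds.id}: bases {run.start}..{run.end} are not all {run.base}")
    if k < -(run.length - 1):
        raise InputError(
            f"deletion of {-k} bases exceeds run length {run.length} (at most {run.length - 1})"
        )
    s = cds.seq
    if k >= 0:
        edited = s[: run.end] + base * k + s[run.end :]
    else:
        edited = s[: run.end + k] + s[run.end :]
    return TranscriptEdit(parent_id=cds.id, k=k, edit_position=run.end, edited_seq=edited)


def protein_mw(p: ProteinSeq | str) -> float:
    """Average molecular mass of a protein in kDa (Expasy residue table).

    Sum of average residue masses plus one water; an empty protein reports
    0 with a warning.
    """
    residues = p.residues if isinstance(p, ProteinSeq) else p
    if not residues:
        warnings.warn("empty protein: mass reported as 0", stacklevel=2)
        return 0.0
    try:
        da = sum(AVERAGE_RESIDUE_MASS[r] for r in residues) + WATER_MASS
    except KeyError as exc:
        raise InputError(f"unknown amino-acid symbol {exc.args[0]!r}") from exc
    return da / 1000.0


def predict_variants(
    cds: Cds,
    run: HomopolymerRun,
    k_set=(-2, -1, 1, 2),
    with_tags: bool = False,
) -> list[ProteinVariant]:
    """Catalog of protein variants for each edit k (0 is always included).

    Each edited transcript is translated from nt 1 until its first stop.
    ``full_length_restored`` marks the edits whose translation proceeds past
    the parent's premature stop — the same membership test used by the
    scanner's ``restoring_edits``. ``with_tags`` adds the masses of an
    N-terminal FLAG and C-terminal 6xHis epitope (not added by default).
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stop = find_premature_stop(cds)
    variants = []
    for k in sorted(set(k_set) | {0}):
        edit = apply_slippage_edit(cds, run, k)
        edited = Cds(id=f"{cds.id}|k={k:+d}", seq=edit.edited_seq, alphabet=cds.alphabet,
                     source="edited")
        prot = translate(edited)
        residues = prot.residues
        if with_tags and residues:
            residues = residues[:1] + FLAG_TAG + residues[1:] + HIS6_TAG
        restored = False if stop is None else is_restoring_edit(cds, run, k, stop)
        variants.append(
            ProteinVariant(
                name=f"{cds.id}|k={k:+d}",
                produced_by_k=k,
                length_aa=len(prot),
                mw_kda=round(protein_mw(residues) if residues else 0.0, 3),
                full_length_restored=restored,
            )
        )
    return variants
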