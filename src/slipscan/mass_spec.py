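"""Average-mass prediction for oligonucleotides and slippage mass ladders.

ESI/MS of RT-PCR products spanning a slippery run resolves amplicon species
that differ by single untemplated A residues. Within one strand, consecutive
ladder entries differ by exactly one nucleotide-residue average mass
(~313.21 Da for dA on the sense strand, ~304.19 Da for dT on the antisense
strand), so measured neutral masses can be assigned to A-counts directly.

Masses are neutral average masses: per-residue nucleoside-monophosphate
masses minus one water per phosphodiester bond (equivalently, residue masses
plus one terminal water). A 5'-phosphate adds one HPO3 (79.9799 Da).
Charge-state deconvolution is assumed to have been done upstream by the
instrument software. Raw spectrum processing and isotope modeling are out of
scope.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.SeqUtils import molecular_weight

from .errors import ConfigError, InputError
from .seq_core import Cds, DNA_BASES, RNA_BASES, reverse_complement
from .slippage_scan import HomopolymerRun

HPO3_MASS = 79.9799


@dataclass(frozen=True)
class Oligo:
    """A single-stranded oligonucleotide with defined 5' end chemistry."""

    seq: str
    kind: str = "ssDNA"  # ssDNA | ssRNA
    five_prime_end: str = "hydroxyl"  # hydroxyl | phosphate

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", self.seq.upper())
        if not self.seq:
            raise InputError("empty oligonucleotide")
        if self.kind not in ("ssDNA", "ssRNA"):
            raise InputError(f"kind must be ssDNA or ssRNA, got {self.kind!r}")
        if self.five_prime_end not in ("hydroxyl", "phosphate"):
            raise InputError(f"five_prime_end must be hydroxyl or phosphate")
        allowed = DNA_BASES if self.kind == "ssDNA" else RNA_BASES
        bad = set(self.seq) - allowed
        if bad:
            raise InputError(f"invalid {self.kind} characters {sorted(bad)}")


@dataclass(frozen=True)
class MassLadder:
    """Predicted masses of both strands of an amplicon across a range of
    run A-counts: ``entries[(strand, a_count)] -> Da``."""

    template_id: str
    run: HomopolymerRun
    a_counts: tuple
    entries: dict


@dataclass(frozen=True)
class PeakAssignment:
    """A measured neutral mass assigned to its nearest predicted ladder entry."""

    measured_mass: float
    assigned_strand: str
    assigned_a_count: int
    predicted_mass: float
    pct_error: float
    within_tolerance: bool


def oligo_average_mass(o: Oligo) -> float:
    """Neutral average mass of a single-stranded oligo in Da."""
    seq_type = "DNA" if o.kind == "ssDNA" else "RNA"
    mass = molecular_weight(o.seq, seq_type=seq_type, double_stranded=False, circular=False)
    if o.five_prime_end == "phosphate":
        mass += HPO3_MASS
    return mass


def build_ladder(
    template: Cds,
    run: HomopolymerRun,
    amplicon_start: int | None = None,
    amplicon_end: int | None = None,
    a_counts=range(10, 16),
    five_prime_end: str = "hydroxyl",
) -> MassLadder:
    """Predict both strand masses of the amplicon with the run resized to each
    A-count.

    ``amplicon_start``/``amplicon_end`` are 1-based inclusive template
    coordinates and must bracket the run; they default to the full template.
    PCR products are modeled as two independent DNA single strands with
    unphosphorylated (5'-hydroxyl) ends, configurable.
    """
    start = 1 if amplicon_start is None else amplicon_start
    end = len(template) if amplicon_end is None else amplicon_end
    if not (1 <= start <= run.start and run.end <= end <= len(template)):
        raise InputError(
            f"amplicon {start}..{end} must bracket the run {run.start}..{run.end} "
            f"within the {len(template)}-nt template"
        )
    s = template.dna  # PCR products are DNA regardless of template alphabet
    left = s[start - 1 : run.start - 1]
    right = s[run.end : end]
    a_counts = tuple(a_counts)
    if not a_counts:
        raise ConfigError("empty a_counts range")
    entries = {}
    for a in a_counts:
        if a < 0:
            raise InputError(f"a_count must be >= 0, got {a}")
        sense = left + run.base * a + right
        antisense = reverse_complement(sense)
        entries[("sense", a)] = oligo_average_mass(
            Oligo(sense, kind="ssDNA", five_prime_end=five_prime_end)
        )
        entries[("antisense", a)] = oligo_average_mass(
            Oligo(antisense, kind="ssDNA", five_prime_end=five_prime_end)
        )
    return MassLadder(template_id=template.id, run=run, a_counts=a_counts, entries=entries)


def assign_peaks(measured, ladder: MassLadder, tolerance_pct: float = 0.02) -> list[PeakAssignment]:
    """Assign each measured neutral mass to the nearest predicted ladder entry.

    Peaks whose percentage error exceeds ``tolerance_pct`` are flagged
    (``within_tolerance=False``) rather than dropped. Output is ordered by
    measured mass; the assignment of each peak is independent of the others.
    """
    if tolerance_pct <= 0:
        raise InputError("tolerance_pct must be > 0")
    if not ladder.entries:
        raise ConfigError("empty mass ladder")
    out = []
    for m in sorted(measured):
        (strand, a), pred = min(
            ladder.entries.items(), key=lambda item: (abs(m - item[1]), item[0])
        )
        pct = 100.0 * (m - pred) / pred
        out.append(
            PeakAssignment(
                measured_mass=m,
                assigned_strand=strand,
                assigned_a_count=a,
                predicted_mass=pred,
                pct_error=pct,
                within_tolerance=abs(pct) <= tolerance_pct,
            )
        )
    return out
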