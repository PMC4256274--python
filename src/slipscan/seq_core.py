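"""Sequence primitives: coding sequences, bacterial-code translation, FASTA/TSV I/O.

Coordinates are 1-based and inclusive on the coding strand throughout the
package, matching the convention used for bacterial gene annotation ("position
2,421 from the start codon" denotes the 2,421st nucleotide of the CDS). A stop
codon "at position p" is read so that a protein of L residues has 3L coding
nucleotides before its stop, i.e. p = 3L names the last nucleotide of the final
sense codon and the stop occupies p+1 .. p+3.

U and T are interchangeable for codon lookup and run scanning; the declared
alphabet is preserved for output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable as _bio_codon_table
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError, InputError

DNA_BASES = frozenset("ACGT")
RNA_BASES = frozenset("ACGU")


@dataclass(frozen=True)
class Cds:
    """A coding sequence with identity and provenance.

    ``seq`` is stored uppercase and validated against the declared alphabet
    ("DNA" or "RNA"). ``source`` is free-text provenance, e.g. an accession
    or "synthetic".
    """

    id: str
    seq: str
    alphabet: str = "DNA"
    source: str = "unknown"

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", self.seq.upper())
        if not self.seq:
            raise InputError(f"{self.id}: empty sequence")
        if self.alphabet not in ("DNA", "RNA"):
            raise InputError(f"{self.id}: alphabet must be DNA or RNA, got {self.alphabet!r}")
        allowed = DNA_BASES if self.alphabet == "DNA" else RNA_BASES
        bad = set(self.seq) - allowed
        if bad:
            raise InputError(
                f"{self.id}: invalid {self.alphabet} characters {sorted(bad)} "
                "(ambiguity codes are not supported)"
            )

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def dna(self) -> str:
        """The sequence with U mapped to T, for codon lookup and run scanning."""
        return self.seq.replace("U", "T")


@dataclass(frozen=True)
class CodonTable:
    """The bacterial genetic code (NCBI translation table 11).

    ``code`` maps each of the 61 sense codons to a one-letter amino acid;
    ``stops`` holds the three stop codons. Together they cover all 64 codons.
    """

    code: dict
    stops: frozenset
    table_id: int = 11

    @classmethod
    def bacterial(cls) -> "CodonTable":
        t = _bio_codon_table.unambiguous_dna_by_id[11]
        return cls(code=dict(t.forward_table), stops=frozenset(t.stop_codons))


BACTERIAL_TABLE = CodonTable.bacterial()
STOP_CODONS = BACTERIAL_TABLE.stops  # {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class ProteinSeq:
    """A translated protein; ``terminated`` is True iff a stop codon was reached."""

    residues: str
    terminated: bool

    def __post_init__(self) -> None:
        if "*" in self.residues:
            raise InputError("stop symbol inside protein residues")

    def __len__(self) -> int:
        return len(self.residues)


def translate(cds: Cds, frame: int = 0, start_at: int = 1) -> ProteinSeq:
    """Translate consecutive codons until the first stop codon or sequence end.

    ``frame`` (0/1/2) offsets the reading frame relative to ``start_at``
    (1-based). A trailing partial codon is ignored; ``terminated`` records
    whether a stop codon was actually reached.
    """
    if frame not in (0, 1, 2):
        raise InputError(f"frame must be 0, 1 or 2, got {frame}")
    if start_at < 1:
        raise InputError(f"start_at must be >= 1, got {start_at}")
    s = cds.dna
    i = start_at - 1 + frame
    if i >= len(s):
        raise InputError(
            f"{cds.id}: translation start {start_at}+{frame} beyond sequence end ({len(s)} nt)"
        )
    residues = []
    terminated = False
    table = BACTERIAL_TABLE
    while i + 3 <= len(s):
        codon = s[i : i + 3]
        if codon in table.stops:
            terminated = True
            break
        residues.append(table.code[codon])
        i += 3
    return ProteinSeq(residues="".join(residues), terminated=terminated)


_DNA_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_RNA_COMPLEMENT = str.maketrans("ACGU", "UGCA")


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement; RNA input yields RNA output."""
    s = seq.upper()
    if not s:
        raise InputError("empty sequence")
    chars = set(s)
    if chars <= DNA_BASES:
        return s.translate(_DNA_COMPLEMENT)[::-1]
    if chars <= RNA_BASES:
        return s.translate(_RNA_COMPLEMENT)[::-1]
    raise InputError(f"invalid nucleotide characters {sorted(chars - (DNA_BASES | RNA_BASES))}")


def _infer_alphabet(seq: str) -> str:
    return "RNA" if "U" in seq.upper() else "DNA"


def read_fasta(path) -> list[Cds]:
    """Read a FASTA file into a list of :class:`Cds`, order preserved.

    The record alphabet is inferred per record (presence of U selects RNA).
    An empty file or a file without a single ``>`` header is a format error.
    """
    path = Path(path)
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if not records:
        raise FormatError(f"{path}: no FASTA records found (missing '>' header or empty file)")
    out = []
    for rec in records:
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
        out.append(Cds(id=rec.id, seq=seq, alphabet=_infer_alphabet(seq), source=str(path)))
    return out


def write_fasta(records: Iterable[Cds], path) -> None:
    seq_records = [SeqRecord(Seq(c.seq), id=c.id, description="") for c in records]
    SeqIO.write(seq_records, str(path), "fasta")


def read_genbank_cds(path) -> list[Cds]:
    """Extract CDS features from a GenBank record as coding-strand sequences.

    Convenience only; FASTA is the contract format.
    """
    path = Path(path)
    out = []
    for rec in SeqIO.parse(str(path), "genbank"):
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            seq = str(feat.extract(rec.seq)).upper()
            name = feat.qualifiers.get("locus_tag", feat.qualifiers.get("gene", [rec.id]))[0]
            out.append(Cds(id=name, seq=seq, alphabet="DNA", source=str(path)))
    if not out:
        raise FormatError(f"{path}: no CDS features found")
    return out


def write_tsv_report(records, path, comments: Sequence[str] = ()) -> None:
    """Write records (a DataFrame or an iterable of mappings) as a TSV report.

    ``comments`` become '#'-prefixed provenance lines above the header row.
    """
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(list(records))
    with open(path, "w") as fh:
        for line in comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    """Read a TSV written by :func:`write_tsv_report` (comment lines skipped)."""
    try:
        return pd.read_csv(path, sep="\t", comment="#")
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty table") from exc
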