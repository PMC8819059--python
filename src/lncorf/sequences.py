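"""Transcript I/O and translation primitives.

Transcripts are plain nucleotide strings over ``{A, C, G, T, N}``. Reading
normalizes RNA alphabets (``U`` -> ``T``) and case-folds to upper, because
lncRNA sources mix DNA and RNA conventions. Species is run-level metadata,
never parsed from FASTA headers.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, List

from Bio import SeqIO
from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ValidationError

VALID_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# standard genetic code (translation table 1)
_TABLE1 = unambiguous_dna_by_id[1]
_CODON_TO_AA = dict(_TABLE1.forward_table)
STOP_CODONS = frozenset(_TABLE1.stop_codons)  # {TAA, TAG, TGA}


def normalize_sequence(sequence: str) -> str:
    """Upper-case a nucleotide string and map U to T.

    Raises :class:`ValidationError` if any character falls outside
    ``{A, C, G, T, N}`` after normalization.
    """
    norm = sequence.upper().replace("U", "T")
    bad = set(norm) - VALID_ALPHABET
    if bad:
        raise ValidationError(
            f"sequence contains non-nucleotide characters: {sorted(bad)}"
        )
    return norm


@dataclass(frozen=True)
class Transcript:
    """A lncRNA transcript: an id, a species label, and a normalized sequence."""

    id: str
    sequence: str
    species: str = "unknown"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("transcript id must be non-empty")
        object.__setattr__(self, "sequence", normalize_sequence(self.sequence))
        if not self.sequence:
            raise ValidationError(f"transcript {self.id!r} has an empty sequence")

    @property
    def length(self) -> int:
        """Transcript length in nucleotides."""
        return len(self.sequence)


def read_fasta(path: str | os.PathLike, species: str = "unknown") -> List[Transcript]:
    """Read a multi-record FASTA file into a list of :class:`Transcript`.

    The header token before the first whitespace becomes the transcript id.
    Records keep file order. Duplicate ids and empty records raise
    :class:`ValidationError`; a missing file raises ``FileNotFoundError``.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"FASTA file not found: {path}")
    transcripts: List[Transcript] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seen:
            raise ValidationError(f"duplicate transcript id in FASTA: {record.id!r}")
        if len(record.seq) == 0:
            raise ValidationError(f"empty FASTA record: {record.id!r}")
        seen.add(record.id)
        transcripts.append(Transcript(id=record.id, sequence=str(record.seq), species=species))
    return transcripts


def write_fasta(transcripts: Iterable[Transcript], path: str | os.PathLike) -> None:
    """Write transcripts as FASTA (id and sequence only)."""
    records = [SeqRecord(Seq(t.sequence), id=t.id, description="") for t in transcripts]
    SeqIO.write(records, str(path), "fasta")


def write_peptides_fasta(peptides: Iterable[tuple[str, str]], path: str | os.PathLike) -> None:
    """Write (peptide_id, amino-acid sequence) pairs as FASTA."""
    records = [SeqRecord(Seq(aa), id=pid, description="") for pid, aa in peptides]
    SeqIO.write(records, str(path), "fasta")


def reverse_complement(sequence: str) -> str:
    """Watson-Crick reverse complement over ``{A, C, G, T, N}``; N maps to N."""
    bad = set(sequence) - VALID_ALPHABET
    if bad:
        raise ValidationError(
            f"cannot reverse-complement non-nucleotide characters: {sorted(bad)}"
        )
    return sequence.translate(_COMPLEMENT)[::-1]


def translate(nt_sequence: str, require_stop: bool = False) -> str:
    """Translate a nucleotide string with the standard genetic code.

    Translation proceeds codon by codon and stops at the first stop codon;
    the returned peptide excludes the stop symbol. Any codon containing N
    translates to ``'X'`` (ambiguous codons are never interpreted as stops).
    Trailing bases that do not fill a codon are ignored unless
    ``require_stop`` is set, in which case the length must be divisible by 3.
    """
    if require_stop and len(nt_sequence) % 3 != 0:
        raise ValidationError(
            f"sequence length {len(nt_sequence)} is not divisible by 3"
        )
    peptide: list[str] = []
    for i in range(0, len(nt_sequence) - 2, 3):
        codon = nt_sequence[i : i + 3]
        if codon in STOP_CODONS:
            return "".join(peptide)
        if "N" in codon:
            peptide.append("X")
        else:
            aa = _CODON_TO_AA.get(codon)
            if aa is None:
                raise ValidationError(f"untranslatable codon {codon!r} at position {i}")
            peptide.append(aa)
    return "".join(peptide)
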