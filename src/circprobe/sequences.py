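"""DNA sequence primitives shared across the probe-design pipeline.

Sequences are stored as plain upper-case DNA strings. At ingest, RNA
``U`` is mapped to ``T`` so one DNA alphabet serves both the host
transcriptome (RNA) and the DNA probe chemistry; any other non-ACGT
letters (IUPAC ambiguity codes, ``N``) are kept verbatim so that
downstream window enumeration can skip windows containing them.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlphabetError, InputError

DNA_ALPHABET = frozenset("ACGT")


def normalize_residues(raw: str) -> str:
    """Upper-case and map U->T; leave other letters untouched."""
    return raw.upper().replace("U", "T")


@dataclass
class NucSequence:
    """A named nucleotide sequence over the normalized DNA alphabet.

    ``residues`` contains only A/C/G/T for clean sequences; ambiguity
    codes may remain and mark positions excluded from k-mer windows.
    """

    id: str
    residues: str
    description: str = ""

    @classmethod
    def from_raw(cls, id: str, raw: str, description: str = "") -> "NucSequence":
        return cls(id=id, residues=normalize_residues(raw), description=description)

    def __len__(self) -> int:
        return len(self.residues)


def validate_alphabet(seq: str) -> None:
    """Raise :class:`AlphabetError` unless ``seq`` is pure A/C/G/T."""
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise AlphabetError(
            f"sequence contains non-ACGT characters: {sorted(bad)!r}"
        )


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement of a pure A/C/G/T string.

    An involution: ``reverse_complement(reverse_complement(s)) == s``.
    """
    validate_alphabet(seq)
    return str(Seq(seq).reverse_complement())


def read_fasta(path: str | Path) -> list[NucSequence]:
    """Read a (multi-record) FASTA file into normalized sequences.

    Record order is preserved; residues are upper-cased with U->T.
    Raises :class:`InputError` if the file yields no records.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"FASTA file not found: {path}")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise InputError(f"no FASTA records found in {path}")
    return [
        NucSequence.from_raw(r.id, str(r.seq), r.description) for r in records
    ]


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write ``(id, sequence)`` pairs as FASTA, one record per pair."""
    seq_records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")
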