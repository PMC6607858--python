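"""Sequence I/O and IUPAC-aware primitives.

Every other module consumes :class:`SeqRecord` objects produced here.  Two
alphabets are supported: ``dna-iupac`` (the 15 IUPAC nucleotide codes plus
the four bases) and ``protein`` (20 standard residues plus X).  DNA input is
normalised to upper case with U converted to T so that RNA-style gene
sequences and primers compare uniformly.

Coordinates are 0-based half-open internally; report writers convert to
1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO as _BioSeqIO
from Bio.Seq import Seq as _Seq

DNA_ALPHABET = set("ACGTRYSWKMBDHVN")
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")

#: Concrete-base expansion of each IUPAC nucleotide code.
IUPAC_EXPANSION: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}


class SequenceError(ValueError):
    """Raised for malformed sequence input (bad characters, duplicate ids, ...)."""


@dataclass(frozen=True)
class SeqRecord:
    """An identified sequence with a declared alphabet.

    ``id`` is the first whitespace-delimited word of the FASTA header;
    ``description`` the remainder.  The sequence is stored upper-case and is
    validated against the declared alphabet at construction.
    """

    id: str
    sequence: str
    alphabet: str = "dna-iupac"
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceError("record id must be non-empty")
        if not self.sequence:
            raise SequenceError(f"record {self.id!r}: empty sequence")
        allowed = _alphabet_set(self.alphabet)
        for pos, ch in enumerate(self.sequence):
            if ch not in allowed:
                raise SequenceError(
                    f"record {self.id!r}: illegal character {ch!r} at "
                    f"position {pos + 1} for alphabet {self.alphabet}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


def _alphabet_set(alphabet: str) -> set[str]:
    if alphabet == "dna-iupac":
        return DNA_ALPHABET
    if alphabet == "protein":
        return PROTEIN_ALPHABET
    raise SequenceError(f"unknown alphabet {alphabet!r}")


def _normalize(raw: str, alphabet: str) -> str:
    seq = raw.upper()
    if alphabet == "dna-iupac":
        seq = seq.replace("U", "T")
    return seq


def read_fasta(path: str | Path, alphabet: str = "dna-iupac") -> list[SeqRecord]:
    """Parse a FASTA file into validated records, in file order.

    Lower-case input is upcased and (for DNA) U is normalised to T.  Raises
    :class:`SequenceError` on an empty file, an empty sequence, an illegal
    character, or a duplicate id.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for bio in _BioSeqIO.parse(str(path), "fasta"):
        if bio.id in seen:
            raise SequenceError(f"duplicate id {bio.id!r} in {path}")
        seen.add(bio.id)
        desc = bio.description
        if desc.startswith(bio.id):
            desc = desc[len(bio.id):].strip()
        records.append(
            SeqRecord(
                id=bio.id,
                sequence=_normalize(str(bio.seq), alphabet),
                alphabet=alphabet,
                description=desc,
            )
        )
    if not records:
        raise SequenceError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA, sequences wrapped at ``width`` columns."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


def _check_dna(seq: str) -> None:
    for pos, ch in enumerate(seq):
        if ch not in DNA_ALPHABET:
            raise SequenceError(
                f"illegal dna-iupac character {ch!r} at position {pos + 1}"
            )


def reverse_complement(seq: str) -> str:
    """IUPAC-aware reverse complement (R<->Y, M<->K, B<->V, D<->H, N<->N)."""
    _check_dna(seq)
    return str(_Seq(seq).reverse_complement())


def iupac_matches(pattern_base: str, template_base: str) -> bool:
    """True iff the expansion sets of the two IUPAC codes intersect.

    The template may itself be ambiguous: ``(R, A)`` matches, ``(R, C)``
    does not, ``(N, Y)`` does.
    """
    try:
        p = IUPAC_EXPANSION[pattern_base]
        t = IUPAC_EXPANSION[template_base]
    except KeyError as exc:
        raise SequenceError(f"illegal dna-iupac character {exc.args[0]!r}") from exc
    return bool(p & t)


def hamming(a: str, b: str) -> int:
    """Substitution count between equal-length strings (exact characters)."""
    if len(a) != len(b):
        raise ValueError("hamming requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))


def to_one_based(start: int, end: int) -> tuple[int, int]:
    """Convert a 0-based half-open span to 1-based inclusive for reports."""
    return start + 1, end
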