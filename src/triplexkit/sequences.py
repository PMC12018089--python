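"""Validated sequence records and small sequence utilities."""

from __future__ import annotations

import enum
from dataclasses import dataclass

__all__ = [
    "Kind",
    "SequenceRecord",
    "AlphabetError",
    "reverse_complement",
]

_DNA_ALPHABET = frozenset("ACGT")
_RNA_ALPHABET = frozenset("ACGU")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class Kind(enum.Enum):
    DNA = "DNA"
    RNA = "RNA"


class AlphabetError(ValueError):
    """An input sequence contains a letter outside the accepted alphabet.

    ``position`` is the 1-based position of the first offending letter.
    """

    def __init__(self, message: str, position: int):
        super().__init__(message)
        self.position = position


def _validate(residues: str, kind: Kind, seq_id: str) -> str:
    """Uppercase, normalize RNA T->U, and reject anything else.

    DNA accepts A/C/G/T; RNA accepts A/C/G/T/U with T normalized to U.
    Any other character (including N and gaps) is a hard error naming the
    first offending 1-based position.
    """
    residues = residues.upper()
    if kind is Kind.RNA:
        residues = residues.replace("T", "U")
        alphabet = _RNA_ALPHABET
    else:
        alphabet = _DNA_ALPHABET
    for i, ch in enumerate(residues):
        if ch not in alphabet:
            raise AlphabetError(
                f"{kind.value} sequence {seq_id!r}: invalid character "
                f"{ch!r} at position {i + 1}",
                position=i + 1,
            )
    return residues


@dataclass(frozen=True)
class SequenceRecord:
    """An identified DNA or RNA sequence with a validated alphabet.

    Residues are stored uppercase; RNA input letter T is normalized to U on
    construction.  The sequence is read 5'->3'.
    """

    id: str
    residues: str
    kind: Kind

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        object.__setattr__(
            self, "residues", _validate(self.residues, self.kind, self.id)
        )

    def __len__(self) -> int:
        return len(self.residues)

    @classmethod
    def dna(cls, residues: str, seq_id: str = "dna") -> "SequenceRecord":
        return cls(seq_id, residues, Kind.DNA)

    @classmethod
    def rna(cls, residues: str, seq_id: str = "rna") -> "SequenceRecord":
        return cls(seq_id, residues, Kind.RNA)


def reverse_complement(dna: str) -> str:
    """Reverse complement of a plus-strand DNA string (uppercase A/C/G/T)."""
    return dna.translate(_COMPLEMENT)[::-1]
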