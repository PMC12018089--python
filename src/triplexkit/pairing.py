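"""Canonical Hoogsteen pairing frames and base-triplet code tables.

A DNA-RNA triplex forms when an RNA third strand (the TFO) occupies the
major groove of duplex DNA at a purine-rich target site (the TTS), pairing
with the purine strand by Hoogsteen hydrogen bonds.  Four canonical triplet
codes exist -- TA:U, CG:C, CG:G and TA:A, written duplex-pyrimidine-base /
duplex-purine-base : third-strand RNA base -- and they are distributed over
four motif/orientation contexts ("frames"):

=====================  ===========  ==================
frame                  orientation  codes
=====================  ===========  ==================
parallel pyrimidine    parallel     TA:U, CG:C
parallel mixed         parallel     TA:U, CG:G
antiparallel purine    antiparallel TA:A, CG:G
antiparallel mixed     antiparallel TA:U, CG:G
=====================  ===========  ==================

Because the TTS is constrained to the purine strand (A/G only), a triplet is
fully determined by the purine-strand DNA base and the RNA base, so each
frame reduces to a two-entry lookup: the RNA base allowed opposite A and the
RNA base allowed opposite G.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

__all__ = [
    "Orientation",
    "Frame",
    "TripletCode",
    "FRAMES",
    "build_code_tables",
    "allowed_rna_base",
    "triplet_matches",
    "NonPurineTTSBaseError",
]


class Orientation(enum.Enum):
    PARALLEL = "parallel"
    ANTIPARALLEL = "antiparallel"


class Frame(enum.Enum):
    """One of the four canonical Hoogsteen matching frames."""

    PARALLEL_PYRIMIDINE = "parallel_pyrimidine"
    PARALLEL_MIXED = "parallel_mixed"
    ANTIPARALLEL_PURINE = "antiparallel_purine"
    ANTIPARALLEL_MIXED = "antiparallel_mixed"

    @property
    def orientation(self) -> Orientation:
        if self.name.startswith("PARALLEL"):
            return Orientation.PARALLEL
        return Orientation.ANTIPARALLEL


#: All four frames in a fixed, deterministic order.
FRAMES: tuple[Frame, ...] = (
    Frame.PARALLEL_PYRIMIDINE,
    Frame.PARALLEL_MIXED,
    Frame.ANTIPARALLEL_PURINE,
    Frame.ANTIPARALLEL_MIXED,
)

# Duplex pair implied by the purine-strand base: the pyrimidine partner is
# the Watson-Crick complement, written pyrimidine-first ("TA", "CG").
_DUPLEX_PAIR = {"A": "TA", "G": "CG"}


@dataclass(frozen=True)
class TripletCode:
    """An allowed (duplex pair : third-strand base) combination in a frame.

    ``duplex_pair`` is written pyrimidine-strand base then purine-strand
    base, e.g. ``"TA"`` is the duplex T.A with A on the purine strand.
    """

    duplex_pair: str
    third_base: str
    frame: Frame

    def __post_init__(self) -> None:
        if self.duplex_pair not in ("TA", "CG"):
            raise ValueError(f"invalid duplex pair {self.duplex_pair!r}")
        if self.third_base not in "ACGU":
            raise ValueError(f"invalid third-strand base {self.third_base!r}")

    @property
    def purine_base(self) -> str:
        """The purine-strand DNA base of the duplex pair."""
        return self.duplex_pair[1]

    def __str__(self) -> str:  # e.g. "TA:U"
        return f"{self.duplex_pair}:{self.third_base}"


# Per frame: RNA base allowed opposite purine-strand A, opposite G.
_FRAME_RULES: dict[Frame, dict[str, str]] = {
    Frame.PARALLEL_PYRIMIDINE: {"A": "U", "G": "C"},
    Frame.PARALLEL_MIXED: {"A": "U", "G": "G"},
    Frame.ANTIPARALLEL_PURINE: {"A": "A", "G": "G"},
    Frame.ANTIPARALLEL_MIXED: {"A": "U", "G": "G"},
}


class NonPurineTTSBaseError(ValueError):
    """Raised when a TTS base is C or T: the target site must be a pure
    purine (A/G) tract, so pyrimidines are rejected rather than treated as
    mismatches."""


def build_code_tables() -> dict[Frame, frozenset[TripletCode]]:
    """Return the triplet-code table of each frame.

    The union over all frames contains exactly the four canonical codes
    TA:U, CG:C, CG:G and TA:A; each frame defines exactly one third-strand
    base per duplex pair.
    """
    return {
        frame: frozenset(
            TripletCode(_DUPLEX_PAIR[purine], third, frame)
            for purine, third in rules.items()
        )
        for frame, rules in _FRAME_RULES.items()
    }


def allowed_rna_base(frame: Frame, tts_base: str) -> str:
    """The single RNA base forming a valid triplet with ``tts_base`` in
    ``frame``.  ``tts_base`` must be a purine (A or G)."""
    if tts_base in ("C", "T"):
        raise NonPurineTTSBaseError(
            f"TTS base {tts_base!r} is a pyrimidine; the target site must "
            "consist of A and G only"
        )
    try:
        return _FRAME_RULES[frame][tts_base]
    except KeyError:
        raise ValueError(f"invalid TTS base {tts_base!r}") from None


def triplet_matches(frame: Frame, tts_base: str, tfo_base: str) -> bool:
    """True iff the triplet (duplex pair implied by ``tts_base``, RNA
    ``tfo_base``) is in the frame's code table.

    Raises :class:`NonPurineTTSBaseError` for a C/T target base.
    """
    if tfo_base not in "ACGU":
        raise ValueError(f"invalid RNA base {tfo_base!r}")
    return allowed_rna_base(frame, tts_base) == tfo_base
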