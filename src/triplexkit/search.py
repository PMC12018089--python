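"""Triplex search: purine-tract scanning against an RNA under an error budget.

The duplex target site (TTS) is constrained to a pure purine (A/G) tract, so
the search first extracts maximal purine tracts from both strands of the DNA
and then aligns each tract against the RNA in each of the four Hoogsteen
frames.  Within one frame, an alignment is a diagonal (a fixed offset between
tract and RNA positions); along a diagonal every position is either a match
(the triplet conforms to the frame's code) or an RNA-side mismatch.  A
candidate triplex is a diagonal window that

* starts and ends on a match,
* keeps its mismatch fraction within the error budget (compared with exact
  rational arithmetic, so a 20 % budget admits exactly 4 mismatches in 20),

and, after filtering (:mod:`triplexkit.filters`), additionally contains an
error-free run of at least ``min_consecutive`` triplets and is at least that
long overall.

Because trimming a window to the nearest match-run boundaries never raises
its error rate and never shortens it, every candidate that can survive
filtering is delimited by match-run boundaries; the engine therefore
enumerates exactly the windows spanning whole match runs on each diagonal.

Orientation conventions: in parallel frames the TFO is read 5'->3' along the
purine strand 5'->3'; in antiparallel frames the TFO runs 3'->5' against the
purine strand (implemented by scanning the reversed RNA and mapping intervals
back).  Minus-strand tracts are reported in plus-strand coordinates with a
strand flag.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Optional, Union

from .pairing import FRAMES, Frame, Orientation, allowed_rna_base
from .sequences import Kind, SequenceRecord, reverse_complement

__all__ = [
    "Strand",
    "PurineTract",
    "SearchParams",
    "TriplexCandidate",
    "TriplexHit",
    "CORE_RUN_FLOOR",
    "find_purine_tracts",
    "scan_pair",
    "compute_stats",
    "search_triplexes",
    "hit_sort_key",
]

#: Minimum admissible value for ``min_consecutive``: a triplex must always
#: contain at least seven consecutive matched triplets.
CORE_RUN_FLOOR = 7

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


class Strand(enum.Enum):
    PLUS = "+"
    MINUS = "-"


@dataclass(frozen=True)
class PurineTract:
    """A maximal run of purines on one strand of the input DNA.

    ``start``/``end`` are 0-based half-open positions on the *plus* strand;
    ``purine_seq`` is the tract read 5'->3' on the purine strand itself (for
    a minus-strand tract this is the reverse complement of the plus-strand
    segment).
    """

    dna_id: str
    strand: Strand
    start: int
    end: int
    purine_seq: str

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.purine_seq):
            raise ValueError("tract interval length != purine_seq length")
        if not set(self.purine_seq) <= _PURINES:
            raise ValueError("purine_seq must contain only A and G")

    def __len__(self) -> int:
        return self.end - self.start

    def plus_interval(self, offset: int, length: int) -> tuple[int, int]:
        """Map a window of ``purine_seq`` to 0-based half-open plus-strand
        coordinates."""
        if self.strand is Strand.PLUS:
            return self.start + offset, self.start + offset + length
        n = len(self)
        return self.start + n - offset - length, self.start + n - offset


def _as_fraction(rate: Union[Fraction, float, int, str]) -> Fraction:
    """Convert an error-rate argument to an exact fraction.

    Floats go through their shortest decimal representation so that the
    literal 0.2 becomes exactly 1/5 and boundary comparisons at 20 % are
    exact.
    """
    if isinstance(rate, Fraction):
        return rate
    if isinstance(rate, float):
        return Fraction(str(rate))
    return Fraction(rate)


@dataclass(frozen=True)
class SearchParams:
    """Search parameters.

    min_consecutive:
        Required number of contiguous matched triplets, and also the minimum
        total triplex length (default 7; must be >= 7).
    max_error_rate:
        Maximum mismatch fraction in [0, 1] (default 0.20).  Stored as an
        exact :class:`fractions.Fraction`.
    report_cpg:
        Whether downstream reporting should include CpG-island annotation.
    """

    min_consecutive: int = CORE_RUN_FLOOR
    max_error_rate: Fraction = Fraction(1, 5)
    report_cpg: bool = False
    core_run_floor: int = field(default=CORE_RUN_FLOOR, init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "max_error_rate", _as_fraction(self.max_error_rate)
        )
        if self.min_consecutive < CORE_RUN_FLOOR:
            raise ValueError(
                f"min_consecutive must be >= {CORE_RUN_FLOOR}, "
                f"got {self.min_consecutive}"
            )
        if not 0 <= self.max_error_rate <= 1:
            raise ValueError("max_error_rate must lie in [0, 1]")

    def within_budget(self, mismatches: int, length: int) -> bool:
        """Exact test of mismatches/length <= max_error_rate."""
        q = self.max_error_rate
        return mismatches * q.denominator <= length * q.numerator


@dataclass(frozen=True)
class TriplexCandidate:
    """A matched TTS-TFO window, pre- or post-filtering.

    ``tts_offset`` is 0-based within ``tract.purine_seq``; ``tfo_start`` /
    ``tfo_end`` are 0-based half-open on the original RNA (5'->3');
    ``mask`` holds '1' for a code-conforming triplet and '0' for an RNA-side
    mismatch, ordered along the TTS 5'->3' on the purine strand.
    """

    tract: PurineTract
    rna_id: str
    tts_offset: int
    tfo_start: int
    tfo_end: int
    frame: Frame
    mask: str

    @property
    def length(self) -> int:
        return len(self.mask)

    @property
    def mismatches(self) -> int:
        return self.mask.count("0")

    @property
    def error_fraction(self) -> Fraction:
        return Fraction(self.mismatches, self.length)

    @property
    def tts_plus_interval(self) -> tuple[int, int]:
        """0-based half-open TTS interval on the DNA plus strand."""
        return self.tract.plus_interval(self.tts_offset, self.length)

    @property
    def tts_seq(self) -> str:
        """TTS read 5'->3' on the purine strand."""
        return self.tract.purine_seq[self.tts_offset : self.tts_offset + self.length]

    def tfo_seq(self, rna: str) -> str:
        """TFO read 5'->3' on the RNA."""
        return rna[self.tfo_start : self.tfo_end]

    @property
    def diagonal(self) -> int:
        return self.tts_offset - self.tfo_start

    def trimmed(self, lead: int, trail: int) -> "TriplexCandidate":
        """Shrink the window by ``lead``/``trail`` positions at the TTS
        5'/3' ends, adjusting the TFO interval on the correct side for the
        frame orientation."""
        if lead == 0 and trail == 0:
            return self
        if self.frame.orientation is Orientation.PARALLEL:
            tfo_start = self.tfo_start + lead
            tfo_end = self.tfo_end - trail
        else:  # RNA index decreases as TTS index increases
            tfo_start = self.tfo_start + trail
            tfo_end = self.tfo_end - lead
        new_mask = self.mask[lead : len(self.mask) - trail]
        return replace(
            self,
            tts_offset=self.tts_offset + lead,
            tfo_start=tfo_start,
            tfo_end=tfo_end,
            mask=new_mask,
        )


@dataclass(frozen=True)
class TriplexHit:
    """A reported triplex.

    All intervals are 1-based inclusive: the TTS on the input DNA plus
    strand (with ``tts_strand`` naming the purine strand), the TFO on the
    input RNA.  ``error_rate`` and ``gu_percent`` are percentages.
    """

    dna_id: str
    rna_id: str
    tts_start: int
    tts_end: int
    tts_strand: Strand
    tfo_start: int
    tfo_end: int
    frame: Frame
    length: int
    mismatches: int
    error_rate: float
    gu_percent: float
    tts_seq: str
    tfo_seq: str
    mask: str

    @property
    def error_fraction(self) -> Fraction:
        return Fraction(self.mismatches, self.length)


def find_purine_tracts(dna: SequenceRecord, min_len: int) -> list[PurineTract]:
    """All maximal A/G runs of length >= ``min_len`` on both strands.

    Plus-strand tracts are runs of A/G; minus-strand tracts are runs of C/T
    on the plus strand (purine on the reverse complement), reported in
    plus-strand coordinates with ``purine_seq`` read 5'->3' on the minus
    strand.  Tracts are maximal and returned sorted by (start, strand).
    """
    if dna.kind is not Kind.DNA:
        raise ValueError("find_purine_tracts requires a DNA record")
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    seq = dna.residues
    tracts: list[PurineTract] = []
    for strand, alphabet in ((Strand.PLUS, _PURINES), (Strand.MINUS, _PYRIMIDINES)):
        i = 0
        n = len(seq)
        while i < n:
            if seq[i] in alphabet:
                j = i
                while j < n and seq[j] in alphabet:
                    j += 1
                if j - i >= min_len:
                    segment = seq[i:j]
                    purine_seq = (
                        segment
                        if strand is Strand.PLUS
                        else reverse_complement(segment)
                    )
                    tracts.append(
                        PurineTract(dna.id, strand, i, j, purine_seq)
                    )
                i = j
            else:
                i += 1
    tracts.sort(key=lambda t: (t.start, t.strand.value))
    return tracts


def _mask_runs(bits: list[bool]) -> list[tuple[int, int]]:
    """Half-open [start, end) spans of consecutive True values."""
    runs = []
    i = 0
    n = len(bits)
    while i < n:
        if bits[i]:
            j = i
            while j < n and bits[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def scan_pair(
    tract: PurineTract,
    rna: SequenceRecord,
    frame: Frame,
    params: SearchParams,
    *,
    min_length: Optional[int] = None,
    min_run: Optional[int] = None,
) -> list[TriplexCandidate]:
    """Candidate triplexes between one purine tract and the RNA in one frame.

    Returns every window on every diagonal that is delimited by match-run
    boundaries and whose mismatch fraction is within the error budget.
    Candidates are raw in the sense that length/core-run requirements and
    regional/tie deduplication are left to :mod:`triplexkit.filters`;
    ``min_length``/``min_run`` are optional pruning hints used by
    :func:`search_triplexes` to skip windows the filters would discard
    anyway.

    With a zero error budget this degenerates to the classic restart
    behaviour: each maximal exact match run is a candidate and matching
    resumes after every mismatch.
    """
    if rna.kind is not Kind.RNA:
        raise ValueError("scan_pair requires an RNA record")
    purine = tract.purine_seq
    n = len(purine)
    m = len(rna)
    if n == 0 or m == 0:
        return []
    parallel = frame.orientation is Orientation.PARALLEL
    r_eff = rna.residues if parallel else rna.residues[::-1]
    allowed = {"A": allowed_rna_base(frame, "A"), "G": allowed_rna_base(frame, "G")}
    out: list[TriplexCandidate] = []
    for off in range(-(n - 1), m):
        i_lo = max(0, -off)
        i_hi = min(n, m - off)
        if i_hi - i_lo < 1:
            continue
        bits = [allowed[purine[i]] == r_eff[i + off] for i in range(i_lo, i_hi)]
        runs = _mask_runs(bits)
        if not runs:
            continue
        diag_len = i_hi - i_lo
        for a in range(len(runs)):
            for b in range(a, len(runs)):
                ws, we = runs[a][0], runs[b][1]
                length = we - ws
                mism = (we - ws) - sum(
                    runs[k][1] - runs[k][0] for k in range(a, b + 1)
                )
                if not params.within_budget(mism, length):
                    # more runs only add mismatches faster than the budget
                    # can absorb once even the longest extension fails
                    if not params.within_budget(mism, diag_len - ws):
                        break
                    continue
                if min_length is not None and length < min_length:
                    continue
                if min_run is not None and max(
                    runs[k][1] - runs[k][0] for k in range(a, b + 1)
                ) < min_run:
                    continue
                mask = "".join(
                    "1" if bit else "0" for bit in bits[ws:we]
                )
                # window position in tract coordinates / effective RNA coords
                t_ws = i_lo + ws
                r_ws = t_ws + off
                r_we = r_ws + length
                if parallel:
                    tfo_start, tfo_end = r_ws, r_we
                else:
                    tfo_start, tfo_end = m - r_we, m - r_ws
                out.append(
                    TriplexCandidate(
                        tract=tract,
                        rna_id=rna.id,
                        tts_offset=t_ws,
                        tfo_start=tfo_start,
                        tfo_end=tfo_end,
                        frame=frame,
                        mask=mask,
                    )
                )
    return out


def compute_stats(candidate: TriplexCandidate, rna: SequenceRecord) -> tuple[float, float]:
    """(error_rate %, G+U % of the TFO) for a candidate."""
    length = candidate.length
    error_rate = 100.0 * candidate.mismatches / length
    tfo = candidate.tfo_seq(rna.residues)
    gu = 100.0 * (tfo.count("G") + tfo.count("U")) / length
    return error_rate, gu


def hit_sort_key(hit: TriplexHit):
    """Deterministic report order: length desc, then error rate asc, TTS
    start asc, frame name, strand, TFO start."""
    return (
        -hit.length,
        hit.error_fraction,
        hit.tts_start,
        hit.frame.name,
        hit.tts_strand.value,
        hit.tfo_start,
    )


def _candidate_to_hit(
    cand: TriplexCandidate, dna: SequenceRecord, rna: SequenceRecord
) -> TriplexHit:
    s0, e0 = cand.tts_plus_interval
    error_rate, gu = compute_stats(cand, rna)
    return TriplexHit(
        dna_id=dna.id,
        rna_id=rna.id,
        tts_start=s0 + 1,
        tts_end=e0,
        tts_strand=cand.tract.strand,
        tfo_start=cand.tfo_start + 1,
        tfo_end=cand.tfo_end,
        frame=cand.frame,
        length=cand.length,
        mismatches=cand.mismatches,
        error_rate=error_rate,
        gu_percent=gu,
        tts_seq=cand.tts_seq,
        tfo_seq=cand.tfo_seq(rna.residues),
        mask=cand.mask,
    )


def search_triplexes(
    dna: SequenceRecord,
    rna: SequenceRecord,
    params: Optional[SearchParams] = None,
) -> list[TriplexHit]:
    """All filtered triplexes between a DNA duplex and an RNA.

    Orchestrates tract extraction (minimum tract length =
    ``params.min_consecutive``, since a shorter tract cannot host a valid
    hit), scanning of every tract in all four frames, the filter chain
    (end-trimming, core-run/length/error validity, regional selection,
    slide-tie resolution) and conversion to 1-based reporting coordinates.
    Deterministically ordered by :func:`hit_sort_key`.
    """
    from .filters import apply_filters  # deferred to avoid import cycle

    if params is None:
        params = SearchParams()
    candidates: list[TriplexCandidate] = []
    for tract in find_purine_tracts(dna, params.min_consecutive):
        for frame in FRAMES:
            candidates.extend(
                scan_pair(
                    tract,
                    rna,
                    frame,
                    params,
                    min_length=params.min_consecutive,
                    min_run=params.min_consecutive,
                )
            )
    survivors = apply_filters(candidates, params)
    hits = [_candidate_to_hit(c, dna, rna) for c in survivors]
    hits.sort(key=hit_sort_key)
    return hits
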