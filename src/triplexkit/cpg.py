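"""CpG-island prediction by running-sum scoring, and TTS annotation.

A CpG island is a DNA span longer than 200 bp with GC content over 50 % and
an observed/expected CpG ratio over 0.6 (all bounds exclusive), where

    obs/exp = (#CpG dinucleotides x span length) / (#C x #G).

Islands are located with the running-sum scheme used by genome-browser CpG
annotation: walking 5'->3', each CG dinucleotide step adds +17 to a running
score and every other dinucleotide step subtracts 1.  A segment opens at a
positive step; when the score falls back to zero (or the sequence ends) the
span from the opening position to the position of the *maximum* score is
assessed against the three criteria, and the scan resumes just after that
maximum (just after the island when one is reported, which also guarantees
non-overlapping output).  The +17/-1 weighting means a lone CG is paid off
after 17 decrement steps, so an isolated CG closes its segment 19 bp after
it opened.

The scan is a heuristic: it is sound (every reported island is re-verified
against the criteria) but makes no completeness claim over all qualifying
substrings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from .search import TriplexHit
from .sequences import Kind, SequenceRecord

__all__ = [
    "CpGParams",
    "CpGIsland",
    "ScanSegment",
    "dinucleotide_score_steps",
    "island_metrics",
    "scan_segments",
    "find_cpg_islands",
    "annotate_tts_islands",
]


@dataclass(frozen=True)
class CpGParams:
    """Scoring and acceptance thresholds for island detection.

    ``min_length_bp``, ``min_gc_percent`` and ``min_obs_exp`` are exclusive
    lower bounds (a 200-bp span is not an island; 201 bp can be).
    """

    cpg_step_score: int = 17
    other_step_score: int = -1
    min_length_bp: int = 200
    min_gc_percent: float = 50.0
    min_obs_exp: float = 0.6

    def __post_init__(self) -> None:
        if self.cpg_step_score <= 0 or self.other_step_score >= 0:
            raise ValueError("CG steps must score positive, others negative")
        if min(self.min_length_bp, self.min_gc_percent, self.min_obs_exp) <= 0:
            raise ValueError("thresholds must be positive")


@dataclass(frozen=True)
class CpGIsland:
    """A detected island, 1-based inclusive on the DNA plus strand."""

    start: int
    end: int
    length_bp: int
    gc_percent: float
    obs_exp_ratio: float

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != self.length_bp:
            raise ValueError("island interval inconsistent with length")


@dataclass(frozen=True)
class ScanSegment:
    """One open-to-close episode of the running sum (0-based step indices).

    ``open_step`` is the first (positive) step, ``close_step`` the step at
    which the sum first returned to <= 0 (or the final step at sequence
    end), ``max_step`` the step attaining the maximum running sum.  The
    scanned span in bases is ``[open_step, close_step + 1]``; the assessed
    candidate span is ``[open_step, max_step + 1]``.
    """

    open_step: int
    close_step: int
    max_step: int
    max_score: int


def dinucleotide_score_steps(seq: str, params: Optional[CpGParams] = None) -> list[int]:
    """Per-step scores of a DNA string: +17 for each CG dinucleotide, -1
    otherwise.  A sequence shorter than 2 has no steps."""
    if params is None:
        params = CpGParams()
    return [
        params.cpg_step_score if seq[i : i + 2] == "CG" else params.other_step_score
        for i in range(len(seq) - 1)
    ]


def island_metrics(seq: str, start: int, end: int) -> tuple[float, float]:
    """(GC %, observed/expected CpG ratio) of ``seq[start:end]`` (0-based
    half-open).  The ratio is defined as 0 when the span lacks C or G."""
    span = seq[start:end]
    n = len(span)
    if n < 2:
        raise ValueError("island span must be at least 2 bp")
    n_c = span.count("C")
    n_g = span.count("G")
    gc_percent = 100.0 * (n_c + n_g) / n
    if n_c == 0 or n_g == 0:
        return gc_percent, 0.0
    n_cg = span.count("CG")
    return gc_percent, n_cg * n / (n_c * n_g)


def scan_segments(seq: str, params: Optional[CpGParams] = None) -> list[ScanSegment]:
    """Running-sum scan episodes over a DNA string.

    Each episode opens at the first positive step at or after the resume
    position, tracks the running sum and its maximum, and closes when the
    sum returns to <= 0 or the sequence ends.  The scan resumes one step
    after the episode's maximum, re-examining the stretch between the
    maximum and the close.
    """
    if params is None:
        params = CpGParams()
    steps = dinucleotide_score_steps(seq, params)
    segments: list[ScanSegment] = []
    pos = 0
    n = len(steps)
    while pos < n:
        # find the next positive (CG) step
        while pos < n and steps[pos] <= 0:
            pos += 1
        if pos >= n:
            break
        total = 0
        max_score = 0
        max_step = pos
        close = pos
        for j in range(pos, n):
            total += steps[j]
            if total > max_score:
                max_score = total
                max_step = j
            close = j
            if total <= 0:
                break
        segments.append(ScanSegment(pos, close, max_step, max_score))
        pos = max_step + 1
    return segments


def find_cpg_islands(
    dna: SequenceRecord, params: Optional[CpGParams] = None
) -> list[CpGIsland]:
    """Predict CpG islands on a DNA record.

    For each scan episode the candidate span runs from the opening step to
    the maximum-score step; it is reported iff it is longer than 200 bp with
    GC content over 50 % and obs/exp CpG ratio over 0.6 (strict bounds,
    re-verified with :func:`island_metrics`).  After a reported island the
    scan resumes past the island, so reported islands never overlap and come
    out sorted by start.
    """
    if dna.kind is not Kind.DNA:
        raise ValueError("find_cpg_islands requires a DNA record")
    if params is None:
        params = CpGParams()
    seq = dna.residues
    steps = dinucleotide_score_steps(seq, params)
    islands: list[CpGIsland] = []
    pos = 0
    n = len(steps)
    while pos < n:
        while pos < n and steps[pos] <= 0:
            pos += 1
        if pos >= n:
            break
        total = 0
        max_score = 0
        max_step = pos
        for j in range(pos, n):
            total += steps[j]
            if total > max_score:
                max_score = total
                max_step = j
            if total <= 0:
                break
        # candidate span: opening base through the 3' base of the max step
        start, end = pos, max_step + 2  # 0-based half-open
        length = end - start
        gc, ratio = island_metrics(seq, start, end)
        if (
            length > params.min_length_bp
            and gc > params.min_gc_percent
            and ratio > params.min_obs_exp
        ):
            islands.append(
                CpGIsland(
                    start=start + 1,
                    end=end,
                    length_bp=length,
                    gc_percent=gc,
                    obs_exp_ratio=ratio,
                )
            )
            pos = end  # resume past the island: output never overlaps
        else:
            pos = max_step + 1
    return islands


def annotate_tts_islands(
    hits: Iterable[TriplexHit], islands: Iterable[CpGIsland]
) -> list[tuple[TriplexHit, Optional[CpGIsland], Optional[int]]]:
    """Pair each hit with the overlapping island, else the nearest one.

    Returns (hit, island or None, signed distance in bp or None); the
    distance is 0 for an overlap, positive when the island lies 3' of the
    TTS on the plus strand, negative when 5'.
    """
    islands = list(islands)
    annotated = []
    for hit in hits:
        best: Optional[CpGIsland] = None
        best_dist: Optional[int] = None
        for isl in islands:
            if isl.start <= hit.tts_end and hit.tts_start <= isl.end:
                dist = 0
            elif isl.start > hit.tts_end:
                dist = isl.start - hit.tts_end
            else:
                dist = isl.end - hit.tts_start  # negative
            if best_dist is None or abs(dist) < abs(best_dist):
                best, best_dist = isl, dist
            if best_dist == 0:
                break
        annotated.append((hit, best, best_dist))
    return annotated
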