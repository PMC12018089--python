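"""Optimization and filtering of raw triplex candidates.

Five rules turn the raw windows produced by the scanner into valid,
non-redundant hits:

1. *Matched ends* -- a reported triplex must begin and end with a correctly
   paired triplet, so leading/trailing mismatches are trimmed away.
2. *Core run* -- every triplex must contain an error-free run of consecutive
   matched triplets of at least the required length (never below 7).
3. *Regional selection* -- where candidates compete for the same TTS/TFO
   region, only the longest is kept among those with equal error rate; a
   shorter candidate survives only when its error rate is strictly lower
   than every longer competitor.
4. *Repeated sequences* -- identical TFO or TTS sequences at distinct
   positions are independent results and are all retained (regional
   selection only ever compares candidates whose intervals overlap).
5. *Slide ties* -- on a repetitive stretch the same pairing can be placed at
   several offsets; only the placement(s) aligning the midpoints of the two
   repeats are kept (one placement when the parities agree, the two central
   placements when one repeat is odd and the other even).

The chain is applied as trim -> validity (core run, length, error budget)
-> regional selection -> slide-tie resolution.  Regional selection compares
every pair of conflicting candidates (>= 50 % reciprocal overlap of the
shorter interval, on both the TTS and the TFO side) against the full
candidate set, which makes the outcome independent of input order and makes
the chain idempotent.
"""

from __future__ import annotations

from typing import Iterable, Optional

from .search import CORE_RUN_FLOOR, SearchParams, TriplexCandidate

__all__ = [
    "trim_to_matched_ends",
    "passes_core_run",
    "longest_match_run",
    "select_by_region",
    "resolve_slide_ties",
    "apply_filters",
]


def trim_to_matched_ends(candidate: TriplexCandidate) -> Optional[TriplexCandidate]:
    """Strip leading and trailing mismatches; None if nothing remains."""
    mask = candidate.mask
    first = mask.find("1")
    if first == -1:
        return None
    last = mask.rfind("1")
    return candidate.trimmed(first, len(mask) - 1 - last)


def longest_match_run(mask: str) -> int:
    """Length of the longest run of '1' in a match mask."""
    return max((len(run) for run in mask.split("0")), default=0)


def passes_core_run(candidate: TriplexCandidate, floor: int = CORE_RUN_FLOOR) -> bool:
    """True iff the candidate contains >= ``floor`` consecutive matches."""
    return longest_match_run(candidate.mask) >= floor


def _conflicts(a: TriplexCandidate, b: TriplexCandidate) -> bool:
    """Same-region test: TTS intervals and TFO intervals each overlap by at
    least 50 % of the shorter candidate."""
    shorter = min(a.length, b.length)
    a_ts, a_te = a.tts_plus_interval
    b_ts, b_te = b.tts_plus_interval
    tts_ov = min(a_te, b_te) - max(a_ts, b_ts)
    if 2 * tts_ov < shorter:
        return False
    tfo_ov = min(a.tfo_end, b.tfo_end) - max(a.tfo_start, b.tfo_start)
    return 2 * tfo_ov >= shorter


def select_by_region(candidates: Iterable[TriplexCandidate]) -> list[TriplexCandidate]:
    """Regional dominance filter (rules 3 and 4).

    A candidate is dropped iff some conflicting candidate is strictly longer
    with an error rate no higher than its own.  Candidates whose intervals do
    not overlap never interact, so identical sequences at distinct positions
    are all retained.
    """
    cands = list(candidates)
    survivors = []
    for c in cands:
        err_c = c.error_fraction
        dominated = any(
            d.length > c.length
            and d.error_fraction <= err_c
            and _conflicts(c, d)
            for d in cands
        )
        if not dominated:
            survivors.append(c)
    return survivors


def _slide_key(c: TriplexCandidate) -> tuple:
    # Mates are alternative placements of the same pairing: same frame,
    # strand and mask, with identical TTS content (TFO content is then
    # identical too, the mask and frame determining it at matched positions).
    return (c.frame, c.tract.strand, c.tract.dna_id, c.mask, c.tts_seq)


def resolve_slide_ties(
    candidates: Iterable[TriplexCandidate],
) -> list[TriplexCandidate]:
    """Midpoint rule for continuous sliding matches (rule 5).

    Candidates with identical content whose TTS and TFO intervals overlap
    are alternative placements of one pairing over a repeat.  Within each
    such maximal group, the placement(s) whose window midpoints sit closest
    to the midpoints of the slid extents are kept: one placement when the
    window and the extent have the same parity, the two central placements
    when the parities differ.
    """
    cands = list(candidates)
    by_key: dict[tuple, list[int]] = {}
    for idx, c in enumerate(cands):
        by_key.setdefault(_slide_key(c), []).append(idx)

    keep: set[int] = set()
    for indices in by_key.values():
        if len(indices) == 1:
            keep.add(indices[0])
            continue
        # union-find over overlapping placements
        parent = {i: i for i in indices}

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for pos_a, i in enumerate(indices):
            for j in indices[pos_a + 1 :]:
                a, b = cands[i], cands[j]
                a_ts, a_te = a.tts_plus_interval
                b_ts, b_te = b.tts_plus_interval
                if (
                    min(a_te, b_te) > max(a_ts, b_ts)
                    and min(a.tfo_end, b.tfo_end) > max(a.tfo_start, b.tfo_start)
                ):
                    parent[find(i)] = find(j)
        groups: dict[int, list[int]] = {}
        for i in indices:
            groups.setdefault(find(i), []).append(i)
        for members in groups.values():
            if len(members) == 1:
                keep.add(members[0])
                continue
            tts_lo = min(cands[i].tts_plus_interval[0] for i in members)
            tts_hi = max(cands[i].tts_plus_interval[1] for i in members)
            tfo_lo = min(cands[i].tfo_start for i in members)
            tfo_hi = max(cands[i].tfo_end for i in members)
            # doubled centers keep the arithmetic exact
            tts_uc = tts_lo + tts_hi - 1
            tfo_uc = tfo_lo + tfo_hi - 1
            best = None
            dists = {}
            for i in members:
                c = cands[i]
                c_ts, c_te = c.tts_plus_interval
                d = abs(c_ts + c_te - 1 - tts_uc) + abs(
                    c.tfo_start + c.tfo_end - 1 - tfo_uc
                )
                dists[i] = d
                if best is None or d < best:
                    best = d
            keep.update(i for i in members if dists[i] == best)
    return [c for idx, c in enumerate(cands) if idx in keep]


def _canonical_key(c: TriplexCandidate) -> tuple:
    s, e = c.tts_plus_interval
    return (
        c.tract.dna_id,
        c.tract.strand.value,
        s,
        e,
        c.frame.name,
        c.tfo_start,
        c.tfo_end,
        c.mask,
    )


def apply_filters(
    candidates: Iterable[TriplexCandidate], params: SearchParams
) -> list[TriplexCandidate]:
    """Full filter chain; returns surviving candidates in canonical order.

    Idempotent, and independent of the input order of ``candidates``.
    """
    floor = max(params.core_run_floor, params.min_consecutive)
    seen: set[tuple] = set()
    valid: list[TriplexCandidate] = []
    for raw in candidates:
        c = trim_to_matched_ends(raw)
        if c is None:
            continue
        key = _canonical_key(c)
        if key in seen:
            continue
        seen.add(key)
        if c.length < params.min_consecutive:
            continue
        if not passes_core_run(c, floor):
            continue
        if not params.within_budget(c.mismatches, c.length):
            continue
        valid.append(c)
    valid.sort(key=_canonical_key)
    return resolve_slide_ties(select_by_region(valid))
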