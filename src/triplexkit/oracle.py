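"""Brute-force reference search, used for equivalence testing.

Enumerates every placement (frame x strand x TTS start x TFO start x
length) on small inputs, keeps the ones passing the validity predicate
literally (pure-purine TTS, matched ends, error budget, required error-free
run, minimum length) and applies regional selection and slide-tie
resolution re-implemented from scratch.  Only the triplet code tables are
shared with the fast engine; scanning, coordinate mapping and filtering are
written independently so that bugs do not correlate.

Not built for speed: inputs are capped at 60 nt.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Optional

from .pairing import FRAMES, Frame, Orientation, build_code_tables
from .search import SearchParams, Strand, TriplexHit
from .sequences import SequenceRecord

__all__ = ["brute_force_triplexes", "ORACLE_MAX_LEN"]

ORACLE_MAX_LEN = 60

_RC = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class _Placement:
    strand: Strand
    frame: Frame
    tts_lo: int  # 0-based half-open, plus strand
    tts_hi: int
    tfo_lo: int  # 0-based half-open, original RNA orientation
    tfo_hi: int
    mask: str
    tts_seq: str  # purine strand 5'->3'
    tfo_seq: str  # RNA 5'->3'

    @property
    def length(self) -> int:
        return len(self.mask)

    @property
    def err(self) -> Fraction:
        return Fraction(self.mask.count("0"), len(self.mask))


def _enumerate(dna: str, rna: str, params: SearchParams) -> list[_Placement]:
    tables = build_code_tables()
    allowed = {
        frame: {code.purine_base: code.third_base for code in codes}
        for frame, codes in tables.items()
    }
    min_len = params.min_consecutive
    run_floor = max(params.core_run_floor, params.min_consecutive)
    q = params.max_error_rate
    out: list[_Placement] = []
    m = len(rna)
    for strand in (Strand.PLUS, Strand.MINUS):
        if strand is Strand.PLUS:
            pstrand = dna
        else:
            pstrand = "".join(_RC[c] for c in reversed(dna))
        lp = len(pstrand)
        # purine run length starting at each position: a valid window
        # needs min_len consecutive purines
        pr = [0] * (lp + 1)
        for i in range(lp - 1, -1, -1):
            pr[i] = pr[i + 1] + 1 if pstrand[i] in "AG" else 0
        for frame in FRAMES:
            amap = allowed[frame]
            parallel = frame.orientation is Orientation.PARALLEL
            reff = rna if parallel else rna[::-1]
            for ts in range(lp):
                max_l_purine = pr[ts]
                if max_l_purine < min_len:
                    continue
                for rs in range(m):
                    if amap[pstrand[ts]] != reff[rs]:
                        continue  # first base must be matched
                    l_cap = min(max_l_purine, m - rs)
                    if l_cap < min_len:
                        continue
                    bits = []
                    mism = 0
                    cur_run = 0
                    max_run = 0
                    for l in range(1, l_cap + 1):
                        ok = amap[pstrand[ts + l - 1]] == reff[rs + l - 1]
                        bits.append(ok)
                        if ok:
                            cur_run += 1
                            if cur_run > max_run:
                                max_run = cur_run
                        else:
                            cur_run = 0
                            mism += 1
                            # hopeless if even the longest remaining
                            # extension cannot absorb the mismatches
                            if mism * q.denominator > l_cap * q.numerator:
                                break
                        if (
                            ok
                            and l >= min_len
                            and max_run >= run_floor
                            and mism * q.denominator <= l * q.numerator
                        ):
                            if strand is Strand.PLUS:
                                tts_lo, tts_hi = ts, ts + l
                            else:
                                tts_lo, tts_hi = lp - ts - l, lp - ts
                            if parallel:
                                tfo_lo, tfo_hi = rs, rs + l
                            else:
                                tfo_lo, tfo_hi = m - rs - l, m - rs
                            out.append(
                                _Placement(
                                    strand,
                                    frame,
                                    tts_lo,
                                    tts_hi,
                                    tfo_lo,
                                    tfo_hi,
                                    "".join("1" if b else "0" for b in bits),
                                    pstrand[ts : ts + l],
                                    rna[tfo_lo:tfo_hi],
                                )
                            )
    return out


def _overlap(a_lo: int, a_hi: int, b_lo: int, b_hi: int) -> int:
    return min(a_hi, b_hi) - max(a_lo, b_lo)


def _region_select(placements: list[_Placement]) -> list[_Placement]:
    kept = []
    for c in placements:
        err_c = c.err
        dead = False
        for d in placements:
            if d.length <= c.length or d.err > err_c:
                continue
            shorter = c.length
            if 2 * _overlap(c.tts_lo, c.tts_hi, d.tts_lo, d.tts_hi) < shorter:
                continue
            if 2 * _overlap(c.tfo_lo, c.tfo_hi, d.tfo_lo, d.tfo_hi) < shorter:
                continue
            dead = True
            break
        if not dead:
            kept.append(c)
    return kept


def _slide_select(placements: list[_Placement]) -> list[_Placement]:
    groups: dict[tuple, list[_Placement]] = {}
    for p in placements:
        groups.setdefault((p.frame, p.strand, p.mask, p.tts_seq), []).append(p)
    kept: list[_Placement] = []
    for members in groups.values():
        # clusters of mutually reachable overlapping placements (BFS)
        unseen = list(range(len(members)))
        clusters: list[list[_Placement]] = []
        while unseen:
            queue = [unseen.pop(0)]
            cluster_idx = []
            while queue:
                i = queue.pop()
                cluster_idx.append(i)
                p = members[i]
                still = []
                for j in unseen:
                    q2 = members[j]
                    if (
                        _overlap(p.tts_lo, p.tts_hi, q2.tts_lo, q2.tts_hi) > 0
                        and _overlap(p.tfo_lo, p.tfo_hi, q2.tfo_lo, q2.tfo_hi)
                        > 0
                    ):
                        queue.append(j)
                    else:
                        still.append(j)
                unseen = still
            clusters.append([members[i] for i in cluster_idx])
        for cl in clusters:
            if len(cl) == 1:
                kept.append(cl[0])
                continue
            t_lo = min(p.tts_lo for p in cl)
            t_hi = max(p.tts_hi for p in cl)
            f_lo = min(p.tfo_lo for p in cl)
            f_hi = max(p.tfo_hi for p in cl)
            t_c = t_lo + t_hi - 1
            f_c = f_lo + f_hi - 1
            dist = {
                id(p): abs(p.tts_lo + p.tts_hi - 1 - t_c)
                + abs(p.tfo_lo + p.tfo_hi - 1 - f_c)
                for p in cl
            }
            best = min(dist.values())
            kept.extend(p for p in cl if dist[id(p)] == best)
    return kept


def brute_force_triplexes(
    dna: SequenceRecord,
    rna: SequenceRecord,
    params: Optional[SearchParams] = None,
) -> list[TriplexHit]:
    """Reference hit list for small inputs, ordered like the fast engine."""
    if params is None:
        params = SearchParams()
    if len(dna) > ORACLE_MAX_LEN or len(rna) > ORACLE_MAX_LEN:
        raise ValueError(
            f"oracle inputs are capped at {ORACLE_MAX_LEN} nt"
        )
    placements = _enumerate(dna.residues, rna.residues, params)
    placements = _region_select(placements)
    placements = _slide_select(placements)
    hits = []
    for p in placements:
        n_mis = p.mask.count("0")
        gu = 100.0 * (p.tfo_seq.count("G") + p.tfo_seq.count("U")) / p.length
        hits.append(
            TriplexHit(
                dna_id=dna.id,
                rna_id=rna.id,
                tts_start=p.tts_lo + 1,
                tts_end=p.tts_hi,
                tts_strand=p.strand,
                tfo_start=p.tfo_lo + 1,
                tfo_end=p.tfo_hi,
                frame=p.frame,
                length=p.length,
                mismatches=n_mis,
                error_rate=100.0 * n_mis / p.length,
                gu_percent=gu,
                tts_seq=p.tts_seq,
                tfo_seq=p.tfo_seq,
                mask=p.mask,
            )
        )
    hits.sort(
        key=lambda h: (
            -h.length,
            h.error_fraction,
            h.tts_start,
            h.frame.name,
            h.tts_strand.value,
            h.tfo_start,
        )
    )
    return hits
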