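"""Deterministic synthetic DNA/RNA generators with planted ground truth.

Fixtures for testing and benchmarking without any external data: a triplex
planter that embeds a purine target site and its frame-consistent RNA third
strand (with a controlled number of interior mismatches) into otherwise
unrelated background, and a CpG-island planter that embeds a CG-dense
segment into AT-rich background.

The triplex background is pyrimidine-biased on the DNA side so that
spurious purine tracts long enough to host a hit are rare, and each draw is
verified with the real search: if an unplanned qualifying hit appears
anywhere, the fixture is re-drawn from a derived seed.  Island background
is generated with no CG dinucleotide at all, so the planted island is the
only possible detection.

These generators emulate sequence composition only; they make no attempt to
model chromatin, methylation, RNA secondary structure or real genomic base
ordering.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .pairing import Frame, Orientation, allowed_rna_base
from .search import SearchParams, Strand, search_triplexes
from .sequences import SequenceRecord

__all__ = [
    "PlantedTriplex",
    "PlantedIsland",
    "plant_triplex",
    "plant_cpg_island",
    "cpg_probe_span",
]

_MAX_ATTEMPTS = 60


@dataclass(frozen=True)
class PlantedTriplex:
    """Ground truth for a planted triplex (1-based inclusive intervals)."""

    tts_start: int
    tts_end: int
    tts_strand: Strand
    tfo_start: int
    tfo_end: int
    frame: Frame
    length: int
    n_errors: int
    mismatch_positions: tuple[int, ...]  # 1-based along the TTS 5'->3'
    expected_error_rate: float  # percent
    tts_seq: str
    tfo_seq: str


@dataclass(frozen=True)
class PlantedIsland:
    """Ground truth for a planted CpG island (1-based inclusive)."""

    start: int
    end: int
    length_bp: int
    gc_percent: float
    obs_exp_ratio: float


def _weighted_base(rng: random.Random, weights: dict[str, float]) -> str:
    return rng.choices(list(weights), weights=list(weights.values()))[0]


_DNA_BACKGROUND = {"C": 0.35, "T": 0.35, "A": 0.15, "G": 0.15}


def _spurious(hits, truth: PlantedTriplex) -> bool:
    for h in hits:
        tts_ok = h.tts_start <= truth.tts_end and truth.tts_start <= h.tts_end
        tfo_ok = h.tfo_start <= truth.tfo_end and truth.tfo_start <= h.tfo_end
        if not (tts_ok and tfo_ok):
            return True
    return False


def _planted_recovered(hits, truth: PlantedTriplex) -> bool:
    return any(
        (h.tts_start, h.tts_end, h.tfo_start, h.tfo_end, h.frame)
        == (truth.tts_start, truth.tts_end, truth.tfo_start, truth.tfo_end,
            truth.frame)
        for h in hits
    )


def plant_triplex(
    dna_len: int = 200,
    rna_len: int = 150,
    tts_len: int = 12,
    frame: Frame = Frame.PARALLEL_PYRIMIDINE,
    n_errors: int = 0,
    seed: int = 0,
    *,
    allow_over_budget: bool = False,
) -> tuple[SequenceRecord, SequenceRecord, PlantedTriplex]:
    """Embed one triplex with ``n_errors`` interior RNA-side mismatches.

    The planted TTS is a pure purine tract on the DNA plus strand, flanked
    by pyrimidines so it is maximal; the planted TFO is the frame-consistent
    third strand (reversed in the RNA for antiparallel frames).  The first
    seven triplets are always left error-free, so a planted triplex within
    the error budget is recoverable at default settings.  Deterministic for
    a fixed seed.

    ``n_errors`` above the default 20 % budget requires
    ``allow_over_budget=True`` (intended-negative fixtures).
    """
    if tts_len < 2:
        raise ValueError("tts_len must be >= 2")
    if dna_len < tts_len + 2 or rna_len < tts_len + 2:
        raise ValueError("sequence too short to host the planted site")
    if n_errors < 0:
        raise ValueError("n_errors must be >= 0")
    if n_errors > max(0, tts_len - 8):
        raise ValueError(
            f"cannot place {n_errors} interior mismatches in a {tts_len}-mer "
            "while keeping the ends and a 7-run matched"
        )
    if not allow_over_budget and 5 * n_errors > tts_len:
        raise ValueError(
            f"{n_errors}/{tts_len} mismatches exceed the 20% budget; pass "
            "allow_over_budget=True for an intended-negative fixture"
        )

    for attempt in range(_MAX_ATTEMPTS):
        rng = random.Random((seed * 1000003 + attempt) % (2**31))
        tts = "".join(rng.choice("AG") for _ in range(tts_len))
        mismatch_pos = tuple(
            sorted(rng.sample(range(7, tts_len - 1), n_errors))
        )
        tfo_along = []
        for k, base in enumerate(tts):
            good = allowed_rna_base(frame, base)
            if k in mismatch_pos:
                tfo_along.append(rng.choice([b for b in "ACGU" if b != good]))
            else:
                tfo_along.append(good)
        rna_insert = "".join(tfo_along)
        if frame.orientation is Orientation.ANTIPARALLEL:
            rna_insert = rna_insert[::-1]

        dna_bg = [_weighted_base(rng, _DNA_BACKGROUND) for _ in range(dna_len)]
        dna_pos = rng.randrange(1, dna_len - tts_len)
        dna_bg[dna_pos : dna_pos + tts_len] = list(tts)
        dna_bg[dna_pos - 1] = rng.choice("CT")  # keep the tract maximal
        if dna_pos + tts_len < dna_len:
            dna_bg[dna_pos + tts_len] = rng.choice("CT")

        rna_bg = [rng.choice("ACGU") for _ in range(rna_len)]
        rna_pos = rng.randrange(0, rna_len - tts_len + 1)
        rna_bg[rna_pos : rna_pos + tts_len] = list(rna_insert)

        dna = SequenceRecord.dna("".join(dna_bg), f"synthetic_dna_seed{seed}")
        rna = SequenceRecord.rna("".join(rna_bg), f"synthetic_rna_seed{seed}")

        truth = PlantedTriplex(
            tts_start=dna_pos + 1,
            tts_end=dna_pos + tts_len,
            tts_strand=Strand.PLUS,
            tfo_start=rna_pos + 1,
            tfo_end=rna_pos + tts_len,
            frame=frame,
            length=tts_len,
            n_errors=n_errors,
            mismatch_positions=tuple(p + 1 for p in mismatch_pos),
            expected_error_rate=100.0 * n_errors / tts_len,
            tts_seq=tts,
            tfo_seq=rna_insert,
        )
        hits = search_triplexes(dna, rna, SearchParams())
        if _spurious(hits, truth):
            continue
        # a positive fixture must be recoverable at its exact placement; a
        # repeat-like draw can slide the reported placement off the planted
        # one (midpoint rule), so such draws are rejected
        positive = tts_len >= 7 and 5 * n_errors <= tts_len
        if positive and not _planted_recovered(hits, truth):
            continue
        return dna, rna, truth
    raise RuntimeError(
        f"could not draw a spurious-free fixture in {_MAX_ATTEMPTS} attempts"
    )


def cpg_probe_span(length: int, n_c: int, n_g: int, n_cg: int) -> str:
    """A DNA span with exact C, G and CpG-dinucleotide counts.

    Deterministic boundary probe for the island criteria: the span starts
    and ends with a full CG dinucleotide, its CG dinucleotides are spread as
    evenly as possible (so the running sum stays positive whenever the
    average inter-CG gap is short enough), and no CG occurs outside the
    designated blocks.  The remaining positions are filled with the extra
    C's and G's (ordered G-side first within each gap so no stray CG forms)
    and alternating A/T.

    GC content is 100*(n_c+n_g)/length; obs/exp = n_cg*length/(n_c*n_g).
    """
    if n_cg < 2:
        raise ValueError("need at least two CG blocks to anchor both ends")
    extra_c = n_c - n_cg
    extra_g = n_g - n_cg
    n_at = length - 2 * n_cg - extra_c - extra_g
    if extra_c < 0 or extra_g < 0 or n_at < 0:
        raise ValueError("infeasible composition")
    gaps = n_cg - 1

    def spread(total: int) -> list[int]:
        base, rem = divmod(total, gaps)
        return [base + (1 if i < rem else 0) for i in range(gaps)]

    per_g = spread(extra_g)
    per_at = spread(n_at)
    per_c = spread(extra_c)
    parts = ["CG"]
    at_cycle = "AT"
    for i in range(gaps):
        filler = (
            "G" * per_g[i]
            + "".join(at_cycle[j % 2] for j in range(per_at[i]))
            + "C" * per_c[i]
        )
        parts.append(filler)
        parts.append("CG")
    span = "".join(parts)
    assert len(span) == length
    assert span.count("C") == n_c and span.count("G") == n_g
    assert span.count("CG") == n_cg
    return span


def plant_cpg_island(
    seq_len: int = 2000,
    island_len: int = 250,
    gc_background: float = 0.30,
    seed: int = 0,
) -> tuple[SequenceRecord, PlantedIsland]:
    """Embed one CpG island in CG-dinucleotide-free background.

    The island is an alternating-CG segment (with one interior G spacer for
    odd lengths so that both ends are a full CG); the background honours the
    requested GC fraction but never produces a C immediately followed by a
    G, so the planted island is the only positive-scoring region.
    """
    if island_len <= 200:
        raise ValueError("island_len must exceed 200 bp")
    if not 0 <= gc_background < 0.40:
        raise ValueError("gc_background must be below 40%")
    if seq_len < island_len + 20:
        raise ValueError("seq_len too short for the island")

    rng = random.Random(seed)
    if island_len % 2 == 0:
        island = "CG" * (island_len // 2)
    else:
        half = (island_len - 1) // 2
        a = half // 2
        island = "CG" * a + "G" + "CG" * (half - a)

    weights = {
        "C": gc_background / 2,
        "G": gc_background / 2,
        "A": (1 - gc_background) / 2,
        "T": (1 - gc_background) / 2,
    }
    pos = rng.randrange(1, seq_len - island_len)
    chars: list[str] = []
    for i in range(seq_len):
        if pos <= i < pos + island_len:
            chars.append(island[i - pos])
            continue
        b = _weighted_base(rng, weights)
        prev = chars[-1] if chars else ""
        if prev == "C" and b == "G":
            b = "A"  # forbid background CG dinucleotides
        if i == pos + island_len and b == "G":
            b = "A"  # island ends in G; avoid extending a CG across the edge
        chars.append(b)
    # island starts with C; a preceding background C is harmless (CC), but a
    # preceding "C" with the island's first letter "G" cannot occur since the
    # island always starts with C.
    seq = "".join(chars)
    span = seq[pos : pos + island_len]
    n_c, n_g, n_cg = span.count("C"), span.count("G"), span.count("CG")
    truth = PlantedIsland(
        start=pos + 1,
        end=pos + island_len,
        length_bp=island_len,
        gc_percent=100.0 * (n_c + n_g) / island_len,
        obs_exp_ratio=n_cg * island_len / (n_c * n_g),
    )
    return SequenceRecord.dna(seq, f"synthetic_cpg_seed{seed}"), truth
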