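"""Shared test helpers: hit comparison keys and random instance generation."""

from __future__ import annotations

import random

import pytest

from triplexkit import (
    FRAMES,
    Frame,
    Orientation,
    SearchParams,
    SequenceRecord,
    Strand,
)
from triplexkit.pairing import allowed_rna_base


def hit_key(hit):
    """Full identifying tuple of a hit, for engine-vs-oracle comparison."""
    return (
        hit.tts_start,
        hit.tts_end,
        hit.tts_strand.value,
        hit.tfo_start,
        hit.tfo_end,
        hit.frame.name,
        hit.mask,
        hit.length,
        hit.mismatches,
        hit.tts_seq,
        hit.tfo_seq,
    )


def hit_keys(hits):
    return [hit_key(h) for h in hits]


_ERROR_RATES = (0, 0.1, 0.2)


def random_instance(seed: int):
    """A small random (dna, rna, params) instance for equivalence checks.

    Purine-rich DNA yields tracts; with probability ~0.6 a frame-consistent
    (possibly imperfect) third strand copied from a DNA segment is embedded
    in the RNA so that deep alignments with mismatches are exercised, not
    just background noise.
    """
    rng = random.Random(seed)
    n = rng.randint(15, 50)
    m = rng.randint(15, 50)
    dna = [rng.choices("AGCT", weights=(35, 35, 15, 15))[0] for _ in range(n)]
    rna = [rng.choice("ACGU") for _ in range(m)]
    if rng.random() < 0.6:
        frame = rng.choice(FRAMES)
        length = rng.randint(8, min(16, n, m))
        start = rng.randrange(0, n - length + 1)
        tts = [rng.choice("AG") for _ in range(length)]
        dna[start : start + length] = tts
        tfo = [allowed_rna_base(frame, b) for b in tts]
        for _ in range(rng.randint(0, 2)):
            k = rng.randrange(1, length - 1)
            tfo[k] = rng.choice([b for b in "ACGU" if b != tfo[k]])
        if frame.orientation is Orientation.ANTIPARALLEL:
            tfo = tfo[::-1]
        rstart = rng.randrange(0, m - length + 1)
        rna[rstart : rstart + length] = tfo
    params = SearchParams(max_error_rate=_ERROR_RATES[seed % len(_ERROR_RATES)])
    return (
        SequenceRecord.dna("".join(dna), f"d{seed}"),
        SequenceRecord.rna("".join(rna), f"r{seed}"),
        params,
    )


def alternating_cg(length: int) -> str:
    """CG-dense span of exact length, starting and ending with a full CG
    (odd lengths carry one interior G spacer)."""
    if length % 2 == 0:
        return "CG" * (length // 2)
    half = (length - 1) // 2
    a = half // 2
    return "CG" * a + "G" + "CG" * (half - a)


def embed_in_poly_a(span: str, flank: int = 850) -> SequenceRecord:
    return SequenceRecord.dna("A" * flank + span + "A" * flank)


def island_overlapping_span(islands, span_start_1b: int, span_end_1b: int):
    return [
        i for i in islands if i.start <= span_end_1b and span_start_1b <= i.end
    ]


@pytest.fixture
def perfect_pair():
    """A 12-mer perfect parallel-pyrimidine pairing."""
    return (
        SequenceRecord.dna("GGAAGGAAGGAA"),
        SequenceRecord.rna("CCUUCCUUCCUU"),
    )
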