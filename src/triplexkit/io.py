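"""FASTA input with alphabet validation, and TSV/BED report output.

The canonical report is a TSV with one row per predicted triplex
(1-based inclusive coordinates, percentages with two decimals), plus BED
files (0-based half-open) for loading the TTS and CpG intervals into a
genome browser.  Output is byte-deterministic for fixed input.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Sequence, Union

from Bio import SeqIO

from .cpg import CpGIsland, annotate_tts_islands
from .search import Strand, TriplexHit
from .sequences import Kind, SequenceRecord
from .pairing import Frame

__all__ = [
    "REPORT_COLUMNS",
    "read_sequence",
    "read_sequences",
    "write_report",
    "read_report",
]

logger = logging.getLogger(__name__)

REPORT_COLUMNS = (
    "dna_id",
    "rna_id",
    "tts_start",
    "tts_end",
    "tts_strand",
    "tfo_start",
    "tfo_end",
    "frame",
    "length",
    "error_rate_pct",
    "gu_pct",
    "tts_seq",
    "tfo_seq",
    "cpg_island",
    "cpg_distance_bp",
)


def read_sequence(path: Union[str, Path], kind: Kind) -> SequenceRecord:
    """Read the first sequence of a FASTA file (or a raw-text sequence).

    Case is normalized; RNA letter T becomes U.  Any letter outside the
    accepted alphabet (DNA: ACGT, RNA: ACGTU) is a hard error naming its
    position.  A multi-record FASTA produces a warning and uses the first
    record.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ValueError(f"{path}: empty input file")
    if text.lstrip().startswith(">"):
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValueError(f"{path}: no FASTA records found")
        if len(records) > 1:
            logger.warning(
                "%s: %d records found; using the first (%s)",
                path,
                len(records),
                records[0].id,
            )
        rec = records[0]
        return SequenceRecord(rec.id, str(rec.seq), kind)
    residues = "".join(text.split())
    return SequenceRecord(path.stem, residues, kind)


def read_sequences(
    dna_path: Union[str, Path], rna_path: Union[str, Path]
) -> tuple[SequenceRecord, SequenceRecord]:
    """Read the DNA and RNA inputs (both 5'->3')."""
    return read_sequence(dna_path, Kind.DNA), read_sequence(rna_path, Kind.RNA)


def _island_str(island: Optional[CpGIsland]) -> str:
    return f"{island.start}-{island.end}" if island is not None else "."


def write_report(
    hits: Sequence[TriplexHit],
    islands: Optional[Sequence[CpGIsland]],
    out_prefix: Union[str, Path],
) -> dict[str, Path]:
    """Write <prefix>.triplexes.tsv, <prefix>.tts.bed and <prefix>.cpg.bed.

    When ``islands`` is None the island columns are left blank (".") and an
    empty cpg BED is still produced so the output layout is fixed.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    tsv_path = out_prefix.with_name(out_prefix.name + ".triplexes.tsv")
    tts_bed = out_prefix.with_name(out_prefix.name + ".tts.bed")
    cpg_bed = out_prefix.with_name(out_prefix.name + ".cpg.bed")

    annotated = annotate_tts_islands(hits, islands or [])
    lines = ["\t".join(REPORT_COLUMNS)]
    for hit, island, dist in annotated:
        lines.append(
            "\t".join(
                (
                    hit.dna_id,
                    hit.rna_id,
                    str(hit.tts_start),
                    str(hit.tts_end),
                    hit.tts_strand.value,
                    str(hit.tfo_start),
                    str(hit.tfo_end),
                    hit.frame.value,
                    str(hit.length),
                    f"{hit.error_rate:.2f}",
                    f"{hit.gu_percent:.2f}",
                    hit.tts_seq,
                    hit.tfo_seq,
                    _island_str(island),
                    str(dist) if island is not None else ".",
                )
            )
        )
    tsv_path.write_text("\n".join(lines) + "\n")

    bed_lines = [
        "\t".join(
            (
                hit.dna_id,
                str(hit.tts_start - 1),
                str(hit.tts_end),
                f"{hit.frame.value}|len{hit.length}|err{hit.error_rate:.2f}",
                "0",
                hit.tts_strand.value,
            )
        )
        for hit in hits
    ]
    tts_bed.write_text("\n".join(bed_lines) + ("\n" if bed_lines else ""))

    dna_id = hits[0].dna_id if hits else "dna"
    cpg_lines = [
        "\t".join(
            (
                dna_id,
                str(isl.start - 1),
                str(isl.end),
                f"CpG|gc{isl.gc_percent:.2f}|oe{isl.obs_exp_ratio:.2f}",
                "0",
                ".",
            )
        )
        for isl in (islands or [])
    ]
    cpg_bed.write_text("\n".join(cpg_lines) + ("\n" if cpg_lines else ""))

    return {"tsv": tsv_path, "tts_bed": tts_bed, "cpg_bed": cpg_bed}


def read_report(tsv_path: Union[str, Path]) -> list[dict]:
    """Parse a triplex TSV back into typed row dictionaries.

    Numeric columns come back as int/float; the island interval as a
    (start, end) tuple or None.  Used for round-trip verification.
    """
    rows = []
    lines = Path(tsv_path).read_text().splitlines()
    header = lines[0].split("\t")
    if tuple(header) != REPORT_COLUMNS:
        raise ValueError(f"{tsv_path}: unexpected report header")
    for line in lines[1:]:
        f = line.split("\t")
        row = dict(zip(REPORT_COLUMNS, f))
        for key in ("tts_start", "tts_end", "tfo_start", "tfo_end", "length"):
            row[key] = int(row[key])
        for key in ("error_rate_pct", "gu_pct"):
            row[key] = float(row[key])
        row["tts_strand"] = Strand(row["tts_strand"])
        row["frame"] = Frame(row["frame"])
        if row["cpg_island"] == ".":
            row["cpg_island"] = None
            row["cpg_distance_bp"] = None
        else:
            s, _, e = row["cpg_island"].partition("-")
            row["cpg_island"] = (int(s), int(e))
            row["cpg_distance_bp"] = int(row["cpg_distance_bp"])
        rows.append(row)
    return rows
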