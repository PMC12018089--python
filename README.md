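# triplexkit

Prediction of DNA–RNA triple helices (triplexes) from a DNA duplex and an
RNA sequence, for researchers studying how nuclear non-coding RNAs (lncRNAs,
and candidate nuclear-acting miRNAs) bind target promoters and enhancers
without unwinding the double helix.

A triplex forms when an RNA third strand — the **triplex-forming
oligonucleotide (TFO)** — occupies the major groove of duplex DNA at a
purine-rich **triplex target site (TTS)**, hydrogen-bonding to the purine
strand by Hoogsteen pairing. Four canonical triplet codes
(`TA:U`, `CG:C`, `CG:G`, `TA:A`, written duplex pyrimidine·purine : RNA base)
are distributed over four motif/orientation frames:

| frame                | orientation  | codes        |
|----------------------|--------------|--------------|
| parallel pyrimidine  | parallel     | TA:U, CG:C   |
| parallel mixed       | parallel     | TA:U, CG:G   |
| antiparallel purine  | antiparallel | TA:A, CG:G   |
| antiparallel mixed   | antiparallel | TA:U, CG:G   |

`triplexkit` scans every maximal purine (A/G) tract on both DNA strands
against the RNA in all four frames and reports every alignment window that

* contains at least `min_consecutive` contiguous matched triplets
  (default 7, the hard floor) and is at least that long,
* begins and ends on a matched triplet,
* keeps its mismatch fraction within `max_error_rate` (default 20 %,
  compared with exact rational arithmetic so 4/20 is accepted and 5/20 is
  not), with mismatches allowed on the RNA side only — a C or T in the DNA
  terminates the target site,

then removes redundant candidates: within one region the longest triplex
wins among equals, shorter ones survive only with strictly lower error,
and placements sliding along a repeat are reduced to the midpoint-aligned
one(s). Each hit reports 1-based TTS/TFO positions, strand, frame, length,
error rate and the G+U percentage of the TFO (a proposed stability
covariate). Optionally the DNA is annotated with **CpG islands** (span
> 200 bp, GC > 50 %, observed/expected CpG > 0.6, found with the +17/−1
running-sum scan) and each TTS with its nearest island — useful when the
RNA is suspected to direct DNA methylation.

## Worked example

```python
from triplexkit import SearchParams, SequenceRecord, search_triplexes

dna = SequenceRecord.dna("TTCCT" + "GGAAGGAAGGAA" + "TCTCT", "demo_dna")
rna = SequenceRecord.rna("AAC" + "CCUUCCUACCUU" + "GCA", "demo_rna")
for h in search_triplexes(dna, rna, SearchParams(max_error_rate=0.10)):
    print(h.tts_start, h.tts_end, h.tfo_start, h.tfo_end,
          h.frame.value, h.length, f"{h.error_rate:.2f}", h.mask)
```

prints

```
6 17 4 15 parallel_pyrimidine 12 8.33 111111101111
6 12 4 10 parallel_pyrimidine 7 0.00 1111111
10 16 4 10 parallel_pyrimidine 7 0.00 1111111
```

The purine tract `GGAAGGAAGGAA` (DNA positions 6–17) pairs with the RNA
under the parallel pyrimidine motif; the single interior mismatch (the `0`
in the mask, RNA `A` opposite DNA `A`) is within the 10 % budget, so the
full 12-mer is reported at 8.33 % error. The error-free 7-mers have a
strictly lower error rate than the overlapping 12-mer, so the regional
filter keeps them as separate valid predictions; two distinct TTS
placements of the same 7-mer pairing exist because the tract is a
four-base repeat. More narrative examples live in `examples/`.

The same run from the shell:

```bash
triplexkit search --dna dna.fa --rna rna.fa --max-error-rate 10 --cpg --out results/run
```

writes `run.triplexes.tsv` (the table above plus G+U % and CpG-island
distance columns), `run.tts.bed` and `run.cpg.bed`.

## Layout

* `triplexkit.pairing` — frames and triplet code tables
* `triplexkit.search` — tract extraction, diagonal scanning, hit assembly
* `triplexkit.filters` — end-trimming, core-run, regional and slide-tie rules
* `triplexkit.cpg` — running-sum island scan and TTS annotation
* `triplexkit.io` / `triplexkit.cli` — FASTA in, TSV/BED out, `triplexkit` command
* `triplexkit.synthetic` — deterministic planted-truth generators
* `triplexkit.oracle` — literal brute-force reference used in tests

See `docs/methods.md` for the algorithmic details and design decisions.
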