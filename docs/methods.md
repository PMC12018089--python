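# Methods

## Model

A DNA–RNA triplex is modelled as an un-gapped alignment between a purine
tract of the duplex (the TTS, read 5'→3' on the purine strand) and a
segment of the RNA (the TFO), scored position-wise by the canonical
Hoogsteen triplet codes. Because the duplex pair is determined by its
purine-strand base (T·A ↔ A, C·G ↔ G), each of the four frames reduces to
a two-entry table giving the single RNA base accepted opposite A and
opposite G:

* parallel pyrimidine: A→U, G→C
* parallel mixed: A→U, G→G
* antiparallel purine: A→A, G→G
* antiparallel mixed: A→U, G→G

Parallel frames read the TFO 5'→3' along the purine strand's 5'→3'
direction; antiparallel frames read it 3'→5' (implemented by scanning the
reversed RNA and mapping intervals back). The parallel-mixed and
antiparallel-mixed frames share a code table and differ only in
orientation; they are searched as disjoint contexts and a hit records its
frame, so palindromic situations can legitimately yield one hit per
orientation. The CG:C code is treated as a plain pairing rule; third-strand
cytosine protonation chemistry is not modelled. Mismatches are RNA-side
only: a pyrimidine on the DNA purine strand ends the tract rather than
counting as a mismatch.

## Search and candidate definition

Maximal A/G runs of length ≥ `min_consecutive` are extracted from the plus
strand and (as C/T runs, reverse-complemented) from the minus strand. Each
tract is aligned against the RNA on every diagonal of every frame. A
candidate is a diagonal window that starts and ends on a match and whose
mismatch count m over length L satisfies m/L ≤ e exactly (integer
cross-multiplication; the float literal 0.2 is first converted to the
rational 1/5 through its decimal representation, so the 20 % boundary
admits exactly 4 mismatches in 20). With e = 0 this degenerates to
restart-after-mismatch behaviour: candidates are exactly the maximal exact
runs.

The engine does not enumerate every window: trimming a window outward to
the nearest match-run boundaries never shortens it and never raises its
error rate, so any window that could survive the filters is delimited by
match-run boundaries. Per diagonal the engine therefore emits exactly the
windows spanning whole match runs (O(runs²) per diagonal rather than
O(L²)). A literal full-enumeration oracle (`triplexkit.oracle`) is kept in
the test suite and must agree hit-for-hit with the engine; the equivalence
is exercised on thousands of randomized and adversarial (homopolymer,
periodic-repeat, minus-strand, antiparallel) instances.

## Filtering

1. **Matched ends** — leading/trailing mismatches are trimmed (a no-op for
   run-boundary windows; retained as a public operation and re-applied for
   idempotence).
2. **Core run and length** — the longest error-free run and the total
   length must both reach `min_consecutive` (floor 7). The single
   parameter deliberately serves as both minimum run and minimum length:
   at the default 7 the two readings coincide, and stricter settings
   (e.g. 16 for lncRNA-scale probes) tighten both.
3. **Regional selection** — candidate c is discarded iff some candidate d
   with both TTS and TFO overlap ≥ 50 % of the shorter candidate is
   strictly longer with error ≤ c's. This keeps the longest triplex among
   equal-error competitors while preserving shorter triplexes of strictly
   lower error, and never merges identical sequences at distinct loci.
   Dominance is evaluated pairwise against the full candidate set (not
   iteratively and not component-wide), which makes the outcome
   order-independent and idempotent.
4. **Slide ties** — placements with identical frame, strand, mask and TTS
   content whose intervals overlap are alternative slidings of one pairing
   over a repeat. Within each connected group the placement(s) minimizing
   the distance between the window midpoints and the midpoints of the slid
   extents are kept: one placement when window and extent parities agree,
   the two central placements when they differ (a 10-base run against a
   7-base probe keeps offsets 2 and 3 of the four possible). Equal-distance
   ties (periodic repeats whose period exceeds 1) keep all minimizers.

Filter order is trim → validity → regional selection → slide-tie
resolution. Running regional selection first is load-bearing: slide groups
must be formed among regionally surviving placements, otherwise a longer
candidate overlapping only the central placements of a repeat would
eliminate different representatives than a full enumeration yields, and
the engine/oracle equivalence would break on homopolymer stretches.

Hits are reported 1-based inclusive (minus-strand TTSs in plus-strand
coordinates with a strand flag) and ordered by length descending, then
error rate ascending (exact fractions), TTS start, frame name, strand and
TFO start — a total, deterministic order.

## CpG islands

Islands are found with the running-sum scan used by genome-browser CpG
annotation: each CG dinucleotide step scores +17, every other step −1. A
segment opens at a positive step; when the sum returns to ≤ 0 (or the
sequence ends) the span from the opening position to the position of the
maximum sum is assessed against three exclusive criteria — length > 200 bp,
GC > 50 %, observed/expected CpG = (#CpG·N)/(#C·#G) > 0.6 (defined 0
without both C and G) — and the scan resumes one step past the maximum
(past the island when reported, so output intervals never overlap and come
out sorted). Assessing the open-to-maximum prefix rather than the full
open-to-zero span matters: with +17/−1 weighting a genuine island's sum
only reaches zero deep inside the downstream background, and assessing
that overshot span would dilute GC content below threshold and reject
every island embedded in AT-rich sequence. The 19-bp pay-off span of an
isolated CG (2 bp + 17 decrement steps) pins the scoring constants and is
exposed through `scan_segments`. The scan is sound — every report is
re-verified against the criteria — but not complete over all qualifying
substrings; two CG-dense regions closer than the accumulated score decays
are legitimately merged into one island when the merged span still passes.
No island merging or minimum-gap post-processing is applied beyond this.

TTS annotation pairs each hit with an overlapping island (distance 0) or
the nearest one (signed bp distance, positive 3' of the TTS on the plus
strand); ties at equal absolute distance keep the first island in
coordinate order.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `min_consecutive` | 7 | minimum error-free run and minimum triplex length, triplets; hard floor 7 |
| `max_error_rate` | 0.20 | maximum mismatch fraction, exact rational comparison |
| `cpg_step_score` / `other_step_score` | +17 / −1 | running-sum step scores per dinucleotide |
| `min_length_bp`, `min_gc_percent`, `min_obs_exp` | 200, 50, 0.6 | exclusive island thresholds |

The CLI accepts the error budget as a percentage (`--max-error-rate 20`)
and stores it as a fraction.

## Synthetic data

`plant_triplex` embeds a random purine TTS (flanked by forced pyrimidines
so the tract is maximal) and its frame-consistent TFO with a requested
number of interior RNA-side mismatches (first/last and an initial 7-run
always matched) into background DNA that is 70 % pyrimidine — chosen so
spurious purine tracts of hostable length are rare — and uniform background
RNA at sizes of a few hundred bases, the scale of a promoter fragment
against an RNA probe. Each draw is verified with the real search: fixtures
with any unplanned qualifying hit, or whose planted placement is displaced
by the slide rule (a repeat-like draw continuing into background), are
re-drawn deterministically from a derived seed. Mismatch counts above the
budget or lengths below 7 are intended-negative fixtures and only need to
be spurious-free. `plant_cpg_island` embeds an alternating-CG span (one
interior G spacer for odd lengths, so both ends are full CGs) in background
that respects a requested GC fraction but never forms a CG dinucleotide,
making the planted island the only positive-scoring region.
`cpg_probe_span` builds spans with exact C/G/CpG counts, CG blocks spread
evenly so the running sum stays positive across the span, for boundary
sweeps of the three island criteria.

These generators emulate composition only: no chromatin context, no RNA
secondary structure, no realistic k-mer statistics, and triplexes are
planted on the plus strand. Passing tests therefore demonstrate
algorithmic correctness of the search and scanner on sequences with known
ground truth, not predictive accuracy on genomic data.

## Numerical and degenerate-input choices

Error comparisons and sort keys use exact fractions throughout; no
floating-point boundary can flip a decision. Reported percentages are
formatted to two decimals. Empty hit lists are valid output (exit 0 from
the CLI). RNA input letter T is normalized to U; any character outside the
DNA/RNA alphabets (including N) is rejected with its 1-based position.
Sequences shorter than the minimum length, all-pyrimidine duplex strands
and island-free DNA all return empty results rather than errors.

## Known limitations

* No genome-scale indexing: the scan is intended for promoter/enhancer
  fragments against one RNA, not whole-genome TTS catalogues.
* Only the four canonical Hoogsteen codes are implemented; reverse-Hoogsteen
  extended code sets are out of scope.
* No scoring or ranking model beyond the deterministic sort: length and
  error rate are reported, not a binding-energy estimate.
* The island scan inherits the running-sum heuristic's incompleteness
  (see above) and applies no merging post-processing.
* The midpoint rule for even/even slide ties keeps all minimal-distance
  placements; the underlying convention is ambiguous and is documented
  here as this package's choice.
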