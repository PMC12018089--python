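"""Predict CpG islands and annotate triplex target sites with them.

Plants a 250-bp CpG island into an AT-rich 2-kb background, runs the
running-sum island scanner (+17 per CG step, -1 otherwise), and shows how
predicted target sites are annotated with their nearest island -- the
readout used to shortlist TTSs for methylation-related follow-up.
"""

from triplexkit import annotate_tts_islands, find_cpg_islands, search_triplexes
from triplexkit.sequences import SequenceRecord
from triplexkit.synthetic import plant_cpg_island

dna, truth = plant_cpg_island(seq_len=2000, island_len=250, seed=7)
islands = find_cpg_islands(dna)

print(f"planted island: {truth.start}-{truth.end} "
      f"(GC {truth.gc_percent:.1f}%, obs/exp {truth.obs_exp_ratio:.2f})")
for isl in islands:
    print(f"detected island: {isl.start}-{isl.end} length {isl.length_bp} bp "
          f"GC {isl.gc_percent:.1f}% obs/exp {isl.obs_exp_ratio:.2f}")

# pair the island prediction with a triplex search on the same DNA: embed a
# purine target right before the island and an RNA that binds it
seq = list(dna.residues)
seq[truth.start - 60 : truth.start - 40] = list("GAGGAAGGGAGGAAGGGAGG")
seq[truth.start - 61] = "T"
seq[truth.start - 40] = "T"
dna2 = SequenceRecord.dna("".join(seq), "dna_with_tts")
rna = SequenceRecord.rna("CUCCUUCCCUCCUUCCCUCC", "probe_rna")

hits = search_triplexes(dna2, rna)
for hit, island, dist in annotate_tts_islands(hits, find_cpg_islands(dna2)):
    where = f"island {island.start}-{island.end}" if island else "no island"
    print(f"TTS {hit.tts_start}-{hit.tts_end} len {hit.length}: "
          f"{where}, distance {dist} bp")
# distance 0 means the TTS overlaps the island; positive = island lies 3'
# of the TTS on the plus strand, negative = 5'.
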