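"""Find triplexes between a DNA duplex and an RNA.

Builds a small DNA/RNA pair whose purine tract pairs with the RNA under the
parallel pyrimidine motif (TA:U, CG:C), once perfectly and once with a
single interior mismatch inside the 20 % error budget, and prints every
predicted triplex.
"""

from triplexkit import SearchParams, SequenceRecord, search_triplexes

dna = SequenceRecord.dna("TTCCT" + "GGAAGGAAGGAA" + "TCTCT", "demo_dna")
rna = SequenceRecord.rna("AAC" + "CCUUCCUACCUU" + "GCA", "demo_rna")

hits = search_triplexes(dna, rna, SearchParams(max_error_rate=0.10))

print(f"{len(hits)} triplexes (length desc, then error rate asc):")
for h in hits:
    print(
        f"  TTS {h.tts_start}-{h.tts_end} ({h.tts_strand.value}) "
        f"TFO {h.tfo_start}-{h.tfo_end}  {h.frame.value:22s} "
        f"len {h.length:2d}  err {h.error_rate:5.2f}%  G+U {h.gu_percent:5.2f}%"
    )
    print(f"    TTS 5'-{h.tts_seq}-3'  TFO 5'-{h.tfo_seq}-3'  mask {h.mask}")

# The 12-mer spans the mismatch at 1/12 = 8.33 % error; the error-free
# 7-mer in front of the mismatch has a strictly lower error rate, so the
# regional filter keeps it as a separate, also-valid prediction.
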