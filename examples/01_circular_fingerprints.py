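"""Why circularize? Single errors always leave shared k-mers.

A 12-nt barcode with k = 8 has only 5 linear k-mers, so one mid-barcode
error can corrupt all of them.  Circularizing guarantees k error-free
k-mers for any single mismatch; the truncated/extended variants extend
the guarantee to deletions and insertions.
"""

from barcycle import BarcodeWindow, circular_kmers, three_variant_kmers

barcode = "TTAGCCAGGCAT"
clean = {p.kmer for p in circular_kmers(barcode, 8)}
print(f"barcode {barcode}: {len(clean)} circular 8-mers (vs 5 linear)")

# worst case for a linear fingerprint: error in the middle (A -> G)
mutated = barcode[:6] + "G" + barcode[7:]
linear_shared = sum(
    mutated[i : i + 8] in {barcode[j : j + 8] for j in range(5)} for i in range(5)
)
w = BarcodeWindow("read", mutated, "G")
circ_shared = {p.kmer for p in three_variant_kmers(w, 8)} & clean
print(f"mismatch at position 6: linear k-mers shared = {linear_shared}, "
      f"circular k-mers shared = {len(circ_shared)}")

# a deletion shifts the downstream base in; the truncated variant recovers
deleted = barcode[:6] + barcode[7:] + "A"
w = BarcodeWindow("read", deleted, "C")
circ_shared = {p.kmer for p in three_variant_kmers(w, 8)} & clean
print(f"deletion at position 6:  circular k-mers shared = {len(circ_shared)}")

print("\nEvery read contributes", len(three_variant_kmers(BarcodeWindow('r', barcode, 'A'), 8)),
      "positioned k-mers (11 truncated + 12 exact + 13 extended).")
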