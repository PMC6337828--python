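"""Levenshtein vs k-mer read assignment, and the exact-match baseline.

Levenshtein assignment is conservative: it misassigns fewer reads but
leaves more unassigned.  k-mer assignment recovers more reads at a
higher misassignment rate.  An exact-window-counting baseline (no
circularization, no edit distance) shows why indel-aware correction
matters at all.
"""

from barcycle import (
    PipelineParams,
    ReadAssigner,
    SimulationConfig,
    generate_dataset,
    naive_baseline,
    run_on_windows,
    score_barcodes,
    windows,
)

cfg = SimulationConfig(n_barcodes=25, n_reads=6000, error_lambda=1.0, seed=5)
reads, truth = generate_dataset(cfg)
ws = windows(reads, 12)
res = run_on_windows(ws, 12, PipelineParams(k=7, breadth=120, depth=5, seed=5))

lev = score_barcodes(res.barcodes, truth, res.assignments)
km = score_barcodes(
    res.barcodes, truth,
    ReadAssigner(res.barcodes, method="kmer", k_assign=7, min_shared=2).assign_all(ws),
)
_, naive_assign = naive_baseline(ws, 12)
naive = score_barcodes([], truth, naive_assign)

print(f"{'mode':<14}{'correct':>10}{'incorrect':>12}{'unassigned':>12}")
for name, s in (("levenshtein", lev), ("kmer", km), ("exact-match", naive)):
    print(f"{name:<14}{s.correct_fraction:>9.1%}{s.incorrect_fraction:>11.2%}"
          f"{s.unassigned_fraction:>11.1%}")
print("\nLevenshtein: fewest misassignments (the default); k-mer: higher yield;")
print("exact matching throws away every read with an error in its barcode.")
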