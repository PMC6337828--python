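# Methods

## Problem setting

Pooled single-cell sequencing tags each read with a cell barcode of
known, fixed length *L* (12 nt here, as in Drop-seq). Split-pool
synthesis produces *random* barcodes — no whitelist exists — and
introduces deletions at high rates on top of the sequencer's mismatches
and insertions. The caller must (i) discover the set of true barcodes
without a prior cell count and (ii) assign each read to one of them or
declare it unassignable. Because the instrument reports a fixed-length
window, an upstream deletion shifts a downstream (UMI/adaptor) base into
the window's last position, and an insertion shifts a true base out:
indel-bearing windows are the right length but locally frame-shifted.

## Circularized three-variant fingerprints

For a useful k (≥ 7 on 12-nt barcodes, to keep random k-mer collisions
manageable), a linear window has only L − k + 1 k-mers and a single
mid-window error can corrupt all of them. Treating the window as a
circular string gives L k-mers and guarantees k clean ones for any
single mismatch. Deletions and insertions are handled by circularizing
two further variants before k-mer counting:

* TRUNCATED (length L − 1): drops the last window base — exactly the
  foreign base a deletion shifted in — restoring a majority-correct
  circle;
* EXACT (length L);
* EXTENDED (length L + 1): appends the first downstream base, which
  restores the circle after an insertion.

Every read therefore contributes 3L positioned k-mers (2L − 1 when the
read is too short to supply the extension base). k-mers are enumerated
as *positions* (duplicates retained), which keeps the (L−1)+L+(L+1)
arithmetic exact for repetitive sequences; each k-mer remembers its
variant and circular offset, which later resolves the rotational phase
of called cycles. k-mers containing N are generated but never indexed —
an ambiguous base cannot support a consensus. Input is uppercased on
ingest.

## Index and subgraphs

A k-mer → postings index (read id, variant, offset) is built from the
first *S* reads of the input (default S = 500,000; head-based
subsampling matches how such files are downsampled in practice and is
deterministic without a seed; a seeded reservoir mode exists). The
`count_stability` diagnostic — Jaccard overlap of the top-n k-mer sets
of two disjoint subsamples — indicates whether S captured the count
spectrum; it is a diagnostic, not a gate, and its absolute value depends
on how densely counts are packed at the top-n boundary.

Rather than one graph of the whole dataset, a de Bruijn subgraph
(nodes = (k−1)-mers, edge (u,v) = the k-mer u+v[-1]) is built per seed
k-mer from only the reads containing that seed in any circular rotation.
Each read adds at most 1 to each edge it supports, so repetitive reads
cannot inflate weights. The subgraph restriction is not just a speed
device: it enforces read-level co-occurrence between the seed and every
edge, which matters again below.

## Cycle search

`find_cycle` is a greedy depth-first search for a closed walk of exactly
L edges: children are tried in descending edge-weight order (ties broken
lexicographically — determinism), zero-weight edges are untraversable,
dead ends backtrack. Nodes and edges may repeat within a walk, because a
barcode containing a repeated (k−1)-mer or k-mer legitimately revisits
them. Closure validity is tiered:

1. **strict** — the spelled circle is aperiodic and no edge is used on
   two circularly consecutive steps;
2. **periodic allowed** — a genuinely periodic barcode (period d | L)
   *only* exists as its d-loop traversed L/d times;
3. **unrestricted** — a barcode carrying a ≥ (k+1) homopolymer run
   legitimately stutters on its self-loop.

`extract_cycles` tries the tiers in order, so degenerate closures are
found only when no strict one exists. Without the strict tier,
near-repetitive barcodes close short heavy loops that decode to spurious
periodic strings while draining the true cycle's weight; without the
laxer tiers, periodic barcodes (expected ≈ 0.12 per 500 random 12-mers)
and long-homopolymer barcodes would be uncallable. After each extracted
cycle, its capacity (minimum edge weight at extraction time) is
subtracted from every distinct edge on it — breaking the cycle at its
weakest edge while removing its contribution to shared edges — and the
search repeats up to the per-subgraph depth.

### Seed schedule

Seeds are taken in descending count order; the search *breadth* is the
number of subgraphs actually searched (default 1000). A candidate seed
already explained by a confidently called barcode — contained in the
exact/truncated/extended k-mer sets of a strict-tier call whose support
is at least a quarter (`MARK_GATE_FRACTION`) of the best so far — is
skipped without consuming budget. This matters because at k = 7 the
count spectrum is dominated by k-mers shared between barcodes: a literal
top-N policy re-finds the most abundant cells hundreds of times while a
cell whose k-mers are shared with nobody never ranks at all. Leftover
budget is then spent revisiting skipped seeds that lie on no extracted
cycle (retired only by collision with another barcode's variant
k-mers). Only strict-tier, well-supported calls retire seeds: a
degenerate-tier find may be a shadow of a barcode not yet discovered and
must not block it. Subgraphs are processed sequentially in this fixed
order whatever the `threads` setting (the search is pure Python and
interpreter-bound), so results are exactly reproducible and trivially
independent of thread count.

### Phase resolution

A cyclic path has no starting position. Error-free reads produce
EXACT-variant k-mers whose recorded offset equals the k-mer's true
barcode position, so every EXACT posting of every cycle k-mer votes for
one rotation with weight 1. The true rotation is supported coherently by
all L k-mers (≈ L × abundance votes) while a k-mer shared with an
unrelated, even more abundant, barcode scatters its votes — weighted
voting is robust where per-k-mer winner-take-all is not. Ties go to the
lexicographically smaller rotation; paths with no offset evidence fall
back to the smallest rotation and are flagged.

## Scoring pooled candidates

Cycles from all subgraphs are pooled and deduplicated by decoded
barcode. Two subtleties make the extraction-time capacity unsuitable
for ranking the pool. First, it is order-dependent: a cycle first
reached in an already-drained subgraph records an arbitrarily low
value. Second, any per-edge statistic — even restricted to co-occurrence
with an anchor k-mer — lets a *chimeric* cycle whose k-mers are each
borrowed from a different abundant barcode score at full abundance.
Pooled paths are therefore re-scored with their **cycle support**: the
number of reads whose three-variant k-mer sets contain *every* k-mer on
the cycle. A real barcode keeps roughly its error-free read count
(× e^−λ under Poisson(λ) errors); a chimera is carried whole by no read
and collapses to ~0. The extraction-time value is retained as
`extraction_capacity`.

A final **absorption filter** removes candidates that are artifacts of a
single real barcode's own reads: if every circle k-mer of X lies within
the exact/truncated/extended k-mer sets of rival Y — a containment two
independent random barcodes essentially cannot satisfy — X is a
truncated circle padded back to length L, or a doubled repeat, of Y.
Which member of such a pair is real is decided by strength: cycle
support first, then minimum EXACT-variant read support (a pad artifact's
junction k-mers never occur in any read's exact circle, while a real
barcode's exact support equals its abundance), with the lexicographically
smaller barcode kept on full ties. Degenerate-tier candidates are
absorbed by any strict-tier rival carrying at least half their support —
a quarter-strength shadow cannot absorb its source, which protects a
genuine periodic barcode from garbage derived from its own reads.

## Knee thresholding

Accepted barcodes are those whose capacity exceeds the knee of the
rank-ordered cumulative capacity curve. The curve is smoothed with a
Savitzky-Golay filter (window 101 ranks or the largest odd number ≤ n,
polynomial order 3 — the filter is forgiving of these choices and both
are overridable). On a descending-rank cumulative curve the first
derivative is the sorted capacity sequence itself — monotone — so the
knee is located where that derivative *falls* fastest (the interior
maximum of curvature magnitude), refined on the unsmoothed capacities to
the largest single-step drop nearby; the threshold is the first capacity
below the drop and acceptance is strictly-above, excluding the
transition value itself. All interior curvature peaks are exposed in the
diagnostic trace, along with rank/capacity/cumulative/smoothed/derivative
columns as TSV. Degenerate inputs raise: fewer points than the window
(advising a smaller one), or a curve with no interior bend (all
capacities equal). The threshold uses no prior cell count anywhere —
that is the method's point.

## Read assignment

Default mode assigns each read to the unique consensus barcode at
minimum Levenshtein distance, unassigned on ties or distance >
`max_dist` (default 2 for L = 12, the largest radius at which random
12-mer collisions stay rare). k-mer mode counts shared k-mer strings
between the read's three-variant circular k-mers and each consensus's
EXACT circular k-mers (a consensus has no errors to absorb), requiring a
unique maximum of ≥ `min_shared` (default 2); assigning with a larger k
than the graph search used trades yield for stringency. Levenshtein is
the conservative default: on simulated data it strictly trades
misassignments for unassigned reads relative to k-mer mode. Distances
are computed with edlib; batch assignment prefilters candidates to
barcodes sharing at least one circular 5-mer with the read, which is
lossless for edit distance ≤ 2 on 12-nt barcodes (two errors leave a
clean circular gap of ≥ 5 bases) and exact for k-mer mode (a
zero-overlap barcode cannot win).

## The simulator, and what passing it does not show

`generate_dataset` emulates the benchmark conditions the caller is
characterized under: N ground-truth random distinct 12-mers (N itself
drawn Normal(500, 50) when unspecified); per-barcode abundances drawn
Normal(200, 20) reads/cell (clipped at one read), uniform, or
Exponential(scale 0.2), normalized to a simplex; 100,000 reads per
dataset; each read carries Poisson(λ) errors, λ ∈ [0, 3], of type
insertion / deletion / mismatch / any (uniform mix), at uniform-random
window positions. Deletions shift random filler bases in and insertions
shift bases out, so emitted windows are always exactly L — as in a real
read — and deletions beyond the 8-base filler are dropped as
unobservable. The standard grid (3 abundance distributions × 4 error
types × λ ∈ {0, 0.5, 1, 2, 3} × 3 replicates) comprises 180 datasets.
Everything is reproducible from one seed; the FASTQ output is
byte-identical across runs.

The simulator does not model sequencing quality scores, PCR
duplication, UMI collisions, barcode-synthesis phasing, or
position-dependent error profiles; real data also violates the
independent-uniform error-position assumption. Passing the benchmark
therefore demonstrates correctness of the graph construction, search,
thresholding, and assignment under the stated error model — not
end-to-end accuracy on any particular instrument's output.

The `naive_baseline` comparison arm counts exact observed windows,
thresholds the count-vs-rank curve with the same knee procedure, and
assigns reads by exact match only. Its knee is applied only when
material (first rejected count < half the last accepted): an error-free
dataset has no low-count tail, and thresholding inside the single
plateau would split real cells on sampling noise.

## Defaults, units, and parameters that matter

| parameter | default | meaning |
|---|---|---|
| `k` | 8 (library), 7 in the benchmark | graph k-mer size; ≥ 8 recommended for L = 12; smaller k uses more error-containing reads but adds spurious edges |
| `breadth` | 1000 | subgraphs searched |
| `depth` | 5 | cycles extracted per subgraph |
| `subsample_size` | 500,000 reads | reads indexed |
| `knee window` | 101 ranks (auto-shrunk) | Savitzky-Golay window |
| `max_dist` | 2 | Levenshtein assignment radius |
| `min_shared`, `k_assign` | 2, = k | k-mer assignment stringency |
| `MARK_GATE_FRACTION` | 0.25 | support (relative to best call) above which a call retires its seed k-mers |

## Known limitations

* Barcodes that are exactly periodic with period ≤ 2 or that consist of
  a single homopolymer cannot be distinguished from their degenerate
  roots; barcodes within a deletion+pad of each other (one equals
  another's truncated circle plus one base) confound the absorption
  filter — both configurations have probability ≈ 10⁻³ or less per
  500-barcode experiment.
* Exponentially distributed abundances obscure the knee (low-abundance
  true cells meet the spurious tail); recovery degrades there by
  design of the problem, not of the implementation.
* The index holds postings in memory; at the default 500k-read
  subsample this is a few GB. Larger experiments should subsample —
  the k-mer spectrum saturates long before the read count does.
* Benchmark problem sizes used by the test suite and the acceptance
  script (500 cells × 100k reads, λ ∈ {0, 1}) complete in a few minutes
  on one CPU; the full 180-dataset grid is provided as configuration
  but not run by default.
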