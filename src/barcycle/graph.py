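"""Per-start-k-mer de Bruijn subgraphs and greedy fixed-length cycle search.

Nodes are (k-1)-mers, a directed edge (u, v) is the k-mer u + v[-1], and
edge weights count how many reads support the k-mer (each read contributes
at most 1 to any edge, so a repetitive read cannot dominate).  Because the
k-mers come from *circularized* barcodes, a true barcode of length L shows
up as a heavy cyclic path of exactly L edges; spurious overlaps between
unrelated barcodes form cycles too, but with far lower capacity (the
minimum edge weight along the cycle), which is what the knee filter later
exploits.

Rather than one graph of the whole dataset, a small subgraph is built per
seed k-mer from only the reads containing that k-mer (in any circular
rotation) — the subgraphs are independent and cheap to search.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from .circkmer import BarcodeWindow, VariantKind, three_variant_kmers
from .errors import InvalidParameterError, NotFoundError
from .kmer_index import KmerIndex, build_index, top_kmers

Edge = tuple[str, str]

#: a called barcode retires its k-mers from seeding only when its cycle
#: support reaches this fraction of the best call so far (uncertain calls
#: must not block future exploration of their k-mers)
MARK_GATE_FRACTION = 0.25


@dataclass
class DeBruijnSubgraph:
    k: int
    edges: dict[Edge, int]
    start_kmer: str

    @property
    def nodes(self) -> set[str]:
        out: set[str] = set()
        for u, v in self.edges:
            out.add(u)
            out.add(v)
        return out

    def adjacency(self) -> dict[str, list[tuple[str, int]]]:
        """Children per node, sorted heaviest-first (ties lexicographic)."""
        adj: dict[str, list[tuple[str, int]]] = {}
        for (u, v), w in self.edges.items():
            if w > 0:
                adj.setdefault(u, []).append((v, w))
        for u in adj:
            adj[u].sort(key=lambda vw: (-vw[1], vw[0]))
        return adj

    def to_dot(self) -> str:
        """Graphviz DOT dump for debugging/visualization."""
        lines = ["digraph debruijn {"]
        for (u, v), w in sorted(self.edges.items()):
            if w > 0:
                lines.append(f'  "{u}" -> "{v}" [label={w}, weight={w}];')
        lines.append("}")
        return "\n".join(lines)


@dataclass
class CyclicPath:
    """A length-L closed walk and the barcode it decodes to.

    ``capacity`` is the minimum edge weight along the walk *at extraction
    time* (extraction decrements weights, so later paths see the residual
    graph).  ``barcode`` is filled in by :func:`linearize`; until then it
    is the lexicographically smallest rotation of the spelled circle.
    """

    nodes: list[str]
    capacity: int
    start_kmer: str
    barcode: Optional[str] = None
    phase_flagged: bool = field(default=False)
    #: capacity at extraction time within the (possibly drained) subgraph;
    #: ``capacity`` itself is re-scored against the full dataset when paths
    #: are pooled by call_barcodes
    extraction_capacity: Optional[int] = None
    #: which closure-validity tier found this cycle (1 = strict); laxer
    #: tiers exist for periodic / homopolymer barcodes and their finds are
    #: treated as less trustworthy during seed retirement
    closure_tier: int = 1

    @property
    def circular_sequence(self) -> str:
        """The L-character circular string spelled by the cycle."""
        return "".join(n[0] for n in self.nodes)

    @property
    def length(self) -> int:
        return len(self.nodes)

    def cycle_kmers(self) -> list[str]:
        """The L k-mers along the cycle; k-mer i starts at circle position i."""
        s = self.circular_sequence
        doubled = s + s
        k = len(self.nodes[0]) + 1
        return [doubled[i : i + k] for i in range(len(s))]


def _rotations(kmer: str) -> list[str]:
    doubled = kmer + kmer
    return [doubled[i : i + len(kmer)] for i in range(len(kmer))]


def _is_periodic(s: str) -> bool:
    """True if s is a whole number (>1) of repeats of a shorter string."""
    n = len(s)
    return any(n % d == 0 and s == s[:d] * (n // d) for d in range(1, n // 2 + 1))


def _no_stutter(nodes: list[str]) -> bool:
    """No edge used on two circularly consecutive steps (self-loop stutter)."""
    edges = list(zip(nodes, nodes[1:] + nodes[:1]))
    return all(edges[i] != edges[i - 1] for i in range(len(edges)))


def _valid_closure(nodes: list[str]) -> bool:
    """Strict closure validity: aperiodic spelling and no edge stutter.

    Two artifact families spell high-capacity cycles that are not
    barcodes: (i) a shorter heavy loop traversed a whole number of times
    (periodic spelling), and (ii) a barcode's own *truncated* circle
    padded back to length L by stuttering on a homopolymer self-loop,
    which requires the same edge on two circularly consecutive steps.
    Genuine barcode cycles need neither — unless the barcode itself is
    periodic or carries a long homopolymer run, which is why extraction
    falls back to the laxer tiers when no strict closure exists.
    """
    return not _is_periodic("".join(n[0] for n in nodes)) and _no_stutter(nodes)


#: closure-validity tiers tried in order by extract_cycles: strict first
#: (aperiodic, no stutter), then periodic barcodes (a period-d circle's only
#: L-closure is its d-loop traversed L/d times), then unrestricted (a
#: >=(k+1)-homopolymer barcode legitimately stutters on its self-loop)
CLOSURE_TIERS = (_valid_closure, _no_stutter, lambda nodes: True)


def _read_edges(
    window: BarcodeWindow, k: int, cache: Optional[dict] = None
) -> tuple[Edge, ...]:
    """Distinct de Bruijn edges a read supports (N-free k-mers only)."""
    if cache is not None:
        hit = cache.get(window.read_id)
        if hit is not None:
            return hit
    edges = tuple(
        {
            (pk.kmer[:-1], pk.kmer[1:])
            for pk in three_variant_kmers(window, k)
            if not pk.contains_n
        }
    )
    if cache is not None:
        cache[window.read_id] = edges
    return edges


def build_subgraph(
    start_kmer: str,
    index: KmerIndex,
    reads: Optional[Mapping[object, BarcodeWindow]] = None,
    edge_cache: Optional[dict] = None,
) -> DeBruijnSubgraph:
    """Build the de Bruijn subgraph of all reads containing ``start_kmer``.

    Reads are pulled in if they contain the seed k-mer in *any* of its
    circular rotations; each read contributes at most 1 to each edge.

    Raises
    ------
    NotFoundError
        If the seed k-mer has no postings in the index.
    """
    if len(start_kmer) != index.k:
        raise InvalidParameterError(
            f"start_kmer length {len(start_kmer)} != index k={index.k}"
        )
    if start_kmer not in index:
        raise NotFoundError(start_kmer)
    if reads is None:
        reads = index.windows
    read_ids: set = set()
    for rot in _rotations(start_kmer):
        for rid, _kind, _off in index.entries.get(rot, ()):
            read_ids.add(rid)
    weights: Counter = Counter()
    for rid in read_ids:
        window = reads.get(rid)
        if window is None:
            continue
        weights.update(_read_edges(window, index.k, edge_cache))
    return DeBruijnSubgraph(k=index.k, edges=dict(weights), start_kmer=start_kmer)


def find_cycle(
    graph: DeBruijnSubgraph,
    start_node: str,
    length: int,
    closure_valid=_valid_closure,
) -> Optional[CyclicPath]:
    """Greedy depth-first search for the first closed walk of ``length`` edges.

    Children are explored in descending edge-weight order (ties broken
    lexicographically by child label); zero-weight edges are never
    traversed; dead ends backtrack.  Nodes and edges may repeat within a
    walk — a barcode containing a repeated (k-1)-mer or k-mer
    legitimately revisits them — but a closure whose spelled circle is
    *periodic* (a shorter loop traversed multiple times) is rejected and
    the search continues: near-repetitive barcodes otherwise close short
    heavy loops that decode to spurious periodic sequences while
    draining the true cycle's weight.  Returns ``None`` if no
    (aperiodic) walk of the requested length exists from ``start_node``.
    """
    if length < 2:
        raise InvalidParameterError("cycle length must be >= 2")
    adj = graph.adjacency()
    if start_node not in graph.nodes:
        raise InvalidParameterError(f"start node {start_node!r} not in subgraph")

    path = [start_node]

    def dfs(node: str, remaining: int) -> bool:
        for child, _w in adj.get(node, ()):
            if remaining == 1:
                if child == start_node and closure_valid(path):
                    return True
                continue
            path.append(child)
            if dfs(child, remaining - 1):
                return True
            path.pop()
        return False

    if not dfs(start_node, length):
        return None
    nodes = list(path)
    edges = list(zip(nodes, nodes[1:] + nodes[:1]))
    capacity = min(graph.edges[e] for e in edges)
    cyc = CyclicPath(nodes=nodes, capacity=capacity, start_kmer=graph.start_kmer)
    cyc.barcode = min(_rotations(cyc.circular_sequence))
    return cyc


def extract_cycles(
    graph: DeBruijnSubgraph, start_node: str, length: int, max_paths: int = 5
) -> list[CyclicPath]:
    """Repeatedly extract cycles, decrementing edge weights by each capacity.

    After each cycle is found, its capacity is subtracted from every
    distinct edge on it; the minimum-weight edge drops to 0, breaking the
    cycle, while the cycle's contribution to shared edges is removed.
    Stops when no further cycle exists or ``max_paths`` have been taken.
    The graph is mutated in place (callers inspect the residual).
    """
    if max_paths < 1:
        raise InvalidParameterError("max_paths must be >= 1")
    out: list[CyclicPath] = []
    while len(out) < max_paths:
        cyc = None
        for tier_no, tier in enumerate(CLOSURE_TIERS, start=1):
            cyc = find_cycle(graph, start_node, length, closure_valid=tier)
            if cyc is not None:
                cyc.closure_tier = tier_no
                break
        if cyc is None:
            break
        # decrement each distinct edge once (a walk may legitimately reuse
        # an edge when the barcode contains a repeated k-mer)
        for e in set(zip(cyc.nodes, cyc.nodes[1:] + cyc.nodes[:1])):
            graph.edges[e] -= cyc.capacity
        out.append(cyc)
    return out


def linearize(path: CyclicPath, index: KmerIndex) -> str:
    """Resolve a cycle's rotational phase into a linear barcode.

    A cyclic path has no intrinsic starting position.  Error-free reads,
    however, produce EXACT-variant k-mers whose recorded circular offset
    equals the k-mer's true position in the barcode, so every EXACT
    posting of every cycle k-mer votes for one rotation with weight 1.
    The true rotation is supported coherently by all L k-mers, while a
    k-mer shared with an unrelated (even more abundant) barcode scatters
    its votes across rotations, so count-weighted voting is robust where
    a per-k-mer winner-take-all would not be.  Ties go to the
    lexicographically smaller string; with no offset evidence at all the
    smallest rotation is returned and the path is flagged.
    """
    s = path.circular_sequence
    L = len(s)
    votes: Counter = Counter()
    for i, kmer in enumerate(path.cycle_kmers()):
        for _rid, kind, off in index.entries.get(kmer, ()):
            if kind is VariantKind.EXACT:
                votes[(i - off) % L] += 1
    if not votes:
        path.phase_flagged = True
        path.barcode = min(_rotations(s))
        return path.barcode
    top = votes.most_common()
    best_n = top[0][1]
    doubled = s + s
    candidates = [doubled[r : r + L] for r, n in top if n == best_n]
    path.phase_flagged = False
    path.barcode = min(candidates)
    return path.barcode


def call_barcodes(
    reads: Iterable[BarcodeWindow],
    k: int,
    L: int,
    breadth: int = 1000,
    depth: int = 5,
    seed: int = 0,
    subsample_size: int = 500_000,
    index: Optional[KmerIndex] = None,
    threads: int = 1,
) -> list[CyclicPath]:
    """End-to-end candidate-barcode search: index, seed, search, pool.

    Seed k-mers are drawn from the index in descending count order; a
    subgraph is built per seed and up to ``depth`` cycles of length ``L``
    extracted from it.  ``breadth`` is the number of subgraphs actually
    searched, and the budget is spent in two passes:

    1. A seed whose k-mer is already *explained* by a confidently called
       barcode (cycle support at least ``MARK_GATE_FRACTION`` of the
       best seen so far) is skipped without consuming budget, so the
       search keeps moving into unexplained parts of the k-mer spectrum
       instead of re-finding the most abundant barcodes.
    2. Remaining budget revisits skipped seeds that lie on *no*
       extracted cycle: a k-mer retired only by collision with another
       barcode's variant k-mers may still be the sole entry point to an
       as-yet-unseen cell.

    All cycles are linearized and pooled, deduplicating cycles that
    decode to the same barcode; pooled paths are then re-scored with
    their cycle support (reads carrying the whole circle).
    Subgraph searches run sequentially whatever ``threads`` is — the
    search is pure Python and interpreter-bound, and a fixed order keeps
    results exactly reproducible — so outputs never depend on it.
    """
    if k > L - 1:
        raise InvalidParameterError(f"k must be <= L-1; got k={k}, L={L}")
    if index is None:
        index = build_index(reads, k=k, subsample_size=subsample_size, seed=seed)
    seeds = top_kmers(index, len(index))
    edge_cache: dict = {}

    def search(seed_kmer: str) -> list[CyclicPath]:
        sub = build_subgraph(seed_kmer, index, edge_cache=edge_cache)
        start_node = seed_kmer[:-1]
        if start_node not in sub.nodes:
            return []
        cycles = extract_cycles(sub, start_node, L, max_paths=depth)
        for c in cycles:
            linearize(c, index)
        return cycles

    covered: set[str] = set()
    on_cycle: set[str] = set()
    all_cycles: list[CyclicPath] = []
    searched = 0
    best_anchor = 0
    skipped: list[str] = []

    def consume(seed_kmer: str) -> None:
        nonlocal searched, best_anchor
        searched += 1
        for c in search(seed_kmer):
            all_cycles.append(c)
            on_cycle.update(c.cycle_kmers())
            cap = cycle_support(c, index)
            best_anchor = max(best_anchor, cap)
            # only confidently called, strictly-valid cycles retire seeds:
            # a lax-tier find may be a degenerate shadow of a barcode not
            # yet discovered, and must not block its discovery
            if c.closure_tier == 1 and cap >= max(
                2, MARK_GATE_FRACTION * best_anchor
            ):
                covered.update(_explained_kmers(c.barcode, k))

    for seed_kmer in seeds:
        if searched >= breadth:
            break
        if seed_kmer in covered:
            skipped.append(seed_kmer)
            continue
        consume(seed_kmer)
    for seed_kmer in skipped:
        if searched >= breadth:
            break
        if seed_kmer not in on_cycle:
            consume(seed_kmer)

    best: dict[str, CyclicPath] = {}
    for c in all_cycles:
        cur = best.get(c.barcode)
        if cur is None or c.capacity > cur.capacity:
            best[c.barcode] = c
    # Re-score each pooled path with its full read support: a cycle first
    # reached in an already-drained subgraph records an arbitrarily low
    # extraction capacity, and per-edge weights — even restricted to
    # co-occurrence with one anchor k-mer — let a chimeric cycle whose
    # k-mers are each borrowed from a *different* abundant barcode score
    # as highly as a real one.  Counting only reads that carry the whole
    # cycle keeps a real barcode at (roughly) its error-free read count
    # while chimeras collapse to zero.
    pooled = list(best.values())
    for c in pooled:
        c.extraction_capacity = c.capacity
        c.capacity = cycle_support(c, index)
    pooled.sort(key=lambda c: (-c.capacity, c.barcode))

    # Absorption filter: a candidate whose circle k-mers are all contained
    # in the variant k-mers (exact/truncated/extended circles) of another
    # candidate is an artifact of that barcode's own reads — a truncated
    # circle padded back to length L, or a doubled repeat — never an
    # independent cell: two random barcodes essentially cannot satisfy
    # the containment.  Which member of a containment pair is the real
    # barcode is decided by strength: capacity first, then minimum
    # EXACT-variant support (a pad artifact's junction k-mers are never
    # seen in any read's exact circle, while a real barcode's exact
    # support equals its abundance).  A lax-tier (periodic/stuttering)
    # find contained in a strict find is dropped outright provided the
    # absorber carries comparable support — a quarter-strength shadow
    # cannot absorb its source.
    owners: dict[str, set[int]] = {}
    for i, c in enumerate(pooled):
        for kmer in _explained_kmers(c.barcode, index.k):
            owners.setdefault(kmer, set()).add(i)
    strength = {
        i: (c.capacity, _min_exact_support(c, index), c.barcode)
        for i, c in enumerate(pooled)
    }
    kept: list[CyclicPath] = []
    for i, c in enumerate(pooled):
        absorbers: Optional[set[int]] = None
        for kmer in set(c.cycle_kmers()):
            ids = owners.get(kmer, set())
            absorbers = set(ids) if absorbers is None else absorbers & ids
            if not absorbers:
                break
        absorbers = (absorbers or set()) - {i}
        absorbed = False
        for j in absorbers:
            cj = pooled[j]
            if (
                c.closure_tier >= 2
                and cj.closure_tier == 1
                and 2 * cj.capacity >= c.capacity
            ):
                absorbed = True
                break
            sj, si = strength[j], strength[i]
            # strictly stronger wins; at full ties the lexicographically
            # smaller barcode is kept (deterministic, arbitrary)
            if (sj[0], sj[1]) > (si[0], si[1]) or (
                (sj[0], sj[1]) == (si[0], si[1]) and sj[2] < si[2]
            ):
                absorbed = True
                break
        if not absorbed:
            kept.append(c)
    return kept


def _min_exact_support(path: CyclicPath, index: KmerIndex) -> int:
    """Minimum over cycle k-mers of distinct reads with EXACT-variant postings."""
    support = []
    for kmer in set(path.cycle_kmers()):
        support.append(
            len(
                {
                    rid
                    for rid, kind, _o in index.entries.get(kmer, ())
                    if kind is VariantKind.EXACT
                }
            )
        )
    return min(support) if support else 0


def _explained_kmers(barcode: str, k: int) -> set[str]:
    """Every k-mer a called barcode's error-free reads would produce.

    Used to retire seed candidates: not just the exact circle's k-mers
    but also the truncated- and extended-variant seam k-mers, which are
    equally abundant and would otherwise waste search budget rediscovering
    the same barcode.
    """
    out: set[str] = set()
    for seq in (
        barcode,
        barcode[:-1],
        *(barcode + n for n in "ACGT"),
    ):
        doubled = seq + seq
        out.update(doubled[i : i + k] for i in range(len(seq)))
    return out


def cycle_support(path: CyclicPath, index: KmerIndex) -> int:
    """Number of reads whose variant k-mers contain *every* cycle k-mer.

    An error-free read of a barcode carries the barcode's whole circle,
    so a true path's support is about its error-free read count; a cycle
    stitched together from the k-mers of several unrelated barcodes is
    carried in full by no read at all.
    """
    supports = sorted(
        (
            {rid for rid, _k, _o in index.entries.get(kmer, ())}
            for kmer in set(path.cycle_kmers())
        ),
        key=len,
    )
    common = supports[0]
    for s in supports[1:]:
        common = common & s
        if not common:
            break
    return len(common)
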