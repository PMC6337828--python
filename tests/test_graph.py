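"""de Bruijn subgraph construction and greedy fixed-length cycle extraction."""

import random

import pytest

from barcycle import (
    BarcodeWindow,
    SimulationConfig,
    VariantKind,
    build_index,
    build_subgraph,
    call_barcodes,
    extract_cycles,
    find_cycle,
    generate_dataset,
    linearize,
    three_variant_kmers,
    top_kmers,
    windows,
)
from barcycle.errors import NotFoundError
from barcycle.graph import CyclicPath, DeBruijnSubgraph, _valid_closure


def cycle_graph(barcode, k=7, weight=100, start_kmer=None):
    """Hand-built subgraph containing exactly one barcode's exact cycle."""
    doubled = barcode + barcode
    edges = {}
    for i in range(len(barcode)):
        km = doubled[i : i + k]
        edges[(km[:-1], km[1:])] = weight
    return DeBruijnSubgraph(
        k=k, edges=edges, start_kmer=start_kmer or barcode[:k]
    )


B1 = "ACGGTCAGTTCA"  # aperiodic, all 6-mers distinct
B2 = "ACGGTCGATCCT"  # shares only the leading 6-mer window with B1


class TestBuildSubgraph:
    def test_error_free_reads_form_single_heavy_cycle(self):
        ws = [BarcodeWindow(f"r{i}", B1, "G") for i in range(50)]
        idx = build_index(ws, k=7, subsample_size=50)
        sub = build_subgraph(B1[:7], idx)
        # brute-force oracle: adjacency dict from each read's variant k-mers,
        # one count per read per edge
        oracle = {}
        for w in ws:
            for e in {
                (p.kmer[:-1], p.kmer[1:]) for p in three_variant_kmers(w, 7)
            }:
                oracle[e] = oracle.get(e, 0) + 1
        assert sub.edges == oracle
        doubled = B1 + B1
        for i in range(12):
            km = doubled[i : i + 7]
            assert sub.edges[(km[:-1], km[1:])] >= 50

    def test_absent_start_kmer_raises(self):
        ws = [BarcodeWindow("r", B1, "G")]
        idx = build_index(ws, k=7, subsample_size=1)
        with pytest.raises(NotFoundError):
            build_subgraph("AAAAAAA", idx)

    def test_high_error_rate_still_decodes(self):
        # one barcode, Poisson-3 errors per 12-nt read: the heaviest cycle
        # still spells the true barcode
        cfg = SimulationConfig(n_barcodes=1, n_reads=1000, error_lambda=3.0, seed=4)
        reads, truth = generate_dataset(cfg)
        idx = build_index(windows(reads, 12), k=7, subsample_size=2000)
        seed_kmer = top_kmers(idx, 1)[0]
        sub = build_subgraph(seed_kmer, idx)
        cyc = find_cycle(sub, seed_kmer[:-1], 12)
        assert cyc is not None
        assert linearize(cyc, idx) == truth.barcodes[0]


def random_graph(rng, n_nodes, max_out=3):
    labels = "ABCDEFGHIJKL"[:n_nodes]
    edges = {}
    for u in labels:
        targets = rng.sample(labels, k=rng.randint(1, max_out))
        for v in targets:
            edges[(u, v)] = rng.randint(1, 10)
    return DeBruijnSubgraph(k=2, edges=edges, start_kmer=labels[0] * 2)


def oracle_greedy_first_walk(graph, start, length):
    """Independent oracle: enumerate *all* valid closed walks of the given
    length, then pick the one a greedy heaviest-first DFS would reach first
    (lexicographically minimal sequence of child ranks)."""
    adj = {}
    for (u, v), w in graph.edges.items():
        if w > 0:
            adj.setdefault(u, []).append((v, w))
    for u in adj:
        adj[u].sort(key=lambda vw: (-vw[1], vw[0]))
    rank = {
        (u, v): i for u, lst in adj.items() for i, (v, _w) in enumerate(lst)
    }

    walks = []

    def enum(node, steps, path):
        if steps == length:
            if node == start and _valid_closure(path[:-1]):
                walks.append(list(path[:-1]))
            return
        for v, _w in adj.get(node, ()):
            path.append(v)
            enum(v, steps + 1, path)
            path.pop()

    enum(start, 0, [start])
    if not walks:
        return None
    keyed = [
        (tuple(rank[(w[i], w[(i + 1) % length])] for i in range(length)), w)
        for w in walks
    ]
    return min(keyed)[1]


class TestFindCycle:
    def test_single_cycle_uniform_weight(self):
        g = cycle_graph(B1, weight=7)
        cyc = find_cycle(g, B1[:6], 12)
        assert cyc is not None
        assert cyc.capacity == 7
        assert len(cyc.nodes) == 12

    def test_heavy_cycle_beats_light_detour(self):
        g = cycle_graph(B1, weight=100)
        # light branch sharing nodes with the heavy cycle
        g.edges[(B1[3:9], "XXXXXX")] = 1
        g.edges[("XXXXXX", B1[4:10])] = 1
        cyc = find_cycle(g, B1[:6], 12)
        expected = oracle_greedy_first_walk(g, B1[:6], 12)
        assert cyc.nodes == expected
        assert "XXXXXX" not in cyc.nodes
        assert cyc.capacity == 100

    def test_no_cycle_of_requested_length(self):
        # a 10-cycle admits no aperiodic 12-step closure
        g = cycle_graph("ACGGTCAGTT", k=7)
        assert find_cycle(g, "ACGGTC", 12) is None

    def test_matches_brute_force_on_random_graphs(self):
        agreements = 0
        for i in range(120):
            rng = random.Random(i)
            g = random_graph(rng, n_nodes=rng.randint(4, 12))
            start = "A"
            got = find_cycle(g, start, 6)
            want = oracle_greedy_first_walk(g, start, 6)
            if want is None:
                assert got is None
            else:
                assert got is not None and got.nodes == want
            agreements += 1
        assert agreements == 120


class TestExtractCycles:
    def make_disjoint_two_cycle_graph(self):
        g1 = cycle_graph(B1, weight=100)
        g2 = cycle_graph(B2, weight=40)
        edges = dict(g1.edges)
        edges.update(g2.edges)
        return DeBruijnSubgraph(k=7, edges=edges, start_kmer=B1[:7])

    def test_two_disjoint_cycles_extracted_heavier_first(self):
        g = self.make_disjoint_two_cycle_graph()
        start = B1[:6]  # shared leading window of both barcodes
        cycles = extract_cycles(g, start, 12, max_paths=5)
        assert [c.capacity for c in cycles] == [100, 40]

    def test_termination_on_exhaustion(self):
        g = cycle_graph(B1, weight=5)
        cycles = extract_cycles(g, B1[:6], 12, max_paths=5)
        assert len(cycles) == 1

    def test_decrement_drives_min_edge_to_zero_and_conserves_weight(self):
        g = self.make_disjoint_two_cycle_graph()
        total_before = sum(g.edges.values())
        cycles = extract_cycles(g, B1[:6], 12, max_paths=5)
        removed = total_before - sum(g.edges.values())
        assert removed == sum(c.capacity * 12 for c in cycles)
        assert all(w >= 0 for w in g.edges.values())
        for c in cycles:
            cycle_edges = list(zip(c.nodes, c.nodes[1:] + c.nodes[:1]))
            assert min(g.edges[e] for e in cycle_edges) == 0


class TestLinearize:
    def test_phase_correct_for_every_rotation(self):
        ws = [BarcodeWindow(f"r{i}", B1, "G") for i in range(30)]
        idx = build_index(ws, k=7, subsample_size=30)
        doubled = B1 + B1
        for r in range(12):
            nodes = [doubled[r + i : r + i + 6] for i in range(12)]
            path = CyclicPath(nodes=nodes, capacity=30, start_kmer=nodes[0] + "X")
            assert linearize(path, idx) == B1

    def test_noisy_reads_still_decode(self):
        cfg = SimulationConfig(n_barcodes=1, n_reads=500, error_lambda=1.0, seed=9)
        reads, truth = generate_dataset(cfg)
        idx = build_index(windows(reads, 12), k=7, subsample_size=1000)
        seed_kmer = top_kmers(idx, 1)[0]
        sub = build_subgraph(seed_kmer, idx)
        cyc = find_cycle(sub, seed_kmer[:-1], 12)
        assert linearize(cyc, idx) == truth.barcodes[0]

    def test_no_evidence_falls_back_to_smallest_rotation(self):
        idx = build_index([BarcodeWindow("r", B2, "A")], k=7, subsample_size=1)
        doubled = B1 + B1
        nodes = [doubled[i : i + 6] for i in range(12)]
        path = CyclicPath(nodes=nodes, capacity=1, start_kmer=B1[:7])
        out = linearize(path, idx)
        assert path.phase_flagged
        assert out == min(doubled[i : i + 12] for i in range(12))


class TestCallBarcodes:
    def test_single_barcode_breadth_one(self):
        ws = [BarcodeWindow(f"r{i}", B1, "G") for i in range(40)]
        paths = call_barcodes(ws, k=7, L=12, breadth=1, depth=5)
        assert any(p.barcode == B1 for p in paths)

    def test_duplicate_paths_pooled(self):
        ws = [BarcodeWindow(f"r{i}", B1, "G") for i in range(40)]
        paths = call_barcodes(ws, k=7, L=12, breadth=30, depth=5)
        barcodes = [p.barcode for p in paths]
        assert len(barcodes) == len(set(barcodes))

    def test_three_well_separated_barcodes(self):
        cfg = SimulationConfig(n_barcodes=3, n_reads=3000, error_lambda=0.0, seed=2)
        reads, truth = generate_dataset(cfg)
        paths = call_barcodes(windows(reads, 12), k=7, L=12, breadth=50, depth=5)
        top3 = {p.barcode for p in paths[:3]}
        assert top3 == set(truth.barcodes)
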