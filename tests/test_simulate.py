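"""Synthetic read generator, scoring, and the naive comparison pipeline."""

import numpy as np
import pytest
from scipy import stats

from barcycle import (
    Abundance,
    ErrorType,
    SimulationConfig,
    benchmark_grid,
    generate_dataset,
    hamming,
    levenshtein,
    naive_baseline,
    score_barcodes,
    windows,
    write_fastq,
)
from barcycle.simulate import _corrupt


class TestGenerateDataset:
    def test_error_free_windows_equal_origin(self):
        cfg = SimulationConfig(n_barcodes=10, n_reads=500, error_lambda=0.0, seed=1)
        reads, truth = generate_dataset(cfg)
        for r in reads:
            assert r.window(12).bases == truth.read_origins[r.read_id]

    def test_single_deletion_geometry(self):
        # one deletion: the window stays length L, the downstream base
        # shifts in, edit distance stays small while hamming blows up
        rng = np.random.default_rng(0)
        for _ in range(200):
            bc = "".join(rng.choice(list("ACGT"), 12))
            filler = "".join(rng.choice(list("ACGT"), 8))
            seq, applied = _corrupt(bc + filler, 12, 1, ErrorType.DELETION, rng)
            window = seq[:12]
            assert len(window) == 12
            assert applied[0][0] == "deletion"
            assert levenshtein(window, bc) <= 2
            assert hamming(window, bc) >= levenshtein(window, bc)

    def test_insertion_keeps_window_length(self):
        rng = np.random.default_rng(1)
        seq, applied = _corrupt("ACGGTCAGTTCA" + "ACGTACGT", 12, 1,
                                ErrorType.INSERTION, rng)
        assert applied[0][0] == "insertion"
        assert len(seq[:12]) == 12

    def test_seed_determinism_byte_identical_fastq(self, tmp_path):
        cfg = SimulationConfig(n_barcodes=10, n_reads=300, error_lambda=1.0, seed=9)
        for name in ("a.fastq", "b.fastq"):
            reads, _ = generate_dataset(cfg)
            write_fastq(reads, str(tmp_path / name))
        assert (tmp_path / "a.fastq").read_bytes() == (tmp_path / "b.fastq").read_bytes()

    def test_abundance_realization_chi_square(self):
        cfg = SimulationConfig(
            n_barcodes=50, n_reads=100_000, error_lambda=0.0,
            abundance=Abundance.UNIFORM, seed=3,
        )
        reads, truth = generate_dataset(cfg)
        counts = np.zeros(50)
        order = {b: i for i, b in enumerate(truth.barcodes)}
        for r in reads:
            counts[order[truth.read_origins[r.read_id]]] += 1
        _, p = stats.chisquare(counts)
        assert p > 1e-4  # uniform draw should not be wildly off

    def test_error_count_realization(self):
        cfg = SimulationConfig(n_barcodes=20, n_reads=20_000, error_lambda=1.5, seed=4)
        reads, _ = generate_dataset(cfg)
        n_err = np.array([len(r.errors) for r in reads])
        se = np.sqrt(1.5 / len(n_err))
        assert abs(n_err.mean() - 1.5) < 3 * se

    def test_cell_count_drawn_when_unspecified(self):
        cfg = SimulationConfig(n_reads=100, error_lambda=0.0, seed=5)
        _, truth = generate_dataset(cfg)
        assert 300 < len(truth.barcodes) < 700  # Normal(500, 50) draw

    def test_grid_has_180_datasets(self):
        assert len(benchmark_grid()) == 180


class TestScoreBarcodes:
    def make_truth(self):
        cfg = SimulationConfig(n_barcodes=10, n_reads=200, error_lambda=0.0, seed=6)
        _, truth = generate_dataset(cfg)
        return truth

    def test_perfect_call(self):
        truth = self.make_truth()
        r = score_barcodes(truth.barcodes, truth)
        assert (r.tp, r.fp, r.fn) == (len(truth.active_barcodes), 0, 0)

    def test_empty_call(self):
        truth = self.make_truth()
        r = score_barcodes([], truth)
        assert r.tp == 0 and r.fn == len(truth.active_barcodes)

    def test_counting_identities(self):
        truth = self.make_truth()
        called = list(truth.barcodes[:6]) + ["AAAAAAAAAAAA"]
        r = score_barcodes(called, truth)
        assert r.tp + r.fp == len(called)
        assert r.tp + r.fn == len(truth.active_barcodes)


class TestNaiveBaseline:
    def test_error_free_data_identical_to_truth(self):
        cfg = SimulationConfig(n_barcodes=50, n_reads=10_000, error_lambda=0.0, seed=3)
        reads, truth = generate_dataset(cfg)
        called, assignments = naive_baseline(windows(reads, 12), 12)
        assert set(called) == set(truth.barcodes)
        assert all(a.assigned for a in assignments)

    def test_unmatched_window_unassigned(self):
        cfg = SimulationConfig(n_barcodes=20, n_reads=5_000, error_lambda=1.0, seed=8)
        reads, truth = generate_dataset(cfg)
        ws = windows(reads, 12)
        called, assignments = naive_baseline(ws, 12)
        called_set = set(called)
        for a, w in zip(assignments, ws):
            if w.bases not in called_set:
                assert a.barcode == "UNASSIGNED"

    def test_indel_blindness_loses_reads(self):
        # with deletion errors the exact-match arm assigns far fewer reads
        # correctly than perfect assignment would
        cfg = SimulationConfig(
            n_barcodes=20, n_reads=10_000, error_lambda=2.0,
            error_type=ErrorType.DELETION, seed=10,
        )
        reads, truth = generate_dataset(cfg)
        _, assignments = naive_baseline(windows(reads, 12), 12)
        r = score_barcodes([], truth, assignments)
        assert r.correct_fraction < 0.5
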