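"""End-to-end orchestration: index → cycle search → knee → assignment.

One seed drives every stochastic choice; identical inputs and parameters
produce byte-identical outputs regardless of thread count.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .assign import ReadAssigner
from .circkmer import BarcodeWindow
from .errors import EmptyInputError
from .graph import CyclicPath, call_barcodes
from .io import FastqStats, ReadStructure, read_fastq
from .kmer_index import build_index
from .knee import ThresholdResult, find_knee

logger = logging.getLogger("barcycle")


@dataclass
class PipelineParams:
    k: int = 8
    breadth: int = 1000
    depth: int = 5
    subsample_size: int = 500_000
    assign_method: str = "levenshtein"  # conservative default
    k_assign: Optional[int] = None  # None -> same as k
    min_shared: int = 2
    max_dist: int = 2
    knee_window: Optional[int] = None
    threads: int = 1
    seed: int = 0


@dataclass
class PipelineResult:
    paths: list[CyclicPath]
    threshold: ThresholdResult
    accepted: list[CyclicPath]
    assignments: list
    stats: FastqStats = field(default_factory=FastqStats)

    @property
    def barcodes(self) -> list[str]:
        return [p.barcode for p in self.accepted]


def run_on_windows(
    windows: Sequence[BarcodeWindow],
    L: int,
    params: PipelineParams | None = None,
) -> PipelineResult:
    """Run the full caller on already-extracted barcode windows."""
    if params is None:
        params = PipelineParams()
    windows = list(windows)
    if not windows:
        raise EmptyInputError("no barcode windows to process")
    logger.info(
        "indexing %d reads (k=%d, subsample=%d)",
        len(windows), params.k, params.subsample_size,
    )
    index = build_index(
        windows, k=params.k, subsample_size=params.subsample_size, seed=params.seed
    )
    logger.info("searching %d subgraphs, depth %d", params.breadth, params.depth)
    paths = call_barcodes(
        windows,
        k=params.k,
        L=L,
        breadth=params.breadth,
        depth=params.depth,
        seed=params.seed,
        index=index,
        threads=params.threads,
    )
    if not paths:
        raise EmptyInputError("cycle search produced no candidate paths")
    threshold = find_knee([p.capacity for p in paths], window=params.knee_window)
    accepted = [
        p for p in paths if p.capacity > threshold.threshold_capacity
    ]
    logger.info(
        "knee at rank %d (capacity %g): %d of %d paths accepted",
        threshold.knee_rank, threshold.threshold_capacity, len(accepted), len(paths),
    )
    assigner = ReadAssigner(
        [p.barcode for p in accepted],
        method=params.assign_method,
        k_assign=params.k_assign if params.k_assign is not None else params.k,
        min_shared=params.min_shared,
        max_dist=params.max_dist,
    )
    assignments = assigner.assign_all(windows)
    return PipelineResult(
        paths=paths, threshold=threshold, accepted=accepted, assignments=assignments
    )


def run_pipeline(
    fastq: str,
    structure: ReadStructure | None = None,
    params: PipelineParams | None = None,
    out_dir: Optional[str] = None,
) -> PipelineResult:
    """Run the caller on a FASTQ file; optionally write the output tables.

    Writes (when ``out_dir`` is given): ``barcodes.tsv`` (sequence,
    capacity, reads assigned), ``assignments.tsv`` (read, barcode,
    method, score) and ``knee.tsv`` (the threshold diagnostic trace).
    """
    if structure is None:
        structure = ReadStructure()
    stats = FastqStats()
    windows = list(read_fastq(fastq, structure, stats))
    if not windows:
        raise EmptyInputError(f"{fastq}: no usable reads")
    if stats.skipped_short:
        logger.warning("%d reads too short for the barcode window", stats.skipped_short)
    result = run_on_windows(windows, structure.barcode_length, params)
    result.stats = stats
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        _write_outputs(result, out_dir)
    return result


def _write_outputs(result: PipelineResult, out_dir: str) -> None:
    n_assigned: dict[str, int] = {}
    for a in result.assignments:
        if a.assigned:
            n_assigned[a.barcode] = n_assigned.get(a.barcode, 0) + 1
    with open(os.path.join(out_dir, "barcodes.tsv"), "w") as fh:
        fh.write("barcode\tcapacity\tn_reads_assigned\n")
        for p in result.accepted:
            fh.write(f"{p.barcode}\t{p.capacity}\t{n_assigned.get(p.barcode, 0)}\n")
    with open(os.path.join(out_dir, "assignments.tsv"), "w") as fh:
        fh.write("read_id\tbarcode\tmethod\tscore\n")
        for a in result.assignments:
            score = "" if a.score is None else a.score
            fh.write(f"{a.read_id}\t{a.barcode}\t{a.method}\t{score}\n")
    result.threshold.to_tsv(os.path.join(out_dir, "knee.tsv"))
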