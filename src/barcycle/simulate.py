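"""Synthetic Drop-seq-style barcode read simulator and benchmark scoring.

The generator emulates the benchmark conditions used to characterize the
caller: a set of ground-truth random 12-nt barcodes (the number of cells
itself drawn Normal(500, 50) unless fixed), per-barcode relative
abundances drawn from a normal (mean 200, sd 20 reads/cell), uniform, or
exponential (scale 0.2) distribution, and 100,000 reads each carrying a
Poisson number of insertion/deletion/mismatch errors at uniform-random
barcode positions.  Deletions shift downstream filler bases into the
window and insertions shift bases out, so emitted windows are always
exactly L bases — as in a real read, where the instrument reports a
fixed-length window regardless of synthesis errors.

Also provides the exact-match "naive" comparison pipeline (simple window
counting, no circularization — blind to indels) and TP/FP/FN scoring of
any caller's output against the ground truth.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np

from .assign import UNASSIGNED, Assignment
from .circkmer import BarcodeWindow
from .errors import InvalidParameterError, NoKneeError
from .knee import find_knee

BASES = "ACGT"


class ErrorType(Enum):
    INSERTION = "insertion"
    DELETION = "deletion"
    MISMATCH = "mismatch"
    ANY = "any"


class Abundance(Enum):
    NORMAL = "normal"
    UNIFORM = "uniform"
    EXPONENTIAL = "exponential"


@dataclass
class SimulationConfig:
    n_barcodes: Optional[int] = None  # None -> drawn Normal(500, 50)
    barcode_length: int = 12
    n_reads: int = 100_000
    error_lambda: float = 1.0
    error_type: ErrorType = ErrorType.ANY
    abundance: Abundance = Abundance.NORMAL
    #: normal abundance: mean/sd in reads per cell
    abundance_mean: float = 200.0
    abundance_sd: float = 20.0
    #: exponential abundance scale parameter
    exponential_scale: float = 0.2
    #: bases of random filler after the barcode (supplies next_base and
    #: backfills deletions)
    filler_length: int = 8
    replicate: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.error_lambda < 0:
            raise InvalidParameterError("error_lambda must be >= 0")
        if self.n_reads < 1 or self.barcode_length < 2:
            raise InvalidParameterError("n_reads >= 1 and barcode_length >= 2")


@dataclass
class SimulatedRead:
    read_id: str
    sequence: str  # window (L bases) + remaining filler
    errors: list[tuple[str, int]]  # (error type, position at application time)

    def window(self, L: int) -> BarcodeWindow:
        next_base = self.sequence[L] if len(self.sequence) > L else None
        return BarcodeWindow(self.read_id, self.sequence[:L], next_base)


@dataclass
class GroundTruth:
    barcodes: list[str]
    read_origins: dict[str, str]  # read_id -> true barcode
    errors: dict[str, list[tuple[str, int]]]
    config: SimulationConfig

    @property
    def active_barcodes(self) -> set[str]:
        """Barcodes that received at least one read."""
        return set(self.read_origins.values())


@dataclass
class BenchmarkResult:
    tp: int
    fp: int
    fn: int
    n_reads: int = 0
    correct: int = 0
    incorrect: int = 0
    unassigned: int = 0
    per_barcode: dict[str, dict[str, int]] = field(default_factory=dict)

    @property
    def correct_fraction(self) -> float:
        return self.correct / self.n_reads if self.n_reads else float("nan")

    @property
    def incorrect_fraction(self) -> float:
        return self.incorrect / self.n_reads if self.n_reads else float("nan")

    @property
    def unassigned_fraction(self) -> float:
        return self.unassigned / self.n_reads if self.n_reads else float("nan")


def _random_barcodes(rng: np.random.Generator, n: int, L: int) -> list[str]:
    out: set[str] = set()
    while len(out) < n:
        draw = rng.integers(0, 4, size=L)
        out.add("".join(BASES[b] for b in draw))
    return sorted(out)  # sort for order determinism independent of set hashing


def _abundances(rng: np.random.Generator, cfg: SimulationConfig, n: int) -> np.ndarray:
    if cfg.abundance is Abundance.NORMAL:
        w = rng.normal(cfg.abundance_mean, cfg.abundance_sd, size=n)
        w = np.clip(w, 1.0, None)  # a cell contributes at least one read's worth
    elif cfg.abundance is Abundance.UNIFORM:
        w = np.ones(n)
    else:
        w = rng.exponential(cfg.exponential_scale, size=n)
        w = np.clip(w, 1e-9, None)
    return w / w.sum()


def _corrupt(
    seq: str, L: int, n_errors: int, etype: ErrorType, rng: np.random.Generator
) -> tuple[str, list[tuple[str, int]]]:
    """Apply errors to the first-L-bases window of a long sequence."""
    applied: list[tuple[str, int]] = []
    chars = list(seq)
    for _ in range(n_errors):
        kind = etype
        if etype is ErrorType.ANY:
            kind = (ErrorType.INSERTION, ErrorType.DELETION, ErrorType.MISMATCH)[
                rng.integers(0, 3)
            ]
        pos = int(rng.integers(0, L))
        if kind is ErrorType.MISMATCH:
            old = chars[pos]
            alt = [b for b in BASES if b != old]
            chars[pos] = alt[rng.integers(0, 3)]
        elif kind is ErrorType.DELETION:
            # downstream (filler) bases shift into the window; once the
            # filler is exhausted further deletions have nothing to shift
            # in and are unobservable, so they are dropped
            if len(chars) <= L:
                continue
            del chars[pos]
        else:
            chars.insert(pos, BASES[rng.integers(0, 4)])  # shifts bases out
        applied.append((kind.value, pos))
    return "".join(chars), applied


def generate_dataset(
    config: SimulationConfig,
) -> tuple[list[SimulatedRead], GroundTruth]:
    """Emit ``n_reads`` error-bearing reads plus their ground truth.

    Fully reproducible from ``config.seed`` (the replicate number is
    folded into the stream so replicates differ).
    """
    rng = np.random.default_rng((config.seed, config.replicate))
    L = config.barcode_length
    n = config.n_barcodes
    if n is None:
        n = max(1, int(round(rng.normal(500, 50))))
    barcodes = _random_barcodes(rng, n, L)
    probs = _abundances(rng, config, n)
    origins = rng.choice(n, size=config.n_reads, p=probs)
    n_errors = rng.poisson(config.error_lambda, size=config.n_reads)

    reads: list[SimulatedRead] = []
    read_origins: dict[str, str] = {}
    errors: dict[str, list[tuple[str, int]]] = {}
    width = len(str(config.n_reads - 1))
    for i in range(config.n_reads):
        bc = barcodes[origins[i]]
        filler = "".join(
            BASES[b] for b in rng.integers(0, 4, size=config.filler_length)
        )
        seq, applied = _corrupt(bc + filler, L, int(n_errors[i]), config.error_type, rng)
        rid = f"read_{i:0{width}d}"
        # keep the emitted read a fixed L + filler_length bases when possible
        seq = seq[: L + config.filler_length]
        reads.append(SimulatedRead(rid, seq, applied))
        read_origins[rid] = bc
        if applied:
            errors[rid] = applied
    truth = GroundTruth(
        barcodes=barcodes, read_origins=read_origins, errors=errors, config=config
    )
    return reads, truth


#: default Poisson error-rate sweep for the benchmark grid
LAMBDA_SWEEP = (0.0, 0.5, 1.0, 2.0, 3.0)


def benchmark_grid(
    seed: int = 0,
    lambdas: Sequence[float] = LAMBDA_SWEEP,
    replicates: int = 3,
) -> list[SimulationConfig]:
    """The full benchmark grid of simulation conditions.

    Three abundance distributions × four error types × the λ sweep ×
    ``replicates`` — 180 datasets at the defaults.  Each config carries a
    distinct replicate number; all derive from one base seed.
    """
    grid = []
    for abundance in Abundance:
        for etype in ErrorType:
            for lam in lambdas:
                for rep in range(replicates):
                    grid.append(
                        SimulationConfig(
                            error_lambda=lam,
                            error_type=etype,
                            abundance=abundance,
                            replicate=rep,
                            seed=seed,
                        )
                    )
    return grid


def windows(reads: Sequence[SimulatedRead], L: int) -> list[BarcodeWindow]:
    return [r.window(L) for r in reads]


def write_fastq(reads: Sequence[SimulatedRead], path: str) -> None:
    """Write simulated reads as FASTQ (gzipped when path ends in .gz)."""
    import gzip

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")


def write_ground_truth(truth: GroundTruth, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\ttrue_barcode\terrors\n")
        for rid, bc in truth.read_origins.items():
            errs = ";".join(f"{t}@{p}" for t, p in truth.errors.get(rid, []))
            fh.write(f"{rid}\t{bc}\t{errs}\n")


def score_barcodes(
    called: Sequence[str],
    truth: GroundTruth,
    assignments: Optional[Sequence[Assignment]] = None,
) -> BenchmarkResult:
    """Exact set comparison of called vs true barcodes, plus read scoring.

    TP/FN are computed against barcodes that actually received reads; a
    read is correct when assigned to its true origin barcode, incorrect
    when assigned elsewhere, unassigned otherwise.
    """
    active = truth.active_barcodes
    called_set = set(called)
    result = BenchmarkResult(
        tp=len(called_set & active),
        fp=len(called_set - active),
        fn=len(active - called_set),
    )
    if assignments is None:
        return result
    for a in assignments:
        origin = truth.read_origins.get(a.read_id)
        if origin is None:
            continue
        result.n_reads += 1
        per = result.per_barcode.setdefault(
            origin, {"correct": 0, "incorrect": 0, "unassigned": 0}
        )
        if a.barcode == UNASSIGNED:
            result.unassigned += 1
            per["unassigned"] += 1
        elif a.barcode == origin:
            result.correct += 1
            per["correct"] += 1
        else:
            result.incorrect += 1
            per["incorrect"] += 1
    return result


def naive_baseline(
    reads: Sequence[BarcodeWindow], L: int
) -> tuple[list[str], list[Assignment]]:
    """Exact-window-counting comparison pipeline (indel-blind).

    Counts observed (non-circularized) barcode windows, thresholds the
    count-vs-rank curve with the same knee procedure as the main caller,
    and assigns each read to its own window when that window was called.
    When the count curve has no material knee (no low-count error tail,
    e.g. error-free input) every distinct window is kept: with nothing to
    reject, thresholding inside the plateau would split real cells on
    sampling noise alone.
    """
    tally = Counter(w.bases for w in reads)
    ordered = sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))
    counts = [c for _bc, c in ordered]
    called: list[str]
    try:
        window_len = min(101, len(counts) if len(counts) % 2 else len(counts) - 1)
        if window_len < 5:
            raise NoKneeError("too few distinct windows")
        res = find_knee(counts, window=window_len)
        last_accepted = res.sorted_capacities[max(res.knee_rank - 1, 0)]
        if res.threshold_capacity > 0.5 * last_accepted:
            raise NoKneeError("knee not material")
        called = [bc for bc, c in ordered if c > res.threshold_capacity]
    except NoKneeError:
        called = [bc for bc, _c in ordered]
    called_set = set(called)
    assignments = [
        Assignment(
            w.read_id,
            w.bases if w.bases in called_set else UNASSIGNED,
            "exact",
            0 if w.bases in called_set else None,
        )
        for w in reads
    ]
    return called, assignments
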