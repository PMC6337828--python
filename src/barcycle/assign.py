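"""Assigning reads to accepted consensus barcodes.

Two modes:

* k-mer compatibility — a read is assigned to the consensus barcode with
  which its three-variant circular k-mers share the most k-mer strings,
  provided the count reaches ``min_shared`` and the maximum is unique.
  Using a larger k here than in the graph search trades yield for
  stringency.
* Levenshtein — a read is assigned to the unique consensus barcode at
  minimum edit distance, provided that minimum is <= ``max_dist``.
  This is the conservative default: fewer reads are misassigned, more
  are left unassigned.

Consensus barcodes carry no errors, so their k-mer sets use the EXACT
circularization only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Optional, Sequence

import edlib

from .circkmer import BarcodeWindow, circular_kmers, three_variant_kmers
from .errors import InvalidParameterError

UNASSIGNED = "UNASSIGNED"

#: prefilter k-mer size for batch Levenshtein assignment; any 12-nt window
#: within edit distance 2 of a barcode shares a circular 5-mer with it
#: (two errors leave a circular gap of >= ceil((12-2)/2) = 5 clean bases)
PREFILTER_K = 5


@dataclass(frozen=True)
class Assignment:
    read_id: Hashable
    barcode: str  # consensus sequence, or UNASSIGNED
    method: str  # "kmer" or "levenshtein"
    score: Optional[int]  # shared-k-mer count, or edit distance

    @property
    def assigned(self) -> bool:
        return self.barcode != UNASSIGNED


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance (insertions, deletions, substitutions)."""
    if a == b:
        return 0
    if not a or not b:
        return max(len(a), len(b))
    return edlib.align(a, b, task="distance")["editDistance"]


def hamming(a: str, b: str) -> int:
    """Substitution count between equal-length strings."""
    if len(a) != len(b):
        raise InvalidParameterError(
            f"hamming requires equal lengths, got {len(a)} and {len(b)}"
        )
    return sum(x != y for x, y in zip(a, b))


def _barcode_kmer_sets(barcodes: Sequence[str], k: int) -> list[frozenset[str]]:
    return [
        frozenset(pk.kmer for pk in circular_kmers(bc, k)) for bc in barcodes
    ]


def assign_by_kmers(
    window: BarcodeWindow,
    barcodes: Sequence[str],
    k_assign: int,
    min_shared: int = 2,
    _barcode_sets: Optional[list[frozenset[str]]] = None,
) -> Assignment:
    """Assign one read to the consensus sharing the most circular k-mers."""
    if not barcodes:
        raise InvalidParameterError("barcodes must be non-empty")
    if k_assign > window.length - 1:
        raise InvalidParameterError("k_assign must be <= L-1")
    sets = (
        _barcode_sets
        if _barcode_sets is not None
        else _barcode_kmer_sets(barcodes, k_assign)
    )
    read_kmers = {
        pk.kmer for pk in three_variant_kmers(window, k_assign) if not pk.contains_n
    }
    best_score, best_bc, tie = -1, UNASSIGNED, False
    for bc, bc_set in zip(barcodes, sets):
        score = len(read_kmers & bc_set)
        if score > best_score:
            best_score, best_bc, tie = score, bc, False
        elif score == best_score:
            tie = True
    if tie or best_score < min_shared:
        return Assignment(window.read_id, UNASSIGNED, "kmer", None)
    return Assignment(window.read_id, best_bc, "kmer", best_score)


def assign_by_levenshtein(
    window: BarcodeWindow, barcodes: Sequence[str], max_dist: int = 2
) -> Assignment:
    """Assign one read to the unique nearest consensus within ``max_dist``."""
    if not barcodes:
        raise InvalidParameterError("barcodes must be non-empty")
    if max_dist < 0:
        raise InvalidParameterError("max_dist must be >= 0")
    best_d, best_bc, tie = None, UNASSIGNED, False
    for bc in barcodes:
        d = levenshtein(window.bases, bc)
        if best_d is None or d < best_d:
            best_d, best_bc, tie = d, bc, False
        elif d == best_d:
            tie = True
    if tie or best_d is None or best_d > max_dist:
        return Assignment(window.read_id, UNASSIGNED, "levenshtein", None)
    return Assignment(window.read_id, best_bc, "levenshtein", best_d)


class ReadAssigner:
    """Batch assigner with a shared-k-mer candidate prefilter.

    Exhaustive comparison of every read against every consensus barcode is
    quadratic; instead candidate barcodes are first narrowed to those
    sharing at least one circular ``PREFILTER_K``-mer with the read, which
    is lossless for Levenshtein distances up to 2 on 12-nt barcodes and
    exact for the k-mer mode (a zero-overlap barcode can never win).
    """

    def __init__(
        self,
        barcodes: Sequence[str],
        method: str = "levenshtein",
        k_assign: int = 8,
        min_shared: int = 2,
        max_dist: int = 2,
    ):
        if method not in ("levenshtein", "kmer"):
            raise InvalidParameterError(f"unknown assignment method {method!r}")
        if not barcodes:
            raise InvalidParameterError("barcodes must be non-empty")
        self.barcodes = list(barcodes)
        self.method = method
        self.k_assign = k_assign
        self.min_shared = min_shared
        self.max_dist = max_dist
        self._pre_k = min(PREFILTER_K, min(len(b) for b in barcodes) - 1)
        self._candidates: dict[str, set[int]] = {}
        for i, bc in enumerate(self.barcodes):
            for pk in circular_kmers(bc, self._pre_k):
                self._candidates.setdefault(pk.kmer, set()).add(i)
        if method == "kmer":
            self._assign_sets = _barcode_kmer_sets(self.barcodes, k_assign)

    def _candidate_ids(self, window: BarcodeWindow) -> set[int]:
        ids: set[int] = set()
        for pk in three_variant_kmers(window, self._pre_k):
            if not pk.contains_n:
                ids.update(self._candidates.get(pk.kmer, ()))
        return ids

    def assign(self, window: BarcodeWindow) -> Assignment:
        ids = sorted(self._candidate_ids(window))
        if not ids:
            return Assignment(window.read_id, UNASSIGNED, self.method, None)
        cand = [self.barcodes[i] for i in ids]
        if self.method == "levenshtein":
            return assign_by_levenshtein(window, cand, self.max_dist)
        sets = [self._assign_sets[i] for i in ids]
        return assign_by_kmers(
            window, cand, self.k_assign, self.min_shared, _barcode_sets=sets
        )

    def assign_all(self, windows) -> list[Assignment]:
        return [self.assign(w) for w in windows]
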