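"""k-mer → read-occurrence index over a subsample of the input reads.

The index maps each circularized k-mer (from all three variants) to the
list of (read_id, variant, offset) occurrences producing it.  It serves
two purposes downstream: the most common k-mers seed the per-subgraph
cycle searches, and the recorded offsets later resolve the rotational
phase of extracted cycles.

k-mers containing N are generated upstream but never indexed: an
ambiguous base cannot support a consensus and would only add spurious
graph nodes.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from .circkmer import BarcodeWindow, VariantKind, three_variant_kmers
from .errors import EmptyInputError, InvalidComparisonError, InvalidParameterError

Posting = tuple[object, VariantKind, int]  # (read_id, variant, circular offset)


@dataclass
class KmerIndex:
    k: int
    entries: dict[str, list[Posting]] = field(default_factory=dict)
    reads_indexed: int = 0
    subsample_size: int = 0
    #: the subsampled windows themselves, keyed by read_id (kept so that
    #: subgraph construction can re-derive k-mers for exactly these reads)
    windows: dict[object, BarcodeWindow] = field(default_factory=dict)

    @property
    def counts(self) -> dict[str, int]:
        """Occurrence count per k-mer (positions, not unique reads)."""
        return {m: len(p) for m, p in self.entries.items()}

    def count(self, kmer: str) -> int:
        return len(self.entries.get(kmer, ()))

    def __contains__(self, kmer: str) -> bool:
        return kmer in self.entries

    def __len__(self) -> int:
        return len(self.entries)


def build_index(
    reads: Iterable[BarcodeWindow],
    k: int,
    subsample_size: int = 500_000,
    seed: int = 0,
    random_sample: bool = False,
) -> KmerIndex:
    """Index the first ``subsample_size`` reads of the stream.

    Head-based subsampling is the default (it mirrors plain
    ``zcat | head`` downsampling of a FASTQ and is deterministic without
    a seed); pass ``random_sample=True`` for seeded reservoir sampling
    when the input ordering is suspected to be biased.

    Indexing roughly half a million reads is typically enough for the
    k-mer count distribution to stabilize; use :func:`count_stability`
    on disjoint subsamples as a diagnostic.

    Raises
    ------
    EmptyInputError
        If the stream yields no windows.
    """
    if subsample_size < 1:
        raise InvalidParameterError("subsample_size must be >= 1")
    if random_sample:
        sample = _reservoir(reads, subsample_size, seed)
    else:
        sample = []
        for window in reads:
            sample.append(window)
            if len(sample) >= subsample_size:
                break
    if not sample:
        raise EmptyInputError("read stream yielded no barcode windows")

    index = KmerIndex(k=k, subsample_size=subsample_size)
    entries = index.entries
    for window in sample:
        index.windows[window.read_id] = window
        for pk in three_variant_kmers(window, k):
            if pk.contains_n:
                continue
            entries.setdefault(pk.kmer, []).append(
                (window.read_id, pk.variant_kind, pk.offset)
            )
    index.reads_indexed = len(sample)
    return index


def _reservoir(
    reads: Iterable[BarcodeWindow], size: int, seed: int
) -> list[BarcodeWindow]:
    rng = random.Random(seed)
    sample: list[BarcodeWindow] = []
    for i, window in enumerate(reads):
        if i < size:
            sample.append(window)
        else:
            j = rng.randrange(i + 1)
            if j < size:
                sample[j] = window
    return sample


def top_kmers(index: KmerIndex, n: int) -> list[str]:
    """The n most frequent k-mers, descending; ties broken lexicographically."""
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    ordered = sorted(index.entries, key=lambda m: (-len(index.entries[m]), m))
    return ordered[:n]


def count_stability(index_a: KmerIndex, index_b: KmerIndex, top_n: int) -> float:
    """Jaccard similarity of the two indices' top-n k-mer sets.

    A diagnostic (not a gate) for choosing the subsample size: build two
    disjoint subsamples and check that their common-k-mer sets agree.
    """
    if index_a.k != index_b.k:
        raise InvalidComparisonError(
            f"indices built with different k: {index_a.k} vs {index_b.k}"
        )
    a = set(top_kmers(index_a, top_n))
    b = set(top_kmers(index_b, top_n))
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def save_index(index: KmerIndex, path: str) -> None:
    """Serialize an index to JSON-lines text; round-trips exactly."""
    with open(path, "w") as fh:
        header = {
            "k": index.k,
            "reads_indexed": index.reads_indexed,
            "subsample_size": index.subsample_size,
        }
        fh.write(json.dumps(header) + "\n")
        for rid, w in index.windows.items():
            fh.write(
                json.dumps({"w": [rid, w.bases, w.next_base]}) + "\n"
            )
        for kmer in sorted(index.entries):
            postings = [
                [rid, kind.value, off] for rid, kind, off in index.entries[kmer]
            ]
            fh.write(json.dumps({"m": kmer, "p": postings}) + "\n")


def load_index(path: str) -> KmerIndex:
    with open(path) as fh:
        header = json.loads(fh.readline())
        index = KmerIndex(
            k=header["k"],
            reads_indexed=header["reads_indexed"],
            subsample_size=header["subsample_size"],
        )
        for line in fh:
            rec = json.loads(line)
            if "w" in rec:
                rid, bases, nb = rec["w"]
                index.windows[rid] = BarcodeWindow(rid, bases, nb)
            else:
                index.entries[rec["m"]] = [
                    (rid, VariantKind(kind), off) for rid, kind, off in rec["p"]
                ]
    return index


def iter_windows(index: KmerIndex) -> Iterator[BarcodeWindow]:
    return iter(index.windows.values())
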