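"""Circularized k-mer fingerprints of barcode windows.

A cell barcode is short (typically 12 nt) relative to a useful k-mer size
(k ~ 7-8), so a single error in a linear barcode can corrupt every one of
its k-mers.  Treating the barcode as a *circular* sequence guarantees that
a single mismatch leaves k error-free k-mers, wherever the error falls.
Indels are handled by circularizing two additional variants of the window:

* TRUNCATED — the window minus its last base.  If the barcode suffered a
  deletion, the base observed at the last window position actually belongs
  to the downstream UMI/adaptor; dropping it restores a majority-correct
  circle.
* EXACT — the window as observed.
* EXTENDED — the window plus the first downstream base, which restores a
  majority-correct circle when the barcode suffered an insertion.

Every read therefore contributes (L-1) + L + (L+1) = 3L positioned k-mers
(36 for Drop-seq's L = 12) when the downstream base is available.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Hashable, Optional

from .errors import InvalidAlphabetError, InvalidParameterError

DNA_ALPHABET = frozenset("ACGTN")

_VALID = DNA_ALPHABET  # chars permitted in a window after uppercasing


class VariantKind(Enum):
    """Which circularization variant a k-mer came from."""

    TRUNCATED = "truncated"
    EXACT = "exact"
    EXTENDED = "extended"


@dataclass(frozen=True)
class BarcodeWindow:
    """The barcode portion of one read plus the first downstream base.

    Parameters
    ----------
    read_id
        Opaque identifier of the source read.
    bases
        The L observed bases of the barcode window (uppercased on ingest).
    next_base
        The single base immediately 3' of the window (first UMI/adaptor
        base), or ``None`` if the read was too short to provide one.
    """

    read_id: Hashable
    bases: str
    next_base: Optional[str] = None

    def __post_init__(self) -> None:
        bases = self.bases.upper()
        object.__setattr__(self, "bases", bases)
        if not bases:
            raise InvalidParameterError("barcode window must be non-empty")
        bad = set(bases) - _VALID
        if bad:
            raise InvalidAlphabetError(
                f"window {self.read_id!r} contains non-DNA characters {sorted(bad)}"
            )
        if self.next_base is not None:
            nb = self.next_base.upper()
            object.__setattr__(self, "next_base", nb)
            if len(nb) != 1 or nb not in _VALID:
                raise InvalidAlphabetError(
                    f"next_base must be one of {sorted(_VALID)}, got {self.next_base!r}"
                )

    @property
    def length(self) -> int:
        return len(self.bases)

    def variant_sequence(self, kind: VariantKind) -> str:
        """The circularized sequence of one variant (length L-1, L or L+1)."""
        if kind is VariantKind.TRUNCATED:
            return self.bases[:-1]
        if kind is VariantKind.EXACT:
            return self.bases
        if self.next_base is None:
            raise InvalidParameterError(
                "EXTENDED variant requires a next_base (read too short)"
            )
        return self.bases + self.next_base


@dataclass(frozen=True)
class PositionedKmer:
    """A k-mer together with the circular variant and offset that produced it.

    The offset is 0-based in the variant's own circular coordinate system;
    it is what later allows a cyclic path (which has no intrinsic phase) to
    be rotated back into a linear barcode.
    """

    kmer: str
    variant_kind: VariantKind
    offset: int

    @property
    def contains_n(self) -> bool:
        return "N" in self.kmer


def _check_sequence(sequence: str) -> str:
    sequence = sequence.upper()
    bad = set(sequence) - _VALID
    if bad:
        raise InvalidAlphabetError(f"non-DNA characters in sequence: {sorted(bad)}")
    return sequence


def circular_kmers(
    sequence: str, k: int, variant_kind: VariantKind = VariantKind.EXACT
) -> list[PositionedKmer]:
    """Enumerate every k-mer of a circular sequence, one per start offset.

    Returns exactly ``len(sequence)`` positioned k-mers in offset order
    0 .. len(sequence)-1.  Duplicate k-mer strings (repetitive sequences)
    are retained as distinct positions.

    Raises
    ------
    InvalidParameterError
        If ``k < 1`` or ``k > len(sequence)``.
    InvalidAlphabetError
        If the sequence contains characters outside {A,C,G,T,N}.
    """
    if not sequence:
        raise InvalidParameterError("sequence must be non-empty")
    sequence = _check_sequence(sequence)
    n = len(sequence)
    if k < 1 or k > n:
        raise InvalidParameterError(
            f"k must satisfy 1 <= k <= len(sequence); got k={k}, len={n}"
        )
    doubled = sequence + sequence
    return [
        PositionedKmer(doubled[i : i + k], variant_kind, i) for i in range(n)
    ]


def three_variant_kmers(window: BarcodeWindow, k: int) -> list[PositionedKmer]:
    """All positioned k-mers of the TRUNCATED, EXACT and EXTENDED circles.

    For a window of length L with a downstream base this is
    (L-1) + L + (L+1) = 3L k-mers; without one the EXTENDED variant is
    skipped and 2L - 1 k-mers are produced.

    Raises
    ------
    InvalidParameterError
        If ``k > L - 1`` (the TRUNCATED variant could not be enumerated).
    """
    if k > window.length - 1:
        raise InvalidParameterError(
            f"k must be <= L-1 = {window.length - 1} so all variants admit "
            f"k-mers; got k={k}"
        )
    kinds = [VariantKind.TRUNCATED, VariantKind.EXACT]
    if window.next_base is not None:
        kinds.append(VariantKind.EXTENDED)
    out: list[PositionedKmer] = []
    for kind in kinds:
        out.extend(circular_kmers(window.variant_sequence(kind), k, kind))
    return out
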