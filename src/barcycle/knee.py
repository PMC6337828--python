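"""Knee-point thresholding of the cumulative path-capacity curve.

True barcode cycles have much higher capacity than cycles formed by
spurious k-mer overlap, so the rank-ordered cumulative sum of capacities
rises steeply over the true paths and then bends sharply — the knee.
The curve is smoothed with a Savitzky-Golay filter before locating the
bend, which makes the inflection unambiguous on noisy real data.

Numerically, the knee is taken where the smoothed curve's first
derivative falls fastest (the interior maximum of curvature magnitude;
on a descending-rank cumulative curve the derivative itself is monotone,
so its level has no interior maximum — its *drop* does).  The candidate
is then refined on the unsmoothed capacities to the largest single-step
drop nearby, and the threshold is set at the first capacity below that
drop.  Paths strictly above the threshold are accepted, so the
transition value itself is excluded.

No prior cell count enters anywhere: the threshold is read off the data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import savgol_filter

from .errors import DegenerateInputError, InvalidParameterError, NoKneeError


@dataclass
class ThresholdResult:
    sorted_capacities: np.ndarray  # descending
    cumulative: np.ndarray
    smoothed: np.ndarray
    derivative: np.ndarray
    knee_rank: int
    threshold_capacity: float
    accepted_count: int
    #: all interior curvature-peak candidates (rank, magnitude), best first
    candidates: list[tuple[int, float]]

    @property
    def accepted_mask(self) -> np.ndarray:
        return self.sorted_capacities > self.threshold_capacity

    def to_tsv(self, path: str) -> None:
        """Diagnostic table: rank, capacity, cumulative, smoothed, derivative."""
        import pandas as pd

        pd.DataFrame(
            {
                "rank": np.arange(len(self.sorted_capacities)),
                "capacity": self.sorted_capacities,
                "cumulative": self.cumulative,
                "smoothed": self.smoothed,
                "derivative": self.derivative,
            }
        ).to_csv(path, sep="\t", index=False)


def find_knee(
    capacities: Sequence[float], window: int | None = None, polyorder: int = 3
) -> ThresholdResult:
    """Locate the inflection of the cumulative capacity-vs-rank curve.

    Parameters
    ----------
    capacities
        Path capacities in any order; sorted descending internally.
    window
        Odd Savitzky-Golay window in ranks.  Default: 101, shrunk to the
        largest odd number <= n when the curve is shorter.  An explicit
        window larger than the data is an error (use a smaller one).
    polyorder
        Savitzky-Golay polynomial order; must be < window.

    Raises
    ------
    DegenerateInputError
        Fewer points than the (explicit) window.
    NoKneeError
        No interior bend exists (e.g. all capacities equal).
    """
    caps = np.asarray(sorted(capacities, reverse=True), dtype=float)
    n = caps.size
    if window is None:
        window = min(101, n if n % 2 == 1 else n - 1)
    if window % 2 == 0:
        raise InvalidParameterError(f"window must be odd, got {window}")
    if n < window or window < 3:
        raise DegenerateInputError(
            f"{n} points < window {window}; pass a smaller odd window"
        )
    if polyorder >= window:
        raise InvalidParameterError("polyorder must be < window")
    if np.allclose(caps, caps[0]):
        raise NoKneeError("all capacities equal; curve has no inflection")

    cumulative = np.cumsum(caps)
    smoothed = savgol_filter(cumulative, window, polyorder)
    derivative = savgol_filter(cumulative, window, polyorder, deriv=1)

    # interior local maxima of how fast the derivative falls
    half = window // 2
    drop = -np.gradient(derivative)
    lo, hi = max(half, 1), min(n - half, n - 1)
    if hi <= lo:
        raise NoKneeError("curve too short for an interior inflection")
    interior = drop[lo:hi]
    candidates = [
        (lo + i, float(interior[i]))
        for i in range(len(interior))
        if interior[i] > 0
        and (i == 0 or interior[i] >= interior[i - 1])
        and (i == len(interior) - 1 or interior[i] > interior[i + 1])
    ]
    if not candidates:
        raise NoKneeError("derivative has no interior inflection")
    candidates.sort(key=lambda rm: (-rm[1], rm[0]))
    bend = candidates[0][0]

    # refine on the raw curve: largest one-step capacity drop near the bend
    a, b = max(0, bend - half), min(n - 1, bend + half)
    steps = caps[a:b] - caps[a + 1 : b + 1]
    knee_rank = a + int(np.argmax(steps)) + 1  # first rank below the drop
    threshold = float(caps[knee_rank])
    accepted = int(np.sum(caps > threshold))
    if accepted == 0:
        raise NoKneeError("knee threshold accepts no paths")
    return ThresholdResult(
        sorted_capacities=caps,
        cumulative=cumulative,
        smoothed=smoothed,
        derivative=derivative,
        knee_rank=knee_rank,
        threshold_capacity=threshold,
        accepted_count=accepted,
        candidates=candidates,
    )
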