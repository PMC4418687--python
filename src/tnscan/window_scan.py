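"""Fixed-size sliding-window scan of insertion counts along a genome.

Counting insertions in windows of a fixed size sidesteps the gene-length
problem of per-gene insertion densities: in a sparsely saturated library,
short genes carry too few unique insertions for densities to be comparable
across genes. When the window is large enough, the per-window count
distribution becomes bimodal — a left peak from windows overlapping
essential regions, a broad right peak from neutral DNA. The window-size
recommendation exploits the complementary observation that at small window
sizes the distribution instead resembles a decaying exponential: the
smallest window whose count histogram fits an exponential poorly (log-linear
R-squared below a cutoff) is recommended.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .formats_io import GenomeRef
from .insertion_calling import CountHistogram, InsertionLibrary

MODES = ("unique_insertions", "reads")


@dataclass
class WindowProfile:
    """Counts for every window position of size ``window_size`` at ``step``."""

    contig: str
    window_size: int
    step: int
    mode: str
    starts: np.ndarray  # 1-based window start coordinates
    counts: np.ndarray
    circular: bool = False

    def items(self) -> List[Tuple[int, int]]:
        return [(int(w), int(c)) for w, c in zip(self.starts, self.counts)]

    def __len__(self) -> int:
        return len(self.starts)


@dataclass
class WindowSizeScan:
    """Result of the automatic window-size recommendation."""

    candidate_sizes: List[int]
    r2_by_size: Dict[int, Optional[float]]
    chosen_size: Optional[int]
    cutoff_used: float

    @property
    def found(self) -> bool:
        return self.chosen_size is not None


def _interval_sum(
    positions: np.ndarray, prefix: np.ndarray, lo: np.ndarray, hi: np.ndarray
) -> np.ndarray:
    """Weighted count of positions p with lo <= p <= hi (vectorized)."""
    left = np.searchsorted(positions, lo, side="left")
    right = np.searchsorted(positions, hi, side="right")
    return prefix[right] - prefix[left]


def _weights(library: InsertionLibrary, contig: str, mode: str):
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    positions, read_counts = library.contig_arrays(contig)
    weights = read_counts if mode == "reads" else np.ones_like(read_counts)
    prefix = np.concatenate(([0], np.cumsum(weights)))
    return positions, prefix


def scan_windows(
    library: InsertionLibrary,
    genome: GenomeRef,
    window_size: int,
    step: int = 10,
    mode: str = "unique_insertions",
) -> WindowProfile:
    """Count unique insertions (or reads) in every window of fixed size.

    Windows start at coordinate 1 and advance by ``step``; the count for
    window [w, w+W-1] pools both strands. On a linear contig no window
    extends past the end; on a circular contig windows wrap past the origin
    so every coordinate is covered by equally many windows.
    """
    L = genome.length
    if window_size < 1 or step < 1:
        raise ValueError("window_size and step must be >= 1")
    if window_size > L and not genome.circular:
        raise ValueError(
            f"window size {window_size} exceeds contig {genome.contig} "
            f"length {L}"
        )
    positions, prefix = _weights(library, genome.contig, mode)
    if genome.circular:
        starts = np.arange(1, L + 1, step, dtype=np.int64)
    else:
        starts = np.arange(1, L - window_size + 2, step, dtype=np.int64)
    ends = starts + window_size - 1
    if genome.circular:
        capped = np.minimum(ends, L)
        counts = _interval_sum(positions, prefix, starts, capped)
        wrapped = ends > L
        if wrapped.any():
            over = ends[wrapped] - L
            counts[wrapped] += _interval_sum(
                positions, prefix, np.ones_like(over), over
            )
    else:
        counts = _interval_sum(positions, prefix, starts, ends)
    return WindowProfile(
        contig=genome.contig,
        window_size=window_size,
        step=step,
        mode=mode,
        starts=starts,
        counts=counts.astype(np.int64),
        circular=genome.circular,
    )


def window_count_histogram(profile: WindowProfile) -> CountHistogram:
    """How many window positions yield each insertion count."""
    values, freqs = np.unique(profile.counts, return_counts=True)
    return CountHistogram({int(v): int(f) for v, f in zip(values, freqs)})


def exponential_fit_r2(histogram: CountHistogram) -> float:
    """Goodness of an exponential fit to a count histogram, as R-squared.

    Frequencies are modeled as ``a * exp(-b * c)`` over count values c; the
    fit is ordinary least squares on log-transformed frequencies of the bins
    with positive frequency (deterministic, no initialization), and the
    R-squared of that log-linear fit is returned, clipped to [0, 1].
    """
    rows = [(c, f) for c, f in histogram.to_rows() if f > 0]
    if len(rows) < 3:
        raise ValueError(
            f"insufficient support: exponential fit needs >= 3 positive bins, "
            f"got {len(rows)}"
        )
    x = np.array([c for c, _ in rows], dtype=float)
    y = np.log([f for _, f in rows])
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res < 1e-12 else 0.0
    return float(np.clip(1.0 - ss_res / ss_tot, 0.0, 1.0))


def auto_window_size(
    library: InsertionLibrary,
    genome: GenomeRef,
    candidate_sizes: Sequence[int] = tuple(range(100, 2001, 50)),
    step: int = 10,
    mode: str = "unique_insertions",
    r2_cutoff: float = 0.90,
) -> WindowSizeScan:
    """Recommend the smallest window size whose count histogram is
    no longer exponential (R-squared below ``r2_cutoff``).

    The full R-squared-by-size table is always returned so the user can
    inspect it and override the recommendation. Sizes whose histogram has
    too few positive bins for a fit are recorded as None and never chosen.
    """
    sizes = sorted(int(w) for w in candidate_sizes)
    if not sizes:
        raise ValueError("candidate_sizes must be non-empty")
    r2_by_size: Dict[int, Optional[float]] = {}
    chosen: Optional[int] = None
    for size in sizes:
        hist = window_count_histogram(
            scan_windows(library, genome, size, step=step, mode=mode)
        )
        try:
            r2 = exponential_fit_r2(hist)
        except ValueError:
            r2_by_size[size] = None
            continue
        r2_by_size[size] = r2
        if chosen is None and r2 < r2_cutoff:
            chosen = size
    return WindowSizeScan(
        candidate_sizes=sizes,
        r2_by_size=r2_by_size,
        chosen_size=chosen,
        cutoff_used=r2_cutoff,
    )


def _smooth(dense: np.ndarray, width: int) -> np.ndarray:
    """Centered moving average of odd ``width``; edges average what exists."""
    half = width // 2
    padded = np.concatenate(([0.0] * half, dense.astype(float), [0.0] * half))
    csum = np.concatenate(([0.0], np.cumsum(padded)))
    sums = csum[width:] - csum[:-width]
    idx = np.arange(len(dense))
    n_avail = np.minimum(idx + half, len(dense) - 1) - np.maximum(idx - half, 0) + 1
    return sums / n_avail


def find_bimodal_minimum(
    histogram: CountHistogram, smoothing_width: int = 3
) -> int:
    """Valley between the two dominant peaks of a bimodal count histogram.

    Frequencies (dense over 0..max count) are smoothed with a centered
    moving average, local maxima are located, the two tallest (leftmost on
    ties) are taken as the essential and non-essential peaks, and the count
    value of the smoothed minimum strictly between them is returned
    (smallest value on ties). That value separates the two populations and
    is the natural classification cutoff.
    """
    if not histogram.bins:
        raise ValueError("empty histogram")
    if smoothing_width < 1 or smoothing_width % 2 == 0:
        raise ValueError("smoothing_width must be a positive odd integer")
    max_c = max(histogram.bins)
    dense = np.zeros(max_c + 1)
    for c, f in histogram.bins.items():
        if c < 0:
            raise ValueError(f"negative count value {c}")
        dense[c] = f
    smoothed = _smooth(dense, smoothing_width)

    from scipy.signal import find_peaks

    padded = np.concatenate(([-1.0], smoothed, [-1.0]))
    peak_idx, _ = find_peaks(padded, plateau_size=(1, None))
    peaks = peak_idx - 1
    if len(peaks) < 2:
        raise ValueError("distribution not bimodal")
    # two tallest peaks; leftmost wins frequency ties
    order = sorted(peaks, key=lambda p: (-smoothed[p], p))
    p1, p2 = sorted(order[:2])
    between = smoothed[p1 + 1 : p2]
    if between.size == 0:  # adjacent peaks cannot both be local maxima
        raise ValueError("distribution not bimodal")
    return int(p1 + 1 + int(np.argmin(between)))
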