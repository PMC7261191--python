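"""Overlap metrics between regulatory elements and ChIP-seq peak sets.

Two summaries: the maximum signal of peaks intersecting an element (used for
H3K27ac), and the count of peaks intersecting a region expressed as a
density per 1000 nt (used for transcription-factor binding events). A
"binding event" is one narrowPeak record sharing at least one base with the
region; alternatively, summit containment can be required.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .intervals import GenomicInterval, NarrowPeak
from .stats import compare_groups  # re-exported: group comparisons live with the stats

__all__ = [
    "OverlapSummary",
    "PeakIndex",
    "max_signal",
    "binding_density",
    "compare_groups",
]


@dataclass(frozen=True)
class OverlapSummary:
    element_id: str
    overlapped: bool
    max_signal: float | None
    n_peaks: int
    density_per_kb: float


class PeakIndex:
    """Per-chromosome sorted arrays for fast interval-intersection counting.

    A peak ``[ps, pe)`` intersects a region ``[s, e)`` iff ``ps < e`` and
    ``pe > s``; with starts and ends sorted independently the count is
    ``P - #(ps >= e) - #(pe <= s)`` (the two excluded sets are disjoint).
    """

    def __init__(self, peaks: Sequence[NarrowPeak], mode: str = "overlap"):
        if mode not in ("overlap", "summit"):
            raise ValueError("mode must be 'overlap' or 'summit'")
        self.mode = mode
        # per chromosome: starts (sorted, with ends/signals aligned) and an
        # independently sorted copy of the ends for the counting formula
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}
        buckets: dict[str, list[NarrowPeak]] = {}
        for p in peaks:
            buckets.setdefault(p.interval.chrom, []).append(p)
        for chrom, plist in buckets.items():
            if mode == "summit":
                starts = np.array(
                    [
                        p.interval.start
                        + (p.summit_offset if p.summit_offset >= 0 else p.interval.length // 2)
                        for p in plist
                    ],
                    dtype=np.int64,
                )
                ends = starts + 1
            else:
                starts = np.array([p.interval.start for p in plist], dtype=np.int64)
                ends = np.array([p.interval.end for p in plist], dtype=np.int64)
            signals = np.array([p.signal for p in plist], dtype=float)
            order = np.argsort(starts, kind="stable")
            self._by_chrom[chrom] = (
                starts[order], ends[order], signals[order], np.sort(ends)
            )

    def count(self, region: GenomicInterval) -> int:
        entry = self._by_chrom.get(region.chrom)
        if entry is None:
            return 0
        starts, _, _, ends_sorted = entry
        n = len(starts)
        n_start_after = n - int(np.searchsorted(starts, region.end - 1, side="right"))
        n_end_before = int(np.searchsorted(ends_sorted, region.start, side="right"))
        return n - n_start_after - n_end_before

    def max_signal(self, region: GenomicInterval) -> float | None:
        entry = self._by_chrom.get(region.chrom)
        if entry is None:
            return None
        starts, ends, signals, _ = entry
        hi = int(np.searchsorted(starts, region.end - 1, side="right"))
        if hi == 0:
            return None
        mask = ends[:hi] > region.start
        if not mask.any():
            return None
        return float(signals[:hi][mask].max())


def max_signal(
    element_id: str,
    region: GenomicInterval,
    peaks: Sequence[NarrowPeak] | PeakIndex,
) -> OverlapSummary:
    """Whether any peak intersects the element and the maximum signal if so."""
    index = peaks if isinstance(peaks, PeakIndex) else PeakIndex(peaks)
    n = index.count(region)
    sig = index.max_signal(region) if n else None
    return OverlapSummary(
        element_id=element_id,
        overlapped=n > 0,
        max_signal=sig,
        n_peaks=n,
        density_per_kb=1000.0 * n / region.length,
    )


def binding_density(
    regions: Sequence[tuple[str, GenomicInterval]],
    peaks: Sequence[NarrowPeak] | PeakIndex,
    mode: str = "overlap",
) -> list[OverlapSummary]:
    """Peak count and per-kb density for each (element_id, region).

    Duplicate peaks within one input list count once each as separate
    records; concatenating two peak lists therefore sums their counts.
    """
    index = peaks if isinstance(peaks, PeakIndex) else PeakIndex(peaks, mode=mode)
    out = []
    for element_id, region in regions:
        if region.length <= 0:
            raise ValueError(f"{element_id}: zero-length region")
        n = index.count(region)
        out.append(
            OverlapSummary(
                element_id=element_id,
                overlapped=n > 0,
                max_signal=index.max_signal(region) if n else None,
                n_peaks=n,
                density_per_kb=1000.0 * n / region.length,
            )
        )
    return out
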