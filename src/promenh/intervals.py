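"""Genomic coordinate primitives.

Coordinates follow the BED convention throughout: 0-based, half-open
``[start, end)``. Relative (anchored) coordinates are integers with
position 0 at the anchor base and negative values upstream *on the
element's strand*, so motif and tag positions read the same way for
plus- and minus-strand elements.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

STRANDS = ("+", "-", ".")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an ``ACGTN`` string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic span; the unit of promoters, enhancers, CGIs and peaks."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"empty or inverted interval: start={self.start}, end={self.end}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True when the two half-open spans share at least one base."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class NarrowPeak:
    """A narrowPeak (BED6+4) record."""

    interval: GenomicInterval
    name: str = "."
    score: int = 0
    signal: float = 0.0
    pvalue_log: float = -1.0
    qvalue_log: float = -1.0
    summit_offset: int = -1

    def __post_init__(self) -> None:
        if self.signal < 0:
            raise ValueError(f"signalValue must be >= 0, got {self.signal}")
        if not (
            self.summit_offset == -1
            or 0 <= self.summit_offset < self.interval.length
        ):
            raise ValueError(
                f"summit offset {self.summit_offset} outside peak of length "
                f"{self.interval.length}"
            )


@dataclass(frozen=True)
class AnchoredSequence:
    """A sequence window expressed in coordinates relative to an anchor base.

    The stored ``sequence`` is in transcription orientation: for minus-strand
    elements it is the reverse complement of the genomic span, so relative
    coordinates always increase in the direction of transcription and the
    anchor (TSS or enhancer midpoint) sits at relative position 0.
    """

    interval: GenomicInterval
    anchor: int
    sequence: str
    clipped: bool = False

    def __post_init__(self) -> None:
        if len(self.sequence) != self.interval.length:
            raise ValueError(
                f"sequence length {len(self.sequence)} != interval length "
                f"{self.interval.length}"
            )
        if not (self.interval.start <= self.anchor < self.interval.end):
            raise ValueError(
                f"anchor {self.anchor} outside interval "
                f"[{self.interval.start}, {self.interval.end})"
            )

    @property
    def _anchor_index(self) -> int:
        if self.interval.strand == "-":
            return (self.interval.end - 1) - self.anchor
        return self.anchor - self.interval.start

    @property
    def rel_start(self) -> int:
        """Smallest relative coordinate covered (inclusive)."""
        return -self._anchor_index

    @property
    def rel_end(self) -> int:
        """One past the largest relative coordinate covered (exclusive)."""
        return len(self.sequence) - self._anchor_index

    def subseq(self, rel_from: int, rel_to: int) -> str:
        """Sequence over relative coordinates ``[rel_from, rel_to)``."""
        if rel_from < self.rel_start or rel_to > self.rel_end:
            raise ValueError(
                f"requested [{rel_from}, {rel_to}) outside covered "
                f"[{self.rel_start}, {self.rel_end})"
            )
        a = self._anchor_index
        return self.sequence[a + rel_from : a + rel_to]

    def base_at(self, rel: int) -> str:
        return self.subseq(rel, rel + 1)


def extract_anchored(
    genome: Mapping[str, str],
    chrom: str,
    anchor: int,
    strand: str,
    upstream: int,
    downstream: int,
) -> AnchoredSequence:
    """Extract the window covering relative positions ``[-upstream, +downstream]``.

    ``upstream``/``downstream`` are measured on the element's strand: for a
    minus-strand anchor the genomic span runs to the *right* of the anchor for
    upstream positions and the returned sequence is reverse-complemented.
    Windows extending past the chromosome ends are clipped and flagged.
    """
    if chrom not in genome:
        raise KeyError(f"unknown chromosome {chrom!r}")
    seq = genome[chrom]
    if strand == "-":
        lo = anchor - downstream
        hi = anchor + upstream + 1
    else:
        lo = anchor - upstream
        hi = anchor + downstream + 1
    clipped = lo < 0 or hi > len(seq)
    lo_c = max(lo, 0)
    hi_c = min(hi, len(seq))
    if not (lo_c <= anchor < hi_c):
        raise ValueError(
            f"anchor {anchor} falls outside chromosome {chrom!r} "
            f"(length {len(seq)})"
        )
    interval = GenomicInterval(chrom, lo_c, hi_c, strand if strand in STRANDS else ".")
    window = seq[lo_c:hi_c].upper()
    if strand == "-":
        window = reverse_complement(window)
    return AnchoredSequence(interval=interval, anchor=anchor, sequence=window, clipped=clipped)


def promoter_region(chrom: str, tss: int, strand: str, upstream: int = 500,
                    downstream: int = 200) -> GenomicInterval:
    """Promoter span covering relative ``[-upstream, +downstream)`` on the strand.

    With the defaults this is the 700-nt region from 500 nt upstream to
    200 nt downstream of the TSS used for binding-density summaries.
    """
    if strand == "-":
        return GenomicInterval(chrom, tss - downstream + 1, tss + upstream + 1, strand)
    return GenomicInterval(chrom, tss - upstream, tss + downstream, strand)


def enhancer_tss_pair(interval: GenomicInterval) -> tuple[int, int]:
    """(reverse-strand TSS, forward-strand TSS) of a bidirectional enhancer.

    The reverse transcript initiates at the interval start, the forward
    transcript at ``end - 1``; divergent transcription reads outward from
    the element body.
    """
    return interval.start, interval.end - 1


def enhancer_midpoint(interval: GenomicInterval) -> int:
    return (interval.start + interval.end) // 2
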