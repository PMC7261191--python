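"""Sliding-window CpG-island detection and CGI-association rules.

A CpG island is called where every 100-nt window across a region of at
least 200 bp has GC content >= 50% and a CpG observed/expected ratio
>= 0.6 (the Gardiner-Garden & Frommer criteria). The observed/expected
ratio of a window of length L is ``n_CpG * L / (n_C * n_G)``; windows
containing ``N`` bases fail both thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .intervals import AnchoredSequence, GenomicInterval, extract_anchored

DEFAULT_WINDOW = 100
DEFAULT_MIN_GC = 50.0
DEFAULT_MIN_OBS_EXP = 0.6
DEFAULT_MIN_REGION = 200


@dataclass(frozen=True)
class WindowComposition:
    gc_percent: float
    cpg_obs_exp: float
    n_c: int
    n_g: int
    n_cpg: int


@dataclass(frozen=True)
class CgiCall:
    """One called island, in the relative coordinates of the scanned sequence."""

    rel_start: int
    rel_end: int
    mean_gc: float
    mean_obs_exp: float

    @property
    def length(self) -> int:
        return self.rel_end - self.rel_start

    def contains(self, rel_pos: int) -> bool:
        return self.rel_start <= rel_pos < self.rel_end


def window_composition(seq: str, window: int = DEFAULT_WINDOW) -> WindowComposition:
    """GC percentage and CpG observed/expected ratio of one window.

    CpG occurrences are counted at every position ``i`` with ``seq[i:i+2] ==
    "CG"`` (overlap with the window requires the full dinucleotide inside it).
    """
    if len(seq) != window:
        raise ValueError(f"expected a window of length {window}, got {len(seq)}")
    seq = seq.upper()
    n_c = seq.count("C")
    n_g = seq.count("G")
    n_cpg = seq.count("CG")
    gc = 100.0 * (n_c + n_g) / window
    if n_c == 0 or n_g == 0:
        oe = 0.0
    else:
        oe = n_cpg * window / (n_c * n_g)
    return WindowComposition(gc_percent=gc, cpg_obs_exp=oe, n_c=n_c, n_g=n_g, n_cpg=n_cpg)


def _window_stats(seq: str, window: int):
    """Vectorised per-start-position window composition arrays.

    Returns (gc_percent, obs_exp, qualifies_has_no_N) arrays over all window
    start positions ``0 .. len(seq) - window``.
    """
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    is_c = (arr == ord("C")).astype(np.int64)
    is_g = (arr == ord("G")).astype(np.int64)
    is_n = (~np.isin(arr, np.frombuffer(b"ACGT", dtype=np.uint8))).astype(np.int64)
    is_cg = np.zeros(len(arr), dtype=np.int64)
    if len(arr) > 1:
        is_cg[:-1] = (arr[:-1] == ord("C")) & (arr[1:] == ord("G"))

    def winsum(x, w):
        cs = np.concatenate([[0], np.cumsum(x)])
        return cs[w:] - cs[:-w]

    n_c = winsum(is_c, window)
    n_g = winsum(is_g, window)
    n_bad = winsum(is_n, window)
    # dinucleotide must start within [s, s+window-1)
    n_cpg = winsum(is_cg, window - 1) if window > 1 else np.zeros(len(arr), dtype=np.int64)
    n_cpg = n_cpg[: len(n_c)]
    gc = 100.0 * (n_c + n_g) / window
    denom = n_c * n_g
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where(denom > 0, n_cpg * window / np.maximum(denom, 1), 0.0)
    return gc, oe, n_bad == 0


def call_cgis(
    anchored: AnchoredSequence | str,
    window: int = DEFAULT_WINDOW,
    step: int = 1,
    min_gc: float = DEFAULT_MIN_GC,
    min_obs_exp: float = DEFAULT_MIN_OBS_EXP,
    min_region: int = DEFAULT_MIN_REGION,
) -> list[CgiCall]:
    """Call CpG islands on an anchored sequence (or raw string).

    A call is emitted for each maximal run of consecutive qualifying window
    start positions whose spanned region (first window start to last window
    end) is at least ``min_region``; calls whose spans overlap are merged so
    that the returned calls are disjoint. Coordinates are relative to the
    anchor (or to the string start when a plain string is passed).
    """
    if step != 1:
        raise NotImplementedError("only step=1 scanning is supported")
    if isinstance(anchored, AnchoredSequence):
        seq = anchored.sequence
        offset = anchored.rel_start
    else:
        seq = anchored
        offset = 0
    if len(seq) < window:
        return []
    gc, oe, clean = _window_stats(seq, window)
    ok = (gc >= min_gc) & (oe >= min_obs_exp) & clean
    calls: list[CgiCall] = []
    n = len(ok)
    i = 0
    while i < n:
        if not ok[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and ok[j + 1]:
            j += 1
        span = (j + window) - i
        if span >= min_region:
            calls.append(
                CgiCall(
                    rel_start=i + offset,
                    rel_end=j + window + offset,
                    mean_gc=float(np.mean(gc[i : j + 1])),
                    mean_obs_exp=float(np.mean(oe[i : j + 1])),
                )
            )
        i = j + 1
    return _merge_overlapping(calls)


def _merge_overlapping(calls: list[CgiCall]) -> list[CgiCall]:
    merged: list[CgiCall] = []
    for call in calls:
        if merged and call.rel_start < merged[-1].rel_end:
            prev = merged[-1]
            w_prev = prev.length
            w_cur = call.length
            total = w_prev + w_cur
            merged[-1] = CgiCall(
                rel_start=prev.rel_start,
                rel_end=max(prev.rel_end, call.rel_end),
                mean_gc=(prev.mean_gc * w_prev + call.mean_gc * w_cur) / total,
                mean_obs_exp=(prev.mean_obs_exp * w_prev + call.mean_obs_exp * w_cur) / total,
            )
        else:
            merged.append(call)
    return merged


def associate_promoter_cgi(
    promoter: AnchoredSequence, **kwargs
) -> tuple[bool, list[CgiCall]]:
    """CGI association of a promoter scanned over [-200, +200] around its TSS.

    The promoter is associated when at least one island is called anywhere in
    the scanned span; the island need not cover the TSS itself.
    """
    if promoter.rel_start > -200 or promoter.rel_end < 200:
        raise ValueError(
            "promoter window must cover at least [-200, +200) around the TSS; "
            f"got [{promoter.rel_start}, {promoter.rel_end})"
        )
    sub = promoter.subseq(-200, min(promoter.rel_end, 201))
    calls = call_cgis(sub, **kwargs)
    calls = [
        CgiCall(c.rel_start - 200, c.rel_end - 200, c.mean_gc, c.mean_obs_exp)
        for c in calls
    ]
    return bool(calls), calls


def associate_enhancer_cgi(
    enhancer: GenomicInterval,
    genome,
    flank: int = 200,
    **kwargs,
) -> bool:
    """True when a called CGI covers at least one of the enhancer's two TSSs.

    Each TSS is scanned over ``[-flank, +flank]``; association requires the
    island call to contain the TSS base itself (a stricter rule than for
    promoters, matching the divergent-transcript definition where the island
    must overlap an initiation site).
    """
    from .intervals import enhancer_tss_pair

    tss_rev, tss_fwd = enhancer_tss_pair(enhancer)
    for tss, strand in ((tss_rev, "-"), (tss_fwd, "+")):
        anchored = extract_anchored(genome, enhancer.chrom, tss, strand, flank, flank)
        for call in call_cgis(anchored, **kwargs):
            if call.contains(0):
                return True
    return False
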