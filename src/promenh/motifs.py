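"""Position-weight-matrix scanning of core promoter elements (CPEs) and the
localized-overrepresentation test.

Twelve CPEs are shipped as an editable YAML asset (``assets/cpe_pwms.yaml``)
built from published IUPAC consensus sequences: TATA, Inr, BREu, BREd, DPE,
MTE, DCE I-III, XCPE1, TCT and the Pause Button. Each matrix carries a score
cutoff, the canonical start position of the motif relative to the TSS, and
(for DPE) a dependency on Inr: DPE is only called in elements that also carry
an Inr hit in the Inr functional window, mirroring the cooperative
TFIID-mediated function of the two elements.

The overrepresentation statistic asks whether more elements carry a motif
hit starting inside the *functional window* (expected position +/- 2 nt)
than inside background 5-nt windows slid across [-500, +200]; both a
Gaussian z-score and a binomial upper tail are computed and significance
requires both.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml
from scipy.stats import binom, norm

from .intervals import AnchoredSequence

SCAN_START = -500
SCAN_END = 200  # inclusive
FUNCTIONAL_HALFWIDTH = 2
BACKGROUND_WINDOW = 5

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def frequencies_from_iupac(consensus: str, off_base: float = 0.02) -> np.ndarray:
    """Per-column base frequencies (shape ``(L, 4)``, order ACGT) for an IUPAC string.

    Bases allowed by the code share the probability mass evenly; each
    disallowed base keeps a small floor ``off_base``.
    """
    rows = []
    for ch in consensus.upper():
        try:
            allowed = IUPAC[ch]
        except KeyError:
            raise ValueError(f"not an IUPAC nucleotide code: {ch!r}") from None
        k = len(allowed)
        share = (1.0 - off_base * (4 - k)) / k
        rows.append([share if b in allowed else off_base for b in _BASES])
    return np.asarray(rows, dtype=float)


def pwm_weights_from_frequencies(
    freqs: np.ndarray,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    pseudocount: float = 0.01,
) -> np.ndarray:
    """Log-odds weights ``w = log2(((f + pc*q) / (1 + pc)) / q)``.

    ``freqs`` has shape ``(L, 4)`` with columns summing to 1; a zero frequency
    with zero pseudocount is rejected (it would give an infinite weight).
    """
    f = np.asarray(freqs, dtype=float)
    if f.ndim != 2 or f.shape[1] != 4:
        raise ValueError(f"frequency matrix must be (L, 4), got {f.shape}")
    if not np.allclose(f.sum(axis=1), 1.0, atol=1e-3):
        raise ValueError("frequency columns must each sum to 1")
    q = np.asarray(background, dtype=float)
    if pseudocount == 0 and np.any(f == 0):
        raise ValueError("zero frequency with zero pseudocount gives an infinite weight")
    adjusted = (f + pseudocount * q) / (1.0 + pseudocount)
    return np.log2(adjusted / q)


@dataclass(frozen=True)
class PWM:
    name: str
    weights: np.ndarray  # (L, 4), columns A C G T
    cutoff: float
    expected_position: int
    functional_halfwidth: int = FUNCTIONAL_HALFWIDTH
    requires: str | None = None
    consensus: str = ""

    def __post_init__(self) -> None:
        if self.cutoff > self.max_score + 1e-9:
            raise ValueError(
                f"{self.name}: cutoff {self.cutoff} exceeds max achievable "
                f"score {self.max_score}"
            )

    @property
    def length(self) -> int:
        return self.weights.shape[0]

    @property
    def max_score(self) -> float:
        return float(self.weights.max(axis=1).sum())

    @property
    def functional_window(self) -> tuple[int, int]:
        """Inclusive start-position window where a hit counts as 'at the expected location'."""
        return (
            self.expected_position - self.functional_halfwidth,
            self.expected_position + self.functional_halfwidth,
        )

    @property
    def consensus_from_weights(self) -> str:
        return "".join(_BASES[i] for i in self.weights.argmax(axis=1))

    def score(self, oligo: str) -> float:
        """Matching score of one oligonucleotide; any non-ACGT base scores -inf."""
        if len(oligo) != self.length:
            raise ValueError(f"oligo length {len(oligo)} != matrix length {self.length}")
        total = 0.0
        for i, ch in enumerate(oligo.upper()):
            j = _BASE_INDEX.get(ch)
            if j is None:
                return float("-inf")
            total += self.weights[i, j]
        return total


def load_pwms(path: str | Path | None = None) -> dict[str, PWM]:
    """Load the PWM asset (the shipped twelve-CPE YAML by default).

    Cutoffs may be given as a number (inclusive score threshold) or as
    ``{fraction: f}``, resolved to ``f * max_score`` at load time.
    """
    if path is None:
        with resources.files("promenh").joinpath("assets/cpe_pwms.yaml").open() as fh:
            spec = yaml.safe_load(fh)
    else:
        with open(path) as fh:
            spec = yaml.safe_load(fh)
    background = spec.get("background", [0.25, 0.25, 0.25, 0.25])
    pseudocount = spec.get("pseudocount", 0.01)
    pwms: dict[str, PWM] = {}
    for entry in spec["pwms"]:
        freqs = np.asarray(entry["matrix"], dtype=float)
        weights = pwm_weights_from_frequencies(freqs, background, pseudocount)
        cutoff = entry["cutoff"]
        if isinstance(cutoff, Mapping):
            max_score = float(weights.max(axis=1).sum())
            cutoff = float(cutoff["fraction"]) * max_score
        pwm = PWM(
            name=entry["name"],
            weights=weights,
            cutoff=float(cutoff),
            expected_position=int(entry["expected_position"]),
            functional_halfwidth=int(entry.get("functional_halfwidth", FUNCTIONAL_HALFWIDTH)),
            requires=entry.get("requires"),
            consensus=entry.get("consensus", ""),
        )
        pwms[pwm.name] = pwm
    for pwm in pwms.values():
        if pwm.requires is not None and pwm.requires not in pwms:
            raise ValueError(f"{pwm.name} requires unknown CPE {pwm.requires!r}")
    return pwms


@dataclass(frozen=True)
class MotifHit:
    element_id: str
    cpe_name: str
    start: int  # relative to the TSS
    score: float


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    idx = np.full(arr.shape, 4, dtype=np.int8)
    for i, b in enumerate(_BASES):
        idx[arr == ord(b)] = i
    return idx


def _raw_hits(element: AnchoredSequence, pwm: PWM,
              scan_start: int, scan_end: int) -> list[tuple[int, float]]:
    lo = max(element.rel_start, scan_start)
    hi = min(element.rel_end - pwm.length, scan_end)
    if hi < lo:
        return []
    sub = element.subseq(lo, hi + pwm.length)
    idx = _encode(sub)
    n = hi - lo + 1
    scores = np.zeros(n, dtype=float)
    bad = np.zeros(n, dtype=bool)
    for i in range(pwm.length):
        col = idx[i : i + n]
        bad |= col == 4
        scores += np.where(col == 4, 0.0, pwm.weights[i][np.clip(col, 0, 3)])
    scores[bad] = -np.inf
    where = np.nonzero(scores >= pwm.cutoff)[0]
    return [(int(j) + lo, float(scores[j])) for j in where]


def scan(
    element: AnchoredSequence,
    pwm: PWM,
    pwms: Mapping[str, PWM] | None = None,
    element_id: str = "",
    scan_start: int = SCAN_START,
    scan_end: int = SCAN_END,
) -> list[MotifHit]:
    """All positions where the PWM score reaches its cutoff (inclusive).

    When the PWM declares a dependency (``requires``), hits are reported only
    if the required CPE itself has a hit inside *its* functional window; a
    mapping of PWMs must then be supplied to resolve the dependency.
    """
    if pwm.requires is not None:
        if pwms is None or pwm.requires not in pwms:
            raise ValueError(
                f"{pwm.name} requires {pwm.requires}; pass the PWM collection"
            )
        req = pwms[pwm.requires]
        lo, hi = req.functional_window
        req_hits = _raw_hits(element, req, scan_start, scan_end)
        if not any(lo <= start <= hi for start, _ in req_hits):
            return []
    return [
        MotifHit(element_id=element_id, cpe_name=pwm.name, start=start, score=score)
        for start, score in _raw_hits(element, pwm, scan_start, scan_end)
    ]


@dataclass
class PositionalProfile:
    """Per-position counts of elements with a motif hit starting there."""

    cpe_name: str
    counts: np.ndarray
    n_elements: int
    start: int = SCAN_START
    element_hits: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def positions(self) -> np.ndarray:
        return np.arange(self.start, self.start + len(self.counts))


def positional_profile(
    hits: Iterable[MotifHit],
    n_elements: int,
    start: int = SCAN_START,
    end: int = SCAN_END,
) -> PositionalProfile:
    """Aggregate hits into distinct-element counts per start position.

    An element with several hits at the same position is counted once there.
    """
    length = end - start + 1
    by_element: dict[str, set[int]] = {}
    name = ""
    for hit in hits:
        name = hit.cpe_name
        if not (start <= hit.start <= end):
            raise ValueError(f"hit start {hit.start} outside [{start}, {end}]")
        by_element.setdefault(hit.element_id, set()).add(hit.start)
    counts = np.zeros(length, dtype=np.int64)
    element_hits = {}
    for element_id, positions in by_element.items():
        arr = np.array(sorted(positions), dtype=np.int64)
        element_hits[element_id] = arr
        counts[arr - start] += 1
    if len(by_element) > n_elements:
        raise ValueError("more elements with hits than n_elements")
    return PositionalProfile(
        cpe_name=name, counts=counts, n_elements=n_elements,
        start=start, element_hits=element_hits,
    )


@dataclass(frozen=True)
class OverrepresentationResult:
    cpe_name: str
    n_plus: int
    background_mean: float
    background_sd: float
    z: float
    p_gaussian: float
    p_binomial: float
    significant: bool
    degenerate: bool = False


def overrepresentation_test(
    profile: PositionalProfile,
    pwm: PWM,
    alpha: float = 0.001,
    window: int = BACKGROUND_WINDOW,
) -> OverrepresentationResult:
    """Test whether the functional window holds more element hits than background.

    ``n_plus`` counts elements with >= 1 hit starting in the functional window
    (expected position +/- 2). Background statistics come from sliding a
    ``window``-nt window across the full scanned span: per window the number
    of elements with a hit starting inside it, with windows overlapping the
    functional window excluded. Significance requires both the Gaussian upper
    tail of the z-score and the binomial upper tail (success probability =
    background mean / number of elements) to fall below ``alpha``.
    """
    start = profile.start
    length = len(profile.counts)
    n_windows = length - window + 1
    if n_windows < 2:
        raise ValueError("profile too short for the background window scan")

    # per-element presence per window, via cumulative hit counts
    win_counts = np.zeros(n_windows, dtype=np.int64)
    if profile.element_hits:
        mat = np.zeros((len(profile.element_hits), length), dtype=np.int8)
        for row, positions in enumerate(profile.element_hits.values()):
            mat[row, positions - start] = 1
        cs = np.zeros((mat.shape[0], length + 1), dtype=np.int32)
        np.cumsum(mat, axis=1, out=cs[:, 1:])
        win_counts = ((cs[:, window:] - cs[:, :-window]) > 0).sum(axis=0)

    fw_lo, fw_hi = pwm.functional_window
    fw_cols = np.arange(max(fw_lo, start), min(fw_hi, start + length - 1) + 1) - start
    n_plus = 0
    if profile.element_hits and fw_cols.size:
        n_plus = int(
            (mat[:, fw_cols].sum(axis=1) > 0).sum()
        )

    window_starts = np.arange(start, start + n_windows)
    overlap = (window_starts <= fw_hi) & (window_starts + window - 1 >= fw_lo)
    background = win_counts[~overlap]
    mu = float(background.mean())
    sd = float(background.std(ddof=1))

    if sd == 0.0:
        degenerate = True
        z = float("inf") if n_plus > mu else float("-inf") if n_plus < mu else 0.0
        p_gauss = 0.0 if n_plus > mu else 1.0
    else:
        degenerate = False
        z = (n_plus - mu) / sd
        p_gauss = float(norm.sf(z))

    n = profile.n_elements
    rate = min(mu / n, 1.0) if n > 0 else 0.0
    p_binom = float(binom.sf(n_plus - 1, n, rate)) if n > 0 else 1.0

    return OverrepresentationResult(
        cpe_name=profile.cpe_name or pwm.name,
        n_plus=n_plus,
        background_mean=mu,
        background_sd=sd,
        z=float(z),
        p_gaussian=p_gauss,
        p_binomial=p_binom,
        significant=(p_gauss < alpha) and (p_binom < alpha),
        degenerate=degenerate,
    )


def elements_with_functional_hit(hits: Iterable[MotifHit], pwm: PWM) -> set[str]:
    """Element ids carrying a hit of this CPE inside its functional window."""
    lo, hi = pwm.functional_window
    return {h.element_id for h in hits if h.cpe_name == pwm.name and lo <= h.start <= hi}


def cooccurrence_table(set1: set[str], set2: set[str], all_elements: Iterable[str]):
    """2x2 table of joint functional-window presence over a universe of elements."""
    from .stats import ContingencyTable2x2

    universe = set(all_elements)
    a = len(set1 & set2 & universe)
    b = len((set1 & universe) - set2)
    c = len((set2 & universe) - set1)
    d = len(universe - set1 - set2)
    return ContingencyTable2x2(a=a, b=b, c=c, d=d)
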