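"""Synthetic input generator with machine-readable ground truth.

Every pipeline input (genome FASTA with planted CpG islands and core
promoter elements, CAGE tag tables with controlled sharpness, tissue
breadth and directionality, and narrowPeak files with controlled per-group
peak densities) can be generated from one :class:`SimConfig`, fully
deterministically for a fixed seed. Group effects default to the direction
observed in FANTOM5/ENCODE-style data — CGI elements are longer, more
broadly expressed, more broadly initiating, more directional, and denser in
binding events — so downstream comparison stages produce directionally
realistic results out of the box.

Each element lives on its own small chromosome, which keeps coordinate
bookkeeping trivial and regions of different elements independent.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .intervals import (
    GenomicInterval,
    NarrowPeak,
    enhancer_midpoint,
    enhancer_tss_pair,
    promoter_region,
    reverse_complement,
)
from . import io as pio
from .motifs import PWM, load_pwms

# 20-nt tile with 13 GC (65%) and exactly two CpG dinucleotides, none across
# the tiling seam: tiled copies give near-constant window composition
# (GC ~65%, CpG obs/exp ~0.95), i.e. a composition-controlled island.
CGI_TILE = "CGCGGATGCAGCTGCATGCA"

PROMOTER_CHROM_LEN = 1801
PROMOTER_TSS = 900
ENHANCER_FLANK = 600


def _per_group(value, key: str) -> float:
    """Accept either a scalar or a {'cgi': x, 'non_cgi': y} mapping."""
    if isinstance(value, Mapping):
        return float(value[key])
    return float(value)


@dataclass
class SimConfig:
    """All knobs of the generator; one YAML file controls everything."""

    seed: int = 0
    n_promoters: int = 300
    n_enhancers: int = 300
    # CGI-association fractions of the FANTOM5/EPDnew-scale datasets
    cgi_fraction_promoters: float = 0.586
    cgi_fraction_enhancers: float = 0.057
    gc_background: float = 0.41
    cgi_length_range: tuple[int, int] = (250, 1200)
    cgi_mutation_rate: float = 0.03
    # per-CPE (plant probability, positional jitter sd in nt)
    motif_plant_rates: dict = field(
        default_factory=lambda: {
            "TATA": (0.15, 1.0),
            "Inr": (0.45, 1.0),
            "DPE": (0.40, 1.0),
            "BREu": (0.10, 1.0),
            "TCT": (0.10, 1.0),
        }
    )
    # CAGE: sharp/broad and specific/ubiquitous mix, by CGI status
    sharp_fraction: dict = field(default_factory=lambda: {"cgi": 0.15, "non_cgi": 0.85})
    specific_fraction: dict = field(default_factory=lambda: {"cgi": 0.2, "non_cgi": 0.8})
    broad_sd: float = 20.0
    tag_depth: int = 200
    enhancer_tag_depth: int = 100
    n_tissues: int = 29
    n_primary_cells: int = 36
    # Beta shape pair per CGI status; directionality = 2*Beta - 1
    directionality_beta_params: dict = field(
        default_factory=lambda: {"cgi": (0.35, 0.35), "non_cgi": (3.0, 3.0)}
    )
    # fixed directionality overrides the Beta draw when set
    directionality_fixed: float | None = None
    # lognormal (meanlog, sdlog) of enhancer body length per CGI status;
    # defaults give group means ~384 / ~289 nt with a >1 kb tail of ~2.6% / ~0.5%
    enhancer_length_lognorm: dict = field(
        default_factory=lambda: {"cgi": (5.7706, 0.6), "non_cgi": (5.516, 0.55)}
    )
    enhancer_length_clip: tuple[int, int] = (100, 2500)
    # transcription-factor binding events per kb, by region kind and CGI status
    peak_density_by_group: dict = field(
        default_factory=lambda: {
            "promoter": {"cgi": 5.06, "non_cgi": 1.89},
            "enhancer": {"cgi": 2.46, "non_cgi": 1.15},
        }
    )
    peak_length_mean: float = 491.5
    peak_length_sd: float = 222.4
    h3k27ac_density: float = 2.0
    h3k27ac_signal_median: dict = field(default_factory=lambda: {"cgi": 5000.0, "non_cgi": 2500.0})
    h3k27ac_signal_sigma: float = 1.0

    def __post_init__(self) -> None:
        for name in ("cgi_fraction_promoters", "cgi_fraction_enhancers", "gc_background"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.n_promoters <= 0 or self.n_enhancers < 0:
            raise ValueError("element counts must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown SimConfig keys: {sorted(unknown)}")
        for key in ("cgi_length_range", "enhancer_length_clip"):
            if key in data:
                data[key] = tuple(data[key])
        for key in ("motif_plant_rates", "directionality_beta_params", "enhancer_length_lognorm"):
            if key in data and isinstance(data[key], dict):
                data[key] = {k: tuple(v) for k, v in data[key].items()}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


@dataclass
class SimData:
    """Bundle of generated inputs plus ground truth."""

    config: SimConfig
    genome: dict[str, str]
    promoters: pd.DataFrame
    enhancers: pd.DataFrame
    cgi_truth: pd.DataFrame
    motif_truth: pd.DataFrame
    promoter_tags: pd.DataFrame
    enhancer_tags: pd.DataFrame
    library_map: pd.DataFrame
    tf_peaks: list
    h3k27ac_peaks: list
    cage_truth: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# genome + CGIs


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    return rng.choice(bases, size=length, p=p).tobytes().decode("ascii")


def _cgi_block(rng: np.random.Generator, length: int, mutation_rate: float) -> str:
    reps = length // len(CGI_TILE) + 1
    block = (CGI_TILE * reps)[:length]
    n_mut = rng.binomial(length, mutation_rate)
    if n_mut:
        positions = rng.choice(length, size=n_mut, replace=False)
        arr = bytearray(block, "ascii")
        subs = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=n_mut)
        for pos, sub in zip(positions, subs):
            arr[pos] = sub
        block = arr.decode("ascii")
    return block


def simulate_genome(config: SimConfig, rng: np.random.Generator | None = None):
    """Generate chromosomes, element tables and the planted-CGI truth BED.

    Returns ``(genome, promoters, enhancers, cgi_truth)``. CGI-positive
    elements carry a composition-controlled island block (length uniform in
    ``cgi_length_range``, GC ~65%, CpG obs/exp ~0.95) covering the designated
    TSS; the truth table records the planted span per element.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    genome: dict[str, str] = {}
    truth_rows = []

    prom_rows = []
    for i in range(config.n_promoters):
        chrom = f"chrP{i:05d}"
        strand = "+" if rng.random() < 0.5 else "-"
        has_cgi = rng.random() < config.cgi_fraction_promoters
        seq = _random_sequence(rng, PROMOTER_CHROM_LEN, config.gc_background)
        tss = PROMOTER_TSS
        if has_cgi:
            blen = int(rng.integers(config.cgi_length_range[0], config.cgi_length_range[1] + 1))
            block = _cgi_block(rng, blen, config.cgi_mutation_rate)
            b0 = max(tss - blen // 2, 0)
            b1 = min(b0 + blen, PROMOTER_CHROM_LEN)
            seq = seq[:b0] + block[: b1 - b0] + seq[b1:]
            truth_rows.append({"element_id": f"p{i:05d}", "chrom": chrom,
                               "start": b0, "end": b1})
        genome[chrom] = seq
        region = promoter_region(chrom, tss, strand)
        prom_rows.append(
            {
                "element_id": f"p{i:05d}", "kind": "promoter", "chrom": chrom,
                "start": region.start, "end": region.end, "strand": strand,
                "tss": tss, "cgi_planted": has_cgi,
            }
        )
    promoters = pd.DataFrame(prom_rows)

    enh_rows = []
    for i in range(config.n_enhancers):
        chrom = f"chrE{i:05d}"
        has_cgi = rng.random() < config.cgi_fraction_enhancers
        meanlog, sdlog = config.enhancer_length_lognorm["cgi" if has_cgi else "non_cgi"]
        length = int(np.clip(np.round(rng.lognormal(meanlog, sdlog)),
                             *config.enhancer_length_clip))
        chrom_len = length + 2 * ENHANCER_FLANK
        seq = _random_sequence(rng, chrom_len, config.gc_background)
        start, end = ENHANCER_FLANK, ENHANCER_FLANK + length
        if has_cgi:
            tss_rev, tss_fwd = start, end - 1
            target = tss_fwd if rng.random() < 0.5 else tss_rev
            blen = int(rng.integers(config.cgi_length_range[0], config.cgi_length_range[1] + 1))
            block = _cgi_block(rng, blen, config.cgi_mutation_rate)
            b0 = max(target - blen // 2, 0)
            b1 = min(b0 + blen, chrom_len)
            seq = seq[:b0] + block[: b1 - b0] + seq[b1:]
            truth_rows.append({"element_id": f"e{i:05d}", "chrom": chrom,
                               "start": b0, "end": b1})
        genome[chrom] = seq
        enh_rows.append(
            {
                "element_id": f"e{i:05d}", "kind": "enhancer", "chrom": chrom,
                "start": start, "end": end, "strand": ".",
                "tss": np.nan, "cgi_planted": has_cgi,
            }
        )
    enhancers = pd.DataFrame(
        enh_rows,
        columns=["element_id", "kind", "chrom", "start", "end", "strand", "tss", "cgi_planted"],
    )
    cgi_truth = pd.DataFrame(truth_rows, columns=["element_id", "chrom", "start", "end"])
    return genome, promoters, enhancers, cgi_truth


# ---------------------------------------------------------------------------
# motifs


def tss_frames(promoters: pd.DataFrame, enhancers: pd.DataFrame) -> pd.DataFrame:
    """One row per TSS-anchored scan frame: promoters plus both enhancer TSSs."""
    rows = []
    for row in promoters.itertuples(index=False):
        rows.append({"frame_id": row.element_id, "element_id": row.element_id,
                     "chrom": row.chrom, "tss": int(row.tss), "strand": row.strand,
                     "kind": "promoter", "cgi_planted": row.cgi_planted})
    for row in enhancers.itertuples(index=False):
        iv = GenomicInterval(row.chrom, int(row.start), int(row.end))
        tss_rev, tss_fwd = enhancer_tss_pair(iv)
        rows.append({"frame_id": f"{row.element_id}:F", "element_id": row.element_id,
                     "chrom": row.chrom, "tss": tss_fwd, "strand": "+",
                     "kind": "enhancer", "cgi_planted": row.cgi_planted})
        rows.append({"frame_id": f"{row.element_id}:R", "element_id": row.element_id,
                     "chrom": row.chrom, "tss": tss_rev, "strand": "-",
                     "kind": "enhancer", "cgi_planted": row.cgi_planted})
    return pd.DataFrame(rows)


def _plant_order(names) -> list[str]:
    priority = {"TATA": 0, "Inr": 1, "DPE": 2}
    return sorted(names, key=lambda n: (priority.get(n, 3), n))


def simulate_motifs(
    config: SimConfig,
    genome: dict[str, str],
    frames: pd.DataFrame,
    pwms: Mapping[str, PWM] | None = None,
    rng: np.random.Generator | None = None,
):
    """Write CPE consensus oligonucleotides into element sequences.

    For each frame and each configured CPE, with the configured probability
    the matrix consensus is planted at ``expected_position + N(0, jitter)``
    (rounded). DPE is planted only in frames where Inr was planted;
    overlapping plants are skipped in priority order TATA > Inr > DPE >
    others. Returns the mutated genome and a truth table of planted
    positions.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    pwms = pwms if pwms is not None else load_pwms()
    unknown = set(config.motif_plant_rates) - set(pwms)
    if unknown:
        raise ValueError(f"motif_plant_rates names unknown CPEs: {sorted(unknown)}")
    mutable = {chrom: bytearray(seq, "ascii") for chrom, seq in genome.items()}
    truth_rows = []
    order = _plant_order(config.motif_plant_rates)
    for frame in frames.itertuples(index=False):
        occupied: list[tuple[int, int]] = []
        planted: set[str] = set()
        for name in order:
            rate, jitter = config.motif_plant_rates[name]
            pwm = pwms[name]
            if pwm.requires is not None and pwm.requires not in planted:
                continue
            if rng.random() >= rate:
                continue
            pos = pwm.expected_position + (
                int(np.round(rng.normal(0.0, jitter))) if jitter > 0 else 0
            )
            span = (pos, pos + pwm.length)
            if any(span[0] < e and s < span[1] for s, e in occupied):
                continue
            oligo = pwm.consensus_from_weights
            arr = mutable[frame.chrom]
            if frame.strand == "-":
                a1 = frame.tss - pos  # genomic coordinate of relative `pos`
                a0 = a1 - pwm.length + 1
                written = reverse_complement(oligo)
            else:
                a0 = frame.tss + pos
                a1 = a0 + pwm.length - 1
                written = oligo
            if a0 < 0 or a1 >= len(arr):
                continue
            arr[a0 : a1 + 1] = written.encode("ascii")
            occupied.append(span)
            planted.add(name)
            truth_rows.append({"frame_id": frame.frame_id, "cpe_name": name,
                               "rel_start": pos})
    new_genome = {chrom: arr.decode("ascii") for chrom, arr in mutable.items()}
    truth = pd.DataFrame(truth_rows, columns=["frame_id", "cpe_name", "rel_start"])
    return new_genome, truth


# ---------------------------------------------------------------------------
# CAGE


def make_library_map(config: SimConfig) -> pd.DataFrame:
    rows = []
    for i in range(config.n_tissues):
        rows.append({"library_id": f"L_T{i + 1:02d}", "group": f"tissue{i + 1:02d}",
                     "class": "tissue"})
    for i in range(config.n_primary_cells):
        rows.append({"library_id": f"L_P{i + 1:02d}", "group": f"primary{i + 1:02d}",
                     "class": "primary_cell"})
    return pd.DataFrame(rows)


def _tag_positions(rng, n, sharp, broad_sd):
    if sharp:
        return rng.integers(-1, 2, size=n)
    pos = np.round(rng.normal(0.0, broad_sd, size=n)).astype(int)
    return np.clip(pos, -50, 50)


def _expressed_libraries(rng, config, library_map, specific):
    if not specific:
        return list(library_map["library_id"])
    libs = []
    for cls in ("tissue", "primary_cell"):
        pool = library_map[library_map["class"] == cls]["library_id"].to_numpy()
        if len(pool):
            libs.append(str(rng.choice(pool)))
    return libs


def simulate_cage(
    config: SimConfig,
    promoters: pd.DataFrame,
    enhancers: pd.DataFrame,
    rng: np.random.Generator | None = None,
):
    """CAGE tag tables for promoters (TSS-relative) and enhancers (midpoint-relative).

    Sharp elements initiate from a point (+/-1 nt); broad elements from a
    truncated Normal(0, ``broad_sd``). Tissue-specific elements express in a
    single tissue and a single primary cell; ubiquitous elements in every
    library. Enhancer tags are split between strands according to a
    per-enhancer directionality drawn from the configured Beta distribution,
    with tag positions clustered around the two edge TSSs.

    Returns ``(promoter_tags, enhancer_tags, library_map, cage_truth)``.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    library_map = make_library_map(config)
    truth_rows = []
    prom_rows = []
    for row in promoters.itertuples(index=False):
        grp = "cgi" if row.cgi_planted else "non_cgi"
        sharp = rng.random() < _per_group(config.sharp_fraction, grp)
        specific = rng.random() < _per_group(config.specific_fraction, grp)
        truth_rows.append({"element_id": row.element_id, "sharp": sharp,
                           "specific": specific, "directionality": np.nan})
        for lib in _expressed_libraries(rng, config, library_map, specific):
            n = int(rng.poisson(config.tag_depth))
            if n == 0:
                continue
            pos = _tag_positions(rng, n, sharp, config.broad_sd)
            for p, c in zip(*np.unique(pos, return_counts=True)):
                prom_rows.append((row.element_id, lib, "+", int(p), int(c)))
    promoter_tags = pd.DataFrame(
        prom_rows, columns=["element_id", "library_id", "strand", "rel_position", "count"]
    )

    enh_rows = []
    for row in enhancers.itertuples(index=False):
        grp = "cgi" if row.cgi_planted else "non_cgi"
        sharp = rng.random() < _per_group(config.sharp_fraction, grp)
        specific = rng.random() < _per_group(config.specific_fraction, grp)
        if config.directionality_fixed is not None:
            d = float(config.directionality_fixed)
        else:
            a, b = config.directionality_beta_params[grp]
            d = 2.0 * rng.beta(a, b) - 1.0
        truth_rows.append({"element_id": row.element_id, "sharp": sharp,
                           "specific": specific, "directionality": d})
        iv = GenomicInterval(row.chrom, int(row.start), int(row.end))
        mid = enhancer_midpoint(iv)
        tss_rev, tss_fwd = enhancer_tss_pair(iv)
        d_fwd = tss_fwd - mid
        d_rev = tss_rev - mid
        for lib in _expressed_libraries(rng, config, library_map, specific):
            n = int(rng.poisson(config.enhancer_tag_depth))
            if n == 0:
                continue
            fwd = rng.random(n) < (1.0 + d) / 2.0
            n_f = int(fwd.sum())
            if n_f:
                pos = d_fwd + _tag_positions(rng, n_f, sharp, config.broad_sd)
                for p, c in zip(*np.unique(pos, return_counts=True)):
                    enh_rows.append((row.element_id, lib, "+", int(p), int(c)))
            n_r = n - n_f
            if n_r:
                pos = d_rev - _tag_positions(rng, n_r, sharp, config.broad_sd)
                for p, c in zip(*np.unique(pos, return_counts=True)):
                    enh_rows.append((row.element_id, lib, "-", int(p), int(c)))
    enhancer_tags = pd.DataFrame(
        enh_rows, columns=["element_id", "library_id", "strand", "rel_position", "count"]
    )
    cage_truth = pd.DataFrame(
        truth_rows, columns=["element_id", "sharp", "specific", "directionality"]
    )
    return promoter_tags, enhancer_tags, library_map, cage_truth


# ---------------------------------------------------------------------------
# peaks


def simulate_peaks(
    config: SimConfig,
    regions: pd.DataFrame,
    density_by_group,
    signal_median=1000.0,
    signal_sigma: float = 1.0,
    rng: np.random.Generator | None = None,
    name_prefix: str = "peak",
) -> list[NarrowPeak]:
    """Poisson-distributed narrowPeak records over element regions.

    ``regions`` needs columns element_id, chrom, start, end, kind,
    cgi_planted. Per region the peak count is Poisson(density x length /
    1000) with the group-specific density (scalar, or nested by kind and CGI
    status); each peak is centred on a summit uniform in the region, with
    length ~ Normal(``peak_length_mean``, ``peak_length_sd``) clipped to >=
    100 nt and signal drawn log-normally around the group median.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 3)
    peaks: list[NarrowPeak] = []
    k = 0
    for row in regions.itertuples(index=False):
        grp = "cgi" if row.cgi_planted else "non_cgi"
        if isinstance(density_by_group, Mapping):
            by_kind = density_by_group[row.kind]
            dens = _per_group(by_kind, grp)
        else:
            dens = float(density_by_group)
        med = _per_group(signal_median, grp)
        length = int(row.end) - int(row.start)
        n = int(rng.poisson(dens * length / 1000.0))
        for _ in range(n):
            summit = int(rng.integers(int(row.start), int(row.end)))
            plen = int(max(np.round(rng.normal(config.peak_length_mean, config.peak_length_sd)), 100))
            p0 = max(summit - plen // 2, 0)
            p1 = p0 + plen
            signal = float(rng.lognormal(np.log(med), signal_sigma))
            peaks.append(
                NarrowPeak(
                    interval=GenomicInterval(row.chrom, p0, p1, "."),
                    name=f"{name_prefix}{k:06d}",
                    score=min(int(signal), 1000),
                    signal=signal,
                    pvalue_log=-1.0,
                    qvalue_log=-1.0,
                    summit_offset=summit - p0,
                )
            )
            k += 1
    return peaks


def element_regions(promoters: pd.DataFrame, enhancers: pd.DataFrame) -> pd.DataFrame:
    """Region table used for peak simulation and density summaries.

    Promoter regions are the [-500, +200) strand-aware TSS windows already
    stored in the promoter table; enhancer regions are the element bodies.
    """
    cols = ["element_id", "chrom", "start", "end", "kind", "cgi_planted"]
    return pd.concat([promoters[cols], enhancers[cols]], ignore_index=True)


# ---------------------------------------------------------------------------
# everything


def simulate_all(config: SimConfig, pwms: Mapping[str, PWM] | None = None) -> SimData:
    """Run every generator stage off one master seed and return the bundle."""
    master = np.random.default_rng(config.seed)
    seeds = master.integers(0, 2**31 - 1, size=4)
    genome, promoters, enhancers, cgi_truth = simulate_genome(
        config, np.random.default_rng(seeds[0])
    )
    frames = tss_frames(promoters, enhancers)
    genome, motif_truth = simulate_motifs(
        config, genome, frames, pwms=pwms, rng=np.random.default_rng(seeds[1])
    )
    promoter_tags, enhancer_tags, library_map, cage_truth = simulate_cage(
        config, promoters, enhancers, rng=np.random.default_rng(seeds[2])
    )
    peak_rng = np.random.default_rng(seeds[3])
    regions = element_regions(promoters, enhancers)
    tf_peaks = simulate_peaks(
        config, regions, config.peak_density_by_group, rng=peak_rng, name_prefix="tf"
    )
    h3k_peaks = simulate_peaks(
        config, regions, config.h3k27ac_density,
        signal_median=config.h3k27ac_signal_median,
        signal_sigma=config.h3k27ac_signal_sigma,
        rng=peak_rng, name_prefix="h3k27ac",
    )
    return SimData(
        config=config, genome=genome, promoters=promoters, enhancers=enhancers,
        cgi_truth=cgi_truth, motif_truth=motif_truth,
        promoter_tags=promoter_tags, enhancer_tags=enhancer_tags,
        library_map=library_map, tf_peaks=tf_peaks, h3k27ac_peaks=h3k_peaks,
        cage_truth=cage_truth,
    )


def write_inputs(data: SimData, outdir: str | Path) -> None:
    """Persist all generated inputs and truth tables as plain-text files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"generator": "promenh.simulate", "seed": data.config.seed}
    pio.write_fasta(data.genome, outdir / "genome.fa")
    data.config.to_yaml(outdir / "sim_config.yaml")
    pio.write_tsv(data.promoters, outdir / "promoters.tsv", meta)
    pio.write_tsv(data.enhancers, outdir / "enhancers.tsv", meta)
    pio.write_tsv(data.cgi_truth, outdir / "cgi_truth.tsv", meta)
    pio.write_tsv(data.motif_truth, outdir / "motif_truth.tsv", meta)
    pio.write_tsv(data.promoter_tags, outdir / "promoter_tags.tsv", meta)
    pio.write_tsv(data.enhancer_tags, outdir / "enhancer_tags.tsv", meta)
    pio.write_tsv(data.library_map, outdir / "library_map.tsv", meta)
    if data.cage_truth is not None:
        pio.write_tsv(data.cage_truth, outdir / "cage_truth.tsv", meta)
    pio.write_bed(data.tf_peaks, outdir / "tf_peaks.narrowPeak")
    pio.write_bed(data.h3k27ac_peaks, outdir / "h3k27ac_peaks.narrowPeak")
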