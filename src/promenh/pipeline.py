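"""End-to-end orchestration: CGI association, CPE scanning and statistics,
CAGE metrics, peak overlap, and the CGI-stratified group comparisons.

The pipeline runs either on generated inputs (a :class:`~promenh.simulate.SimConfig`)
or on files previously written by the generator / supplied by the user, and
emits a consolidated :class:`Report` of per-element annotations and
per-comparison statistics.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import cage as pcage
from . import cgi as pcgi
from . import io as pio
from .intervals import GenomicInterval, enhancer_midpoint, enhancer_tss_pair, extract_anchored
from .motifs import (
    SCAN_END,
    SCAN_START,
    cooccurrence_table,
    elements_with_functional_hit,
    load_pwms,
    overrepresentation_test,
    positional_profile,
    scan,
)
from .peaks import PeakIndex, binding_density
from .simulate import SimConfig, SimData, simulate_all, tss_frames
from .stats import ContingencyTable2x2, FisherResult, compare_groups, fisher_exact_two_sided


def association_test(table: ContingencyTable2x2) -> FisherResult:
    """Two-sided Fisher's exact test with odds ratio for a 2x2 association table.

    Log-space combinatorics keep the p-value meaningful at arbitrarily
    extreme tables (use ``log_p`` below ~1e-300).
    """
    return fisher_exact_two_sided(table)


def length_comparison(enhancers: pd.DataFrame, cgi_column: str = "cgi_called") -> dict:
    """Mean/median length and Mann-Whitney p for CGI vs non-CGI enhancers.

    Accepts either a ``length`` column or ``start``/``end`` coordinates.
    """
    if "length" in enhancers.columns:
        lengths = enhancers["length"].astype(float)
    else:
        lengths = (enhancers["end"] - enhancers["start"]).astype(float)
    flag = enhancers[cgi_column].astype(bool)
    if flag.all() or (~flag).all():
        raise ValueError("both CGI and non-CGI groups must be nonempty")
    res = compare_groups(lengths[flag], lengths[~flag])
    return {
        "mean_cgi": res.mean1, "mean_non_cgi": res.mean2,
        "median_cgi": res.median1, "median_non_cgi": res.median2,
        "n_cgi": res.n1, "n_non_cgi": res.n2, "p": res.p,
    }


def enhancer_transcript_tags(enhancer_tags: pd.DataFrame,
                             enhancers: pd.DataFrame) -> pd.DataFrame:
    """Re-anchor midpoint-relative enhancer tags onto the two edge TSSs.

    Each enhancer yields a forward transcript (``<id>:F``, plus-strand tags,
    positions relative to the forward TSS) and a reverse transcript
    (``<id>:R``), both expressed in transcription orientation with strand
    ``+`` meaning sense. The result feeds the same sharp/broad classification
    as promoter tag tables.
    """
    offsets = {}
    for row in enhancers.itertuples(index=False):
        iv = GenomicInterval(row.chrom, int(row.start), int(row.end))
        mid = enhancer_midpoint(iv)
        tss_rev, tss_fwd = enhancer_tss_pair(iv)
        offsets[row.element_id] = (tss_fwd - mid, tss_rev - mid)
    frames = []
    fwd = enhancer_tags[enhancer_tags["strand"] == "+"].copy()
    if len(fwd):
        fwd["rel_position"] = fwd.apply(
            lambda r: r["rel_position"] - offsets[r["element_id"]][0], axis=1
        )
        fwd["element_id"] = fwd["element_id"] + ":F"
        fwd["strand"] = "+"
        frames.append(fwd)
    rev = enhancer_tags[enhancer_tags["strand"] == "-"].copy()
    if len(rev):
        rev["rel_position"] = rev.apply(
            lambda r: offsets[r["element_id"]][1] - r["rel_position"], axis=1
        )
        rev["element_id"] = rev["element_id"] + ":R"
        rev["strand"] = "+"
        frames.append(rev)
    if not frames:
        return enhancer_tags.iloc[0:0].copy()
    return pd.concat(frames, ignore_index=True)


@dataclass
class Report:
    """Consolidated pipeline output."""

    config: SimConfig
    elements: pd.DataFrame
    comparisons: pd.DataFrame
    cpe_results: pd.DataFrame
    cooccurrence: pd.DataFrame
    sharpness: pd.DataFrame
    tau: pd.DataFrame
    directionality: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in ("elements", "comparisons", "cpe_results", "cooccurrence",
                     "sharpness", "tau", "directionality"):
            pio.write_tsv(getattr(self, name), outdir / f"{name}.tsv", self.metadata)


def _config_hash(config: SimConfig) -> str:
    text = yaml.safe_dump(dataclasses.asdict(config), sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def _comparison_row(name, kind, values_cgi, values_non, test="mann-whitney"):
    v1 = np.asarray(values_cgi, dtype=float)
    v2 = np.asarray(values_non, dtype=float)
    v1 = v1[np.isfinite(v1)]
    v2 = v2[np.isfinite(v2)]
    row = {"comparison": name, "kind": kind, "test": test,
           "n_cgi": v1.size, "n_non_cgi": v2.size}
    if v1.size and v2.size:
        res = compare_groups(v1, v2)
        row.update({"mean_cgi": res.mean1, "mean_non_cgi": res.mean2,
                    "median_cgi": res.median1, "median_non_cgi": res.median2,
                    "p": res.p})
    else:
        row.update({"mean_cgi": np.nan, "mean_non_cgi": np.nan,
                    "median_cgi": np.nan, "median_non_cgi": np.nan, "p": np.nan})
    return row


def run_pipeline(config: SimConfig, outdir: str | Path | None = None,
                 pwms=None, data: SimData | None = None) -> Report:
    """Execute all stages on synthetic (or pre-generated) inputs.

    Stage order: CGI association -> CPE scan / overrepresentation /
    co-occurrence -> dispersion, tau, directionality -> peak overlap and
    densities -> CGI-stratified comparisons. Fully deterministic for a fixed
    config (seed included).
    """
    pwms = pwms if pwms is not None else load_pwms()
    unknown = set(config.motif_plant_rates) - set(pwms)
    if unknown:
        raise ValueError(f"config names unknown CPEs: {sorted(unknown)}")
    if data is None:
        data = simulate_all(config, pwms=pwms)
    genome = data.genome
    promoters, enhancers = data.promoters, data.enhancers
    have_enhancers = len(enhancers) > 0

    # --- CGI association -------------------------------------------------
    prom_cgi = {}
    cgi_regions = []  # called islands in absolute coordinates
    for row in promoters.itertuples(index=False):
        anchored = extract_anchored(genome, row.chrom, int(row.tss), row.strand, 200, 200)
        associated, calls = pcgi.associate_promoter_cgi(anchored)
        prom_cgi[row.element_id] = associated
        for call in calls:
            if row.strand == "-":
                a0, a1 = int(row.tss) - call.rel_end + 1, int(row.tss) - call.rel_start + 1
            else:
                a0, a1 = int(row.tss) + call.rel_start, int(row.tss) + call.rel_end
            cgi_regions.append({"element_id": row.element_id, "chrom": row.chrom,
                                "start": a0, "end": a1, "kind": "cgi",
                                "cgi_planted": True})
    enh_cgi = {}
    for row in enhancers.itertuples(index=False):
        iv = GenomicInterval(row.chrom, int(row.start), int(row.end))
        enh_cgi[row.element_id] = pcgi.associate_enhancer_cgi(iv, genome)

    # --- CPE scanning ----------------------------------------------------
    frames = tss_frames(promoters, enhancers)
    max_len = max(p.length for p in pwms.values())
    hits_by_kind: dict[str, list] = {"promoter": [], "enhancer": []}
    frames_by_kind = {
        "promoter": list(frames[frames["kind"] == "promoter"]["frame_id"]),
        "enhancer": list(frames[frames["kind"] == "enhancer"]["frame_id"]),
    }
    for frame in frames.itertuples(index=False):
        anchored = extract_anchored(
            genome, frame.chrom, int(frame.tss), frame.strand,
            -SCAN_START, SCAN_END + max_len,
        )
        for pwm in pwms.values():
            hits_by_kind[frame.kind].extend(
                scan(anchored, pwm, pwms=pwms, element_id=frame.frame_id)
            )
    cpe_rows = []
    cooc_frames = []
    for kind, kind_hits in hits_by_kind.items():
        ids = frames_by_kind[kind]
        if not ids:
            continue
        functional: dict[str, set] = {}
        for pwm in pwms.values():
            phits = [h for h in kind_hits if h.cpe_name == pwm.name]
            profile = positional_profile(phits, n_elements=len(ids))
            profile.cpe_name = pwm.name
            res = overrepresentation_test(profile, pwm)
            functional[pwm.name] = elements_with_functional_hit(phits, pwm)
            cpe_rows.append({
                "kind": kind, "cpe": pwm.name, "n_elements": len(ids),
                "n_plus": res.n_plus, "mu": res.background_mean,
                "sigma": res.background_sd, "z": res.z,
                "p_gaussian": res.p_gaussian, "p_binomial": res.p_binomial,
                "significant": res.significant, "degenerate": res.degenerate,
            })
        names = sorted(pwms)
        tables = {}
        for i, n1 in enumerate(names):
            for n2 in names[i + 1 :]:
                tables[(n1, n2)] = cooccurrence_table(functional[n1], functional[n2], ids)
        from .stats import cooccurrence_tests

        cooc = cooccurrence_tests(tables, n_items=len(names))
        cooc.insert(0, "kind", kind)
        cooc_frames.append(cooc)
    cpe_results = pd.DataFrame(cpe_rows)
    cooccurrence = pd.concat(cooc_frames, ignore_index=True) if cooc_frames else pd.DataFrame()

    # --- CAGE metrics ----------------------------------------------------
    sharp_prom = pcage.dispersion_table(data.promoter_tags)
    sharp_prom["kind"] = "promoter"
    sharp_frames = [sharp_prom]
    if have_enhancers and len(data.enhancer_tags):
        transcript_tags = enhancer_transcript_tags(data.enhancer_tags, enhancers)
        sharp_enh = pcage.dispersion_table(transcript_tags)
        sharp_enh["kind"] = "enhancer_transcript"
        sharp_frames.append(sharp_enh)
    sharpness = pd.concat(sharp_frames, ignore_index=True)

    tau_frames = []
    for kind, tags, window, mode in (
        ("promoter", data.promoter_tags, (-100, 100), "sense"),
        ("enhancer", data.enhancer_tags, (-200, 200), "both"),
    ):
        if not len(tags):
            continue
        for cls in ("tissue", "primary_cell"):
            expr = pcage.group_expression(
                tags, data.library_map, window=window, strand_mode=mode,
                library_classes=(cls,),
            )
            top = pcage.select_top_groups(expr, n_top=15)
            tt = pcage.tau_table(expr[top])
            tt["kind"] = kind
            tt["library_class"] = cls
            tau_frames.append(tt)
    tau = pd.concat(tau_frames, ignore_index=True) if tau_frames else pd.DataFrame()

    if have_enhancers and len(data.enhancer_tags):
        directionality = pcage.directionality_table(data.enhancer_tags)
    else:
        directionality = pd.DataFrame(
            columns=["element_id", "forward", "reverse", "directionality", "defined"]
        )

    # --- peak overlap -----------------------------------------------------
    from .simulate import element_regions

    regions_df = element_regions(promoters, enhancers)
    region_list = [
        (r.element_id, GenomicInterval(r.chrom, int(r.start), int(r.end)))
        for r in regions_df.itertuples(index=False)
    ]
    tf_index = PeakIndex(data.tf_peaks)
    h3k_index = PeakIndex(data.h3k27ac_peaks)
    density = {s.element_id: s for s in binding_density(region_list, tf_index)}
    h3k = {s.element_id: s for s in binding_density(region_list, h3k_index)}
    cgi_region_list = [
        (f"cgi:{r['element_id']}", GenomicInterval(r["chrom"], r["start"], r["end"]))
        for r in cgi_regions
    ]
    cgi_density = binding_density(cgi_region_list, tf_index) if cgi_region_list else []

    # --- per-element annotation table ------------------------------------
    sharp_by_id = dict(zip(sharpness["element_id"], sharpness["label"]))
    disp_by_id = dict(zip(sharpness["element_id"], sharpness["mean_dispersion"]))
    tau_maps = {}
    if len(tau):
        for (kind, cls), sub in tau.groupby(["kind", "library_class"]):
            tau_maps[(kind, cls)] = dict(zip(sub["element_id"], sub["tau"]))
    dir_by_id = dict(zip(directionality["element_id"], directionality["directionality"]))

    rows = []
    for row in pd.concat([promoters, enhancers], ignore_index=True).itertuples(index=False):
        eid, kind = row.element_id, row.kind
        cgi_called = prom_cgi[eid] if kind == "promoter" else enh_cgi[eid]
        dens = density.get(eid)
        hs = h3k.get(eid)
        if kind == "promoter":
            label = sharp_by_id.get(eid, "unclassified")
            dispersion = disp_by_id.get(eid, np.nan)
        else:
            labels = {sharp_by_id.get(f"{eid}:F"), sharp_by_id.get(f"{eid}:R")} - {None}
            label = ";".join(sorted(labels)) if labels else "unclassified"
            dvals = [disp_by_id.get(f"{eid}:{s}", np.nan) for s in "FR"]
            dispersion = float(np.nanmean(dvals)) if not np.all(np.isnan(dvals)) else np.nan
        rows.append({
            "element_id": eid, "kind": kind,
            "length": int(row.end) - int(row.start),
            "cgi_called": bool(cgi_called), "cgi_planted": bool(row.cgi_planted),
            "sharpness": label, "mean_dispersion": dispersion,
            "tau_tissue": tau_maps.get((kind, "tissue"), {}).get(eid, np.nan),
            "tau_primary_cell": tau_maps.get((kind, "primary_cell"), {}).get(eid, np.nan),
            "directionality": dir_by_id.get(eid, np.nan),
            "n_tf_peaks": dens.n_peaks if dens else 0,
            "tf_density_per_kb": dens.density_per_kb if dens else 0.0,
            "h3k27ac_max": hs.max_signal if hs and hs.max_signal is not None else np.nan,
        })
    elements = pd.DataFrame(rows)

    # --- comparisons ------------------------------------------------------
    comp_rows = []
    prom = elements[elements["kind"] == "promoter"]
    enh = elements[elements["kind"] == "enhancer"]

    def split(df, column):
        return df[df["cgi_called"]][column], df[~df["cgi_called"]][column]

    if have_enhancers:
        comp_rows.append(_comparison_row("length_by_cgi", "enhancer", *split(enh, "length")))
    comp_rows.append(_comparison_row("tau_tissue_by_cgi", "promoter", *split(prom, "tau_tissue")))
    if have_enhancers:
        comp_rows.append(_comparison_row("tau_tissue_by_cgi", "enhancer", *split(enh, "tau_tissue")))
        d1, d2 = split(enh, "directionality")
        comp_rows.append(_comparison_row("abs_directionality_by_cgi", "enhancer",
                                         d1.abs(), d2.abs()))
    for kind, df in (("promoter", prom), ("enhancer", enh)):
        if not len(df):
            continue
        comp_rows.append(_comparison_row("tf_density_by_cgi", kind,
                                         *split(df, "tf_density_per_kb")))
        comp_rows.append(_comparison_row("h3k27ac_max_by_cgi", kind,
                                         *split(df, "h3k27ac_max")))
    # sharp/broad x CGI association (Fisher)
    for kind in ("promoter", "enhancer_transcript"):
        sub = sharpness[sharpness["kind"] == kind]
        if not len(sub):
            continue
        if kind == "promoter":
            cgi_of = prom_cgi
            key = sub["element_id"]
        else:
            cgi_of = enh_cgi
            key = sub["element_id"].str.rsplit(":", n=1).str[0]
        flags = key.map(cgi_of)
        classified = sub["label"].isin(["sharp", "broad"])
        a = int(((sub["label"] == "sharp") & flags & classified).sum())
        b = int(((sub["label"] == "sharp") & ~flags & classified).sum())
        c = int(((sub["label"] == "broad") & flags & classified).sum())
        d = int(((sub["label"] == "broad") & ~flags & classified).sum())
        row = {"comparison": "sharpbroad_cgi_association", "kind": kind,
               "test": "fisher-exact", "n_cgi": a + c, "n_non_cgi": b + d,
               "mean_cgi": np.nan, "mean_non_cgi": np.nan,
               "median_cgi": np.nan, "median_non_cgi": np.nan, "p": np.nan}
        if min(a + b, c + d, a + c, b + d) >= 0 and a + b + c + d > 0:
            fres = association_test(ContingencyTable2x2(a, b, c, d))
            row["p"] = fres.p
            row["log_p"] = fres.log_p
            row["odds_ratio"] = fres.odds_ratio
            row.update({"a_sharp_cgi": a, "b_sharp_noncgi": b,
                        "c_broad_cgi": c, "d_broad_noncgi": d})
        comp_rows.append(row)
    if cgi_density:
        vals = [s.density_per_kb for s in cgi_density]
        comp_rows.append({
            "comparison": "tf_density_in_called_cgis", "kind": "cgi",
            "test": "summary", "n_cgi": len(vals), "n_non_cgi": 0,
            "mean_cgi": float(np.mean(vals)), "mean_non_cgi": np.nan,
            "median_cgi": float(np.median(vals)), "median_non_cgi": np.nan,
            "p": np.nan,
        })
    comparisons = pd.DataFrame(comp_rows)

    metadata = {
        "pipeline_version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
    }
    report = Report(
        config=config, elements=elements, comparisons=comparisons,
        cpe_results=cpe_results, cooccurrence=cooccurrence,
        sharpness=sharpness, tau=tau, directionality=directionality,
        metadata=metadata,
    )
    if outdir is not None:
        report.write(outdir)
    return report
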