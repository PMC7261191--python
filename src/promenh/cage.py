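"""CAGE-derived transcription statistics.

Inputs are pre-tabulated tag tables (element_id, library_id, strand,
rel_position, count) with positions relative to the element's reference
point — the TSS for promoters, the midpoint for bidirectional enhancers —
in transcription orientation. Four statistics are computed:

* the per-library dispersion index ``s_i`` (tag-weighted standard deviation
  of initiation positions within +/-50 nt) and its mean, classifying an
  element as *sharp* (mean <= 2.5) or *broad*;
* τ (tau) tissue specificity over grouped, normalized expression;
* transcription directionality ``(F - R) / (F + R)`` of enhancers from
  strand-specific tag counts within 200 nt of the midpoint;
* grouped log2 expression, the input to τ.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SHARP_THRESHOLD = 2.5
DISPERSION_WINDOW = (-50, 50)
EXPRESSION_WINDOW = (-100, 100)
DIRECTIONALITY_FLANK = 200


def dispersion_index(positions, counts) -> float:
    """Tag-count-weighted standard deviation of tag positions for one library.

    ``s = sqrt((1/c) * sum_j (j - m)^2 x_j)`` with ``c = sum_j x_j`` and
    ``m`` the tag-weighted mean position. Undefined (ValueError) when the
    library has no tags.
    """
    j = np.asarray(positions, dtype=float)
    x = np.asarray(counts, dtype=float)
    c = x.sum()
    if c <= 0:
        raise ValueError("dispersion index undefined for a library with no tags")
    m = (j * x).sum() / c
    return float(np.sqrt(((j - m) ** 2 * x).sum() / c))


@dataclass(frozen=True)
class DispersionResult:
    element_id: str
    per_library: dict[str, float]
    mean_dispersion: float  # nan when unclassified
    label: str  # sharp | broad | unclassified


def classify_sharpness(
    per_library_s: dict[str, float],
    element_id: str = "",
    min_informative_libraries: int = 1,
    threshold: float = SHARP_THRESHOLD,
) -> DispersionResult:
    """Sharp/broad call from per-library dispersion indices.

    The mean is taken over informative libraries only; elements with fewer
    than ``min_informative_libraries`` such libraries are left unclassified
    (insufficient tag coverage). The threshold is inclusive: mean <= 2.5 is
    sharp.
    """
    values = [s for s in per_library_s.values() if np.isfinite(s)]
    if len(values) < min_informative_libraries or not values:
        return DispersionResult(element_id, dict(per_library_s), float("nan"), "unclassified")
    mean = float(np.mean(values))
    label = "sharp" if mean <= threshold else "broad"
    return DispersionResult(element_id, dict(per_library_s), mean, label)


def dispersion_table(
    tags: pd.DataFrame,
    window: tuple[int, int] = DISPERSION_WINDOW,
    min_informative_libraries: int = 1,
    threshold: float = SHARP_THRESHOLD,
) -> pd.DataFrame:
    """Sharp/broad classification for every element in a tag table.

    Only sense-strand tags (strand ``+`` = the element's transcription
    direction) within ``window`` are informative.
    """
    lo, hi = window
    sel = tags[
        (tags["strand"] == "+")
        & (tags["rel_position"] >= lo)
        & (tags["rel_position"] <= hi)
        & (tags["count"] > 0)
    ]
    rows = []
    grouped = sel.groupby(["element_id", "library_id"])
    s_by_element: dict[str, dict[str, float]] = {}
    for (element_id, library_id), sub in grouped:
        s = dispersion_index(sub["rel_position"].to_numpy(), sub["count"].to_numpy())
        s_by_element.setdefault(element_id, {})[library_id] = s
    for element_id in tags["element_id"].unique():
        res = classify_sharpness(
            s_by_element.get(element_id, {}),
            element_id=element_id,
            min_informative_libraries=min_informative_libraries,
            threshold=threshold,
        )
        rows.append(
            {
                "element_id": element_id,
                "n_informative_libraries": len(res.per_library),
                "mean_dispersion": res.mean_dispersion,
                "label": res.label,
            }
        )
    return pd.DataFrame(rows)


def group_expression(
    tags: pd.DataFrame,
    library_map: pd.DataFrame,
    window: tuple[int, int] = EXPRESSION_WINDOW,
    scale: float = 1000.0,
    strand_mode: str = "sense",
    library_classes: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Per-element, per-group log2 expression matrix.

    Per library, raw counts become tags-per-million (normalizing by that
    library's total over the whole table); per element the windowed TPM sum
    is averaged over a group's member libraries, scaled, and transformed as
    ``log2(1 + scale * value)``. ``strand_mode`` selects sense-strand tags
    only (promoters) or both strands (enhancer midpoint windows).
    """
    if strand_mode not in ("sense", "both"):
        raise ValueError("strand_mode must be 'sense' or 'both'")
    lm = library_map
    if library_classes is not None:
        lm = lm[lm["class"].isin(library_classes)]
    lib_totals = tags.groupby("library_id")["count"].sum()
    empty = lib_totals[lib_totals == 0].index
    if len(empty):
        lm = lm[~lm["library_id"].isin(empty)]
    lo, hi = window
    sel = tags[(tags["rel_position"] >= lo) & (tags["rel_position"] <= hi)]
    if strand_mode == "sense":
        sel = sel[sel["strand"] == "+"]
    sel = sel[sel["library_id"].isin(lm["library_id"])]
    tpm = sel.groupby(["element_id", "library_id"])["count"].sum().reset_index()
    tpm["tpm"] = tpm["count"] / tpm["library_id"].map(lib_totals).astype(float) * 1e6
    wide = tpm.pivot_table(index="element_id", columns="library_id", values="tpm",
                           fill_value=0.0, aggfunc="sum")
    all_elements = pd.Index(tags["element_id"].unique(), name="element_id")
    wide = wide.reindex(index=all_elements, fill_value=0.0)
    group_of = dict(zip(lm["library_id"], lm["group"]))
    cols = {}
    for group in sorted(set(group_of.values())):
        members = [l for l in wide.columns if group_of.get(l) == group]
        if not members:
            cols[group] = np.zeros(len(wide))
        else:
            cols[group] = wide[members].mean(axis=1).to_numpy()
    expr = pd.DataFrame(cols, index=wide.index)
    return np.log2(1.0 + scale * expr)


@dataclass(frozen=True)
class TauResult:
    element_id: str
    tau: float  # nan when all-zero expression
    n_groups: int
    defined: bool


def tau(expression, element_id: str = "") -> TauResult:
    """Tissue-specificity index over per-group expression values.

    ``tau = sum_i (1 - x_i / max_j x_j) / (n - 1)``; 0 for perfectly uniform
    (housekeeping) profiles, 1 for single-group expression. Undefined for
    all-zero profiles or fewer than two groups.
    """
    x = np.asarray(expression, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("tau requires at least two groups")
    if np.any(x < 0):
        raise ValueError("expression values must be non-negative")
    peak = x.max()
    if peak <= 0:
        return TauResult(element_id, float("nan"), n, False)
    xhat = x / peak
    return TauResult(element_id, float((1.0 - xhat).sum() / (n - 1)), n, True)


def tau_table(expr: pd.DataFrame) -> pd.DataFrame:
    """τ per element from a per-group expression matrix (rows = elements)."""
    rows = []
    for element_id, values in expr.iterrows():
        res = tau(values.to_numpy(), element_id=element_id)
        rows.append({"element_id": element_id, "tau": res.tau,
                     "n_groups": res.n_groups, "defined": res.defined})
    return pd.DataFrame(rows)


def select_top_groups(expr: pd.DataFrame, n_top: int = 15) -> list[str]:
    """The ``n_top`` groups with the largest total log expression over all elements.

    Ties break lexicographically by group name so the selection is
    deterministic; when fewer groups are available all are returned.
    """
    sums = expr.sum(axis=0)
    order = sorted(expr.columns, key=lambda g: (-sums[g], g))
    return order[: min(n_top, len(order))]


@dataclass(frozen=True)
class DirectionalityResult:
    enhancer_id: str
    forward: int
    reverse: int
    directionality: float  # nan when no tags in the windows
    defined: bool


def directionality(
    tags: pd.DataFrame,
    enhancer_id: str = "",
    flank: int = DIRECTIONALITY_FLANK,
    min_tags: int = 1,
) -> DirectionalityResult:
    """Transcription directionality of one enhancer from midpoint-relative tags.

    ``R`` pools reverse-strand tags over ``[-flank, 0)`` and ``F`` forward-
    strand tags over ``[0, +flank]`` (half-open at the midpoint so no tag is
    double counted); directionality is ``(F - R) / (F + R)``, undefined when
    fewer than ``min_tags`` tags fall in the two windows.
    """
    pos = tags["rel_position"]
    r = int(tags[(tags["strand"] == "-") & (pos >= -flank) & (pos < 0)]["count"].sum())
    f = int(tags[(tags["strand"] == "+") & (pos >= 0) & (pos <= flank)]["count"].sum())
    if f + r < max(min_tags, 1):
        return DirectionalityResult(enhancer_id, f, r, float("nan"), False)
    return DirectionalityResult(enhancer_id, f, r, (f - r) / (f + r), True)


def directionality_table(tags: pd.DataFrame, flank: int = DIRECTIONALITY_FLANK,
                         min_tags: int = 1) -> pd.DataFrame:
    rows = []
    for enhancer_id, sub in tags.groupby("element_id"):
        res = directionality(sub, enhancer_id=enhancer_id, flank=flank, min_tags=min_tags)
        rows.append({
            "element_id": enhancer_id, "forward": res.forward, "reverse": res.reverse,
            "directionality": res.directionality, "defined": res.defined,
        })
    return pd.DataFrame(rows)
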