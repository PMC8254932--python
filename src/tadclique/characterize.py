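"""Genomic characterization of TAD categories.

Covers the descriptive analyses run per clique-size category: aggregate
(pileup) intra-TAD contact heatmaps on a common 25x25 grid, convergent
CTCF motif orientation at domain boundaries with exact binomial
enrichment, repeat-class coverage, expression comparison between clique
and non-clique TADs, and subcompartment overlap by base-pair Jaccard
index. A compartment filter supports rerunning any of these on
B-compartment TADs only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import intervals
from .core import BinnedContactMap, TadSegment, TadSegmentation

HEATMAP_SIZE = 25
B_LABELS = ("B1", "B2", "B3", "B4")


@dataclass
class AggregateHeatmap:
    category: str
    matrix: np.ndarray  # HEATMAP_SIZE x HEATMAP_SIZE mean rescaled counts
    n_tads: int


def resize_nearest(matrix: np.ndarray, size: int = HEATMAP_SIZE) -> np.ndarray:
    """Nearest-neighbor resize: target (r, c) takes source
    (floor(r*m/size), floor(c*m/size)) for an m-bin source."""
    m = matrix.shape[0]
    idx = (np.arange(size) * m) // size
    return matrix[np.ix_(idx, idx)]


def intra_tad_matrix(cmap: BinnedContactMap, tad: TadSegment) -> np.ndarray:
    """Dense symmetric bin-level submatrix of one TAD."""
    res = cmap.resolution
    b0 = tad.interval.start // res
    b1 = (tad.interval.end + res - 1) // res
    dense = cmap.to_dense()
    return dense[b0:b1, b0:b1]


def aggregate_intra_tad_heatmap(cmap: BinnedContactMap, tads: list[TadSegment],
                                category: str = "") -> AggregateHeatmap:
    """Element-wise mean of per-TAD intra-TAD matrices resized to 25x25."""
    if not tads:
        raise ValueError(f"no TADs in category {category!r}")
    acc = np.zeros((HEATMAP_SIZE, HEATMAP_SIZE))
    for tad in tads:
        acc += resize_nearest(intra_tad_matrix(cmap, tad))
    return AggregateHeatmap(category, acc / len(tads), len(tads))


def _boundary_strand(motifs: pd.DataFrame, lo: int, hi: int) -> str | None:
    """Strand of the highest-score motif whose midpoint lies in
    [lo, hi], or None when the window is empty."""
    mid = (motifs["start"] + motifs["end"]) // 2
    sel = motifs[(mid >= lo) & (mid <= hi)]
    if sel.empty:
        return None
    return str(sel.loc[sel["score"].idxmax(), "strand"])


def tad_is_convergent(tad: TadSegment, motifs: pd.DataFrame, window_bp: int) -> bool:
    """True iff the TAD's 5' boundary is oriented '+' and its 3'
    boundary '-' — the loop-extrusion-compatible configuration.

    Each boundary is scanned over its inward-facing window (the
    ``window_bp`` of sequence just inside the domain, where loop-anchor
    CTCF sites reside; a symmetric window would pick up the adjacent
    domain's anchor of opposite orientation at every shared boundary).
    When several motifs fall in a window the highest-score motif's
    strand decides that boundary.
    """
    if window_bp <= 0:
        raise ValueError("window must be positive")
    start, end = tad.interval.start, tad.interval.end
    return (_boundary_strand(motifs, start, start + window_bp) == "+"
            and _boundary_strand(motifs, end - window_bp, end) == "-")


def binomial_two_sided(x: int, n: int, p0: float) -> float:
    """Two-sided exact binomial p-value by tail doubling, capped at 1."""
    lower = stats.binom.cdf(x, n, p0)
    upper = stats.binom.sf(x - 1, n, p0)
    return float(min(1.0, 2.0 * min(lower, upper)))


def convergence_enrichment(seg: TadSegmentation, stats_df: pd.DataFrame,
                           motifs: pd.DataFrame, window_bp: int = 50_000) -> pd.DataFrame:
    """Per-category convergent-CTCF summary with binomial enrichment.

    ``stats_df`` is the per-TAD clique-statistics table (indexed by TAD
    id, with a ``category`` column). The null proportion p0 is the
    genome-wide convergent fraction over all categorized TADs; each
    category's count is tested against p0 with a two-sided exact
    binomial test.
    """
    tads = {s.id: s for s in seg.called_domains()}
    conv = {tid: tad_is_convergent(tads[tid], motifs, window_bp)
            for tid in stats_df.index if tid in tads}
    n_all = len(conv)
    if n_all == 0:
        raise ValueError("no categorized TADs found in the segmentation")
    p0 = sum(conv.values()) / n_all
    rows = []
    for cat, grp in stats_df.groupby("category", observed=True):
        ids = [t for t in grp.index if t in conv]
        n = len(ids)
        x = sum(conv[t] for t in ids)
        rows.append({
            "category": cat, "n_tads": n, "n_convergent": x,
            "percent": 100.0 * x / n if n else np.nan,
            "p0_percent": 100.0 * p0,
            "binomial_p": binomial_two_sided(x, n, p0) if n else np.nan,
        })
    return pd.DataFrame(rows).set_index("category")


def interval_coverage(tads: list[TadSegment],
                      annotation: pd.DataFrame) -> pd.Series:
    """Fraction of each TAD covered by the union of annotation intervals.

    Overlapping annotation intervals are merged before intersection, so
    each base pair counts once.
    """
    by_chrom = {
        chrom: intervals.merge(list(zip(grp["start"], grp["end"])))
        for chrom, grp in annotation.groupby("chrom")
    }
    out = {}
    for tad in tads:
        merged = by_chrom.get(tad.interval.chrom, [])
        out[tad.id] = intervals.coverage_fraction(
            (tad.interval.start, tad.interval.end), merged)
    return pd.Series(out, name="coverage")


def repeat_coverage(seg: TadSegmentation, repeats: pd.DataFrame,
                    stats_df: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-TAD coverage fraction for each repeat class (BED name column)."""
    tads = seg.called_domains()
    cols = {}
    for cls, grp in repeats.groupby("name"):
        cols[cls] = interval_coverage(tads, grp)
    df = pd.DataFrame(cols)
    df.index.name = "tad_id"
    if stats_df is not None:
        df = df.join(stats_df[["category", "max_clique_size"]])
    return df


def expression_compare(expression: pd.DataFrame, seg: TadSegmentation,
                       stats_df: pd.DataFrame, min_clique_size: int = 3):
    """Two-sample KS test of gene expression: clique vs non-clique TADs.

    Genes are assigned to the TAD containing their TSS; genes falling in
    gap segments are dropped. Clique TADs are those with maximal clique
    size >= ``min_clique_size``.
    """
    clique_ids = set(stats_df.index[stats_df["max_clique_size"] >= min_clique_size])
    starts = np.array([s.interval.start for s in seg])
    segs = list(seg)
    values = {"clique": [], "non_clique": []}
    for row in expression.itertuples(index=False):
        if row.chrom != seg.chrom or not (seg.start <= row.tss_pos < seg.end):
            continue
        s = segs[int(np.searchsorted(starts, row.tss_pos, side="right")) - 1]
        if not s.is_called_domain:
            continue
        key = "clique" if s.id in clique_ids else "non_clique"
        values[key].append(float(row.value))
    for key, v in values.items():
        if len(v) < 2:
            raise ValueError(f"fewer than 2 genes in class {key!r}")
    ks = stats.ks_2samp(values["clique"], values["non_clique"])
    summary = pd.DataFrame({
        "n_genes": [len(values["clique"]), len(values["non_clique"])],
        "median": [np.median(values["clique"]), np.median(values["non_clique"])],
        "mean": [np.mean(values["clique"]), np.mean(values["non_clique"])],
    }, index=["clique", "non_clique"])
    return float(ks.statistic), float(ks.pvalue), summary


def subcompartment_overlap(seg: TadSegmentation, subcompartments: pd.DataFrame,
                           per_label_union: bool = False) -> pd.DataFrame:
    """Best-overlapping subcompartment per TAD by base-pair Jaccard index.

    By default each annotated segment competes individually; with
    ``per_label_union`` the union of all segments sharing a label
    competes instead. TADs overlapping nothing get JI 0 and label None.
    """
    sub = subcompartments[subcompartments["chrom"] == seg.chrom]
    if per_label_union:
        units = [(label, intervals.merge(list(zip(grp["start"], grp["end"]))))
                 for label, grp in sub.groupby("name")]
    else:
        units = [(str(r.name), [(int(r.start), int(r.end))])
                 for r in sub.itertuples(index=False)]
    rows = []
    for tad in seg.called_domains():
        t_iv = [(tad.interval.start, tad.interval.end)]
        best_label, best_ji = None, 0.0
        for label, ivs in units:
            if intervals.intersect_length(t_iv, ivs) == 0:
                continue
            ji = intervals.jaccard(t_iv, ivs)
            if ji > best_ji:
                best_label, best_ji = label, ji
        rows.append({"tad_id": tad.id, "label": best_label, "jaccard": best_ji})
    return pd.DataFrame(rows).set_index("tad_id")


def b_compartment_tads(overlap_df: pd.DataFrame) -> list[str]:
    """TAD ids whose best subcompartment label is a B subtype."""
    sel = overlap_df["label"].isin(B_LABELS)
    return list(overlap_df.index[sel])
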