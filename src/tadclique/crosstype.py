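"""Cross-cell-type comparison of TAD cliques.

A clique's footprint is the merged base-pair union of its member TADs,
which makes comparisons robust to differing TAD boundary calls between
cell types. For each reference clique, the best-matching clique in
every other cell type is found by maximal base-pair Jaccard index; the
resulting (cliques x cell types) profile matrix is clustered with
k-means to separate conserved from cell-type-specific clique
configurations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from . import intervals
from .core import GenomicInterval


@dataclass
class CliqueFootprint:
    cell_type: str
    clique_id: str
    by_chrom: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    @classmethod
    def from_intervals(cls, cell_type: str, clique_id: str,
                       ivs: list[GenomicInterval]) -> "CliqueFootprint":
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in ivs:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        return cls(cell_type, clique_id,
                   {c: intervals.merge(v) for c, v in by_chrom.items()})

    def total_bp(self) -> int:
        return sum(intervals.total_length(v) for v in self.by_chrom.values())


def clique_jaccard(a: CliqueFootprint, b: CliqueFootprint) -> float:
    """Base-pair Jaccard index of two footprints over all chromosomes."""
    if a.total_bp() == 0 and b.total_bp() == 0:
        raise ValueError("Jaccard undefined for two empty footprints")
    inter = sum(
        intervals.intersect_length(a.by_chrom[c], b.by_chrom[c])
        for c in a.by_chrom.keys() & b.by_chrom.keys()
    )
    union = a.total_bp() + b.total_bp() - inter
    return inter / union


def max_ji_matrix(reference: list[CliqueFootprint],
                  others: dict[str, list[CliqueFootprint]]) -> pd.DataFrame:
    """Max-JI profile of each reference clique against each cell type.

    Entry (clique, cell type) is the maximum Jaccard index over that
    cell type's cliques. A cell type with no cliques yields a column of
    zeros (with a warning).
    """
    if not reference:
        raise ValueError("reference cell type has no cliques")
    mat = pd.DataFrame(
        0.0, index=[c.clique_id for c in reference], columns=list(others))
    for ct, cliques in others.items():
        if not cliques:
            warnings.warn(f"cell type {ct!r} has no cliques; column set to 0")
            continue
        for ref in reference:
            mat.loc[ref.clique_id, ct] = max(
                clique_jaccard(ref, other) for other in cliques)
    return mat


def cluster_cliques(matrix: pd.DataFrame, k: int = 8, seed: int = 0,
                    n_init: int = 10) -> tuple[pd.Series, pd.DataFrame]:
    """k-means clustering of the max-JI profile matrix.

    Labels are canonicalized in descending order of cluster mean JI
    (cluster 1 = most conserved connectivity). Returns the per-clique
    labels and a per-cluster summary (size, mean JI).
    """
    if len(matrix) < k:
        raise ValueError(
            f"{len(matrix)} cliques cannot form {k} clusters; reduce k")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw = km.fit_predict(matrix.to_numpy())
    mean_ji = np.array([matrix.to_numpy()[raw == c].mean() for c in range(k)])
    order = np.argsort(-mean_ji, kind="stable")
    relabel = {int(old): rank + 1 for rank, old in enumerate(order)}
    labels = pd.Series([relabel[int(c)] for c in raw], index=matrix.index,
                       name="cluster")
    summary = pd.DataFrame({
        "n_cliques": [int((labels == c).sum()) for c in range(1, k + 1)],
        "mean_ji": [float(matrix.to_numpy()[(labels == c).to_numpy()].mean())
                    if (labels == c).any() else np.nan
                    for c in range(1, k + 1)],
    }, index=pd.Index(range(1, k + 1), name="cluster"))
    return labels, summary


def footprints_from_tables(cell_type: str, cliques_df: pd.DataFrame,
                           tads_df: pd.DataFrame) -> list[CliqueFootprint]:
    """Build footprints from a cliques table (clique_id, size, members)
    and a TAD BED table (chrom, start, end, name)."""
    tad_iv = {
        str(r.name): GenomicInterval(r.chrom, int(r.start), int(r.end))
        for r in tads_df.itertuples(index=False)
    }
    out = []
    for r in cliques_df.itertuples(index=False):
        members = str(r.members).split(",")
        out.append(CliqueFootprint.from_intervals(
            cell_type, str(r.clique_id), [tad_iv[m] for m in members]))
    return out
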