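"""Readers and writers for the plain-text formats the pipeline touches.

Supported formats:

* HiC-Pro dialect contact maps: a sparse triplet ``.matrix`` file
  (tab-separated ``bin_i bin_j count`` with 1-based bin ids) plus a
  companion ``.bed`` of 0-based half-open bins whose 4th column is the
  bin id.
* BED4/BED6 interval files (TAD segmentations, motifs, repeats,
  subcompartments).
* TSV expression tables (``gene_id chrom tss_pos value``).

Lines starting with ``#`` are treated as comments in every format.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import (
    BinnedContactMap,
    GenomicInterval,
    TadContactMatrix,
    TadSegment,
    TadSegmentation,
)

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]
GAP_PREFIX = "gap_"


def _read_table(path, n_min_cols: int) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < n_min_cols:
        raise ValueError(f"{path}: expected >= {n_min_cols} columns, found {df.shape[1]}")
    return df


def read_bed(path, min_columns: int = 3) -> pd.DataFrame:
    """Read a BED file into a DataFrame with canonical column names.

    Validates 0 <= start < end per record and strand in {+, -, .} when a
    strand column is present. Raises ValueError naming the offending
    1-based line number on malformed input.
    """
    try:
        df = _read_table(path, min_columns)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=BED_COLUMNS[:min_columns])
    df = df.iloc[:, : len(BED_COLUMNS)]
    df.columns = BED_COLUMNS[: df.shape[1]]
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    if "score" in df.columns:
        df["score"] = pd.to_numeric(df["score"])
    bad = (df["start"] < 0) | (df["start"] >= df["end"])
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 1
        raise ValueError(f"{path}: malformed interval at record {line} "
                         f"(require 0 <= start < end)")
    if "strand" in df.columns:
        bad = ~df["strand"].isin(["+", "-", "."])
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise ValueError(f"{path}: invalid strand at record {line}")
    return df


def write_bed(df: pd.DataFrame, path, header: str | None = None) -> None:
    """Write a DataFrame produced by :func:`read_bed` back to BED."""
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        df.to_csv(fh, sep="\t", header=False, index=False)


def read_contact_matrix(matrix_path, bins_path) -> BinnedContactMap:
    """Load a HiC-Pro triplet ``.matrix`` + bin ``.bed`` pair.

    Duplicate and transposed triplets are summed after canonicalization
    to the upper triangle. The bin bed must describe a single chromosome
    of fixed-width bins.
    """
    bins = read_bed(bins_path, min_columns=4)
    chroms = bins["chrom"].unique()
    if len(chroms) != 1:
        raise ValueError(f"{bins_path}: expected one chromosome, found {list(chroms)}")
    bins = bins.sort_values("start").reset_index(drop=True)
    widths = (bins["end"] - bins["start"]).to_numpy()
    resolution = int(widths.max())
    n_bins = len(bins)
    bin_ids = bins["name"].astype(np.int64).to_numpy()
    id_to_index = dict(zip(bin_ids.tolist(), range(n_bins)))

    try:
        trip = _read_table(matrix_path, 3)
    except pd.errors.EmptyDataError:
        trip = pd.DataFrame(columns=[0, 1, 2])
    if len(trip) == 0:
        return BinnedContactMap(str(chroms[0]), resolution, n_bins,
                                np.array([]), np.array([]), np.array([]))
    i_raw = trip.iloc[:, 0].astype(np.int64).to_numpy()
    j_raw = trip.iloc[:, 1].astype(np.int64).to_numpy()
    counts = trip.iloc[:, 2].astype(np.int64).to_numpy()
    if counts.min() < 0:
        raise ValueError(f"{matrix_path}: negative contact count")
    for raw in (i_raw, j_raw):
        missing = set(raw.tolist()) - id_to_index.keys()
        if missing:
            raise ValueError(
                f"{matrix_path}: bin id {sorted(missing)[0]} absent from {bins_path}")
    idx = np.vectorize(id_to_index.__getitem__, otypes=[np.int64])
    return BinnedContactMap(str(chroms[0]), resolution, n_bins,
                            idx(i_raw), idx(j_raw), counts)


def write_contact_matrix(cmap: BinnedContactMap, matrix_path, bins_path) -> None:
    """Serialize to the HiC-Pro dialect (1-based bin ids in the matrix)."""
    starts = np.arange(cmap.n_bins, dtype=np.int64) * cmap.resolution
    bins = pd.DataFrame({
        "chrom": cmap.chrom,
        "start": starts,
        "end": starts + cmap.resolution,
        "name": np.arange(1, cmap.n_bins + 1),
    })
    write_bed(bins, bins_path)
    trip = pd.DataFrame({
        "i": cmap.bin_i + 1,
        "j": cmap.bin_j + 1,
        "count": cmap.counts,
    })
    trip.to_csv(matrix_path, sep="\t", header=False, index=False)


def segmentation_to_bed(seg: TadSegmentation) -> pd.DataFrame:
    names = [s.id if s.is_called_domain else f"{GAP_PREFIX}{s.id}" for s in seg]
    return pd.DataFrame({
        "chrom": [s.interval.chrom for s in seg],
        "start": [s.interval.start for s in seg],
        "end": [s.interval.end for s in seg],
        "name": names,
    })


def bed_to_segmentation(df: pd.DataFrame) -> TadSegmentation:
    segments = []
    for row in df.itertuples(index=False):
        is_dom = not str(row.name).startswith(GAP_PREFIX)
        name = str(row.name)
        if not is_dom:
            name = name[len(GAP_PREFIX):]
        segments.append(TadSegment(
            GenomicInterval(row.chrom, int(row.start), int(row.end)), name, is_dom))
    return TadSegmentation(segments)


def write_segmentation(seg: TadSegmentation, path, header: str | None = None) -> None:
    write_bed(segmentation_to_bed(seg), path, header=header)


def read_segmentation(path) -> TadSegmentation:
    return bed_to_segmentation(read_bed(path, min_columns=4))


def read_expression_table(path) -> pd.DataFrame:
    """Read a ``gene_id chrom tss_pos value`` TSV (``#`` comments allowed)."""
    df = _read_table(path, 4)
    df.columns = ["gene_id", "chrom", "tss_pos", "value"][: df.shape[1]]
    df["tss_pos"] = df["tss_pos"].astype(np.int64)
    df["value"] = df["value"].astype(float)
    return df


def write_expression_table(df: pd.DataFrame, path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        fh.write("# gene_id\tchrom\ttss_pos\tvalue\n")
        df.to_csv(fh, sep="\t", header=False, index=False)


def aggregate_to_tads(cmap: BinnedContactMap, seg: TadSegmentation) -> TadContactMatrix:
    """Sum bin-level contacts to the TAD level.

    Each bin is assigned to the unique segment containing its midpoint;
    the segmentation must tile the chromosome the map covers. Total
    counts are conserved exactly.
    """
    if seg.chrom != cmap.chrom:
        raise ValueError(f"segmentation chromosome {seg.chrom} != map {cmap.chrom}")
    starts = np.array([s.interval.start for s in seg])
    ends = np.array([s.interval.end for s in seg])
    mids = np.arange(cmap.n_bins) * cmap.resolution + cmap.resolution // 2
    # segment index per bin via searchsorted on segment starts
    assign = np.searchsorted(starts, mids, side="right") - 1
    bad = (assign < 0) | (mids >= ends[np.clip(assign, 0, len(ends) - 1)])
    if bad.any():
        b = int(np.flatnonzero(bad)[0])
        raise ValueError(f"bin {b} midpoint {mids[b]} outside segmentation "
                         "(segmentation must tile the chromosome)")
    n = len(seg)
    mat = np.zeros((n, n), dtype=np.float64)
    si = assign[cmap.bin_i]
    sj = assign[cmap.bin_j]
    np.add.at(mat, (si, sj), cmap.counts)
    np.add.at(mat, (sj, si), cmap.counts)
    # the two scatters double the diagonal contribution
    diag = np.zeros(n)
    on_diag = si == sj
    np.add.at(diag, si[on_diag], cmap.counts[on_diag])
    mat[np.diag_indices(n)] -= diag
    return TadContactMatrix(seg, mat)
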