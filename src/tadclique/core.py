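"""Core in-memory containers for the TAD-clique pipeline.

Coordinates are 0-based half-open (BED convention) everywhere in memory.
HiC-Pro files use 1-based bin ids; conversion happens at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


class BinnedContactMap:
    """Sparse symmetric intra-chromosomal contact counts at fixed resolution.

    Triplets are stored upper-triangular (bin_i <= bin_j, 0-based) and
    queried symmetrically.
    """

    def __init__(
        self,
        chrom: str,
        resolution: int,
        n_bins: int,
        bin_i: np.ndarray,
        bin_j: np.ndarray,
        counts: np.ndarray,
    ) -> None:
        bin_i = np.asarray(bin_i, dtype=np.int64)
        bin_j = np.asarray(bin_j, dtype=np.int64)
        counts = np.asarray(counts, dtype=np.int64)
        if not (bin_i.shape == bin_j.shape == counts.shape):
            raise ValueError("triplet arrays must have equal length")
        if counts.size and counts.min() < 0:
            raise ValueError("negative contact count")
        # canonicalize to upper triangle and sum duplicates
        lo = np.minimum(bin_i, bin_j)
        hi = np.maximum(bin_i, bin_j)
        if lo.size and (lo.min() < 0 or hi.max() >= n_bins):
            raise ValueError("bin index outside [0, n_bins)")
        keys = lo * n_bins + hi
        uniq, inv = np.unique(keys, return_inverse=True)
        summed = np.zeros(uniq.size, dtype=np.int64)
        np.add.at(summed, inv, counts)
        self.chrom = chrom
        self.resolution = int(resolution)
        self.n_bins = int(n_bins)
        self.bin_i = (uniq // n_bins).astype(np.int64)
        self.bin_j = (uniq % n_bins).astype(np.int64)
        self.counts = summed

    @property
    def n_triplets(self) -> int:
        return int(self.counts.size)

    def total(self) -> int:
        """Total count over the upper triangle (each unordered pair once)."""
        return int(self.counts.sum())

    def to_dense(self) -> np.ndarray:
        """Full symmetric dense matrix (float64)."""
        m = np.zeros((self.n_bins, self.n_bins), dtype=np.float64)
        m[self.bin_i, self.bin_j] = self.counts
        upper = np.triu(m, 1)
        return m + upper.T


@dataclass(frozen=True)
class TadSegment:
    """One segment of a full-chromosome tiling.

    ``is_called_domain`` distinguishes caller-identified TADs from the
    gap-filler segments inserted to keep the segmentation exhaustive.
    """

    interval: GenomicInterval
    id: str
    is_called_domain: bool = True


class TadSegmentation:
    """Ordered, non-overlapping segments jointly tiling one chromosome."""

    def __init__(self, segments: list[TadSegment]) -> None:
        if not segments:
            raise ValueError("empty segmentation")
        segments = sorted(segments, key=lambda s: s.interval.start)
        chroms = {s.interval.chrom for s in segments}
        if len(chroms) > 1:
            raise ValueError(f"segmentation spans multiple chromosomes: {chroms}")
        for a, b in zip(segments, segments[1:]):
            if a.interval.end != b.interval.start:
                raise ValueError(
                    f"segments {a.id} and {b.id} do not tile: "
                    f"{a.interval.end} != {b.interval.start}"
                )
        self.segments = segments
        self.chrom = segments[0].interval.chrom

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)

    @property
    def start(self) -> int:
        return self.segments[0].interval.start

    @property
    def end(self) -> int:
        return self.segments[-1].interval.end

    def ids(self) -> list[str]:
        return [s.id for s in self.segments]

    def called_domains(self) -> list[TadSegment]:
        return [s for s in self.segments if s.is_called_domain]

    def locate(self, pos: int) -> TadSegment:
        """Segment containing base-pair position ``pos``."""
        for s in self.segments:
            if s.interval.start <= pos < s.interval.end:
                return s
        raise KeyError(f"position {pos} outside segmentation "
                       f"[{self.start}, {self.end})")


@dataclass
class TadContactMatrix:
    """Symmetric TAD-level contact matrix aligned with a segmentation.

    Entry (i, j) is the total bin-level count between segments i and j;
    the diagonal holds intra-TAD totals.
    """

    segmentation: TadSegmentation
    matrix: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.segmentation)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match segmentation")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("TAD contact matrix must be symmetric")

    def total(self) -> int:
        """Grand total with each unordered pair counted once."""
        return int(np.triu(self.matrix).sum())


@dataclass
class TadPairTest:
    """Significance test result for one linearly non-contiguous TAD pair."""

    tad_a: str
    tad_b: str
    distance_bp: int
    observed: int
    n_a: int
    n_b: int
    total_n: int
    expected: float
    odds: float
    p_value: float
    q_value: float = field(default=np.nan)
    significant: bool = field(default=False)

    @property
    def fold(self) -> float:
        return self.observed / self.expected if self.expected > 0 else np.inf
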