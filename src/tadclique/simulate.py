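"""Ground-truthed synthetic Hi-C data with planted TAD-clique structure.

The generator emulates the statistical structure the downstream analysis
assumes: power-law distance decay of contact frequency, block-enriched
TADs of 0.2–1 Mb, planted long-range clique interactions between
linearly non-contiguous TADs, convergent CTCF motifs preferentially at
non-clique TAD boundaries, LINE enrichment and reduced expression inside
clique TADs, and B-subcompartment labels over clique footprints.

Counts for a bin pair (i, j) are Poisson with mean

    mu_ij = L * (1 + |i - j|)**(-alpha)
              * (1 + beta  * [same TAD])
              * (1 + gamma * [bins lie in two TADs joined by a planted
                              clique edge])

where ``L`` is the base intensity, ``alpha`` the distance-decay
exponent, ``beta`` the intra-TAD boost and ``gamma`` the planted
clique-edge boost.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import BinnedContactMap, GenomicInterval, TadSegment, TadSegmentation
from . import genomic_io

MOTIF_WIDTH = 20


@dataclass
class PlantedClique:
    """One clique to plant: ``size`` member TADs, contact boost ``gamma``."""

    size: int
    gamma: float
    members: list[int] | None = None  # TAD indices; sampled when None

    def __post_init__(self) -> None:
        if self.size < 3:
            raise ValueError("a clique needs >= 3 member TADs")
        if self.gamma < 0:
            raise ValueError("clique boost must be >= 0")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic chromosome.

    Defaults give a 40 Mb chromosome at 50 kb bins (~65 TADs of
    0.2–1 Mb) with planted cliques of sizes 3, 5 and 8 at an eight-fold
    edge boost.
    """

    chrom: str = "chrS"
    chrom_length_bp: int = 40_000_000
    resolution_bp: int = 50_000
    decay_exponent: float = 1.0
    tad_size_range_bp: tuple[int, int] = (200_000, 1_000_000)
    intra_tad_boost: float = 3.0
    planted_cliques: list[PlantedClique] = field(
        default_factory=lambda: [PlantedClique(3, 8.0),
                                 PlantedClique(5, 8.0),
                                 PlantedClique(8, 8.0)])
    base_intensity: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.decay_exponent <= 0:
            raise ValueError("decay exponent must be > 0")
        if self.base_intensity <= 0:
            raise ValueError("base intensity must be > 0")
        if self.intra_tad_boost < 0:
            raise ValueError("intra-TAD boost must be >= 0")
        lo, hi = self.tad_size_range_bp
        if not (0 < lo <= hi):
            raise ValueError("invalid TAD size range")

    @property
    def n_bins(self) -> int:
        return self.chrom_length_bp // self.resolution_bp


@dataclass
class GroundTruth:
    """What was planted: the targets downstream recovery is scored against."""

    segmentation: TadSegmentation
    cliques: list[list[str]]                 # member TAD ids per planted clique
    clique_edges: set[frozenset[str]]        # complete subgraph over each clique
    in_planted_clique: dict[str, bool]       # per called-domain TAD id
    motif_orientations: dict[str, bool] = field(default_factory=dict)
    expression_shift: float = 0.0

    def clique_tad_ids(self) -> list[str]:
        return [t for t, f in self.in_planted_clique.items() if f]

    def boundaries_bp(self) -> list[int]:
        """Internal boundaries between consecutive called domains."""
        doms = self.segmentation.called_domains()
        return [d.interval.start for d in doms[1:]]

    def to_json_dict(self) -> dict:
        return {
            "chrom": self.segmentation.chrom,
            "tads": [
                {"id": s.id, "start": s.interval.start, "end": s.interval.end,
                 "is_called_domain": s.is_called_domain}
                for s in self.segmentation
            ],
            "cliques": self.cliques,
            "clique_edges": sorted(sorted(e) for e in self.clique_edges),
            "in_planted_clique": self.in_planted_clique,
            "expression_shift": self.expression_shift,
        }


def _draw_segmentation(config: SimulationConfig, rng: np.random.Generator) -> TadSegmentation:
    """Sequentially sample TAD sizes uniform on the configured range,
    rounded to whole bins; a final fragment below the minimum size
    becomes a gap segment."""
    res = config.resolution_bp
    lo, hi = config.tad_size_range_bp
    length = (config.chrom_length_bp // res) * res
    segments, pos, k = [], 0, 0
    while pos < length:
        size = int(rng.integers(lo, hi + 1))
        size = max(res, round(size / res) * res)
        if length - pos - size < 0:
            size = length - pos
        seg_is_tad = size >= lo
        if seg_is_tad:
            k += 1
            name = f"T{k:04d}"
        else:
            name = f"G{k:04d}"
        segments.append(TadSegment(
            GenomicInterval(config.chrom, pos, pos + size), name, seg_is_tad))
        pos += size
    seg = TadSegmentation(segments)
    if len(seg.called_domains()) < 2:
        raise ValueError("degenerate simulation: chromosome shorter than 2 TADs")
    return seg


def _choose_clique_members(
    cliques: list[PlantedClique],
    n_tads: int,
    rng: np.random.Generator,
) -> list[list[int]]:
    """Pick member TAD indices with >= 1 intervening TAD between any two
    members of the same clique, and no TAD shared across cliques."""
    used: set[int] = set()
    chosen: list[list[int]] = []
    for pc in cliques:
        if pc.members is not None:
            members = list(pc.members)
            if len(members) != pc.size:
                raise ValueError("member list length does not match clique size")
            for a in members:
                for b in members:
                    if a != b and abs(a - b) < 2:
                        raise ValueError(
                            f"clique members {a},{b} are linearly contiguous")
            used.update(members)
            chosen.append(members)
            continue
        members: list[int] = []
        for _ in range(20):  # a random greedy pass can miss a feasible layout
            order = rng.permutation(n_tads)
            members = []
            for idx in order:
                idx = int(idx)
                if idx in used:
                    continue
                if any(abs(idx - m) < 2 for m in members):
                    continue
                members.append(idx)
                if len(members) == pc.size:
                    break
            if len(members) == pc.size:
                break
        if len(members) < pc.size:
            raise ValueError(
                f"cannot place a clique of size {pc.size} on {n_tads} TADs")
        used.update(members)
        chosen.append(sorted(members))
    return chosen


def simulate_contact_map(config: SimulationConfig) -> tuple[BinnedContactMap, GroundTruth]:
    """Sample a contact map and return it with its ground truth."""
    rng = np.random.default_rng(config.seed)
    seg = _draw_segmentation(config, rng)
    doms = seg.called_domains()
    member_idx = _choose_clique_members(config.planted_cliques, len(doms), rng)

    cliques = [[doms[i].id for i in members] for members in member_idx]
    clique_edges: set[frozenset[str]] = set()
    for members in cliques:
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                clique_edges.add(frozenset((members[a], members[b])))
    in_clique = {d.id: any(d.id in c for c in cliques) for d in doms}

    n = config.n_bins
    res = config.resolution_bp
    # per-bin segment index (over the full tiling) via midpoints
    starts = np.array([s.interval.start for s in seg])
    mids = np.arange(n) * res + res // 2
    assign = np.searchsorted(starts, mids, side="right") - 1

    # segment-level boost factor matrix
    nseg = len(seg)
    boost = np.ones((nseg, nseg))
    seg_index = {s.id: i for i, s in enumerate(seg)}
    for i, s in enumerate(seg):
        if s.is_called_domain:
            boost[i, i] = 1.0 + config.intra_tad_boost
    for members, pc in zip(cliques, config.planted_cliques):
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                ia, ib = seg_index[members[a]], seg_index[members[b]]
                boost[ia, ib] = boost[ib, ia] = 1.0 + pc.gamma

    d = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    mu = config.base_intensity * (1.0 + d) ** (-config.decay_exponent)
    mu *= boost[assign[:, None], assign[None, :]]

    iu, ju = np.triu_indices(n)
    counts = rng.poisson(mu[iu, ju])
    nz = counts > 0
    cmap = BinnedContactMap(config.chrom, res, n, iu[nz], ju[nz], counts[nz])
    truth = GroundTruth(seg, cliques, clique_edges, in_clique)
    return cmap, truth


def simulate_ctcf_motifs(
    truth: GroundTruth,
    p_convergent_nonclique: float = 0.6,
    p_convergent_clique: float = 0.1,
    window_bp: int = 25_000,
    seed: int = 0,
    decoy_per_bp: float = 1 / 500_000,
) -> pd.DataFrame:
    """Place CTCF motifs (BED6 DataFrame) at TAD boundaries.

    Each TAD receives, with a probability depending on its planted-clique
    status, a forward-strand motif near its start and a reverse-strand
    motif near its end (the convergent configuration). Decoy motifs with
    uniform position and random strand are added at ``decoy_per_bp``.
    """
    for p in (p_convergent_nonclique, p_convergent_clique):
        if not 0 <= p <= 1:
            raise ValueError("probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    seg = truth.segmentation
    rows = []
    for s in seg.called_domains():
        p = p_convergent_clique if truth.in_planted_clique[s.id] else p_convergent_nonclique
        convergent = bool(rng.random() < p)
        truth.motif_orientations[s.id] = convergent
        if not convergent:
            continue
        w = min(window_bp, s.interval.length // 2)
        for anchor, strand in ((s.interval.start, "+"), (s.interval.end, "-")):
            off = int(rng.integers(-w, w + 1))
            pos = anchor + off
            pos = min(max(pos, s.interval.start), s.interval.end - MOTIF_WIDTH)
            rows.append((seg.chrom, pos, pos + MOTIF_WIDTH,
                         "ctcf_boundary", round(float(rng.uniform(8, 10)), 3), strand))
    n_decoys = rng.poisson(decoy_per_bp * (seg.end - seg.start))
    for _ in range(n_decoys):
        pos = int(rng.integers(seg.start, seg.end - MOTIF_WIDTH))
        strand = "+" if rng.random() < 0.5 else "-"
        rows.append((seg.chrom, pos, pos + MOTIF_WIDTH,
                     "ctcf_decoy", round(float(rng.uniform(0, 10)), 3), strand))
    df = pd.DataFrame(rows, columns=genomic_io.BED_COLUMNS)
    return df.sort_values(["start", "end"]).reset_index(drop=True)


_SUBCOMPARTMENTS = ["A1", "A2", "B1", "B2", "B3"]
_ANNOTATION_TILE = 1_000  # bp; resolution of simulated repeat mosaics


def simulate_annotations(
    truth: GroundTruth,
    line_frac_clique: float = 0.40,
    line_frac_other: float = 0.25,
    sine_frac: float = 0.25,
    expr_shift: float = 1.0,
    genes_per_bp: float = 1 / 100_000,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate repeats, expression and subcompartments over the truth TADs.

    Returns ``(repeats, expression, subcompartments)``:

    * repeats — BED4, name = LINE or SINE; each TAD is a 1-kb tile mosaic
      where tiles are LINE with the class-dependent fraction and SINE
      with ``sine_frac`` of the remainder, so LINE-rich TADs are
      SINE-poor (complementary coverage).
    * expression — per-gene TSV (gene_id, chrom, tss_pos, value); gene
      log2 levels are Normal(5, 2) shifted down by ``expr_shift`` inside
      planted-clique TADs.
    * subcompartments — BED4 with labels A1/A2/B1/B2/B3; planted-clique
      footprints draw B2/B3 with probability 0.8.
    """
    for f in (line_frac_clique, line_frac_other, sine_frac):
        if not 0 <= f <= 1:
            raise ValueError("fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    seg = truth.segmentation
    truth.expression_shift = expr_shift

    repeat_rows = []
    for s in seg.called_domains():
        f = line_frac_clique if truth.in_planted_clique[s.id] else line_frac_other
        n_tiles = s.interval.length // _ANNOTATION_TILE
        u = rng.random(n_tiles)
        is_line = u < f
        is_sine = (~is_line) & (rng.random(n_tiles) < sine_frac)
        for cls, mask in (("LINE", is_line), ("SINE", is_sine)):
            idx = np.flatnonzero(mask)
            if idx.size == 0:
                continue
            # merge consecutive tiles into maximal runs
            breaks = np.flatnonzero(np.diff(idx) > 1)
            run_starts = np.concatenate(([0], breaks + 1))
            run_ends = np.concatenate((breaks, [idx.size - 1]))
            for a, b in zip(run_starts, run_ends):
                start = s.interval.start + int(idx[a]) * _ANNOTATION_TILE
                end = s.interval.start + (int(idx[b]) + 1) * _ANNOTATION_TILE
                repeat_rows.append((seg.chrom, start, end, cls))
    repeats = pd.DataFrame(repeat_rows, columns=["chrom", "start", "end", "name"])
    repeats = repeats.sort_values(["start", "end"]).reset_index(drop=True)

    expr_rows = []
    g = 0
    for s in seg.called_domains():
        n_genes = rng.poisson(genes_per_bp * s.interval.length)
        shift = -expr_shift if truth.in_planted_clique[s.id] else 0.0
        for _ in range(n_genes):
            g += 1
            tss = int(rng.integers(s.interval.start, s.interval.end))
            value = float(rng.normal(5.0 + shift, 2.0))
            expr_rows.append((f"gene{g:05d}", seg.chrom, tss, round(value, 4)))
    expression = pd.DataFrame(
        expr_rows, columns=["gene_id", "chrom", "tss_pos", "value"])

    sub_rows = []
    for s in seg:
        if s.is_called_domain and truth.in_planted_clique[s.id] and rng.random() < 0.8:
            label = "B2" if rng.random() < 0.5 else "B3"
        else:
            label = _SUBCOMPARTMENTS[int(rng.integers(len(_SUBCOMPARTMENTS)))]
        sub_rows.append((seg.chrom, s.interval.start, s.interval.end, label))
    subcompartments = pd.DataFrame(
        sub_rows, columns=["chrom", "start", "end", "name"])
    return repeats, expression, subcompartments


def score_edge_recovery(truth: GroundTruth, called: TadSegmentation,
                        significant_pairs) -> tuple[float, float]:
    """Score recovered interactions against the planted clique edges.

    Each called TAD is mapped to the truth segment containing its
    midpoint. Precision is the fraction of significant called pairs
    whose mapped truth pair is a planted clique edge; recall is the
    fraction of planted edges hit by at least one significant pair.
    """
    id_to_seg = {s.id: s for s in called.called_domains()}

    def to_truth(tid: str) -> str | None:
        s = truth.segmentation.locate(id_to_seg[tid].interval.midpoint)
        return s.id if s.is_called_domain else None

    mapped = []
    for p in significant_pairs:
        ta, tb = to_truth(p.tad_a), to_truth(p.tad_b)
        mapped.append(frozenset((ta, tb)) if ta and tb and ta != tb else None)
    if not mapped:
        return 0.0, 0.0
    tp_pairs = sum(1 for e in mapped if e in truth.clique_edges)
    hit_edges = {e for e in mapped if e} & truth.clique_edges
    precision = tp_pairs / len(mapped)
    recall = len(hit_edges) / len(truth.clique_edges) if truth.clique_edges else float("nan")
    return precision, recall


def collapse_to_truth_graph(truth: GroundTruth, called: TadSegmentation,
                            significant_pairs):
    """Project significant called-TAD pairs onto the planted TADs.

    The caller may segment more finely than the planted domains; for
    recovery scoring each called TAD is mapped to the truth segment
    containing its midpoint and edges are merged. Returns an undirected
    graph over planted TAD ids (planted TADs with no edge included as
    isolated nodes).
    """
    import networkx as nx

    id_to_seg = {s.id: s for s in called.called_domains()}
    g = nx.Graph()
    g.add_nodes_from(s.id for s in truth.segmentation.called_domains())
    for p in significant_pairs:
        ta = truth.segmentation.locate(id_to_seg[p.tad_a].interval.midpoint)
        tb = truth.segmentation.locate(id_to_seg[p.tad_b].interval.midpoint)
        if ta.is_called_domain and tb.is_called_domain and ta.id != tb.id:
            g.add_edge(ta.id, tb.id)
    return g


def write_fixture(out_dir, config: SimulationConfig | None = None, seed: int | None = None,
                  **annotation_kwargs) -> GroundTruth:
    """Generate the full synthetic dataset and serialize it under ``out_dir``.

    Writes matrix.matrix / bins.bed (HiC-Pro dialect), true_tads.bed,
    ctcf_motifs.bed, repeats.bed, subcompartments.bed, expression.tsv and
    ground_truth.json.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config is None:
        config = SimulationConfig()
    if seed is not None:
        config.seed = seed
    cmap, truth = simulate_contact_map(config)
    motifs = simulate_ctcf_motifs(truth, seed=config.seed + 1)
    repeats, expression, subcomp = simulate_annotations(
        truth, seed=config.seed + 2, **annotation_kwargs)

    genomic_io.write_contact_matrix(cmap, out / "matrix.matrix", out / "bins.bed")
    genomic_io.write_segmentation(truth.segmentation, out / "true_tads.bed")
    genomic_io.write_bed(motifs, out / "ctcf_motifs.bed")
    genomic_io.write_bed(repeats, out / "repeats.bed")
    genomic_io.write_bed(subcomp, out / "subcompartments.bed")
    genomic_io.write_expression_table(expression, out / "expression.tsv")
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(truth.to_json_dict(), fh, indent=1, sort_keys=True)
    return truth
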