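import numpy as np
import pytest

from tadclique import cliques, domains, genomic_io, interactions
from tadclique import simulate as sim
from tadclique.core import BinnedContactMap, GenomicInterval, TadSegment, TadSegmentation


def small_config(seed: int, **kwargs) -> sim.SimulationConfig:
    """A 10 Mb chromosome with one planted 3-clique: fast unit-test scale."""
    kwargs.setdefault("chrom_length_bp", 10_000_000)
    kwargs.setdefault("planted_cliques", [sim.PlantedClique(3, 8.0)])
    return sim.SimulationConfig(seed=seed, **kwargs)


def random_map(rng: np.random.Generator, n_bins: int, max_count: int = 20,
               resolution: int = 50_000) -> BinnedContactMap:
    iu, ju = np.triu_indices(n_bins)
    counts = rng.integers(0, max_count + 1, size=iu.size)
    return BinnedContactMap("chrT", resolution, n_bins, iu, ju, counts)


def uniform_segmentation(chrom: str, length: int, n_segments: int) -> TadSegmentation:
    edges = np.linspace(0, length, n_segments + 1, dtype=np.int64)
    return TadSegmentation([
        TadSegment(GenomicInterval(chrom, int(a), int(b)), f"T{i + 1:04d}")
        for i, (a, b) in enumerate(zip(edges[:-1], edges[1:]))
    ])


@pytest.fixture(scope="session")
def default_fixture():
    """The canonical synthetic dataset (40 Mb, 50 kb bins, cliques 3/5/8,
    gamma_c = 8, seed 1) run through the full analysis pipeline once."""
    cfg = sim.SimulationConfig(seed=1)
    cmap, truth = sim.simulate_contact_map(cfg)
    seg = domains.call_tads(cmap)
    tm = genomic_io.aggregate_to_tads(cmap, seg)
    pairs = interactions.call_significant_interactions(tm)
    sig = [p for p in pairs if p.significant]
    graph = cliques.build_tad_graph(sig, nodes=[s.id for s in seg.called_domains()])
    max_cl = cliques.maximal_cliques(graph)
    stats_df = cliques.assign_clique_stats(graph, max_cl)
    return {
        "config": cfg, "cmap": cmap, "truth": truth, "seg": seg,
        "tad_matrix": tm, "pairs": pairs, "sig": sig, "graph": graph,
        "cliques": max_cl, "stats": stats_df,
    }
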