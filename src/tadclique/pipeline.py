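"""End-to-end orchestration: simulate/ingest → call TADs → test
interactions → cliques → characterize → cluster across cell types.

Every stage reads and writes plain TSV/BED files, so any stage's input
can be swapped for real-data equivalents (e.g. published TAD calls in
place of the caller). A provenance manifest records parameters, seeds,
input checksums and row counts per output.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__, characterize, cliques, crosstype, domains, genomic_io, interactions, simulate

logger = logging.getLogger(__name__)


def _sim_config(cfg: "PipelineConfig", seed: int) -> "simulate.SimulationConfig":
    return simulate.SimulationConfig(
        chrom_length_bp=cfg.chrom_length_bp,
        resolution_bp=cfg.resolution_bp,
        planted_cliques=[simulate.PlantedClique(int(s), float(g))
                         for s, g in cfg.planted_cliques],
        seed=seed)


class PipelineError(RuntimeError):
    """Raised when a stage fails; carries the failing stage's name."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    out_dir: str = "tadclique_out"
    # simulate (None matrix/bins paths) or ingest existing files
    matrix_path: str | None = None
    bins_path: str | None = None
    tads_path: str | None = None        # bypass the caller with published TADs
    chrom_length_bp: int = 40_000_000
    resolution_bp: int = 50_000
    planted_cliques: list = field(
        default_factory=lambda: [[3, 8.0], [5, 8.0], [8, 8.0]])
    seed: int = 1
    gamma: float = 1.2
    fdr: float = 0.01
    min_fold: float = 5.0
    n_strata: int = 30
    window_bp: int = 50_000
    kmeans_k: int = 8
    n_other_celltypes: int = 3          # simulated partners for clustering
    run_characterize: bool = True
    run_cluster: bool = True

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _file_entry(path: Path) -> dict:
    n_rows = sum(1 for line in path.open() if not line.startswith("#"))
    return {"path": path.name, "sha256": _sha256(path), "rows": n_rows}


def _tsv_header(cfg: PipelineConfig, stage: str) -> str:
    return f"tadclique {__version__} stage={stage} seed={cfg.seed}"


def _stage_cliques_for_map(cmap, cfg: PipelineConfig):
    """TADs → significant pairs → cliques for one contact map."""
    seg = domains.call_tads(cmap, domains.DomainQualityParams(gamma=cfg.gamma))
    tm = genomic_io.aggregate_to_tads(cmap, seg)
    pairs = interactions.call_significant_interactions(
        tm, fdr=cfg.fdr, min_fold=cfg.min_fold, n_strata=cfg.n_strata)
    sig = [p for p in pairs if p.significant]
    graph = cliques.build_tad_graph(sig, nodes=[s.id for s in seg.called_domains()])
    max_cl = cliques.maximal_cliques(graph)
    return seg, [c for c in max_cl if len(c) >= 3]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all enabled stages; returns the provenance manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "config": asdict(cfg), "stages": []}

    def record(stage: str, outputs: list[Path]) -> None:
        manifest["stages"].append(
            {"stage": stage, "outputs": [_file_entry(p) for p in outputs]})
        logger.info("stage %s complete (%d outputs)", stage, len(outputs))

    # ---- stage 1: simulate or ingest -------------------------------------
    stage = "simulate" if cfg.matrix_path is None else "ingest"
    try:
        if cfg.matrix_path is None:
            simulate.write_fixture(out, _sim_config(cfg, cfg.seed))
            matrix_path, bins_path = out / "matrix.matrix", out / "bins.bed"
            ctcf_path, repeats_path = out / "ctcf_motifs.bed", out / "repeats.bed"
            sub_path, expr_path = out / "subcompartments.bed", out / "expression.tsv"
            record(stage, [matrix_path, bins_path, out / "true_tads.bed",
                           ctcf_path, repeats_path, sub_path, expr_path])
        else:
            matrix_path, bins_path = Path(cfg.matrix_path), Path(cfg.bins_path)
            for p in (matrix_path, bins_path):
                if not p.exists():
                    raise FileNotFoundError(f"input path not found: {p}")
            ctcf_path = repeats_path = sub_path = expr_path = None
            record(stage, [matrix_path, bins_path])
        cmap = genomic_io.read_contact_matrix(matrix_path, bins_path)
    except Exception as e:  # noqa: BLE001 — abort with the stage named
        raise PipelineError(stage, str(e)) from e

    # ---- stage 2: call TADs ----------------------------------------------
    try:
        if cfg.tads_path is not None:
            seg = genomic_io.read_segmentation(cfg.tads_path)
        else:
            seg = domains.call_tads(
                cmap, domains.DomainQualityParams(gamma=cfg.gamma))
        tads_out = out / "tads.bed"
        genomic_io.write_segmentation(seg, tads_out,
                                      header=_tsv_header(cfg, "call-tads"))
        record("call-tads", [tads_out])
    except Exception as e:
        raise PipelineError("call-tads", str(e)) from e

    # ---- stage 3: test interactions --------------------------------------
    try:
        tm = genomic_io.aggregate_to_tads(cmap, seg)
        pairs = interactions.call_significant_interactions(
            tm, fdr=cfg.fdr, min_fold=cfg.min_fold, n_strata=cfg.n_strata)
        pairs_df = interactions.pairs_to_dataframe(pairs)
        pairs_out = out / "pairs.tsv"
        with open(pairs_out, "w") as fh:
            fh.write(f"# {_tsv_header(cfg, 'test-interactions')}\n")
            pairs_df.to_csv(fh, sep="\t", index=False)
        record("test-interactions", [pairs_out])
    except Exception as e:
        raise PipelineError("test-interactions", str(e)) from e

    # ---- stage 4: cliques -------------------------------------------------
    try:
        sig = [p for p in pairs if p.significant]
        graph = cliques.build_tad_graph(
            sig, nodes=[s.id for s in seg.called_domains()])
        max_cl = cliques.maximal_cliques(graph)
        stats_df = cliques.assign_clique_stats(graph, max_cl)
        cl_out, stats_out = out / "cliques.tsv", out / "tad_stats.tsv"
        with open(cl_out, "w") as fh:
            fh.write(f"# {_tsv_header(cfg, 'cliques')}\n")
            cliques.cliques_to_dataframe(max_cl).to_csv(fh, sep="\t", index=False)
        with open(stats_out, "w") as fh:
            fh.write(f"# {_tsv_header(cfg, 'cliques')}\n")
            stats_df.to_csv(fh, sep="\t")
        record("cliques", [cl_out, stats_out])
    except Exception as e:
        raise PipelineError("cliques", str(e)) from e

    # ---- stage 5: characterize -------------------------------------------
    if cfg.run_characterize and ctcf_path is not None:
        try:
            outputs = []
            motifs = genomic_io.read_bed(ctcf_path, min_columns=6)
            conv = characterize.convergence_enrichment(
                seg, stats_df, motifs, window_bp=cfg.window_bp)
            conv_out = out / "convergence.tsv"
            conv.to_csv(conv_out, sep="\t")
            outputs.append(conv_out)

            repeats = genomic_io.read_bed(repeats_path, min_columns=4)
            cov = characterize.repeat_coverage(seg, repeats, stats_df)
            cov_out = out / "coverage.tsv"
            cov.to_csv(cov_out, sep="\t")
            outputs.append(cov_out)

            expr = genomic_io.read_expression_table(expr_path)
            ks_stat, ks_p, summary = characterize.expression_compare(
                expr, seg, stats_df)
            expr_out = out / "expression_stats.tsv"
            with open(expr_out, "w") as fh:
                fh.write(f"# ks_statistic={ks_stat:.6g}\tks_p={ks_p:.6g}\n")
                summary.to_csv(fh, sep="\t")
            outputs.append(expr_out)

            sub = genomic_io.read_bed(sub_path, min_columns=4)
            ji = characterize.subcompartment_overlap(seg, sub)
            ji_out = out / "subcompartment_ji.tsv"
            ji.to_csv(ji_out, sep="\t")
            outputs.append(ji_out)

            for cat, grp in stats_df.groupby("category", observed=True):
                tads = [s for s in seg.called_domains() if s.id in set(grp.index)]
                hm = characterize.aggregate_intra_tad_heatmap(cmap, tads, cat)
                hm_out = out / f"heatmap_{cat}.tsv"
                pd.DataFrame(hm.matrix).to_csv(hm_out, sep="\t",
                                               header=False, index=False)
                outputs.append(hm_out)
            record("characterize", outputs)
        except Exception as e:
            raise PipelineError("characterize", str(e)) from e

    # ---- stage 6: cross-cell-type clustering ------------------------------
    if cfg.run_cluster:
        try:
            ref_foot = [
                crosstype.CliqueFootprint.from_intervals(
                    "reference", f"C{i + 1:04d}",
                    [s.interval for s in seg.called_domains() if s.id in c])
                for i, c in enumerate(max_cl) if len(c) >= 3
            ]
            others: dict[str, list[crosstype.CliqueFootprint]] = {}
            for t in range(cfg.n_other_celltypes):
                ct = f"celltype{t + 1}"
                other_map, _ = simulate.simulate_contact_map(
                    _sim_config(cfg, cfg.seed + 100 * (t + 1)))
                o_seg, o_cliques = _stage_cliques_for_map(other_map, cfg)
                others[ct] = [
                    crosstype.CliqueFootprint.from_intervals(
                        ct, f"{ct}_C{i + 1:04d}",
                        [s.interval for s in o_seg.called_domains() if s.id in c])
                    for i, c in enumerate(o_cliques)
                ]
            if not ref_foot:
                raise ValueError("reference run produced no cliques of size >= 3")
            ji_mat = crosstype.max_ji_matrix(ref_foot, others)
            k = min(cfg.kmeans_k, len(ji_mat))
            labels, summary = crosstype.cluster_cliques(ji_mat, k=k, seed=cfg.seed)
            ji_out, cl_out2, mean_out = (out / "ji_matrix.tsv",
                                         out / "clusters.tsv",
                                         out / "cluster_means.tsv")
            ji_mat.to_csv(ji_out, sep="\t")
            labels.to_frame().to_csv(cl_out2, sep="\t")
            summary.to_csv(mean_out, sep="\t")
            record("cluster-cliques", [ji_out, cl_out2, mean_out])
        except Exception as e:
            raise PipelineError("cluster-cliques", str(e)) from e

    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
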