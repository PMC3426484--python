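"""End-to-end orchestration: filter -> scans -> empirical p-values ->
gene-level Fisher scores (+ background) -> pathway part tests -> network
centrality, with one config, reproducible seeds and TSV outputs.

All stages run single-process and deterministically under a fixed seed; a
manifest records the resolved configuration and library versions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import core_io, empirical, gene_level, pathway, synthetic
from .centrality import centrality_association, compute_centralities
from .core_io import GlycoscanError, logger
from .fst import SnpScoreTrack, fst_scan
from .ihs import IhsParams, ihs_scan

STATISTICS = ("FST", "ABS_IHS")


@dataclass
class PipelineConfig:
    """Resolved pipeline settings; defaults match the study design
    (100 kb flanks, 5% MAF, 10,000-SNP bins, alpha 0.05, 7 groups x 2
    methods)."""

    # inputs: either a synthetic simulation, or explicit file paths
    simulate: synthetic.SimulationConfig | None = None
    vcf_path: str | None = None
    genes_path: str | None = None
    annotation_path: str | None = None
    groups_path: str | None = None
    edges_path: str | None = None
    background_path: str | None = None

    statistics: tuple[str, ...] = STATISTICS
    flank_bp: int = 100_000
    maf_threshold: float = 0.05
    group_maf_threshold: float = 0.05
    snps_per_bin: int = 10_000
    alpha: float = 0.05
    estimator: str = "weir_cockerham"
    convention: str = "centiscape"
    ihs: IhsParams = field(default_factory=IhsParams)
    seed: int = 0

    def __post_init__(self) -> None:
        bad = set(self.statistics) - set(STATISTICS)
        if bad:
            raise GlycoscanError(f"unknown statistics {sorted(bad)}")

    @classmethod
    def synthetic_default(cls, seed: int = 0, **overrides) -> "PipelineConfig":
        """The default synthetic study: 7 groups x 30 diploids x 5,000 SNPs,
        56 pathway genes, 500 background regions, with the region flank and
        bin size scaled to the simulated SNP density."""
        sim = synthetic.SimulationConfig(seed=seed)
        return cls(
            simulate=sim,
            flank_bp=sim.region_flank_bp,
            snps_per_bin=500,
            seed=seed,
            **overrides,
        )


def load_inputs(config: PipelineConfig):
    """Panel + catalog + annotation + scheme + graph + background from the
    configured source (simulation or files)."""
    if config.simulate is not None:
        panel = synthetic.simulate_panel(config.simulate)
        catalog, annotation, graph, background = synthetic.make_pathway_fixture(config.simulate)
        scheme = core_io.GroupScheme.from_samples(panel.samples)
    else:
        needed = [config.vcf_path, config.genes_path, config.annotation_path,
                  config.groups_path, config.edges_path, config.background_path]
        if any(p is None for p in needed):
            raise GlycoscanError("file-based run requires all input paths")
        panel = core_io.read_haplotype_vcf(config.vcf_path)
        catalog, annotation, scheme, graph = core_io.read_tables(
            config.genes_path, config.annotation_path, config.groups_path, config.edges_path
        )
        panel, scheme = core_io.read_groups_into_panel(panel, config.groups_path)
        background = core_io._read_gene_table(config.background_path)
    return panel, catalog, annotation, scheme, graph, background


def compute_tracks(panel, scheme, config: PipelineConfig) -> list[SnpScoreTrack]:
    """MAF-filter the panel and compute all per-SNP score tracks with
    empirical p-values attached."""
    panel = core_io.filter_maf(panel, config.maf_threshold, "global")
    tracks: list[SnpScoreTrack] = []
    if "FST" in config.statistics:
        for group, track in fst_scan(
            panel, scheme, estimator=config.estimator,
            group_maf_threshold=config.group_maf_threshold,
        ).items():
            tracks.append(track)
    if "ABS_IHS" in config.statistics:
        for group in scheme.groups:
            tracks.append(ihs_scan(panel, scheme, group, config.ihs))
    out = []
    for track in tracks:
        binning = empirical.assign_maf_bins(track, config.snps_per_bin)
        out.append(empirical.empirical_p(track, binning))
    return out


def run_full_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in dependency order; returns the result bundle.

    Bundle keys: ``tracks`` (list of SnpScoreTrack), ``gene_results``,
    ``background_results``, ``part_counts``, ``part_tests``,
    ``part_rank_tests``, ``hypergeometric``, ``centrality``,
    ``centrality_association``, ``summary`` plus the input objects.
    """
    panel, catalog, annotation, scheme, graph, background = load_inputs(config)
    n_groups = len(scheme.groups)
    n_methods = len(config.statistics)

    tracks = compute_tracks(panel, scheme, config)
    gene_results = gene_level.gene_scan(tracks, catalog, config.flank_bp)
    bg_results = gene_level.background_scan(background, tracks, config.flank_bp)
    gene_results = gene_level.empirical_gene_significance(
        gene_results, bg_results, config.alpha, n_groups, n_methods
    )
    bg_results = gene_level.empirical_gene_significance(
        bg_results, bg_results, config.alpha, n_groups, n_methods, exclude_self=True
    )

    part_count_rows, part_test_rows, hyper_rows, rank_rows = [], [], [], []
    assoc_frames = []
    n_bg = background.table["gene_id"].nunique()
    centrality_table = compute_centralities(graph, config.convention)
    for stat in config.statistics:
        counts = pathway.count_events_by_part(gene_results, annotation, stat)
        for part, (ng, ne) in counts.counts.items():
            part_count_rows.append((stat, part, ng, ne))
        total_events = sum(e for _, e in counts.counts.values())
        if total_events >= 1:
            chi2, p = pathway.chi2_goodness_of_fit(counts)
            part_test_rows.append((stat, chi2, p))
        else:
            logger.info("no %s events; part chi-squared skipped", stat)
            part_test_rows.append((stat, np.nan, np.nan))
        bg_stat = bg_results[bg_results["statistic"] == stat]
        bg_events = int(
            bg_stat.groupby("gene_id")["significant"].any().sum()
        )
        for part, (pu, po) in pathway.hypergeometric_part_test(counts, n_bg, bg_events).items():
            hyper_rows.append((stat, part, pu, po, n_bg, bg_events))
        for group in scheme.groups:
            try:
                r = pathway.compare_part_scores(gene_results, annotation, stat, group)
            except GlycoscanError:
                continue
            rank_rows.append(
                (stat, group, r.n1, r.n2, r.rank_sum_1, r.rank_sum_2, r.u, r.z, r.p_two_sided)
            )
        stat_res = gene_results[gene_results["statistic"] == stat]
        sig_genes = set(stat_res.loc[stat_res["significant"], "gene_id"])
        in_graph = centrality_table["gene_id"].isin(sig_genes)
        if 0 < in_graph.sum() < len(centrality_table):
            assoc = centrality_association(centrality_table, sig_genes)
            assoc.insert(0, "statistic", stat)
            assoc_frames.append(assoc)

    bundle = {
        "config": config,
        "panel": panel,
        "catalog": catalog,
        "annotation": annotation,
        "scheme": scheme,
        "graph": graph,
        "tracks": tracks,
        "gene_results": gene_results,
        "background_results": bg_results,
        "part_counts": pd.DataFrame(
            part_count_rows, columns=["statistic", "part", "n_genes", "n_events"]
        ),
        "part_tests": pd.DataFrame(part_test_rows, columns=["statistic", "chi2", "p"]),
        "part_rank_tests": pd.DataFrame(
            rank_rows,
            columns=["statistic", "group", "n1", "n2", "rank_sum_1", "rank_sum_2", "u", "z", "p"],
        ),
        "hypergeometric": pd.DataFrame(
            hyper_rows,
            columns=["statistic", "part", "p_under", "p_over", "background_n", "background_events"],
        ),
        "centrality": centrality_table,
        "centrality_association": (
            pd.concat(assoc_frames, ignore_index=True) if assoc_frames else pd.DataFrame()
        ),
    }
    bundle["summary"] = report(bundle)
    return bundle


def report(bundle: dict) -> str:
    """Plain-text summary: significant genes per group x statistic with raw
    and corrected p (hit-list layout), part tests, centrality association."""
    lines = []
    res = bundle["gene_results"]
    ann = bundle["annotation"].table.set_index("gene_id")
    hits = res[res["significant"]].sort_values(["statistic", "p_fisher"])
    lines.append("== Significant gene regions ==")
    lines.append("Statistic\tSub-pathway\tGene\tContinental Group\tp-value\tCorrected p-value")
    if hits.empty:
        lines.append("No significant genes in any continental group.")
    else:
        for _, r in hits.iterrows():
            sub = ann.loc[r["gene_id"], "sub_pathway"] if r["gene_id"] in ann.index else "."
            lines.append(
                f"{r['statistic']}\t{sub}\t{r['gene_id']}\t{r['group']}\t"
                f"{r['p_fisher']:.3g}\t{r['corrected_p']:.3g}"
            )
    lines.append("")
    lines.append("== Part comparison (upstream vs downstream) ==")
    lines.append(bundle["part_counts"].to_string(index=False))
    lines.append(bundle["part_tests"].to_string(index=False))
    lines.append("")
    lines.append("== Part rank tests (Mann-Whitney on gene Fisher Z) ==")
    lines.append(bundle["part_rank_tests"].to_string(index=False))
    lines.append("")
    lines.append("== Hypergeometric vs genomic background ==")
    lines.append(bundle["hypergeometric"].to_string(index=False))
    lines.append("")
    lines.append("== Centrality association ==")
    assoc = bundle["centrality_association"]
    lines.append(assoc.to_string(index=False) if not assoc.empty else
                 "Not computed (a significance group was empty).")
    return "\n".join(lines) + "\n"


def write_bundle(bundle: dict, out_dir: str | Path) -> list[Path]:
    """Write every stage table, the summary and the run manifest."""
    out_dir = Path(out_dir)
    tables = {
        "gene_results": bundle["gene_results"],
        "background_results": bundle["background_results"],
        "part_counts": bundle["part_counts"],
        "part_tests": bundle["part_tests"],
        "part_rank_tests": bundle["part_rank_tests"],
        "hypergeometric": bundle["hypergeometric"],
        "centrality": bundle["centrality"],
        "centrality_association": bundle["centrality_association"],
    }
    for track in bundle["tracks"]:
        t = track.table.copy()
        t.insert(0, "group", track.group)
        t.insert(0, "statistic", track.statistic)
        tables[f"track_{track.statistic}_{track.group}"] = t
    config = bundle["config"]
    manifest = asdict(config) if hasattr(config, "__dataclass_fields__") else dict(config)
    written = core_io.write_results_tsv(tables, out_dir, manifest)
    summary_path = out_dir / "summary.txt"
    summary_path.write_text(bundle["summary"])
    written.append(summary_path)
    return written
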