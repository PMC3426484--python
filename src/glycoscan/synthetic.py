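"""HGDP-like synthetic data with known ground truth.

The generator emulates the study conditions of a continental-scale SNP-array
scan: seven labeled groups of phased diploid samples, biallelic SNPs with a
known ancestral allele, an array-like (roughly uniform) MAF spectrum, tunable
between-group differentiation under the Balding-Nichols model, linkage
disequilibrium induced by a Markov template-copying pass, an optional
constructed selective sweep producing extended haplotype homozygosity, and a
pathway fixture (gene catalog, upstream/downstream/substrates annotation,
connected pathway graph, disjoint background-region catalog).

The sweep is constructed (founder mosaic), not forward-simulated, so the
ground truth -- carrier set and haplotype decay rate -- is exact. RNG streams
are split per stage so toggling the sweep does not perturb the neutral
background.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core_io import (
    CONTINENTAL_GROUPS,
    GeneCatalog,
    GlycoscanError,
    GroupScheme,
    HaplotypePanel,
    PathwayAnnotation,
    PathwayGraph,
)

# part proportions of the pathway under study: 25 upstream, 21 downstream,
# 10 substrate-biosynthesis genes
_PART_WEIGHTS = {"upstream": 25, "downstream": 21, "substrates": 10}
_SUB_PATHWAYS = {
    "upstream": ["precursor_biosynthesis", "OST_complex", "CNX_CRT"],
    "downstream": ["branching_early_golgi", "branching_late_golgi"],
    "substrates": ["substrates_biosynthesis"],
}


@dataclass
class SweepParams:
    """Constructed-sweep parameters.

    The derived allele at the core SNP is set on a target fraction of
    haplotypes; carriers are rebuilt as mosaics of a single founder haplotype
    with recombination escapes at ``recomb_switch_rate`` per bp, limited to
    ``flank_bp`` on either side of the core (None = whole chromosome).
    """

    core_position: int
    derived_frequency: float = 0.6
    founder_fraction: float = 1.0
    recomb_switch_rate: float = 5e-8
    flank_bp: int | None = 100_000


@dataclass
class SimulationConfig:
    seed: int = 0
    n_groups: int = 7
    samples_per_group: int = 30
    n_snps: int = 5000
    chromosome_length_bp: int = 50_000_000
    wright_F: float = 0.10
    copy_switch_rate: float = 1e-6  # per bp; Markov LD-copying template switch rate
    sweep: SweepParams | None = None
    maf_floor: float = 0.05
    gene_count: int = 56
    gene_length_bp: int = 10_000
    region_flank_bp: int = 15_000
    background_region_count: int = 500
    chromosome: str = "chr1"

    def __post_init__(self) -> None:
        if min(self.n_groups, self.samples_per_group, self.n_snps, self.gene_count) <= 0:
            raise GlycoscanError("all counts must be positive")
        if not 0 <= self.wright_F < 1:
            raise GlycoscanError("wright_F must be in [0, 1)")
        if self.sweep is not None and not 0 < self.sweep.derived_frequency < 1:
            raise GlycoscanError("sweep derived_frequency must be in (0, 1)")

    def rng(self, stage: int) -> np.random.Generator:
        # independent stream per stage: frequencies / positions / haplotypes /
        # copying / sweep / fixture
        return np.random.default_rng([int(self.seed), stage])


def group_labels(n_groups: int) -> list[str]:
    if n_groups == len(CONTINENTAL_GROUPS):
        return list(CONTINENTAL_GROUPS)
    return [f"G{i + 1}" for i in range(n_groups)]


def simulate_frequencies(
    p_anc: np.ndarray | float,
    wright_F: float,
    n_groups: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-group derived-allele frequencies under the Balding-Nichols model.

    Each group's frequency is drawn from Beta(p(1-F)/F, (1-p)(1-F)/F), which
    has mean p and variance F p (1-p). F = 0 returns p exactly for all groups.
    """
    p = np.atleast_1d(np.asarray(p_anc, dtype=float))
    if np.any((p <= 0) | (p >= 1)):
        raise GlycoscanError("ancestral frequencies must lie in (0, 1)")
    if wright_F == 0:
        out = np.tile(p, (n_groups, 1))
    else:
        scale = (1.0 - wright_F) / wright_F
        out = rng.beta(p * scale, (1.0 - p) * scale, size=(n_groups, p.size))
    return out if np.ndim(p_anc) else out[:, 0] if p.size == 1 else out


def _copying_pass(
    base: np.ndarray,
    positions: np.ndarray,
    switch_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Markov LD pass: each haplotype copies a panel mate along the
    chromosome, switching template with probability 1 - exp(-rate * dist)
    between adjacent SNPs."""
    n, m = base.shape
    if switch_rate <= 0 or n < 2:
        return base.copy()
    p_switch = 1.0 - np.exp(-switch_rate * np.diff(positions.astype(float)))
    out = np.empty_like(base)
    for i in range(n):
        switches = np.concatenate([[True], rng.random(m - 1) < p_switch])
        seg_ids = np.cumsum(switches) - 1
        templates = rng.integers(0, n, size=seg_ids[-1] + 1)
        out[i] = base[templates[seg_ids], np.arange(m)]
    return out


def simulate_panel(config: SimulationConfig) -> HaplotypePanel:
    """Simulate a neutral structured panel (plus the configured sweep)."""
    c = config
    pos_rng = c.rng(1)
    positions = np.sort(
        pos_rng.choice(c.chromosome_length_bp, size=c.n_snps, replace=False)
    ) + 1
    freq_rng, hap_rng, copy_rng = c.rng(0), c.rng(2), c.rng(3)
    p_anc = freq_rng.uniform(c.maf_floor, 1.0 - c.maf_floor, size=c.n_snps)
    group_freq = simulate_frequencies(p_anc, c.wright_F, c.n_groups, freq_rng)

    n_hap_group = 2 * c.samples_per_group
    blocks = []
    for g in range(c.n_groups):
        base = (hap_rng.random((n_hap_group, c.n_snps)) < group_freq[g]).astype(np.int8)
        blocks.append(_copying_pass(base, positions, c.copy_switch_rate, copy_rng))
    H = np.vstack(blocks)

    # enforce the global MAF floor by redrawing violating columns (the
    # copying template paths are column-independent, so a per-column redraw
    # leaves the rest of the panel untouched)
    for _ in range(200):
        n = H.shape[0]
        d = H.sum(axis=0)
        bad = np.flatnonzero(np.minimum(d, n - d) + 1e-9 < c.maf_floor * n)
        if bad.size == 0:
            break
        p_anc[bad] = freq_rng.uniform(c.maf_floor, 1.0 - c.maf_floor, size=bad.size)
        gf = simulate_frequencies(p_anc[bad], c.wright_F, c.n_groups, freq_rng)
        for g in range(c.n_groups):
            rows = slice(g * n_hap_group, (g + 1) * n_hap_group)
            base = (hap_rng.random((n_hap_group, bad.size)) < gf[g]).astype(np.int8)
            sub = _copying_pass(
                np.ascontiguousarray(base), positions[bad], c.copy_switch_rate, copy_rng
            )
            H[rows][:, bad] = sub  # H[rows] is a slice view
    else:  # pragma: no cover
        raise GlycoscanError("could not satisfy maf_floor")

    labels = group_labels(c.n_groups)
    samples = pd.DataFrame(
        {
            "sample_id": [f"S{g}_{i:03d}" for g in range(c.n_groups) for i in range(c.samples_per_group)],
            "population": [f"POP_{labels[g]}" for g in range(c.n_groups) for _ in range(c.samples_per_group)],
            "continental_group": [labels[g] for g in range(c.n_groups) for _ in range(c.samples_per_group)],
        }
    )
    snps = pd.DataFrame(
        {
            "snp_id": [f"snp{j:06d}" for j in range(c.n_snps)],
            "chromosome": c.chromosome,
            "position_bp": positions,
            "ancestral_allele": "A",
            "derived_allele": "G",
        }
    )
    panel = HaplotypePanel(H, snps, samples)
    if c.sweep is not None:
        panel = implant_sweep(panel, c.sweep, c.rng(4))
    return panel


def implant_sweep(
    panel: HaplotypePanel, sweep: SweepParams, rng: np.random.Generator
) -> HaplotypePanel:
    """Rebuild a target fraction of haplotypes as founder mosaics at a core SNP.

    Carriers get the derived core allele and copy the founder haplotype
    outward from the core until a recombination escape (exponential in bp at
    ``recomb_switch_rate``), after which they keep their own alleles;
    non-carriers are untouched. The result is slower EHH decay around the
    core for the derived allele.
    """
    pos = panel.snps["position_bp"].to_numpy()
    if not pos[0] <= sweep.core_position <= pos[-1]:
        raise GlycoscanError("sweep core position outside panel range")
    core = int(np.argmin(np.abs(pos - sweep.core_position)))
    n_hap = panel.n_haplotypes
    n_carriers = int(round(sweep.derived_frequency * n_hap))
    if not 2 <= n_carriers <= n_hap:
        raise GlycoscanError(
            f"derived_frequency {sweep.derived_frequency} unreachable with {n_hap} haplotypes"
        )
    H = panel.haplotypes.copy()
    carriers = rng.choice(n_hap, size=n_carriers, replace=False)
    founder_row = H[int(rng.choice(carriers))].copy()
    founder_row[core] = 1
    H[:, core] = 0
    H[carriers, core] = 1

    n_mosaic = int(round(sweep.founder_fraction * n_carriers))
    mosaic_rows = carriers[:n_mosaic]
    rate = sweep.recomb_switch_rate
    core_pos = pos[core]
    dist = np.abs(pos.astype(float) - core_pos)
    within = np.ones_like(dist, bool) if sweep.flank_bp is None else dist <= sweep.flank_bp
    for row in mosaic_rows:
        if rate > 0:
            esc_left = rng.exponential(1.0 / rate)
            esc_right = rng.exponential(1.0 / rate)
        else:
            esc_left = esc_right = np.inf
        left = (pos < core_pos) & (dist <= esc_left) & within
        right = (pos > core_pos) & (dist <= esc_right) & within
        span = left | right
        span[core] = True
        H[row, span] = founder_row[span]
    return HaplotypePanel(H, panel.snps, panel.samples)


def _split_counts(total: int, weights: dict[str, int]) -> dict[str, int]:
    wsum = sum(weights.values())
    counts = {k: int(round(total * w / wsum)) for k, w in weights.items()}
    keys = list(counts)
    while sum(counts.values()) != total:
        k = keys[0] if sum(counts.values()) < total else max(keys, key=lambda k: counts[k])
        counts[k] += 1 if sum(counts.values()) < total else -1
    return counts


def make_pathway_fixture(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[GeneCatalog, PathwayAnnotation, PathwayGraph, GeneCatalog]:
    """Tile non-overlapping pathway genes and background regions on the
    simulated chromosome and build a connected pathway graph.

    Genes are annotated upstream/downstream/substrates in 25/21/10
    proportions; the graph is a chain through the upstream and downstream
    genes with substrate branches and a few extra downstream branch edges.
    Background regions are gene-length regions in slots disjoint from the
    pathway slots, so gene +/- flank regions never overlap background
    regions.
    """
    c = config
    if c.gene_count < 4:
        raise GlycoscanError("gene_count must be >= 4")
    rng = c.rng(5) if rng is None else rng
    n_regions = c.gene_count + c.background_region_count
    slot = c.chromosome_length_bp // n_regions
    need = c.gene_length_bp + 2 * c.region_flank_bp + 2
    if slot < need:
        raise GlycoscanError(
            f"chromosome too short: {n_regions} regions need >= {need * n_regions} bp"
        )
    slots = rng.permutation(n_regions)
    gene_slots = np.sort(slots[: c.gene_count])
    bg_slots = np.sort(slots[c.gene_count :])

    def region_rows(slot_ids, prefix):
        rows = []
        for k, s in enumerate(slot_ids):
            start = int(s) * slot + c.region_flank_bp + 1
            rows.append((f"{prefix}{k + 1:04d}", c.chromosome, start, start + c.gene_length_bp - 1))
        return pd.DataFrame(rows, columns=["gene_id", "chromosome", "tx_start", "tx_end"])

    catalog = GeneCatalog(region_rows(gene_slots, "PWY"))
    background = GeneCatalog(region_rows(bg_slots, "BG"))

    counts = _split_counts(c.gene_count, _PART_WEIGHTS)
    parts, subs = [], []
    for part in ("upstream", "downstream", "substrates"):
        labels = _SUB_PATHWAYS[part]
        for i in range(counts[part]):
            parts.append(part)
            subs.append(labels[i * len(labels) // max(counts[part], 1)])
    annotation = PathwayAnnotation(
        pd.DataFrame({"gene_id": catalog.gene_ids, "sub_pathway": subs, "part": parts})
    )

    genes = catalog.gene_ids
    chain = [g for g, p in zip(genes, parts) if p in ("upstream", "downstream")]
    substrates = [g for g, p in zip(genes, parts) if p == "substrates"]
    edges = {tuple(sorted(e)) for e in zip(chain[:-1], chain[1:])}
    for g in substrates:  # substrate branches keep the graph connected
        partner = chain[int(rng.integers(0, len(chain)))]
        edges.add(tuple(sorted((g, partner))))
    down = [g for g, p in zip(genes, parts) if p == "downstream"]
    for _ in range(max(2, len(down) // 4)):  # extra branch edges downstream
        a, b = rng.choice(len(down), size=2, replace=False)
        if down[a] != down[b]:
            edges.add(tuple(sorted((down[a], down[b]))))
    graph = PathwayGraph.from_edges(sorted(edges), nodes=genes)
    return catalog, annotation, graph, background
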