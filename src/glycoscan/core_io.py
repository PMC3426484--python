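"""Domain containers and file I/O for the selection-scan pipeline.

The pipeline works on phased diploid haplotype panels with ancestral-allele
orientation (0 = ancestral, 1 = derived), a sample -> population ->
continental-group scheme, a gene catalog with 1-based inclusive transcript
coordinates, a pathway-membership annotation (upstream / downstream /
substrates / excluded) and a simple undirected pathway graph whose edges are
shared metabolites.

Coordinates are 1-based inclusive internally; BED input (0-based half-open)
is converted at the boundary.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("glycoscan")

#: allele code for a missing call in a haplotype matrix
MISSING = -1

PARTS = ("upstream", "downstream", "substrates", "excluded")

#: the seven HGDP continental groups, used as default labels
CONTINENTAL_GROUPS = ("SSAFR", "MENA", "EUR", "CSASIA", "EASIA", "OCE", "AME")

SNP_COLUMNS = ["snp_id", "chromosome", "position_bp", "ancestral_allele", "derived_allele"]


class GlycoscanError(ValueError):
    """Raised on invalid inputs or contract violations."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class HaplotypePanel:
    """Phased haplotype matrix plus SNP and sample metadata.

    haplotypes : int8 array, shape (2 * n_samples, n_snps); rows 2i, 2i+1
        belong to sample i; codes 0 = ancestral, 1 = derived, -1 = missing.
    snps : DataFrame with columns snp_id, chromosome, position_bp (1-based),
        ancestral_allele, derived_allele and optionally genetic_pos_cM.
    samples : DataFrame with columns sample_id, population, continental_group.
    """

    haplotypes: np.ndarray
    snps: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        self.snps = self.snps.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)
        self.validate()

    # -- invariants --------------------------------------------------------
    def validate(self) -> None:
        n_hap, n_snp = self.haplotypes.shape
        if n_hap != 2 * len(self.samples):
            raise GlycoscanError(
                f"haplotype rows ({n_hap}) != 2 x samples ({len(self.samples)})"
            )
        if n_snp != len(self.snps):
            raise GlycoscanError(f"haplotype columns ({n_snp}) != SNP rows ({len(self.snps)})")
        codes = np.unique(self.haplotypes)
        if not np.isin(codes, [MISSING, 0, 1]).all():
            raise GlycoscanError(f"invalid allele codes {codes!r}")
        for chrom, sub in self.snps.groupby("chromosome", sort=False):
            pos = sub["position_bp"].to_numpy()
            if not (np.diff(pos) > 0).all():
                raise GlycoscanError(f"positions not strictly increasing on {chrom}")
        if self.samples["sample_id"].duplicated().any():
            raise GlycoscanError("duplicate sample_id")

    # -- basic accessors ---------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    def derived_counts(self, rows: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Per-SNP (non-missing haplotype count, derived-allele count)."""
        H = self.haplotypes if rows is None else self.haplotypes[rows]
        n = (H != MISSING).sum(axis=0)
        d = (H == 1).sum(axis=0)
        return n, d

    def derived_freq(self, rows: np.ndarray | None = None) -> np.ndarray:
        n, d = self.derived_counts(rows)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, d / np.maximum(n, 1), np.nan)

    def maf(self, rows: np.ndarray | None = None) -> np.ndarray:
        f = self.derived_freq(rows)
        return np.minimum(f, 1.0 - f)

    def take_snps(self, index: np.ndarray) -> "HaplotypePanel":
        index = np.asarray(index)
        return HaplotypePanel(
            self.haplotypes[:, index],
            self.snps.iloc[index].reset_index(drop=True),
            self.samples.copy(),
        )


@dataclass
class GroupScheme:
    """Ordered continental-group labels and the sample -> group assignment."""

    groups: list[str]
    assignment: dict[str, str]

    def __post_init__(self) -> None:
        if len(self.groups) < 2:
            raise GlycoscanError("need >= 2 groups")
        bad = {g for g in self.assignment.values() if g not in self.groups}
        if bad:
            raise GlycoscanError(f"assignment uses unknown groups {sorted(bad)}")

    @classmethod
    def from_samples(cls, samples: pd.DataFrame) -> "GroupScheme":
        groups = list(dict.fromkeys(samples["continental_group"]))
        assignment = dict(zip(samples["sample_id"], samples["continental_group"]))
        return cls(groups, assignment)

    def sample_indices(self, panel: HaplotypePanel, group: str) -> np.ndarray:
        if group not in self.groups:
            raise GlycoscanError(f"unknown group {group!r}")
        mask = panel.samples["sample_id"].map(self.assignment) == group
        return np.flatnonzero(mask.to_numpy())

    def haplotype_rows(self, panel: HaplotypePanel, group: str) -> np.ndarray:
        """Haplotype row indices (2i, 2i+1) of the samples in *group*."""
        idx = self.sample_indices(panel, group)
        return np.sort(np.concatenate([2 * idx, 2 * idx + 1])) if idx.size else np.array([], int)


@dataclass
class GeneCatalog:
    """Gene transcript coordinates, 1-based inclusive."""

    table: pd.DataFrame  # gene_id, chromosome, tx_start, tx_end

    def __post_init__(self) -> None:
        t = self.table.reset_index(drop=True)
        if t["gene_id"].duplicated().any():
            dups = t.loc[t["gene_id"].duplicated(), "gene_id"].tolist()
            raise GlycoscanError(f"duplicate gene_id: {dups}")
        if (t["tx_start"] > t["tx_end"]).any():
            bad = t.loc[t["tx_start"] > t["tx_end"], "gene_id"].tolist()
            raise GlycoscanError(f"tx_start > tx_end for {bad}")
        self.table = t

    def __len__(self) -> int:
        return len(self.table)

    @property
    def gene_ids(self) -> list[str]:
        return self.table["gene_id"].tolist()


@dataclass
class PathwayAnnotation:
    """gene -> (sub-pathway, part) mapping driving the part-level tests."""

    table: pd.DataFrame  # gene_id, sub_pathway, part

    def __post_init__(self) -> None:
        t = self.table.reset_index(drop=True)
        if t["gene_id"].duplicated().any():
            raise GlycoscanError("duplicate gene_id in annotation")
        bad = sorted(set(t["part"]) - set(PARTS))
        if bad:
            raise GlycoscanError(f"unknown part labels {bad}; allowed {PARTS}")
        self.table = t

    def part_of(self, gene_id: str) -> str:
        row = self.table.loc[self.table["gene_id"] == gene_id]
        if row.empty:
            raise GlycoscanError(f"gene {gene_id!r} not annotated")
        return row["part"].iloc[0]

    def genes_in_part(self, part: str) -> list[str]:
        return self.table.loc[self.table["part"] == part, "gene_id"].tolist()

    @property
    def gene_ids(self) -> list[str]:
        return self.table["gene_id"].tolist()


@dataclass
class PathwayGraph:
    """Simple undirected gene graph; each edge is a shared metabolite."""

    graph: nx.Graph

    def __post_init__(self) -> None:
        if any(u == v for u, v in self.graph.edges):
            raise GlycoscanError("self-loop in pathway graph")

    @classmethod
    def from_edges(cls, edges, nodes=None) -> "PathwayGraph":
        g = nx.Graph()
        if nodes is not None:
            g.add_nodes_from(nodes)
        for u, v in edges:
            if u == v:
                raise GlycoscanError(f"self-loop on {u}")
            g.add_edge(u, v)
        return cls(g)

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_haplotype_vcf(path: str | Path, ancestral_tag: str = "AA") -> HaplotypePanel:
    """Read a phased VCF into an ancestral-oriented haplotype panel.

    Only biallelic SNPs are kept. Alleles are recoded so 0 is the ancestral
    allele given by INFO/*ancestral_tag*; sites whose ancestral allele matches
    neither REF nor ALT (e.g. "N") are dropped and counted in the log, as are
    sites lacking the tag. Any unphased genotype is an error naming the sample
    and site. Sample metadata (population, continental group) is not in the
    VCF; the returned panel assigns placeholder labels, which callers replace
    via a groups table (see :func:`read_tables`).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    n = len(sample_ids)
    cols, rows = [], []
    n_no_tag = n_mismatch = n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_multi += 1
            continue
        aa = var.INFO.get(ancestral_tag)
        if aa is None:
            logger.warning("site %s:%d lacks INFO/%s; dropped", var.CHROM, var.POS, ancestral_tag)
            n_no_tag += 1
            continue
        aa = str(aa).upper()
        ref, alt = var.REF.upper(), var.ALT[0].upper()
        if aa == ref:
            anc, der, flip = ref, alt, False
        elif aa == alt:
            anc, der, flip = alt, ref, True
        else:
            n_mismatch += 1
            continue
        col = np.full(2 * n, MISSING, dtype=np.int8)
        for i, gt in enumerate(var.genotypes):
            a, b, phased = gt[0], gt[1], gt[-1]
            if a >= 0 and b >= 0 and not phased:
                raise GlycoscanError(
                    f"unphased genotype for sample {sample_ids[i]} at {var.CHROM}:{var.POS}"
                )
            for k, allele in enumerate((a, b)):
                if allele < 0:
                    continue
                code = int(allele)
                col[2 * i + k] = (1 - code) if flip else code
        cols.append(col)
        rows.append((var.ID or f"{var.CHROM}:{var.POS}", var.CHROM, var.POS, anc, der))
    if n_no_tag or n_mismatch or n_multi:
        logger.info(
            "VCF %s: dropped %d sites without %s, %d ancestral-mismatch, %d non-biallelic",
            path, n_no_tag, ancestral_tag, n_mismatch, n_multi,
        )
    if not cols:
        raise GlycoscanError(f"no usable biallelic SNPs in {path}")
    haplotypes = np.column_stack(cols)
    snps = pd.DataFrame(rows, columns=SNP_COLUMNS)
    samples = pd.DataFrame(
        {"sample_id": sample_ids, "population": "NA", "continental_group": "NA"}
    )
    return HaplotypePanel(haplotypes, snps, samples)


def filter_maf(
    panel: HaplotypePanel,
    threshold: float = 0.05,
    scope: str = "global",
    scheme: GroupScheme | None = None,
) -> HaplotypePanel:
    """Drop SNPs with minor allele frequency below *threshold* (>= is kept).

    scope is "global" or "per_group:<G>"; the latter computes MAF over the
    haplotypes of group G only and requires *scheme*. The comparison is done
    on allele counts so the 5% boundary is exact (e.g. 95 of 100 derived
    copies is MAF 0.05 and is retained).
    """
    if not 0 < threshold <= 0.5:
        raise GlycoscanError(f"threshold {threshold} outside (0, 0.5]")
    if scope == "global":
        rows = None
    elif scope.startswith("per_group:"):
        if scheme is None:
            raise GlycoscanError("per_group scope requires a GroupScheme")
        rows = scheme.haplotype_rows(panel, scope.split(":", 1)[1])
    else:
        raise GlycoscanError(f"unknown scope {scope!r}")
    n, d = panel.derived_counts(rows)
    keep = np.minimum(d, n - d) + 1e-9 >= threshold * n
    if not keep.any():
        raise GlycoscanError("no SNPs survive filter")
    dropped = int((~keep).sum())
    if dropped:
        logger.info("MAF filter (%s, %.3g): dropped %d of %d SNPs", scope, threshold, dropped, len(keep))
    return panel.take_snps(np.flatnonzero(keep))


def _read_gene_table(path: str | Path) -> GeneCatalog:
    path = Path(path)
    if path.suffix.lower() == ".bed":
        t = pd.read_csv(
            path, sep=r"\s+", header=None, comment="#",
            names=["chromosome", "start0", "end0", "gene_id"],
            usecols=[0, 1, 2, 3],
        )
        t = pd.DataFrame(
            {
                "gene_id": t["gene_id"],
                "chromosome": t["chromosome"],
                "tx_start": t["start0"] + 1,  # 0-based half-open -> 1-based inclusive
                "tx_end": t["end0"],
            }
        )
    else:
        t = pd.read_csv(path, sep="\t")
        missing = {"gene_id", "chromosome", "tx_start", "tx_end"} - set(t.columns)
        if missing:
            raise GlycoscanError(f"gene catalog {path} missing columns {sorted(missing)}")
        t = t[["gene_id", "chromosome", "tx_start", "tx_end"]]
    return GeneCatalog(t)


def read_tables(
    gene_catalog_path: str | Path,
    annotation_path: str | Path,
    groups_path: str | Path,
    edgelist_path: str | Path,
) -> tuple[GeneCatalog, PathwayAnnotation, GroupScheme, PathwayGraph]:
    """Read and validate the catalog, annotation, group and edge-list TSVs."""
    catalog = _read_gene_table(gene_catalog_path)
    ann = PathwayAnnotation(pd.read_csv(annotation_path, sep="\t"))
    groups_t = pd.read_csv(groups_path, sep="\t")
    scheme = GroupScheme(
        list(dict.fromkeys(groups_t["continental_group"])),
        dict(zip(groups_t["sample_id"], groups_t["continental_group"])),
    )
    edges_t = pd.read_csv(edgelist_path, sep="\t")
    annotated = set(ann.gene_ids)
    offenders = sorted(
        {g for g in pd.concat([edges_t["gene_a"], edges_t["gene_b"]]) if g not in annotated}
    )
    if offenders:
        raise GlycoscanError(f"edges name unannotated genes: {offenders}")
    graph = PathwayGraph.from_edges(
        edges_t[["gene_a", "gene_b"]].itertuples(index=False, name=None)
    )
    return catalog, ann, scheme, graph


def read_groups_into_panel(panel: HaplotypePanel, groups_path: str | Path) -> tuple[HaplotypePanel, GroupScheme]:
    """Attach population/continental-group labels from a groups TSV."""
    t = pd.read_csv(groups_path, sep="\t").set_index("sample_id")
    missing = [s for s in panel.samples["sample_id"] if s not in t.index]
    if missing:
        raise GlycoscanError(f"samples missing from groups table: {missing[:5]}")
    samples = panel.samples.copy()
    samples["population"] = samples["sample_id"].map(t["population"]).to_numpy()
    samples["continental_group"] = samples["sample_id"].map(t["continental_group"]).to_numpy()
    new = HaplotypePanel(panel.haplotypes, panel.snps, samples)
    return new, GroupScheme.from_samples(samples)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_results_tsv(
    tables: dict[str, pd.DataFrame],
    out_dir: str | Path,
    manifest: dict | None = None,
) -> list[Path]:
    """Write one TSV per stage table, '.' for missing, plus a run manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name in sorted(tables):
        p = out_dir / f"{name}.tsv"
        tables[name].to_csv(p, sep="\t", index=False, na_rep=".", float_format="%.10g")
        written.append(p)
    if manifest is not None:
        info = dict(manifest)
        info["versions"] = {
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "pandas": pd.__version__,
        }
        p = out_dir / "manifest.json"
        p.write_text(json.dumps(info, indent=2, sort_keys=True, default=str) + "\n")
        written.append(p)
    return written


def read_results_tsv(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", na_values=["."], keep_default_na=True)
    except pd.errors.EmptyDataError:
        return pd.DataFrame()


def write_haplotype_vcf(panel: HaplotypePanel, path: str | Path, ancestral_tag: str = "AA") -> Path:
    """Write the panel as a phased VCF with the ancestral allele as REF."""
    path = Path(path)
    H = panel.haplotypes
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(
            f'##INFO=<ID={ancestral_tag},Number=1,Type=String,Description="Ancestral allele">\n'
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.samples["sample_id"])
            + "\n"
        )
        snps = panel.snps
        for j in range(panel.n_snps):
            row = snps.iloc[j]
            gts = []
            for i in range(panel.n_samples):
                a, b = H[2 * i, j], H[2 * i + 1, j]
                gts.append(f"{'.' if a < 0 else a}|{'.' if b < 0 else b}")
            fh.write(
                f"{row.chromosome}\t{row.position_bp}\t{row.snp_id}\t"
                f"{row.ancestral_allele}\t{row.derived_allele}\t.\tPASS\t"
                f"{ancestral_tag}={row.ancestral_allele}\tGT\t" + "\t".join(gts) + "\n"
            )
    return path


def write_fixture_tables(
    catalog: GeneCatalog,
    annotation: PathwayAnnotation,
    samples: pd.DataFrame,
    graph: PathwayGraph,
    background: GeneCatalog,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write the gene/annotation/groups/edges/background TSVs core_io reads."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genes": out_dir / "genes.tsv",
        "annotation": out_dir / "annotation.tsv",
        "groups": out_dir / "groups.tsv",
        "edges": out_dir / "edges.tsv",
        "background": out_dir / "background.tsv",
    }
    catalog.table.to_csv(paths["genes"], sep="\t", index=False)
    annotation.table.to_csv(paths["annotation"], sep="\t", index=False)
    samples[["sample_id", "population", "continental_group"]].to_csv(
        paths["groups"], sep="\t", index=False
    )
    pd.DataFrame(sorted(tuple(sorted(e)) for e in graph.graph.edges), columns=["gene_a", "gene_b"]).to_csv(
        paths["edges"], sep="\t", index=False
    )
    background.table.to_csv(paths["background"], sep="\t", index=False)
    return paths
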