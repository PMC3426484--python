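"""Gene-region Fisher combination and background-calibrated significance.

For each gene, the SNP-level empirical p-values in the gene +/- flank region
(100 kb flanks at genome scale) are pooled with Fisher's combination,
Z_F = -2 * sum(ln p_i), which under the null follows a chi-squared
distribution with 2k degrees of freedom (k = number of SNPs in the region).
The chi-squared upper-tail p-value is then ranked against the same statistic
computed on a catalog of non-overlapping background gene regions, and a gene
x group x statistic cell is called significant when its background rank
p-value falls in the most extreme alpha after a Bonferroni correction for
the number of continental groups times the number of statistics
(0.05 / (7 x 2) at the study's defaults).

Background ranking uses the chi-squared tail p (not raw Z_F) so regions with
different SNP counts are comparable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import GeneCatalog, GlycoscanError, logger
from .fst import SnpScoreTrack


def assemble_region(
    gene: pd.Series, track_table: pd.DataFrame, flank_bp: int = 100_000
) -> np.ndarray:
    """Row indices of track SNPs inside gene tx_start - flank .. tx_end + flank
    (both bounds inclusive) on the gene's chromosome."""
    lo = gene["tx_start"] - flank_bp
    hi = gene["tx_end"] + flank_bp
    on_chrom = track_table["chromosome"] == gene["chromosome"]
    pos = track_table["position_bp"]
    return np.flatnonzero((on_chrom & (pos >= lo) & (pos <= hi)).to_numpy())


def fisher_combine(p_values: np.ndarray) -> tuple[float, int, float]:
    """(Z_F, k, chi2 tail p) for a list of p-values in (0, 1]."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise GlycoscanError("empty p-value list")
    if np.any((p <= 0) | (p > 1)):
        raise GlycoscanError("p-values must lie in (0, 1]")
    z = float(-2.0 * np.log(p).sum())
    k = int(p.size)
    return z, k, float(stats.chi2.sf(z, 2 * k))


def _scan_catalog(
    catalog: GeneCatalog, tracks: list[SnpScoreTrack], flank_bp: int
) -> pd.DataFrame:
    rows = []
    for track in tracks:
        t = track.table
        for _, gene in catalog.table.iterrows():
            idx = assemble_region(gene, t, flank_bp)
            p = t["emp_p"].to_numpy()[idx]
            p = p[~np.isnan(p)]
            if p.size == 0:
                rows.append((gene["gene_id"], track.group, track.statistic, 0, np.nan, np.nan))
                continue
            z, k, pf = fisher_combine(p)
            rows.append((gene["gene_id"], track.group, track.statistic, k, z, pf))
    return pd.DataFrame(
        rows, columns=["gene_id", "group", "statistic", "k", "z_fisher", "p_fisher"]
    )


def gene_scan(
    tracks: list[SnpScoreTrack], catalog: GeneCatalog, flank_bp: int = 100_000
) -> pd.DataFrame:
    """One GeneRegionResult row per gene x group x statistic.

    Tracks must carry empirical p-values (``emp_p`` column). Genes whose
    region holds no scored SNP are reported unscored (k = 0, missing p).
    Genes with overlapping flanks share SNPs; each region is scored
    independently.
    """
    for track in tracks:
        if "emp_p" not in track.table.columns:
            raise GlycoscanError("tracks must have empirical p-values (run empirical_p first)")
    out = _scan_catalog(catalog, tracks, flank_bp)
    n_unscored = int((out["k"] == 0).sum())
    if n_unscored:
        logger.info("%d gene x track cells unscored (no SNPs in region)", n_unscored)
    return out


def background_scan(
    background_catalog: GeneCatalog, tracks: list[SnpScoreTrack], flank_bp: int = 100_000
) -> pd.DataFrame:
    """Same pipeline over the background regions; errors on region overlap."""
    t = background_catalog.table.sort_values(["chromosome", "tx_start"])
    for chrom, sub in t.groupby("chromosome"):
        starts = sub["tx_start"].to_numpy() - flank_bp
        ends = sub["tx_end"].to_numpy() + flank_bp
        if (starts[1:] <= ends[:-1]).any():
            raise GlycoscanError(f"background regions overlap on {chrom} (with flanks)")
    out = _scan_catalog(background_catalog, tracks, flank_bp)
    return out[out["k"] > 0].reset_index(drop=True)


def bonferroni_correct(p: float | np.ndarray, n_groups: int = 7, n_methods: int = 2) -> float | np.ndarray:
    """min(1, p x n_groups x n_methods); 14 comparisons at study defaults."""
    return np.minimum(1.0, np.asarray(p, dtype=float) * n_groups * n_methods)[()]


def empirical_gene_significance(
    results: pd.DataFrame,
    background: pd.DataFrame,
    alpha: float = 0.05,
    n_groups: int = 7,
    n_methods: int = 2,
    exclude_self: bool = False,
) -> pd.DataFrame:
    """Attach background rank p-values and the Bonferroni significance call.

    emp_rank_p = (#{background p_fisher <= gene p_fisher} + 1) / (N_bg + 1),
    computed within the gene's group x statistic context; significant iff
    emp_rank_p <= alpha / (n_groups x n_methods), inclusive. With
    ``exclude_self`` (used when ranking the background against itself) each
    region's own value is left out of its count.
    """
    if background.empty:
        raise GlycoscanError("empty background distribution")
    out = results.copy()
    rank_p = np.full(len(out), np.nan)
    for (group, stat), sub in out.groupby(["group", "statistic"]):
        bg = background.loc[
            (background["group"] == group) & (background["statistic"] == stat), "p_fisher"
        ].to_numpy()
        bg = np.sort(bg[~np.isnan(bg)])
        if bg.size == 0:
            raise GlycoscanError(f"no background for {group}/{stat}")
        pf = sub["p_fisher"].to_numpy()
        counts = np.searchsorted(bg, pf, side="right")
        if exclude_self:
            counts = counts - 1  # leave-one-out: each region is in bg once
            vals = (counts + 1) / bg.size
        else:
            vals = (counts + 1) / (bg.size + 1)
        rank_p[sub.index.to_numpy()] = np.where(np.isnan(pf), np.nan, vals)
    out["emp_rank_p"] = rank_p
    out["corrected_p"] = bonferroni_correct(out["p_fisher"].to_numpy(), n_groups, n_methods)
    threshold = alpha / (n_groups * n_methods)
    out["significant"] = (out["emp_rank_p"] <= threshold).fillna(False)
    return out
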