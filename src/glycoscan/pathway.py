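"""Upstream-vs-downstream comparison of the pathway.

Three complementary tests compare how selection signals distribute between
the constitutive (upstream) and environment-facing (downstream) parts of the
pathway; substrate-biosynthesis genes and explicitly excluded genes never
enter these comparisons, since their products feed both parts.

* an observed-vs-expected goodness-of-fit chi-squared on event counts (a
  gene is an "event" if significant in at least one continental group),
* a Mann-Whitney rank test on the per-gene Fisher Z scores,
* hypergeometric under/over-representation tests of each part against the
  genomic background.

The Mann-Whitney Z is signed from group 1's U and uses midranks with the
tie-corrected normal approximation by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import GlycoscanError, PathwayAnnotation

COMPARED_PARTS = ("upstream", "downstream")


@dataclass
class PartEventCounts:
    """Per part: number of genes and number of genes with >= 1 significant call."""

    counts: dict[str, tuple[int, int]]  # part -> (n_genes, n_events)

    def __post_init__(self) -> None:
        for part, (n, e) in self.counts.items():
            if not 0 <= e <= n:
                raise GlycoscanError(f"{part}: events {e} outside [0, {n}]")


@dataclass
class MannWhitneyResult:
    n1: int
    n2: int
    rank_sum_1: float
    rank_sum_2: float
    u1: float
    u2: float
    u: float
    z: float
    p_two_sided: float
    tie_corrected: bool


def count_events_by_part(
    results: pd.DataFrame, annotation: PathwayAnnotation, statistic: str
) -> PartEventCounts:
    """Event counts for the upstream/downstream parts, all groups pooled."""
    sub = results[results["statistic"] == statistic]
    events = set(sub.loc[sub["significant"].astype(bool), "gene_id"])
    counts = {}
    for part in COMPARED_PARTS:
        genes = annotation.genes_in_part(part)
        counts[part] = (len(genes), sum(g in events for g in genes))
    return PartEventCounts(counts)


def chi2_goodness_of_fit(counts: PartEventCounts) -> tuple[float, float]:
    """Observed-vs-expected chi-squared (1 df) on part event counts.

    Expected events per part are proportional to the part's gene count.
    """
    parts = list(counts.counts)
    n_genes = np.array([counts.counts[p][0] for p in parts], dtype=float)
    observed = np.array([counts.counts[p][1] for p in parts], dtype=float)
    total_events = observed.sum()
    if total_events < 1:
        raise GlycoscanError("no events to test")
    expected = n_genes * total_events / n_genes.sum()
    if (expected == 0).any():
        raise GlycoscanError("zero expected count in a part")
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(chi2, df=1))
    return chi2, p


def mann_whitney(values_1, values_2, tie_correction: bool = True) -> MannWhitneyResult:
    """Mann-Whitney U with midranks and a signed normal-approximation Z.

    Z is computed from group 1's U: Z = (U1 - n1 n2 / 2) / sigma, with the
    tie-corrected sigma by default. Errors when the pooled values admit no
    ranking (sigma = 0).
    """
    x1 = np.asarray(values_1, dtype=float)
    x2 = np.asarray(values_2, dtype=float)
    n1, n2 = x1.size, x2.size
    if n1 < 1 or n2 < 1:
        raise GlycoscanError("both groups must be non-empty")
    pooled = np.concatenate([x1, x2])
    ranks = stats.rankdata(pooled)
    r1 = float(ranks[:n1].sum())
    r2 = float(ranks[n1:].sum())
    u1 = r1 - n1 * (n1 + 1) / 2
    u2 = r2 - n2 * (n2 + 1) / 2
    u = min(u1, u2)
    N = n1 + n2
    if tie_correction:
        _, t = np.unique(pooled, return_counts=True)
        tie_term = float(((t**3 - t).sum()) / (N * (N - 1)))
        var = n1 * n2 / 12 * ((N + 1) - tie_term)
    else:
        var = n1 * n2 * (N + 1) / 12
    if var <= 0:
        raise GlycoscanError("degenerate ranking (all values identical)")
    z = (u1 - n1 * n2 / 2) / np.sqrt(var)
    p = float(2 * stats.norm.sf(abs(z)))
    return MannWhitneyResult(n1, n2, r1, r2, u1, u2, u, float(z), p, tie_correction)


def u_from_rank_sums(rank_sum_1: float, rank_sum_2: float, n1: int, n2: int) -> float:
    """Reconstruct U = min(U1, U2) from the two rank sums and group sizes."""
    expected_total = (n1 + n2) * (n1 + n2 + 1) / 2
    if abs(rank_sum_1 + rank_sum_2 - expected_total) > 1e-9:
        raise GlycoscanError(
            f"rank sums {rank_sum_1}+{rank_sum_2} != N(N+1)/2 = {expected_total}"
        )
    u1 = rank_sum_1 - n1 * (n1 + 1) / 2
    u2 = rank_sum_2 - n2 * (n2 + 1) / 2
    return float(min(u1, u2))


def compare_part_scores(
    results: pd.DataFrame,
    annotation: PathwayAnnotation,
    statistic: str,
    group: str,
    level: str = "gene",
) -> MannWhitneyResult:
    """Mann-Whitney of upstream vs downstream gene Fisher Z scores for one
    group and statistic (``level="snp"`` is not implemented here; per-SNP
    pooling is done by passing SNP-level values to :func:`mann_whitney`)."""
    sub = results[(results["statistic"] == statistic) & (results["group"] == group)]
    sub = sub.dropna(subset=["z_fisher"])
    values = {}
    for part in COMPARED_PARTS:
        genes = set(annotation.genes_in_part(part))
        v = sub.loc[sub["gene_id"].isin(genes), "z_fisher"].to_numpy()
        if v.size == 0:
            raise GlycoscanError(f"no scored genes in {part} part")
        values[part] = v
    return mann_whitney(values["upstream"], values["downstream"])


def hypergeometric_part_test(
    part_counts: PartEventCounts, background_n: int, background_events: int
) -> dict[str, tuple[float, float]]:
    """Exact under/over-representation p-values per part vs the background.

    For each part, the population is the background genes plus the part's
    genes, with K total significant; X counts significant genes in a draw of
    the part's size. Returns {part: (P[X <= obs], P[X >= obs])}.
    """
    if background_events > background_n:
        raise GlycoscanError("background_events > background_n")
    out = {}
    for part, (n_genes, n_events) in part_counts.counts.items():
        M = background_n + n_genes
        K = background_events + n_events
        if n_genes > M:
            raise GlycoscanError("part larger than population")
        rv = stats.hypergeom(M, K, n_genes)
        out[part] = (float(rv.cdf(n_events)), float(rv.sf(n_events - 1)))
    return out
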