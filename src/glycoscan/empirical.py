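"""Genome-context empirical p-values within bins of similar MAF.

Raw per-SNP scores (F_ST or |iHS|) are ranked against all scored SNPs of
similar minor allele frequency: SNPs are sorted by MAF (ties broken by
position then snp_id) and chunked into consecutive bins of ``snps_per_bin``
SNPs (10,000 at genome scale; synthetic runs use a scaled value). The
empirical p-value is the proportion of same-bin SNPs with a strictly greater
score, with a +1/(n+1) correction so the top SNP gets p = 1/(n+1) rather
than 0 -- the downstream Fisher combination takes logs, so p must be bounded
away from zero. The correction preserves the ranking exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import logger
from .fst import SnpScoreTrack


@dataclass
class MafBinning:
    """Bin assignment for the scored SNPs of one track."""

    bin_id: np.ndarray  # per track row; -1 for unscored SNPs
    bins: pd.DataFrame  # bin_id, snp_count, maf_min, maf_max


def assign_maf_bins(track: SnpScoreTrack, snps_per_bin: int, maf_column: str = "maf_global") -> MafBinning:
    """Chunk the track's scored SNPs into consecutive similar-MAF bins.

    A final partial bin smaller than half the target size is merged into its
    neighbour; fewer scored SNPs than ``snps_per_bin`` yields a single bin
    with a warning.
    """
    t = track.table
    scored = t["value"].notna().to_numpy()
    n_scored = int(scored.sum())
    bin_id = np.full(len(t), -1, dtype=int)
    if n_scored == 0:
        return MafBinning(bin_id, pd.DataFrame(columns=["bin_id", "snp_count", "maf_min", "maf_max"]))
    if n_scored < snps_per_bin:
        logger.warning("only %d scored SNPs < bin size %d; using a single bin", n_scored, snps_per_bin)
    order = np.flatnonzero(scored)
    key = t.iloc[order]
    order = order[np.lexsort((key["snp_id"].to_numpy(), key["position_bp"].to_numpy(),
                              key[maf_column].to_numpy()))]
    # chunk into bins of the target size; a final remainder smaller than half
    # the target merges into the previous bin, otherwise it stands alone
    n_bins = max(1, n_scored // snps_per_bin)
    remainder = n_scored - n_bins * snps_per_bin
    if remainder >= (snps_per_bin + 1) // 2:
        n_bins += 1
    edges = [i * snps_per_bin for i in range(n_bins)] + [n_scored]
    rows = []
    maf = t[maf_column].to_numpy()
    for b in range(len(edges) - 1):
        idx = order[edges[b] : edges[b + 1]]
        bin_id[idx] = b
        rows.append((b, idx.size, float(maf[idx].min()), float(maf[idx].max())))
    bins = pd.DataFrame(rows, columns=["bin_id", "snp_count", "maf_min", "maf_max"])
    return MafBinning(bin_id, bins)


def empirical_p(track: SnpScoreTrack, binning: MafBinning) -> SnpScoreTrack:
    """Attach per-SNP empirical p = (#strictly greater in bin + 1)/(n + 1)."""
    t = track.table.copy()
    values = t["value"].to_numpy(dtype=float)
    p = np.full(len(t), np.nan)
    for b in binning.bins["bin_id"]:
        idx = np.flatnonzero(binning.bin_id == b)
        v = values[idx]
        sorted_v = np.sort(v)
        n = v.size
        greater = n - np.searchsorted(sorted_v, v, side="right")
        p[idx] = (greater + 1) / (n + 1)
    t["bin_id"] = binning.bin_id
    t["emp_p"] = p
    return SnpScoreTrack(track.statistic, track.group, t)
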