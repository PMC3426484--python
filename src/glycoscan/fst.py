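"""Per-SNP population differentiation, one continental group versus the rest.

Haplotype-level (haploid) allele counting is used throughout, since inputs
are phased. Three two-population estimators are available:

* ``weir_cockerham`` -- the variance-components theta-hat for haploid allele
  counts (the default; the field standard for outlier scans),
* ``nei_gst`` -- (H_T - H_S) / H_T with H = 2p(1-p) and H_S the
  sample-size-weighted average,
* ``hudson`` -- 1 - H_w / H_b with small-sample-corrected within
  heterozygosity.

Negative estimates are clamped to 0 by default so downstream empirical
p-values are monotone in differentiation. Sites monomorphic over all
haplotypes get a missing value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import GlycoscanError, GroupScheme, HaplotypePanel, MISSING, logger

ESTIMATORS = ("weir_cockerham", "nei_gst", "hudson")


@dataclass
class SnpScoreTrack:
    """Per-SNP statistic values for one continental group.

    ``table`` columns: snp_id, chromosome, position_bp, value, maf_global,
    maf_group, derived_freq_group (+ emp_p / bin_id once empirical p-values
    are attached). Row order matches the panel's SNP order.
    """

    statistic: str  # "FST" or "ABS_IHS"
    group: str
    table: pd.DataFrame


def group_allele_counts(
    panel: HaplotypePanel, scheme: GroupScheme, group: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP haplotype counts (n_focal, derived_focal, n_rest, derived_rest).

    Missing codes are excluded from the counts.
    """
    focal_rows = scheme.haplotype_rows(panel, group)
    if focal_rows.size == 0:
        raise GlycoscanError(f"group {group!r} has zero samples")
    mask = np.zeros(panel.n_haplotypes, dtype=bool)
    mask[focal_rows] = True
    n1, d1 = panel.derived_counts(np.flatnonzero(mask))
    n2, d2 = panel.derived_counts(np.flatnonzero(~mask))
    return n1, d1, n2, d2


def fst_snp(
    counts: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray],
    estimator: str = "weir_cockerham",
    clamp: bool = True,
) -> np.ndarray:
    """Two-population F_ST per SNP from haploid allele counts.

    Returns NaN where a subsample has n < 2 or the site is monomorphic
    over the pooled haplotypes.
    """
    if estimator not in ESTIMATORS:
        raise GlycoscanError(f"unknown estimator {estimator!r}; choose from {ESTIMATORS}")
    n1, d1, n2, d2 = (np.asarray(a, dtype=float) for a in counts)
    valid = (n1 >= 2) & (n2 >= 2)
    if not valid.all():
        logger.warning("%d SNPs with n < 2 in a subsample -> missing", int((~valid).sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = d1 / n1
        p2 = d2 / n2
        N = n1 + n2
        pbar = (d1 + d2) / N
        poly = (pbar > 0) & (pbar < 1)
        if estimator == "weir_cockerham":
            # haploid two-population variance components (r = 2):
            # MSP between, MSG within, n_c the variance-effective sample size
            msp = n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2
            msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (N - 2)
            n_c = N - (n1**2 + n2**2) / N
            value = (msp - msg) / (msp + (n_c - 1) * msg)
        elif estimator == "nei_gst":
            h_t = 2 * pbar * (1 - pbar)
            h_s = (n1 * 2 * p1 * (1 - p1) + n2 * 2 * p2 * (1 - p2)) / N
            value = (h_t - h_s) / h_t
        else:  # hudson
            h_w = (n1 / (n1 - 1) * 2 * p1 * (1 - p1) + n2 / (n2 - 1) * 2 * p2 * (1 - p2)) / 2
            h_b = p1 * (1 - p2) + p2 * (1 - p1)
            value = 1 - h_w / h_b
    value = np.where(valid & poly, value, np.nan)
    if clamp:
        value = np.where(np.isnan(value), np.nan, np.clip(value, 0.0, 1.0))
    return value


def fst_scan(
    panel: HaplotypePanel,
    scheme: GroupScheme,
    estimator: str = "weir_cockerham",
    group_maf_threshold: float | None = 0.05,
    clamp: bool = True,
) -> dict[str, SnpScoreTrack]:
    """One F_ST track per continental group (focal group vs pooled rest).

    SNPs below the within-group MAF threshold in the focal group are set to
    missing for that group's track (the panel-wide filter is assumed done).
    """
    maf_global = panel.maf()
    tracks: dict[str, SnpScoreTrack] = {}
    for group in scheme.groups:
        n1, d1, n2, d2 = group_allele_counts(panel, scheme, group)
        value = fst_snp((n1, d1, n2, d2), estimator=estimator, clamp=clamp)
        with np.errstate(invalid="ignore"):
            freq_g = np.where(n1 > 0, d1 / np.maximum(n1, 1), np.nan)
        maf_g = np.minimum(freq_g, 1 - freq_g)
        if group_maf_threshold is not None:
            low = np.minimum(d1, n1 - d1) + 1e-9 < group_maf_threshold * n1
            value = np.where(low, np.nan, value)
        table = pd.DataFrame(
            {
                "snp_id": panel.snps["snp_id"],
                "chromosome": panel.snps["chromosome"],
                "position_bp": panel.snps["position_bp"],
                "value": value,
                "maf_global": maf_global,
                "maf_group": maf_g,
                "derived_freq_group": freq_g,
            }
        )
        tracks[group] = SnpScoreTrack("FST", group, table)
    return tracks
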