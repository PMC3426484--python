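"""Extended haplotype homozygosity (EHH) and the integrated haplotype score.

EHH at extent x is the probability that two randomly chosen distinct
chromosomes carrying the core allele are identical over the interval from
the core to x; it is computed by grouping carrier haplotypes on the spanned
columns: EHH = sum_h C(n_h, 2) / C(n_c, 2). Curves start at 1 at the core,
are non-increasing, and are truncated at the first point below the cutoff
(that point included; cutoff 0.05 by default).

iHH is the trapezoidal integral of EHH against distance (bp by default, cM
when a genetic map column is present), summed over the left and right sides.
The unstandardized score is ln(iHH_ancestral / iHH_derived); scores are then
standardized to mean 0 / sd 1 within equal-width derived-allele-frequency
bins (20 bins of width 0.05, small bins merged into their nearest occupied
neighbour) and reported as absolute values, since the scan looks for
unusually long haplotypes on either allele.

SNPs whose EHH has not decayed below the cutoff at a chromosome end are
excluded by default (qc_flag "edge"); SNPs with derived frequency outside
[0.05, 0.95] are not scored (unstable integrals).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import GlycoscanError, GroupScheme, HaplotypePanel, MISSING
from .fst import SnpScoreTrack

QC_OK = "ok"
QC_FREQ = "freq"
QC_EDGE = "edge"
QC_ZERO = "zero_ihh"
QC_RARE = "rare"


@dataclass
class EhhCurve:
    """EHH values walking outward from a core SNP for one allele."""

    core_snp_id: str
    allele: str  # "ancestral" | "derived"
    direction: str  # "left" | "right"
    positions: np.ndarray  # bp, first entry is the core
    ehh: np.ndarray
    truncated_at_end: bool = False  # cutoff never reached before chromosome end
    genetic_pos: np.ndarray | None = None

    @property
    def points(self) -> list[tuple[int, float]]:
        return list(zip(self.positions.tolist(), self.ehh.tolist()))


@dataclass
class IhsParams:
    cutoff: float = 0.05
    n_bins: int = 20
    min_bin_count: int = 10
    freq_min: float = 0.05
    freq_max: float = 0.95
    distance_mode: str = "bp"  # or "cM"
    boundary: str = "exclude"  # or "truncate"
    min_carriers: int = 2


def _grouped_ehh_walk(
    H: np.ndarray,
    carriers: np.ndarray,
    core: int,
    step: int,
    cutoff: float,
) -> tuple[list[int], list[float], bool]:
    """Walk columns from the core in one direction, maintaining haplotype
    groups; returns (column indices, EHH values, hit-chromosome-end flag)."""
    n = carriers.size
    pairs_total = n * (n - 1) // 2
    gid = np.zeros(n, dtype=np.int64)
    cols: list[int] = []
    ehhs: list[float] = []
    j = core + step
    m = H.shape[1]
    while 0 <= j < m:
        col = H[carriers, j]
        if (col == MISSING).any():
            raise GlycoscanError(f"missing genotype in EHH window at column {j}")
        key = gid * 2 + col
        _, gid = np.unique(key, return_inverse=True)
        counts = np.bincount(gid)
        ehh = float((counts * (counts - 1) // 2).sum() / pairs_total)
        cols.append(j)
        ehhs.append(ehh)
        if ehh < cutoff:
            return cols, ehhs, False
        j += step
    return cols, ehhs, True


def ehh(
    panel: HaplotypePanel,
    core: int | str,
    allele: str,
    direction: str,
    cutoff: float = 0.05,
    rows: np.ndarray | None = None,
) -> EhhCurve:
    """EHH curve for one core allele in one direction.

    *core* is a SNP index or snp_id; *rows* optionally restricts to a subset
    of haplotypes (e.g. one continental group). Errors if fewer than two
    haplotypes carry the allele.
    """
    if isinstance(core, str):
        hits = np.flatnonzero((panel.snps["snp_id"] == core).to_numpy())
        if hits.size == 0:
            raise GlycoscanError(f"unknown core snp_id {core!r}")
        core = int(hits[0])
    if allele not in ("ancestral", "derived"):
        raise GlycoscanError("allele must be 'ancestral' or 'derived'")
    if direction not in ("left", "right"):
        raise GlycoscanError("direction must be 'left' or 'right'")
    H = panel.haplotypes if rows is None else panel.haplotypes[rows]
    code = 0 if allele == "ancestral" else 1
    carriers = np.flatnonzero(H[:, core] == code)
    if carriers.size < 2:
        raise GlycoscanError(f"allele too rare for EHH ({carriers.size} carriers)")
    step = -1 if direction == "left" else 1
    cols, ehhs, hit_end = _grouped_ehh_walk(H, carriers, core, step, cutoff)
    pos = panel.snps["position_bp"].to_numpy()
    positions = np.concatenate([[pos[core]], pos[cols]])
    values = np.concatenate([[1.0], ehhs])
    gpos = None
    if "genetic_pos_cM" in panel.snps.columns:
        gp = panel.snps["genetic_pos_cM"].to_numpy(dtype=float)
        gpos = np.concatenate([[gp[core]], gp[cols]])
    snp_id = panel.snps["snp_id"].iloc[core]
    return EhhCurve(snp_id, allele, direction, positions, values, hit_end, gpos)


def _side_integral(curve: EhhCurve, distance_mode: str) -> float:
    if distance_mode == "cM":
        if curve.genetic_pos is None:
            raise GlycoscanError("cM distance requested but no genetic_pos_cM column")
        x = np.abs(curve.genetic_pos - curve.genetic_pos[0])
    else:
        x = np.abs(curve.positions.astype(float) - float(curve.positions[0]))
    return float(np.trapezoid(curve.ehh, x))


def ihh(curve_left: EhhCurve, curve_right: EhhCurve, distance_mode: str = "bp") -> float:
    """Integrated EHH: trapezoidal area of both sides against distance."""
    if curve_left.core_snp_id != curve_right.core_snp_id:
        raise GlycoscanError("curves do not share a core SNP")
    return _side_integral(curve_left, distance_mode) + _side_integral(curve_right, distance_mode)


def ihs_unstandardized(ihh_ancestral: float, ihh_derived: float) -> float:
    """ln(iHH_A / iHH_D); NaN when either integral is zero."""
    if ihh_ancestral <= 0 or ihh_derived <= 0:
        return float("nan")
    return float(np.log(ihh_ancestral / ihh_derived))


def _raw_freq_bin(freq: np.ndarray, n_bins: int, n_hap: int | None = None) -> np.ndarray:
    """Equal-width derived-frequency bin with mirror-consistent boundaries.

    Frequencies below 0.5 use left-closed intervals, frequencies above 0.5
    right-closed ones, so bin(1 - f) is always the mirror of bin(f) even for
    values sitting exactly on a bin edge. Exactly 0.5 gets the sentinel
    ``n_bins`` (its own self-mirror class) when n_bins is even. When the
    haplotype count is known the computation runs on integer allele counts,
    which makes the mirror exact (1 - f is not exact in floating point).
    """
    k = np.empty(freq.size, dtype=int)
    if n_hap is not None:
        d = np.rint(freq * n_hap).astype(np.int64)
        low = 2 * d < n_hap
        high = 2 * d > n_hap
        k[low] = np.clip(d[low] * n_bins // n_hap, 0, n_bins - 1)
        k[high] = n_bins - 1 - np.clip((n_hap - d[high]) * n_bins // n_hap, 0, n_bins - 1)
    else:
        low = freq < 0.5
        high = freq > 0.5
        k[low] = np.clip(np.floor(freq[low] * n_bins).astype(int), 0, n_bins - 1)
        k[high] = n_bins - 1 - np.clip(
            np.floor((1.0 - freq[high]) * n_bins).astype(int), 0, n_bins - 1
        )
    mid = ~(low | high)
    k[mid] = (n_bins - 1) // 2 if n_bins % 2 else n_bins
    return k


def standardize_ihs(
    results: pd.DataFrame,
    n_bins: int = 20,
    min_bin_count: int = 10,
    n_haplotypes: int | None = None,
) -> pd.DataFrame:
    """Standardize unstandardized scores within derived-frequency bins.

    Bins are equal-width in derived frequency (width 1/n_bins). Undersized
    bins are merged with their nearest occupied neighbours; the merge
    operates on folded (MAF) classes so that each standardization cell is
    either one of a mirror pair or a mirror-symmetric set, which makes the
    absolute standardized score exactly invariant under a global
    ancestral/derived relabeling. Adds bin_id, standardized,
    abs_standardized.
    """
    out = results.copy()
    scored = out["unstandardized"].notna().to_numpy()
    if not scored.any():
        raise GlycoscanError("no scored SNPs to standardize")
    freq = out["derived_freq"].to_numpy(dtype=float)
    raw = _raw_freq_bin(freq, n_bins, n_haplotypes)

    center = n_bins if n_bins % 2 == 0 else None
    half = n_bins // 2
    # the fold index whose class is its own mirror image (exact-0.5 sentinel
    # for even n_bins, the middle bin for odd)
    self_mirror_fold = half if n_bins % 2 == 0 else (n_bins - 1) // 2

    def fold(k: int) -> int:
        return half if k == center else min(k, n_bins - 1 - k)

    folds = np.array([fold(k) for k in raw])
    occupied = sorted(set(folds[scored]))
    merged = {f: f for f in occupied}

    def class_cells(eff: int) -> list[np.ndarray]:
        members = [f for f in occupied if merged[f] == eff]
        in_class = scored & np.isin(folds, members)
        if any(f == self_mirror_fold for f in members):
            # a class containing the self-mirror fold is one symmetric cell
            return [in_class]
        return [c for c in (in_class & (raw < half), in_class & (raw >= half)) if c.any()]

    def cell_sizes(eff: int) -> list[int]:
        return [int(c.sum()) for c in class_cells(eff)]

    while True:
        effective = sorted({merged[f] for f in occupied})
        if len(effective) == 1:
            break
        undersized = [e for e in effective if min(cell_sizes(e)) < min_bin_count]
        if not undersized:
            break
        # merge the emptiest undersized class into its nearest neighbour
        e = min(undersized, key=lambda e: (min(cell_sizes(e)), e))
        others = [o for o in effective if o != e]
        target = min(others, key=lambda o: (abs(o - e), -o))
        for f in occupied:
            if merged[f] == e:
                merged[f] = target

    unstd = out["unstandardized"].to_numpy(dtype=float)
    standardized = np.full_like(unstd, np.nan)
    bin_id = np.full(len(out), -1, dtype=int)
    for e in sorted({merged[f] for f in occupied}):
        for cell in class_cells(e):
            vals = unstd[cell]
            if vals.size < 2 or np.ptp(vals) == 0:
                raise GlycoscanError("degenerate frequency bin (sd = 0)")
            mu, sd = vals.mean(), vals.std(ddof=1)
            standardized[cell] = (vals - mu) / sd
            bin_id[cell] = int(raw[cell].min())
    out["bin_id"] = bin_id
    out["standardized"] = standardized
    out["abs_standardized"] = np.abs(standardized)
    return out


def ihs_scan(
    panel: HaplotypePanel,
    scheme: GroupScheme,
    group: str,
    params: IhsParams | None = None,
) -> SnpScoreTrack:
    """Full |iHS| track for one continental group.

    Runs EHH -> iHH -> ln-ratio -> within-bin standardization -> absolute
    value over the group's haplotypes; SNPs failing QC are missing with the
    reason in qc_flag.
    """
    params = params or IhsParams()
    rows = scheme.haplotype_rows(panel, group)
    if rows.size == 0:
        raise GlycoscanError(f"group {group!r} has zero samples")
    H = panel.haplotypes[rows]
    if (H == MISSING).any():
        raise GlycoscanError(f"missing genotypes in group {group}; iHS requires complete haplotypes")
    sub = HaplotypePanel(H, panel.snps, panel.samples.iloc[(rows[::2] // 2)])

    n = H.shape[0]
    d = H.sum(axis=0)
    freq = d / n
    m = panel.n_snps
    ihh_a = np.full(m, np.nan)
    ihh_d = np.full(m, np.nan)
    unstd = np.full(m, np.nan)
    qc = np.array([QC_OK] * m, dtype=object)
    for j in range(m):
        f = freq[j]
        if f < params.freq_min - 1e-12 or f > params.freq_max + 1e-12:
            qc[j] = QC_FREQ
            continue
        if min(d[j], n - d[j]) < params.min_carriers:
            qc[j] = QC_RARE
            continue
        edge = False
        integrals = {}
        for allele in ("ancestral", "derived"):
            left = ehh(sub, j, allele, "left", params.cutoff)
            right = ehh(sub, j, allele, "right", params.cutoff)
            if left.truncated_at_end or right.truncated_at_end:
                edge = True
            integrals[allele] = ihh(left, right, params.distance_mode)
        if edge and params.boundary == "exclude":
            qc[j] = QC_EDGE
            continue
        val = ihs_unstandardized(integrals["ancestral"], integrals["derived"])
        if np.isnan(val):
            qc[j] = QC_ZERO
            continue
        ihh_a[j], ihh_d[j] = integrals["ancestral"], integrals["derived"]
        unstd[j] = val

    results = pd.DataFrame(
        {
            "snp_id": panel.snps["snp_id"],
            "chromosome": panel.snps["chromosome"],
            "position_bp": panel.snps["position_bp"],
            "derived_freq": freq,
            "ihh_ancestral": ihh_a,
            "ihh_derived": ihh_d,
            "unstandardized": unstd,
            "qc_flag": qc,
        }
    )
    results = standardize_ihs(results, params.n_bins, params.min_bin_count, n_haplotypes=n)

    maf_global = panel.maf()
    maf_g = np.minimum(freq, 1 - freq)
    table = pd.DataFrame(
        {
            "snp_id": panel.snps["snp_id"],
            "chromosome": panel.snps["chromosome"],
            "position_bp": panel.snps["position_bp"],
            "value": results["abs_standardized"],
            "maf_global": maf_global,
            "maf_group": maf_g,
            "derived_freq_group": freq,
            "ihh_ancestral": results["ihh_ancestral"],
            "ihh_derived": results["ihh_derived"],
            "ihs": results["standardized"],
            "bin_id": results["bin_id"],
            "qc_flag": results["qc_flag"],
        }
    )
    return SnpScoreTrack("ABS_IHS", group, table)
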