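# Methods

This note documents the models, defaults and numerical choices behind each
pipeline stage, what the synthetic data generator does and does not emulate,
and the design decisions taken where the problem was genuinely open.

## Input model

The substrate of every statistic is a phased haplotype panel: an
(2·samples) × SNPs matrix of allele codes with 0 = ancestral, 1 = derived,
−1 = missing, plus SNP metadata (1-based positions, ancestral/derived
bases, optional genetic-map column) and a sample → population →
continental-group table. Coordinates are 1-based inclusive throughout; BED
input is converted at the boundary. Ancestral orientation comes from the
VCF `INFO/AA` tag and is required — the reader never infers it; sites whose
stated ancestral allele matches neither REF nor ALT are dropped and
counted. Unphased genotypes are an error (phasing and imputation are out of
scope; statistics use complete haplotypes, and iHS refuses panels with any
missingness in the analyzed group).

MAF filtering is two-level: a global ≥ 5% filter defines the shared SNP set,
and each per-group analysis additionally drops SNPs below 5% within that
group. The comparison runs on allele counts, so the boundary (e.g. 95 of
100 haplotypes derived) is exactly inclusive. Both thresholds are
configurable.

## F_ST

One continental group versus all remaining haplotypes pooled, per SNP, on
haploid counts. The default estimator is the Weir–Cockerham two-population
θ̂ written in mean-square form,

    MSP = n₁(p₁ − p̄)² + n₂(p₂ − p̄)²
    MSG = (n₁p₁q₁ + n₂p₂q₂) / (N − 2)
    n_c = N − (n₁² + n₂²)/N
    θ̂  = (MSP − MSG) / (MSP + (n_c − 1)·MSG)

with Nei's G_ST ((H_T − H_S)/H_T, sample-size-weighted H_S) and Hudson's
1 − H_w/H_b selectable. The original scan's software did not pin down a
formulation; the estimator switch exists to probe sensitivity, and the
downstream stages consume ranks, which are robust to the choice. Negative
estimates are clamped to 0 by default so empirical p-values are monotone in
differentiation; monomorphic sites and subsamples with n < 2 are missing.
Note the per-SNP mean of θ̂ is mildly downward-biased relative to the
simulation parameter (a ratio-of-means vs mean-of-ratios effect): a
Balding–Nichols panel at F = 0.15 yields mean θ̂ ≈ 0.13.

## EHH and iHS

EHH at a SNP x for a core allele is the probability that two random
distinct carrier chromosomes are identical over [core, x], computed by
grouping carriers on the spanned columns (Σ_h C(n_h,2)/C(n_c,2)); a
pairwise-homozygosity oracle in the test suite checks the grouped formula
to 1e-12. Curves are truncated at the first point with EHH < 0.05 (point
included); the cutoff is the conventional choice, configurable. iHH
integrates EHH against physical distance (bp) by the trapezoid rule on both
sides of the core; a genetic-map column switches integration to cM. SNPs
whose EHH has not decayed below the cutoff at a chromosome end are excluded
(`qc_flag = edge`), configurable to truncate-and-keep. SNPs with derived
frequency outside [0.05, 0.95] are not scored (unstable integrals).

The unstandardized score ln(iHH_A/iHH_D) is standardized to mean 0 / sd 1
(sd with one delta degree of freedom) within 20 equal-width derived-
frequency bins; bins whose SNP count falls below 10 are merged with their
nearest occupied neighbour. Two numerical details make |iHS| *exactly*
invariant under a global ancestral/derived relabeling, which the suite
asserts: bin boundaries are evaluated on integer allele counts with
left-closed intervals below frequency 0.5 and right-closed above (so
bin(1 − f) is always the mirror of bin(f), immune to the float asymmetry of
1 − f), and merging operates on folded (MAF) classes, so every
standardization cell is either one of a mirror pair or a mirror-symmetric
set. Frequencies exactly 0.5 form their own self-mirror class.

## Empirical p-values

Scores are ranked within bins of similar MAF: scored SNPs sorted by MAF
(ties by position, then SNP id) and chunked into consecutive bins of 10,000
SNPs at genome scale (synthetic runs scale the bin size via config); a
final remainder smaller than half the target merges into the previous bin.
The p-value is (#{strictly greater} + 1)/(n + 1) — the +1 correction bounds
p away from 0, which the downstream log transform requires, and preserves
ranking exactly; the literal "proportion greater" rule would hand the top
SNP p = 0. Binning is computed per group × statistic on the global MAF of
the track's SNPs (each track is its own genome context). On tracks with
continuous scores the resulting p is uniform under the null (asserted by
KS at the 1% level); F_ST tracks are tie-granular — allele counts are
discrete and clamping adds a point mass at zero — so their empirical p is
uniform only up to that granularity.

## Gene-level scores and significance

A gene region is all SNPs with tx_start − flank ≤ pos ≤ tx_end + flank,
bounds inclusive, flank 100 kb at genome scale. Fisher's combination
Z_F = −2 Σ ln pᵢ is referred to χ²(2k); genes with no scored SNP are
reported unscored, and genes sharing SNPs through overlapping flanks are
scored independently (no deduplication). The background catalog — disjoint
gene-centred regions built the same way — yields the calibration
distribution; ranking uses the χ² tail p rather than raw Z_F so regions
with different k are comparable. The rank p is
(#{background ≤ p} + 1)/(N_bg + 1); when the background is ranked against
itself (to count background "events" for the hypergeometric test) the
region's own value is left out. A cell is significant when its rank p ≤
α/(n_groups × n_methods), inclusive — 0.05/14 at the study's scale. The
Bonferroni-corrected χ² p (min(1, p × 14)) is reported alongside.

## Part comparison and centralities

A gene is an "event" for a statistic if significant in ≥ 1 group
(substrates-biosynthesis genes and explicitly excluded genes never enter
part tests — their products feed both parts). The χ² test is the
observed-vs-expected goodness of fit with expectations proportional to part
sizes, df = 1; this construction reproduces the published haplotype-scan
value (2.14) exactly from its printed counts, whereas the published
differentiation-scan companion (9.33) is not reproducible from its printed
counts under either this construction (8.33) or a 2×2 Pearson χ² (9.83) —
that value is therefore documented here and not used as a check. The
Mann–Whitney implementation uses midranks, the tie-corrected normal σ, and
signs Z from group 1's U, which reproduces the published sign pattern; the
rank test on part scores runs on per-gene Fisher Z by default. The
hypergeometric part test is exact (population = background ∪ part).

Centralities follow the reciprocal eccentricity/closeness conventions of
the plugin the original analysis used (a flag restores the classical
definitions); betweenness sums over unordered endpoint pairs, endpoints
excluded, unnormalized; centroid(v) = min_w [γ_v(w) − γ_w(v)] with the
census ranging over all vertices and distance ties counting for neither
node. All five are checked against definition-level brute force on graphs
up to 8 nodes. On disconnected graphs the distance-based centralities are
computed per component with a warning.

## Synthetic data

The generator emulates the study conditions of a continental SNP-array
panel: 7 labeled groups (HGDP-style names), 30 diploid samples per group,
5,000 biallelic SNPs uniformly placed on a 50 Mb chromosome, ancestral
frequencies uniform on [0.05, 0.95] (an array-ascertainment-like, flat MAF
spectrum), per-group frequencies from the Balding–Nichols Beta model with
Wright's F = 0.10, and LD induced by a Markov copying pass (each haplotype
copies group-mates along the chromosome, switching template at 10⁻⁶/bp).
The global 5% MAF floor is enforced by redrawing violating columns; the
copying template paths are column-independent, so redraws leave the rest
of the panel untouched. RNG streams are split per stage, so toggling the
sweep does not perturb the neutral background, and everything is
bit-reproducible from (seed, config).

The sweep is constructed, not forward-simulated: a target fraction (0.6) of
haplotypes receives the derived core allele and is rebuilt as mosaics of
one founder with exponential recombination escapes (5 × 10⁻⁸/bp) within
±100 kb of the core. Ground truth — carrier set and decay rate — is
therefore exact and assertable; the trade-off is that the sweep spans all
groups and carries no allele-frequency trajectory. Not emulated: demographic
history (bottlenecks, migration, expansions), recombination-map
heterogeneity, array ascertainment against an out-group, genotyping error.
Passing tests therefore demonstrate correctness of the statistics and
calibration under a clean structured model, not robustness to demography.

The pathway fixture tiles 56 genes (25 upstream / 21 downstream / 10
substrates, the part sizes of the pathway under study) and 500 background
regions in disjoint slots, builds a connected chain-plus-branches graph,
and uses a 15 kb region flank scaled to the simulated SNP density (the
100 kb genome-scale flank stays the default for file-based runs). With 500
background regions the finest attainable rank p is 1/501, comfortably below
the 0.05/14 threshold.

## Problem sizes

The default synthetic study (7 × 30 diploids, 5,000 SNPs, 56 + 500 regions)
runs end to end in about a minute on one CPU. The test suite and the
acceptance script use reduced replicates of the same conditions — 2,000-SNP
panels for parameter recovery and the neutral tail, 800-SNP panels × 10
seeds for sweep power, and a 4-group, 1,500-SNP, 120-background null
pipeline for calibration — chosen as the smallest sizes at which the
statistical tolerances above are meaningful.

## Known limitations

* The per-SNP mean of clamped θ̂ is a biased estimator of Wright's F; the
  pipeline consumes ranks, so this does not affect calls.
* Fisher's combination assumes independent SNP p-values; tag-SNP panels
  approximate this, dense sequencing data would not. No LD-aware effective-k
  correction is applied.
* Empirical p-values inherit the granularity of their bin size; with fewer
  scored SNPs than one bin the whole track is a single genome context.
* The constructed sweep is panel-wide; group-specific sweeps require
  implanting on a group's haplotype rows externally.
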