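# Methods

## TFCR calling by kernel density estimation

TFBSs are reduced to their interval midpoints, `floor((start + end) / 2)`
(no convention for the anchor point of a motif hit is established in the
field; the midpoint is symmetric and stable under strand flips). The
density on a chromosome is the **unnormalised** Gaussian kernel sum

    f(x) = Σ_j exp(−(x − m_j)² / (2σ²)),      σ = 300 bp,

so that a single site at zero distance contributes exactly 1.0. This
choice is load-bearing: the contribution threshold of 0.1 then has an
absolute meaning (a site contributes to a peak iff it lies within
σ·√(2 ln 10) ≈ 643.8 bp), whereas a normalised density would make the
threshold depend on the number of sites. σ = 300 bp is the method's
single bandwidth-like constant; it sets the cluster scale (contribution
radius ≈ 644 bp) that separates "one element" from "two elements".

The density is evaluated on a 10-bp grid spanning
[min midpoint − 4σ, max midpoint + 4σ] per chromosome, with kernels
truncated beyond 4σ (per-site truncation error < 3.4e−4, far below the
0.1 threshold). Both the grid step and the truncation are configurable.
Every local maximum of the grid is one TFCR; runs of exactly equal values
(plateaus) collapse to their central grid point, while two equal-height
maxima separated by a strict dip remain distinct TFCRs. The test suite
verifies on random clustered layouts that grid peaks agree with an
exhaustive 1-bp evaluation to within one grid step and that the
contributing-site sets are identical.

The TFCR interval is the span of its contributing site intervals, not a
density level set: width then measures the physical extent of binding
sites, which is what the width–expression analyses intend. Grid
discretisation can land a peak a few bp outside the span of very narrow
site intervals; the stored peak position is clamped into the interval.

## Complexity, width, and derived scores

Complexity TC sums the kernel weights of contributing sites after
**family deduplication**: within a TF family, sites whose intervals form a
chain of mutual overlaps count once, keeping the chain's maximum weight.
Stacked redundant motifs of one family at one locus therefore do not
inflate TC, while same-family sites at separate loci count separately.
Axioms checked by tests: a lone site at its peak scores exactly 1.0;
adding an overlapping same-family site never changes TC; adding a
distinct-family site at the peak adds exactly 1.0.

TW is the interval width in bp; cw = TC / TW; CAS is the mean score of
ATAC peaks overlapping the TFCR by ≥ 1 bp (missing when nothing
overlaps — the accessibility score's original formulation is not restated
in the literature this package follows, so the transparent mean-of-
overlapping-peak-scores is used and documented here prominently).
TC deciles (TC0..TC9) are assigned within a sample by minimum rank, so
tied values always share a bin; deciles are deliberately not pooled
across stages because the stage comparisons are within-sample.

## Gene linking and distance classes

Distance is |TSS − peak| in bp, clamped to 0 when the TSS falls inside the
TFCR interval. The peak anchors the distance because complexity is
peak-anchored. Strand is ignored (no signed upstream/downstream
treatment). Nearest pairing runs in both directions — each TFCR to its
nearest gene(s) and each gene to its nearest TFCR(s) — with all
exact-distance ties retained; genes on TFCR-free chromosomes become
explicit `no_TFCR` records rather than silently vanishing.

The published cuts t1/t2/t3 = 2 kb / 27 kb / 50 kb are authoritative
defaults; boundary membership is R1 at d = t1, R2 at d = t2, R3 at d = t3,
R4 beyond. `derive_thresholds` exists as a reproducibility diagnostic: it
fits a Gaussian KDE (Scott bandwidth) to log10(distance + 1), locates its
local extrema on a uniform 512-point log grid, and reports t1 as the
valley between the first two modes, t2 as the second mode, and t3 as the
smaller of 50 kb and the 99th distance percentile. The 99 percentile
values of the distance set are returned as diagnostics. Extrema are
reported at their grid location rather than snapped to the nearest
percentile value: the valley between a promoter mode and a mid-range mode
is by construction sample-sparse, so the nearest observed percentile can
sit far up the second mode and would misstate the cut by several kb.
A unimodal density or fewer than 100 positive distances falls back to the
defaults (flagged by `provenance`).

## Association statistics

Expression enters every analysis as log10(FPKM + 1). Correlations are
Spearman with mid-ranks for ties; p-values use the t approximation above
n = 10 and exact permutation enumeration at n ≤ 10 (the full n! set,
cached per n). A constant vector yields an explicitly flagged undefined
result, never rho = 0. The saturating law y = a·log10(x + c) + b is fit
by least squares with c = 0.03 by default; with `estimate_offset` the
offset is profiled by a bounded 1-D search on log10(c) over [1e−4, 1].
Note that when x is bounded away from zero — as called complexities are,
since any called TFCR has at least one near-unit contribution — the
profile over c is nearly flat and the offset is weakly identified; the
end-to-end test therefore checks that the planted offset is *not
rejected* (profile R² within 0.01 of the maximum) rather than demanding a
tight point estimate, while offset recovery at spec conditions (x spanning
zero, σ = 0.05, n = 500) is tested directly.

Gene groups by correlation use the deterministic |cor| > 0.5 rule
(TC / TW / TC&TW / nTC&TW, strict inequality on absolute values); k-means
on the correlation pairs is available as a seeded diagnostic only, since
a centroid method's group boundaries are initialisation-dependent.
Group differences use Welch's unequal-variance t-test with the
significance ladder * p<0.05, ** p<0.01, *** p<0.001, **** p<0.0001.
The top-n (default 200) TFCRs by cw break ties by TC then id, and the
"sampling-n" control is a seeded uniform draw from the remainder,
disjoint from the top set by construction.

## Cross-stage dynamics

Stages are called independently; identity across stages is positional:
two TFCRs are the same element when their intervals overlap by at least
1 bp ("more than 1 bp" is read as ≥ 1 bp of genuine overlap — a strict
> 1 reading would drop single-base overlaps arbitrarily; the threshold is
configurable). Gained at stage s means no partner in stage s−1; lost
means no partner in stage s+1; gained is undefined (empty) at the first
stage and lost at the last. Stage-stable regions are the sequential
intersection of the per-stage interval-set unions — an order-invariant
operation — with each surviving fragment annotated by the overlapping
TFCR ids of every stage. Long-range links histogram into 50–100k,
100–150k, 150–200k and >200k distance bins.

Trajectories are **gene-anchored**: a gene's value per stage is the TC of
its nearest TFCR there (maximum TC on exact-distance ties), because rows
must be alignable across stages and TFCR ids are not. Genes missing a
TFCR in any stage, or with a constant trajectory (undefined shape after
standardisation), are excluded and logged. Rows are z-standardised and
clustered by fuzzy c-means with c = 6 and fuzzifier m = 2.0 — c mirrors
the six-trajectory-cluster presentation of the developmental series, and
a fixed m keeps the procedure deterministic where data-estimated
fuzzifiers would not be. Memberships initialise from a seeded Dirichlet
draw; the objective Σ u^m d² is asserted non-increasing at every
iteration and iteration stops when the maximum center shift falls below
1e−6 (at most 300 iterations). A point coinciding with a center receives
full membership there (the limit of the update rule).

## Spatial context

TAD membership is by point containment in half-open domains: the TFCR by
its peak (a region straddling a boundary belongs to its peak's domain —
deterministic, and consistent with the peak-anchored distance
convention), the gene by its TSS; a point exactly at a domain end belongs
to the next domain. Overlapping TADs within one sample are rejected with
the offending pairs listed. PSTF annotation matches upper-cased TF names
between the LLPS-derived list and the contributing sites' TF names
(aliasing beyond case is out of scope; unmatched names are logged);
counts are over distinct TF names and the percentage denominator is the
number of distinct TFs on the TFCR.

## Synthetic data: what it emulates and what it does not

The generator plants one TFBS cluster per gene. Defaults (the study
conditions of the test suite and the acceptance script): 500 genes on 4
chromosomes, TSSs on a 750-kb lattice with ±50 kb jitter — wide enough
that a cluster is always nearest to its own gene; the TSS distance drawn
from 0.45·|N(500, 300)| + 0.35·N(27 kb, 8 kb; truncated > 2 kb) +
0.20·U(50 001, 300 000), reproducing the promoter mode, mid-range mode,
2-kb valley and long-range tail that the threshold derivation must
recover; 3 + Poisson(3) distinct TF families per cluster, one site each
scattered N(center, 150 bp), with a 25% chance per family of a second,
overlapping same-family site (family-dedup fodder); 35% of clusters
PSTF-flagged, receiving 2 extra families from a dedicated PSTF-family
pool (the planted complexity/expression shift); expression
log10(FPKM + 1) = 1.5·log10(TC_true + 0.03) + 0.2 + N(0, 0.15), clipped
at 0; one ATAC peak per cluster (±400 bp, score ≈ 2 per family ± 1);
800-kb tiling TADs. The five-stage panel shares genes and cluster centers
across stages; ZGA-flagged genes (30%) carry 1 family before the
activation stage (index 2), 9 at it, decaying 7, 5 after — a trajectory
whose standardised profile peaks unambiguously at activation; expression
is independent noise ("maternal transcripts") at every pre-activation
stage and follows the complexity law from activation onward; 8% of
clusters per stage are stage-specific transients placed in intergenic
deadzones to create gained/lost turnover.

What passing tests on this generator do **not** show about real data: no
sequence or PWM scanning (sites are placed directly, the FIMO-dialect
writer only keeps the I/O path honest), exactly one planted cluster per
gene (real regulatory landscapes have many-to-many structure), no
read-level noise, no overlapping or nested regulatory elements, TADs as
exact non-overlapping tiles, and independent site placement within a
cluster. Recovery rates near 100% here bound implementation correctness,
not biological performance.

## Problem sizes and numerical choices

The default test and acceptance problem sizes — 500 genes (≈ 4 300 sites)
for the single-stage bundle, 400 genes × 5 stages for the panel — were
chosen as the smallest sizes at which every planted-recovery property is
stable across seeds (center recovery ≥ 95%, truth correlation ≥ 0.9,
region accuracy ≥ 90%, derived t1 ∈ [1, 5] kb and t2 ∈ [20, 35] kb,
activation-cluster capture ≥ 90%).

Degenerate inputs are handled explicitly rather than silently: empty
TFBS input yields no tracks; zero-contribution density plateaus are
discarded; constant vectors flag correlations as undefined; zero variance
in both Welch groups with equal means gives p = 1; a gene set smaller
than the bin count raises. All randomness (control sampling, k-means,
fuzzy c-means, the generator) flows from explicit seeds, and all writers
use fixed 6-decimal formatting with sorted keys, so identical configs
give byte-identical outputs.
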