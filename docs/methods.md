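# Methods

## Data model

All analysis operates on cell tables: one row per segmented bacterium
with an image identifier, continuous µm coordinates in the image-local
frame (origin at the FoV corner), and an integer taxon id. Coordinates
are validated against the FoV extent (default 135 × 135 µm) and taxon
ids against the probe panel. No geometry is ever computed across images:
each FoV is an independent observation window, and the FoV is the
replication unit of every statistical test. Taxon names may carry
cluster notation ("A | B"); the integer id is the analysis key. Cells
carrying a pan-bacterial catch-all label (a mixture of unprobed taxa)
are kept in totals and load counts but can be excluded from
taxon-specific scores (`include_catchall=False`), since taxon-level
statistics are not meaningful for a mixed bucket.

## Tier 1: image-level diversity

Shannon entropy uses the natural log (an even two-taxon split scores
ln 2 ≈ 0.693); the base is configurable. Simpson is the Gini–Simpson
form 1 − Σpᵢ². Empty images keep richness 0 with missing entropy values.
Beta diversity "to the control group" is computed as all cross-pairs
between each treatment image and each control image within the same
tissue × day; the control group's own cross-pairs measure within-group
dispersion. Bray–Curtis is computed on raw counts at this tier (FoV area
is constant, so counts are comparable). Group comparisons use the
two-sample Wilcoxon rank-sum test per treatment pair with Holm
adjustment within each tissue × day family (Benjamini–Hochberg is
available); ordination of image counts uses log(count + 1) — the
pseudocount is a package decision.

## Tier 2: pairwise colocalization

Pairs are counted as **ordered** pairs of distinct cells with centroid
distance ≤ r (closed ball, r = 5 µm default). Ordered counting makes the
independence expectation exactly P(A)·P(B), so the score

    CS = P(AB) / (P(A) P(B))

needs no factor-of-2 correction for heterospecific pairs; CS(A,B) =
CS(B,A) and results are reported on unordered pairs. P(AB) is the
proportion of ordered neighbor pairs of type (A,B) among **all ordered
neighbor pairs in the image** — this denominator gives CS = 1 under
random labeling; an `all_pairs` mode (dividing by n(n−1)) exists for
sensitivity analysis. Division guards return missing scores, never
infinities. Cell size and shape are ignored (centroid analysis), and no
edge correction is applied at r = 5 µm in a 135 µm window (the perimeter
bias is ≤ ~4 %).

Treatment-vs-control comparisons: per (tissue, day, treatment, pair),
Kruskal–Wallis over per-image scores against the control group, BH
adjustment within each (tissue, day, treatment) family. Effect size is
the eta-squared-for-H form (H − k + 1)/(n − k), computed only for pairs
with adjusted p < 0.1 and labelled "large" at ≥ 0.14. The "significant"
count uses adjusted p < 0.05; both thresholds are configurable (the two
thresholds intentionally differ: effect sizes are reported for a wider
set than the significance tally). log2 fold changes use group means of
per-image CS; a zero group mean is replaced by the smallest positive
float and **flagged**, and flagged rows are excluded from heatmap and
network export (their fold change is undefined, not huge).

The heatmap filter retains a pair iff both taxa pass the study-wide
abundance filter (total count ≥ 2,000 **and** prevalence ≥ 25 % of
images), |log2FC| > 1 in at least one stratum, and the pair is
significant in at least one stratum. Networks are undirected edge lists
per (tissue, treatment) at the recovery day: weight |log2FC|, sign the
direction of change, self-pairs removed.

## Mark equality function kf(r)

kf(r) is the conditional probability that two cells at distance r carry
the same label, normalized by the random-labeling expectation. The
estimator is a kernel-weighted pair ratio with:

- **Epanechnikov kernel**, bandwidth by the Stoyan rule
  h = 0.15/√λ with λ the overall intensity (both configurable);
- **translation edge correction** (weights A/((W−|dx|)(H−|dy|))), since
  10 µm is not negligible against a 135 µm window; a `none` mode exists
  for oracle tests;
- **without-replacement normalization** E_rand = Σnᵢ(nᵢ−1)/(n(n−1)),
  exact for a finite image (the Σpᵢ² form is biased upward by O(1/n)).

A single-mark pattern gives kf ≡ 1 exactly. Grid points with no pair
support inside the kernel window return missing values with an
`n_pairs_per_bin` diagnostic. Curves are estimated per image and then
averaged within groups (per-image-then-average keeps the image as the
replication unit); group means carry pointwise bootstrap CIs over
images, and a single-image group's CI collapses to its curve.

## Tier 3: neighborhood analysis

For each image and center taxon y, neighbor counts within r of every
cell of y are pooled into one composition row (the center cell never
counts itself; conspecific neighbors are included by default, a flag
excludes them). The neighborhood score N_yx = xy_c/(x_p·ny_c) compares
the observed share of x among y's neighbors with x's image-level
proportion.

PERMANOVA is one-factor on Bray–Curtis distances between per-image
composition rows (proportions by default; raw counts and scores are
options). The pseudo-F uses the distance-based sum-of-squares partition
(total SS = mean squared distance over pairs; within SS per group).
p = (b + 1)/(n_perm + 1) over label permutations (999 default); when the
number of distinct label arrangements is at most n_perm the p-value is
computed by exhaustive enumeration instead (exact, identity included).
Coefficients are differences of group means per neighbor taxon — the
classic multivariate-linear-model convention — and the top driver is the
taxon with the largest |coefficient|. Rows are per image (neighborhoods
of a center taxon pooled within an image), matching the FoV replication
unit; per-cell rows are available by constructing the matrix per cell.
Significance listing uses p < 0.1 by convention for the
supplementary-style tables.

NMDS uses nonmetric MDS on precomputed Bray–Curtis with Kruskal stress-1;
species vectors are correlations of each taxon's values with the two
axes. UMAP uses 10 neighbors and is deterministic under the seed.

## Keystone / foundation screen

Neighborhood richness: for every cell in baseline images, the number of
unique taxa among its ≤ 5 µm neighbors (center excluded, conspecifics
counted as one species; a flag excludes them). Summaries are per center
taxon × tissue (mean over cells) with the log mean per-image baseline
abundance.

Recovery: for every (baseline image i, recovery image j) cross-pair in a
tissue × treatment stratum, y = 1 − Bray–Curtis(i, j) **on proportions**
— recovery measures compositional return, not load (cross-day load
differences would otherwise dominate); a raw-count mode exists. All
cross-pairs are pooled, including cross-mouse pairs. For each taxon,
Pearson r between its baseline relative abundance (x, the i side) and y
over all pairs; zero-variance taxa are flagged. In the unperturbed
control group the same quantity measures stability.

The richness–recovery trend is the Pearson correlation across taxa
between mean richness and the recovery coefficient, restricted to
significant recovery correlations (p < 0.05, configurable).

Calls: percentile ranks across taxa (mean rank for ties). Keystone:
richness ≥ 75th, abundance ≤ 80th ("bottom 80th percentile" is read as
*not in the top 20 %*), correlation ≥ 75th. Foundation: abundance ≥ 80th
and richness ≥ 75th. All thresholds configurable. Degenerate screens
(no variation on an axis) yield no calls and a flag. The screen
reproduces a selection procedure, not a biological proof of keystoneness.

## Synthetic study generator

The generator emulates the statistical structure of a multiplexed-FISH
antibiotic-recovery study so every stage can be tested against known
ground truth:

- **Design**: tissue × treatment × day × mouse × FoV; the full default is
  2 tissues × 3 treatments × 3 days (−8, 0, 35) × 3 mice × 12 FoV = 648
  images of 135 × 135 µm.
- **Abundances**: ~60 taxa with log-normal (σ = 1.5) relative
  abundances, ~1,500 cells per FoV; per-mouse log-normal jitter
  (σ = 0.3 default) models cage effects — this scale is a free
  parameter, documented rather than calibrated; per-FoV log-normal
  intensity jitter (σ = 0.15, mean-one).
- **Conspecific clustering**: Thomas-type parent/offspring placement
  (offspring mean 5, Gaussian σ = 1.5 µm), motivated by daughters
  staying near mothers after division; `offspring_mean ≤ 1` degenerates
  exactly to a homogeneous Poisson process. Parent intensity is derived
  from the taxon's expected count divided by the offspring mean so that
  abundance remains the primary dial under perturbation multipliers; an
  explicit parent rate can override this. Out-of-window offspring are
  redrawn (conditional simulation), keeping intensities exact.
- **Microhabitat hotspots**: a few dense mixed discs per image
  (digesta-like regions) occupied with taxon-specific affinity. This is
  what makes a taxon's neighborhoods rich: conspecific clumping alone
  can only *add* the conspecific mark and therefore cannot create
  low-richness taxa. Off by default (the neutral configuration is
  exactly CSR per taxon).
- **Interactions**: a planted pair (A, B) with strength φ relocates a
  fraction |φ−1|/max(φ,1) of B's cells into (φ > 1) or out of (φ < 1) a
  ρ-disc around A cells — relocation rather than a Gibbs model, so the
  link between φ and CS is monotone and the ground truth tractable.
  Interactions can be knocked out by a treatment from day 0 on.
- **Perturbation and recovery**: treatment × day survival multipliers
  knock taxa down at day 0 with one-to-two bloom taxa (> 95 % of cells
  under the vancomycin-like default). At the recovery day the load is
  restored and the composition is a mixture w·(own baseline) +
  (1−w)·(residual), where the residual blends the perturbed state with a
  **driver-enriched rebuild state** (the global baseline with driver
  taxa boosted; the keystone's boost is disproportionate to its
  abundance — that is precisely the keystone concept). The mixing weight
  w increases with the mouse's baseline driver abundance, so mice
  starting with more of the drivers recover closer to their baseline.
  Both channels matter: w carries the per-mouse recovery story, while
  the rebuild state makes baselines already rich in drivers more similar
  to recovered samples — the channel that a pooled cross-pair
  correlation can actually detect.
- **Determinism**: all randomness flows from one seed through
  `SeedSequence` keys (tissue, treatment, day, mouse, FoV); any image is
  regenerable independently and a study is byte-identical under a seed.

What the generator does **not** emulate: cell size and shape,
segmentation and classification errors, spectral bleed-through,
within-image intensity gradients beyond hotspots, true Gibbs-type
interactions, or temporal autocorrelation beyond the three modeled days.
Passing tests therefore demonstrate correctness of the estimators and
recoverability of planted structure, not robustness to imaging
artifacts.

## Problem sizes and numerical choices

Tests and the acceptance script run a scaled study — one tissue,
water + ampicillin, days −8/35, 6 mice × 6 FoV (36 images per group, the
per-group image count of the full design), 12 taxa, ~600 cells per FoV —
chosen so the whole suite completes in minutes while every planted
effect (attraction knockout, hotspot hubs, keystone-driven recovery)
remains recoverable. With only ~12 taxa the richness–recovery trend is
estimated over few points, so its significance is marginal at some
seeds even though its sign is stable; the keystone *call* (a percentile
rank) is robust.

Other numerical choices: KD-tree (scipy cKDTree) neighbor queries with
closed-ball semantics everywhere, verified exactly against O(n²) scans;
Kruskal–Wallis with tie correction (identical constant groups short-
circuit to p = 1); exhaustive PERMANOVA enumeration via multiset
permutations when feasible; percentile ranks with mean-rank ties;
permutation p-values always of the (b+1)/(m+1) form, never zero.

## Limitations

- The colocalization score conditions on the realized neighbor-pair
  total per image; images with very few cells yield noisy or missing
  scores and are excluded pairwise, which can bias strata with heavy
  knockdown toward the surviving taxa (visible as smaller "tested"
  counts immediately post-treatment).
- No edge correction in pair counting (documented above); the mark
  equality estimator does correct edges, so the two tiers treat the
  window slightly differently, by design.
- PERMANOVA assumes exchangeability of images within groups; mouse-level
  pseudo-replication (12 FoV per mouse) is not modeled — a restricted
  permutation scheme would be the extension.
- The keystone screen is a selection procedure on three percentile axes;
  its calls inherit all noise of the recovery correlations, which pool
  cross-mouse pairs.
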