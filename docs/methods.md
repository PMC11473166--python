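# Methods

## The zone model

`rizmap` quantifies the concentric architecture that forms around necrotic
lesions in regenerating (dystrophic) muscle. The geometric model is defined
by the signed Euclidean distance `d` from each capture spot to the lesion
core boundary — negative inside the core, positive outside, boundary at
`d = 0`:

| zone | definition | biology | default panel |
|------|------------|---------|---------------|
| A | `d <= 0` | damage-clearing core (proinflammatory macrophages, Langhans giant cells) | *Ccl7*, *Ccl2*, *Il1rn* |
| B | `0 < d <= w_B` | barrier of resolution-related and growth-factor-expressing macrophages | *Mmp12*, *Nckap1l*, *Itgb2*, *Atf3* |
| C | `w_B < d <= w_C` | periphery of newly regenerating myofibers | *Myh3*, *Myog*, *Myl4* |
| none | `d > w_C` | unaffected tissue | — |

Defaults `w_B = 100 um` and `w_C = 440 um` follow the extents over which
zone-associated cells are observed inside (to -100 um) and outside (to
+440 um) the necrotic boundary; both are configurable. All intervals are
half-open on the outer edge, one convention across the package.

Distances are centroid-to-centroid Euclidean, not graph-geodesic: reported
micron distances from a tissue boundary are Euclidean in intent. The
boundary is implicit in the sign change between core and non-core spots; no
polygon is drawn. For a non-core spot, `d` is the distance to the nearest
core-spot centroid; for a core spot, minus the distance to the nearest
non-core centroid. Consequently `d` jumps by up to two lattice spacings
across the boundary (the reference set switches there); along the lattice it
is 1-Lipschitz on either side. Multi-lesion attribution is by nearest core
spot, ties toward the smaller lesion id.

## Observed zones from expression

Counts are normalized as `log(1 + c * M / total)` with `M` the median spot
total ("log-normalized" with median-total scaling). Zero-total spots are
dropped with a warning.

The module score of a gene set at a spot is the set's mean normalized
expression minus the mean of expression-matched controls: genes are ranked
by mean normalized expression, cut into `n_bins = 25` equal-count bins, and
each set gene draws up to `n_ctrl = 50` controls (seeded, without
replacement) from its own bin, excluding set genes. This is the standard
control-matched construction for gene-set activity; it centers on zero in
the absence of signal and is insensitive to per-spot depth.

A spot's observed zone is the argmax of its three zone scores, with
abstention: the call requires the top score to reach `tau` and to beat the
runner-up by `m`; sub-threshold spots and exact ties are `none`. Defaults
`tau = 0.8`, `m = 0.1`. The threshold was calibrated on the synthetic null:
with 3-4-gene panels at shallow counts (background mean ~2, dispersion 2)
the per-spot null max-score has a 95th percentile of ~0.85, while genuine
zone spots at an 8-fold contrast score ~1.5-2.0. `tau = 0.8` therefore
abstains on essentially all no-signal spots at ~95% sensitivity; a much
lower threshold would label noise spots with arbitrary zones and mask the
collapse of a zone whose signal has vanished. For deeply sequenced data or
larger panels the null tightens and `tau` can be lowered.

## Lesion detection

Candidate core spots have zone-A scores strictly above the
`threshold_quantile` of the score distribution; connected components under
lattice adjacency (hex: 6 neighbors within 1.05x spacing; square: queen, 8
within 1.5x) with at least `min_core_spots = 5` spots become lesions,
ordered by size then smallest spot id. The rule uses ranks only, so any
strictly monotone transform of the scores yields identical lesions. Lesion
area is core size times the tile area ((sqrt(3)/2) s^2 hex, s^2 square).

The default quantile 0.90 suits sections where lesions occupy up to ~10% of
spots, as in severely dystrophic tissue. The quantile should be matched to
the expected lesion burden: recovery experiments with a single planted
r = 300 um lesion (~2% of spots) use 0.96; leaving 10% of spots as
candidates there produces spurious small components from score noise.
Expression-based detection substitutes for histological annotation; a
user-supplied core spot list (`lesions_from_spots`, CLI `--cores`)
reproduces annotation-driven analysis exactly.

Spots within `w_C` of the lattice bounding box are flagged `edge`; their
annuli may be clipped by the section border. They are included in agreement
denominators by default (`exclude_edge` switches them off).

## The obs/exp agreement ratio

For spots with expected zone in {A, B, C} (expected `none` excluded from
every denominator), the per-zone ratio is `n_match / n_expected`; the
overall ratio pools matches and denominators, and equals the
expected-count-weighted mean of the per-zone ratios. An observed `none`
counts as a mismatch (conservative). A zone with no expected spots reports
a missing ratio, never 0/0. Significance comes from permuting observed
labels among the scored spots (`p = (1 + #{null >= obs}) / (n_perm + 1)`,
default `n_perm = 1000`).

Two runs with identical widths are compared by per-zone ratio differences;
zone `z` is flagged **collapsed** when its ratio falls to <= 0.05 in the
perturbed run from >= 0.5 in the reference — the glucocorticoid phenotype
for zone C.

## Collapse correlation, radial profiles, proximity

**Cross-zone correlation.** Pairwise Spearman correlation of panel markers
over spots (mid-ranked ties; constant genes reported missing). The summary
is the mean over gene pairs from different zones: near zero or negative
when territories are disjoint, elevated when they intermix. The two-
condition test permutes condition labels over pooled spots and recomputes
the difference of means (one-sided). Correlation uses all in-tissue spots
by default; a foci-only option restricts to expected-zone spots.

**Radial profiles.** Labeled cell points are binned by signed boundary
distance (default 50-um bins, -100 to +450 um, bins `(lo, hi]`; a point
exactly on the boundary falls in the innermost inside bin). Densities are
count/area with areas analytic for planted disk lesions (annulus bands) and
tile-count-based for detected lesions (points inherit the nearest spot's
distance). Out-of-range points go to an overflow bucket so counts are
conserved. Mean boundary distance per class uses points within +-500 um.

**Proximity.** The fraction of class-X cells whose nearest reference cell
(e.g. regenerating fiber) lies within `d_max = 20 um`, monotone in
`d_max`. Enrichment is tested against a competing class by relabeling the
pooled X + competitor positions; the competing class is required because the
null needs an exchangeable pool. Nearest-neighbor queries are exact
(KD-tree); instance sizes are desk-scale.

Permutation p-values are valid but conservative when the statistic is very
discrete (small point sets, tiny `d_max`); calibration experiments use
configurations with adequate granularity.

## Synthetic tissues

The generator emulates the study conditions: a 40x40 hex lattice at 100 um
spacing (regular triangular lattice, row pitch (sqrt(3)/2) x spacing —
close to, not identical to, the commercial array geometry); one disk lesion
of radius 300 um placed so the disk plus the full zone-C annulus fits
inside the section (rejection sampling, minimum center separation 1500 um
for multiple lesions); negative-binomial counts with mean/dispersion
parameterization `var = mu + mu^2 / theta` (the standard count-noise family
for spot data — no generative model is implied by the assay itself), with
`mu_high = 16` for a panel gene inside its own zone, `mu_low = 2`
elsewhere, `theta = 2`, and 200 background genes.

The `collapsed` condition operationalizes the glucocorticoid phenotype
qualitatively: zone-C panel genes drop to `mu_low` everywhere, and zone-A/B
panel genes intermix at mean `(mu_high + mu_low)/2` across the merged A+B
territory. The cell layer is a per-zone homogeneous Poisson process
(implemented by thinning a bounding-box process, which is exact); default
intensities put CCL2+ cells in the core, MMP12+ in the barrier and eMyHC+
fibers in the periphery, with the fibers lost and A/B classes mixed under
collapse. The 8-fold expression contrast and the cell intensities are
simulator conventions — the real-data contrast between zones is not known —
so passing recovery tests demonstrates correctness of the estimators under
a plausible noise model, not performance on tissue. Real data additionally
carry irregular lesion shapes, cell-type mixtures within spots, batch
effects and segmentation errors, none of which are emulated.

All generation stages draw from independent seeded streams; identical
configurations reproduce bit-identical lattices, counts and points.

## Numerical choices and degenerate inputs

- Distance ties (nearest core spot, nearest lesion) break toward the
  smaller lesion id at 1e-9 um tolerance; gene-rank ties in binning are
  ordinal (stable), making scores deterministic under a fixed seed.
- A core covering every spot has no boundary and raises a degenerate-
  geometry error rather than returning a sentinel.
- Empty marker sets after symbol matching raise an error naming the
  symbols; partially matched sets warn and proceed.
- An all-zero count matrix is an error; zero-total spots are dropped.
- Infeasible lesion placement (bounding box or separation) raises after a
  bounded retry budget, naming the violated constraint.
- JSON reports use sorted keys and full-precision floats; positions CSVs
  are written with `%.17g` and read with round-trip parsing, so pipelines
  re-run byte-identically.

## Problem sizes

Recovery and calibration experiments run on 40x40 lattices (1600 spots, 210
genes) with 20 replicate seeds, 200-run null calibrations and 199-999
permutations — sizes chosen so the full suite and the acceptance script
each complete in well under a minute on one CPU while keeping binomial
check margins wide.

## Known limitations

- Expression-based core detection needs a zone-A contrast well above the
  score noise; very small or weak lesions fall below `min_core_spots` or
  fragment. The explicit core-list path covers annotated data.
- The obs/exp ratio treats spots as independent; no mixed-effects
  structure across lesions, sections or animals is modeled (per-lesion
  stratification is available via the lesion id channel).
- Zone widths are global constants; real zones vary with lesion size and
  section angle.
- Whole-transcriptome matrices are densified during normalization;
  desk-scale (<= ~10^4 spots x ~10^4 genes) is the intended regime.
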