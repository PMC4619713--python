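# Methods

`benthoscape` implements the statistical machinery of a shelf-habitat
baseline survey — spatially balanced site selection, acoustic substrate
classification, and design-based estimation — and exercises it end to end on
synthetic seascapes whose truth is known. This note records the models, the
parameters that matter, the numerical choices, and what the synthetic
experiments do and do not demonstrate.

## Spatially balanced sampling (GRTS)

A finite frame of units (cells or candidate site centres) with relative
inclusion intensities π_i is sampled by hierarchical randomization: the
frame extent is recursively split into quadrants to a depth of
`min(14, ⌈log₄ N⌉ + 4)` levels; at every node of the recursion the four
sub-quadrants are permuted independently at random; units are laid out on
the resulting base-4 address line occupying segments of length proportional
to π_i (rescaled so Σπ_i = n, with the standard certainty-unit loop when a
unit's scaled probability exceeds 1); a systematic sample with a uniform
random start and unit spacing selects exactly n units. This construction
gives every unit first-order inclusion probability exactly equal to its
normalized π_i, verified empirically over 2000 replicate draws in the test
suite. Co-located units are separated by a seeded jitter of 10⁻⁶ of the
extent so that address leaves are unique and ties are reproducible.

**Master-sample prefix ordering.** The selected sites are re-ordered so that
any prefix of the ordered list is itself spatially balanced, which lets a
field campaign grow or shrink in increments without redrawing the design.
We order selection ranks by the golden-ratio (Kronecker) low-discrepancy
sequence, frac((k+1)·φ), rather than by classic base-4 digit reversal:
digit reversal is only near-systematic when the prefix size divides a power
of 4, and for a 30-of-100 prefix its dyadic rank gaps (alternating g and
2g) inflate the Voronoi balance loss to about 1.6× that of a direct 30-site
draw, while the golden-ratio ordering — whose prefixes take ranks with at
most three distinct gap lengths, by the three-distance theorem — keeps the
ratio near 1.2 for every prefix size. The measured comparison is in the
acceptance suite.

**Balance diagnostic.** Spatial balance is scored by the variance, across
selected sites, of the total normalized inclusion probability of the frame
units in each site's Voronoi cell (expected total 1 per cell); lower is
better, and a simple-random-sampling reference value is computed by internal
replication. Duplicate site coordinates are rejected rather than silently
jittered.

**One-dimensional GRTS** (image selection along a transect) uses the same
construction with binary segments to 16 levels of recursion; positions are
returned in prefix-balanced order. For n = 10 points every dyadic 1/8 cell
of the line holds at least one point, so the maximum gap is structurally
below 2.5× the average spacing (a 2× bound holds only in ~74% of draws —
the test asserts the provable bound).

## Design-based estimation

Substrate percentages use the Hájek (ratio) form of the Horvitz–Thompson
estimator, p̂_c = 100·Σ(y_ic/π_i)/Σ(1/π_i), where y_ic is the proportion of
class c in site i's standardized 0.04 km² footprint and π_i the adjusted
inclusion probability (π_design × n_realized/n_planned, clamped to (0,1]).
The ratio form is used because the realized site count is random after the
adjustment and because it forces the three class estimates to sum to
exactly 100. Biota totals are the same ratio estimator on site-level mean
covers, scaled by the frame area in km².

**Local neighborhood variance.** The variance of the estimated total of the
residuals t_j = (y_j − p̂)/π_j is

V̂ = c · Σ_i Σ_{j∈D(i)} w_ij (t_j − Σ_k w_ik t_k)²,

where D(i) is site i plus its 4 nearest sampled neighbours (symmetrized so
j ∈ D(i) ⇒ i ∈ D(j)), w are inverse-distance initial weights (self-distance
taken as the nearest-neighbour distance) balanced by Sinkhorn iteration
until rows and columns both sum to 1 within 10⁻⁶ (rows exact), and
c = n/(n − Σ_ij w_ij²) is a finite-neighborhood correction: each local
contrast loses a w_ij² share of the variance to its own neighborhood mean,
and c restores exact unbiasedness for the anticipated variance under an
exchangeable (spatially unstructured) population. Without c the estimator
is biased low by roughly 1 − Σw²/n ≈ 17% for 5-member neighborhoods. With
fewer than 4 sites the SRS variance formula is used with a logged warning.
Confidence intervals are normal-approximation, estimate ± 1.96·SE,
truncated to the domain ([0, 100] for percentages, ≥ 0 for areas); the
truncated-at-zero lower bounds in the output tables are intentional.

**Coverage behaviour.** On the default synthetic seascape (hard 5%, mixed
20%, soft 75%), 1000 replicate 40-site draws give empirical 95%-interval
coverage of about 95% for soft, 94% for mixed, and only ~86–90% for hard.
The hard-class shortfall is a property of the conditions, not of the
estimator: hard substrate is rare and strongly clustered, a few percent of
replicates sample no hard site at all (degenerate interval [0, 0]) and many
sample one or two, so the sampling distribution of p̂_hard is too skewed for
a symmetric normal interval — misses are almost entirely one-sided
(interval below the truth) while the variance estimator itself is close to
unbiased. This is a known small-sample limitation of normal intervals on
rare, spatially aggregated attributes and is left visible in the acceptance
suite rather than patched.

**Two-phase biota sampling.** Phase-II sites are drawn from the phase-I
sample with class-weighted intensities (default mixed/hard : soft = 3 : 1;
the weighting favours the reef systems where sessile biota concentrate);
the overall inclusion probability is the product π* = π₁ · π₂|₁, and a
census second phase reduces bit-identically to single-phase estimation.
Site-level cover is the unweighted mean over the site's 10 images (images
are themselves GRTS-balanced along the transects, so equal weights), and
image cover is points-hit/25 from 25-point annotations aggregated up a
CATAMI-style hierarchy (slash-path codes; level 4 = broad biological group;
child-level covers sum exactly to their parent's). Image-level subsampling
variance is not propagated into the totals' SEs: site means are treated as
observations. With 10 balanced images per site the within-site component is
small relative to between-site variability, but the totals' intervals are
accordingly slightly narrow.

## Substrate classification

**Rule-based (manual-mapping emulation).** Soft requires slope below
`soft_slope_max` and backscatter inside `soft_bs_band`; hard-candidate
cells must be raised within `hard_relief` above the local datum and exceed
`hard_bs_min`; candidates are grouped into 8-connected components and kept
hard only if the component covers at least `hard_min_area` (100 m²) and
contains a flank gradient inside `hard_gradient`; demoted components and
everything else are mixed. The local datum is the median depth in a moving
window (`relief_window`, default 25 cells), since "raised" is only
meaningful against a local reference; inside raised complexes wider than
the window the datum is partly self-contaminated, roughly halving observed
relief, which the derived thresholds account for. Field defaults describe
2 m-resolution multibeam (1° slope, −30..−25 dB soft band, 1–5 m relief,
5–15° gradients, > −25 dB, > 100 m²); `rule_thresholds_for()` derives the
analogous thresholds for a synthetic grid from its configured class
parameters (band edges at class-mean midpoints, relief band 0.4·rmin to
2.5·rmax, gradient unrestricted because a 1–3 m rise across a 50 m cell is
well under 5°, window 41 cells).

**ARC / p-hard.** A reference angular response curve is the pointwise mean
of curves from known-hard training cells (the canonical split in a
continuously mapped area: 100 training samples from a pool of 720, 620 held
out for validation). Each cell's curve is compared to the reference by a
Kolmogorov–Smirnov goodness of fit: both curves are shifted by their joint
minimum, normalized to unit mass over angle, D is the maximum gap between
the two cumulative curves, and p-hard is the asymptotic KS p-value with
effective size n/2 for n shared angle bins — 1 for identical curves,
monotonically decreasing in D. The conversion of a dB-vs-angle curve into a
distribution (joint-minimum shift + unit-mass normalization) and the
p-value convention are this package's concrete choices; they are isolated
in one function so an alternative construction can be swapped in. A curve
that is flat at the joint minimum has no mass and is rejected rather than
given an arbitrary value. Thresholds 10%/90% split p-hard into soft /
mixed / hard, with the mixed band closed on both ends. Sparse p-hard
observations are spread onto a grid by inverse-distance weighting (power 2,
all observations as neighbours — sites are small), exact at observed
points and bounded by the observed range.

## The synthetic seascape

The generator emulates the statistical structure such surveys face, not the
physics that produces it. Bathymetry is a linear across-shelf gradient
(default 40–160 m over 14 km) plus smooth Gaussian roughness (default sd
1.5 m, correlation ~4 cells). Reef geometry comes from a Gaussian random
field smoothed at `patch_scale_cells` (default 8 cells = 400 m): the top
`reef_fraction` quantile becomes hard cores, the band below it down to
`reef_fraction + mixed_fraction` becomes the mixed sand-veneer halo — the
banded thresholds produce the halo-around-core geometry while recovering
the configured class fractions exactly up to grid discreteness. Hard cores
are raised rank-uniformly across `reef_relief` (default 1–3 m, matching
low-profile shelf reef); the halo is raised up to 0.4·rmin. Defaults for
the class fractions (hard 5%, mixed 20%, soft 75%) mirror the sand-dominated
composition such shelves show.

Backscatter is drawn per cell from class-conditional normals (soft
−27.5 ± 0.8 dB inside the −30..−25 dB band, mixed −25 ± 1.0, hard
−22 ± 1.2) with no additional spatial correlation ("uniform spatial
structure"). The class distributions deliberately overlap — on a real
sand-inundated shelf the mixed class is acoustically ambiguous — so the
rule classifier on the default seascape is imperfect by design; tests that
assert ≥ 90% recovery use a separated configuration (class means several
sd apart, low depth noise) and score interior cells (1-cell boundary bands
excluded), which is what "well-separated" recovery means here.

Angular response curves are exponential-decay-plus-offset templates,
I(θ) = offset + amp·e^(−θ/scale) over 1°–60°, with per-cell white noise
(default sd 0.4 dB): hard (−20, 10, 45) sits higher and decays slower than
soft (−31, 8, 10) at every angle, with mixed (−24, 10, 40) in between. The
real functional family of seabed angular response is not modelled; these
are stand-in curves chosen so that the three classes are separable by the
KS construction at the default noise level (noiseless KS distances ≈ 0,
0.20, 0.50 against the 0.104/0.223 distances implied by the 90%/10%
p-value cuts). All curve parameters are exposed in the config.

Biota cover per group is zero-inflated: Bernoulli occupancy (class-
dependent; reef groups concentrate on mixed/hard) × Beta cover (mean per
group, concentration 5), with macroalgae forced to zero deeper than 50 m.
Realized group/class mean cover equals occupancy × mean cover, verified by
Monte-Carlo at ≥ 10⁵ cells.

All randomness descends from one root seed through five named substreams
(depth, reef, backscatter, arc, biota), so a fixed config reproduces every
layer bit-identically regardless of which layers are generated.

**What the synthetic experiments show.** They validate the survey
mathematics — inclusion probabilities, spatial balance, estimator algebra,
variance calibration, classifier logic — against known truth. They do not
validate acoustic physics, the realism of the ARC family, positional error
between acoustic and imagery data, or annotation error, all of which affect
real surveys and none of which are modelled.

## Accuracy assessment

Error matrices are oriented rows = predicted, columns = truth (both axes
labelled in every output, since the convention is not universal). Overall
accuracy is trace/total; producer's accuracy is per-class recall against
the truth column, user's accuracy per-class precision along the prediction
row; ratios with an empty margin are reported missing (NaN), never 0.
Cohen's κ = (p_o − p_e)/(1 − p_e) with the usual margins-product chance
term; undefined (NaN) when p_e = 1. Interpretation bands are half-open:
[0, 0.20) poor, [0.20, 0.40) fair, [0.40, 0.60) moderate, [0.60, 0.80)
good, [0.80, 1] very good, negative κ "worse than chance".

## Route planning

Field routes over nested prefixes are open paths from a supplied start
point (vessels transit from an anchorage; no return leg). Instances of ≤ 9
sites are solved exactly by Held–Karp dynamic programming; larger ones by
nearest-neighbour construction (distance ties broken by lowest unit id)
followed by 2-opt reversals and single-node relocation until no improving
move remains. Route lengths are Euclidean on plane coordinates, reported
in km; site sets nest across increments, the routes themselves are
recomputed per increment.

## Problem sizes used in the shipped experiments

The demonstration run uses a 280×280 grid of 50 m cells (14×14 km, 196 km²),
0.04 km² sites (4×4-cell blocks, matching the standardized swath area), a
100-site master sample with 40 realized sites, routes at increments
30, 35, …, 100, and 11 phase-II biota sites × 10 images × 25 points. The
replicated coverage/unbiasedness experiment draws 1000 direct 40-site
samples from the 4900-block frame of that seascape; balance comparisons use
200 paired draws on a 2500-unit uniform frame. The full test suite runs in
well under a minute on one CPU; the acceptance script in under a minute.

## Known limitations

- Normal-z intervals undercover for rare clustered classes at n = 40 (see
  coverage behaviour above); a practitioner wanting calibrated intervals
  for a ~5% class needs either more sites or a non-normal interval form.
- The KS formulation treats an angular curve as a distribution over angle;
  absolute backscatter level enters only through the joint-minimum shift,
  so two curves differing by a constant offset but sharing shape after
  normalization can look alike. The backscatter-band rules complement this.
- The CATAMI table shipped is a small stand-in hierarchy, editable but not
  the official scheme.
- No geostatistical small-area estimation, no temporal/rotating-panel
  designs, no sonar physics, no georeferencing beyond plane metres.
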