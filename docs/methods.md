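# Methods

This note documents the models, numerical conventions, and design
choices behind `topouptake`, and what the synthetic phantoms do and do
not establish about real data.

## Intensity functions and preprocessing

An image is a 3D array of nonnegative intensities proportional to
radiotracer activity, indexed (i, j, k), 0-based, values at voxel
centers. Preprocessing applies, in order:

1. **Decay correction** — multiplication by e^{(ln 2/τ½)·t}, t hours
   post-injection, τ½ = 67.32 h (In-111) by default. Removes physical
   decay so intensities compare across hours.
2. **Gaussian smoothing** — separable convolution with a Gaussian
   sampled at integer offsets in a 3×3×3 box, σ = 0.69, normalized to
   unit sum, zero padding at array borders. The 1D weights are
   ≈ (0.2058, 0.5883, 0.2058). Minimal smoothing suppresses single-voxel
   noise maxima; it also makes exact value ties vanishingly unlikely on
   noisy data, which the tree construction relies on for genericity.
3. **ROI masking** — f equals the smoothed image on the mask and is
   exactly zero off it. Smoothing is applied to the full array *before*
   masking, so ROI-boundary voxels are smoothed against their true
   neighborhood rather than against zeros. The original processing
   order is not documented anywhere we could find; this choice avoids
   ringing at the mask edge and is fixed here.

Negative or non-finite voxels are rejected at load time. All three steps
are linear, so they commute up to floating-point round-off; tests pin
this at 1e−12.

Two normalizations put subjects on comparable scales: **H24** divides a
subject's images by that subject's mean hour-24 ROI intensity (common
baseline for rate comparisons), and **heart** divides each image by its
own mean heart uptake (removes blood-clearance effects, isolating
binding). Both are positive scalar multiplications, so they commute with
the tree construction exactly; the pipeline builds one tree per image
and rescales its diagrams per normalization rather than re-sweeping.

## Merge trees

A voxel is a strict local maximum iff its value strictly exceeds all 26
neighbors of its 3×3×3 box (clipped at borders, no wraparound; off-ROI
values are 0). Plateau voxels are never maxima. Maxima are ranked
1..m by decreasing value, ties broken by flat voxel index.

The merge tree is built by a single union-find sweep over positive ROI
voxels in decreasing value order (ties again by flat index). Births and
deaths are reported at attained voxel values — the fine-filtration
limit — rather than on an interleaved grid of non-critical thresholds;
the two agree as the grid refines, and the limit removes an arbitrary
discretization choice. A voxel with no previously added neighbor founds
a leaf; for generic (distinct-valued) input these founders are exactly
the strict local maxima, and the test suite checks the equality on
every phantom. A voxel joining k ≥ 2 components resolves into k − 1
binary merges at the same value, absorbing components into the running
winner in decreasing label-maximum order; this preserves the
binary-tree invariant and has no effect on any birth/death value.

At a merge at value v: both active branches record childhood death
d′ = v; the branch whose label maximum is smaller records the elder
death d = v of that maximum (elder rule); a new internal branch is born
at v carrying the union of maxima and the larger label. The terminal
filtration value defaults to 0 (below every positive intensity), so the
global maximum's leaf has d = 0 and the final superlevel set is the
whole ROI. Internal branches inherit the elder death of their label's
maximum.

Degenerate inputs: an all-zero function is an error; a disconnected ROI
(possible when mask voxels carry zero intensity, or the mask itself is
disconnected — the mask validator warns) yields a forest with
`connected=False`, one root per component, every root finalized at the
terminal value. Exactly tied values are handled deterministically by the
total order but tie-dependent quantities (e.g. which plateau voxel
founds a component) are only meaningful for generic data.

Correctness is established against an independent brute-force oracle
that thresholds at every distinct value and flood-fills components
(scipy.ndimage.label), with exact multiset agreement of (b, d) and
(b, d′) pairs over hundreds of random arrays, including a
hypothesis-driven generic-input property test.

## Diagrams and segmentation

Persistence points use (b − d, (b + d)/2), childhood points
(b − d′, (b + d′)/2); the inverse map b = y + x/2, d = y − x/2 is exact.
Childhood diagrams contain leaves only by default; internal branches
also carry (b, d′) and can be included explicitly. All points are kept
regardless of lifetime — small b − d is signal here (low local
heterogeneity), not topological noise.

High/low segmentation is per image, *before* any pooling: a point is
high iff its maximum's value is at or above the q-th percentile
(default 95, with 80/85 supported) of the image's maximum values.
Percentiles interpolate linearly between order statistics and the
threshold is inclusive; the original convention is not recorded, so this
one is fixed and documented. Since segmentation ranks maxima within one
image, it is invariant under either normalization.

## Aggregate measures

%ID/g = (uptake/dose × 100)/(volume/1000) with uptake the summed
decay-corrected ROI intensity (µCi), dose in µCi, volume in mm³, tissue
density taken as water. Because region size cancels in mean-based form,
heart %ID/g can be computed from a heart-mean scalar alone. T:H is
tumor %ID/g over heart %ID/g per image. High/low region variants split
ROI voxels at the per-image 95th percentile of voxel values (same
inclusive convention); uptake and volume of the two regions recompose
to the whole ROI exactly. A constant ROI makes the split meaningless:
the high region is flagged empty and low = all. Measures are computed on
smoothed values by default, matching the input of the topological
branch; `roi_measures` accepts any intensity function, so unsmoothed
measurement is a caller choice. Heart normalization of intensity
functions (mean heart intensity) and the T:H denominator (heart %ID/g)
are deliberately distinct code paths, as they are distinct quantities.

## Statistics

- **Kruskal–Wallis** across hours (tie-corrected, χ² reference) screens
  whether a coordinate changes over the study period at all; only
  coordinates that the analysis configuration lists (H24: y; heart: x
  and y) proceed to trend comparisons.
- **Trend comparison** fits value ~ hour + set + hour:set by OLS and
  tests the interaction (the slope difference) two-sided on the pooled
  residual variance. This is the standard comparison-of-two-regression-
  lines; the exact variant used originally is not recorded. Exact fits
  (zero residual variance) are flagged degenerate with the slope
  difference still reported.
- p ≥ 0.05 is not significant, 0.01 ≤ p < 0.05 significant, p < 0.01
  highly significant; boundary values fall in the less-significant
  class since the defining inequalities are strict. No multiple-testing
  correction is applied; all raw p-values are reported.
- Points are pooled across subjects within a group and treated as
  independent. Within-subject correlation is knowingly ignored: a
  subject's anatomy contributes a constant offset per point track,
  which inflates the residual variance estimate (conservative for the
  slope test) but is not modeled. Mixed-effects modeling is out of
  scope.

Property (i) is read on the all-region between-group comparison (an
any-region readout is also reported, since either reading is
defensible); property (ii) per group on the within-group high-vs-low
comparison; property (iii) requires (ii) in exactly one group.

## Synthetic cohorts

The generator emulates the study design: 2 groups × 4 subjects ×
hours {3, 24, 48, 72} = 32 images, 100 µCi dose, 0.4 mm voxels.
Each phantom is an ellipsoid (24³ grid, semi-axes 9/8/7 voxels,
~2100 ROI voxels) with a vascularized outer shell (outer 30% of the
radius, +60% baseline), 30 Gaussian bumps (4 in the shell with
amplitudes 0.85–1.05 of baseline, 26 interior at 0.25–0.6; widths
0.9–1.4 voxels), multiplicative Gaussian noise with SD = 5% of local
intensity (reconstruction noise is proportional to counts), physical
In-111 decay on the emitted values, and a per-subject heart mean
following e^{−rate·t}. Subject anatomy (bump layout) is drawn once per
subject and reused across hours; noise and small per-hour amplitude
jitter (2%) come from per-acquisition streams. Everything is
deterministic given the seed via numpy SeedSequence spawn keys.

Planted time trends are **additive and uniform**: the whole ROI gains
baseline·slope·(t − 24). An additive uniform trend gives every diagram
coordinate the same expected slope, so "homogeneous uptake" coincides
exactly with the null of the absolute-slope trend comparison the
analysis performs; a multiplicative trend would make absolute slopes
scale with intensity level and manufacture spurious within-group
heterogeneity in the declining group. Heterogeneity is planted as extra
additive growth of the shell-bump amplitudes only.

Default effects: group 1 slope −0.004/h (targeting antibody: clearance
outpaces accumulation), group 2 slope +0.004/h with shell-bump growth
+0.04/h (control antibody: EPR-driven accumulation concentrated in the
vascularized periphery); heart clearance 0.020/h vs 0.016/h (the
targeting antibody clears ~25% faster). These effect sizes were chosen
so that the planted qualitative significance pattern is recovered in
well over 80% of seeded cohorts at this cohort size — the true effect
sizes of the motivating study are not publishable — and they are all
configuration-exposed.

What the phantoms do **not** emulate: SPECT projection/reconstruction
physics (noise is Gaussian-multiplicative, not reconstructed Poisson),
CT anatomy, non-ellipsoidal tumor shapes, necrotic cores, spatially
correlated noise, and subject motion. Passing the planted-effect tests
therefore shows that the pipeline detects effects of this structure and
size under these idealizations — not that it would attain the same
power on real reconstructions.

## Problem sizes and runtime choices

The default phantom (≈2100 ROI voxels, ~15–30 maxima after smoothing)
keeps a full 32-image cohort analysis under a second, which makes
100-cohort recovery studies routine. Statistical calibration checks use
1000 null replicates with ~50 points per set; the structural acceptance
checks use 100 random 5³ arrays against the brute-force oracle and 100
small (14³) phantoms. These sizes are the package's test defaults, not
limits of the implementation; the sweep is near-linear in ROI volume
after the sort.

## Known limitations

- The forest behavior for disconnected ROIs is an extension; the
  motivating analysis assumes a connected ROI.
- Exact ties are resolved by a fixed total order, not by symbolic
  perturbation or random jitter; adversarial tied inputs make founder
  selection depend on that order. Results are bit-reproducible, but
  tied inputs should be pre-jittered by the caller if the order policy
  is unwanted.
- Diagram distances (bottleneck/Wasserstein), persistence landscapes,
  and homology in dimension ≥ 1 are out of scope.
- NRRD input is not supported; images are NIfTI.
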