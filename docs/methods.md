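# Methods

## Scope and data model

The package consumes reconstructed tomograms — stacks of axial grayscale
slices with isotropic voxels (default 35 µm) — and produces aerated-lung
volumes, per-respiratory-phase volumes, pressure-volume summaries and the
statistics used to design and validate such experiments. Projection-domain
processing, tomographic reconstruction and its artifact corrections
(beam hardening, ring artifacts) are upstream and out of scope, as are
lung-function mechanics, histology scoring and biochemistry.

Axis convention: `voxels[z, y, x]`, z being slice-file order under
natural sort (`s2` before `s10`), 0-based. Stored 8/16-bit integers are
used as grayscale indices without rescaling, because the HU calibration
is defined directly on stored indices.

## HU calibration

A two-point affine map anchored on a scanned water/air phantom:
`HU(g) = 1000·(g − g_water)/(g_water − g_air)`. Both anchors map exactly
(the implementation divides before scaling so `g_air` lands on −1000.0 in
floating point, not −1000.0000000000001). The water grayscale depends on
scanner bit depth and reconstruction settings, so anchors are always
measured inputs, never hard-coded. Full-stack histograms use 1-HU
half-open bins `[h, h+1)` over [−1000, +1000] (last bin closed); voxels
outside the range are tallied in explicit under/overflow counters so the
histogram conserves the ROI voxel count.

## Respiratory gating

The thorax-marker displacement is smoothed by a centered moving average
(default window: 25% of the dominant period, estimated from the
periodogram) and cycle onsets are the smoothed local minima — the
displacement trough at end-expiration, which is also the initiation of
the next inspiration. Trough detection enforces a minimum spacing of half
the dominant period, which makes the cycle count robust to noise at the
few-percent-of-amplitude level. Partial cycles at the ends of the trace
are discarded (phase fraction is undefined there). The marker's sign
convention is hardware-dependent; an `invert` flag flips the trace.

A projection at phase fraction φ ∈ [0, 1) is assigned bin `⌊n·φ⌋` with
n = 4 bins of exactly equal phase width. Projections outside every
detected cycle are flagged with bin −1 and listed in the QC report, never
dropped silently. The binning is `valid` only when every bin holds ≥ 2
projections. Bin 0 volume is EIV, bin 3 volume is EEV; a consistency flag
is lowered when EIV < EEV.

A note on occupancy balance: projections uniformly spaced over complete
cycles balance the 4 bins within ±1 when the phase fractions are all
distinct (projection count coprime with the cycle count, or an integer
projections-per-cycle count). Commensurate spacings repeat phase
fractions and can widen the spread by the multiplicity (e.g. 36
projections over 10 unit cycles give occupancy 10, 8, 10, 8); this is a
property of uniform sampling, not of the binning rule.

## Segmentation

Stages, in order: (1) global air threshold, mask = HU ≤ threshold —
"exclude densities above the threshold" and "select below it" are adopted
as the single rule `≤`, the 1-HU boundary being sub-voxel-irrelevant;
(2) external-air isolation per axial slice: 2D air components
(8-connectivity) touching the slice border are kept, enclosed "pores"
removed — valid because the lungs are enclosed in every axial thorax
slice; (3) body ROI = complement of external air (animal + internal air +
bed); (4) per-slice erosion by a Chebyshev square of radius 10 px
(side 21), with pixels beyond the image border treated as background, so
the ROI also recedes from the image edge — equivalent to thresholding the
2D Chebyshev distance-to-background at > r; (5) re-threshold inside the
eroded ROI; (6) sweep: keep the largest 26-connected 3D component.
26-connectivity is required so the left and right lungs, joined through
the trachea and main bronchi, form one object; the sweep then removes
sub-threshold gas pockets outside the lung (e.g. in subcutaneous fat).
Exact ties between equal largest components are broken toward the
component containing the lexicographically smallest (z, y, x) voxel,
which labeling in raster-scan order provides for free.

Thresholds: −580 HU for euthanized animals (the full histogram of a
reference air tube lies below −580 HU) and −383 HU in vivo, where
residual motion blur contaminates lung-border voxels and a higher cut is
needed to capture inflation. The two modes differ in nothing else.

Error contracts: an all-air field of view ("no subject"), an ROI that
vanishes under erosion, and a subject with no internal air ("empty
segmentation") all raise rather than return empty results.

## Pressure-volume curves

Points are stored in ascending pressure (descending 30 → 3 cmH₂O
acquisition order is normalized); duplicate pressures are rejected. AUC
is the trapezoid rule over the measured pressure range only — no
extrapolation to 0 cmH₂O, since no integration rule or extended range is
defined for these curves. Volumes may be mm³ or raw voxel counts; units
propagate to the AUC.

## Repeatability, agreement, group tests

`sw` is the square root of the residual mean square of a one-way ANOVA
with subject as factor, computed directly from the within-subject sum of
squares (unbalanced designs supported; for balanced designs sw² equals
the mean per-subject variance). Subjects with a single measurement are
excluded with a warning rather than failing the analysis, mirroring
realistic scan attrition. The 95% repeatability coefficient is
`1.96·√2·sw`. Heteroscedasticity is screened by the Spearman correlation
of per-subject mean vs SD. Agreement is ordinary least squares
(statsmodels) with R², the two-sided slope p-value, and 95% prediction
intervals from residual variance plus leverage. Group comparisons use
Welch's t-test with Welch–Satterthwaite df unconditionally: always
applying the unequal-variance correction is uniformly valid and removes
an unstated "if necessary" branch. All tests are two-sided at α = 0.05.

## Power and sample size

Two-sample t-test power is computed from the noncentral t distribution
with df = n₁+n₂−2 and noncentrality δ = d·√(n₁n₂/(n₁+n₂)); one-way
ANOVA power from the noncentral F with (k−1, N−k) df and λ = f²·N. At
zero effect both reduce to α (scipy's noncentral F is undefined at λ = 0,
so the central F is used there; scipy's noncentral-t CDF can return NaN
in the far tail opposite a large noncentrality, where the term is
< 10⁻²⁰ — a normal-approximation bound stands in for non-finite values).
A-priori sample sizes search balanced designs upward from n = 2 per
group and return the first reaching the target power, so the achieved
power is ≥ target while the next-smaller design is below it. Only
balanced designs are searched because a-priori questions are posed that
way; post-hoc queries accept arbitrary group sizes. Powers are kept at
full precision and rounded to whole percent only for display.
Repeated-measures ANOVA power is not implemented: it requires
inter-measurement correlation and nonsphericity inputs that are not
available.

## The phantom

The digital thorax is an ellipsoidal soft-tissue body (+40 HU) in
external air (−1000 HU), resting on a bed slab (+100 HU), with two
air-filled (−1000 HU) lung ellipsoids joined by a tracheal channel so the
aerated compartment is a single 26-connected object. Geometry is
specified in grid fractions of the default 200³ grid; margins between
lung and body surface exceed the 10 px erosion radius at this size (the
erosion radius is in pixels, so much smaller grids shrink the margins —
use the default size when segmentation fidelity matters). Optional
features: three sub-threshold gas pockets (−600 HU) in the subcutaneous
body, disjoint from the lung, which survive thresholding and erosion and
must be removed by the sweep; patchy fibrotic consolidation (−200 HU,
above both air thresholds) replacing a requested fraction of lung air,
placed as seeded spheres on the most-inflated phase and intersected with
each phase (consolidation is anatomy, not a per-phase event); an
emphysema factor ≥ 1 scaling the aerated compartment volume. Lungs
deflate across 4 phases with relative volumes (1.00, 0.93, 0.87, 0.82) —
a plausible anesthetized-mouse tidal excursion ending at end-expiration —
so EIV > EEV by construction.

Ground truth (masks and volumes) is recorded on the noiseless geometry;
Gaussian HU noise (default SD 20) is then added from a seed-derived
stream that is independent of the geometry options, so paired phantoms
(e.g. with and without speckle pockets) share identical noise. The
phantom deliberately omits beam hardening, ring artifacts, anatomical
texture (parenchymal density distributions, vasculature, airway tree)
and motion blur. Passing tests therefore demonstrate the correctness of
the algorithmic chain and its bookkeeping — not segmentation accuracy on
real tissue contrast, where parenchyma straddles the in-vivo threshold
and boundary voxels are genuinely ambiguous.

The calibration phantom is an air cylinder inside a water cylinder in
raw grayscale (water 81.32, air 0 by default), with interface-eroded
region masks so region means estimate the anchors cleanly.

## Test and verification sizes

End-to-end recovery is checked on the default 200³ grid across 10 seeds
(Dice ≥ 0.95 and volume within 5% of ground truth at σ = 20 HU);
disease-monotonicity checks compare end-expiratory volumes across
fibrosis fractions (0, 0.15, 0.30) and emphysema factors (1.0, 1.1, 1.2)
on matched seeds. Morphology stages are verified against independent
oracles on small random fixtures: per-slice flood fill for external air,
Chebyshev distance transform for erosion, exhaustive component
bookkeeping for the sweep. Noncentral-t power is validated against a
100 000-replicate simulation of the test's sufficient statistics on a
3×3 (d, n) grid to within 0.005. These sizes keep the full suite under a
minute on one CPU while leaving the acceptance margins wide.

## Known limitations

* The despeckle "pore" semantics of the original acquisition software
  are not published; border-connectivity per 2D slice is this package's
  stated interpretation.
* The conversion from breathing video to the 1-D displacement trace is
  outside the package; gating starts from the extracted trace.
* No airway/lobe separation, no density-based fibrosis subtyping, no
  registration between time points.
* In-vivo parenchymal HU distributions are not modelled in the phantom;
  the aerated compartment is pure air, which makes ground truth exact
  but optimistic relative to real parenchyma.
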