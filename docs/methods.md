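# Methods

This note documents the models, defaults and numerical choices behind
`lnulm`, what the synthetic generator does and does not emulate, and the
limitations a user should know before trusting a green test suite.

## Coordinate and unit conventions

Axial = row axis (depth, increasing downward); lateral = column axis.
Physical positions are micrometres measured from the **center** of pixel
(0, 0); indices are 0-based. Speeds are mm/s; a step of *d* μm between
consecutive frames at frame rate *f* Hz is a step speed of *d·f*/1000
mm/s. Super-resolution (SR) pixel (0,0) starts at the upper-left corner
of acquisition pixel (0,0), i.e. at −pitch/2.

## Clutter filtering and motion

The Casorati matrix (pixels × frames) is fully decomposed with a dense
SVD; the filter keeps an explicit, logged 1-based band `[low_rank,
high_rank]` of singular components. There is no automatic rank-selection
rule: a logged band is reproducible where an "appropriate threshold" is
not. The library default is `low_rank = ceil(0.05·n_frames)` with no
upper cut, a conservative choice for in-vivo-like data where tissue
occupies several components (motion, modulation). On the synthetic
fixtures the tissue pattern is a single spatial field times a temporal
modulation — exactly rank 1 — so the fixture analyses use `low_rank=2`,
recorded in `resolved-config.yaml`.

Stage order is: motion-frame rejection → rigid compensation → SVD.
Rejection must come first (decorrelated frames poison both the shift
estimate and the clutter subspace); compensating before the SVD makes
tissue more nearly stationary and therefore lower-rank. Rigid motion is
translation only, estimated by phase correlation with subpixel
refinement (default 1/10 px) and undone by Fourier shift (periodic
boundaries; adequate for sub-pixel to few-pixel breathing shifts).

## Detection and localization

The per-frame detection threshold is mean + k·sd of the magnitude image
(default k = 5). Filtered frames are signed residuals, so detection uses
|I|. Candidate regions are compared with the theoretical PSF — an
anisotropic Gaussian with FWHM 143 μm (axial) × 173 μm (lateral) by
default, magnitudes typical of a 25 MHz linear array — on three
criteria:

* **size**: region area within [0.5, 3.0] × the elliptical footprint
  π·(FWHMa/2)·(FWHMl/2) in pixel units. The upper bound is 3.0 rather
  than a half-max-based 2.0 because the adaptive threshold sits below
  quarter-maximum at realistic SNR, where a genuine single-bubble region
  spans ~2.5 footprints; merged bubble pairs still exceed 4 and are
  rejected.
* **intensity**: region peak ≥ `min_peak_factor` × the detection
  threshold (default 1.3). This rejects clutter-filter afterimages: a
  bubble that dwells at one location leaks into the removed low-rank
  subspace and leaves a low-amplitude residual of opposite sign at other
  frames, which would otherwise pass the size and shape gates.
* **shape**: zero-mean normalized correlation with the model Gaussian,
  centered at the region peak, computed on the region's bounding box
  ± 1 px ≥ 0.6.

The centroid uses pedestal-subtracted weights, |I| − threshold, rather
than raw intensities: a hard-thresholded region carries a constant
pedestal whose truncation at the region boundary biases the plain
centroid by ~0.1 px toward the region center; subtracting it makes the
weights vanish smoothly at the boundary and reduces the noiseless bias
to ~0.02 px. FWHM is measured through the peak by linear interpolation
of the half-maximum crossings; at 50 μm sampling the axial profile is
only ~2.9 px wide and the interpolation overestimates the width by
~2.6%, so the simulator-consistency test samples at 25 μm (error
< 0.5%). This is an estimator sampling artifact, not a property of the
rendered PSF.

## Tracking

Frame-to-frame linking minimizes total Euclidean distance via the
Hungarian algorithm on an augmented square matrix: each track end and
each new localization also has a "skip" alternative priced at the gate
distance, so termination and birth compete fairly with linking, and any
pair beyond the gate is forbidden. The objective is therefore
Σ matched distances + gate × (number unmatched). Defaults: gate =
v_max/frame rate with v_max = 50 mm/s (100 μm at 500 Hz); minimum track
length 5. There is no gap closing — a missed detection ends the track —
and no motion-model prediction. Within-frame localizations are sorted by
position before assignment, which makes the result invariant to input
order (an index-based tie rule cannot be). Kinematics are step-averaged:
mean speed is the mean of step magnitudes, so a closed loop has positive
speed and zero net displacement; velocity is never derived from
endpoints alone.

## Super-resolution maps

Tracks are rasterized onto the SR grid (default factor 4) by supercover
line traversal — every cell the segment touches, including all adjacent
cells at exact lattice-corner crossings — so a continuous trajectory
never skips pixels. A track increments a pixel's count at most once (one
bubble = one passage; re-entry is not double-counted). The velocity map
is the unweighted mean of the covering tracks' mean speeds; the signed
direction map averages their mean axial velocity components. ROI
masking keeps a pixel iff its center is inside or on the boundary
polygon. Plane stacking stores the inter-plane spacing (default 150 μm,
a typical motorized-stage step) and performs no registration.

## Subtyping and vascular parameters

The velocity threshold is the unweighted mean of the velocity map over
ROI pixels with count > 2 (strictly: ≥ 3), read per node; if no pixel
qualifies the mean over all vascular pixels is used and flagged
`fallback`. "Regions" is read as SR pixels, not connected components.
Type 1 requires mean speed **strictly** above the threshold. The
arterial/venous decision uses the sign of dot(net displacement, unit
vector from hilum to track centroid); an exact zero is reported as
unclassified rather than silently assigned, and classification without a
hilum point is refused — the whole-node outputs still complete and the
exclusion is logged. Mean flow speed is track-weighted (the mean of
per-track mean speeds), matching the parameter's definition as an
average over trajectories.

## Histology

Otsu's threshold is computed in-package on a 256-bin histogram of the
min–max-scaled channel (upper edge of the background bin maximizing
between-class variance, lowest cut on ties) so the exhaustive-search
oracle is exact; empty bins between well-separated modes can tie at
machine precision, in which case any tying cut yields the identical
mask. Opening uses a disk of radius 1 px by default. Lumen filling
fills 4-connected background components that cannot reach the image
border (the dual of 8-connected foreground). The default order is fill
CD31 lumina first, subtract LYVE-1 second; `--subtract-first` flips it,
and in that order the blood mask is re-subtracted after filling to keep
the masks disjoint. The manual validation step of a wet-lab workflow is
replaced by the automated enclosed-hole rule plus a processing log.

## Statistics

Pearson r with a two-sided p from t = r·√((n−2)/(1−r²)) on n−2 df,
R² = r², and an ordinary least-squares line. One-way ANOVA with Tukey
HSD from the studentized-range distribution. p-values are reported,
never used for automated decisions; no multiple-testing correction is
applied across the report table — the table carries the number of tests
so a reader can adjust.

## The synthetic world

The generator states explicit, fixed conditions rather than tunable
realism:

* **Acquisition** defaults follow the study geometry: 500 Hz compounded
  frame rate, 1500 frames per plane (desk-scale fixtures use 200 frames
  at 128×128, 50 μm pixels). PSF FWHM defaults 143/173 μm.
* **Vessel tree**: recursive bifurcation from a hilum-anchored trunk;
  radius ratio uniform in [0.6, 0.8] per branch, speed ∝ radius²
  (laminar heuristic), growth directions kept within 65° of the
  hilum-radial so branches run hilum → surface and the direction-based
  subtype labels are well defined. Trunk 15 mm/s; published per-class
  in-vivo speeds are not available, so the branch magnitudes
  (~1.5–9.6 mm/s) are stated placeholders.
* **Transport**: bubbles ride segment centerlines with a fixed
  perpendicular offset ≤ the radius; a 250 μm minimum pairwise
  separation enforces the dilute-contrast regime ULM requires, and
  in-plane residence is capped at 15% of the ensemble (2D imaging
  sections 3D flow; an uncapped quasi-static bubble bleeds into the
  clutter subspace and leaves ghost residuals — visible at desk-scale
  ensembles, negligible at in-vivo frame counts).
* **Rendering**: Gaussian echoes (truncated at 6σ) + one smooth tissue
  field × (1 + 0.02·sin) temporal modulation (Casorati rank 1 by
  construction) + optional axial sinusoidal rigid motion + additive
  Gaussian noise, floored at 0.
* **Histology cohort**: one latent activation per node drives the
  LYVE-1 area fraction (disks painted until the target fraction is
  reached; overshoot bounded by one disk, ~0.05% of the image), the CD31
  ring count, and the ground-truth vascular measures — affinely when
  `rho` is unset (noiseless correlation exactly 1), or jointly Gaussian
  at a stated latent correlation.

What the generator does **not** emulate: speckle statistics, nonlinear
bubble oscillation, out-of-plane motion blur, depth-dependent PSFs,
stain bleed-through, or tissue autofluorescence. A green test therefore
establishes that the algorithms implement their definitions and recover
a stated world — not that they are robust to every artifact of real
acquisitions.

## Numerical notes and limitations

* Identical seeds and parameters reproduce movies, tracks and result
  bundles bit-for-bit; outputs carry no timestamps.
* At SR factor 4 the SR pixel (12.5 μm) is comparable to the
  localization precision (~7 μm), so pixel-identity overlap between
  recovered and ground-truth maps drops to ~84%; at factor 2 it exceeds
  95%. Density/area comparisons across factors should use the same
  factor on both sides.
* Mean speeds of slow tracks are biased upward by localization jitter
  (|v + ε| > |v| in expectation); at the default fixture's SNR the bias
  is ≲ 1 mm/s, small against the Type 1 threshold margin but visible in
  per-track speed tables.
* The velocity threshold is meaningful only when count > 2 pixels carry
  a mix of vessel calibers; in very sparse acquisitions the `fallback`
  flag indicates the weaker rule was used.
* `simulate_mb_flow` resamples rejected placements up to 200× the bubble
  budget; at extreme densities it may emit fewer tracks than requested
  rather than violate the separation constraint.
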