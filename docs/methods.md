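# Methods

This note documents the models, conventions and design choices behind
`nucleodyn`, in the spirit of the methods documentation of mature
scientific Python packages.

## Conventions

Axis order is `(t, z, y, x)` everywhere; indices are 0-based; physical
coordinates are `index × pixel_size_um`, with voxels treated as isotropic
(the z-step equals the in-plane pixel size).  Defaults: pixel size
0.3 μm/px (so the 17 px heatmap bin spans ≈ 5 μm) and frame interval 30 s
(40 frames ≈ a 20-min imaging window).  Both are configuration
parameters, not constants of the method: acquisition settings vary
between microscopes and the defaults are declared stand-ins.

## Shape Factor

Shape is measured on the 2D maximum projection of each segmented 3D
nucleus.  The central second moments of the uniform binary mask form a
2×2 covariance tensor; its eigenvalues λ₁ ≥ λ₂ define the equivalent
ellipse with semi-axes a = 2√λ₁, b = 2√λ₂ (exact for a uniform ellipse).
The default Shape Factor is SF = (a − b)/(a + b), which is 0 for an
isotropic shape and tends to 1 with elongation.  A second formula with
the same limits, 1 − b/a, is selectable (`sf_formula="one_minus_ratio"`);
the squeezing threshold is coupled to the formula choice and must be
re-declared if the alternative is used.  The literature definition
"from the integral over the nuclear area" admits both candidates; the
default is a declared package choice, not an inference of original
intent.

Numerical details: each pixel contributes the second moment of a unit
square about its own centre (1/12 per diagonal term) before the axes are
derived, keeping b > 0 for any mask of ≥ 2 pixels and reducing
small-mask digitization bias; the raw double-sum moments are exposed
separately (`central_moments`) for oracle comparison.  Circularity
4π·area/perimeter² uses the 4-direction Crofton perimeter estimator,
because naive pixel-edge counting inflates the perimeter of a digital
disk by ~11 % and would bias circularity well below 1.  Feret diameters
are computed over the convex hull of pixel *corner* points: the minimum
caliper width by the edge-direction minimum, the maximum by rotating
calipers (antipodal pairs); a w×h pixel rectangle therefore measures
exactly w and √(w²+h²).  The minimum nuclear diameter reported by
`min_diameter` is the min Feret — the automated analogue of a manual
between-arrowheads measurement.

## Squeezing events and track statistics

A frame is squeezing when SF ≥ 0.4 (inclusive, per the source
definition); an event is a maximal run of consecutive squeezing frames;
its duration is run length × frame interval.  Frames missing due to gap
closing break runs and are excluded from the proportion denominator —
interpolating SF across a gap would fabricate a deformation measurement.
No smoothing is applied to SF series before thresholding.

Migration statistics are standardised to a 15-min window: longer tracks
are truncated to their first window; shorter tracks are linearly rescaled
by `15 min / duration` and flagged (`window_rescaled`).  Mean speed is
the mean of frame-to-frame instantaneous speeds (not net displacement
over total time, which the word "average speed" could also mean).
Persistence is the directness ratio Euclidean distance / path length
over the window; for a stationary track (zero path length) it is
undefined and excluded, not set to zero.  Correlation matrices use
Spearman (rank transform with average ranks, then product-moment) or
Pearson, with two-sided p-values from the t-approximation with n − 2
degrees of freedom and pairwise-complete handling of missing entries.

The spatial heatmap assigns each observation's SF to the square bin
(default 17 px) containing its centroid under half-open intervals
[k·s, (k+1)·s); a centroid exactly on a boundary falls in the
higher-index bin; empty bins are NaN ("no data").  The count-weighted
mean of bin values equals the global mean SF identically, which the
tests exploit as a conservation oracle.

## Segmentation and tracking

The pixel classifier is a deliberately small, deterministic stand-in for
an interactively trained forest: per-slice Gaussian smoothing
(σ ∈ {1, 2, 4} px), gradient magnitude (σ = 2) and Laplacian-of-Gaussian
(σ ∈ {2, 4}) features plus the raw intensity feed an L2-regularized
logistic model fit by lbfgs on standardized features — deterministic
given the annotations, and serializable to JSON with exact float
round-trip, so a reloaded classifier reproduces probabilities
bit-identically.  Indistinguishable class annotations trigger a
`SeparabilityWarning` and yield probabilities near the class prior.
Segmentation thresholds the probability map at 0.5 (inclusive), labels
26-connected 3D components, removes components below 30 voxels, and
renumbers survivors by descending volume (scan-order tie-break).  The
probability threshold and minimum volume are unreported in the original
protocol and are exposed as configuration.  2D operations use
8-connectivity.  Touching-nuclei splitting (watershed) is out of scope:
the default synthetic regime keeps nuclei separated.

Tracking is greedy nearest-neighbour linking with gap closing: candidate
(track, detection) pairs within `max_disp × gap_length` are matched in
ascending distance with deterministic tie-breaks (distance, lower track
id, lower label id), making output invariant to detection order within a
frame.  This diverges from global LAP optimisation by design — at the
nucleus densities of interest greedy matching is sufficient, and it is
exactly reproducible.  Default `max_disp` 10 μm/frame (≈ 3× the fastest
default speed at 30 s), `max_gap` 1.  Track filters: fewer than 4
timepoints removed; with a region (vessel) mask, a track is removed when
the strict majority of its centroids falls outside (the original rule
does not define partial-overlap handling; majority-of-centroids is the
declared operationalisation).

## Intensity quantification

Rim intensity per nucleus is the mean over three line profiles (sampled
at ~1 px spacing, nearest pixel) averaged over the three central
z-slices, minus the mean of three background lines at the same z.
Negative corrected values are retained and flagged, never clamped, so
group means stay unbiased.  Sample positions are quantized to 1e-6 px
before rounding so that translated copies of the same line geometry
sample identical pixel offsets.  The automated rim-line rule (three
diameters through the nucleus centre at 0°, 60°, 120°) is a
deterministic stand-in for unknowable manual line placement; explicit
line endpoints are also accepted.  Normalization divides each corrected
value by the mean corrected value of the reference class (epithelial) in
the same age group.  Lamin stoichiometry uses per-age medians per
channel, each normalised to the reference age's median; the relative
ratio is the normalised A-channel median over the normalised B-channel
median, so the reference age is 1 by construction.  3D nuclear means
subtract a negative-control mean per batch.  Phagosome quantification
counts distinct labels intersected with the cell mask and sums their
in-mask areas; instability rates are events per 100 cells.

## Vessel transit

Vessel diameter is the distance between the two outermost local maxima
of the intensity profile along a measurement line crossing both walls,
where qualifying peaks exceed half the profile's dynamic range; each
peak is refined by a 3-point parabolic fit (the original measurements
were manual on in-focus planes; the peak criterion and subpixel
refinement are package decisions).  Fewer than two qualifying peaks
raise `UnmeasurableError`.  The measurement can be averaged over several
parallel lines offset along the vessel axis.  Transit frames are those
in which the nuclear-channel mean intensity along the line exceeds a
background mean + 3 SD (background pooled from a nucleus-free corner
box); the in-focus z-plane is the slice with the brightest nuclear
signal.  The nuclear diameter entering the residual space is the
min-Feret of the thresholded nucleus in the central transit frame
("nuclear diameter" being otherwise unspecified, the smallest caliper
width is the declared choice).  Reported metrics: relative change
D_during/D_pre and residual space D_during − D_nucleus, plus Pearson
correlations with regression slope and R² across a transit cohort.

## Synthetic generator

The generator emulates what the analysis needs and no more: migrating
fluorescent nuclei (default diameter 4 μm) drawn as uniform-intensity
ellipsoids, their in-plane semi-axes realising the frame's true SF while
conserving projected area (a·b = r²), major axis aligned with velocity,
motion confined to a channel when the regime defines one.  Squeeze state
follows a two-state Markov chain; emitted SF adds truncated Gaussian
jitter (sd 0.03) clipped to the state's side of 0.4, so the ground-truth
flag and SF ≥ 0.4 agree frame by frame and threshold crossings are
non-degenerate.  Imaging noise is Poisson (shot) followed by additive
Gaussian (read), applied last.  Each nucleus draws from its own stream
derived from the master seed and the nucleus id via the seed-sequence
spawn key, so adding a nucleus never perturbs the others; identical seed
and config give bit-identical output.  Nuclei keep to disjoint
territories along the channel, guaranteeing pairwise spacing of at least
twice the diameter — which is what makes 100 % tracking purity an
expected property rather than luck.

The stock regimes encode the qualitative contrast the analysis must
resolve, with parameters chosen once on field-plausible scales (the
originating measurements come from undeposited data, so the transition
probabilities are not published values): **vessel** — p_enter = 0.30,
p_exit = 0.30 per 30-s frame (stationary occupancy 0.50, mean event
100 s), baseline SF 0.18, squeeze SF 0.55, 6 μm channel, 2 μm/min;
**open** — p_enter = 0.05, p_exit = 0.50 (occupancy 0.091, mean event
60 s), baseline 0.10, squeeze 0.50, unconfined, 3 μm/min.  Vessel nuclei
thus squeeze more often, longer, and to higher SF, reproducing the
direction of the real contrast.

What the generator does not emulate: point-spread-function blur, focal
drift, photobleaching, spectral crosstalk, touching or dividing nuclei,
and nuclear shapes beyond ellipsoids.  Passing recovery tests therefore
demonstrates the correctness of the measurement chain on data whose
generative truth is known — not robustness to every artefact of real
microscopy.

## Problem sizes and statistical expectations

The recovery experiment uses 20 seeded vessel movies with 50 nuclei in
total, 40 frames each (2000 observations).  At these sizes the pooled
squeezing-proportion estimate has a sampling SD of ≈ 3–4 % relative
(autocorrelated Markov frames, decay factor 1 − p_enter − p_exit = 0.4),
so the 5 %-relative recovery check is attainable but genuinely
statistical.  Mean event duration measured on 40-frame windows is biased
a few percent below 1/p_exit by end-of-track censoring (events in
progress at the window edge are cut short); this sits well inside the
15 % recovery band and is a property of windowed observation, not an
implementation artefact.

## Known limitations

- The greedy tracker has no motion model and no split/merge handling;
  it is not suitable for dense or dividing populations.
- The pixel classifier is linear in a small fixed feature bank; heavily
  textured backgrounds would need a richer model.
- Vessel measurement assumes locally straight, roughly parallel walls
  crossed by a user-supplied line; arbitrary curved vessels are out of
  scope.
- The 15-min rescaling of short tracks assumes statistical homogeneity
  of motion within a track.
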