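# Methods

This note documents the models, conventions and design choices behind
each stage of the pipeline, what the synthetic generator does and does
not emulate, and the known limitations. Units are micrometers (µm) for
lengths, µm² for areas, and arbitrary fluorescence units (AU) for
intensities unless stated otherwise.

## Synthetic imaging model

The generator stands in for per-well multichannel confocal fields of
primary neuron cultures. A field has four channels — neurochemical
marker, MAP2, Syt-1, nuclei — on a common grid with physical pixel size
`pixel_size_um` (default 0.3 µm/px, a 60×-like sampling at which
varicosity widths of 0.2–1 µm span roughly 1–3 px). Coordinates are
0-based pixel indices; physical positions are pixel centers ×
`pixel_size_um`.

**Somata** are rendered as soft-edged disks of 8–15 µm diameter, placed
by dart throwing with a separation floor (centers at least one maximum
diameter plus 3 µm apart; after 200 failed darts a crowded position is
accepted, so overlap remains possible but rare, as in sparsely plated
cultures). Each soma also contributes a MAP2 disk and a nuclear disk.

**Neurites** are curvature-bounded random walks: unit pixel steps whose
heading receives Gaussian increments (SD 0.05 rad/step, i.e. a
persistence length of ~120 µm — axons are nearly straight at the 10-µm
scale), with smooth steering toward the field center inside a 15-px
boundary band (mirror reflection was rejected because a grazing
reflection retraces the incoming path and double-counts length).
Branching is a Poisson process per unit length (`branch_prob_per_um`,
default 0.02/µm); a branch starts a new walk at ~57° from the parent.
Walks are not anchored to somata: the imaged axonal field of long-range
projection neurons extends far beyond the cell bodies in the same frame.
Axon segments passing within a soma radius + 2 µm of a soma center are
occluded (the fluorophore-dense cell body hides them); occluded vertices
are removed from both the rendering and the ground truth, visible
fragments shorter than 2 µm are dropped, and the generator grows walks
until the *visible* summed length reaches `neurite_total_length_um`.
Ground-truth total length is therefore exactly the sum of the emitted
polyline lengths (conservation is asserted in tests).

**Varicosities** are planted along the polylines with gaps of
`min_gap + Exponential(mean − min_gap)` (default mean 5 µm, minimum gap
1.5 µm — two enlargements closer than ~1.5 µm are one blob at this
resolution, so the truth annotation only lists resolvable objects). Each
site is an anisotropic Gaussian bump aligned with the local tangent,
with FWHM width drawn from `varicosity_width_range_um` (default
0.3–0.9 µm) and length from 0.6–2.0 µm. A fraction `offgate_fraction`
(default 0.15) of sites is oversized (width 1.2–1.8 µm, outside the
width gate); these carry Syt-1 from the *negative* mixture component
only, modelling non-synaptic swellings and debris — the background-like
structures whose Syt-1 signal the positivity cutoff is estimated from.
In-gate sites are Syt-1-positive with probability `syt1_pos_fraction`;
intensities are Normal(120, 10) AU for positives and Normal(20, 10) AU
for negatives (a clearly bimodal mixture; the separation, not the
absolute scale, is what matters downstream).

**Camera model**: constant background (10 AU) plus additive Gaussian
noise (SD 2 AU), clipped at zero. No Poisson shot noise, no channel
bleed-through (acquisition is modelled as sequential), no astrocyte
texture, no photobleaching, 2-D only. Equal seeds give bit-identical
fields, truths and traces.

`generate_straight_field` renders the same primitives on a single
horizontal neurite with enlargements at fixed spacing — the controlled
fixture used for detector benchmarks, so that recall/precision are
measured against unambiguous, well-separated truth.

**What passing on synthetic data does and does not show.** The generator
reproduces the *statistical structure* the analysis relies on (sparse
bright somata over background, thin tubular neurites with focal
enlargements, bimodal Syt-1, plateaued calibration traces), so green
tests demonstrate the pipeline's internal correctness and its recovery
of known quantities under that structure. They do not certify
performance on real micrographs, where point-spread blur, uneven
illumination, astrocyte autofluorescence and segmentation ambiguity are
harsher than anything simulated here.

## Soma census

Segmentation is median filter (radius 1 px) → Otsu threshold (the
standard parameter-free choice; a fixed intensity quantile is available
as an alternative) → morphological opening with a 1.5-µm-radius disk
(removes thin neurite pixels; anything narrower than ~3 µm cannot
survive) → hole filling → removal of regions under `min_soma_area_um2`
(default 30 µm², well below the ≥50 µm² area of an 8-µm soma but above
varicosities and debris). A constant image yields an empty mask, not an
error.

Counting accuracy against ground truth uses greedy nearest-pair
one-to-one matching of predicted centroids to true centers within 5 µm,
with accuracy = matches / max(n_true, n_predicted) — a symmetric
penalty for both misses and false positives. This matching rule is a
declared convention of this package.

Survival normalization divides each well's count by the mean count of
the *same population's* dose-0 wells (pooling across populations is a
config option, off by default). A zero or missing dose-0 mean flags the
population's normalized values as undefined rather than raising.

## Neurite morphometry

The neurite mask is the union of a tubular-structure detection (Sato
ridge filter at σ = 1–1.5 px, Otsu-thresholded over its positive
support) and a robust intensity detection (Gaussian-smoothed image
above median + 6 robust SDs) — the intensity term keeps varicosity
sites, where a pure ridge response dips. The dilated soma mask
(+1.5 µm) is subtracted and connected components shorter than 2 µm are
removed (8-connectivity, so single-pixel diagonal sections survive).

Skeletonization reduces the mask to a 1-px centerline, converted to a
graph with an explicit length convention: orthogonal pixel steps count
1 × and diagonal steps √2 × the pixel size; a diagonal link is skipped
when the two pixels already share an orthogonal neighbour (avoids
double-counting staircases). Terminal spurs under 1 µm — skeletonization
artifacts well below the varicosity scale — are pruned. A "segment"
("section") is a maximal path between nodes of degree ≠ 2; this package
defines the term this way and records it in outputs, since branch
units can also be defined as detector fragments.

Per-well metrics are total length, segment count, and the per-neuron
ratios; the identity mean_length_per_neuron × n_neurons =
total_neurite_length holds exactly, and wells with zero neurons are
flagged invalid and excluded. Only the marker channel is traced: in
these cultures the large majority of neurites are MAP2-negative, so
total neurite length serves as a proxy for axonal length; MAP2 exclusion
is available as a config flag.

Numerical behaviour: measured length is essentially unbiased at low
neurite density and loses a few percent at high density, where parallel
passes closer than ~2 px merge under the effective line width and the
skeleton collapses them — the recovery regression (slope ~0.94 over
fields of 500–1500 µm at the default field size) quantifies the
residual. The √2 convention slightly overestimates oblique straight
lines (up to +8% at 22.5°, +5% on average over angles), which partly
offsets the merging loss.

## Varicosity analysis

Candidates are intensity peaks along skeleton segments. The local
neurite baseline is a rolling 25th percentile over a 9-µm window — a
low quantile, because a median is contaminated by the enlargements
themselves when they cluster. A peak must (i) exceed 4 robust noise SDs,
(ii) exceed 1.2 × the local neurite brightness above background (an
enlargement carries more fluorophore than the line it sits on; plain
line crossings roughly double brightness and fail this test), and
(iii) be a 2-D local maximum of the smoothed image (rejects off-center
"ghosts" where another line crosses a blob). The first and last micron
of segments ending in a free (degree-1) node are skipped — a terminal
taper mimics a peak — while junction-adjacent peaks remain eligible,
since crossings fragment the skeleton exactly where varicosities sit.

Width is the transverse FWHM of the peak's profile after subtracting a
reference transverse profile sampled ±3 µm along the same segment
(elementwise minimum of the two sides, removing the neurite's own
ridge); length is the along-tangent FWHM above the local baseline. Both
are obtained from a least-squares Gaussian fit (every sample informs the
estimate; half-max crossing interpolation is the fallback), which cuts
the width error to ~0.03 µm SD on clean fixtures — essential, because
gate misassignment near the 0.2/1 µm boundaries leaks Syt-1-positive
objects into the cutoff pool. Candidates within 1 µm are de-duplicated
keeping the brighter.

The size gate passes widths in [0.2, 1] µm (boundaries inclusive) and
lengths in [0.3, 5] µm by default. The narrow literal gate [0.3, 0.5] µm
is available via `strict_length_gate` and every output row records which
gate was applied; the narrow range would exclude most objects longer
than they are wide, so the permissive upper bound is the default.

Syt-1 intensity is the mean over a fixed 0.45-µm-radius footprint at the
candidate center, minus the Syt-1 channel median. The fixed footprint —
rather than one scaled to the object — keeps excluded and gate-passing
candidates on one intensity scale, which the cutoff transfer requires.
The positivity cutoff is the 95th percentile of the excluded
(gate-failing) candidates' intensities (mean + 2 SD available as an
alternative; with fewer than 5 excluded candidates it falls back to
background mean + 2 SD and is flagged). In pipeline runs the cutoff is
estimated once per plate from all wells' excluded candidates: it is an
experiment-level calibration, and per-well pools are too small to be
stable. Classification is strict (> cutoff), applied to gate-passing
candidates only; the positive fraction is NaN when nothing passes.

Spacing is the 2-D Euclidean nearest-neighbour distance between passing
centroids (not along-skeleton path length); density is passing count per
mm of skeleton length.

## Redox dynamics

Stacks are registered by translation-only cross-correlation against the
first frame (plain cross-correlation, not phase normalization — more
robust at low SNR; rigid-body rotation is not modelled, a documented
limitation for recordings with stage rotation). ROI traces are per-label
mean intensities per frame.

Epoch summaries F, F_DTT, F_ALD are medians of the last half of each
epoch (the plateau; the chemical calibration reaches steady state well
before the epoch ends). QC applies two rules. Drift: a least-squares
line over the whole baseline epoch; the drift fraction is
|slope × duration| / fitted value at baseline start, and traces above
0.10 are excluded. Responsiveness: DTT must raise and ALD must lower
fluorescence by at least 3 detrended-baseline SDs each, in those
directions (with a tiny absolute floor so noiseless non-responders are
still excluded). Relative oxidation `1 − (F − F_ALD)/(F_DTT − F_ALD)` is
computed for included traces only, clipped to [0, 1] with a flag; it is
exactly 0 at F = F_DTT, 1 at F = F_ALD, and invariant under common
affine rescaling of the three intensities. F_DTT ≤ F_ALD is a
calibration error.

Inter-mitochondrial distances are consecutive center-to-center gaps
after sorting by axial position. The simulation default — gamma gaps
with mean 13 µm, SD 5.4 µm — is the consensus spacing observed across
neuron types. Somatodendritic spacing is not computed (density too
high to resolve single puncta).

## Estimation statistics

The resampling unit is always the well. The BCa interval for an
unpaired mean difference mean(b) − mean(a) uses 5000 resamples by
default (the coverage benchmark uses 1000, a deliberate scale-down);
bias correction z₀ = Φ⁻¹ of the fraction of resampled differences below
the observed one, with ties counted half so heavily tied (lattice)
statistics stay centred; acceleration from the jackknife skewness over
both samples (delete-one means, a = Σd³ / 6(Σd²)^{3/2}). Interval
endpoints are linear-interpolation quantiles of the resample
distribution. Zero variance in both groups degenerates to [d, d] with a
flag. Identical (seed, n_resamples) reproduce intervals bit-exactly;
shared-control runs derive each pair's seed from SHA-256 of
"master_seed:group_label" (31-bit), so results are invariant to group
order. Empirical 95% coverage at n = 20/group over 1000 Gaussian
simulations lands at ~0.93–0.94, the known mild undercoverage of BCa at
this sample size.

Omnibus testing routes on a per-group Shapiro–Wilk screen at α = 0.05
(a declared convention): all groups normal → one-way ANOVA + Tukey HSD;
otherwise Kruskal–Wallis + pairwise Mann–Whitney with Bonferroni
adjustment (min(1, m·p)). Zero-spread groups route nonparametric
directly. Both routes can be forced. Mann–Whitney is exact for combined
n ≤ 20 without ties, and a tie-corrected normal approximation otherwise;
the vulnerable/resilient class map is fixed: vulnerable = {SNc, LC, R,
DMV}, resilient = {VTA, XII, STR}. Tukey box statistics use
linear-interpolation (type-7) hinges — recorded in the output, since
hinge conventions differ — and whiskers at the most extreme data values
within 1.5 IQR of the hinges.

## Pipeline and demo plate

A run is a single plate: `manifest.csv` maps wells to population, dose
and image; wells flagged `excluded` (e.g. contamination) are skipped
with the exclusion tallied. Stages run in order census → trace →
varicosities → redox → stats; morphometry and varicosity stages analyse
dose-0 wells (treated wells are counted for survival only). Outputs are
pure functions of (inputs, config, master seed), and the run record
stores the config snapshot, per-stage counts, exclusion tallies,
version and wall time.

The demo plate is 7 populations × 4 doses × 3 wells at 352×352 px, with
~10 neurons per untreated well. Planted conditions: survival fractions
1/0.70/0.45/0.30 (vulnerable) vs 1/0.85/0.70/0.55 (resilient) across
0/100/150/200 µM; visible neurite length 950 µm vs 550 µm per field
(±8% well-to-well), i.e. a class effect of several well-level SDs;
Syt-1-positive fractions 0.75 vs 0.35; 12 roGFP ROIs per population
with ~10% drifting and ~10% non-responding traces and oxidation uniform
on [0.2, 0.8]. Problem sizes throughout (field size, 100–200 fields for
census recovery, 50 fields for the length regression, 500 traces, 1000
coverage simulations) were chosen so the full suite and the acceptance
script each run in minutes on one CPU.

## Known limitations

- Detection quality is quantified on well-separated enlargements; in
  dense tangles (≥1.5 mm of axon in a 115-µm field) skeleton
  fragmentation and blob interference reduce recall to ~0.7–0.8 and
  precision to ~0.5–0.6, and the recovered Syt-1 fraction is attenuated
  toward zero — class *differences* survive (the demo detects them at
  p < 10⁻³) but absolute fractions from dense fields underestimate.
- Measured neurite length loses a few percent to parallel-line merging
  at high density; the recovery slope is ~0.94, not 1.
- Translation-only registration; no rotation.
- The synthetic camera model omits shot noise, blur beyond the rendered
  line width, and non-uniform illumination.
- The a-priori power analysis behind the survival-assay sample size is
  not implemented: its variance assumption is not recoverable, so the
  published n cannot be verified from first principles.
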