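# Methods

This note documents the models, estimators, parameter choices and known
limitations of the `perinexus` pipeline. Units are nm (localizations,
membrane traces), ms (times), Ω (impedance), cm/s (conduction velocity)
throughout.

## 1. STORM relative-localization analysis

**Registration.** Fiducial beads visible in both channels are paired by
mutual nearest neighbour within a 500 nm gate; the rigid transform mapping
channel B onto channel A is the Kabsch/SVD least-squares solution, with the
residual RMS reported. Fewer than three usable pairs, or collinear beads
(second singular value of the centred bead matrix below 1e-9 of the first),
are hard errors — the rotation is not identifiable in either case.

**Cluster detection** is DBSCAN in physical units: a molecule is a core
point with ≥ `min_points` neighbours (self included) within `radius_nm`;
components smaller than `min_cluster_size` are discarded as background.
Defaults — radius 30 nm, 5 points, 10-member minimum — sit near three times
the nominal 10 nm localization precision; all three are exposed in the
config and echoed in every run manifest, because cluster counts are
sensitive to them. No axial rescaling is applied: the metric is physical nm
in all three axes, and the poorer axial precision enters only through the
per-point precision used for dilation.

**Volumes** are voxelized occupancies on a world-anchored grid (voxel index
`floor(x / v)`, default v = 20 nm), so occupancies of different clusters
are directly intersectable. A voxel is occupied if it contains a member
point or its centre lies within the dilation radius of one (default
dilation = median point precision). Volume is occupied-voxel count × v³.
Voxel counting of a ball overestimates its volume by up to a half-voxel
surface shell, ~3v/2r relative for radius r; this is the dominant error in
overlap fractions of small lens-shaped intersections and is the bound used
in the tests. Convex-hull volume (`hull_volume`) is available for
comparison; it is not the default because plaques are concave.

**Signed distance.** Disjoint clusters: the closest surface-voxel pair
locates the approach region and the value is refined to sub-voxel precision
as the minimum pairwise distance between member points minus the dilation
applied to each surface (for clusters up to ~2000×2000 points the exact
point-pair minimum is used directly; beyond that the refinement is
restricted to the closest-approach neighbourhood). Without this refinement
the centre-to-centre voxel distance can deviate from the true surface
distance by up to √3 voxels in 3D. Overlapping clusters: minus the maximum
Euclidean-distance-transform depth of any shared voxel inside the reference
occupancy — a magnitude convention chosen here; only the sign matters for
classification. Distances are always edge-to-edge, never
centroid-to-centroid.

**Classification.** Each partner takes its nearest reference by signed
distance (the three nearest reference centroids are screened; ties broken
by lower reference id) and is classed overlapping (< 0), adjacent
(≤ 200 nm — the perinexal shell around the GJ cluster edge) or distant.
An empty reference set classes every partner distant with distance +∞.
The overlap degree is reported against the partner volume by default and
against the reference volume alongside, since either denominator is
defensible; no "tangential overlap" subclass is invented — the full
overlap-fraction distribution is exported instead.

## 2. Conduction analysis

**Activation** is the time of the maximum first derivative of each pixel
trace after a 5-frame moving average, refined to sub-frame precision by a
parabolic fit through the three derivative samples around the peak — at
1000 frames/s, frame quantization would otherwise dominate the error of
fast-axis gradients (~0.2 ms/pixel at 50 cm/s and 0.1 mm pixels). Pixels
whose derivative peak is below `snr_min` (default 5) times a
MAD-based noise estimate are masked; a constant trace is therefore masked,
and a movie with no valid pixel is an error.

**Velocity** comes from the activation-surface gradient, `v = ∇T/|∇T|²`.
The global 6-coefficient parabolic surface `T = ax²+by²+cxy+dx+ey+f`
(ordinary least squares, rank-checked) is exact for planar and genuinely
quadratic maps and is kept as the `mode="global"` contract. It cannot
represent the conical activation surface of a focally paced wave — fitting
a single quadratic to an isotropic cone provably inflates wedge-mean speeds
by ~25% — so the default `mode="local"` fits the same quadratic in a
sliding window (half-width 4 pixels) around every pixel and takes the
gradient at the window centre; on a quadratic map both modes agree to
machine precision. Pixels within 8 pixels of the pacing site (gradient
singularity, window-flattening bias) and pixels whose window leaves the
valid region are masked. A radial mask further restricts vectors to the
largest pacing-centred circle inscribed in the field so that every
propagation direction is sampled with equal area; without it the corners of
a square field bias the fast-axis estimate by several degrees.

**CV summary.** CV_L is the mean speed of velocity vectors pointing within
±15° of the fast axis, CV_T the mean in the perpendicular wedge,
AR = CV_L/CV_T. The fast axis is identified by fitting the conduction
ellipse: for an elliptical wave the time gradients satisfy `gᵀSg = 1`
exactly, so a least-squares conic fit pooled over all vectors yields the
axis as the leading eigenvector of S — far steadier (±0.2° on the benchmark)
than locating the maximum of the nearly flat wedge-mean-versus-angle curve,
which scatters by ±3°. The angular-scan method remains available
(`axis_method="scan"`) and is the automatic fallback when the conic fit is
degenerate (planar wave, or fewer than three independent gradient
directions). A planar wave has no transverse vectors at all; the summary
then raises rather than inventing a CV_T. One inherent property of the
±15° wedge mean on a conical wave is worth knowing: vectors up to 15° off
the slow axis travel up to ~16% faster than CV_T, so the wedge mean
overestimates CV_T by ~4% at AR 2.5 even with exact gradients. This is a
property of the summary statistic itself, not an estimator defect.

**APD** is measured from the activation time to the first crossing of
`peak − level·amplitude` after the peak with linear interpolation; the
default level is 0.8 (APD80) and is configurable, as conventions vary.
Level 0 is degenerate and raises unless `on_zero_level="full"` is set.

## 3. ECIS junctional resistance

Junctional resistance is the unweighted mean over in-band frequencies
(62.5 ≤ f ≤ 4000 Hz inclusive, whatever grid the instrument provides) of
the real impedance at each time point — the quantity itself, not an
equivalent-circuit (Giaever–Keese) inversion, which would estimate a
different parameter. Baseline normalization divides by the mean over a
stated window; attachment deltas are nearest-sample differences over 24 h
by default. Dose–response tables report per-dose mean ± SE over replicate
traces, with SE absent for single replicates.

On the synthetic series the band average inverts the generating model
exactly (the generator's `g(f)` is 1 in band by construction), and with
noise σ per reading the band average of n in-band frequencies has standard
error σ/√n; the 3σ/√n envelope used as a sanity bound is a pointwise bound
that the *maximum* over ~121 time samples can exceed in roughly a quarter
of random runs — the reported `ecis_noise_error_over_bound` is expected to
hover around 1.

## 4. Ultrastructure width profiles

The profile samples trace A every 5 nm of arc length from the GJ-edge
anchor and takes the minimum point-to-polyline distance to trace B —
deliberately not the normal projection, which is unstable where hand-traced
membranes kink; a normal-projection variant would disagree only in regions
of high curvature, and the A→B/B→A asymmetry (`profile_asymmetry`) is
exposed as the QC metric for that. Samples whose nearest point on B is one
of B's endpoints are masked with a warning (B does not span opposite A
there). The perinexal zone is 0 < s ≤ 150 nm at 5 nm steps (30 samples);
both are configurable. Summaries pool profiles to per-heart means first and
compute condition mean ± SE across hearts, because biological n is hearts,
and a heart contributing more images must not dominate the condition mean.

## 5. ECG

Beats are peaks of the rectified 10–40 Hz band-passed signal with a
prominence floor and a 50 ms refractory distance, refined to the raw-signal
extremum within ±10 ms; beats within 10 ms of a pacing stimulus are flagged
paced. The VT rule — ≥3 consecutive non-paced beats, cycle length
< 130 ms — is applied with the cycle-length criterion on *every* interval
in the run (a run's first beat qualifies through the interval to its
successor); a mean-cycle-length mode exists because the rule's boundary
behaviour is a convention. Detection reports maximal runs; a minimum
episode duration (e.g. 1 min) is a reporting filter, not part of detection.
QRS onset/offset are the outermost crossings of 10% of the peak |dV/dt|
within ±80 ms of the R peak; the T-wave end uses the tangent method
(steepest T downslope intersected with the trace-median baseline) inside an
80–250 ms post-R window — bounded below 250 ms so the next beat's QRS at a
300 ms paced cycle length cannot masquerade as a T wave. On a
raised-cosine T bump the tangent method lands ~0.09 of the bump width
before the geometric end; QT values are therefore systematically slightly
short of the template truth, as they are on real ECGs.

## 6. Synthetic-data generators

All generators are deterministic in (config, seed) and store their full
configuration plus per-scene ground truth in a `SceneTruth` JSON record.

**STORM scenes.** Reference clusters are oriented disks (radius
100–200 nm, thickness 40 nm — plaque-like GJ geometry); partners are
random-orientation ellipsoids (semi-axes 40–100 nm). Each partner is placed
along a random direction such that the support points of the two convex
bodies are aligned and separated by exactly the drawn gap, making the
planted hull-to-hull edge distance analytically exact (negative gaps give
genuine interpenetration). Gaps are drawn uniformly on (−100, 600) nm with
a ±75 nm exclusion band around the class boundaries (0 and 200 nm) so
planted labels are unambiguous: the band covers the dilation bias
(2 × 10 nm), voxel quantization (20 nm) and localization-noise extremes
(~3σ√2 ≈ 42 nm) of the measured distance. Pairs sit on a grid with enough
clearance that no partner can fall within the adjacency shell of a foreign
reference; a field too small for the requested pair count is a hard error.
Molecules are uniform draws inside each body plus anisotropic Gaussian
noise (σ_xy 10 nm, σ_z 25 nm), counts Poisson around 600 (reference) and
300 (partner) — densities that keep intra-cluster point spacing well under
the 30 nm clustering radius. A uniform Poisson background (2 µm⁻³) and
TetraSpeck-like fiducials (2 nm localization noise) complete the scene; an
optional rigid misregistration (rotation about z + translation) is applied
to channel B and its fiducials. The 300-pair recovery benchmark uses a
20 × 20 × 4.8 µm field — larger than a single camera field, acceptable for
a synthetic benchmark whose purpose is tight fraction statistics.

**Optical movies.** The wave is kinematic: activation time is the
elliptical travel time `√((u/CV_L)² + (v/CV_T)²)` from the pacing site in
the rotated fast/slow frame; each pixel's trace is a sigmoidal upstroke
(τ 1.5 ms, derivative maximal at the activation time by construction), a
30 ms plateau and exponential repolarization (τ 30 ms), plus white noise
(σ = 5% of amplitude). Defaults: 100 × 100 pixels (a typical mapping
camera), 0.1 mm pixels, 1000 frames/s, CV_L 50 / CV_T 20 cm/s, fast axis
30° — guinea-pig ventricular values.

**ECIS.** `Re Z(f,t) = R_el(f) + R_j(t)·g(f)` with g ≡ 1 on 62.5–4000 Hz
and rolling off as 4000/f above; `Im Z` from a series capacitance. The
default run is 3 h sampled every 90 s (121 points) over a doubling
frequency ladder 62.5…64000 Hz. `R_j(t)` may be a constant, an array or a
callable, so ramps and logistic attachment curves are first-class.

**Membranes.** Trace A is a straight or sinusoidally curved polyline
sampled every 2 nm; B is offset along the local normal by d(s) > 0.
Requested curvature whose offset would self-intersect (separation exceeding
the radius of curvature) is an error. Tracing jitter is applied along the
local normal only — across-membrane error is what hand-tracing produces,
and along-trace jitter would create non-simple polylines at fine sampling.

**ECGs.** Beats are raised-cosine QRS complexes (default 30 ms wide,
1 mV) with a later raised-cosine T wave (100 ms wide, 0.25 mV, centred
160 ms after R — T slopes stay below the 10% QRS-derivative threshold);
paced beats at a 300 ms cycle length are flagged and mirrored as pacing
stimulus times, and an optional run of short-cycle non-paced beats is
inserted. T waves are omitted for beats whose successor arrives before
repolarization would complete, as during rapid runs. Beats closer than the
QRS width are an error. The truth record lists the planted VT runs by
enumerating the rule over the planted beat times, independently of the
detector.

**What the generators do not emulate** — and hence what passing recovery
tests does not establish about real data: photophysics (blinking,
multiple localizations per fluorophore, astigmatic PSF distortion),
antibody linkage error and labelling efficiency; curved or re-entrant
wavefronts, motion artefacts, heterogeneous tissue; electrode micromotion
and well-to-well drift in ECIS; membrane segmentation error upstream of the
digitized polylines; and realistic PVT morphology (the inserted run is a
clean fast rhythm). Parameter recovery here validates the estimators under
the stated noise models, not the upstream measurement physics.

## 7. Problem sizes and tolerances used in the checks

The recovery benchmarks use 300 planted cluster pairs (class agreement
≥ 95%, fractions within 3 points), 100 random cluster pairs for the
brute-force distance oracle (agreement within one 10 nm voxel; the
refinement makes it exact), 100 × 100-pixel movies (CVs within 5%, AR
2.50 ± 5%, axis ± 2°, isotropic AR 1.00 ± 0.05), 121-point impedance
series (ramp exact; noise within the σ/√n envelope), 24 membrane profiles
across 3 hearts per condition (fold change ± 5%), and 1000 random beat
sequences for the VT rule (exact match to exhaustive enumeration). The
whole suite runs in well under a minute of compute beyond the STORM
benchmark (~6 s).

## 8. Known limitations

Voxel volumes carry the half-shell overestimation bias described above;
comparisons between conditions are unaffected (the bias is common), but
absolute volumes of small clusters are inflated. The wedge CV_T bias
(~+4% at AR 2.5) is inherent to the ±15° wedge statistic on elliptical
waves. The tangent-method QT is systematically slightly short of the
geometric repolarization end. The global parabolic surface is retained for
compatibility but should not be used for velocity fields of focally paced
waves. Cluster detection parameters are not estimated from the data; they
are conventions that must be reported with any result.
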