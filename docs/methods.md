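# Methods

This note documents the models, algorithms and numerical choices behind
`filoscaffold`, and what the synthetic benchmarks do and do not
demonstrate about real data.

## Coordinate and unit conventions

Image coordinates: x rightward (columns), y downward (rows), z = 0 at the
glass substrate increasing upward. All lengths are reported in µm, times
in seconds, speeds in nm/s. Defaults when a file carries no calibration:
0.183 µm/px, 0.3 µm z-step, 20 s frame interval. The scaffold reference
axis is the direction of hexagon elongation for elongated structures
(`l<w>L<l>-open/closed` names) and the perpendicular to one hexagon side
for regular ones (`D<d>-...`); orientation angles are axial quantities
folded to [0°, 90°].

## Synthetic data generator

### Filopodia kinematics

A filopodium nucleates at a minimal visible length ℓ₀ (1.2 µm), elongates
at a per-filopodium speed v_e to a peak length, optionally holds a plateau,
retracts at v_r back to ℓ₀, and disappears. Per-filopodium parameters are
drawn independently: v_e ~ truncated normal (45.8 ± 9 nm/s), v_r ~
truncated normal (48.6 ± 9 nm/s), peak excess over ℓ₀ ~ truncated normal
(σ = 1.2 µm, capped so lengths stay ≤ 12 µm), plateau ~ gamma (shape 3).
The piecewise-linear profile is a declared modelling choice; only summary
speeds are constrained by data.

Two ensemble statistics are emergent rather than direct parameters: the
frame-weighted mean length (what a per-frame detector averages — longer
lived filopodia contribute more frames) and the mean lifetime under the
`(death − birth + 1)·Δt` frame-counting convention.
`calibrate_kinematics` therefore solves the mean peak excess and mean
plateau numerically (nested bisection on a common-random-number Monte
Carlo of 4·10⁴ profiles) so that the ensemble hits mean length 3.36 µm
and mean lifetime 233 s. With the speed distributions above the solution
is peak excess ≈ 2.7 µm, plateau ≈ 111 s. The birth rate then follows
from Little's law: 0.037 filopodia per µm of perimeter ÷ mean lifetime.
A closed-form check with zero spread: lifetime = (peak − ℓ₀)(1/v_e +
1/v_r) + plateau, frame-mean length = ℓ₀ + (elongation and retraction
triangles + plateau shelf)/lifetime.

Births are a Poisson process along the islet boundary, started one
warm-up period (several lifetimes) before frame 0 so movies open in the
stationary state; filopodia alive at the first or last frame are exactly
the ones the censoring rules must discard. Birth sites are uniform on
the boundary; directions are uniform within ±45° of the local outward
normal (protrusions radiate away from the membrane; for rotationally
symmetric bodies this still gives uniform axial orientations). A
candidate trajectory is rejected and re-drawn if its fully grown tip
would leave the field or pass within 1.2 µm of any islet body, including
its own — cells obstruct protrusions, and a filament overlapping a body
is not a measurable filopodium. Re-drawing replaces only the site, so
the count and the length/speed distributions are unaffected. With
`orientation_bias` > 0 directions instead concentrate (von Mises) around
the scaffold reference axis, emulating the orientation asymmetry seen on
elongated lattices.

Bases are static: the (+) tip does all the motion. Real filopodia also
translocate their pointed end; (−)-end speed readouts on synthetic data
are therefore near-empty and say nothing about real (−)-end dynamics.

### Islets and rendering

The default field holds three elongated blunt-ended (superellipse,
exponent 4) islets with mild low-order radial waviness, ~70 × 13 µm each,
total perimeter ≈ 480 µm in an 84.5 µm field (256 px at 0.33 µm/px). At
the calibrated density this keeps the live count in the tens per frame.
Perimeter and area ground truth come from the polygon before
rasterization. Filopodia are rendered as Gaussian-profile capsules at
sub-pixel endpoint coordinates (integer-endpoint line drawing would
quantize tip positions and dominate end-speed jitter). Frames are blurred
with a Gaussian PSF (σ 0.45 µm) and degraded with Poisson shot noise
(photon scale 600/unit intensity over background 20) plus Gaussian read
noise (σ 3) — the standard camera model; peak filopodium SNR ≈ 8–10.
Pillar autofluorescence discs can be added (off by default, as for
dye-quenched structures). Identical (config, seed) gives bit-identical
output.

### Nuclei stacks

Nuclei are solid ellipsoids (semi-axes ~4 × 2.5 × 1.8 µm) with random
in-plane angles, placed without xy overlap. An engagement preset fixes
the exact number of engaged nuclei (round(fraction·n)): engaged bottoms
uniform in 0–4 µm (substrate contact side), the rest in 6.2–8.2 µm (top
monolayer above the 7 µm structure). Presets: l7L14-open 62%,
l7L14-closed 2%, D13.5/D10/D8.8/D6.6/D4.5-open 58/78/64/44/6%.

## Nuclei analysis

Segmentation: Gaussian pre-smoothing (σ 0.5 µm), per-stack Otsu
threshold, 3D connected components, optional marker-based watershed on
the anisotropic distance transform, minimum volume 50 µm³. This recipe
is a declared stand-in for the original unpublished segmentation; all
parameters are exposed. Orientation uses only voxels above z = 4 µm (the
monolayer above the structures); the principal axis is the leading
eigenvector of the xy covariance, and nuclei with an eigenvalue ratio
below 1.2 are flagged low-anisotropy and excluded from mean-orientation
claims (round nuclei have no meaningful axis). Bottom-z is the lowest
voxel of the segmented nucleus, accurate to one z-step on clean stacks.

## Filopodia detection

The stages, per frame:

1. **Islets** — Otsu threshold, morphological opening (0.8 µm radius,
   removes thin protrusions), hole filling, small-object removal;
   perimeter by the Crofton estimate. For the *exclusion region* and the
   body model the raw (unopened) foreground is used instead: opening
   shaves convex corners whose halo would otherwise leak into the map.
2. **Flattening** — Anscombe transform (unit shot-noise variance at all
   intensities), then subtraction of a pixelwise-max background: a
   running disk median (exact over straight PSF-blurred edges, blind to
   thin ridges) and a PSF-blurred body-mask model scaled to the islet
   level (correct at convex corners, where the median is too low). Each
   estimator covers the other's failure mode.
3. **Detection map** — multiscale Hessian tubeness (sato, σ ∈ {1, 2, 3}
   px) of the noise-normalized flattened frame. This is the default
   "detection map"; any callable with the same signature (e.g. a trained
   model's probability map) can replace it.
4. **Binary map** — tubeness-seeded hysteresis: pixels above 1.5 noise
   units of tubeness seed components, extended by flattened intensity
   above 3 noise units; clipped outside the dilated body.
5. **Paths** — skeletonize, prune spurs < 3 px, split at junctions,
   rejoin fragments whose end directions are anti-aligned across a
   junction (resolves X crossings and V merges), split paths at sharp
   bends (> 55° over a 3-px window — filopodia are straight, a bend
   marks two fused filaments). Over-wide paths trigger one local
   re-thresholding pass to separate unresolved parallel crests.
6. **Measurements** — base = islet-proximal endpoint; the sub-pixel tip
   is the half-maximum crossing of the intensity profile along the
   terminal direction (three parallel rays averaged), pulled back by
   0.75·σ_PSF for the apparent extension of the diffraction-rounded tip
   cap. Length = geodesic path length + the base gap to the body edge +
   the signed tip refinement. Filters: length ≥ 1 µm, PSF-corrected
   width ≤ 1.5 µm (declared thresholds). Orientation is the folded angle
   of base→tip against the reference axis.

Measured on planted ground truth at the default preset (tip match ≤ 3 px):
per-frame recall ≈ 0.84 and precision ≈ 0.96–0.98 on noisy movies
(recall ≈ 0.92, precision ≈ 0.95 on sparse noise-free fixtures), with
per-detection length bias ≈ 0 ± 0.45 µm. Known blind spots: filopodia
shorter than ~2 µm lose their first/last frames in the exclusion band,
and filaments crossing at shallow angles can swap or fuse. These were
measured against planted truth, never against the reported acceptance
values.

## Tracking

Consecutive frames are linked by exact linear assignment (augmented
square cost matrix) maximizing total mask IoU; pairs below `iou_min`
(0.2) are forbidden and unmatched detections allowed. Ties break toward
smaller centroid displacement, then lower index, via perturbations far
below the IoU quantization (~10⁻⁹), so output is deterministic without
affecting optimality. The pipeline closes single-frame gaps
(`max_gap = 1`): per-frame detection dropout at the preset SNR otherwise
fragments tracks and biases lifetimes down ~40%. `build_tracks` itself
defaults to no gap closing.

Extremities: per frame, the endpoint nearer the **parent** islet
(Euclidean distance transform) is the pointed (−) end — using the union
of all bodies instead would flip the polarity of filopodia growing
toward a neighbouring islet. Labels are stabilized along the track by
majority vote; tracks whose endpoints are equidistant (< 0.5 px) on more
than half their frames are flagged ambiguous.

## Dynamics statistics

Lifetimes use only tracks with both censor flags false,
`(death − birth + 1)·Δt`. For exponential lifetimes in movies 20× the
mean, the exclusion rule's length bias (−5.3% analytically) and the
+1-frame discretization nearly cancel; simulated net bias ≈ −1%.
Track-based statistics ignore tracks shorter than 3 frames: with the
calibrated kinematics, P(true lifetime < 60 s) < 1%, while 1–2-frame
tracks in the detected stream are nearly all transient noise.

End speeds project each endpoint's frame-to-frame displacement on a
track-level axis — the mean (−)→(+) chord over all frames. A per-frame
chord is direction-noisy while the filopodium is short, which
asymmetrically suppresses elongation readouts (retraction moves along
the chord by construction); the track-level axis assumes straight
filaments, which holds for the generator and approximately for real
filopodia. Displacements below the noise floor (`min_step`, default
1 px) are discarded; remaining outward steps pool as elongation, inward
as retraction; per-track mean speeds are averaged per movie, then across
movies (each movie is one observation).

The per-frame normalized number is count / total islet perimeter.
Fraction elongating = per frame, the fraction of live filopodia whose
length grew by more than `min_step` since the previous frame, averaged
over frames.

Kinetic curves are smoothed with a Savitzky–Golay filter (window 21
intervals = 7 min at 20 s; cubic; endpoint windows fitted on truncated
supports, so polynomials up to degree 3 pass through unchanged).
Pre/post-treatment comparisons average fixed 10.3-min windows: control
ending at drug addition (5 min earlier for lifetime curves, whose values
near the interruption are undefined), treated starting 21.3 min after
addition (40 min for slow-acting compounds); windows are right-open.
Significance: Shapiro–Wilk on the paired differences as a normality
flag (reported, never an automatic test switch), then a paired t-test
with df = n − 1. No multiple-testing correction is applied; the report
states this next to the p-values.

## What the benchmarks show — and what they do not

The acceptance experiments demonstrate that the full pipeline recovers
planted dynamics within tolerance under the calibrated conditions:
15 movies, 256×256 px at 0.33 µm/px, 135 frames at 20 s, peak SNR ≈ 10,
straight filopodia on static, well-separated islets. They do not
exercise: moving or dividing cell bodies, curved or branching filopodia,
(−)-end translocation, photobleaching, uneven illumination, pillar
autofluorescence (supported but off by default), or densities far above
~0.04 µm⁻¹ where crossings dominate. Problem sizes were chosen so the
whole suite and the acceptance script each run in minutes on one CPU.
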