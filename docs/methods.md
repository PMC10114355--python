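# Methods

This note documents the models, measurement conventions and parameter
choices behind aggremorph, and what the synthetic data do and do not
establish about real micrographs.

## Synthetic scenes: the growth model

Fractal-shaped aggregates are built from tangent discs ("puncta") of
diameter 0.5 µm, following the observed growth mode in which puncta
dock to each other by diffusion:

* **Stage 1 (linear):** puncta are chained one by one; consecutive bond
  directions wander by a Gaussian angle (sd 0.35 rad), and candidates
  that would touch a non-neighbour are rejected, so the tangency graph
  is exactly a path.
* **Stages 2–3 (cluster–cluster docking):** sub-clusters approach the
  growing cluster by an off-lattice 2-D random walk (step d/4) and
  stick at first contact; the final step is bisected so the contact
  separation equals one diameter within a 1 % tangency tolerance. This
  is a diffusion-limited cluster–cluster aggregation (DLCA) process.
* **Branched study-scale clusters:** pure DLCA at these scales mostly
  extends chain tips (tip screening) and yields few resolvable branch
  points, so the branched-class generator decorates a 4–6-punctum main
  chain with 4–7 short arms: each arm seed docks by the same random
  walk, the contact is accepted only at a punctum that already has two
  neighbours (so the joint is a genuine branch point), and the arm then
  grows 2–3 puncta outward from the landing site — the
  tip-polymerisation behaviour of diffusion-limited growth, where new
  material arrives from outside. Arms that cannot be placed without
  overlap are skipped; class labels are always derived from the
  realised adjacency graph, so an unbranched outcome is labelled
  linear.

Ground truth per cluster: the longest chain is the weighted diameter of
the tangency graph (one diameter per bond plus one diameter for the two
end caps) and branch points are graph nodes of degree ≥ 3.

**Fibrils** are worm-like chains: heading increments are i.i.d.
Gaussian with variance ds/ℓp per arc step ds (persistence length ℓp,
default 50 µm), so the requested arc length is met exactly by
construction. Embedded puncta (0–3) are placed on the backbone.
Study-scale fibril lengths are lognormal with median 27 µm and
log-sd 0.72 (quartiles ≈ 19–50 µm), clipped to 10–60 µm.

The default class mix is 56 % linear / 32 % branched / 12 % fibril,
with linear chains of 2–4 puncta.

## Rendering

Point sources are deposited on the pixel grid by bilinear splatting and
blurred with a Gaussian PSF (σ = 0.12 µm, the diffraction scale of a
0.95-NA objective at ~500 nm; puncta carry an additional d/4 size
term). Fibril backbones carry a line density of photons. Exposure is
`Poisson(photons)·gain + background + N(0, σ_read)` on the 16-bit
camera scale (background 20 a.u., read noise 3 a.u., gain 1); the
renderer raises if the noiseless field would exceed 65535. The ThT
channel is the mCherry channel's noiseless field translated by the
configured chromatic shift and noised independently — both dyes label
the same structures. Default pixel calibration is 0.1625 µm/px (6.5-µm
camera pixel behind 40× optics); this is a configuration value, not a
measured constant.

What the simulator does **not** emulate: out-of-focus light and 3-D
structure, flat-field inhomogeneity, camera fixed-pattern noise,
photobleaching, aggregate motion during exposure, and the 20-nm
sub-punctum texture seen by TEM (rendered only as an optional ribbon
interior). Pipeline accuracy measured on these scenes therefore bounds
segmentation/measurement behaviour under idealised optics; it does not
certify performance on crowded fields or low-SNR real data.

## Skeleton measurements

Masks are thinned with `skimage.morphology.skeletonize`. The skeleton
pixel graph uses 8-connectivity with unit axial and √2 diagonal steps;
a diagonal adjacency is pruned when a shared axial neighbour shortcuts
it, the standard geodesic length estimate. Adjacent junction pixels
(degree ≥ 3) are merged into single junction nodes; edges are the
junction-free pixel walks between nodes, and the total length is the
sum of walk lengths (equal to the sum of pixel-step weights by
construction). The longest chain is the maximum-weight simple path
between endpoint nodes — unique tree paths via Dijkstra on forests,
exhaustive enumeration over the (small) collapsed multigraph otherwise.
A skeleton with no endpoints is a ring: it is flagged and its cycle
circumference is used as both chain and total length.

Two conventions matter downstream:

* **Width** at a chain pixel is `2·EDT − 1 px` (half-pixel convention:
  a 1-px line has width 1 px), averaged along the chain. Widths via the
  distance transform are well defined at junctions and equal the
  perpendicular extent on straight segments.
* **End-cap correction:** thinning retracts each endpoint about half a
  local width inside the object tip, which biases the raw chain length
  ≈ −18 % at the study's punctum scale. The reported longest chain is
  therefore `raw chain + mean width` (no correction for rings, which
  have no tips); on simulated branched clusters this estimator is
  median-unbiased (−0.6 % over 40 clusters). The chain-fraction feature
  f7 uses the uncorrected ratio.

**Punctum counting** uses scale-normalised Laplacian-of-Gaussian blob
detection over punctum radii 0.15–0.5 µm, with an absolute response
threshold of 0.3 on the region's max-normalised crop. Two refinements
make the count robust: overlap pruning is disabled (tangent puncta
overlap heavily, and the pruner would otherwise keep the merged
large-scale blob instead of the pair, with near-coincident multi-scale
hits merged within one minimum blob sigma), and a Hessian
principal-curvature-ratio test at the detection scale rejects
ridge-like responses. Measured ratios: isolated puncta ≈ 1.0, members
of tangent chains ≈ 0.5, fibril tips ≈ 0.25, fibril bodies < 0.1 — the
threshold 0.35 keeps puncta and rejects fibril bodies and tips.

Recovery limits: arms docked onto adjacent puncta (0.5 µm apart, below
the ~0.8 µm blur-limited width) merge into the body, so ~12 % of
simulated branched clusters lose two branch points at once; the branch
estimator is otherwise within ±1.

## Classification

The seven features are standardised column-wise; scale-type features
(chain length, width, width/chain, total intensity) are
log10-transformed first, because fibril lengths span half an order of
magnitude and would otherwise dominate the correlation structure and
make k-means split the fibril class by length instead of separating
morphologies. PCA signs are fixed so each component's
largest-magnitude loading is positive. k-means runs on (PC1, PC2) with
k = 4 and 50 seeded restarts.

Cluster → class resolution: (i) singleton clusters whose member is an
outlier in both PCs (|PC| > 3 sd) or ring-flagged go to the fibril
class (rings arise when a fibril's two ends join); (ii) of the
remaining clusters, the one with greatest median chain length is
fibril; each other cluster is branched when its median branch count is
≥ 1 (branching defines the class), fibril when its median punctum-peak
density is below 0.5 µm⁻¹ (a smooth elongated body rather than a chain
of resolvable puncta — this catches k-means splitting the broad fibril
length distribution), and linear otherwise. Quartiles in the class
summary use linear interpolation (the numpy default).

An optional eighth feature (total skeleton length) is available behind
`include_total_length`; it is off by default.

## Kinetics

Aggregate-bound ThT intensity is the per-frame sum over segmented
aggregates (threshold 250 a.u., > 9 px). The logistic fit uses
least squares with eight t_mid starting points spread over the time
span and bounded parameters; the best converged start wins. Lag is
defined by the max-slope tangent's baseline intercept
(`t_mid − 2/r`) and the plateau at 95 % of amplitude
(`t_mid + ln 19 / r`); the simulator parameterises its traces with the
same tangent convention, so generator and estimator share one
definition. Traces whose fitted amplitude is below 2 % of their level
are reported flat with the lag flagged undefined rather than as an
error. The optional initial monomer peak (a decaying exponential,
τ = 120 min) models the high non-aggregate ThT signal immediately
after mixing dye with monomer.

Study conditions used by the analysis scripts and acceptance run:
24 h sampled every 10 min, three replicates, amplitude 1000 a.u. over
baseline 100 a.u., replicate noise 50 a.u. (5 % of amplitude), growth
rate 0.01 min⁻¹ with lag 300 min unseeded (placing the 95 % plateau at
~794 min) and lag 80 min seeded.

## TEM widths

Negative-stain fibrils are rendered as ribbons whose perpendicular
profile has Gaussian maxima (σ = 2 px) exactly at ±width/2 around the
backbone, plus a faint interior plateau retracted 4σ inside the rim so
it cannot displace the peaks; a sinusoidal twist modulates the local
width. Measurement: the image is resampled along the user-traced
polyline at 1-px arc steps with perpendicular offsets (bilinear), and
per straightened column the width is the separation of the two most
prominent `scipy.signal.find_peaks` maxima with prominence ≥ 10 % of
the column's dynamic range — invariant to intensity scale and offset.
Columns with fewer than two peaks are excluded. Calibration (nm/px) is
a required user input for real data. Recovery on rendered ribbons of
100–1200 nm is within 10 % (exact at 1 nm/px for straight ribbons).

## Registration and background

Channel displacement is estimated per ROI by normalised
cross-correlation of a 16-px moving-channel patch against a ±10-px
reference search region, with parabolic subpixel refinement (skipped
when the peak is an exact integer match) and one warp-and-re-estimate
pass to suppress interpolation bias; the four ROI estimates are
combined by component-wise median for robustness to one structureless
ROI. Residual after correction is ≤ 0.25 px over random subpixel
shifts up to ±4 px. Correction resamples bilinearly and marks invented
border pixels invalid; segmentation ignores them.

Rolling-ball background estimation uses `skimage.restoration.
rolling_ball`; for radii > 40 px it runs on a grid downsampled by
`ceil(radius/40)` and is linearly upsampled back — the accepted
approximation for large balls. Note the intrinsic behaviour on tilted
backgrounds: a plane of slope m leaves a uniform residual ≈ r·m²/2.

## Numerical and degenerate-input choices

* Tangency tolerance 1 % of punctum diameter; docking walks have a
  200 k-step budget and raise on non-convergence.
* "More than 9 pixels" and "beyond 60 a.u." are strict inequalities.
* Single-pixel skeletons floor the chain length at one pixel so
  per-length features stay finite.
* Flat kinetics traces are flagged, not errors; fewer than 10 time
  points is an error.
* All randomness flows from explicit integer seeds; identical seeds
  give bit-identical scenes, traces and tables.

## Problem sizes

The simulated validation uses 50 scenes × 6 aggregates (~300
aggregates) for the classification round trip, 100 noisy traces for
the lag-recovery check, 20 random shifts for registration, and four
ribbon widths for TEM — the scale at which the simulated medians are
stable run to run.

## Known limitations

* Branch counts saturate at the optical resolution: arms closer than
  the blurred width merge (see above).
* The cluster→class mapping assumes the three morphologies are all
  present; on data containing a single class the summary will still
  name three classes and the resolution heuristics may assign
  near-empty classes (an error is raised only for the degenerate
  all-identical case).
* Touching aggregates are not split (no watershed); crowded fields
  will merge objects.
* No rotation/scale/nonlinear registration; translation only.
* TEM fibril tracing is manual by design; no automated ridge tracing.
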