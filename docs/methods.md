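# Methods

This note documents the models, algorithms and numerical choices behind
crowdspot, in the order the pipeline uses them.

## Synthetic spot images (spotimage)

Spots are isotropic 2-D Gaussians `A · exp(−r²/2σ²)` added to a
background of Gaussian noise (mean 100, std 10 by default), optionally
mixed with an equal-power Gaussian-smoothed texture field whose
correlation length is `texture_scale`; the mix is rescaled so the total
standard deviation equals the requested `noise_std`, and intensities
are clipped at zero.

**SNR definition.** SNR ≜ A / σ_bg, where A is the Gaussian amplitude
above the local background offset and σ_bg is the robust standard
deviation (1.4826 × median absolute deviation) of the pixels in the
annulus [4σ, 8σ] around the spot center. The MAD estimator keeps the
background estimate insensitive to neighboring spots that intrude on
the annulus. Measurement fits the Gaussian in a window of half-width
⌈4σ⌉ with the center free within ±2 px. The definition is a ratio, so
it is invariant to rescaling the image.

**Amplitude calibration.** Per spot, a target SNR is drawn from
N(snr_mean, snr_spread²) (clipped at 0.1) and the amplitude is set to
`target · σ_bg` with σ_bg measured on the background *before* any spot
is added, which avoids circularity between rendering and measurement.
On a strictly noiseless background (σ_bg = 0) the amplitude equals the
numeric target so noise-free renders remain usable for σ-fit round
trips. Rendering truncates each Gaussian at 5σ (relative error
< e⁻¹²·⁵).

**Placement.** Spot centers are rejection-sampled uniformly with two
constraints: at least 3σ from every border (so spots render fully and
remain fittable) and pairwise distance ≥ `min_nnd`. A hexagonal-packing
feasibility pre-check rejects impossible configurations immediately;
otherwise sampling aborts with a packing error after 10,000·n
proposals. Defaults (100 spots, SNR 15, σ 1.5, min_nnd 12 px on a
256×256 image) put the synthetic data inside the annotatability
guidelines below; only the uniform-with-minimum-NND spatial law is
implemented.

Image inversion (dark spots on light background) is `max(I) − I`.
Display export rescales linearly to 8-bit between the 0.1 and 99.9
intensity percentiles.

## Simulated annotators (workersim)

No generative model of crowd workers is established in the literature;
this module is an explicit stand-in whose *parameters* are observable
behaviors: a per-image click budget (default 120), SNR-dependent
detection, click jitter, false positives, and merging of close pairs.
Defaults are invented but configurable:

| parameter | default | meaning |
| --- | --- | --- |
| p_detect_midpoint | 5 | SNR at which detection probability is 0.5 |
| p_detect_slope | 1 | logistic steepness in SNR units |
| click_jitter_sigma | 1 px | isotropic Gaussian click error |
| fp_rate | 2 | Poisson mean of uniform false clicks per image |
| click_budget | 120 | hard cap on clicks per worker per image |
| merge_radius_frac | 0.04 | pair-merge radius as a fraction of image width |
| p_merge | 0.6 | probability a close pair collapses to one click |
| p_multiclick | 0.3 | probability of a second click inside a merged pair |

Spots with σ < 1 px have their effective SNR halved (small spots are
disproportionately hard to see). Budget truncation preferentially
keeps spot-derived clicks over false positives, then randomizes order.
Each worker is an independent RNG stream keyed by
`(model.seed XOR crc32(worker_id)) & 0x7fffffff`, so adding workers
never perturbs existing ones and streams are stable across processes.

## Image preparation (imageprep)

**Filtering.** Per z-plane: subtract a Gaussian blur (high-pass,
default σ = 4.5 ≈ 3× the expected spot σ), apply a *negated* Laplacian
(a bright blob has negative curvature at its peak, so negation makes
spot centers positive), rectify negatives to zero; then take the
pixel-wise maximum across planes. Filtering before projection keeps
plane-specific noise from contaminating the projected result.

**LoG detection.** Scale-normalised responses `−σ²·∇²G_σ ∗ I` are
computed on a geometric σ grid; detections are voxels that attain the
maximum of their 3×3×3 (x, y, scale) neighborhood and exceed the
threshold. Overlap pruning is greedy strongest-first: a weaker
detection within √2·σ (of the larger σ) of an accepted one is
suppressed. Because suppression flows only from stronger to weaker
candidates, the detection set at a higher threshold is exactly the
amplitude-filtered subset of the set at a lower threshold — threshold
sweeps therefore reuse one detection pass. Pruning work is bounded by
keeping at most the 10,000 strongest candidates.

**Annotatability guidelines.** A displayed sub-image is annotatable
when it has at most 100 spots and no pair of spots closer (after
upscaling to the display width D) than 4% of D — the radius of the
click marker at the annotation interface obscures closer neighbors.
Since a crop of width w is upscaled by D/w, the displayed-spacing rule
reduces to `nnd ≥ 0.04·w` independent of D. Spot SNR should be ≥ 10
and mean NND between 12 and 15 px for reliable annotation; the
synthetic defaults respect these targets.

**Crowded regions and subdivision.** Spots whose nearest neighbor is
closer than `target_nnd_hi` (15 px) are grouped by single linkage at
that radius; each group's bounding box is padded by 2×`target_nnd_hi`.
A non-compliant region is split into the 2×2 quadrants of its spots'
padded bounding box with a 10% overlap margin (overlap prevents losing
boundary spots; deduplication handles the duplicates), recursing to
`max_depth` (4). Leaves that still violate the guidelines — including
spots at identical coordinates, which no amount of zooming separates —
are flagged `saturated` rather than recursed forever.

**Coordinate mapping.** Crops record offset (x0, y0) and scale
(displayed px per parent px); `parent = displayed/scale + (x0, y0)` is
an exact arithmetic inverse. Reassembly maps per-crop points to the
parent frame and repeatedly collapses single-linkage groups within
`dedup_radius` to their means until no pair of representatives is
closer than the radius.

## Annotation QC (annoqc)

**Clustering.** Clicks are clustered by affinity propagation
(similarity = −squared Euclidean distance, damping 0.9, max 400
iterations, random_state fixed). For scalability and determinism the
clicks are first partitioned into spatial connected components at
`partition_radius` (6 px, below any sensible spot spacing but above
the click-jitter spread) and AP runs per component. The exemplar
preference is `−(n · median pairwise d²)` of the component: AP trades
summed within-cluster distances against one preference per exemplar,
and the conventional median-similarity preference (≈ −4σ_j² for a
single spot's n jittered clicks) is cheaper than the ~n·σ_j² saving
from splitting, so it fragments coherent blobs; scaling by n makes
splitting a single blob unprofitable at any jitter scale while leaving
genuinely multi-spot clumps — whose split saving grows with the
squared spot separation — intact for the declumping stage, which is
where the pipeline resolves them. `preference='median'` and
`partition_radius=None` restore the conventional global behavior. A
non-converged component falls back to single-linkage clustering at
3 px with a logged warning, so batch runs never abort.

**Size thresholding.** Cluster sizes (annotation counts) are split by
exact 1-D 2-means — in one dimension the optimum is a split of the
sorted values, found by exhaustive scan, which avoids the poor local
optima that seeded Lloyd iterations hit when a few clumped clusters
sit above the main mode. The threshold is the midpoint of the two
centers; clusters at or above it are kept. Removal fires only when the
size distribution is genuinely bimodal (low center < 0.5 × high
center): a clean unimodal distribution must not lose its main mode.
Removal is monotone: every removed cluster is no larger than any kept
one.

**Clump detection.** For each cluster, `multi_frac` is the fraction of
its unique workers contributing more than one click — workers who
resolve two merged spots click twice inside the cluster. The
multi_frac values are histogrammed (10 bins over [0, 1], counts not
densities); scanning rightward from the modal bin, the largest
positive first-difference marks the clump tail, and its bin's left
edge is the threshold. Clusters at or above the threshold (the
threshold bin itself belongs to the tail) are routed to declumping;
with no rise beyond the mode nothing is flagged.

**Declumping.** Flagged clusters are split by deterministic 2-D
k-means (k = 2 by default, matching the dominant merged-pair case):
the first center is the point farthest from the centroid, subsequent
centers maximise the minimum distance to chosen centers, then Lloyd
iterations run to convergence. Children inherit the parent's members
and are marked `origin="declumped"`.

**Order.** cluster → size-threshold → clump-detect → declump.
Removing false positives before declumping means declumping can only
add back true detections, preserving recall on the kept set.

`qc_confusion` scores a removal decision against synthetic truth: a
cluster is *correct* when its centroid claims an unclaimed true spot
within the correctness radius (greedy nearest assignment); sensitivity
is the fraction of incorrect clusters removed, specificity the
fraction of correct clusters kept (each reported as 1.0 when its
denominator is empty).

## Detector tuning (tuning)

**σ fitting.** `offset + A·exp(−r²/2σ²)` is fitted by bounded
least-squares in a window of half-width 6 (center free within ±2 px,
σ ∈ [0.3, 4·halfwidth]). A flat window or failed fit returns a flagged
record with σ from second moments.

**Parameter extraction.** Per annotated point a σ is fitted; the
detector's range is [0.9·min σ (floored at 0.5), 1.1·max σ] — the ±10%
guard compensates for annotations marking centers, not extents. The
LoG intensity threshold is chosen from a 50-point geometric grid over
the response range to maximise precision × recall against the
annotations, ties broken toward the larger threshold (missing a spot
is preferred to detecting a spurious one).

**Local-max peak finder.** Candidate cutoffs are a 100-point linear
grid over the local-maximum intensity range; the peak-count-vs-cutoff
staircase has a longest run of constant count (the stable plateau)
whose start is the base cutoff; integer stringency s selects the
cutoff s distinct count-levels further down the staircase, clamping
(with a warning) past the end. This plateau mechanism is a
scale-invariant reconstruction of the "stringency raises the intensity
cutoff" behavior of local-max peak finders in spot-calling libraries,
not a clone of any particular implementation. Detection count is
non-increasing in stringency by construction.

**Stringency tuning and training curves.** `tune_stringency` sweeps a
grid, records precision/recall per value and returns the
precision × recall argmax (ties toward higher stringency).
`training_curve` repeats parameter extraction on random ground-truth
subsets (without replacement) and evaluates against the full truth;
a subset equal to the full set is evaluated once since extraction is
deterministic.

## Evaluation (evalmetrics)

Matching is one-to-one and greedy: candidate pairs within the
correctness threshold (default 4 px) are visited by ascending distance
(ties by index, making the result stable under input order) and
accepted when both endpoints are unclaimed. TP/FP/FN follow;
precision is defined as 1.0 for empty predictions with empty truth and
0.0 when there are no true positives but truth exists; recall is 1.0
for empty truth. An optimal maximum-cardinality bipartite matcher is
provided alongside and serves as the test oracle; greedy matching is a
1/2-approximation in general but provably optimal when true spots are
separated by more than twice the threshold (each prediction is then
adjacent to at most one truth), which is the regime the validation
suites use.

## What the synthetic studies do and do not show

The worker simulator reproduces the *mechanisms* of crowd noise
(misses, jitter, false positives, merging, budgets) with invented
parameters; it does not reproduce any real crowd's rates, worker
correlation, fatigue, or payment effects. Passing QC suites on
simulated crowds therefore demonstrates that the pipeline's rules
behave correctly against the failure modes they target — low-support
clusters are removed without touching true ones, clumps are detected
and split, precision/recall move in the right direction — not that any
particular precision or recall will be attained on a real
crowdsourcing service. Likewise the synthetic images are flat-noise
fields with isotropic Gaussian spots: no autofluorescence structure,
anisotropic PSFs, or z-blur.

## Problem sizes and determinism

The validation suites use 256–512 px images, 50–200 spots, 25 workers,
20–50 seeded replicates per study — large enough for stable rates
while keeping the full suite to a few minutes on one CPU. Every
stochastic component takes an explicit integer seed; identical
configurations reproduce bit-identical images, annotation sets and
consensus tables.

## Known limitations

- Affinity propagation's preference rule is this package's own
  (documented above); the conventional median preference is available
  but under- or over-clusters redundant click data at realistic
  densities.
- Declumping uses a fixed k (default 2); clumps of three or more spots
  are only partially resolved unless k is raised.
- The stringency knob's numeric meaning is the plateau-step
  reconstruction described above; other implementations' integer
  stringencies need not coincide.
- Physical units are not modelled; all distances are pixels.
- Multi-channel registration and illumination correction are out of
  scope for the preparation step.
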