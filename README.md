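# crowdspot

Crowd-annotation tooling for fluorescence spot images: simulate
single-molecule-style spot images and the annotators who click on them,
prepare real images for point annotation, merge redundant clicks into
consensus spot locations, and use those consensus (or expert)
annotations to tune and validate spot-calling detectors.

## The problem

Imaging-based transcriptomics (smFISH, in situ sequencing) produces
images in which each RNA molecule appears as a diffraction-limited
bright spot. Detecting the sub-pixel centers of those spots ("spot
calling") requires ground-truth annotations to tune detector parameters
and to measure precision and recall — but expert annotation is slow,
and crowdsourced annotation is noisy: workers miss faint spots, jitter
their clicks, invent false positives, merge adjacent spots into one
click, and stop clicking after a per-image budget (empirically about
120 clicks; at ~25 spots per cell that bounds one worker to about
`120 / 25 = 4.8` cells per image).

crowdspot implements the full workflow around those realities:

- **spotimage** — synthetic images with controlled spot size σ, count,
  minimum nearest-neighbor distance (NND) and signal-to-noise ratio,
  where SNR ≜ A / σ_bg: the spot's Gaussian amplitude A above local
  background over the robust (MAD-based) background standard deviation.
- **workersim** — simulated annotators: detection probability logistic
  in SNR, Gaussian click jitter, Poisson false positives, a click
  budget, and merging of spot pairs closer than 4% of the image width.
- **imageprep** — Gaussian high-pass + Laplacian + max z-projection
  filtering, first-pass multi-scale Laplacian-of-Gaussian (LoG)
  detection, crowded-region finding, and recursive subdivision into
  crops that satisfy annotatability guidelines (≤ 100 spots per crop,
  no displayed pair closer than 4% of the displayed width), with exact
  crop↔parent coordinate mapping.
- **annoqc** — affinity-propagation clustering of clicks, removal of
  low-support clusters (1-D 2-means split of cluster sizes), detection
  of "clumpy" clusters via the fraction of workers clicking more than
  once, and 2-D k-means declumping.
- **tuning** — Gaussian σ fitting at annotated spots, LoG parameter
  extraction (threshold chosen to maximise precision × recall),
  a stringency-controlled local-max peak finder, and training curves
  over ground-truth subset size.
- **evalmetrics** — one-to-one point matching under a correctness
  radius; precision = TP/(TP+FP), recall = TP/(TP+FN), Jaccard =
  TP/(TP+FP+FN); NND statistics and worker-performance tables.

## Worked example

`examples/02_crowd_qc_consensus.py` simulates 25 annotators on a
100-spot SNR-15 image and runs the QC pipeline:

```
2541 clicks from 25 workers on 100 spots
clusters: 125, removed by size threshold: 27
size threshold: 13.3 annotations
consensus vs truth: precision 1.000, recall 1.000, Jaccard 1.000
```

2,541 raw clicks form 125 clusters: 100 well-supported ones (one per
true spot, ~25 clicks each) and 27 stray low-support clusters from
false-positive clicks (two stray clicks joined true-spot clusters). The
size threshold found by the 1-D 2-means split (13.3 annotations)
removes exactly the stray clusters, so the consensus centroids match
the true spot locations perfectly at the default 4 px correctness
radius.

The other example scripts each exercise one capability — simulator
fidelity, crop subdivision and exact reassembly, detector parameter
extraction with held-out validation, and the stringency sweep /
training-curve studies. Each is a short narrative script:

```sh
python examples/01_simulate_image.py
```

A thin CLI mirrors the library (`crowdspot simulate-image`,
`simulate-workers`, `prep`, `qc`, `extract-params`, `tune`, `evaluate`,
`run`); `crowdspot run --config pipeline.yaml` executes the whole
simulate → prepare → annotate → QC → reassemble → tune → evaluate
pipeline and writes a reproducible manifest.

## Coordinate conventions

All point tables use 0-based pixel coordinates with x = column
(rightward) and y = row (downward), pixel centers at integers.
Annotation CSVs follow the `annotation_id,worker_id,image_id,x,y`
schema; other dialects can be mapped with
`crowdspot.register_dialect`.
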