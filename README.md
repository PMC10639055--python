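# rloopkit

Quantitative analysis of live-cell R-loop imaging: wavelet-based 3D foci
detection, FRAP normalization and recovery kinetics, telomere
above-background scoring, single-locus intensity tracking, and the
statistics that go with them — plus a synthetic-microscopy generator with
ground truth so the whole pipeline is testable without raw microscope data.

## Who this is for

R-loops (three-stranded RNA:DNA hybrid structures formed mostly during
transcription) can now be imaged in live cells with genetically encoded
hybrid-binding sensors. A typical experiment produces multi-channel 3D
confocal z-stacks and time-lapses in which the sensor forms discrete
nuclear foci over a diffuse background. This package implements the
downstream quantification for such experiments:

* **Foci detection and counting** — undecimated à-trous (B3-spline)
  wavelet decomposition of each z-slice, per-scale robust thresholds,
  intersection across scales, 26-connected 3D grouping, a 2–50 voxel size
  filter and centroid-based restriction to a nuclear polygon ROI.
* **FRAP kinetics** — the per-frame measurement triple (bleach ROI,
  extracellular background, whole-nucleus reference), double
  normalization with acquisition-photobleaching correction, model-free
  t50/t80 readouts, plateaus, fast/slow population classification and
  fold-over-diffusion ratios.
* **Telomere scoring** — 3D segmentation of a telomere-marker channel and
  the fraction of telomeres whose mean sensor intensity exceeds the
  cell's diffuse background.
* **Locus tracking** — center-of-intensity tracking of a marker-labelled
  gene locus with locally background-subtracted sensor readout, burst
  cycle detection and treatment-response testing.
* **Statistics** — Mann–Whitney U (exact for small tie-free samples),
  paired and Welch two-sample t-tests, `*`/`**`/`***` significance marks
  and box-plot summary tables.

## The core quantities

FRAP curves are normalized so that the pre-bleach mean is 1 and the first
post-bleach value 0, after background subtraction and reference
correction:

    b(t) = roi(t) − bg(t)            ROI signal over background
    r(t) = ref(t) − bg(t)            reference (whole nucleus minus ROI)
    x(t) = b(t) · mean_pre(r) / r(t) acquisition-bleaching correction
    N(t) = (x(t) − x(t₀⁺)) / (mean_pre(x) − x(t₀⁺))

Recovery times t50 and t80 are the first times after the bleach at which
N(t) reaches 0.5 and 0.8 of the pre-bleach level (linear interpolation
between frames, no model fit). A population is *fast* if t80 is reached
within the short-protocol window (36 s by default), otherwise *slow*.
The diffusion-corrected turnover of a bound population is its recovery
time divided by the mean recovery time of freely diffusing / binding-dead
control molecules ("fold over reference").

Spot detection thresholds the wavelet detail planes d_j at

    τ_j = (100 / s_j) · 3 · MAD(d_j) / 0.6745

where s_j is the per-scale sensitivity (defaults: scale 2 → 60,
scale 3 → 130; scale 1 disabled), so sensitivity 100 corresponds to a
3σ-equivalent robust threshold and larger values keep more voxels.

## Worked example

```
$ python examples/frap_kinetics.py
fast population: t50 = 3.50 s, t80 = 8.15 s, plateau = 1.00, classified fast
slow population: t50 = 12.20 s, t80 = never, plateau = 0.64, classified slow
fast telomeric fold over mutants (t80): 3.6
```

Two simulated photobleaching experiments mimic the two telomeric R-loop
populations: the fast one recovers 80% of its fluorescence in ~8 s and is
classified fast; the slow one plateaus at ~0.65 and never reaches 80%,
so its t80 is reported as `never` and it is classified slow. The fold of
3.6 (8.1 s over the 2.25 s mean of the two binding-dead mutants) says the
fast population dwells on its target several times longer than free
diffusion alone would explain.

The other scripts in `examples/` cover foci detection against ground
truth, telomere scoring (`fraction above background: 0.32` on a cell
with 32 of 100 telomeres marked), locus burst detection (13 bursts at a
45 s period recovered from a 10-minute time-lapse) and condition
comparisons with the Mann–Whitney test.

A command-line interface mirrors the library:

```
rloopkit simulate-scene --seed 1 --out-dir run/
rloopkit detect-spots --in run/scene.tif --rois run/scene_rois.yaml --out-dir run/
rloopkit frap-analyze --in movie.tif --rois rois.yaml --n-pre 5 --out-dir run/
```

Each subcommand writes CSV tables plus a JSON sidecar echoing its
parameters.

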