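# Methods

This note records the models, parameter choices and numerical decisions
behind `rloopkit`, and what the synthetic-data tests do and do not show
about real microscopy data.

## Image model and conventions

Voxel indices are 0-based; `(x, y)` are column/row pixel centers; axis
labels are a subset of `(t, c, z, y, x)` kept in that order. Physical
units are micrometres and seconds everywhere; conversions happen only at
I/O boundaries. Acquisition defaults follow a spinning-disk/confocal
setup with a 100× objective: 0.16 µm pixels in the sample plane (a
config default, not a constant — it is inferred from the objective and
camera, not directly measured), 0.32 µm z-steps, and 0.3 s frame
intervals for the short FRAP protocol (5 pre-bleach + 120 post-bleach
frames; the long protocol is 2 s × 63 frames). ROIs are stored in a
package-defined YAML format because hand-drawn vendor ROIs are not
reproducible; polygons must be simple, circles carry the 25-pixel
default bleach diameter.

## Spot detection

Each z-slice is decomposed with the undecimated à-trous transform
(B3-spline kernel (1,4,6,4,1)/16, holes doubling per scale, mirror
boundary); detail plane j is the difference of successive smooths, so
`Σ details + residual = input` holds to machine precision. A voxel is
retained iff its detail coefficient exceeds the scale threshold at
*every* enabled scale (defaults: scale 2 at sensitivity 60, scale 3 at
130, scale 1 disabled — single-pixel structures are noise) *and* the
voxel is brighter than the residual smooth (the local background
estimate). Retained voxels are grouped 26-connected in 3D (anisotropic
voxels make diagonal z-contact common), filtered to 2–50 voxels, and a
spot is kept only if its intensity-weighted centroid lies inside the
nuclear polygon and z-range.

Numerical decisions:

* **Sensitivity mapping.** The sensitivity values are UI-style numbers
  with no published closed form; here `τ_j = (100/s_j)·3·MAD/0.6745`, so
  sensitivity 100 is a 3σ-equivalent robust threshold and larger values
  are more permissive. The raw defaults 60/130 are honoured under this
  mapping and both the mapping and the values sit in config.
* **Degenerate (noise-free) planes.** When a detail plane's MAD is
  exactly zero the mapping would give τ = 0 and mark every positive
  coefficient; the threshold then falls back to 0.1 × the largest detail
  amplitude, keeping only the cores of genuine structures. Real data
  never hits this branch.
* **Support positivity.** Requiring `voxel > residual smooth` keeps an
  isolated hot pixel a one-voxel component (removed by the minimum-size
  filter, consistent with scale 1 being disabled) and trims noise
  support around real foci.
* **Size filter in 3D.** Whether the original interactive tool filtered
  sizes per slice or per 3D component is ambiguous; 3D-component
  filtering is used here and exposed in config.
* **Border components** are retained by default (`exclude_border` flag
  available).

Per-nucleus foci counting (the DNA-damage-marker variant) segments
nuclei on the nuclear-stain maximum-intensity projection (global Otsu,
hole filling, minimum area 200 px) and counts per-nucleus foci whose
area strictly exceeds 3 px after a per-nucleus Otsu threshold.

## FRAP

The measurement triple per frame: mean bleach-ROI intensity, mean
extracellular background, and mean of the labelled nucleus excluding
the bleach ROI. Double normalization divides out the reference decay
(compensating continuous-imaging photobleaching) and anchors the curve
at pre-bleach mean 1 / first post-bleach 0; both anchors are exact by
construction on every input. For a generator experiment with per-frame
multiplicative acquisition decay the correction cancels the decay
exactly (error at machine precision, asserted at ≤1e−6).

t50/t80 are read from the curve by linear interpolation, not fitted;
thresholds are relative to the pre-bleach level 1.0, never the plateau.
A crossing must be confirmed by the following frame also sitting at or
above the fraction, which suppresses single-frame noise spikes; an
optional centered moving-average smoothing (window 3) exists but is off
by default. The plateau is the mean of the last 10 post-bleach frames.
Population labels: fast iff t80 is defined and ≤ 36 s (the
short-protocol observation window); curves that plateau below 0.8 are
slow by construction. The fold-over-reference of a population is its
recovery time divided by the arithmetic mean of the reference
(diffusion-limited) times; for telomeric populations the reference is
the mean of the two binding-dead mutants (2.4, 2.1 s at 80%; 0.6, 0.6 s
at 50%), for nucleolar foci the diffuse nucleolar molecules — the
unique simple convention that reproduces all six published fold values
(16.875, 12.5, 3.6, 17.78, 2.5, 6.67). Display rounding is half-up at
the printed precision; comparisons use full precision.

Frame registration is translation-only integer-pixel cross-correlation
against the first pre-bleach frame (sub-pixel alignment is unnecessary
for ROI means); constant frames get zero shift with a warning and the
search radius bounds the shift on degenerate input. Wherever a
"two-sample t-test" is called for, the Welch (unequal-variance) form is
used; the pointwise curve-comparison test reports a two-sided Welch p
per time point, with p = 1 at frames where both groups are constant and
equal.

## Telomere scoring and locus tracking

Telomeres are segmented by the same wavelet detector on the marker
channel, keeping voxel sets. Each object's mean sensor intensity is
compared to the diffuse nucleoplasmic background of the same cell; the
criterion is `mean > bg_mean + 2·bg_sd` with the factor exposed as
`k_sd`. Strict mean-exceedance would mislabel ~half of null telomeres;
at k_sd = 2 the null expectation is bounded by the one-sided Gaussian
tail (~2.3%) and in practice far lower because object means average
~20–40 voxels.

The locus tracker uses a background-subtracted intensity-weighted 3D
centroid (center of intensity) inside a search box around the previous
position — a deliberate simplification of Gaussian spot fitting,
adequate for ROI-mean readouts. The centroid weights clip at
`median + 3·MAD` of the box; without this cutoff the clipped shot-noise
floor biases the centroid toward the box center and the tracker lags a
drifting spot. Sensor intensity is the mean in a 3-px sphere at the
tracked position minus the median of a 2–4 px surrounding shell (the
shell absorbs slow photobleaching). If the marker vanishes the position
carries forward and the frame is flagged. Fluctuation cycles: centered
moving-average smoothing (edge-preserving), peaks with prominence ≥ 1
series-SD, median inter-peak interval as the period (`None` below two
peaks).

## Statistics

Mann–Whitney U uses midranks; the two-sided p is exact (full
enumeration) when the smaller sample has ≤ 8 values and there are no
ties, and otherwise the tie-corrected normal approximation with
continuity correction; the chosen path is recorded in the result. The
paired t-test reports t = 0, p = 1 for all-zero differences and flags
identical nonzero differences as degenerate (p → 0). All tests are
two-sided. Quartiles use linear interpolation (type 7). Significance
marks use strict inequalities at 0.05/0.01/0.001. No multiple-testing
correction is applied across p-value curves.

## The synthetic generators

The generators define the conditions every test runs under; expected
values always come from their ground-truth records, never from the
rendered images.

* **Nuclear scenes** (default 14×128×128 voxels — a scaled-down version
  of the 30–40 × 512 × 512 acquisition stacks, chosen to keep the test
  suite fast while leaving foci, nucleus and background at realistic
  relative scales): extranuclear background 10 photons, diffuse
  nucleoplasm 100, optional nucleolar regions at 150, foci as
  anisotropic Gaussians (σ 0.11 µm lateral / 0.3 µm axial) of
  1500–4000 total photons (peak SNR ≈ 14–57 against the shot noise of
  the diffuse level). Foci are placed ≥ 10 px inside the nuclear
  envelope and ≥ 7 voxels apart — discrete, well-separated foci as seen
  in sensor images. The envelope is softened by a 1-px Gaussian: a hard
  polygon step is unphysical and produces wavelet edge artifacts that
  real confocal data do not show.
* **Camera noise** is fixed as Poisson → additive Gaussian read noise →
  gain → integer quantisation, so means and variances of every readout
  have closed forms (used directly by the statistical assertions).
* **FRAP experiments** model recovery as a sum of exponentials
  (reaction-dominated binding), `R(t) = Σ f_i(1−e^{−k_i t}) / (Σf_i +
  f_imm)`, with a bleach depth, per-frame acquisition decay applied
  consistently to ROI and reference, and ROI-mean noise via the normal
  approximation of the averaged noise chain. Spatial diffusion is not
  modelled: the readouts are times-to-fraction and plateaus, which a
  multi-exponential reproduces. Presets mirror the two telomeric
  populations (fast: single k = ln5/8.1 s⁻¹; slow: 0.65 mobile at
  0.12 s⁻¹ + 0.35 immobile).
* **Locus time-lapses** drive the sensor amplitude with square on/off
  bursts (one per period, phase-shifted half a period so no burst
  straddles the first frame; exactly ⌊T/period⌋ bursts are emitted). A
  DRB-style block decays the amplitude exponentially with τ = 6 min, so
  the signal sits at background within ~30 min as observed for
  transcription inhibition.
* **Telomere scenes** place 100 marker foci on a flat marker background
  and add sensor accumulation at a chosen subset at a chosen contrast
  over the diffuse level; the background ROI is a reserved focus-free
  nucleoplasmic patch.

What passing tests show — and do not. The generators reproduce the
statistical structure the algorithms rely on (PSF-scale foci over
diffuse backgrounds, Poisson-dominated noise, multiplicative
acquisition decay, burst-like locus signals). They do not emulate cell
motion beyond translation, chromatic shift, nucleolar exclusion
patterns, clustered or overlapping foci, fluorophore blinking, or
depth-dependent aberrations; detector scores on real data will be lower
than the ≥ 95% recall/precision measured here, and the FRAP recovery
accuracy assumes the reference region tracks the true acquisition
decay.

## Known limitations

Single-locus tracking only (no multi-particle linking); no deconvolution
before detection; no spatial FRAP (diffusion-reaction) model; stacks
must fit in memory; TIFF metadata round-trips only through this
package's own shaped-metadata convention, with an `axes_hint` escape
hatch for foreign files.
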