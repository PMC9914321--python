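# Methods

## Model and procedure

The toolkit implements a three-stage contrast-elevation pipeline for
single-channel breast images:

1. **Normalization.** Pixels are mapped from the display range
   [L_min, L_max] (default [0, 255]) to [0, 1] by a linear map; the
   bounds travel with the image so the map is undone exactly. All
   arithmetic is floating point; quantization to 8 bits happens only
   when a file is written (round-half-up).

2. **Sigmoid enhancement.** The gray-level mapping
   s(r) = α + (β − α)/(1 + exp(−(r − γ)/δ)) stretches mid-tone contrast
   and compresses the extremes. With the reference constants
   (α = 0.9642, β = 8.594·10⁻⁴, γ = 0.4962, δ = 0.07598) the curve is
   strictly decreasing — an inverting stretch. The code evaluates the
   formula exactly as stated and offers `inverted()` as an explicit
   escape hatch rather than silently reordering α and β. Output is
   clamped to [0, 1]; with the reference constants the clamp is inert
   (range ≈ (0.0021, 0.9628)), but tuned constants at the bound corners
   (α = 1, β = 0) touch it.

3. **Wavelet fusion.** The original and enhanced images are decomposed
   with a one-level separable 2-D DWT, corresponding sub-band
   coefficients merged with the elementwise maximum, and the result
   reconstructed by the inverse transform and clamped to the display
   range. Selecting the stronger coefficient from either source retains
   the salient structure of both — the enhancement's contrast gain and
   the original's fine features.

## Local (tiled) application

"Local" application divides the image into a k×k *grid* of tiles (ceil
division at the edges), not tiles of k×k pixels; grid semantics keeps
the tile count independent of image size, matching adaptive-histogram
conventions. Each tile is renormalized to [0, 1] (its own min → 0,
max → 1), transformed, and mapped back to its original span; a constant
tile passes through untouched. Tile renormalization is a switchable
flag: without it the sigmoid acts on the raw normalized values per tile.
With blending on (default), each pixel's output is the bilinear
interpolation of the mappings of its four nearest tiles — the standard
seam-suppression scheme — with clamped extrapolation at the borders.
Defaults: k = 8, renormalize on, blend on.

## Swarm optimizer

A canonical global-best PSO tunes (α, β); γ and δ stay fixed. The
velocity rule is v′ = w·v + c₁r₁(xBest − x) + c₂r₂(gBest − x) with
r₁, r₂ drawn uniformly per component per iteration, followed by the
unit-time-step position update x′ = x + v′. Settings:

| parameter | default | notes |
|---|---|---|
| swarm size | 30 | reference operating point |
| iterations | 10 | plus the initialization evaluation (trace length 11) |
| w | 0.7 | convergent inertia |
| c₁, c₂ | 1.5 | cognitive/social weights |
| α bounds | [0.5, 1.0] | search box |
| β bounds | [0.0, 0.5] | keeps β < α, preserving the printed orientation |
| v_max | 0.2 × bound width | per-component velocity cap |

Velocities start at zero; positions are clipped into the box with
absorbing walls (a clipped component's velocity is zeroed). One elitist
particle starts at the reference constants so the tuned fitness can
never fall below the untuned one; the flag is on by default. The
fitness is the EME of the enhanced, denormalized image using the
configured application mode (tiled, blended, k = 8 by default). gBest
updates greedily, so its trace is non-decreasing by construction, and
the whole run is reproducible from the seed. On smooth low-contrast
inputs the EME landscape is monotone toward the widest sigmoid span, so
the swarm typically converges to the corner (α, β) = (1, 0); fitness is
evaluated, never assumed, and the elitist guarantee holds regardless.

## Metrics

* **EME** — mean over non-overlapping 3×3 blocks of
  20·log10(I_max/I_min). Log base 10, the decibel convention. I_min is
  floored at ε = 1 (8-bit units) to keep the ratio finite; a block whose
  I_max is below ε contributes 0. Trailing partial blocks are dropped,
  not padded — padding would fabricate contrast at the borders.
* **AMBE** — |mean(reference) − mean(processed)|; the reference is
  always the original source image, including for fused outputs.
* **Entropy** — Shannon entropy in bits of the 256-bin histogram after
  rounding to the integer grid (so values reflect the image as an 8-bit
  display would render it).
* **SD** — population standard deviation (divide by N).
* **IQI** — the Wang–Bovik universal index
  Q = 4σ_xy·x̄·ȳ / ((σ_x² + σ_y²)(x̄² + ȳ²)), averaged over 8×8 sliding
  windows at stride 1; windows with zero denominator are skipped; a
  fully constant pair is an error (the index is undefined).
* All metrics operate on the raw 0–255 scale; computing them on [0, 1]
  data would rescale EME/SD/AMBE.

## Wavelet choices

Default wavelet haar (hand-checkable fixtures), with any PyWavelets
family selectable (db2/db4/sym4 covered by tests); decomposition level 1
(one AC/DC split), configurable — deeper decompositions keep the finer
detail triples so reconstruction stays exact. Boundary extension is
symmetric half-sample padding, the least artifact-prone for images; the
inverse transform is cropped back to the input shape (odd sizes
overshoot by one pixel per side). The literal elementwise max is the
default fusion rule on every band; because a plain max on signed detail
coefficients discards negative edges, an `abs_max` mode (larger
magnitude wins, sign kept, LL still plain max) is provided but not
default.

## Phantom generator

The phantom emulates the acquisition features the pipeline targets:
a smooth tissue background (Gaussian white noise low-pass filtered at a
correlation length of 12 px, rescaled to a ±10 intensity swing around
level 120), Gaussian-profile lesion blobs (default 3, peak +25, radii
6–14 px), 1–3 px microcalcification specks (default 8, +80), and i.i.d.
Gaussian pixel noise (σ = 3), clamped to [0, 255]. The `low_contrast`
preset narrows everything into roughly [90, 140] (swing ±4, lesions +10,
specks +20, σ = 1.5) to imitate poorly acquired, low-entropy screening
images. Generation is bitwise-reproducible from the seed, and the
ground truth (lesion centres/radii, speck coordinates) is returned as an
annotation.

What the phantom does **not** model: breast anatomy (ducts, vasculature,
skin line, pectoral muscle), X-ray physics (scatter, beam hardening,
detector response), compression artifacts, or labels/markers present in
clinical files. Passing tests therefore demonstrate the pipeline's
algorithmic correctness and its contrast-elevation direction on
low-contrast inputs, not clinical image quality.

## Numerical choices and degenerate inputs

* Tolerances: normalize/denormalize round trip 1e−9 per pixel; wavelet
  perfect reconstruction 1e−8; sigmoid identities 1e−12; metric oracles
  1e−10.
* Constant images: EME and entropy are exactly 0, the sigmoid tile map
  passes constants through, PSO fitness is 0 for every candidate, and
  IQI raises an undefined-metric error for a fully constant pair.
* Blended tiling accumulates four weighted mappings whose weights sum
  to 1 up to float round-off; a constant image can therefore come back
  with ~1e−16 ripple.
* Problem sizes in the test-suite and the acceptance script (32–128 px
  phantoms, swarm 30, 10 iterations) are chosen so the full suite runs
  in well under a minute of compute per module while exercising every
  code path at the reference operating point.

## Known limitations

* The decreasing orientation of the reference constants means enhanced
  images are intensity-inverted relative to the source; IQI against the
  original is then negative. Whether this inversion is intended or a
  typo in the constants cannot be settled from the formula alone, so
  the toolkit implements it literally and exposes `inverted()`.
* Tables of per-image clinical scores cannot be reproduced without the
  original database images, the optimizer's seed/bounds, and the IQI
  reference convention used there; the toolkit validates directions and
  properties instead.
* PSO with 30 particles over a 2-D box is ample; the optional widening
  to four tuned parameters is exposed through custom bounds but not the
  validated default.
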