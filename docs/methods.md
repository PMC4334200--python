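# Methods

## Overview

`myoscreen` implements the analysis chain of a high-content RNAi autophagy
screen in primary muscle cultures: synthetic or real multi-channel field
images → muscle mask → GFP puncta → per-field autophagy index → per-well
aggregation → plate normalization → per-amplicon SSMD → two-tier gene
calls.  This note documents the models, the parameters that matter, the
numerical choices, and what the synthetic data can and cannot show.

## Imaging stage

### Muscle segmentation (`segment_muscle`)

Muscles are the only brightly phalloidin-stained objects in the mixed
culture.  The actin channel is Gaussian-smoothed (`smooth_sigma`, default
2 px), thresholded (Otsu by default; a fixed threshold may be supplied),
morphologically closed (disk radius 3) and filtered by component area
(`min_area`, default 500 px).  Non-muscle cells are both dimmer
(~5× lower actin) and far smaller than muscle ribbons, so either criterion
rejects them.  Connectivity is 4-neighbor throughout (8-neighbor
selectable).  A constant (blank) image yields an empty mask rather than an
error.

### Puncta detection (`detect_puncta_granularity`)

The screen's original granularity operator is proprietary; the package uses
a standard, fully specified replacement: white top-hat with a disk of
`tophat_radius` (default 8 px) removes all structures wider than the disk —
the diffuse cytoplasmic reporter, and the nuclei, which are larger than
puncta (~10 px radius vs ~3 px) — leaving puncta as positive residues.  The
residue is thresholded at `median + k_mad · MAD` (normal-consistent MAD,
`k_mad` default 4) computed *inside the muscle mask*, and 4-connected
components within `size_band` (default 4–2000 px) that lie inside the
muscle are kept.  Because the threshold is relative to robust statistics of
the same field, the detector — and hence the autophagy index — is invariant
under uniform intensity rescaling.  Defaults were chosen so that noise-free
synthetic fields are recovered within 10% (in practice within ~2%).

Degenerate case worth knowing: on a perfectly noise-free field the MAD can
be exactly zero, making the threshold equal to the median; any positive
top-hat residue (e.g. the corner wedges of an artificially *rectangular*
mask, which a disk opening cannot reach) then fires.  Real muscles and the
capsule-shaped synthetic ones have rounded boundaries, where this does not
occur.

### RATS local thresholding (`rats_threshold`)

Used for single-muscle confocal sections (puncta counting).  Parameters:
`noise_threshold` (gradient units, default 20), `lambda_factor` (default 3),
`min_leaf_size` (pixels, default 100).  The gradient magnitude is the max
of |horizontal| and |vertical| central differences (one-sided at borders);
weights are `g^λ` where `g > noise_threshold`, else 0.  The image is
decomposed by recursive 4-way splitting while all four children keep at
least `min_leaf_size` pixels.  A region is *valid* when
`Σw > noise_threshold^λ · area · validity_fraction` (default 1/100, a
plugin-style heuristic surfaced in the config); valid leaves threshold at
`Σ(w·I)/Σw`, invalid leaves inherit the nearest valid ancestor, and images
with no valid region anywhere return an empty foreground plus a flag.
Foreground is `I > T(x, y)`.  Larger λ concentrates the estimate on the
strongest edges, pulling each leaf threshold toward the gradient-maximal
pixels' intensities.

### Other readouts

- `autophagy_index` = puncta area / muscle area; errors on zero muscle area
  (such fields are excluded upstream and logged).
- `max_intensity_projection`: per-pixel maximum of a z-stack.
- `manders_overlap`: MOC = ΣAB / √(ΣA²·ΣB²) over an ROI; symmetric, scale
  invariant, in [0, 1]; undefined (error) if a channel is identically zero
  in the ROI.
- `flux_ratio`: red puncta are matched to green puncta by centroid distance
  (KD-tree, `match_radius` default 5 px); the ratio is red-only/dual.  The
  alternative red-total/dual convention would equal this plus one; the
  red-only/dual choice is flagged in the docstring.  No red puncta → 0 with
  a warning; no dual puncta → `inf` with a warning.
- Per-well aggregation is *pooled* (Σ puncta area / Σ muscle area over the
  well's fields), robust to fields with little muscle; an unweighted
  per-field mean is selectable.

## Screen statistics

- Normalization: `d = log A − median(log A)` over the plate's negative
  controls; natural log (SSMD is scale-free, so the base only rescales `d`
  uniformly).  Plates need ≥ 4 usable negative-control wells or are
  rejected with a logged message.  Zero-index wells are offset by
  `ε = min positive index on the plate × 10⁻³` (logged; dropping them is
  selectable) so replicate counts stay ≥ 3.
- Replicate unit is the plate; duplicate wells of an amplicon within a
  plate are averaged on the log scale first.  The replicate standard
  deviation is taken across plates.
- `ssmd_umvue`: `c(n)·mean(d)/sd(d)` with
  `c(n) = Γ((n−1)/2)/Γ((n−2)/2)·√(2/(n−1))` (computed via log-gamma),
  sample sd with n−1 denominator.  Unbiased for the population mean/sd
  ratio under normality (verified by Monte Carlo in the tests).  n < 3 or
  sd = 0 are errors (the sign of the mean is reported in the sd = 0 case).
- Gene calling: tier *multi* if ≥ 2 amplicons at `|SSMD| ≥ 0.5` with one
  sign (genes qualifying in both directions are flagged ambiguous and not
  called); tier *single* if exactly one amplicon at `|SSMD| ≥ 1.0` and no
  other amplicon at ≥ 0.5 in the opposite direction.  Threshold ties count
  as passing.  Calls are permutation-invariant in amplicon order, and
  making a qualifying score more extreme never removes a hit.  No
  multiple-testing correction is applied — hits are threshold calls only.
- `compare_groups`: classical equal-variance two-sample Student t-test
  (two-sided), delegated to scipy; zero pooled variance is an error.

### Null behavior of SSMD at three replicates — a real limitation

For i.i.d. normal null differences, `SSMD = c(n)·mean/sd` is distributed as
`(c(n)/√n)·t_{n−1}` — *independent of the noise scale*.  At n = 3 this is
≈ 0.326·t₂: about 26% of null amplicons exceed |0.5| and the 99th
percentile of |SSMD| is ≈ 3.2, whatever σ is.  Consequences measured by the
package's own studies:

- the strong-suppressor control contract (score < −1) holds essentially
  always (the 95th percentile of control scores is ≈ −7);
- a "null amplicons stay within ±0.5" contract cannot hold at the 99% level
  under an i.i.d. noise model — the observed fraction is ≈ 74%;
- the two-tier rule's gene-level false-positive rate on null genes with two
  amplicons is ≈ 0.18 (≈ 0.035 from the multi tier, the rest from the
  single tier), while sensitivity for planted θ = 0.3 / 3.0 effects is
  ≥ 0.9 with no wrong-direction calls.

Real screens that report tightly calibrated controls are benefiting from
empirical structure (many control wells pooled, correlated within-plate
variability inflating sd(d)) that an i.i.d. lognormal generator
deliberately does not include.  The package reports what the estimator
actually does rather than tuning the generator to flatter it.

## Synthetic data

### Field generator (`simulate_field`)

Muscles are rotated capsules (length 120–240 px, width 24–36 px by default,
up to 4 per 512×512 canvas; optional sinusoidal actin striation), among
~40 dim non-muscle disks.  Nuclei (radius 10 px) are placed with centers in
the *eroded* muscle interior so each nucleus disk lies wholly inside its
muscle — a nucleus clipped to a thin sliver would defeat the size
separation the top-hat detector relies on.  Puncta are hard disks (radius
3 ± 0.8 px, Gaussian-profile option) with count
`Poisson(autophagy_level × muscle_area × puncta_density)`,
`puncta_density` default 2×10⁻³ per pixel, clipped to the muscle.
Channels: actin 120 (muscle) / 25 (non-muscle); GFP 60 diffuse + 90 nuclei
+ 160 puncta (arbitrary fluorescence units on a 16-bit-like scale);
additive Gaussian noise σ = 4, clipped at zero.  Ground truth (exact masks
and index) is emitted alongside; identical seeds give bit-identical
output, and field and screen simulations draw from separately named
substreams of one integer seed.

What the generator does **not** emulate: real myotube texture and
striation detail, uneven illumination, cell-to-cell fusion, 3-D structure
(a synthetic z-stack exists only for projection tests), or spatially
correlated plate artifacts.  Passing tests therefore demonstrate correct
*algorithmic* behavior, not robustness to every real-data pathology.

### Screen generator (`simulate_screen`)

`y = A0 · θ_g · π_r · ε` with baseline index A0 = 0.02, per-plate lognormal
factor π_r (σ_plate = 0.1) and i.i.d. lognormal well noise ε (σ_well =
0.2); multiplicative lognormal effects match the log transform the scoring
applies.  3 replicate plates (the minimum SSMD needs; enforced), 2
amplicons per gene sharing θ_g unless an off-target map overrides one, 16
lacZ-like null wells and 8 Atg18-like wells (θ = 0.1 — the assay reports
only the resulting score bound, so a strong suppression value was fixed
once) spread evenly across each 384-well plate, identical layout across
replicates.  True effect sizes of hits are unknown in general, so recovery
studies sweep θ rather than assume one value.

## Problem sizes for desk-scale studies

Chosen once as package defaults: control-calibration studies use 100
simulated screens of 3×384 wells (~seconds); rank-monotonicity uses 200
default-geometry fields; the image-level end-to-end recovery study uses
20 seeds × 3 plates of 96-well layouts (8 negative / 4 positive control
wells), 176×176 px fields with two muscles, one field per well and a base
autophagy level of 2 so that a null well expects a few dozen puncta —
enough for Poisson noise not to swamp a θ = 0.3 effect.

## Known limitations

- The null-calibration consequences above are inherent to SSMD at n = 3.
- The granularity operator replaces an unpublished proprietary module;
  absolute puncta counts are comparable only within a parameter setting.
- Whether the original screen measured areas on shading-corrected images is
  unknown; no flat-field correction is applied by default.
- Orthology mapping, GO enrichment and network rendering are out of scope;
  a static gene table is the only cross-species artifact shipped.
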