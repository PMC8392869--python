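# Methods

## Problem and unit of analysis

The package decides, per square image tile, whether a colonoscopy(-like)
frame region shows a colorectal polyp. Tiles — not pixels — are the unit:
the goal is to direct an examiner's attention to suspicious segments, not
to segment the lesion. Images are partitioned into the ⌊H/T⌋·⌊W/T⌋
non-overlapping T×T tiles in row-major order (partial border remainders are
discarded; the tiling stride is a config knob should overlapping tiles be
wanted later). Ground truth comes from a binary expert mask on the same
pixel grid: a tile is labelled `polyp` when at least a fraction θ of its
pixels are mask-positive, with θ = 0.05 by default. The choice of θ is a
genuine free parameter: very small polyp shares give tiles that look like
background, and the default trades a harder positive class for not
discarding lesion rims. At θ = 0 any positive pixel marks the tile.

Training and test sets come from strict index interleaving (tiles
0, 2, 4, … train; 1, 3, 5, … test) within each image's row-major order.
This is deterministic and spatially balanced, but note its consequence:
train and test tiles share images, so the split estimates within-domain
tile discrimination, not cross-patient generalisation.

## Antecedents (the 99 tile features)

For each of the three channels of the chosen colour representation
(HSV by default; hue is stored as angle/360 and treated as a *linear*
variable — its circularity is deliberately ignored, so data whose hue
straddles the 0/1 wrap will produce noisy channel-1 features):

* mean and population standard deviation (indices 1–6);
* Canny edge density (7–9): fraction of pixels on edges, with Gaussian
  σ = 1.0 and hysteresis thresholds 0.1/0.2 expressed as fractions of the
  maximum smoothed Sobel gradient magnitude. A raw Sobel-threshold mode is
  available (`FeatureConfig.edge_method = "sobel"`) because the literature
  is ambiguous about which detector the edge-ratio feature should use;
* structural entropy S_str = S₁ − S₂ and log spatial filling factor
  ln q = S₂ − S₀ (10–15), from the Rényi entropies of the tile normalised
  to a probability field p_i = I_i / ΣI_j. Natural logarithms throughout.
  S₀ counts only strictly positive p_i (the 0⁰ ambiguity resolved as
  exclusion). An exactly uniform field returns S_str = ln q = 0 with no
  floating-point residue (special-cased); an all-zero channel returns
  zero-valued descriptors flagged invalid instead of raising, so dark
  tiles do not abort a batch.
* the same fifteen quantities on each of the four one-level 2-D discrete
  wavelet sub-bands LL, LH, HL, HH (16–75). Haar is the default wavelet:
  the shortest orthonormal filter, exact on desk tests; any PyWavelets
  name is accepted. The transform uses periodized boundaries, so for
  orthonormal filters the four sub-bands conserve the tile's energy and
  reconstruct it exactly. Detail-band coefficients are signed, while the
  probability normalisation needs nonnegative intensities; all detail-band
  statistics therefore use |coefficients| — magnitude is the physically
  meaningful "local variation" quantity. The LL band of a nonnegative tile
  is itself nonnegative under Haar and is used as-is;
* Sobel gradient statistics (76–99): mean and standard deviation of the
  gradient magnitude, direction, x component and y component per channel.
  Kernels are the standard ±1/±2 Sobel pair applied by correlation with
  reflect padding; direction is atan2(g_y, g_x) ∈ (−π, π], treated
  linearly, and defined as 0 where the magnitude is numerically zero.

The canonical ordering and the column names live in
`polyptile.features.ANTECEDENT_NAMES`; indices quoted anywhere in the
package are 1-based positions in this order.

## Rule fitting

Per antecedent and consequent class, a triangular membership function
(left, core, right) is fitted to that class's training values:

* `mean` / `median` modes: support = [min, max] of the data, core at the
  mean / median;
* `histogram` mode (default): histogram with 100 equal-width bins over the
  class's data range, counts normalised so the tallest bin is 1; the core
  sits at the centre of the tallest bin (leftmost on ties) and the support
  ends at the centres of the first bins from each side whose normalised
  height exceeds 0.01. Characteristic points at bin *centres* keep the fit
  stable under bin-width changes. 100 bins is a compromise: enough
  resolution for the support rule, few enough that a class with a few
  hundred tiles still fills the bulk bins.

Degenerate samples (all values identical) produce a point triangle flagged
`degenerate`. Min-max normalisation constants per antecedent come from the
*pooled* training values and are frozen into the rulebase; test-time
observations and all distance computations use these frozen constants.

Optionally each triangle is smoothed into a strictly positive bell with
`extend_support`: `half_gaussian` uses separate left/right widths so the
membership at both triangle support ends equals 0.01 exactly
(σ = d / √(2 ln 100) for a flank of length d); `gaussian` uses a single
width chosen by least squares on the same two boundary conditions. The
0.01 level ties the extension to the histogram support rule.

## Antecedent selection

Two separation measures compare each antecedent's polyp and no_polyp
triangles after min-max scaling to [0, 1] (so the measures are
dimensionless and invariant under affine rescaling of the raw feature):

* total distance = |Δleft| + |Δcore| + |Δright|;
* centre distance = |Δcore|.

`select_by_distance` keeps antecedents strictly above a threshold, ordered
by decreasing distance. `prune_narrow` removes antecedents whose
normalised support width is below a cutoff (default 0.05) for either
class: very narrow rules rarely overlap observations and measurably hurt
every inference variant. The package also carries, as presets, the fixed
index subsets identified by this procedure on the public MICCAI polyp
databases, including the 30-antecedent entropy preset (all S_str/ln q
indices: 10–15, 25–30, 40–45, 55–60, 70–75).

## Inference

Consequents are singletons on the decision axis: polyp → 1, no_polyp → 0.
This is the simplest contract consistent with a "fuzzy decision value" in
[0, 1]; no consequent shape information is lost because only two classes
exist.

* **Mamdani–Assilian** (Zadeh norms): firing strength per consequent =
  min over active antecedents of the observation's membership in that
  consequent's rule; decision value = w_polyp / (w_polyp + w_no_polyp).
  If both strengths are zero the result is *indeterminate*.
* **Stabilized Kóczy–Hirota interpolation**: used when Mamdani is
  indeterminate (mode `auto`, the default), or always (mode
  `interpolation`). For the conclusion's characteristic α-cuts, each of
  the three points (α = 0 lower, α = 1 core — the two α = 1 endpoints
  coincide for triangles — and α = 0 upper) is the (1/d)^k-weighted
  average of the rules' consequent values, where d is the Euclidean
  distance over active antecedents between the crisp observation and the
  rule's corresponding triangle points, on the normalised scale. The
  exponent k defaults to the number of active antecedents. Observations
  are crisp feature vectors, so their α-cuts collapse to the point itself;
  fuzzy observations would be a straightforward extension. A distance
  below 10⁻¹² is an exact hit and returns that rule's consequent (the
  limit of the weights); the defuzzified value is the centroid (mean) of
  the three conclusion points, which is monotone in each point and always
  inside the convex hull [0, 1] of the consequents. The summation runs
  over all rules of all consequents — with one rule pair per antecedent
  bundle this is the "2n" bound of the classical formulation.

The decision threshold is 0.5; exact ties go to `no_polyp`, the majority
class in screening data. Both the threshold and the mode are configurable
(`InferenceConfig`), and mode `mamdani` with extended supports reproduces
the classical-inference-only variant.

## Evaluation

Tile-level confusion counts give TPR, TNR, PPV, NPV, the Matthews
correlation coefficient and Cohen's κ. Metrics with zero denominators are
reported as undefined (`None`), never as 0. Confidence intervals use the
subsample scheme: n = 100 resamples, each drawing 80% of the test tiles
*without replacement* (the scheme is subsampling, not a classical
bootstrap; a with-replacement mode exists), metric recomputed per
resample, interval M ± 1.96·σ/√n from the resample mean and standard
deviation (ddof = 1). Resamples on which the metric is undefined are
skipped, counted, and reported. All resampling is seeded; the seed is
recorded in the report.

## The phantom generator

`polyptile.phantoms` renders colonoscopy-like images with exact masks so
every stage is testable without external databases. The appearance model
encodes, deliberately and only, the attributes that motivate the feature
set:

* **wall**: narrow pink hue band (0.93–0.96, kept clear of the 0/1 hue
  wrap because hue is linear downstream), saturation 0.25–0.45, soft
  large-scale mottling, 2–4 broad darker fold arcs, and thin darker,
  more saturated vessel curves;
* **illumination**: the reflectance image is modulated by a smooth field —
  directional ramp (amplitude 0.15), off-centre vignette, per-image
  exposure factor 0.8–1.15. Smooth on the tile scale, it rescales a
  tile's intensities approximately multiplicatively: intensity means and
  gradients shift, the entropy descriptors do not. This is the mechanism
  by which the all-99 antecedent set degrades relative to the entropy
  subset;
* **polyps** (default one per image, radius 20–40 px in a 200×200 frame):
  additive hemispherical dome I(r) = A·√(R² − r²)/R with A = 0.35, a
  uniform tissue colour shift over the whole disk (hue +0.05, saturation
  −0.08), a narrow darker contour ring at the circumference (the cue that
  makes a zenithal outline visible where the dome shading vanishes), and
  for lateral/semilateral views a darker crescent at the base;
* **reflections**: 20 small saturated white discs (radius 1.5–7 px) per
  frame — endoscopic frames are full of specular highlights, and these
  are precisely the structures that fool brightness/gradient antecedents
  while leaving the localisation descriptors comparatively calm;
* **noise**: i.i.d. Gaussian, σ = 0.01 in RGB, clipped to [0, 1].

The mask is the exact union of the polyp disks. Everything derives from
one integer seed; a fixed seed reproduces images bit for bit, and dataset
generation derives per-image seeds deterministically from a master seed.

What the phantoms do *not* model: pit-pattern texture, mucus and debris,
motion blur, lens distortion, real vascular trees, and inter-patient
variability (train and test tiles share images). Passing the phantom
study therefore shows that the pipeline recovers strongly expressed
polyp structure under illumination and reflection nuisance — it does not
certify clinical performance on real endoscopic data, where reported
tile-level rates for this class of methods are far lower.

## Study sizes and numerical choices

The bundled study (tests and `scripts/acceptance.py`) uses 200 phantom
images of 200×200 px with 50 px tiles — 16 tiles per image, 1600 training
and 1600 test tiles, roughly a fifth polyp-positive — a size at which the
class histograms are well resolved by 100 bins and the whole study runs
in about a minute on one CPU. Distances in the KH weights are floored at
10⁻¹² short of the exact-hit path; membership evaluation outside a
triangle's support is exactly 0, and the uniform-field entropy
special-case avoids spurious 10⁻¹⁶-level descriptor values. Rulebase
serialization is versioned JSON and round-trips losslessly.
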