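# polyptile

Fuzzy-inference classification of colonoscopy image tiles: does this image
segment show a colorectal polyp?

Computer-aided polyp screening needs methods that work with few annotated
images. `polyptile` implements a transparent, data-efficient alternative to
deep segmentation networks: each image is cut into square tiles, every tile
is summarised by 99 interpretable *antecedents*, and a fuzzy rulebase fitted
to training-set histograms decides per tile whether a polyp is present. The
package ships a synthetic colonoscopy phantom generator with exact masks, so
the whole pipeline is testable end to end without any external image
database; real image/mask pairs (e.g. the public MICCAI polyp databases)
drop in through the same manifest convention.

## The model

**Antecedents.** For each tile and colour channel (HSV by default): mean and
standard deviation, Canny edge density, and two Rényi-entropy shape
descriptors; the same fifteen quantities on the four sub-bands LL, LH, HL,
HH of a one-level 2-D Haar wavelet transform; and Sobel gradient statistics
(magnitude, direction, x and y components) — 99 values in total.

The entropy descriptors view a tile as a 2-D probability distribution,
p_i = I_i / Σ_j I_j, with generalized Rényi entropies

    S_n = ln(Σ_i p_i^n) / (1 − n),      S_1 = −Σ_i p_i ln p_i.

Two combinations characterise the distribution's shape independently of its
overall intensity scale:

    structural entropy      S_str = S_1 − S_2   ≥ 0
    log spatial filling     ln q  = S_2 − S_0   ≤ 0

A hemispherical polyp blob localises intensity and moves (ln q, S_str) away
from the flat-wall origin, while a multiplicative illumination change moves
it not at all — the property that makes these 30 entropy antecedents (raw
channels + four sub-bands) the most robust feature subset.

**Rules.** For every antecedent and each consequent (`polyp` / `no_polyp`) a
triangular membership function is fitted to the training distribution:
support and core from the min/mean/max (or median), or — the recommended
mode — core at the tallest histogram bin and support at the outermost bins
whose height exceeds 1% of the tallest. Triangles can be smoothed into
strictly positive Gaussian or two-sided half-Gaussian bells.

**Inference.** Mamdani–Assilian with Zadeh norms: a consequent's firing
strength is the minimum membership over the active antecedents, and the
fuzzy decision value in [0, 1] is the strength-weighted average of the
singleton consequents {polyp → 1, no_polyp → 0}. When an observation fires
no rule at all, stabilized Kóczy–Hirota rule interpolation takes over: the
conclusion's characteristic α-cut points are (1/d)^k-weighted averages of
the rule consequents, with d the Euclidean distance between the observation
and each rule's α-cut endpoints on the normalised antecedent scale.

**Selection.** Antecedents are ranked by how far the two classes' fitted
triangles sit apart on the min-max-normalised axis (total distance of the
three characteristic points, or core distance alone); very narrow rules can
be pruned. Fixed reference subsets from the public-database study are
available as presets (`entropy`, `total02`, `total035`, `center`).

## Worked example

```python
import pandas as pd
from polyptile import PolypTileClassifier, features, imaging, phantoms

records = phantoms.generate_dataset(30, phantoms.PhantomSpec(), seed=42)
train_frames, test_frames = [], []
for rec in records:
    img = imaging.to_hsv(rec.image)
    tiles = imaging.label_tiles(imaging.tile_image(img, 50), 0.05)
    tr, te = imaging.split_train_test(tiles)
    train_frames.append(features.features_to_frame(
        [features.extract_antecedents(t) for t in tr]))
    test_frames.append(features.features_to_frame(
        [features.extract_antecedents(t) for t in te]))
train = pd.concat(train_frames, ignore_index=True)
test = pd.concat(test_frames, ignore_index=True)

model = PolypTileClassifier(train, antecedents="entropy")
results = model.fit(mode="histogram")
print(results.summary())
print(results.evaluate(test, ci=True, n=100, seed=0).to_frame().to_string())
```

prints

```
Fuzzy polyp tile classifier
============================================
training tiles:      240
  no_polyp           190
  polyp              50
fit mode:            histogram
histogram bins:      100
membership kind:     triangle
active antecedents:  30 of 99

most separated antecedents (normalised total distance):
   30 LL_lnq_ch3               total=1.120  centre=0.937
   27 LL_Sstr_ch2              total=1.082  centre=0.188
   ...

metric    value   ci_low  ci_high  ci_n  seed
   TPR 0.940000 0.936726 0.943769   100     0
   TNR 0.931579 0.930242 0.933737   100     0
   PPV 0.783333 0.778442 0.788430   100     0
   NPV 0.983333 0.982529 0.984481   100     0
   MCC 0.817441 0.813918 0.821721   100     0
 kappa 0.811765 0.807840 0.816006   100     0
```

The summary ranks antecedents by class separation — the spatial-filling and
structural-entropy descriptors of the smoothed (LL) V and S channels
dominate, which is exactly the premise behind the entropy preset. On the
test half of the tiles the 30 entropy antecedents reach TPR 0.94 / TNR 0.93;
the confidence intervals come from 100 resamples of 80% of the test tiles.
94% of tiles that truly contain ≥5% polyp pixels are flagged, at a ~7%
false-alarm rate per clean tile.

The same pipeline is scriptable from a shell:

```sh
polyptile pipeline --out run/ --seed 42 --n-images 50 --criterion entropy
```

which writes phantom images and masks, the tile feature table, the
serialized rulebase, per-tile decisions and the metric report (with
provenance records) under `run/`.

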