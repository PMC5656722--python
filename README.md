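# octwall

Layered vessel-wall analysis for intracoronary optical coherence tomography
(OCT).

A healthy coronary artery shows three concentric tunicas in OCT — a bright
intima, dark media and bright adventitia — while diseased wall segments are
hidden behind plaque and show a single attenuating layer. `octwall`
implements a fully automatic two-stage framework for polar OCT frames:

1. **Simultaneous three-contour segmentation.** The intima–media (IM),
   media–adventitia (MA) and adventitia–periadventitia (AP) interfaces are
   extracted *at once* as the globally optimal multi-parametric path of a
   dynamic program running in the 4D space `(x, y1, y2, y3)`:

   ```
   C(x, y1, y2, y3) = min_{dy1,dy2,dy3}  C(x-1, y+dy)
       + Σ_n ω_n (1 + κ|dy_n|) (C^±(x, y_n) + C^±(x-1, y_n + dy_n))
   ```

   where `C± = N[0,1](± I'''_G)` are complementary cost maps built from the
   triple-replicated derivative-of-Gaussian gradient image of the
   lumen-flattened sub-image, the non-crossing constraint
   `y1 + g ≤ y2 ≤ y3 − g` is enforced on every state, and keeping the
   central replica closes the contours. Defaults are σ = 30 µm,
   ω = (0.2, 1, 1), g = 45 µm, 2N+1 = 7, κ = 0.1.

2. **Healthy-region classification.** Seventeen features per angular column
   (GLCM texture, interface gradients, profile-shape indices, band
   intensities, interface distances) are derived from the tentative
   contours over the region from the lumen to 300 µm below the AP contour;
   the eight selection-confirmed features feed a 100-round AdaBoost stump
   ensemble, followed by adjacent-frame majority voting and circular
   morphological cleanup (erosion 4, dilation 9).

The package is aimed at image-analysis researchers working on intravascular
imaging: it ships a synthetic phantom generator with exact ground truth, so
every stage is testable without clinical data, plus evaluation metrics
(point-to-point contour error, layer-thickness agreement, Dice /
accuracy / sensitivity / specificity of healthy arcs).

## Worked example

```sh
# 1. generate a synthetic pullback (Terumo-like geometry, 512x512, 8.8 um/px)
#    with 60% of the circumference healthy and the rest diseased
octwall simulate --preset terumo --n-frames 10 --seed 1 --healthy-fraction 0.6 \
    --out pb.tif --labels-out ref_labels.csv

# 2. segment the three wall interfaces of every frame
octwall segment pb.tif --seed 1 --out contours.csv

# 3. train the classifier on the labelled pullback, then classify it
octwall train pb.tif --labels-csv ref_labels.csv --seed 1 --out model.json
octwall classify pb.tif model.json --out labels.csv --carpet-png carpet.png

# 4. compare against the reference labels
octwall evaluate labels.csv ref_labels.csv --out report.json
```

`contours.csv` holds one row per frame and angular column with the three
interface depths in pixels and micrometres below the lumen, e.g.

```
frame_index,column,y1_px,y2_px,y3_px,y1_um,y2_um,y3_um
0,0,16,28,40,140.8,246.4,352
```

— at that angle the intima ends ≈ 141 µm below the lumen and the media is
≈ 106 µm thick, consistent with the phantom's 130/95/105 µm layer template
(the speckled frame shifts interfaces by a pixel or so). `report.json`
carries per-frame rows and the pullback medians:

```
"median": {"dice": 0.957, "accuracy": 0.948, "sensitivity": 1.0, "specificity": 0.875}
```

on this self-trained example: every healthy column is found, and the
morphological cleanup (dilation kernel larger than the erosion kernel)
slightly over-extends the healthy arc into the diseased side, which is what
the specificity below 1 reflects. Held-out numbers come from the cohort
experiment below. The same steps are available as library calls
(`octwall.pipeline.segment_pullback`, `train_on_cohort`,
`classify_pullback`); `docs/methods.md` describes the model, parameters and
limitations in detail.

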