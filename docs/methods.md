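# Methods

This note documents the models, numerical conventions and design choices
behind `citrusyield`, and what its synthetic benchmark does and does not
demonstrate about real orchard imagery.

## Scale model

All ground scale derives from the similar-triangles pinhole relation: at
altitude *a* (m) a sensor axis of length *s* (mm) behind focal length *f*
(mm) images `a·s/f` meters of ground. The package deliberately ignores any
separately quoted field-of-view angle: only the pinhole relation reproduces
the survey's footprint, pixel-density and pixels-per-fruit tables, so it
governs every conversion. The sensor long axis (17.3 mm) is mapped to the
image long axis (8192 px). Note the published sensor/grid combination is
mildly inconsistent — 17.3/13 = 1.33 vs 8192/5460 = 1.50 — so ground pixels
are ~13% anisotropic (0.181 × 0.204 cm at 30 m); `CameraModel` warns about
aspect mismatches above 5% but proceeds, and all per-axis computations
(ground sample distance, disc rasterization, the coarser-axis linear
resolution used by `min_altitude_for_resolution`) honor the anisotropy.

The calibration constant *pixels-per-fruit* is areal pixel density times the
exact circular fruit cross-section π(d/2)² with d = 46.7 mm (17.1287 cm²).
Two conventions are load-bearing and were chosen because they reproduce
every published table cell:

* the **unrounded** pixels-per-fruit (463.671 at 30 m, not 464) divides the
  pixel counts in the yield equation;
* reported integers use **half-up** rounding (0.5 → 1; e.g. 18 px at 110 m
  is a raw 0.52 and reports as 1 fruit). The truncated per-fruit area
  sometimes quoted (17.12 cm²) is kept only as a documented constant.

## Preprocessing

Histogram equalization is global and per-RGB-channel (256 bins, classic
`lut(v) = round(255·(cdf(v) − cdf_min)/(n − cdf_min))`), applied before HSV
conversion. The mapping is monotone per channel, the identity on an already
uniform histogram, and idempotent to within one intensity level. A key
consequence used throughout the benchmark: equalization is invariant to a
global multiplicative dimming of the image (quantiles are unchanged), which
is exactly why it recovers fruit detection on under-exposed frames whose
raw brightness falls below the V-threshold.

HSV uses the standard hexcone conversion with **all channels scaled to
0–255** (hue fraction × 255, undefined hue → 0). The citrus thresholds
(19, 39, 31, 243, 255, 221) are 8-bit values; converting hue to [0, 360) or
to 179 silently empties the selection, hence the explicit color-space tag on
`RasterImage` and the hard error on mismatched inputs. The published
threshold pair has its "upper"/"lower" labels swapped; the only reading that
yields a non-empty box — per-channel [min, max] = H∈[19,39], S∈[31,243],
V∈[221,255] — is used. Hue wrap-around is rejected rather than supported:
the citrus band does not cross zero.

## Segmentation

`I_PCA` is implemented verbatim, including its duplicated first/third term
(both |R−B|, effective weight 1.908); a `distinct` variant with a 0.914|R−G|
third term exists for sensitivity studies only. Tree/ground separation is
I_PCA + Otsu (256 bins over the observed range), foreground above the cut;
no published cut value exists, and Otsu is parameter-free and reproducible.
Two practical caveats, both visible in the synthetic scenes:

* with a very bright, high-I_PCA minority class (the fruit itself) in the
  frame, the Otsu cut can land below the fruit but above part of the canopy;
  fruit always has the maximal index, so the fruit mask — candidate ∩ tree —
  is unaffected, but the tree mask should not be read as a precise crown
  delineation;
* Otsu restricted to tree pixels needs the fruit class to carry
  non-negligible histogram mass; below a few percent it may split the canopy
  cluster instead (a generic weakness of the criterion for extremely
  unbalanced classes).

For the index-based fruit detectors the index is computed on the raw image,
thresholded by Otsu over tree-mask pixels only, with foreground **above**
the cut for all three indices. For CIVE this inverts the usual
"vegetation is low" reading on purpose: restricted to vegetation-plus-fruit
pixels, foliage (CIVE ≈ −80, dominated by −0.811·G) is the low class and
orange fruit (≈ +13) the high one. On synthetic scenes this ordering gives
precisions of ~0.95 (I_PCA), ~0.84 (CIVE) and ~0.57 (I₁) at recall ≈ 1 —
the same qualitative ranking, with I₁ weakest, that the original comparison
reported. No morphological cleanup is applied by default: raw threshold
pixels are what gets counted.

ROI counting uses pixel-center point-in-polygon with boundary pixels
included; an ROI wholly outside the raster yields zero with a warning.

## Statistics

Groups are tiny (n = 3 trees per treatment), which drives several choices:

* The normality gate is Shapiro–Wilk per group at α = 0.05 — a protocol
  device with essentially no power at n = 3, so `compare_treatments` also
  accepts a forced test choice; the published altitude→test split (t at
  30/50/70 m, rank-sum at 90/110 m) reproduces the full p-value column.
* The default t variant is **Welch**. Both variants round the 50 m p-value
  to 0.03, but only Welch also reproduces the published 0.08 at 70 m
  (Student gives 0.0745 → 0.07); Welch is likewise base-R's default.
* The rank-sum test enumerates all C(n_a+n_b, n_a) assignments exactly when
  that count is ≤ 10⁵ and there are no ties (two-sided p =
  2·min(P(W≤w), P(W≥w)) capped at 1; complete separation at 3v3 gives
  exactly 0.10). With ties it uses mid-ranks and the tie-corrected normal
  approximation with continuity correction, which reproduces the published
  0.18 at 110 m where two zero counts tie.
* Tests are unpaired, mirroring the original protocol, although the same
  trees appear in both treatments.
* The published "±" dispersions mix conventions (sd/√n for pixel columns,
  sd/√(n−1) for estimate columns); `GroupSummary` reports `sd`, `se` and the
  `paper_style_dispersion` sd/√(n−1) so either can be quoted. Group means
  are the quantity the acceptance checks pin.
* No multiple-testing correction across altitudes is applied, matching the
  original analysis.

## Synthetic scenes

`SceneSpec` defaults describe one surveyed frame: three non-overlapping
crowns (radius 1.6 ± 0.15 m) in a 14.8 × 11.1 m field (the 30 m footprint),
gamma-Poisson fruit loads with mean 118 (the mean of the reported actual
yields 124/88/141; shape 20 gives mild overdispersion), 46.7 mm fruit, and
visible fraction 0.75 standing in for canopy occlusion (the ratio of
detected to actual counts in the original data; occlusion is a scalar, not
geometric leaf cover). Rendering is flat 2-D nadir composition — no
perspective, shadows or BRDF — because the pipeline consumes only color
statistics and areas, and the footprint model is itself flat-ground.

Colors are five mixture components (means ± per-channel Gaussian noise):
base soil (150,140,125), brighter soil patches (210,204,192; 10% of ground),
shaded canopy (40,95,30), sunlit canopy (85,200,60; 30% of canopy) and fruit
(245,185,95), whose HSV sits centered in the detection box. The two bright
components are not decoration: per-channel equalization maps values by their
quantile, and if nothing in the scene had R or G above the fruit's, both
channels would map to ~255 and the equalized hue would collapse to 60°
(outside the citrus band). Broad, overlapping channel histograms — which
real imagery has — are what make global equalization behave sensibly; the
bright-soil and sunlit-leaf components provide them. The residual artifact
is a thin tail of bright-soil pixels that passes the HSV box; these lie
outside every crown polygon, so per-tree counts are unaffected, but
whole-frame mask totals should not be used as yield estimates.

`render(supersample=s)` area-averages an s×s sub-pixel grid, a crude model
of sensor pixel integration. With s = 1 rasterization is crisp; with s ≥ 3
fruit-edge pixels blend into canopy, and because blending with dark foliage
quickly drags V below 221, per-pixel recall degrades monotonically with
altitude (0.95 at 30 m to ~0.82 at 110 m on the benchmark world) — the
qualitative altitude trend of the original tables, reproduced by geometry
rather than by tuning. The dimming fixture (`he_benefit_fixture`, gain 0.8)
exploits the gain-invariance of equalization: raw counts collapse to ~0
while equalized counts stay at truth, and at gain 1 the two agree within a
few per mil.

Problem sizes in the test suite (fields of ~2–6 m, 25–90 fruits per tree,
20 seeds for the recovery property) were chosen so the full chain runs in a
few minutes on one core; the estimates they validate are scale-free ratios,
so nothing about the check depends on frame size.

## What passing tests do and do not show

The synthetic benchmark demonstrates internal consistency: correct geometry,
faithful implementation of the published formulas, and the *mechanism* of
the equalization benefit. It does not demonstrate field accuracy: real
canopies have geometric occlusion, specular leaves, shadows and mixed soil
spectra far richer than five color components, and the published real-orchard
comparison (actual yields vs image estimates) cannot be reproduced here
because the imagery is not deposited and the index thresholds used for that
comparison are unstated. Occlusion correction ("hidden fruit" factors) is
explicitly out of scope.
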