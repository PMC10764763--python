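# citrusyield

Estimating per-tree *Citrus unshiu* fruit counts from nadir UAV RGB imagery,
with explicit treatment of flight altitude.

Orchard yield surveys traditionally count fruit by hand on sample trees. A
drone photographing the canopy from above can replace much of that labor —
but the flight altitude fixes the ground resolution, and with it how many
pixels one fruit occupies and how reliably orange fruit pixels can be told
apart from foliage. `citrusyield` implements that whole chain as a tested
library and CLI:

1. **Camera geometry.** A pinhole camera at altitude *a* with focal length
   *f* images a ground rectangle of `a · s / f` per sensor axis *s*. From the
   footprint follow the areal pixel density ρ(a) (px/cm², falling as 1/a²)
   and the calibration constant

   &nbsp;&nbsp;&nbsp;&nbsp;*pixels per fruit* = ρ(a) · π(d/2)²,

   with d = 46.7 mm the average fruit diameter. At 30 m one fruit covers
   ~464 px; at 110 m only ~34 px.
2. **Preprocessing.** Per-channel global histogram equalization (contrast
   recovery for under-exposed frames), then RGB → HSV with all channels on
   the 0–255 scale.
3. **Segmentation.** Tree crowns are separated from bare ground by the index
   `I_PCA = 0.994|R−B| + 0.961|G−B| + 0.914|B−R|` with an Otsu cut; fruit
   candidates come from an HSV box (H ∈ [19,39], S ∈ [31,243], V ∈ [221,255])
   or from the vegetation indices CIVE (`0.441R − 0.811G + 0.385B + 18.78`)
   and `I₁ = R + G − 2B`. The fruit mask is candidate ∩ tree; fruit pixels
   are counted inside each crown polygon.
4. **Estimation.** *fruits ≈ fruit pixels / pixels-per-fruit*, using the
   unrounded divisor, rounded half-up for reporting.
5. **Statistics.** Raw vs equalized treatments are compared per altitude:
   Shapiro–Wilk gates between a two-sample t-test (Welch by default) and the
   Wilcoxon rank-sum test, whose null distribution is enumerated exactly for
   small samples.
6. **Simulation.** A synthetic orchard generator (crowns, fruit discs at the
   altitude-correct pixel scale, controllable occlusion and global dimming)
   provides ground truth so the entire pipeline is testable with no field
   data.

## Worked example

Flight planning table for the default camera (13 × 17.3 mm sensor, 35 mm
focal length, 5460 × 8192 px) and 46.7 mm fruit:

```sh
$ citrusyield plan
altitude_m,footprint_w_m,footprint_h_m,area_ha,px_per_cm2,px_per_fruit
30.0,14.82857142857143,11.142857142857142,0.01652326530612245,27.06990366088632,463.67144689391586
50.0,24.714285714285715,18.571428571428573,0.045897959183673474,9.745165317919074,166.92172088180968
70.0,34.6,26.0,0.08996,4.972023121387283,85.16414330704576
90.0,44.48571428571429,33.42857142857143,0.14870938775510206,3.007767073431813,51.51904965487953
110.0,54.371428571428574,40.857142857142854,0.22214612244897958,2.0134639086609663,34.48795885987804
```

Rounded as reported in survey practice these rows read 0.02/0.05/0.09/0.15/
0.22 ha, 27/10/5/3/2 px/cm² and 464/167/85/52/34 px/fruit: below ~30 m a
fruit-sized object keeps the ≈5 px/cm linear resolution needed for reliable
detection, while each frame covers only 0.02 ha.

Converting observed fruit-pixel counts at 30 m into fruit numbers:

```python
>>> from citrusyield import CameraModel, estimate_fruit_count
>>> from citrusyield.camera import altitude_profile
>>> prof = altitude_profile(CameraModel(), 30.0)
>>> [estimate_fruit_count(px, prof).estimate for px in (33667, 25301, 41256)]
[73, 55, 89]
```

A fully synthetic run — simulate a scene, segment it, estimate:

```sh
citrusyield simulate --seed 5 --altitude 30 --out-dir scene
citrusyield segment --image scene/scene.png --roi scene/rois.json \
    --no-equalize --out-dir seg
citrusyield estimate --counts seg/counts.csv --altitude 30
```

On fully visible, well-exposed scenes the estimates land within ~10% of the
generator's true per-tree counts (rasterization, overlap and rounding are
the residual error sources).

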