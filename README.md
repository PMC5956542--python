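# uswicrack

In-silico ultrasonic shear-wave imaging (USWI) of cracks — lacerations —
in a liver-mimicking elastic medium.

Blunt liver trauma tears the parenchyma and fills the tear with blood.
On conventional B-mode ultrasound such a crack is nearly invisible: the
blood-filled band is hypo-echoic and the surrounding tissue is
homogeneous, so there is no echo contrast to see.  A shear wave, however,
cannot cross the band — blood has essentially no shear stiffness — so
nearly all shear-wave energy arriving at the crack is reflected.  This
package simulates that physics end to end and detects the crack from the
*reflected* shear wave alone, without reconstructing an elasticity map:

1. **`phantom`** — a 5 x 5 cm liver block (rho = 1200 kg/m^3, nu = 0.499,
   E = 6 kPa, shear speed c = sqrt(mu/rho) ~ 1.29 m/s) containing a thin
   blood-mimicking band: straight (3.2 cm deep, 1.6 mm thick, 15 degrees
   from vertical), curved (two intersecting 4.5 cm circles, 1.8 cm deep),
   or slim (0.5 cm deep, 0.5 mm thick), with closed-form edge positions
   as ground truth.
2. **`wavesim`** — explicit finite-difference solution of the
   heterogeneous scalar shear-wave equation
   `rho u_tt = div(mu grad u)` for the axial displacement, driven by one
   100 Hz cycle of a vertical push rod; 106 frames at 5000 frames/s, ROI
   export on a 200 x 400 grid.
3. **`rf`** — ultrasound RF speckle movies via the 2-D linear scattering
   model: ~475k random scatterers ride the displacement field and are
   convolved with a separable 5 MHz PSF (50% bandwidth, 0.5 mm lateral
   FWHM; 2596 samples x 256 beams at 40 MHz).
4. **`tracking`** — phase-sensitive 2-D speckle tracking on the complex
   baseband: normalized correlation over a lag search window, separable
   Hanning filtering of the correlation fields, phase zero-crossing
   refinement (`dy = phi c / (4 pi f0)`), and Eulerian accumulation over
   all 105 frame pairs.
5. **`dirfilter`** — [k, omega] directional filtering: per depth row, the
   2-D FFT quadrant pairs separate the incident (toward -x) from the
   reflected (toward +x) wave; the per-pixel sum of |reflected
   displacement| over the one-way transit window is the detection image.
6. **`detection`** — 3x3 Sobel edge detection on the reflected-amplitude
   map (Otsu threshold), selection of the leftmost tall oblique
   component, and a per-depth report of detected vs analytic edge
   positions (relative errors, detected depth).

Both imaging paths of the study are available: `speckle` (the full chain
above) and `direct` (directional filter and edge detection applied to the
simulated displacement movie itself).

## Worked example

```python
from uswicrack.pipeline import PipelineConfig, run

result = run(PipelineConfig.reduced(shape="straight", path="speckle", seed=1))
print(result.report.summary())
```

prints (about two minutes on one CPU):

```
crack detection report (speckle)
  detected depth: 3.00 cm (given 3.20 cm, ratio 93.8%)
  max |relative error|: 6.28%
 depth_cm  given_x_cm  detected_x_cm  relative_error_pct
    0.208       1.463          1.471               0.512
    0.291       1.441          1.432              -0.625
    0.416       1.408          1.348              -4.254
    0.917       1.273          1.216              -4.514
    1.291       1.173          1.161              -1.035
    1.709       1.061          1.045              -1.468
    2.083       0.961          0.942              -1.923
    2.500       0.849          0.841              -0.929
    2.917       0.737          0.691              -6.283
```

Reading the output: the crack's right (rod-facing) edge is recovered at
every reference depth, a few hundredths of a centimetre to the left of
the analytic position — the reflected-amplitude ramp of the tracked
field leans slightly into the crack — and the detected depth is slightly
short of the 3.2 cm ground truth, as expected when the deep tip reflects
weakly.  The deepest row carries the largest relative error because the
same ~0.5 mm absolute bias divides by the smallest edge position there
(see `docs/methods.md`).  A homogeneous control (`shape="none"`) reports
`no crack detected`.

The same run from the shell:

```bash
uswi-crack run --reduced --shape straight --path speckle --seed 1
```

`uswi-crack simulate/synth/track/dfilter/detect` expose the individual
stages with HDF5 intermediates; see `--help`.

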