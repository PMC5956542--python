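# Methods

`uswicrack` simulates ultrasonic shear-wave imaging (USWI) of a thin,
blood-filled crack in a liver-mimicking elastic block, end to end: wave
physics, ultrasound image formation, motion estimation, directional wave
separation, and edge-based crack delineation.  This note records the model,
the numerical choices, and what the synthetic experiments do and do not
demonstrate.

## Geometry and materials

The medium is a 5.0 x 5.0 cm block; `x` runs from its left boundary, `y`
is depth below the top free surface.  A vertical push rod (3.8 cm x
0.05 cm) sits on the centre plane `x = 2.5 cm`; the imaging region of
interest (ROI) is the left half, `x in [0, 2.5]`, `y in [0, 5]`, sampled
on a 200 x 400 grid (0.0125 cm pitch).  Inside the ROI the incident shear
wave therefore travels toward `-x`, and the crack's right edge — the one
facing the rod — is the near end that reflects.

Background tissue: density 1200 kg/m^3, Poisson ratio 0.499, Young's
modulus 6 kPa, hence shear modulus mu = E/(2(1+nu)) ~ 2.0 kPa and shear
speed c = sqrt(mu/rho) ~ 1.29 m/s (~ sqrt(E/(3 rho)) in the
incompressible limit).  The crack filler mimics blood: 1060 kg/m^3,
nu = 0.499, E = 0.005 Pa — essentially zero shear stiffness, so the band
reflects nearly all incident shear-wave energy.

Three crack bands, all opening at the top surface:

| shape    | depth  | thickness | top edges (x, cm)   | definition |
|----------|--------|-----------|---------------------|------------|
| straight | 3.2 cm | 1.6 mm    | 1.354 - 1.519       | 15 deg from vertical, tilting away from the rod |
| slim     | 0.5 cm | 0.5 mm    | 1.467 - 1.519       | same direction, same right edge |
| curved   | 1.8 cm | ~1.6 mm   | 1.354 - 1.519       | band between two r = 4.5 cm circles centred at depth 0, x = -3.146 and -2.981 |

Closed forms for the right (near) edge: `x_r(d) = 1.519 - d tan(15deg)`
(straight/slim) and `x_r(d) = -2.981 + sqrt(4.5^2 - d^2)` (curved).  The
reference comparison table of edge positions at fixed depths is generated
from these forms; all printed positions agree to 0.002 cm (their own
rounding).

## Shear-wave solver

The rod oscillates vertically, so the dominant field is the axial (depth)
displacement `u`, governed to good approximation by the heterogeneous
scalar shear-wave equation

    rho(x, y) u_tt = div( mu(x, y) grad u ).

We solve it with an explicit second-order leapfrog scheme on the
rasterised material grid (default: the ROI pitch, 0.0125 cm ~ lambda/103).
Working with the scalar axial component avoids the volumetric locking a
displacement-based vector discretisation suffers at nu ~ 0.5, and it is
the only component the imaging chain consumes; the trade-off is that the
crack filler, having no shear coupling, stays at rest instead of being
dragged inertially, and fluid-solid surface waves at the top interface are
not represented.  Face shear moduli use harmonic averaging, so the
near-zero-stiffness crack blocks flux essentially exactly; the measured
transmitted/incident peak ratio across the 1.6 mm crack is < 1e-3 at
depths where the band lies between the probes.

Boundary conditions: stress-free top (zero flux), fixed bottom (u = 0),
zero normal flux at the side walls — the scalar analogue of a roller,
which for vertically polarised shear motion at a vertical wall reflects at
full amplitude.  The source prescribes `u = A sin(2 pi f t)` on the rod
cells for one cycle of f = 100 Hz, then releases them.  The push amplitude
A = 100 um (not stated in the source study) keeps frame-to-frame motion
<= ~13 um, well under a quarter ultrasound wavelength, so phase tracking
is unambiguous.  The internal step is half the CFL bound, sub-stepped so
frames land exactly on the 0.2 ms output clock (5000 frames/s, 106 frames
over 21 ms).

Verification: the front speed estimated from half-maximum arrival times
versus distance is 1.296 m/s (closed form 1.291); the one-cycle pulse's
max-to-min spatial distance gives a wavelength of 1.32 cm (c/f = 1.29);
halving the grid changes a mid-depth interior trace by ~4% relative RMS
(the residual is dominated by the staircase representation of the thin
rod, which decays with distance from the source).

## RF speckle synthesis

Frames are formed with the 2-D linear scattering model: point scatterers
deposited on the RF grid (amplitude-weighted bilinear splatting) and
convolved with a separable point-spread function.  The axial PSF is a
5 MHz cosine under a Gaussian envelope whose two-sided -6 dB spectral
width is 50% of the centre frequency; the lateral PSF is a Gaussian of
0.5 mm FWHM.  Sampling is 40 MHz at c = 1540 m/s, i.e. 19.25 um of depth
per RF sample (pulse-echo), 2596 samples x 256 beams covering the 5.0 x
2.5 cm ROI.  Between frames each scatterer rides the simulated
displacement field (bilinear interpolation, axial only).

Scatterer density is 6 per ultrasound wavelength **per dimension**
(36 per lambda^2, ~475k scatterers in the ROI, ~45 per resolution cell).
The per-area reading (6/lambda^2, ~8 per cell) was tested and produces
measurably sub-Rayleigh (K-distributed) envelopes — decorrelated KS test
against Rayleigh rejects at p ~ 1e-11 and the envelope mean/std ratio is
1.75 — which would contradict the premise that the synthesis yields fully
developed speckle.  At the per-dimension density the envelope passes the
KS test (p ~ 0.2) and the mean/std ratio is 1.90, at the Rayleigh limit
sqrt(pi/(4-pi)) ~ 1.91.  Reported envelope SNR values above that limit
(e.g. 2.3) are not reproducible from Rayleigh statistics and are logged,
not targeted.

Speckle size is measured as the FWHM, per axis, of the envelope
autocovariance (the squared magnitude of the normalized complex baseband
autocorrelation) — the usual speckle-cell definition.  With the PSF above
this gives 0.27 mm axially and ~0.51 mm laterally, matching the axial
reference value exactly and the lateral one within 15%.

## Phase-sensitive speckle tracking

Each RF frame is mixed down by the carrier and low-pass filtered
(zero-phase Butterworth at f0) to complex baseband.  The estimation grid
lives on the RF lattice itself — every beam laterally, every 6th sample
axially at the default 0.125 mm step — so each estimate carries its
exact physical coordinate (snapping a nominal grid to the nearest beam
would mislabel positions by up to half a beam pitch, a visible bias at
the deep end of the crack contour).  For every grid point, a kernel of
roughly the speckle size (0.270 mm axial x 0.586 mm lateral, rounded to
odd sample counts) is correlated against the next frame over a lag
search window; the complex normalized correlation
is computed with integral-image kernel sums, exact to round-off.  Per lag,
the correlation field over grid points is smoothed with a separable
unit-sum Hanning window (0.781 mm lateral x 0.308 mm axial) before the
peak search.  The axial estimate is refined from the phase at the peak
lag: echo delay = lag/fs + wrap(phase - 2 pi f0 lag/fs)/(2 pi f0),
distance = delay * c/2.  Estimates at frame borders (kernel or search
window leaving the frame) and estimates whose peak correlation falls
below `min_correlation` are zeroed as unreliable.

Frame-to-frame axial increments are accumulated at fixed grid points
(Eulerian).  Per-frame motions (<= ~13 um) are two orders of magnitude
below the grid pitch, so material-point advection would change the sums
negligibly; this is a deliberate simplification of accumulation "referred
to the original geometry".

Tracking accuracy on synthesized speckle with known uniform shifts:
mean absolute error < lambda_us/20 over shifts in (0, lambda_us/4), with
the 1.5-sample shift (28.9 um) recovered within 3 um.  Against the full
simulated field, the accumulated estimate tracks the true movie with
relative RMS error ~0.2-0.4 (dominated by the decorrelated region at the
crack, where true displacement is near zero); its signed error is
negative on average — correlation tracking under a finite PSF
underestimates motion.

## Directional filtering

For each depth row, the 2-D FFT of `u(x, t)` splits into quadrant pairs
by the sign of (wavenumber x frequency): one pair is the `-x`-travelling
(incident) wave, the complementary pair the `+x`-travelling (reflected)
wave.  The pair-to-direction assignment is calibrated once per process
against a synthetic rightward wave instead of hard-coding an FFT sign
convention.  Zero-frequency and Nyquist lines are split 50/50, making the
masks complementary: `u_i + u_r` reconstructs the input to round-off.  A
Tukey taper (alpha = 0.25) along x and t suppresses periodic wrap-around;
it is divided back out after inversion where it exceeds 1e-3 (elsewhere
the field is split 50/50 between components to preserve exact
reconstruction).  Inside the taper margins the division amplifies mask
crosstalk, so all downstream consumers crop a lateral margin equal to the
taper width (0.3125 cm).

Two systematic floors are worth knowing about.  First, while the rod is
still completing its single cycle, every row contains laterally smooth
(near-zero-wavenumber) displacement whose direction is undefined; the
50/50 split puts half of it in the reflected component of *every* run,
including the crack-free control.  Second, after one transit time
(2.5 cm / 1.29 m/s ~ 19.4 ms) the incident front reaches the outer roller
wall and echoes back at full amplitude.  The reflected-amplitude map

    R(x, y) = sum_t |u_r(x, y, t)|

is therefore accumulated only over frames before the wall echo exists.
With these guards the accumulated reflected amplitude within 5 mm of the
true edge exceeds the crack-free level by ~13x (post-push window); the
broader rod-to-crack corridor reaches ~6x, capped by the push-period
floor.

## Crack detection

The crack edge is the sharp boundary of the reflected region in `R`.
After cropping the taper margins, `R` is lightly Gaussian-smoothed
(sigma 0.025 cm, about a quarter of the tracking kernel) so tracker
noise does not dominate the gradient histogram, then a 3x3 Sobel
magnitude is thresholded with Otsu's method (a percentile override is
available).  The binary mask is closed with a 3x3 element — the two
gradient lines flanking a band thinner than a few pixels (the slim
crack) belong to one structure.  Each connected component is traced as
its per-row mask centroid; rows wider than 3x the component's median row
width are dropped (horizontal cap segments, e.g. the curved band's
bottom closure, which would otherwise inflate the detected depth beyond
the given depth).  Components are then filtered:

* vertical extent >= 3 mm (rejects sparse speckle artefacts);
* the trace must be a coherent oblique line: fitted |dx/dy| >= 0.1
  (~6 degrees from vertical) and linear-fit R^2 >= 0.5.  Measured across
  every phantom/path combination, true edges have slope 0.21-0.37 with
  R^2 0.81-0.98, while the residual structures of a crack-free run are
  near-vertical or incoherent (|slope| <= 0.1, R^2 <= 0.36); this test
  is what makes the homogeneous control report "no crack detected".  A
  genuinely vertical crack edge would be rejected — a documented
  limitation of the discriminator.

Among the survivors, the component with the smallest mean x is the crack
edge; the parallel line to its right is the reflection artefact.
Detected depth is the trace's vertical span.  Reports interpolate the
contour at the reference depths and give `(detected - given)/given` per
row.

The detected edge sits slightly left of (beyond) the true edge,
systematically: correlation kernels straddling the motionless crack
interior pull near-edge displacement estimates toward zero, shifting the
reflected-amplitude ramp outward by ~0.5 mm.  The direct path (filtering
the simulated field itself, no speckle) does not carry that bias and
localises the edge to a few hundredths of a cm.  The absolute bias is
roughly depth-independent, so the *relative* error is largest at the
deepest comparison row, where the edge position is smallest: for the
straight crack the deepest row reaches 5-8% depending on the scatterer
realization while every other row stays within ~4.5%.  In a full elastic
model the nearly incompressible blood filler is dragged inertially by
pressure coupling, preserving near-edge correlation; the scalar
surrogate cannot represent that, and the residual deep-row bias is the
price.

## Problem sizes and presets

The default configuration is the full study condition: 0.0125 cm solver
and estimation grids, 106 frames, 2596 x 256 RF frames, 0.781 mm search.
The packaged `reduced` preset used by the test-suite's end-to-end checks
and the acceptance script keeps the grids and frame counts but caps the
lag search at +-4 axial samples and +-1 beam: the physical inter-frame
motion is below one RF sample, so the cap loses nothing while cutting the
correlation cost by an order of magnitude.  One full speckle-path run at
the reduced preset takes on the order of two minutes on one CPU.

## Limitations

* Scalar shear-wave surrogate: no mode conversion, no Scholte wave at the
  top interface, motionless crack filler (a nearly incompressible fluid
  filler would be dragged inertially in a full elastic model).
* Eulerian accumulation and axial-only scatterer motion.
* The obliqueness discriminator assumes a tilted crack.
* Single scatterer realization per run; detection scatter across seeds is
  of the same order as the per-row relative errors.
* No attenuation, no electronic noise, no beamforming artefacts: passing
  tests show the method's behaviour under ideal image formation, not its
  robustness on a clinical scanner.
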