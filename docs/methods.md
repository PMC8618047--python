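# Methods

## Problem and model

Infrared breast thermography records the skin temperature field of the
breast. A warm lesion (elevated metabolic heat plus perfusion) buried at
depth `d` below the surface behaves, in the steady-state analysis of the
bio-heat balance, like a point heat source. Its surface signature along a
radial coordinate `a` measured from the point directly above the source is

    T(a) = Te + q / (4 π h0 (d² + a²)),

with `Te` the ambient temperature (°C), `h0` the skin–environment heat
exchange coefficient (W/m²·°C) and `q` the source intensity (W). The peak
temperature is `Tmax = T(0) = Te + q / (4 π h0 d²)`. A spherical source of
radius `R` is a point source at effective depth `d + R`.

Two inverse routes recover `(d, q)` from an observed radial profile:

1. **Closed-form (D-I-R) inversion** at a single offset `a`:
   `d = a·√((T(a) − Te)/(Tmax − T(a)))` and
   `q = 4 π h0 a² (T(a) − Te)(Tmax − Te)/(Tmax − T(a))`. These are exact
   algebraic inversions of the forward model (the square root follows from
   dimensional consistency and the forward–inverse identity, which the
   test suite enforces to 1e-9). An equivalent source radius
   `R = ∛(q/(Qm·At))` is derived from the metabolic heat rate `Qm` of
   active tissue; the sphere-volume alternative `∛(3q/(4πQm))` is
   selectable via `ModelConstants(radius_convention="sphere")`. Since `R`
   enters only as a classification feature, only its strictly monotone
   relation to `q` matters.
2. **Lorentz-curve fitting** of the whole profile to
   `y = A/(a² + w²) + y0` by least squares, giving `d = |w|` and, under
   the `4πh0 = 1` unit convention, `q = A`. `w` only enters squared, so it
   is reported positive.

Evaluated at an offset `a`, either route yields the five-feature pattern
vector `{Tmax, d, q, R, θ}` with `θ = arctan(q/a)` in degrees. The ratio
`q/a` is dimensionally inhomogeneous (intensity over length); it is
implemented literally as the numeric ratio in the method's own units,
because the angle is a discriminative feature, not a physical quantity.

## Profile extraction

The breast region is delimited semi-automatically: cubic polynomials
`row = p(col)` are least-squares fitted to annotated inframammary-fold
points and everything strictly below the curve (or outside the lateral
annotation span) is masked. Annotations come from a CSV file rather than
interactive clicks, for reproducibility.

The hottest masked pixel anchors the region of interest (ties broken
row-major, deterministically). The surface temperature distribution is the
mean of four axis-aligned rays (up, down, left, right) sampled at integer
pixel offsets `k`; with the default camera geometry the object-plane pixel
is exactly 0.06 cm, so the offset grid step is 0.0006 m and sampling is
on-lattice with no interpolation. A ray that leaves the image or mask is
dropped from that offset onward; the profile truncates when all four are
gone, and is capped at 1.8 cm because hotspots sit close to the image
boundary in frontal views. Because the four directions are averaged,
signed offsets are redundant and the profile lives on |a| ∈ {0, 0.0006, …,
0.018} m (31 offsets). Diagonal rays are deliberately not sampled: their
lattice step is √2 pixels and would require resampling.

## Camera geometry

Thin-lens scaling: object height `lo = sensor_height/f · distance`
(2.16 cm / 7.5 cm × 100 cm = 28.8 cm), pixel size `Sp = lo / n_rows`
(28.8/480 = 0.06 cm). The vertical axis is used; pixels are square (45 μm
detector pitch). Defaults: `h0 = 8.77 W/m²·°C`, `Qm = 418.6 W/m³`,
`At = 1`, `Te = 22 °C`. `At` as printed in the source literature is
dimensionally ambiguous (a "cell volume" quoted in length units); it is
treated as a configurable dimensionless constant, again because only the
monotone `q → R` map matters downstream.

## Numerical choices

- Lorentz fitting uses Levenberg–Marquardt (`scipy.optimize.curve_fit`)
  with tolerances 1e-12 and at most 1000 function evaluations. Initial
  values: `y0⁰` = profile minimum, `w⁰` = first offset at half prominence
  (last offset if the profile never drops that far), `A⁰ = (Tmax − y0⁰)·(w⁰)²`.
  A profile with no prominence (flat) raises a fit failure rather than
  returning a degenerate amplitude.
- Closed-form inversion rejects samples at or above `Tmax` (singular) and
  below `Te` (unphysical); a sample exactly at `Te` returns zero depth and
  intensity with a warning.
- Pattern vectors are only evaluated on the profile's own offset grid — no
  interpolation — and only at `a > 0` (θ is otherwise a saturated constant).
- The Lorentz route fits once per profile, so its `(d, q)` are independent
  of `a`; `Tmax` and `θ(a)` carry the positional dependence of its pattern
  vector. Fitting per position would refit the identical curve.
- For both methods a coefficient of determination R² between the observed
  profile and the profile reconstructed from the recovered parameters is
  attached to the result. For the closed-form route the reconstruction is
  anchored at `Te`; when the real baseline skin temperature sits well above
  ambient this anchors the tail wrong and R² is low even though `(d, q)`
  are perfectly discriminative — the Lorentz route absorbs the baseline
  into `y0` and scores near 1. This asymmetry is expected on the synthetic
  cohort (flat elevated background) and is reported, not hidden.

## Classification

At a fixed offset the cohort's pattern vectors form an n × 5 feature table
with binary labels (normal = 0, abnormal = 1); rows whose extraction fails
are dropped and logged. A C-classification SVM with an RBF kernel
(delegated to scikit-learn; the dual optimization is textbook machinery,
not this package's contribution) is evaluated by stratified 10-fold
cross-validation with a mandatory fold seed — stratification because the
cohort is imbalanced (49/38). Features are standardized with the training
fold's statistics only; raw-feature behaviour is available via
`scale_features=False` (RBF kernels are scale-sensitive, so scaling is the
default). Hyperparameters default to `C = 1`, `gamma = "scale"`; both are
exposed. CRC is the percentage of correct out-of-fold predictions — every
row is predicted exactly once, out of fold. Scanning CRC over the positive
offset grid gives the optimal extraction position, ties broken toward the
smallest offset (smallest region of interest). Sensitivity and specificity
take abnormal as the positive class; the ROC/AUC uses the signed distance
to the separating hyperplane as the score.

## Synthetic cohort

The generator emulates the screening-study conditions: 87 members
(49 normal / 38 abnormal), ambient 22 °C, 0.6 mm pixels, additive Gaussian
sensor noise of 0.04 °C (the detector sensitivity), a flat per-subject
baseline skin temperature drawn from 30–34 °C (an optional vertical ramp
stresses robustness), a gentle cubic inframammary fold masking the bottom
of the frame, and one embedded point source per member placed at least
40 px from the frame edge so the full 1.8 cm profile survives hotspot
jitter under noise.

Source parameters are sampled per class as a depth range plus a
peak-elevation range, with the intensity induced as
`q = ΔTpeak · 4 π h0 d²`. Sampling `q` directly from a box would either
produce unphysical skin temperatures or mostly violate the labeling
constraint; the induced joint `(d, q)` ranges are still class-disjoint
(normal: deep and mild, d ∈ [10, 15] mm, peak +0.5–1.2 °C; abnormal:
shallow and hot, d ∈ [4, 8] mm, peak +2.5–5 °C). Every abnormal member
must satisfy the peak-minus-mean criterion ΔT ≥ 2 °C and every normal
member ΔT < 2 °C; violators are resampled (bounded retries), and labels
remain tied to ground-truth source presence.

What the synthetic cohort does **not** emulate: vascular texture,
left/right asymmetry, perfusion heterogeneity, body-contour temperature
gradients, acquisition artifacts. Passing tests therefore demonstrate the
correctness of the extraction/inversion/classification machinery and its
qualitative behaviour (separable cohorts classify perfectly; label-
permuted cohorts classify at chance), not clinical performance on real
thermograms.

## Problem sizes

Unit tests use 14–26-member cohorts on 120 × 120 grids; the acceptance
script runs the full 87-member cohort on 120 × 120 grids with the
30-position scan for both methods, which completes in a few seconds. The
120 × 120 frame at 0.6 mm/px spans 7.2 cm — ample for the 1.8 cm radial
profile — and is the package's default cohort frame; full 640 × 480 frames
are supported everywhere a `Thermogram` is.

## Known limitations

- Semi-automated segmentation only; no automatic inframammary detection.
- Single-source model: overlapping sources bias `(d, q)` toward an
  effective blend.
- The closed-form route is exact only when the true baseline equals `Te`;
  an elevated baseline turns its `(d, q)` into consistent but biased
  features (still discriminative, as the cohort tests show).
- Frontal views only; no lateral views, armpit or lymph-node regions.
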