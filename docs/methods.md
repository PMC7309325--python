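# Methods

`respvol` estimates respiratory volume from a sequence of depth images of
a person's torso. The core idea: the chest wall bulges toward the camera
during inspiration, so the volume of air moved per breath can be read off
as the surface integral of the depth change over the *respiration-related
region* — provided that region can be isolated from everything else that
moves or merely sits at a similar distance. The isolation is done with
level-set active contours carrying two extra sources of information: the
shape of the chest wall (spatial) and the segmentation of the previous
frame (temporal).

## Pipeline

1. **Chest wall W** (one frame). A Chan-Vese two-phase evolution on the
   min-max-normalized depth image, plus a shape-dissimilarity penalty
   against a reference chest-wall outline. Depth alone cannot separate
   the chest from arms resting against the torso — the depth values
   coincide — so the shape term supplies the missing boundary.
2. **Respiration-related region R_t** (every frame pair). The difference
   image between consecutive frames is segmented by magnitude into a
   motion class, weighted by a region-information function p(x): 1
   inside W, smoothly decaying outside it, so depth changes far from the
   chest wall are discounted. The adaptive variant transfers weight from
   R_{t-1}: pixels that stayed in the region keep a bonus of up to TH,
   which retains weak but sustained motion (shallow abdominal breathing)
   while one-off events (a jolt, a noise blob) never accumulate weight.
3. **Volume**. Per frame, V(t) = Σ_{r∈R_t} Δdepth(r) · C(d(r))² in mm³,
   where C(d) = 0.0041·d + 0.0046 is the physical side length (mm) of a
   pixel at depth d. The running sum of {V(t)} is the volume trajectory;
   a breath is a valley-to-peak excursion of that trajectory and its
   height is the tidal volume.
4. **Evaluation**. Tidal volume error (mean per-breath relative error),
   volume waveform error (summed absolute discrepancy relative to the
   reference), ICC in the absolute-agreement single-measure form, and a
   Kruskal-Wallis + Dunn comparison of per-breath errors across method
   variants.

The three method variants mirror the design's ablation: `spatial` fixes
R_t = W; `temporal` segments each difference image with the static
weights; `adaptive` adds the previous-frame transfer.

## Level-set numerics

A region is the positive set of a signed distance field φ (positive
inside). The regularized Heaviside is H_ε(z) = ½(1 + (2/π)·arctan(z/ε))
with its analytic derivative as the Dirac bump; ε = 1.5 px during
evolution. Signed distances come from the Euclidean distance transform
with a 0.5 px boundary offset. Reinitialization (every 10 iterations)
rebuilds the far field from the sign mask but keeps the sub-pixel front
position in the interface band via φ/|∇φ| — a purely grid-snapped
rebuild freezes any front slower than ~0.05 px/iteration, which silently
halts evolutions whose driving force is modest.

Gradient descent uses an explicit scheme with dt ≤ 0.45/μ (μ = curvature
weight, default 0.2) and a backtracking step that halves dt when a trial
update raises the total energy, so the energy trace is non-increasing up
to round-off between reinitializations. Convergence is declared when the
sign flips summed over a 25-iteration window fall below 0.1% of pixels:
slow fronts flip pixels in bursts ~15 iterations apart, so a
per-iteration test stops evolutions that have not finished. c1/c2 are
recomputed every iteration; invalid pixels (depth 0) are excluded from
the means and carry no data force.

## Shape prior

The dissimilarity energy is the summed squared Heaviside difference
between the evolving region and the prior after mapping both into a
pose-normalized frame; the pose is the centroid plus principal axes and
eigenvalues of the region's second central moments. Pose weights use a
compactly supported ramp indicator rather than the arctan Heaviside,
whose slowly decaying tails otherwise bias the moments toward the image
center. Normalization is a similarity transform (rotation + isotropic
geometric-mean scale): an anisotropic stretch is treated as genuine
mismatch, because a torso-plus-arms blob differs from a torso mostly by
width.

The evolution alternates pose recomputation with descent of the
pose-frozen first variation (the full variation's pose-derivative terms
are numerically fragile and are not evolved). Three further choices make
the term work as a force:

* **Weight normalization.** The raw first variation carries
  |det(Λ^-1/2)| ≈ 1/(σ₁σ₂) of the region, which is vanishingly small for
  body-sized shapes next to the O(1) Chan-Vese data force on a
  unit-normalized image. The evolution instead scales the force so that
  a full mismatch at the contour center exerts exactly `lambda_shape`
  (default 0.5) in data-force units. The `shape_energy_gradient`
  operation still returns the unscaled formula.
* **Sharper mismatch width.** The mismatch uses its own ε_shape = 0.75 px:
  the arctan tails are fat, and with the evolution width the contour can
  creep several pixels past the prior boundary before the mismatch
  saturates.
* **Translation-only alignment during segmentation.** A torso's second
  moments are nearly isotropic, so the fitted rotation is arbitrary and
  letting it float spins the warped prior, destabilizing the force; the
  camera-to-subject distance is fixed, so the prior's scale is trusted
  too. Only the centroid tracks the evolving region. `shape_energy`
  itself retains the full similarity normalization.

## Temporal stage

Motion segmentation operates on the smoothed magnitude of the difference
image (Gaussian σ = 2 px; breathing produces signed changes and
Chan-Vese separates by mean intensity). Differences are additionally
averaged over a 3-frame window for segmentation only — breathing varies
over tens of frames, so the signal is untouched while sensor noise drops
by √3; volume integration always uses the raw differences. Magnitudes
are normalized by the 99th percentile over the sequence.

The region term enters as a normal speed λ_region·(p − 1): neutral at
the in-W baseline, contractive outside W (p < 1), expansive where the
adaptive bonus raises p above 1. This is the descent direction of
−λ·∫_IF (p − 1), i.e. the region-information energy recentred at its
in-W value; the uncentred version is an unconditional ballooning force
(p ≥ 0 everywhere) that cannot reject off-chest motion.

Each frame's contour is initialized at the strong-motion pixels
(normalized magnitude ≥ 0.5 where p ≥ 0.5, cleaned by a radius-2
morphological opening that rejects speckle excursions of the noise
field) and grows outward. Starting from all of W would require shedding
every motionless pixel, which a finite iteration budget cannot do.

The adaptive transfer needs two guards, both applied to the evolution
only (`adaptive_region_info` returns the plain branch values):

* **Support gating with a noise-adaptive floor.** The plain bonus
  (TH = 1) outweighs any Chan-Vese data deficit, so a pixel annexed once
  — e.g. from a noise blob — could never be expelled, and under sensor
  noise R ratchets up to the whole chest wall. The bonus is therefore
  gated by current motion support above a retention floor, estimated per
  sequence as 1.8 × the robust spread (MAD) of the far-background motion
  values and clipped to [0.08, 0.45]. On a noiseless recording the floor
  is minimal and shallow sustained motion is retained; under heavy noise
  the floor rises automatically.
* **Growth band and quiet-frame persistence.** The bonus extends 1.5 px
  outside R_{t-1}, so a sustained weak region is annexed ring by ring
  instead of being unreachable from outside. At breath turnarounds
  motion pauses everywhere and the support gate would empty R; on a
  globally quiet frame (99th percentile of in-W motion below twice the
  floor) nothing can be misincluded, so the region persists. The carry
  is further gated on the bonus being material (f ≥ 0.25), which makes
  the whole adaptive machinery vanish continuously as TH → 0.

"Applied from the second iteration" is implemented at frame level: the
first tracked frame has no previous result and uses the static weights.

## Volume and breaths

The sign convention is inhale-positive (depth is distance to camera, so
inspiration decreases depth; the difference is previous − current).
C is evaluated at the mean of the two frames' depths: with a single
noisy frame, the noise inside C² correlates with the same noise in the
difference (E[n·C²(d+n)] ≠ 0) and biases every frame volume by about
−2Cσ²·slope per pixel — roughly 1 mL/frame at the phantom's geometry
with 1.5 mm noise, which integrates into a severe drift. The symmetric
average cancels the correlation exactly. The mm³→mL factor is 1/1000.

Tidal volumes are read from the cumulative series (the per-frame series
is exposed alongside): volume increments are what the masked difference
sums deliver, and a valley-to-peak rise of their integral is the
physically meaningful tidal volume. Breath detection uses prominence-
and spacing-filtered peak finding (defaults: 1.0 s minimum duration,
50 mL minimum prominence). Linear detrending of the cumulative series is
available but off by default.

## Evaluation formulary

The ICC is computed from the two-way (time × waveform) ANOVA mean
squares in the single-measure absolute-agreement form

    ICC = (MS_R − MS_E) / (MS_R + (k−1)·MS_E + (k/n)·(MS_C − MS_E)),

which penalizes both noise and constant bias. The Kruskal-Wallis H uses
average ranks with tie correction and a chi-square reference; Dunn's
pairwise z statistics use the tie-corrected pooled variance with
Bonferroni adjustment (the most common pairing with Dunn's test).
Breaths are matched between estimate and reference by greatest temporal
overlap of their valley-to-peak intervals, falling back to index order;
unmatched breaths are counted and reported, never silently dropped.

## Phantom

The generator renders a torso (domed ellipse at 450 mm, within the
40–50 cm working range of a close-range depth camera), optional arms at
a 3 mm depth offset, and a background plane at 800 mm; 16 fps; default
320 × 240 with all geometry in frame fractions so one config scales
(presets use 120 × 160, and the pixel-size calibration is scaled by the
column ratio so a coarser rendering keeps the same physical scene).
Breathing displaces a flat-topped raised-cosine envelope toward the
camera by A·u(t), u(t) = (1 − cos 2πt/T)/2, with A = 12 mm and T = 4 s
(≈ 292 mL tidal volume at the desk scale — a normal resting breath; 30
breaths in the 2-minute clean run). Optional ingredients: a weaker
(0.3×) abdominal patch lagging the rib cage by 0.5 s; brief 8 mm jolts
on an arm; a slow whole-body sway (2 mm at 17 s in the `jolt` preset —
seated postural sway is 1–3 mm, and this magnitude makes the fixed-mask
variant's handicap visible without corrupting the depth data for every
method); Gaussian sensor noise (1.5 mm in the `noisy` preset) and 1 mm
depth quantization everywhere (consumer time-of-flight class).

Ground truth is computed from the pre-noise displacement field: the
chest mask, per-frame-pair respiration-region masks (frame-to-frame
breathing displacement change above a 0.1 mm floor), the analytic
cumulative waveform, and the analytic tidal volume. Truth volumes use
the same pixel calibration as the estimator, so calibration error
cancels and the comparison isolates segmentation quality.

What the phantom does *not* emulate: perspective foreshortening and lens
distortion, depth shadows and dropout, specular or material-dependent
noise, cardiac micro-motion, clothing wrinkles, and multi-frequency
breathing. Passing on the phantom therefore shows that the segmentation
machinery behaves as designed under controlled interference, not that
the clinical accuracy figures of any particular camera are reproduced.

## Known limitations

* Whole-body motion inside the chest wall (axial sway) at breathing
  amplitude is indistinguishable from breathing at the per-pixel level;
  all variants degrade, the fixed-mask one fastest. In practice,
  recordings with breath-synchronized body movement have to be
  discarded.
* The adaptive region's first breath is a warm-up (the region is still
  being annexed), so its tidal volume reads ~5–8% low.
* The static temporal variant's threshold cannot recover motion below
  the sensor noise floor near breath turnarounds; its volumes are biased
  low by design — that gap is precisely what the adaptive transfer
  closes.
* The alternating pose scheme can tolerate a few pixels of prior
  misalignment but is not a registration method; a grossly wrong prior
  yields a grossly wrong chest wall.
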