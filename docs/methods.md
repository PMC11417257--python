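# Methods

This note documents the models, estimators, defaults and known limitations
behind `fibremech`, in the order data flows through the pipeline.

## Conventions and units

Heights and displacements in nm; lateral positions and pixel sizes in µm;
forces in nN; stresses in MPa; strains as dimensionless fractions (rendered
as percent in reports); wavenumbers in cm⁻¹; transmittance in %T. Force is
positive-repulsive; attractive excursions are negative and the reported
attraction/adhesion are magnitudes. Images are row-major with origin
top-left and physical positions at pixel centers. One fixed dataset layout:
`<root>/<dye_count>/<fiber_id>.<modality>.txt` with `manifest.csv` at the
root.

## Synthetic cohort: what it emulates

The generator produces per-fiber data for four modalities with the truth
parameters recorded exactly in the manifest, so each analyzer can be tested
by parameter recovery.

**Topography.** A cuticle surface is modeled as a staircase along the column
(fiber) axis — terraces of length `terrace_length` (default 4.5 µm, so a
15 µm field of view spans three to four scales) separated by rises drawn
from Normal(step_height_mean, step_height_sd²) — plus a tilt plane, a
correlated Gaussian roughness field (white noise smoothed to the stated
correlation length and rescaled to the target point sd), and optional
Gaussian debris bumps. The first terrace starts at column position 0, so a
terrace longer than the field of view degenerates to a flat image by
construction.

**Force–distance curves.** Piezo displacement increases toward the sample.
The approach is a zero-force baseline, a sharp 3-sample attractive ramp to
−attraction_depth at the contact point (snapped onto the displacement grid
so noiseless dip depths are exact), then a linear contact rise with the
series-spring slope k·S/(k+S) up to the setpoint (default 9 nN; the
instrument class this emulates is limited to 10 nN). The retract follows the
same contact line down through −adhesion_depth, touches it exactly at the
pull-off sample, and returns to baseline. `sample_stiffness = inf` is the
rigid-surface flag (slope = k). Gaussian force noise (default 0.02 nN) is
added per branch.

**Tensile curves.** Piecewise-linear stress over an equally spaced strain
grid ending at fracture: slope E on [0, ε_y], a yield plateau with slope
0.02·E on [ε_y, ε_p], slope E_post up to ε_fracture. The plateau slope is
deliberately 2 % of E rather than zero: the yield region shows minimal — not
degenerate — stress change, so segmentation cannot cheat. Default noise
2 MPa.

**Spectra.** Transmittance = 100 %T + a small linear slope − a sum of
Gaussian dips (center, depth, sigma), clipped at 0, plus noise (default
0.3 %T), sampled on the instrument grid 400–4000 cm⁻¹ at 4 cm⁻¹.

**Default dose–response truths** (0/1/3/5/7/10 dye cycles, 25 fibers per
group — the study design this emulates measured 20–30 fibers per group):
step height 430.2 → 343.3 nm after one dye (−20 %) with partial recovery but
never back to control; fine-scale roughness sd rising monotonically 5 → 14
nm; contact slope 0.163 nN/nm flat to three dyes, dipping at five, +4 % at
seven and +10 % at ten; attraction 0.591 nN falling 38–51 %; adhesion rising
from five dyes on; elastic modulus 3000 → 8700 MPa (+190 % at ten dyes);
fracture strain 47 % control vs 52–54 % dyed; amide and water dips shrinking
(water at ≥5 dyes set to 48 % of control), cysteic-acid dip shrinking after
three dyes, and a 5 %T NH₂ dip at 1575 cm⁻¹ present only in dyed groups.
Where the emulated study reports a number it is used directly as the truth;
where it reports only a direction, a value consistent with that direction
was fixed once. Noise defaults (0.02 nN / 2 MPa / 0.3 %T / 5 nm roughness
on the control surface) are small enough for recovery within the stated
tolerances and large enough that every detector must actually reject noise.

**What the generator does not emulate:** tip convolution and scanner
artifacts, cantilever calibration error, viscoelastic hysteresis beyond a
single adhesion dip, slack/toe-in at the start of tensile records,
absorbance nonlinearity and ATR penetration-depth effects, and any dye
chemistry — group differences enter only through the truth parameters.
Passing recovery tests therefore demonstrates the estimators are correct and
unbiased under this noise model, not that they are robust to every artifact
of real instruments.

## Topography metrology

**Flattening** is a least-squares polynomial surface fit (order 0/1/2;
default 1, i.e. the mean plane) subtracted from the image; it is idempotent
and preserves step magnitudes up to the removed affine trend.

**Step detection** works on a line profile along the column axis (single row
or an averaged row band; the pipeline averages all rows, which suppresses
white noise by √k and washes out debris bumps). The profile is detrended
with a robust slope — the median of pairwise slopes at a lag of half the
minimum terrace, not single-pixel differences, which would let noise
accumulate across a terrace — then segmented by an O(n²)
optimal-partitioning dynamic program minimizing within-segment squared error
with a per-segment penalty 8·σ̂²·log n (σ̂ from the median absolute first
difference; a tiny span-scaled term keeps the noiseless case determinate)
and a minimum segment length. The common slope is then re-estimated jointly
with per-terrace offsets by least squares and the terraces re-referenced to
it. Adjacent segments whose medians differ by less than `min_height`
(default 50 nm) are merged; each remaining boundary with flanking terraces
at least `min_terrace` (default 1 µm) long is reported with height =
difference of terrace medians. Medians rather than edge differences make
the heights robust to edge rounding and debris spikes. On noiseless
staircases the recovery is exact.

**Roughness.** After flattening, Sa = mean |z − mean(z)| and Sz = max − min
over the full sampled area (areal convention; a profile-wise Sz is exposed
as `sz_profile_max` since the phrase "of the profile" is ambiguous in
common usage). The two-scale analysis computes Sa/Sz on the full (step-
spanning) image and on a 3 × 3 µm² crop; the pipeline places the crop on the
flattest candidate window (minimum Sz over a 1 µm stride grid), emulating an
operator choosing a single cuticle surface. Step-spanning windows are
rougher than single-terrace windows whenever the step height exceeds the
surface noise.

## Force–distance analysis

Baseline correction fits a line to the far-from-surface quarter of each
branch and subtracts it — per branch, so attraction is a function of the
approach only and adhesion of the retract only, and a constant force offset
or small baseline tilt changes nothing. A curve whose "far" segment rises as
steeply as its contact end has no identifiable non-contact region and is
rejected. Attraction and adhesion are the dip magnitudes (minimum force) of
the baselined approach and retract; values not exceeding 3× the robust
(MAD-based) far-segment noise sd are reported as 0 with a not-detected flag.
No ordering between attraction and adhesion is imposed. The contact point
is the first crossing of +3·σ̂ after the snap-in minimum (a deterministic
threshold rule, since the convention is not standardized); stiffness is the
least-squares slope over the top 70 % (configurable) of the contact region,
with R² < 0.9 flagged. Stiffness is reported raw (bounded by the cantilever
constant; a noisy fit marginally above k is clipped to k) with the
series-spring inversion as a secondary output; whether approach or retract
contact data is used is configurable (default approach). No Hertz/DMT/JKR
contact-mechanics fitting is attempted — only the slope stiffness.

## Tensile analysis

σ = F/A with a circular cross-section from the recorded diameter; gram-force
pre-tension converts at 1 gf = 9.80665 mN and its subtraction is off by
default (whether the gauge force appears in σ is instrument convention).
Segmentation fits a continuous three-piece linear model (basis 1, ε,
(ε−b₁)₊, (ε−b₂)₊) by exhaustive coarse search over a breakpoint grid
(b₁ ∈ [1 %, 30 %], b₂ ∈ [20 %, 90 %] of the strain span, minimum gap 5 %)
followed by three factor-5 local grid refinements — deterministic, no random
initialization. A fit is degenerate (whole curve treated as pre-yield) when
three pieces improve the single-line SSE by less than 20 %; a middle slope
that is not the smallest of the three sets a segmentation-failure flag.
Modulus = least-squares slope over the pre-yield segment; yield stress = the
maximum stress within pre-yield (so under noise it carries the expected
positive extreme-value bias — documented, not corrected); fracture = the
last recorded sample, since the instrument stops at break (a max-stress-drop
detector for real traces that run past the break is deliberately not
needed for synthetic data and out of scope here).

## FT-IR quantification

Band intensity is the transmittance dip depth below a local linear baseline
(the chord through the window endpoints), with the center at the maximum
depth. Depth-below-local-baseline is the reproducible surrogate for "band
intensity" when the instrument's global normalization is unknown; a deeper
dip means stronger absorption, and the package reports depth and its
direction of change explicitly rather than a sign-ambiguous "transmittance
change". No absorbance (−log T) conversion or ATR correction is applied.
Presence requires depth ≥ 3× the noise sd of a depth reading — √2 times the
spectrum noise estimate, because a depth subtracts a two-point chord from a
point, all noisy — plus at least one immediate neighbour of the peak at half
that threshold (real bands are wider than one 4 cm⁻¹ sample; single-point
noise spikes are not; one-sided support tolerates bands riding a
neighbouring band's shoulder, as the 1575 cm⁻¹ NH₂ band rides amide II).
This keeps the false-positive rate on noise-only windows below 1 % while
detecting every configured band. Known estimator biases: the chord baseline
clips the tails of bands that are broad relative to their window (amide I
reads ~3 % low, water ~5 % low), and the max rule adds a small positive
noise bias that matters only for shallow narrow bands (cysteic acid, NH₂) —
which is why the truth-recovery table tracks amide I and water but not the
two shallow bands, whose role is trend/presence read-out. Optional width-3
moving-average smoothing is off by default.

## Statistics

Mean ± SEM (sd/√n, n−1 denominator) with the fiber as the experimental unit:
per-fiber values (e.g. the mean of a fiber's detected step heights) are
computed first and group statistics run over fibers. Comparisons vs the
undyed control use the classic pooled-variance two-tailed Student's t
(df = n_A + n_B − 2), matching the named method of the emulated analysis;
Welch's correction is available behind a flag. Stars use the inclusive
thresholds *p ≤ 0.05, **p ≤ 0.01, ***p ≤ 0.001, ****p ≤ 0.0001. Degenerate
inputs: zero variance with equal means gives t = 0, p = 1; zero variance
with unequal means gives p = 0 flagged degenerate. No multiple-testing
correction by default (a Bonferroni option exists) — consistent with
reporting each metric's dose-response as its own family.

## Problem sizes and reproducibility

Default sizes — 128 × 128 topography over 15 × 15 µm², 500-point FD
branches, 800-point tensile records, 4 cm⁻¹ spectra, 25 fibers × 6 groups —
were chosen so a full simulate → analyze → report cycle completes in well
under a minute on one CPU while every estimator still faces nontrivial
noise; all generators accept larger sizes (e.g. the instrument-native
512 × 512) unchanged. Every generator is a pure function of (truth,
geometry, seed); cohort seeds are spawned from a single SeedSequence, so a
config and seed reproduce a byte-identical dataset, manifest and report.

## Known limitations

- Step detection assumes the scan is aligned with the cuticle axis (steps
  run along the image columns); arbitrarily oriented scans would need a
  rotation step that is out of scope.
- The segmentation penalty and thresholds are tuned for staircase-like
  profiles with steps ≥ ~10× the profile noise; gradual ramps between
  terraces blur the boundary position (heights remain robust via medians).
- The FD contact-point rule is threshold-based and will place the contact
  point slightly late on very soft samples (slope ≪ noise/point-spacing);
  the stiffness fit over the top of the contact region is insensitive to
  this.
- Tensile curves are assumed to start taut at ε = 0; toe-in from slack
  mounting would bias the modulus low.
- FT-IR depths are in %T on a local baseline: they are comparable within a
  band across groups, not across bands with different window widths.
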