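# Methods

This note records the scientific model implemented by `periq`, its
assumptions, the defaults that matter, and the numerical and design
choices made where more than one convention was defensible.

## Optical model

Wavefronts are 6th-order Zernike expansions over a 3 mm pupil, OSA/ANSI
double-indexed with unit-variance normalisation, coefficients in
micrometres. The conversion between the defocus coefficient and
spherical-equivalent refraction is M = −4√3 · c(2,0) / r² (c in µm, r the
pupil radius in mm, M in dioptres), so a positive defocus coefficient is
myopic.

The PSF is computed by Fraunhofer propagation: the generalised pupil
function A·exp(i2πW/λ) is embedded in a zero-padded grid and Fourier
transformed; the squared modulus is cropped to a 128 × 128 window
(≈ 30 arcmin) and renormalised to unit sum. The padded grid size N is the
integer that makes the PSF pixel pitch λ/(N·Δx) equal the reference-image
pitch of 0.234375 arcmin **exactly**; the pupil sampling is then re-derived
from N, which perturbs the requested 128 samples across the pupil by well
under 0.1 % (the constructor rejects configurations where no integer N
lands within 10 %). Piston and tilt, if present, are ignored: piston is
invisible and tilt only translates the image, which a registered zero-lag
metric must not see. A single wavelength (532 nm) is used; chromatic and
polychromatic effects are out of scope.

Validated behaviour: the aberration-free PSF reproduces the Airy first
dark ring at 1.22λ/D ≈ 0.744 arcmin (checked on a 4× finer pitch, where
the discretisation is ±0.059 arcmin); even aberrations give
centro-symmetric PSFs to 1e−10; Strehl never exceeds the diffraction
limit; doubling the pupil sampling changes the PSF by < 1e−3 RMS.

## Retinal-image simulation

The reference scene is a 512 × 512 grayscale image subtending 2°
(0.234375 arcmin/pixel). The built-in reference is a **synthetic** seeded
1/f-amplitude-spectrum texture — the canonical natural-image statistic —
because the classical photographic test images are copyright-encumbered;
any user image ≥ 512 px can be substituted (centre-cropped/rescaled,
normalised to [0, 1]).

Convolution is linear, evaluated over the full reference extent with
symmetric boundary padding. Edge reflection can leak a mean shift of
order 1e−4 on a natural texture, so the output is rescaled
multiplicatively to preserve the input mean exactly; the Pearson metric is
affine-invariant, so this is cosmetic, and it keeps the stated
mean-preservation contract at machine precision.

The neural cutoff surface is piecewise linear (Delaunay triangulation,
`scipy` LinearNDInterpolator) over 20 anchors on the five measured
meridians, decaying from 48 cyc/deg at the fovea to ≈ 6 cyc/deg at 40°,
with a mild nasal-temporal asymmetry; outside the anchors' convex hull the
nearest anchor value is used. The anchor table is a literature-plausible
**fixture**, not measured data, and is fully replaceable
(`CutoffSurface.from_csv`). The Gaussian low-pass reaches half amplitude
at the cutoff, σ_f = f_cutoff/√(2 ln 2); 1/e and 2σ conventions are
selectable. DC gain is exactly 1. Filtered images are cropped by
64 px/side (to 384 × 384), removing the band that convolution padding can
contaminate.

One consequence worth knowing: because the limit path keeps the
diffraction-limited PSF, and the broadband 1/f reference carries energy to
the 128 cyc/deg image Nyquist, the foveal neural-limit correlation is
≈ 0.92 rather than 1 — perfect quality is unreachable by construction,
which is exactly why quality is reported *relative to* that limit.

## Quality maps

The metric is the zero-lag Pearson correlation of pixel intensities,
clamped below at 0 so it reads from 0 (worst) to 1 (best); images are
registered by construction, so no lag search is performed. If exactly one
image is constant the metric is defined as 0; two constant images are an
error. Sampling locations default to x ∈ {−20…+20} every 5° on the five
fixation meridians y ∈ {−20, −10, 0, +10, +20} (45 samples). Maps are
piecewise-linear interpolations of those samples onto a 40 × 40 grid at
half-integer degrees (−19.5…+19.5), clamped to [0, 1]; the half-integer
convention is what makes the innermost field segments hold exactly 16
cells. Coefficients are interpolated directly (not residuals against an
intermediate surface fit — with piecewise-linear interpolation the two
formulations collapse to the same map wherever both are defined).
Difference maps are cellwise limit − optical; tiny negatives (≥ −0.02)
can arise from interpolation and are reported, not clamped.

## Segmentation and classification

Cells are assigned by strict dominance to nasal/temporal/superior/inferior
sectors split on the ±45° diagonals, crossed with [0,5), [5,10), [10,15),
[15,20) annuli; cells exactly on a diagonal and cells at ≥ 20° are
excluded. On the standard grid this yields 16-cell innermost segments,
134-cell outermost segments, and 1208 of 1600 cells assigned.

Refraction archetypes are decided from the naked-eye horizontal profile:
with Δ_N and Δ_T the nasal/temporal edge-window ([30°, 40°]) means minus
the central (|e| ≤ 5°) mean, an asymmetry |Δ_N − Δ_T| ≥ 0.25 D labels the
profile PNS or PTS by sign; otherwise the sign of (Δ_N + Δ_T)/2 separates
RPM from RPH. The 0.25 D threshold and both windows are configurable; the
10°-wide edge windows average out measurement noise.

## Statistics

- **Mann-Whitney-U**: two-sided; for n_x + n_y ≤ 16 (or on request) the
  exact null is enumerated over all group assignments, which remains valid
  under ties because the permutation distribution of U is symmetric about
  n_x·n_y/2; otherwise the tie-corrected normal approximation
  (`scipy.stats.mannwhitneyu`) is used. A paired Wilcoxon variant is
  available for the RMSE tier.
- **Kruskal-Wallis**: `scipy.stats.kruskal` (tie-corrected H, χ² p-value);
  a pooled sample with zero variance is reported as H = 0, p = 1.
- **Scheffé pairwise**: pair (i, j) is significant when
  |R̄_i − R̄_j| > √( χ²_{k−1,1−α} · C · N(N+1)/12 · (1/n_i + 1/n_j) ),
  with mid-ranks from the pooled ranking and tie-correction factor
  C = 1 − Σ(t³−t)/(N³−N). Each pair also carries the unadjusted normal
  p-value on the same contrast; since χ²_{k−1} ≥ χ²_1 quantiles, the
  adjusted decision is never more liberal than the raw one.
- Full-field groups pool all 1600 difference-map cells of each member
  subject by default; a `subject_means` mode (one mean per subject) is
  provided because pooled cells are spatially correlated and overstate the
  effective sample size — the cells mode mirrors map-level analyses, the
  means mode is the conservative alternative.
- α = 0.05 with a 0.01 reporting tier.

Calibration is verified by simulation: under identical generating
distributions the approximate M-W-U rejects at 5 % (measured 4.3 % over
1000 seeded repetitions, within the expected binomial spread).

## Synthetic cohort

The generator emulates the measurement protocol: 81 horizontal positions
(−40°…+40°, 1° inclusive) at five vertical fixations, four noisy scans
averaged per location (324 frames per fixation), 6th-order coefficients at
a 3 mm pupil. Defaults, chosen once as field-plausible values:

| parameter | default | meaning |
|---|---|---|
| magnitude_D | 1.0 D | quadratic relative peripheral refraction at ±40° (RPM/RPH) |
| skew_D | 1.0 D | nasal-minus-temporal edge difference (PNS/PTS); the linear slope is skew/2 so the edge-to-edge difference equals skew_D |
| noise_sd_D | 0.1 D | per-eccentricity refraction noise |
| central M | N(−3.25, 1.5) D, clipped to [−6.5, −0.75] | myopic cohort baseline |
| astig_40deg_um | 0.6 µm | with-the-rule c(2,+2) at 40° (quadratic growth ≈ 1.3 D of J180) |
| coma slope | 0.0025 µm/° | linear growth of c(3,±1) with signed field angle |
| c(4,0) base | 0.03 µm | spherical aberration, drawn once per subject |
| scan noise | 0.005 µm | per-coefficient, per-scan measurement noise |
| lens weight | w(e) = exp(−(e/10°)²) | radial add-power profile |

The lens model places the add centrally for the centre-near design
(offset = distance + add·w(e)) and peripherally for centre-distance
(distance + add·(1−w(e))); manufacturers do not publish radial power
profiles, so w is an explicit stand-in with configurable width, not an
inferred design. The same subject seed drives all three conditions, so
the eye's higher-order draws are shared and conditions are paired, as in
a real repeated-measures study.

What the generator does **not** emulate: lens decentration and flexure,
tear-film dynamics, accommodation, axial-length coupling, chromatic
effects, and realistic spatial noise correlation along a scan. Passing
tests therefore demonstrate that the pipeline measures what it should on
data with the assumed structure — not that any particular clinical effect
size is reproduced. Archetype labels are recoverable from generated
profiles at the default effect sizes in ≥ 95 % of draws, so grouped
analyses operate on essentially correctly labelled subjects.

## Problem sizes and determinism

The default study — 13 subjects × 3 conditions × 45 field locations plus
the shared limit map — fits in about two minutes on a single core, the
scale the package targets for routine use; unit tests run smaller cohorts
(1–2 subjects). All randomness flows from explicit integer seeds
(`numpy.random.default_rng`); a fixed seed reproduces cohorts, maps and
serialized reports byte-identically.

## Known limitations

- The cutoff-anchor fixture and the 1/f reference are synthetic stand-ins;
  absolute correlation values depend on both, so only comparisons within a
  configuration are meaningful.
- Pooled-cell statistics treat spatially correlated cells as independent
  observations (the subject-means mode exists for exactly this reason).
- The PSF support (30 arcmin) clips extreme blur: beyond roughly 3 D of
  relative defocus at a 3 mm pupil, energy outside the window is folded
  back by renormalisation and quality differences saturate.
- Zernike fields are sampled, not modelled continuously; quality samples
  require measured locations (no spatial interpolation of coefficients).
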