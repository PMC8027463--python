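# Methods

This note records the models, numerical choices and known limitations
behind `hemoflow`, in the spirit of a methods appendix: what each stage
assumes, which parameters matter, and what the synthetic-data tests do
and do not demonstrate about real slit-lamp video.

## Calibration and intensity model

All analysis operates on single-channel intensities in [0, 1]
(T × H × W). Integer sources are divided by their dtype's full scale;
color video is reduced to the green channel by default, where
hemoglobin absorption gives the strongest erythrocyte contrast (luma is
available as an alternative). The spatial calibration (μm/pixel) and
frame rate are required inputs with no defaults: the pixel scale
depends on the slit-lamp magnification, adapter and camera, and a wrong
scale silently rescales D, Va, Q and WSR. All worked examples and
synthetic defaults use 1.0 μm/pixel at 60 frames/s, a plausible
operating point for a smartphone camera on a slit lamp at low
magnification.

## Stabilization

The sharpest frame — variance of the Laplacian, a standard focus
measure that is zero for constant frames and strictly decreases under
Gaussian blur — is the registration reference. The transform model is
rigid; in practice rotation is negligible for fixation-target
acquisitions, so rotation estimation (polar correlation of spectral
magnitudes) is off by default and translation dominates.

Translation estimation must contend with an aperture problem specific
to this application: the moving erythrocyte column is the
highest-contrast structure in the scene, and a straight vessel
constrains no motion along its own axis, so an unconstrained
correlation will happily "stabilize" the blood motion itself —
destroying the very signal the velocimetry needs. Registration
therefore (1) masks the correlation to the extravascular background
(vessel pixels found by grey-closing background subtraction on the
denoised reference frame), then (2) iterates a sub-pixel least-squares
(optical-flow style) alignment of every frame against the temporal
median of the stack, again weighted to background pixels. The temporal
median is a template of the static scene: the advected texture is
suppressed, so nothing in the template can track blood. The arbitrary
common offset to the template is removed so the reference frame is
returned bit-exact. On synthetic scenes with σ = 2 px jitter the
residual alignment scatter is ≈ 0.1–0.4 px; frames whose residual
exceeds an optional threshold are flagged and passed through
untransformed rather than dropped, so blink-like outliers remain
visible to the caller.

## Vessel mapping

Vessels are enhanced with a multiscale Hessian ridge measure for dark
tubes (Frangi-type, β = 0.5). Two details matter:

- Eigenvalues are scale-normalized (multiplied by σ²) and one *global*
  structureness cutoff γ = half the maximum normalized Hessian norm is
  shared by all scales. Per-scale automatic cutoffs saturate weak
  texture to the same response as real vessels; a cutoff dominated by
  the finest scale suppresses wide vessels by orders of magnitude.
  The shared global cutoff on normalized eigenvalues balances 6 px and
  30 px tubes of equal contrast to within a few percent while leaving
  low-contrast scleral texture far below threshold.
- Derivatives use reflective boundaries; constant-padding creates
  strong spurious ridges along the frame border.

Default scales correspond to vessel diameters of roughly 5–45 μm at
the supplied calibration. Binarization is hysteresis thresholding at
(0.05, 0.15) of the response maximum — the permissive low threshold
preserves thin vessels — with components under a minimum area removed.

Because the filter response support depends on filter scale rather than
vessel width, the pipeline re-draws the binary support at the **full
width at half maximum of the intensity deficit**: with background
estimated by grey closing (element larger than the widest expected
vessel, so it bridges every tube), a pixel is vessel if its depth
exceeds half the strongest centreline depth within a window sized to
the widest vessel present. Anchoring on a local window maximum rather
than the nearest skeleton pixel matters at high-curvature bends, where
the discrete skeleton shortcuts the bend and would anchor the threshold
off-peak, inflating the mask. The refinement is iterated twice so the
anchor comes from the refined support. The FWHM convention matches how
a blurred vessel profile is conventionally read and makes the binary
width scale-free; a depth floor (0.1 intensity units) rejects
low-contrast texture ridges outright.

Skeletonization is topology-preserving thinning. Short terminal spurs
(boundary-roughness artifacts, pruned up to 1.5 × the maximal vessel
radius) are removed so one vessel does not fragment at spurious
junctions; redundant corner pixels left by pruning are deleted with a
local simple-point test. End points have one 8-connected neighbour;
branch points have three or more, merged into clusters so a junction
counts once. Each node-to-node path becomes a segment; per-point radii
are the EDT of the binary map at centreline pixels, excluding points
within 2 px of a junction (EDT inflates there) and points whose
inscribed disc does not fit inside the frame (the radius is truncated
where a vessel leaves the field of view). The summary diameter is
`2 × mean(radii) × pixel scale`, with no half-pixel correction — the
convention's sub-pixel positive bias (up to ~0.5 px) is accepted and
documented. The full mapping stage runs on a 2× upsampled grid, which
halves the worst-case EDT quantization; this matters for vessels under
~10 μm. On hard-edged synthetic bands, width 4–40 px at any
orientation, the recovered diameter is within 1.5 px of truth; the
recovered width of rendered Gaussian-profile vessels is within ~8%
across 8–35 μm.

Segments shorter than 15 skeleton pixels (native grid) are discarded;
the space-time analysis needs spatial extent, and the velocity grid is
additionally truncated so no candidate's per-frame displacement exceeds
a third of the segment length — steeper slopes are simply not
measurable on a short segment, and without the truncation they can win
the orientation search spuriously.

## Velocimetry

The space-time image I(x, t) resamples the centreline at uniform
arc-length spacing of one pixel (bilinear interpolation per frame).
The raw 8-connected skeleton polyline is up to ~8% longer than the
underlying smooth curve (staircase effect), which would inflate Va by
the same factor, so the polyline is resampled to unit spacing and
smoothed with a short moving average before the arc-length
parameterization. Each row's temporal mean is subtracted: the static
vessel silhouette would otherwise put an energy ridge at zero slope.

The STI is band-pass filtered along space with a Morlet continuous
wavelet transform (default scales spanning erythrocyte-texture
wavelengths of ~4–40 samples), and the dominant streak slope is found
by exhaustive search over a log-spaced speed grid (default 200
candidates over 0.05–3.0 mm/s, both polarities, plus an explicit
zero-motion candidate). Each candidate slope s is scored by the mean of
the normalized 2-D autocorrelation along the ray
(Δx, Δt) = (s·τ, τ), τ = 1…min(T/4, 30). The autocorrelation domain
was chosen over a spectral line integral deliberately: broadband
texture is weighted by its total power, so a single strong narrowband
component — whose slope is genuinely ambiguous under temporal aliasing
once the per-frame displacement exceeds half its wavelength — cannot
dominate, and white sensor noise contributes only at lag zero, leaving
the ray samples unbiased. The winning slope is refined by parabolic
interpolation on the log grid; speed (not signed velocity) is reported,
matching the centreline's lack of intrinsic direction.

Quality is the peak-to-baseline contrast of the orientation-energy
profile, in [0, 1]: ≈ 0.5–0.8 for clear streaks, < 0.05 for pure
noise. Estimates below 0.2 (configurable) are treated as "no
observable flow" and excluded from downstream records. On synthetic
STIs at 6 dB SNR the median speed error is under 1% across
0.2–1.0 mm/s; grid resolution bounds the noise-free error at ~2%.

## Hemodynamics

Vs, Q, WSR and the diameter grouping are implemented exactly as
stated in the README, including the ~5% discontinuity of the
profile-factor function at D = 0.6·Dc (≈ 4.6 μm): smoothing it would
silently shift Q and WSR for the narrowest capillaries. The group
bins are half-open ([11, 16), [16, 22)) so every diameter maps to
exactly one group; a diameter of exactly 16 μm is group 3. Units: D in
μm and velocities in mm/s at the interface, converted internally to
μm/s; Q in pl/s (1 pl/s = 1000 μm³/s); WSR in s⁻¹.

## Cohort statistics

Two aggregation rules coexist deliberately and are never conflated:
overall comparisons average each parameter over all of a subject's
segments first (one value per patient); per-diameter-group comparisons
pool segments as units. Both paths are exposed, and a test constructs
unbalanced data on which they differ.

Normality gating uses the Kolmogorov–Smirnov test with parameters
estimated from the sample (a Lilliefors-corrected variant is available
as an option); both arms normal → independent-samples t-test, otherwise
Mann–Whitney U. 2×2 tables use Pearson chi-square without continuity
correction, switching to Fisher's exact when any expected count is
below 5 *or* any observed cell is zero (the asymptotic approximation is
unreliable in both situations). One-way ANOVA is followed by
Bonferroni-corrected pairwise t-tests when Levene's test
(center = mean, α = 0.05) accepts homogeneous variances, and by
Games–Howell otherwise; Games–Howell is implemented in-package (Welch
statistics with studentized-range p-values) and cross-checked in the
tests against pingouin's implementation. The coefficient of
repeatability is 1.96 × the sample SD of paired differences, with the
95% interval mean ± CR. Under a shared-normal null at n = 50/arm the
gated comparison's rejection rate is ≈ 0.05 (checked at 2000
replicates). No correction is applied across the many parameter × group
comparisons, mirroring common reporting practice; this is a reporting
convention, not an endorsement.

## Synthetic data

The generator emulates a slit-lamp view of the bulbar conjunctiva: a
0.8-intensity scleral background with weak coarse static texture
(SD 0.015, correlation length ~6 px), a dark tube of Gaussian
cross-section whose FWHM equals the true diameter (soft edges, as
optical blur produces), a quasi-periodic pattern of dark erythrocyte
clusters advected along the curve at the true speed with periodic
wraparound, per-frame rigid jitter, and additive Gaussian sensor noise
(SD 0.01). Defaults: 60 frames/s, 1 μm/px, 0.45 vessel contrast,
30 μm cell spacing, 1 px jitter. Curves are straight lines, circular
arcs or gentle sinusoids. The background texture is not decoration: a
featureless background would leave registration unconstrained along the
vessel axis (the aperture problem above), which no algorithm can
overcome; its amplitude is kept far below vessel contrast so the vessel
filter ignores it. Truth records store D, Va and the analytic Vs, Q,
WSR derived through the hemodynamics module, so recovery errors are
measured against a consistent chain. A fixed seed makes every output
bit-reproducible.

Synthetic cohorts draw per-segment D and Va independently from
truncated normal distributions with each arm's mean and SD (defaults:
the two-arm study profile, 56 + 59 subjects, ~34 and ~38 segments per
subject, Poisson-distributed), then derive Vs/Q/WSR per record. Because
D and Va are drawn independently, the joint distribution of Q is not
claimed to match any particular study — the cohort generator validates
the statistical machinery, not microvascular physiology.

What passing synthetic tests shows: the pipeline recovers geometry and
kinematics it can see, with the stated error budgets, under realistic
noise, jitter and vessel curvature. What it does not show: robustness
to specular reflections, blinks, uneven illumination, vessel crossings,
focus drift, or real erythrocyte-column statistics; and single-vessel
phantoms do not exercise junction-dense fields of view. Real-data use
should treat the quality flags (registration residuals, STI quality,
masked-sample fraction) as first-class outputs.

## Known limitations

- Arterioles and venules are not distinguished; all vessels pool.
- Signed flow direction is not reported, only speed.
- The EDT diameter convention carries a sub-pixel positive bias; at
  1 μm/px this is a few percent for the narrowest vessels.
- Velocities outside 0.05–3.0 mm/s (configurable) are not searched,
  and speeds whose per-frame displacement exceeds a third of a
  segment's length are unmeasurable on that segment.
- The registration model is rigid; slow deformations of the globe
  surface are not corrected.
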