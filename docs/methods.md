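# Methods

## Signal model and phantom

The phantom emulates a single 5 mm axial slice of the cervical cord at C2
on a 128×128 grid of 0.78×0.78 mm² pixels (100×100 mm² field of view).
Geometry is built in continuous mm coordinates (pixel centers at
(i+0.5)·spacing; rows run posterior → anterior):

* cord: ellipse with semi-axes 6.8 mm (right–left) × 4.6 mm (AP);
* CSF: a 2.2 mm ring around the cord, isotropic diffusivity
  3.0×10⁻³ mm²/s, brightest tissue on b0;
* gray-matter butterfly: a central commissure disc (1.0 mm), two
  anterior-horn lobes (2.0 mm radius at ±150° from the posterior midline,
  radial fraction 0.45) and two thin posterior horns (0.6 mm capsules
  reaching fraction 0.75 at exit angles ±40°);
* tract ground-truth discs: PT at exit+25° (fraction 0.70) and DC at ±15°
  (fraction 0.72), radius 1.3 mm, carrying their own tensors inside
  otherwise homogeneous white matter.

Region sizes were chosen once for region separability rather than
anatomical fidelity: each 1.05 mm ROI must sit inside a homogeneous tensor
region with enough margin that cubic-spline interpolation ringing from the
CSF and gray/white boundaries (kernel reach ≈ 2 native pixels ≈ 1.6 mm)
does not contaminate the ROI mean.  With smaller horns/discs the
noise-free extraction error exceeds 0.01 FA purely through boundary
ringing.

Default eigenvalues (10⁻³ mm²/s, principal axis along the slice normal):
DC (2.0, 0.32, 0.32), PT (1.9, 0.38, 0.38), generic WM (1.8, 0.40, 0.40),
GM/AH oblate (1.1, 0.85, 0.75), CSF isotropic 3.0.  These give true FA of
0.82 (DC) > 0.77 (PT) > 0.20 (AH), the rank order typical of cord tissue.
The b-value is configurable with default 750 s/mm², consistent with the
diffusivity magnitudes above; the six printed directions have norm √2 and
are normalised before use, so attenuation is independent of their listed
scale.

Signals follow Stejskal–Tanner, S = S₀·exp(−b·ĝᵀDĝ), with per-tissue S₀
(background 0, WM 400, GM 440, CSF 1000).  Noise is Rician:
|S + ε₁ + iε₂| with ε ~ N(0, σ), σ = 20 by default (WM b0 SNR ≈ 20);
noise-free-zero pixels acquire the Rayleigh floor σ√(π/2).  Motion is a
per-volume AP translation; the default is an integer-rounded random walk
(step SD 0.5 px, clipped to ±4 px), emulating breathing displacement.
Each of the 32 repetitions contains a b0 followed by the six diffusion
volumes.

## Cohort simulation

Biological and session variability are modelled as relative perturbations
of the axial and radial eigenvalues of the tract regions: per participant
one pair of draws (between-participant SD, default 4%/6% axial/radial) and
per session another (between-session SD, default 2%/3%), plus optional
fixed additive scanner offsets on the diffusivities.  Because the
perturbations are multiplicative, any eigenvalue-proportional metric (AD,
RD, MD) has true single ICC exactly σ²ₚ/(σ²ₚ+σ²ₛ) by construction; for FA
the identity holds to first order.  Eigenvalues pushed below a floor
(0.05×10⁻³ mm²/s) are clamped with a warning.  `simulate_cohort` produces
full image stacks; `simulate_cohort_truths` reproduces the same draws
without images for cheap large-n calibration studies.

What the phantom does **not** model: EPI/susceptibility distortion,
eddy currents, cardiac-gating timing, through-plane or rotational motion,
partial-volume gradients inside regions, and 3-D cord curvature.  Passing
tests therefore demonstrate correctness of the processing chain and the
statistics under the stated acquisition model, not robustness to every
artifact of real scanner data.

## Preprocessing

Cropping uses the intensity centroid of the mean b0 (the bright CSF ring
dominates), replacing an interactive centering step; default half-width 16
px → 33×33 crop.  Motion correction estimates one integer AP shift per
volume by maximising the normalised cross-correlation of midsagittal
profiles (central 3 columns averaged) over ±5 px, ties broken toward the
smaller shift.  Two design choices proved necessary and are deliberate:

* profiles are compared through their gradient magnitude (edge profile),
  because the b0 (bright CSF) and DWI (dark CSF) contrasts can
  anti-correlate in raw intensity;
* the reference is the mean of the b0 volumes *after* aligning them to
  the first b0, since the raw mean b0 of a moving stack is itself smeared.

With these choices, integer shifts are recovered exactly on noise-free
stacks (the translation uses nearest-row edge padding, so recovery is
exact up to the padded edge rows).  An optional raw-intensity mode is
retained.  Eddy-current correction is deliberately not implemented.
Repetitions are averaged after correction, one mean image per direction.

## Tensor fit and maps

The fit is ordinary least squares on log-signals: A·d = ln(S₀/Sᵢ) with
row i = b·[g²ₓ, g²ᵧ, g²_z, 2gₓgᵧ, 2gₓg_z, 2gᵧg_z].  With exactly six
non-collinear directions A is square and full-rank, so the noise-free fit
is an interpolation (recovery to ~1e-14 relative).  Background pixels
(mean b0 below 10% of its 98th percentile) are masked.  Eigenvalues are
sorted descending and negatives clamped to 0 (counted in QC) before
FA = √(3/2)·√Σ(λᵢ−λ̄)²/√Σλᵢ², MD, AD = λ₁, RD = (λ₂+λ₃)/2.  A printed
variant RD = (λ₁+λ₂)/2 sometimes seen in the literature is available
behind `rd_printed_variant` for auditability only.  Metric maps (not raw
DWIs) are interpolated to 0.2×0.2 mm² with an interpolating cubic spline;
FA is clipped back to [0,1]; since the spline is linear in the samples,
MD = (AD+2·RD)/3 survives interpolation to machine precision.

## ROI geometry

The cord mask keeps b0 intensities between 10% and 60% of the 98th
percentile (largest connected component, holes filled).  The ellipse comes
from image moments: centroid, orientation and axis ratio from second
central moments (for a uniform filled ellipse the semi-axis is twice the
per-axis SD), rescaled so the ellipse area matches the mask area; a
near-circular mask reports rotation 0 by convention.  FA is sampled at 600
angles (0.6°) on the ellipse scaled to radial fraction 0.72 by bilinear
interpolation; the posterior-horn exit angles are the FA minima nearest
the posterior midline within a 10–70° window per side (flat profiles keep
the priors with a warning).  ROI placement (all parameters exposed): DC at
±15°/0.72, PT at exit+25°/0.70, AH at ±150°/0.45, diameter 1.05 mm,
mirror-symmetric by construction.  Pixel membership is center-in-circle
(≈21 pixels at 0.2 mm); region values are the unweighted mean of the left
and right ROI means, without normalisation.

## Reliability battery

For each comparison (per-scanner test vs retest; inter-scanner on
per-participant session means) and each metric × region:

* paired t (df = n−1, two-sided); Bonferroni-corrected p across the 12
  tests per comparison (raw p always reported; correction switchable);
* paired Cohen's d = mean(diff)/SD(diff), banded at 0.2/0.5/0.8;
* t-based 95% CIs of the test/retest/pooled means; the pooled value is
  the per-participant session mean, so pooled mean ≡ (test+retest)/2;
* Bland–Altman: D, SD of differences, LOA = D ± 1.96·SD (fixed 1.96
  multiplier — this reproduces the published LOA cells exactly), t-based
  CI of D, count of pairs outside the LOA;
* within-participant CV = (|x₁−x₂|/√2)/pair mean × 100, aggregated as the
  arithmetic mean across participants (RMS switchable); bands close the
  published 10–11% gap at 10%: ≤10 acceptable, ≤20 moderate, >20 high;
* ICC from the two-way ANOVA mean squares, both consistency
  ((MSR−MSE)/(MSR+(k−1)MSE)) and absolute agreement
  ((MSR−MSE)/(MSR+(k−1)MSE+k(MSC−MSE)/n)); the average-measurement forms
  are the exact Spearman–Brown step-ups.  CIs use the standard F
  constructions (Satterthwaite df for absolute agreement); average CIs are
  Spearman–Brown step-ups of the single CI, matching common statistical
  packages — verified against the published tables, where average ICC and
  CI equal the stepped-up single values, and cross-checked numerically
  against an independent implementation.  The default reported form is
  absolute agreement.

Degenerate inputs are handled explicitly: zero difference variance gives
p = 1 (identical pairs) or a flagged undefined d; non-positive pair means
are excluded from CV with a warning; negative ICCs are reported as
computed.  Report output rounds half-away-from-zero to 3 decimals; full
precision is retained internally and in the JSON output.

## Problem sizes used in the bundled studies

The estimator-calibration study uses 500 replicates of 16-participant
paired cohorts at true single ICC 0.75 (median recovery within 0.05,
CI coverage 92–98%).  The end-to-end acceptance cohort runs 16
participants × 2 scanners × 2 sessions with 8 repetitions per direction —
repetitions scaled down from 32 because averaging beyond 8 changes the
extracted means only marginally on this phantom while quartering the
simulation volume.

## Known limitations

* The elliptical-ROI adjustment emulated here is fully automatic; the
  original workflow it mirrors involved consensus reading, so placement
  criteria are stand-ins with every parameter exposed in config.
* Sub-pixel motion is corrected only to the nearest integer pixel.
* The single-tensor model is a poor description of gray matter with
  crossing microstructure; AH values are interpreted accordingly.
* Rician bias is simulated but not corrected; at the default SNR the
  residual FA bias in low-anisotropy regions is a few hundredths.
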