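# cordti

Axial spinal-cord diffusion tensor imaging (sDTI) is one of the few
quantitative probes of the long fiber tracts — pyramidal tracts (PT),
dorsal columns (DC) — and the anterior-horn gray matter (AH) at the
cervical level, but its clinical use hinges on whether the extracted
metrics are reproducible across repeat scans and scanners.  `cordti` is a
reusable, fully tested re-implementation of a complete test–retest
reliability pipeline for single-slice axial cervical-cord DTI at C2:

1. **Simulation** (`cordti.phantom`) — a 128×128, 0.78×0.78 mm², 5 mm axial
   slice phantom: elliptical cord with a gray-matter butterfly inside a
   bright CSF ring, one b0 plus six diffusion directions
   e₁=(1,0,1), e₂=(−1,0,1), e₃=(0,1,1), e₄=(0,1,−1), e₅=(1,1,0),
   e₆=(−1,1,0) (normalised; b = 750 s/mm²), 32 repetitions,
   anterior–posterior breathing motion and Rician noise, with known
   per-pixel tensors and a cohort layer (participants × sessions ×
   scanners) whose variance components make the true reliability known by
   construction.
2. **Preprocessing** (`cordti.preprocess`) — cropping to the intra-spinal
   space, automatic AP motion correction from midsagittal intensity
   profiles, repetition averaging.  No eddy-current correction is applied.
3. **Tensor fit** (`cordti.tensor`) — log-linear least-squares fit of
   S = S₀·exp(−b·ĝᵀDĝ) per pixel (exact with six directions), eigenvalue
   metrics FA, MD = (λ₁+λ₂+λ₃)/3, AD = λ₁, RD = (λ₂+λ₃)/2, and cubic-spline
   interpolation of the metric maps to 0.2×0.2 mm².
4. **Tract ROIs** (`cordti.roi`) — moment-based cord ellipse fit, 600-point
   (0.6°) angular FA profile, posterior-horn exit angles from the profile
   minima, six mirror-symmetric circular ROIs of 1.05 mm diameter
   (PT/DC/AH, left+right averaged).
5. **Reliability statistics** (`cordti.reliability`) — paired t-tests,
   paired Cohen's d with bands, t-based 95% CIs, Bland–Altman analysis
   (D ± 1.96·SD limits of agreement), within-participant CV
   (≤10% acceptable, ≤20% moderate, >20% high), and single/average
   two-way ICCs (consistency and absolute agreement) with F-based 95% CIs
   and Cicchetti/Koo classification, wrapped in a statsmodels-style
   `ReliabilityModel` → `ReliabilityResults` pair.

A thin CLI (`cordti simulate|preprocess|fit|extract|reliability|full-run|validate-tables`)
wraps the library; images travel as NIfTI plus FSL-style `bval`/`bvec`
text files, metrics as tidy CSV.

## Worked example

Simulate the default noisy, motion-corrupted acquisition and run the whole
single-stack chain:

```python
from cordti import PhantomSpec, generate_phantom
from cordti.pipeline import process_stack

spec = PhantomSpec(seed=42)           # 32 reps, Rician noise, AP motion
truth, stack = generate_phantom(spec)
tm, shifts, maps, ellipse = process_stack(stack, spec.scheme)
print(tm.region_means.round(3))
```

```
           fa     md     ad     rd
region
PT      0.769  0.895  1.904  0.390
DC      0.815  0.904  2.019  0.346
AH      0.218  0.889  1.110  0.779
```

against the ground truth of this phantom realisation
(`truth.true_region_metrics`): PT 0.770 / DC 0.819 / AH 0.198 FA — i.e.
despite noise and motion the pipeline recovers each tract's FA to within
about 0.02, and diffusivities (in 10⁻³ mm²/s) to a few percent.

The reliability battery runs on any tidy (participant, scanner, session,
region, metric, value) table:

```python
from cordti.phantom import CohortSpec, simulate_cohort_truths
from cordti.reliability import ReliabilityModel

tidy = simulate_cohort_truths(CohortSpec(seed=1), PhantomSpec())
res = ReliabilityModel.from_dataframe(tidy).fit()
print(res.summary())
```

which prints one row per comparison × metric × region, e.g. for the
simulated `prisma` test–retest, DC FA:

```
metric region  test_mean  retest_mean  pooled_mean     p  diff_mean  loa_lo  loa_hi  cv_pct  icc_single  icc_average icc_single_koo
    fa     DC      0.821        0.820        0.820 0.493      0.001  -0.010   0.012   0.424       0.928        0.962      excellent
```

Here the single/average ICCs (0.93/0.96) track the cohort generator's
variance components, the limits of agreement bracket the mean difference,
and the CV sits deep in the "acceptable" band — the same table layout a
reproducibility study reports.

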