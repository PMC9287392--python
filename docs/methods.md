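# Methods

This note documents the models, parameter choices and numerical decisions
behind `ondti`, and what the synthetic phantoms do and do not establish
about real orbital DWI.

## Coordinate and unit conventions

World coordinates are RAS+ millimetres. Voxel indices are 0-based with
voxel centres at integer indices; the affine maps indices to mm and is the
single source of geometry for ROIs, streamlines and interpolation.
Diffusivities are stored and reported on the clinical printed scale
(numerically ~0.5–3.0, i.e. units of 10⁻³ mm²/s); the factor 10⁻³ is
applied only inside the signal model and the tensor-fit design matrix, so
b·D is dimensionless while reported numbers match the clinical convention.
b-values are s/mm². The bval/bvec dialect is FSL's row-major text format;
b0 phase-encoding tags (`AP`/`PA`) travel in a JSON sidecar.

## Preprocessing: the b0 merge

Real orbital DWI needs susceptibility and eddy-current correction from
opposed-phase b0 pairs. The phantoms contain no distortion, so the package
implements only the data contract of that stage: the b0 volumes (at least
one AP- and one PA-tagged) are replaced by their voxel-wise arithmetic
mean, placed first, giving a corrected dataset of (#DWI + 1) volumes — 49
at the default 48-direction acquisition. Distortion-field estimation
itself is a non-goal.

## Tensor fit

Per voxel, ln S_i = ln S₀ − b_i gᵢᵀ D gᵢ is solved by ordinary least
squares with 7 unknowns (six tensor components + ln S₀). Log-linear rather
than weighted or nonlinear LS is the primary fit; a nonlinear
signal-domain fit exists in the test suite as an independent oracle and
agrees to < 1e-6 on noiseless voxels. Measurements with S ≤ 0 are dropped
rather than clamped (clamping biases the log fit at high SNR); a voxel
with fewer than 7 usable measurements is excluded from the mask with a
logged count. Negative eigenvalues are clamped to zero **for FA only**;
MD/AD/RD use raw eigenvalues so MD = (AD + 2·RD)/3 holds exactly under
every linear average (node, nerve, group).

Uncertainty comes from a residual bootstrap (default 500 replicates):
whole-model residuals are resampled with replacement per voxel and the fit
repeated; the mean tensor and the SD of each measure over replicates are
reported. A residual (not repetition) bootstrap is the natural choice for
a single-shell, repetition-free acquisition. Replicate measures are
accumulated as deviations from the point fit so that noiseless data yield
SDs at machine precision rather than at the cancellation floor of a
two-pass variance. Reported summaries default to the point fit; the
bootstrap mean is available alongside.

## Tractography

The scoring engine of the original tool chain is only cited in the
literature, not specified, so this package uses one transparent angular
model for both generation and scoring: a Watson density
p(d | μ, κ) ∝ exp(κ (d·μ)²) about the local principal axis μ, with
κ = κ_max · FA (κ_max = 30 by default, so a healthy tube at FA ≈ 0.37
tracks at κ ≈ 11, and isotropic background is uniform). Sampling is exact
rejection sampling; the normalising constant uses the confluent
hypergeometric function M(1/2, 3/2, κ).

Walkers are seeded uniformly in the retrobulbar ROI (ROI 1, 3 mm radius at
5 % of the centerline arc length; the apex ROI sits at 95 %), take 1 mm
steps with a 45° turning cap (re-sampled up to 10 times before the walker
dies), and are accepted on entering ROI 2 within a length cap of twice the
straight-line ROI distance. Generation stops at the requested 1000
accepted candidates or 100× that many attempts. Each candidate's score is
the length-normalised sum of step log-likelihoods; the top ⌈10 %⌉ are
kept, ties broken by shorter length then creation index.

Cleaning follows the automated-fiber-quantification convention: fibers are
resampled to 20 nodes, the bundle core is the node-wise mean with node-wise
spatial covariance, and a fiber's core distance is its **fiber-averaged**
Mahalanobis distance (a per-node variant is a one-line switch in
`_core_distances`). Fibers beyond mean + 2.6 SD core distance or
mean + 3 SD arc length are removed, iterating at most 5 rounds to
convergence; zero-variance bundles have no outliers by definition. The
central fiber is the node-wise mean of the cleaned, oriented
(nerve-head-first) bundle, endpoint-projected into the ROI spheres, then
iteratively resampled until its 20 nodes are equidistant along its own
polyline to 1e-9 relative.

A note on what top-10 % selection buys: on a noiseless straight tube the
*individual* kept fibers hug the true centerline more tightly as the kept
fraction shrinks (mean per-fiber RMS distance ≈ 1.42 mm at keep = 1.0 vs
≈ 1.23 mm at keep = 0.1), but the *averaged central fiber* is slightly
more accurate with more fibers, because node-wise averaging over a larger
symmetric bundle suppresses noise faster than selection removes it. The
selection stage is retained for architectural fidelity and because it
bounds the cost of cleaning.

Severely degenerate nerves (ground-truth FA near zero) may yield fewer
candidates than the attempt budget allows; if fewer than 5 fibers survive
selection the cleaning stage is skipped and the selected fibers averaged
directly, and a nerve with no accepted pathway at all is recorded as
missing in cohort runs — mirroring how an untrackable scan would be
handled in a real cohort.

## Tract profile

Scalar maps are interpolated trilinearly at the central fiber's node
positions (nearest-voxel sub-sampling is available as `mode="nearest"`,
matching the single-voxel description of the original analysis). The 5
nodes nearest the nerve head (25 % of 20) are excluded — "five nodes" and
"posterior 75 %" are treated as the same rule with configurable k — and
the remaining 15 nodes averaged without weights. Trilinear sampling mixes
a small amount of surrounding tissue near the tube boundary; this shifts
MD upward by up to ~0.05–0.15 in the phantoms (the surround is CSF-like,
MD 3.0) while FA is affected by ≲ 0.02. The central-fiber design exists
precisely to keep this partial-volume term small.

## Phantoms

The generator emulates: a 2 mm-isotropic acquisition with 48
electrostatically spread directions at b = 2000 s/mm² plus AP/PA b0s
(S₀ = 1000); a gentle ~25 mm S-curve centerline with ≥ tube-radius margin
inside the grid; a 4 mm-diameter tube whose voxels carry an axially
symmetric tensor (AD, RD, RD) along the local tangent; CSF-like isotropic
surround (MD 3.0); and Rician noise |S + ε₁ + iε₂| with
σ = S₀/SNR (default SNR 20; `snr=inf` disables noise, and a Gaussian mode
exists for analytic tests). Voxels take the tensor of their centre by
default; an optional 3³ sub-voxel mixing mode adds partial-volume realism
at the boundary.

It does **not** emulate susceptibility distortion, eddy currents, eye
motion, fat/CSF multi-compartment signal, or the irregular cross-section
of a real nerve. Passing tests therefore demonstrate correctness of the
algorithms under the stated signal model and realistic SNR — not
robustness to the artifacts that the excluded preprocessing stages exist
to fix.

Default grid: 64×64×33 voxels. The test suite and the acceptance script
run the same phantoms on a 32×32×24 grid (a tighter orbital field of view
around the same 25 mm nerve), which leaves every stage and parameter
untouched while keeping a full 34-nerve cohort run to a couple of minutes.

### Cohort generator

Six patients contribute one atrophic and one healthy ("non-affected")
nerve each; eleven controls contribute two control nerves. Group
diffusivity profiles default to the published group means
(AD/RD: atrophic 1.123/0.920, non-affected 0.955/0.510, control
0.998/0.532), with per-nerve jitter drawn from a bivariate normal on
(AD, RD) using the published group SDs and correlation 0.9 — strongly
correlated jitter keeps the implied FA spread near the published FA SDs
(~0.06), whereas independent jitter would inflate it to ~0.2 — and half of
the jitter variance shared at subject level so the subject random
intercept in the statistics is a real feature of the data. Draws are
clipped to keep AD ≥ RD > 0.

RNFL thickness is linear in ground-truth FA plus Gaussian noise. The
default link is *derived*, not tuned: the line passes through the two
patient-group anchor points (analytic FA of each profile vs the published
mean RNFL of 49.83 µm affected / 109.83 µm fellow eyes), giving intercept
≈ 21.9 µm and slope ≈ 236 µm per FA unit, and the noise SD (≈ 7.8 µm)
reproduces the published FA–RNFL R² = 0.936 given the between-group FA
gap. The control profile then lands at ≈ 110 µm automatically, matching
the published control mean — a consistency check on the whole
construction.

## Statistics

Controls' two eyes are averaged per subject before analysis (the
published design, justified by non-significant inter-eye differences;
`control_inter_eye_tests` reproduces that check). Demographics use the
two-sided Mann–Whitney U (exact when both n ≤ 25 without ties, otherwise
tie-corrected normal approximation with continuity correction) and the
Pearson χ² without continuity correction.

The mixed models Y ~ RNFL + (1|Subject) and Y ~ Group + (1|Subject) are
fit by profiled REML: for a single random intercept the GLS solution is
closed-form given the variance ratio θ = σ²_u/σ²_e, and the REML criterion
is optimised over θ ≥ 0 by a grid plus bounded scalar minimisation
(xatol 1e-12), preferring the θ = 0 boundary when it is as good — which
makes the zero-variance case reproduce OLS exactly (to 1e-8, tested).
REML rather than ML because n = 6 patients makes variance bias material.
The reported p-value is the ANOVA (Wald F) test of the fixed effect with
containment-style denominator df: n − n_subj − (p − 1) when the effect
varies within subjects, n_subj − p when it is a between-subject effect
(simulated null type-I error ≈ 0.05–0.09 at these n). R² for a mixed
model is not uniquely defined; the squared Pearson correlation between the
fixed-effect fitted values and the observations (≈ marginal R²) is used.
Group contrasts are fit pairwise (atrophic vs control, atrophic vs
non-affected). All tests are two-sided at α = 0.05 with no multiplicity
correction, mirroring the original analysis.

## Known limitations

- Single-shell, single-tensor model only; no kurtosis or multi-compartment
  extensions.
- The Watson tracking/scoring model is a transparent substitute for an
  unspecified legacy scoring algorithm; absolute scores are not comparable
  to that tool, only the select-top-fraction architecture is preserved.
- Nearest-voxel tensor lookup during tracking (no tensor interpolation).
- Containment df for the fixed-effects ANOVA is an approximation (as is
  any small-sample mixed-model test); it is calibrated by simulation in
  the test suite rather than claimed exact.
- Phantom realism limits listed above; group-level effect sizes measured
  on phantoms track the published pattern and significance levels, but
  absolute atrophic FA is biased upward (~0.17 vs 0.136) by the Rician
  noise floor at low anisotropy.
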