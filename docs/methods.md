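# Methods

This note documents the models the package implements, the parameter
choices that matter, what the synthetic data do and do not emulate, and the
numerical decisions taken where the design was genuinely open.  Every
number quoted here is computed by the test suite or by
`scripts/acceptance.py`.

## Signal models

**IR-TrueFISP (joint T1/T2).**  After adiabatic inversion and an α/2
preparation, the balanced-SSFP signal relaxes mono-exponentially to its
steady state with an apparent constant that mixes both relaxation times:

    S(t)  = S_ss (1 − INV e^(−t/T1*))
    1/T1* = cos²(α/2)/T1 + sin²(α/2)/T2
    S_ss  = M0 sin α / ((T1/T2 + 1) − cos α (T1/T2 − 1))
    INV   = 1 + (M0/S_ss) sin(α/2)

The acquisition protocol names the sequence and its TE/TR but not the
inversion-time sampling or flip angle, so both are recorded on the protocol
object rather than inferred: twelve inversion times log-spaced over
30–5005 ms and α = 70° by default.  Simulator and fitter share these
equations — that self-consistency is the testable contract.  The fitter
uses variable projection (the model is linear in (S_ss, S_ss·INV) once T1*
is fixed) with a coarse log-grid plus golden-section refinement of the 1-D
objective, restores the magnitude-data polarity at the two candidate flip
points around the minimum-signal frame, and inverts the steady-state
relations in closed form.  Noiseless round trips recover heterogeneous T1
and T2 fields to ≲10⁻⁵ % on the full 128 × 128 grid.

**MTR.**  S_off ∝ proton density, S_on = S_off(1 − δ) with δ the fractional
saturation; MTR% = 100(S_off − S_on)/S_off.  No relaxation weighting of the
RARE readout is modelled: MTR is a ratio and the common factor cancels.

**ADC and R2\*.**  Mono-exponential decays over five b-values
(200–1000 s·mm⁻², avoiding perfusion contamination at b < 200) and eight
echoes at 3–24 ms.  The default estimator is log-linear least squares —
exactly testable and standard for this b-range — with a nonlinear
(variable-projection) option behind a flag.  For R2\*, echoes that have
decayed below the noise floor are excluded per voxel; the nonlinear option
instead fits an offset that absorbs the Rician magnitude floor.

**Noise.**  Magnitude frames receive Rician noise (Gaussian on the two
quadrature channels, then magnitude), the physically correct model for
magnitude MRI; elastography snapshots receive additive Gaussian noise.
The noise scale is specified relative to the mean viable-tissue signal;
the default 0.02 corresponds to SNR ≈ 50.  Voxels below 3× the noise sd
are masked invalid, not clamped, because Rician bias dominates there.
Empirical mean and variance of the noise generator match the analytic
Rice moments within Monte-Carlo error in the tests.

## Elastography

The simulated wavefield is a time-harmonic plane shear wave,
u(x, t) = Re[v(x) e^{iωt}] with v = A e^{−ik·x} and
k = ω√(ρ/G\*) on the principal branch, so a lossy modulus
(G_l > 0) yields spatial decay with attenuation coefficient |Im k|.  For
piecewise-constant modulus fields the phase is accumulated voxel by voxel
along the propagation axis, which keeps the field an exact Helmholtz
solution within every homogeneous region.  Density is fixed at
ρ = 1000 kg·m⁻³ (soft-tissue convention).

Reconstruction extracts the fundamental temporal Fourier coefficient of
the ≥3 equally spaced wave phases (exact for a pure tone; DC offsets drop
out by orthogonality) and inverts algebraically:
G\* = −ρω²u/∇²u with a second-order central-difference Laplacian.  Because
the synthetic fields are pure shear by construction, no curl or
compressional-wave decomposition is applied — a documented simplification
relative to full scanner-data reconstructions, whose absolute moduli this
package does not attempt to reproduce.

Numerical behaviour: the discrete Laplacian of a plane wave carries a
relative bias of ≈(kh)²/12, so the recovered modulus converges
quadratically as the grid is refined — measured order 2.02, with the
homogeneous 5 + 2i kPa oracle recovered to 1.5 % at 0.15 mm spacing and
0.37 % at 0.075 mm.  At the native 0.3 mm acquisition grid the bias for a
~5 kPa/1 kHz wave is ≈6 % and is common to both arms of a cohort, leaving
contrasts and percent changes essentially unaffected.  A one-voxel rim is
always masked; thin (≤3-slice) volumes default to the in-plane 2-D
Laplacian (a 3-D Laplacian over three slices would leave only the middle
slice and is available behind a flag).  Wave nodes, where |∇²u| falls
below 10⁻³ of its ROI median, are masked to avoid division blow-up, as are
voxels with non-positive recovered storage modulus.  Waves sampled at
fewer than 4 voxels per wavelength are rejected at simulation time.

## Histology mapping

Stain images are binary HA-positive indicators at 0.46 μm (20×
magnification); each MRI voxel corresponds to a 518 × 518 pixel block.
Note these constants are mutually inconsistent at the 2 % level
(518 × 0.46 μm = 238.3 μm against the 234.4 μm voxel of a 30 mm/128 FOV);
both are exposed in configuration and neither is silently corrected — the
grid-matching tolerance accepts the discrepancy.  The generator draws each
pixel as an independent Bernoulli with the enclosing voxel's HA fraction,
the simplest model whose block statistics are analytically known
(binomial).  Aggregation keeps integer positive counts alongside the
fractions, so pixel conservation is exact, not approximate.  Edge blocks
smaller than the full block are dropped by default (avoiding
edge-inflated denominators); a `normalise` mode divides by the actual
block size instead.  The voxel-by-voxel pairing of a parametric map with
the HA-fraction map is a deliberate numerical extension of what was a
purely visual comparison in the workflow this emulates.

## Cohort statistics

Percent change is 100(post − pre)/pre on viable-ROI medians (necrosis
excluded; even-count medians average the middle pair).  The test–retest
coefficient of variation uses CV_WS% = 100·√(ΣΔᵢ²/2n)/m with m the grand
mean of all 2n saline measurements — the typeset form of this formula is
ambiguous, so it is implemented per the stated symbol definitions, with a
per-pair-mean variant behind a flag.

Treated-vs-saline comparisons are classic equal-variance Student t-tests
(Welch behind a flag) on percent change, one per parameter, with q-values
from the two-stage adaptive step-up FDR procedure: stage one runs linear
step-up at α′ = α/(1+α) to estimate the true-null count m₀ = m − r₁, stage
two reruns step-up with m₀ in the thresholds.  q-values are defined as the
smallest level at which a hypothesis is rejected and computed by bisection
(the rule is monotone in α); they agree exactly with a brute-force
transcription of the procedure on 1000 random p-vectors and with an
independent library implementation of the same procedure.  Families are
formed per model group, matching how per-model panels are reported; this
choice is recorded rather than claimed unique.  Under a global null the
empirical FDR over 2000 simulated cohorts is ≈4–5 %, at the nominal 5 %
bound within Monte-Carlo error.

Pearson correlations use the exact two-sided p from
t = r√(n−2)/√(1−r²) on n−2 df; a summary-statistic entry point computes p
from printed (r, n) pairs alone.  Correlation matrices use
pairwise-complete deletion (each pair carries its own n, as the varying
printed n values imply) and exclude percent HA from the treated stratum
when its mean falls below 2 % — after enzymatic degradation the column
carries no usable variance.  ANOVA post-hoc comparisons are pairwise Welch
tests with the same FDR control; the choice is recorded in the output
metadata because the original post-hoc method is unnamed.

## Synthetic cohorts and the closed loop

The study generator emulates three model groups — low-HA fast-growing,
HA-overexpressing, and collagen-dense — with two arms of 6 subjects each.
Subject baselines get multiplicative between-subject spread (8 %) and a
per-subject HA level that couples into T2, ADC, MTR and T1, producing the
cross-subject correlations the matrices probe.  Each scan session adds a
per-parameter physiological jitter (1.5–16 % depending on parameter),
chosen so the saline-arm CV_WS lands where repeat small-animal imaging
does: low single digits for T1, mid-single digits for T2/MTR, low-to-mid
teens for ADC, R2\* and the moduli.  Saline tumours grow ~34–45 % between
scans, so the volume CV_WS is large by construction.  Treatment is
injected directly on the ground-truth fields (e.g. ADC × 0.75, HA
collapsed to ~1 %), standing in for the biology of enzymatic HA
degradation; statistical recovery of the configured effect — sign and
approximate size — is therefore a closed-loop test of the entire
simulate → fit → statistics chain.

What the generator does **not** emulate: k-space sampling and
reconstruction artefacts, B0/B1 inhomogeneity, partial-volume and motion
effects, compressional or reflected waves in the elastogram, stain colour
and its deconvolution, deformable histology–MRI registration, and any
pharmacokinetics or growth dynamics.  Passing tests therefore demonstrate
the correctness of the estimators and statistics under their stated
models, not robustness to those real-world confounds.

## Problem sizes and determinism

Unit and property tests run on 32 × 32 phantoms; the round-trip and
elastography acceptance checks use the full 128 × 128 (and up to 256²
refinement) grids; the closed-loop study drivers use a 32–64² acquisition
matrix with 6 subjects per arm, sizes chosen to keep each driver in the
seconds-to-a-minute range while leaving every estimator's behaviour
unchanged.  All randomness flows from explicit seeds (one root seed per
study, spawned per subject/session), and rerunning any driver or study
with the same seed is bit-identical, down to byte-identical CSV outputs.
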