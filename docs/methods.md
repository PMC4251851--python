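# Methods

This note records the models implemented by the package, the conventions
chosen where the source study's description is silent or ambiguous, the
design of the synthetic generators, and known limitations.

## Image-derived PET indices

**SUV.** The body-weight convention: SUV = C_t / (ID / BW), with tissue
concentration C_t converted from kBq/ml to kBq/g through a tissue density
of 1 g/ml (configurable), injected dose ID in kBq and body weight BW in
g. No additional decay correction is applied at this level; activity
images are assumed decay-corrected upstream in reconstruction, as is
standard for the scanner generation concerned. Doubling dose and weight
together leaves SUV unchanged (dimensional invariant, tested).

**Isocontour tumor volume.** The metabolically active volume is the
number of voxels with SUV ≥ threshold (default 4.0) times the voxel
volume, summed over all planes. The threshold is inclusive; whether the
original contour tool used ≥ or > is unknowable, so the comparison is a
configuration point with ≥ as default. When a seed region is supplied
(the analogue of confirming the tumor area against anatomy), the mask is
restricted to the 26-connected components intersecting the seed.

**3×3 maximum SUV.** The per-patient SUV is the maximum over in-plane
3×3-pixel windows of the window-*mean* SUV, windows centred on ROI
voxels. The alternative reading — the maximum single voxel of a 3×3
neighbourhood — is rejected because the stated window geometry
(7.04 × 7.04 mm at 2.35 mm pixels) only matters if the window is
averaged; a 3×3 mean hot-spot is also the conventional reading for
scanners of that era. At image edges the default treats out-of-bounds
cells as zeros (mean over 9); a `clip_at_edge` mode averages only
in-bounds cells. The returned plane index identifies the hot-spot plane.

**T/P ratio.** Voxelwise tissue activity divided by the scalar plasma
activity of the late (90–120 min) window. The per-patient summary is the
tumor *maximum* (the study's table footnote states maximum); the ROI
mean is exposed as an option but is not the pipeline default.

**Hypoxia threshold and FHV.** The threshold is pooled-normal-tissue
mean + 3 × SD, with the sample (n−1) SD — at the study's pool size
(10,968 pixels) the denominator choice is numerically irrelevant, but
the contract must be fixed. FHV is the percentage of tumor-ROI voxels
with T/P ratio *strictly above* the threshold ("above" is read as
strict; at the study's precision the difference is at most one voxel in
a continuous image). FHV is computed over the full 3-D tumor ROI; the
per-plane pooling mode exists for threshold derivation, which the
original procedure performed on planes. The study's threshold constant
0.93 is packaged as the default since its pixel pool is not recoverable.

**Blood flow.** The original flow analysis is cited without equations,
so the package implements a clearly-labelled simplified stand-in: the
one-tissue Kety model with partition coefficient p = 0.9 ml/g and a
250 s integration time. The tissue response to an arterial input Ca(t)
is dC/dt = f·Ca − (f/p)·C; the autoradiographic observation is the
scan-accumulated activity, which has the closed form

    A(f) = p · ∫₀ᵀ Ca(t) · (1 − exp(−(f/p)(T−t))) dt   [kBq·s/ml].

The integrand increases pointwise in f, so A is strictly increasing and
saturates at p·∫Ca: the lookup (tabulate A on a flow grid, invert by
linear interpolation) is well posed over the whole physiological range.
The instantaneous end-of-window concentration C(T) was considered and
rejected as the observable: it is non-monotone in f for bolus-shaped
input curves (high flow washes out early uptake), which would break the
inversion precisely in the hyperperfused-tumor regime (the study's flows
reach 63 ml/100 g/min). The default grid spans 0–150 ml/100 g/min in
601 steps; the table is validated as strictly increasing at run time.
This estimator is exercised on synthetic data only.

## Rank statistics

All tests use midranks (ties receive the mean of the ranks they span;
ranks sum to n(n+1)/2 exactly) and pairwise deletion of missing values.
Pairwise deletion is the only rule consistent with the per-cell sample
sizes implied by the published analysis; each reported cell carries its
n so any discrepancy is auditable rather than hidden.

**Spearman.** r_s is the Pearson correlation of midranks, clipped to
[−1, 1] with exact ±1 short-circuit for perfectly monotone data. The
default two-sided p is the t approximation t = r_s·√((n−2)/(1−r_s²)) on
n−2 df — the default of the statistical software used in the original
analysis — with an exact/Monte-Carlo permutation alternative: full n!
enumeration for n ≤ 8, otherwise seeded Monte-Carlo with an add-one
correction (so p ∈ (0, 1]). For |r_s| = 1 under the t method the
permutation probability of a perfectly monotone arrangement, 2/n!, is
reported instead of an infinite t.

**Wilcoxon rank-sum.** The statistic is the pooled-sample midrank sum of
the first group. The exact null enumerates all C(n_a+n_b, n_a) equally
likely group assignments with ties honoured; internally a dynamic
program over doubled midranks (always integers) computes the null
distribution in polynomial time, and the test suite proves it equal to
direct itertools enumeration for every split with pooled n ≤ 10. The
normal approximation uses the standard tie-corrected variance with a 0.5
continuity correction. Two-sided p doubles the smaller (inclusive) tail,
capped at 1 — classical behaviour, no mid-p. Exact and approximate
p-values are both available per cell; the pipeline default is exact,
which is fully feasible at the study scale (C(15,8) = 6435).

**Median dichotomization.** LOW iff value ≤ median, with the even-n
median the midpoint of the two central order statistics. On the packaged
cohort this puts the patient at the SUV median (13.0) into the LOW
group, giving the 8-vs-7 split the published analysis reports. An
all-LOW degenerate split is flagged, not fatal.

## Pipeline conventions

The correlation grid is 7 biomarkers × 5 PET indices, all columns
treated symmetrically. VEGF staining intensity is ordinal
(weak/moderate/intense) and enters only through its two-group split
(weak vs moderate-or-intense), never the continuous grid. Outcome
comparisons use vital status at end of follow-up. No multiple-testing
adjustment is made, mirroring the original analysis; the report counts
the comparisons it performed (82 on the packaged cohort).

## Synthetic phantom

The phantom emulates the acquisition geometry of the study — a static
FDG-SUV volume and a late-window hypoxia-tracer ratio volume on a
(plane, row, col) grid with 4.25 mm planes and 7.04/3 mm pixels — with
an ellipsoidal tumor, a *contiguous* hypoxic sub-region of exactly
round(f_h · N_tumor) voxels (nearest-to-centre ball, deterministic
tie-break, so multi-plane ROI logic is exercised), three normal-tissue
reference boxes (brain/muscle/lung analogues) spanning three adjacent
planes each with Gaussian ratio distributions whose pooled mean + 3 SD
lands near the study's threshold, and a 3×3 single-plane lesion-peak
block whose window mean equals the configured peak SUV exactly. Signal
defaults follow the cohort medians (lesion peak SUV 13, FHV fraction
0.48, T/P around 1). Noise is additive Gaussian per voxel: the images
being emulated are late-frame reconstructed ratio/SUV images, where
reconstruction noise is approximately Gaussian; a Poisson counting model
would describe raw projections, which are out of scope. At zero noise
the quantification chain recovers the planted FHV within the one-voxel
discretization bound (100/N_tumor), the plateau and peak SUV exactly,
and the isocontour volume exactly — these recoveries are what the test
suite asserts, and they validate operator correctness, not realism of
scanner physics: no point-spread function, scatter, attenuation,
partial-volume effect or reconstruction is simulated, so passing tests
say nothing about performance on real reconstructed images.

## Synthetic cohorts

Cohorts with a target pairwise Spearman structure are drawn through a
latent-Gaussian copula: latent correlations r = 2·sin(π·ρ_s/6) (the
standard rank-to-latent mapping, exact in the large-sample limit),
Cholesky sampling, then strictly monotone maps of the normal CDF onto
the requested marginal ranges (defaults: the study's observed ranges).
Because every downstream statistic is rank-based, only the
rank-correlation structure matters and the copula family is immaterial —
any monotone marginal transform leaves all statistics unchanged
(property-tested). If the implied latent matrix is not positive
semidefinite it is replaced by the nearest valid correlation matrix
(eigenvalue clipping) and a warning reports the largest entry change.
Missingness is missing-completely-at-random per cell. Ordinal VEGF and
vital status are drawn independently with study-scale frequencies
(weak:moderate:intense ≈ 0.4:0.4:0.2, death probability 0.6).

## Numerical choices

Exact permutation comparisons use an absolute tolerance of 1e−12 when
counting permutations at least as extreme as observed, guarding against
float round-off in rank correlations. Doubled midranks are validated as
integers before the rank-sum dynamic program. The flow lookup refuses
non-monotone tables and out-of-range integrals with errors naming the
bracketing values. JSON output serializes at full precision and maps NaN
to null.

## Packaged cohort and known limitations

The packaged fixture transcribes the published per-patient tables
(15 patients; five PET indices; seven biomarker percentages; VEGF
intensity; vital status). The source rendering of the biomarker table
concatenates digits across cells; the transcription was resolved by
exhaustive tokenization against the table's own printed marginals
(per-column medians, ranges, the 6-vs-9 VEGF split, the published
missing-value pattern), which admit a single consistent reading, and
cross-checked against the published correlation grid, which that reading
reproduces to printed precision for the Ki-67, p53, HIF-1α, CD31 and
CD68 columns.

Two limitations follow from working with printed tables rather than the
authors' raw data. First, printed values are rounded and heavily tied
(e.g. three GLUT-1 values of 60), whereas the original analysis ran on
unrounded, effectively untied data; midrank statistics on the printed
values therefore differ from the published ones wherever ties are dense.
The recomputed GLUT-1 correlations differ beyond what rounding alone
explains (e.g. r_s(GLUT-1, SUV) = −0.284 against a published −0.166),
and the published sample sizes implied by some p-values exceed the
number of non-missing cells in the printed table — the published
summary statistics are not fully self-consistent with the published
per-patient values, and no transcription can reconcile them. Second, the
exact rank-sum test is discrete: at the 8-vs-7 study split its
achievable size at nominal 0.05 is about 0.040, so calibration checks
centred exactly on 0.05 sit at the edge of its conservatism. Both
effects are surfaced, not hidden, by the test suite.
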