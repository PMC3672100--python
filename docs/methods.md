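# Methods

## Signal model of the synthetic generator

Each subject consists of a conventional BOLD series (default 360 volumes, TR
0.9 s) and an interleaved pCASL series (60 volumes, TR 4 s, label duration
1.77 s, post-labeling delay 1.0 s) on one shared grid, default 24×24×12 at
3 mm isotropic — the working resolution of the analysis (full 64×64×16
generation is supported but not the default; the small grid keeps a full
cohort run in tens of seconds). The brain is an ellipsoid occupying 92% of
each grid axis, partitioned into a CSF core, a WM shell, and a GM rind
(mutually disjoint, union = brain mask).

Voxel signal is additive:

```
cvBOLD(v,t) = B·[v∈brain] + Σ_k M_k(v)·a_cv·s_k(t) + d(v)·t + ε
ASL(v,t)    = B·[v∈brain] + Σ_k M_k(v)·a_asl·s_k(t) + ½·ΔM(v)·p(t) + d(v)·t + ε
```

where `M_k` are binary network maps, `s_k` are shared band-limited time
courses sampled at each modality's TR, `p(t) ∈ {−1,+1}` is the labeling
paradigm (first volume label, +1 = control; the convention is recorded in
metadata because the field leaves it implicit), and `ΔM` is the forward
perfusion difference implied by the planted CBF map under the same
quantification model the analysis inverts — so quantification is a genuine
round trip, not a tautology of shared code.

Time courses are finite Fourier sums over the in-band FFT bins of the cvBOLD
sampling grid with Gaussian quadrature amplitudes (uniform random phases),
normalized to unit variance. All of their power is inside 0.01–0.08 Hz by
construction, and the same continuous sum is evaluated on both time grids.

Network 0 is DMN-like: a 9 mm sphere on the posterior cingulate seed
coordinate (0, −50, 31) mm plus a mirrored midline blob, both on the GM rind
(the grid's affine anchors that coordinate at 0.8 of the ellipsoid's y
semi-axis — deliberately **not** at the grid center, which is CSF/WM; a
network planted in the CSF core would be removed verbatim by the CSF-mean
nuisance regressor). Further networks are single 7.5 mm blobs staggered
around the mid-surface.

### Default study conditions (and why)

| parameter | default | rationale |
|---|---|---|
| baseline signal B | 1000 | arbitrary EPI units |
| cvBOLD network amplitude | 20 (2%) | typical resting-state fluctuation size |
| ASL BOLD amplitude | 12 (1.2%) | shorter TE ⇒ weaker BOLD weighting |
| cvBOLD noise sd | 20 (tSNR 50) | typical raw 3 T EPI |
| ASL noise sd | 10 (tSNR 100) | smoothed-EPI-like perfusion series |
| GM / WM / CSF CBF | 60 / 20 / 12 ml/100g/min | standard physiological values |
| between-subject GM CBF sd | 5 ml/100g/min | normal inter-individual spread |
| drift slope sd | 0.01 units/s | slow scanner drift, small vs. signal |
| motion random-walk step | 0.01 mm / 0.01° | compliant subjects (rule still exercised) |

With GM CBF 60 and the default pCASL constants, ΔM ≈ 11 signal units — a
1.1% labeling modulation, matching real pCASL.

Motion traces are **emitted but not applied** as spatial displacement;
realignment is out of scope and the generator does not pretend otherwise.
The 2 mm / 2.0° exclusion rule operates on the traces (strict inequality:
boundary values pass). Cardiac/respiratory physiological noise and
susceptibility dropout are not modeled.

## Preprocessing

Default chain, recorded in provenance: Gaussian smoothing (4 mm FWHM,
volume-wise, σ = FWHM/2√(2 ln 2) converted to voxels; nearest-neighbor edge
handling so constants are preserved) → per-voxel linear detrend (mean
retained) → ideal rectangular band-pass 0.01–0.08 Hz (exact FFT-bin zeroing,
inclusive edges, DC removed; idempotent and exactly testable, matching the
classic resting-state toolchain) → nuisance regression (intercept + 6 motion
parameters + global/WM/CSF mean signals; residuals + intercept). When the
target series is band-passed, the motion regressors are band-passed with the
same filter and the tissue means are extracted from the already-filtered
series, so regression cannot reintroduce out-of-band variance. Constant
regressor columns are dropped; rank-deficient designs are rejected naming
the collinear columns.

ReHo is computed from an unsmoothed chain (smoothing trivially inflates
local concordance); both orders remain available through configuration. The
ICA arm consumes only smoothed + detrended data: global-signal regression
removes one temporal dimension and converts planted sources into contrast
components, and the classic group-ICA workflow decomposes data without
band-pass or nuisance regression.

The 60-volume ccBOLD series is band-passed with the same 0.01–0.08 Hz band
(Nyquist at TR 4 s is 0.125 Hz, so the band is representable).

## Metrics

* **Seed FC**: boundary-inclusive sphere membership by world-space distance
  of voxel centers; Pearson correlation against the seed-mean series;
  constant voxels get r = 0 and a flag; Fisher z with |r| = 1 clipped to
  1 − 10⁻⁷ and flagged.
* **ALFF**: single-sided amplitude 2|X_k|/N of the demeaned series, averaged
  over in-band bins (closed interval on both edges). The normalization is a
  convention — any positive scaling cancels in comparisons — and is recorded
  in map provenance. No division by the global-mean ALFF.
* **ReHo**: Kendall's W with the standard tie correction over the voxel plus
  its 3×3×3-cube neighbors (neighborhood 27 by default; 19 and 7 supported).
  Voxels with fewer than 13 of 26 in-mask neighbors are flagged and set
  to 0; all-tied neighborhoods (denominator 0) are defined as W = 0 and
  flagged. Implementation ranks each voxel once and accumulates rank sums by
  27 shifted-array additions.

## Group ICA

Per-voxel variance normalization per subject, temporal concatenation, then
FastICA (fixed-point, logcosh contrast, deflation) with internal whitening
to exactly `n_components` dimensions — single-stage reduction is adequate at
these cohort sizes and simpler to verify. The decomposition is deterministic
given a seed; non-convergence triggers restarts with derived seeds and an
explicit error when exhausted. Component maps are z-scored over in-mask
voxels, sign-fixed to non-negative skewness, thresholded at z ≥ 1. Greedy
one-to-one template matching (spatial correlation; ties by template order
then component index) replaces visual component selection; unmatched
components are labeled noise. One decomposition is run per modality (a
joint decomposition of both modalities is a possible alternative reading of
the classic workflow; the per-modality choice keeps the arms symmetric).

## Statistics

Voxel-wise one-sample t (df = n−1) and paired t (one-sample on differences).
Zero-variance voxels carry a signed-infinity sentinel, are flagged, surface
in a QC table, and are excluded from significance masks. FWE control is
Bonferroni by default — deterministic and exactly calibratable — with a
seeded max-statistic sign-flip permutation option; random-field-theory
cluster inference is out of scope, though an optional cluster-extent filter
on connected components is provided. Across-network tests: one-way ANOVA on
subject-level RSN means; per-network paired tests between modalities are
Bonferroni-corrected across the networks.

## What passing tests do and do not show

The generator produces linear, Gaussian, spatially-uncorrelated-noise data
with binary networks and stationary time courses. Recovery there
demonstrates the machinery is correct and self-consistent (round trips,
oracle agreement, calibrated error rates), not that real acquisitions meet
these assumptions: no physiological noise, no motion displacement, no
susceptibility dropout, no spatial autocorrelation of noise, and a
desk-scale cohort. Relative CBF error in WM/CSF is dominated by the small
true ΔM there (30–40% at any realistic noise level); quantification accuracy
is therefore quoted for gray matter, the tissue the perfusion literature
quotes and the tissue RSN means are extracted from.

## Numerical choices and problem sizes

Float64 throughout (NIfTI stored float32; masks uint8). Band-edge
comparisons use a 10⁻¹² tolerance; the seed-sphere boundary is inclusive
with a 10⁻⁹ mm² slack. OLS via `lstsq`/explicit normal equations;
correlations clipped to [−1, 1] before atanh. Cohort seeds derive from a
`SeedSequence` spawn of the master seed (kept below 2³¹). The default test
and acceptance problem sizes — 24×24×12 grid, 10-subject cohorts, 200 null
cohorts for FWE calibration, 20 seeds for the noisy CBF round trip, 10 seeds
for noisy ICA recovery — were chosen so the whole verification cycle runs in
a few minutes on one CPU while leaving the measured margins wide.
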