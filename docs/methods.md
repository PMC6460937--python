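# Methods

This note documents the generative model behind the synthetic cohorts,
the estimation choices in each pipeline stage, the parameters that
matter, and what the validation experiments do and do not establish.

## Synthetic cohort model

Each subject's run is a linear mixing model on a common voxel grid with
an ellipsoidal brain mask:

    X_s (T × V) = TC_sᵀ A_s + σ_s E,   E ~ N(0, 1) i.i.d. in-mask

**Spatial sources.** Network sources are 3D Gaussian blobs (FWHM 3
voxels, truncated at 3σ so backgrounds are exactly zero) centered at
random interior points with a minimum pairwise spacing of 2 FWHM
(relaxed gradually on small grids, never below 1 FWHM). Artefact sources
cycle through a rim band, rim-weighted salt-and-pepper speckle, and
scattered rim patches — edge/CSF/motion-like geometry that is mostly
outside the gray-matter mask (the mask interior; rim = mask minus
interior). All artefact patterns are spatially sparse, hence
super-Gaussian, which is what Infomax with a logistic nonlinearity
separates; this is also true of real fMRI artefact topographies.

**Timecourses.** Synthesized in the Fourier domain with deterministic
magnitude envelopes and random phases. Network sources use a Lorentzian
envelope 1/(1 + (f/0.03 Hz)²) below 0.10 Hz with a 3% floor above;
artefact sources use a 5% floor plus a quadratic ramp from 0.155 Hz that
peaks at Nyquist. Deterministic envelopes make the band-power contract
(≥ 80% of network power below 0.10 Hz; ≥ 50% of artefact power at/above
0.15 Hz) hold for every seed, not merely in expectation, and give
artefact spectra their flat/edge-peaked signature (near-zero dynamic
range) despite the high-frequency concentration. The artefact support
starts at 0.155 Hz rather than 0.15 Hz so spectral-window leakage does
not cross the 0.15 Hz boundary. With TR = 3 s the Nyquist frequency is
≈ 0.167 Hz, so the 0.15–0.25 Hz denominator band of the fALFF ratio is
clipped at Nyquist; the clipping is this package's choice of how to
handle a band that partly exceeds Nyquist.

**Planted structure.** Sex effects are additive shifts on female
subject-map intensities at known voxels (positive β ⇒ F > M under the
F = 1 / M = 0 coding); they act on spatial maps, not timecourses,
because the downstream statistics operate on maps. Subject-level map
variability is a smooth Gaussian random field (σ = 0.1 by default).
Covariates: age bins uniform on 19–35 in 2-year steps, IQ ~ N(114, 8),
five scanners uniform, and a log-normal motion multiplier with a +0.25
log-shift for males that scales each subject's noise σ_s — the DVARS
column of the covariate table is then *measured* from the generated run,
so the male motion excess emerges in the data rather than being written
into a table. Nuisance covariate effects on maps default to zero and can
be planted explicitly.

**Amplitudes.** Source peak amplitude defaults to 2.0 with noise σ = 1.
Intrinsic networks in BOLD data are low-contrast; a peak SNR of 2 is
realistic, and because the group-ICA prewhitening variance-normalizes
voxels (mapping a planted amplitude a to a/√(a²+σ²)), much larger
amplitudes would saturate the recovered maps and *reduce* their
correlation with the planted Gaussian profiles.

## Group ICA

Prewhitening for the decomposition demeans each voxel's timecourse and
scales it to unit variance. Subject-level PCA reduces the temporal
dimension (orthonormal basis from the T × T covariance); the temporal
concatenation is reduced again to the model order and whitened. Infomax
uses the natural gradient with a logistic nonlinearity, block updates
(block ≈ √(V/3)), learning rate 1e-2 annealed by 0.9 whenever successive
weight updates point more than 60° apart, restart at half the rate on
blow-up, tolerance 1e-6, at most 500 iterations; non-convergence returns
the best iterate with a flag. Components are scaled to unit variance and
sign-aligned to positive skew.

Stability clustering pools the R runs' components, clusters them by
average linkage on 1 − |r|, and represents each cluster by its
centrotype (the member with the greatest summed intra-cluster
similarity). The dendrogram is cut at the smallest k ≥ C that yields C
clusters with at least R/2 members and the C largest are kept: cutting
at exactly C lets a single degenerate run glue two genuine clusters
together. The stability index is mean intra-cluster minus mean
extra-cluster similarity clipped to [0, 1]; note that chance similarity
between distinct components keeps it slightly below 1 even for R
identical runs.

Guided back-reconstruction estimates, per component, the unit-norm
combination w of the subject's spatially whitened principal components
maximizing a log-cosh negentropy contrast plus λ·corr(map, reference)
(λ = 1 by default), initialized at the projection of the reference onto
the subject subspace; non-converged components fall back to the dual
regression estimate and are flagged. Back-reconstruction demeans but
does **not** variance-normalize the run: on noiseless data generated
from the group maps the estimate must reproduce them exactly, which
per-voxel rescaling would break. Subject timecourses are the
least-squares projection of the run on the estimated maps; maps and
timecourses are z-scored. Dual regression (spatial then temporal least
squares) is implemented separately and serves as the independent
reference method in the validation experiments, never as the primary
estimator.

## Sorting and network maps

The PSD estimator is Welch (Hann window, 50% overlap, segment length
min(T, 64)) rescaled so its integral equals the series variance exactly.
For cohort components the per-subject spectra are averaged — the
spectrum of the mean timecourse would cancel across subjects' phases.
Band integrals are trapezoidal with interpolated band edges, so a flat
spectrum gives a fALFF ratio of exactly 1. Classification thresholds:
fALFF ≥ 2.0, gray-matter overlap ≥ 0.5 (supra-threshold voxels at
|z| > 2), dynamic range ≥ half the batch median. The half-median default
is deliberate: a full-median cut necessarily discards the weakest
genuine network whenever networks are the majority of the batch, while
half the median still rejects flat artefact spectra and adapts to the
batch's scale. A single near-miss failure (within 10% of its threshold)
marks a component "mixed" and it is still discarded — the conservative
rule. Network maps threshold the one-sample t-map at mean + 4σ computed
over in-mask t-values; zero-variance voxels get t = 0 so the threshold
stays finite.

## Dimorphism statistics

The design codes sex F = 1 / M = 0 (so "positively correlated" voxels
are F > M), centers age, IQ and DVARS, and dummy-codes scanner against
its first level; rank is checked and collinear columns named. The
multivariate reduction projects the network's subject maps onto the
fewest principal components capturing 90% variance (capped at n/10, and
at n − q − 2 so the F approximation stays defined), then removes the
nuisance predictor with the largest Lawley–Hotelling p until all pass
α = 0.01; sex is then retained if and only if its own multivariate test
passes — never forced. Voxelwise testing returns to the full original
design (OLS; nuisance partialled out by inclusion). Voxels whose
residual variance is numerically zero are exact fits: p = 0 when the sex
beta is nonzero, p = 1 otherwise — without this rule, noise-free data
would produce arbitrary t-ratios from machine-precision residuals. FDR
is Benjamini–Hochberg on the pooled p-values of all networks within one
model order, significant at q ≤ 0.01; a two-stage (per-network then
across-network) variant was considered and rejected as the default
because the pooled family implements "correction among all networks plus
FDR" as a single coherent procedure. Cluster effect sizes use
26-connectivity by default (configurable to 6 or 18). Model-level
"average area" is the arithmetic mean over networks of each direction's
significant-voxel fraction.

## Footprint

Association maps are consumed as 3D z-maps on the analysis grid (the
pipeline refuses silent grid mismatches); the default binarization takes
z > 0 active since the maps arrive pre-thresholded. Per term and
direction, overlap voxels are unioned across networks with duplicates
removed; the table reports both counts, the male-excess percentage
(M − F)/F × 100 (flagged undefined at F = 0) and the relative
proportions. The default 16-term battery (9 sex-difference terms, 7
cognitive-control terms) ships in the config; any NIfTI z-maps may be
substituted. Live meta-analytic database access is intentionally not
implemented; maps are file inputs.

## Validation experiments and their scope

`netmosaic.experiments` fixes two benchmark settings: the decomposition
benchmark (40 subjects, 6+3 sources, 20×20×12, 120 timepoints) and a
scaled statistics benchmark (12×12×8, 3+2 sources, 60 timepoints) whose
sizes keep 200-cohort calibrations to minutes on one CPU. The
experiments measure: exact trimming; ≥ 8/9 planted sources recovered at
|r| ≥ 0.9 over five seeds; perfect neural/artefact classification of the
planted components over ten seeds; the 4σ tail of a million-voxel
standard-normal map within 3 binomial SEs; mean false-discovery
proportion within the BH level plus 3 Monte-Carlo SEs over 200 null
cohorts; ≥ 80% detection with ≥ 99% correct direction and ≤ 25% cluster
effect-size error for |β| = σ at 50/sex; exact agreement of the
connected-component and set operations with brute-force oracles on 1000
random instances; guided back-reconstruction within median |r| ≥ 0.8 of
dual regression; the exact noise-free footprint identity; and the
mosaic/asymmetry constructions. The noise-free identity feeds detection
with the generator's own subject maps — the output an error-free
back-reconstruction would give — because at exactly zero noise any
numerical remixing in an estimated reconstruction registers as
significant, and the identity is a property of the detection→footprint
chain, not of reconstruction error.

Classification accuracy is likewise measured on the planted components
(ground-truth maps and timecourses): it validates the metrics and the
decision rule under the generator's band-power contract. Estimated
timecourses from small, noisy cohorts carry broadband estimation noise
that dilutes the spectral contrast; on real data the same metrics are
computed on back-reconstructed components, where long scans and large
cohorts keep the contrast usable.

**What passing these experiments does not show.** The generator has no
hemodynamic lag, slice-timing or susceptibility artefacts, no spatial
autocorrelation beyond the planted blobs and the smooth subject fields,
and its artefacts are stylized geometries. Effect sizes, grids and
source counts are orders of magnitude below real whole-brain data.
The experiments validate correctness of the machinery — recovery of
known structure, calibration of error rates, exactness of the set
operations — not the empirical claims any particular real-data study
would make.

## Known limitations

- Infomax separates super-Gaussian (sparse) sources; strongly
  sub-Gaussian artefacts (e.g., bimodal stripe patterns) would need the
  extended variant, which is not implemented.
- The MANCOVA F-approximation requires n comfortably above the predictor
  count plus the response dimension; very small cohorts raise validation
  errors rather than returning unstable statistics.
- Motion matching is a greedy heuristic (largest gap reduction, age-bin
  balance preferred, lowest id on ties); it finds *a* matched sample,
  not an optimal one.
- Stage caching is keyed by config hash at the ICA level only; upstream
  simulation is cheap enough to regenerate.
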