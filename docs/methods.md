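# Methods

This note documents the models, parameter choices and numerical decisions
behind each stage of the pipeline, and what the synthetic fixtures do and
do not establish about real instrument data.

## Synthetic data model

The fixture generator (`organellems.fixtures`) is first-class, tested code:
it defines the operating conditions under which every downstream stage is
validated.

**Images.** Vesicles are rendered as radially symmetric Gaussian blobs
(sigma = radius/2) of depth `vesicle_contrast × background_mean` on a
uniform background with additive Gaussian noise, dark-on-bright by default
(brightfield contrast of dense-core vesicles) with a `bright` polarity flag
for digitally inverted images. Defaults: 50 objects on a 512 × 512 px grid
at 1 µm/px, background 100, contrast 0.5, noise 1% of background, radii
2–4 px, and a 30 µm placement guard so blobs never overlap. Blob placement
is dart throwing; an impossible packing raises a `PlacementError` rather
than silently under-filling. The generator does not model the optical
point-spread function, mosaic stitching seams, illumination gradients, or
debris — detection scores on fixtures are therefore upper bounds on what a
real slide would give, and the acceptance numbers should be read as
verifying the algorithmic contract (thresholding, labeling, size window,
weighted centroids), not microscope performance.

**Spectra.** A spectrum is a sum of Gaussian peaks (sigma 0.04 Da) on a
uniform m/z grid (0.01 Da step, window 450–1,450 by default) over a small
positive baseline (mean 1.0) with additive Gaussian noise (sd 0.1).
Peak heights are jittered by a mean-preserving log-normal factor
(CV 0.3 — strictly positive and heavy-tailed, like MALDI intensities), and
all peaks of one spectrum share a uniform ppm drift drawn from ±5 ppm,
emulating per-spot calibration drift. Two vesicle classes are planted
("DCV": peptide-like peaks including two tall calibrant peaks at m/z
1,221.6878 and 1,396.7225, plus the protonated and sodiated ions of
PC(34:1); "LV": a disjoint lipid-like peak set), and the DCV class carries
three subpopulations of 5 marker peaks each. No isotope envelopes are
simulated — the analysis operates on picked monoisotopic features — and no
matrix-cluster chemical noise is modeled. The noise level is a free
choice: it is set so that peak-apex mass precision is sub-ppm, the regime
a high-resolution FTICR instrument actually delivers for well-formed
peaks; the calibration acceptance bound (≤ 0.5 ppm worst case after
correcting a planted +5 ppm drift) is only meaningful in that regime.

The baseline is deliberately positive: clipping zero-mean noise at zero
would make half the grid exactly zero, which both misrepresents profile
data and breaks any median/MAD noise estimator.

All randomness flows through `FixtureConfig.seed`; identical configs give
byte-identical fixtures.

## Detection

Global Otsu threshold (a manual threshold is available), 8-connected
components, equivalent-diameter window, intensity-weighted centroids
(weights are contrast relative to the background side of the threshold, so
dark and bright polarities behave symmetrically). Coordinates are
row-major, 0-based, origin at the top-left pixel center, everywhere in the
package. A constant image returns an empty table with a warning, not an
exception. Otsu needs the foreground to carry a nonneglible share of the
histogram (≳0.1%); extremely sparse slides should use the manual
threshold. `filter_objects` only flips the `accepted` flag — rows are
never deleted, so manual curation keeps a full audit trail.

## Registration and targeting

The pixel→stage map is a full 6-parameter affine (accommodating stage-axis
shear; it reduces to a similarity when the data allow), least-squares
fitted on centered coordinates for conditioning — stage offsets of 10⁴–10⁵
µm otherwise dominate the normal equations and the "exact fit" property
(residual ≤ 1e-9 µm on affine-consistent fiducials) fails in float64.
Fewer than 3 fiducials, or collinear ones, raise an error naming the
geometric deficiency.

The distance filter is symmetric: every point with *any* neighbor strictly
closer than `min_spacing` (default 200 µm) is removed, because a laser
spot over either member of a close pair would sample both organelles. A
greedy keep-first mode exists behind a flag. A distance exactly equal to
the spacing is kept (strict "closer than"). The implementation uses a k-d
tree (`scipy.spatial.cKDTree.query_pairs`) and is tested for exact
agreement with an O(n²) brute-force oracle; every exported `TargetList`
re-asserts the minimum-spacing guarantee in its constructor.

## Spectral preprocessing

**Peak picking.** Candidates are local maxima; the local baseline is a
running median over 101 grid points and the noise is 1.4826 × the running
median absolute deviation over the same window (a robust stand-in for the
proprietary vendor noise model; reflect-padding at the spectrum edges —
replicate-padding collapses the MAD there). Retention requires
(apex − baseline)/noise ≥ 5 and raw apex strictly greater than 0.01% of
the base peak (the boundary rule is strict-greater, documented and
tested). Apex m/z and height are refined by a least-squares parabola on
the log intensities of up to 7 points centered on the maximum: a Gaussian
peak is exactly quadratic in log space, so the fit is unbiased, and
averaging over 7 points rather than interpolating through 3 reduces the
noise-limited apex error about threefold — the difference between ~0.8 ppm
and ~0.2 ppm worst-case mass error at the default fixture noise, i.e.
between failing and meeting the sub-0.5-ppm post-calibration behavior the
workflow depends on. The classic 3-point parabola remains as the fallback
for degenerate windows.

**Internal calibration.** Calibrants are matched to the nearest picked
peak within 50 ppm. Two or more matches fit m_corr = a·m_obs + b in m/z
space (handling both gain and offset drift); a single match applies a
constant-ppm correction; zero matches leave the spectrum unchanged with a
per-spectrum warning flag — the pipeline keeps such spectra, matching
analyses run without internal calibrants (e.g. lipid-window
classification). Residuals are reported in ppm.

**Alignment.** Pooled peaks are sorted and split into bins wherever the
gap between adjacent peaks exceeds 5 ppm of the local m/z (single-linkage
1-D clustering, so bin widths adapt to local density — "nonuniform
binning"). The 5 ppm default is deliberately below the 7 ppm annotation
tolerance so bin width never dominates annotation error. Each spectrum
contributes at most one intensity per bin (the maximum); a bin's
representative m/z is the intensity-weighted mean of its member peaks;
features outside the requested window (inclusive) are dropped. Zero means
"feature absent".

## CX feature selection

Deterministic CX (exact SVD leverage scores, top-c selection) rather than
randomized column sampling. No centering or scaling is applied before the
SVD by default: intensities are nonnegative and zero encodes absence;
centering would destroy that structure (a `center` switch exists). Ties
in leverage break toward the lower column index for reproducibility.

`choose_rank` uses the closed form for the best rank-k relative Frobenius
error, sqrt(Σ_{i>k} s_i² / Σ s_i²), so the full error curve costs one SVD;
the chosen k is the smallest with error < 0.25 (the largest grid value,
with a warning, if none qualifies).

One caution on error bounds: ‖A − CX‖_F is bounded below by the best
*rank-c* SVD error, not the rank-k one — C spans up to c dimensions, so
with c > k the CX error can legitimately beat the rank-k optimum.
`CXResult` therefore reports both `svd_rel_error_k` and `svd_rel_error_c`;
the rank-c bound is the invariant asserted unconditionally.

## Clustering and marker statistics

Rows are RMS-normalized (each divided by its root mean square; zero rows
are left zero with a warning) before k-means, which runs with k-means++
initialization and 10 restarts per cluster count. The cluster count is the
maximum second difference of the WCSS curve — the sharpest elbow — which
makes the choice deterministic and testable; only interior grid points are
eligible, so the default grid 2–8 brackets the expected 3.

Markers are one-vs-rest two-sided Wilcoxon rank-sum tests per (cluster,
feature): the exact null distribution when both groups have ≤ 10 members
and no ties, otherwise the normal approximation with tie correction; a
pooled sample with all values identical returns p = 1. Benjamini–Hochberg
correction is applied across features within each cluster (raw p values
are also reported). Violin-plot data are RMS-normalized intensities in
long format.

## Classification and SHAP

Gradient-boosted trees (depth 4, 200 trees, learning rate 0.1 — fixed and
logged; reproducibility over tuning) under stratified 3-fold validation
with a seed-fixed split; accuracies, confusion matrices and ROC curves are
computed on held-out folds only. SHAP values use the exact tree-path
algorithm built into XGBoost (`pred_contribs`), evaluated on each fold's
held-out instances (computing attribution on data the model was fitted to
would overstate importances) and averaged across folds; features with
nonzero mean |SHAP| are "selected", importances are also reported
normalized to [0, 1]. Additivity (contributions + base value = raw margin)
holds to float32 precision (~1e-5 on margins of order 10), the arithmetic
XGBoost uses internally. Retraining on a feature subset repeats the
identical protocol so reports are comparable side by side. The t-SNE
embedding (cosine distance, seed recorded, perplexity auto-reduced for
small n) is for visualization only and never feeds back into inference.

On the default separable fixtures the trees need very few features, so the
nonzero-SHAP set can be as small as one feature; the count of selected
features is a dataset property, not a contract of the method.

## Annotation

Peptide [M+H]⁺ = Σ residue monoisotopic masses + 18.010565 (water) +
1.007276 (proton) + PTM deltas (amidation −0.984016; acetylation
+42.010565; pyro-Glu from Q −17.026549; pyro-Glu from E −18.010565;
phospho +79.966331; half-disulfide −1.007825 per participating cysteine;
closed bridge −2.015650). Residue coordinates are 1-based inclusive
throughout. Candidate lists are plain CSV — no live database queries — and
lipid candidates are considered as [M+H]⁺ and [M+Na]⁺ adducts at a 7 ppm
tolerance, boundary inclusive; ambiguous features (multiple hits) are
flagged rather than resolved. Sequence coverage is the size of the union
of detected residue intervals divided by the precursor length (overlaps
counted once). LC–MS/MS evidence enters only as a list of validated
candidate names that flags annotations; no search engine is implemented.

## Problem sizes and determinism

The test-suite and acceptance-script problem sizes — 512² px images with
50 vesicles, 120 spectra of ~100k grid points, feature matrices of order
120 × 120, 200 random point sets up to n = 2,000 for the filter oracle —
were chosen so the full validation runs in well under a minute per stage
while still exercising every code path at realistic dimensionality ratios
(more features than informative ones, more spectra than clusters). Every
stochastic operation takes an explicit seed and the acceptance script
derives all of its seeds from a single `--seed` argument.

## Known limitations

- Otsu thresholding degrades on extremely sparse slides (foreground
  ≲ 0.1% of pixels); use the manual threshold there.
- Peak picking assumes approximately Gaussian, baseline-resolved peaks;
  overlapping isotopologues or shoulders are not deconvolved (isotope
  deconvolution and charge assignment are out of scope).
- The single-linkage ppm-gap binning is a documented substitute for an
  unspecified vendor alignment step, not a claim of equivalence.
- The dense SVD inside CX is comfortable to a few thousand columns;
  larger matrices would need a truncated solver.
- Fixtures are far cleaner than real single-organelle spectra (no chemical
  noise, no isotopes, no peak-shape asymmetry); passing the suite
  validates the algorithms' contracts, not instrument-level performance.
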