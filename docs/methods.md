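# Methods

## The assay model

The pipeline models a translocation screen: in diseased cells a
transmembrane cargo protein accumulates in the trans-Golgi network (TGN)
instead of being exported to the cytoplasm. Each imaged field carries four
co-registered channels — nuclear stain, cell-body/cytoskeleton stain, TGN
marker, cargo — and each cell is summarised by the translocation ratio,
the mean cargo intensity over the TGN mask divided by the mean over the
cytoplasm (cell minus TGN). Means, not integrated intensities, are used so
the ratio is independent of compartment area; this is the reading that
makes the ratio a concentration contrast rather than a mass split.

## Segmentation

Nuclei: global Otsu threshold (configurable fixed offset), hole filling,
removal of components below `min_nucleus_area` (default 64 px). Cell
bodies: seeded watershed on the distance-from-nucleus surface restricted
to the thresholded body mask, so a body blob containing two nuclei is cut
along the midline between them; nuclei are forced to belong to their cell.
TGN: thresholded TGN signal intersected with each cell mask, so a blob
straddling a boundary is split by ownership. Cells touching the field
border are excluded, as are cells with an empty TGN or a zero cytoplasmic
cargo mean (undefined ratio); every exclusion carries a reason code.
Pixels are half-open sets, origin top-left, row-major. A constant
background — the median intensity outside all cell masks — is subtracted
from the cargo channel before compartment means are taken; no other
illumination correction is attempted.

## Morphology

For any compartment mask: elongation = minor/major axis of the best-fit
ellipse (≤ 1, 1 for a disk); compactness = perimeter²/(4π·area) (≥ 1, 1
only for a disk); roughness = perimeter of the mask divided by the
perimeter of the equal-area circle (the "shape factor" normalisation, and
exactly √compactness under this definition — kept as a separate named
output because the two are conventionally reported separately). The
perimeter is the marching-squares contour length after a 3-point circular
moving average of the contour polygon. This choice was validated against
analytic shapes: raw boundary-pixel counting inflates a circle's perimeter
by ~27% (compactness 1.56), the unsmoothed contour by ~5%, and the Crofton
estimator deflates axis-aligned rectangles by ~7%; the lightly smoothed
contour reproduces a rasterised disk at compactness 1.02, a square at
1.25 (analytic 4/π ≈ 1.273) and a 100×10 rectangle at 3.77 (analytic
3.85), all within the tolerances the tests assert.

The per-cell descriptor vector has 90 entries in a fixed, documented order
(`FEATURE_NAMES`): 10 shape descriptors for each of nucleus/cell/TGN, 4
intensity statistics for each of the 4 channels over each of the 3 masks,
and 12 cargo-specific readouts (compartment means, ratio, quartiles,
cargo-positive area, puncta count and mean size, area ratios, TGN fragment
count). The published workflow this emulates reports "ninety" descriptors
without enumerating them, so the implemented set is a documented stand-in
with the same structure, not a reconstruction.

Neurite puncta density = local cargo maxima above threshold within the
neurite mask, divided by the skeleton polyline length (orthogonal steps +
√2·diagonal steps, in µm).

## Plate QC and normalization

Robust Z′ = 1 − 3(σ̃⁻ + σ̃⁺)/|m⁻ − m⁺| with medians m and
normal-consistent MADs σ̃ (1.4826·MAD); SSMD = (μ⁻ − μ⁺)/√(s⁻² + s⁺²) in
moment form (robust form behind a flag), positive when the negative
(disease) control exceeds the positive; CV = 100·s/μ of the
negative-control wells, per plate (an across-plate variant of control
means is available for the "inter-assay" reading). Gates are inclusive:
Z′ ≥ 0.3, SSMD ≥ 3, CV ≤ 10%. All statistics use sample SD (ddof = 1).

Well normalization is z-scoring against the same plate's negative
controls, for both the ratio and the cell count; additive plate shifts
cancel exactly. Negative controls are the reference because both screen
gates are defined as reductions relative to them. Whether robust or
moment statistics were used in the original z-scores is not published;
moment statistics are the default here.

A caveat the simulations make explicit: with negative/positive control
SDs of 0.05/0.02 ratio units and a separation of 0.24 — the *pooled*
well-level spreads of the emulated assay — the expected robust Z′ is
1 − 3·0.07/0.24 ≈ 0.13, below the 0.3 gate, while SSMD (≈ 4.5) and CV
(≈ 3.7%) pass with margin. Pooled SDs include plate-to-plate variability,
so within-plate Z′ of a real screen can be much higher; simulated plates
drawn directly at pooled SDs will mostly fail the Z′ gate, and the test
suite asserts the SSMD/CV gates as the reliable ones under these
conditions. Replicate reproducibility is estimated by splitting plates
into two random halves (⌊N/2⌋/⌈N/2⌉ for odd N), correlating per-position
half-means, and averaging Pearson r over 100 samplings. Control
separability is the held-out AUC (rank-sum estimator, 70/30 split) of a
logistic model on the ratio.

## Triage and dose-response

Primary triage applies two inclusive gates to per-plate z-scores:
active ⇔ ratio_z ≤ −3, toxic ⇔ cellcount_z ≤ −2, giving four disjoint
categories (inactive / toxic / active_toxic / active_nontoxic) that
partition the retained compounds. Headline reports additionally quote a
"toxic total" that includes the active_toxic compounds, matching screening
convention. A prefilter removes wells that cannot be scored at all
(non-quantifiable signal, absolute cell-count floor of 50, artifact
flags) with recorded reasons. Gate thresholds were applied per plate; the
alternative (screen-wide SDs) is not implemented because all assay
statistics are defined per plate here.

The 4PL is fitted by bounded least squares in log10-dose space with a
multi-start over 3 Hill slopes × 5 EC50 decades; EC50 is bounded to
[min dose/10, max dose×10]. `bottom ≤ top` is normalised via the
hill → −hill symmetry. Non-convergence and flat (degenerate) curves
return flagged results, never exceptions; EC50 is reported only when
`ec50_in_range`. Counter-screen activity requires the ratio gate in
*both* replicates at ≥ 2 concentrations ("more than one concentration"
and "at least 2 different concentrations" being the same rule), with
toxic concentrations excluded from the evidence; the call is invariant to
row order.

An identifiability limit worth knowing: on the 11-point two-fold grid
with duplicate wells, response span 6 z-units and noise SD 0.5, the
median relative EC50 error of the maximum-likelihood fit is ≈ 20% at a
potency of ~5 µM (the bottom asymptote is never reached at max
dose/EC50 ≈ 8.6, so EC50 and bottom are strongly correlated). This is a
property of the design, not the fitter — a truth-initialised
unconstrained fit performs identically — and noiseless recovery is exact
to < 0.1%.

## Profiling

Per-image medians of the single-cell features (medians for robustness to
segmentation outliers) → drop rows with missing values and zero-variance
columns (logged) → standardize to mean 0, sample SD 1 → full-rank PCA on
the standardized (correlation-structure) matrix. Component signs are
fixed by making each component's largest-magnitude loading positive so
reports are reproducible across BLAS builds. Profile features are those
with |Pearson r| > 0.75 against PC1 (the magnitude reading of the
published cutoff); the exploratory feature-feature correlation matrix
uses pairwise-complete observations, while PCA uses the fully cleaned
matrix, in that order. `clean_and_scale` is idempotent and selection is
monotone in the cutoff.

## Synthetic data

`generate_field` renders non-overlapping elliptical cells (rejection
sampling of centres, so segmentation is tested separately from
under-segmentation pathology), one central nucleus, and one compact
perinuclear TGN disk per cell sized to `tgn_area_fraction` of the cell.
The cargo budget is split: a designed fraction uniformly over the TGN,
the remainder over the cytoplasm as a diffuse floor plus Poisson-count
puncta. Because compartment *means* are fully determined by the budget
split and mask areas, the designed per-cell ratio is exact regardless of
puncta placement; `target_ratio` inverts the split per cell from realised
areas. Noise is additive Gaussian per channel, clipped at zero — the
simplest model sufficient for testing estimators. Everything is
deterministic given the seed.

`generate_screen` draws per-well means directly (no image rendering) so
28k-compound simulations stay desk-scale: negative controls and inactive
compounds from Normal(1.34, 0.05), positive controls from
Normal(1.10, 0.02) — the emulated assay's printed well-level control
distributions — with 1.7% actives shifted −5 negative-control SDs and 5%
toxics shifted −3 cell-count SDs, matching the observed screen
composition; an additive per-plate shift (SD 0.01 ratio units, chosen
small relative to the control spread) exercises per-plate normalization.
Single-cell ratio dispersion is not characterised by the emulated assay's
publications, so it is a free parameter of `FieldSpec` rather than a
calibrated one. `generate_titration` adds Gaussian noise in z-units to a
4PL curve over the 11-point counter-screen grid in biological duplicate.

What the generator does not emulate — and hence what green tests do not
establish about real data: optical blur and chromatic shifts, spatial
plate artifacts (edge/row/column effects), autofluorescent compounds,
cell-cycle and density-dependent morphology variation, overlapping or
clipped cells, and non-Gaussian intensity noise. Tests against this
generator validate the estimators' correctness, not the robustness of
segmentation on difficult real images.

## Problem sizes

Default test and reproduction runs use fields of 384–640 px with 8–25
cells, screens of 4–8 plates (≈ 1,400–2,800 compounds), 100-plate QC
simulations, 200-seed titration ensembles, and 120-image profile
matrices — sizes chosen so the whole suite runs in well under a minute of
simulation time per stage while keeping every statistical check
adequately powered.
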