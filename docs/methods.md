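# Methods

This note documents the models, defaults and numerical choices behind
`deltarad`. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Geometry and preprocessing

Arrays are `(z, y, x)` with axial slices along `z`; voxel centers sit at
`origin + index * spacing` (0-based, world mm). Volume/mask pairs must
match in shape, spacing and origin to 1e-6 and the mask must be nonempty.

Isotropic resampling uses trilinear interpolation for the image and
nearest-neighbour for the mask, so the mask stays binary; the output grid
size is `round(extent / target)` per axis, preserving world extent to
within one voxel. The clinically motivated target for thin-slice chest CT
is 0.25 mm; the synthetic pipeline and tests default to a 1 mm isotropic
grid, which is the generator's native resolution — every feature is
parameterized by spacing, so the analysis is resolution-aware rather than
resolution-specific. The interpolation scheme is a documented assumption;
NIfTI-1 stores spacing/origin as float32, so geometry round-trips are exact
only to ~1e-7 relative.

## Feature catalogue (183 features)

The default manifest is declarative YAML-backed configuration; only its
total is fixed by convention. Composition:

| block | count | parameters |
|---|---|---|
| size/shape | 12 | Volume, Max_Diameter, Boundary_Radius_Std, Shape_SI1–9 |
| sigmoid margin | 6 | Offset/Slope/Amplitude means, half-length 3 and 5 mm |
| Laws energy | 14 | kernel ids 1–14 |
| Gabor energy | 16 | orientations {0,45,90,135}° × wavelengths {3,5,7,9} px |
| GLCM | 135 | 15 statistics × distances {1,2,4} × {mean, std, range} |

**Laws.** Basis vectors L5=(1,4,6,4,1), E5=(−1,−2,0,2,1), S5=(−1,0,2,0,−1),
R5=(1,−4,6,−4,1) and the standard wave vector W5=(−1,2,0,−2,1). The 14
zero-sum 5×5 kernels are the 10 symmetrized cross-products
(uᵀv + vᵀu)/2 over unordered pairs, ordered lexicographically with
L<E<S<R<W (ids 1–10: LE, LS, LR, LW, ES, ER, EW, SR, SW, RW), then the four
zero-mean self-products E5ᵀE5, S5ᵀS5, R5ᵀR5, W5ᵀW5 (ids 11–14). L5ᵀL5 is
excluded as non-zero-mean. Under this numbering `Laws_Energy-10` is the
R5/W5 cross kernel and `Laws_Energy-13` is R5ᵀR5; an alias map in the
manifest allows remapping to any external numbering. Filtering is 2D per
axial slice (CT is axially acquired and the filter parameters are
in-plane) with half-sample-symmetric boundary handling; the energy is the
sum of squared responses over lesion voxels, hence homogeneous of degree 2
in image intensity.

**Gabor.** Real part of an oriented Gaussian-enveloped sinusoid
(scikit-image kernel); orientation measured in-plane from +x toward +y,
wavelength in pixels, envelope width set by a 1-octave bandwidth. Same
per-slice protocol and energy definition as Laws.

**GLCM.** Intensities inside the mask are quantized into 32 equal-width
bins over the masked [min, max] (the binning is a documented choice; the
statistics are bin-index based). Pairs are counted at offset
`distance × direction` over the 13 unique non-antiparallel 3D directions,
symmetrized and normalized. Statistics: Contrast, Dissimilarity,
Homogeneity, ASM, MaxProb, Entropy, Correlation, ClusterShade,
ClusterProminence, SumAverage, SumEntropy, DiffEntropy, Autocorrelation,
IMC1 = (HXY − HXY1)/max(HX, HY), and MCC = √(second-largest eigenvalue of
Q(i,j) = Σₖ p(i,k)p(j,k)/(pₓ(i)p_y(k))), clamped to [0,1]. Entropies use
natural logs. Degenerate fallbacks (never NaN): single occupied gray level
gives IMC1 = 0, MCC = 1, Correlation = 0; directions with no valid voxel
pair are dropped from the 13-direction aggregation, and a mask with no
pair in any direction is an error.

**Shape index.** The mask indicator is Gaussian-smoothed (default
σ = 1.5 mm) into an implicit function; at each surface voxel (foreground
with a 6-neighbour outside) the principal curvatures κ₁ ≥ κ₂ come from the
level-set shape operator −P H P/|∇F| restricted to the tangent plane, with
the outward-positive convention (sphere: κ₁ = κ₂ = 1/r > 0). The index
s = 1/2 − (1/π)·atan2(κ₁+κ₂, κ₁−κ₂) ∈ [0,1] is histogrammed into 9 equal
bins; fractions sum to 1. Under this mapping a dome/spherical cap falls in
SI1, a cup in SI9, and SI6 covers the saddle/rut transition band of the
rescaled Koenderink index; vanishing gradients fall back to the flat bin
(s = 1/2, SI5). The [0,1] mapping and the bin-to-name assignment are
interpretations, fixed and documented here.

**Sigmoid margin.** For each surface voxel a line along the outward normal
(−∇ of the smoothed indicator) is sampled at 0.5 mm steps over ±L
(L = 3 or 5 mm) by trilinear interpolation and fitted with
f(t) = B + A/(1 + exp(−s(t − t₀))) by Levenberg–Marquardt least squares.
Initialization: B from the outer 20 % of samples, A = inner mean − B,
t₀ = 0, s = −sign(A)·4/L (the sign makes the decreasing inside→outside
branch the starting point). Reported per line: offset = B + A/2 (the
mid-transition density), slope = |sA|/4 (maximum density change rate,
HU/mm), amplitude = |A|; features are means over fitted lines. Lines that
leave the volume or fail to converge are skipped and counted. For
tractability at cohort scale at most 200 lines per lesion are fitted,
chosen by an even deterministic stride over the sorted surface voxels; on
the phantoms this changes the means by far less than their voxelization
noise.

**Size.** Volume = foreground count × voxel volume. Max diameter = largest
pairwise distance between surface-voxel centers (computed on the convex
hull for large surfaces, which attains the same maximum).
Boundary-radius std = population std of centroid-to-surface distances,
zero for a perfect sphere.

## Synthetic cohort generator

Each lesion is a perturbed ellipsoid: directional radius
R(d) = r_ell(d)·(1 + b·f(d)) with semi-axes drawn per subject
(default Uniform(5, 15) mm per axis), bumpiness b = 0.15, and f a
band-limited angular field (Legendre lobes of degree ≤ 4 with seeded axes
and weights, normalized to [−1,1]) — enough to produce non-spherical
shape-index variety without topology changes. The image is a parenchyma
plateau (−780 HU) rising to a lesion plateau (+30 HU) through a logistic
radial transition of width w (default 1 mm) whose maximum slope is
ΔHU/w; the transition is clipped to exact plateaus beyond 2w so that
deep-interior voxels equal the plateau exactly. Inside the lesion a
stationary Gaussian random field (white noise convolved with a Gaussian of
the texture correlation length, default 2 mm, rescaled to 25 HU) is added,
weighted by the lesion membership; i.i.d. Gaussian scan noise (20 HU) is
added everywhere. Defaults are plausible chest-CT contrasts chosen once
for reproducibility; the correctness of the feature math does not depend
on them. Grid: 64³ at 1 mm, with a containment check (lesion + margin +
5 mm context).

**Response model.** The follow-up lesion is the same continuous lesion
(same seed → same bump field and texture noise) re-rendered with radii
scaled by ratio^(1/3). Post/pre volume ratios are log-normal:
mutants LogNormal(ln 0.55, 0.25), wild-type LogNormal(ln 0.98, 0.08), so
mutants shrink ~45 % on average while wild-type is static up to noise. The
effect sizes are calibrated choices (the source cohort reports no
quantitative ones): they produce a delta-volume AUC around 0.95–1.0 at
20 + 20 subjects, the regime in which a strong responder-vs-nonresponder
contrast lives. Mutant margins widen ×1.8 and texture correlation lengths
grow ×1.5 after treatment, giving the margin and texture features a
genuine (weaker) delta signal too. No baseline label effect is modelled,
so baseline AUCs fluctuate around 0.5.

**Test–retest pairs** share geometry, texture and plateaus; the second
scan differs by an independent noise realization and a sub-voxel
translation (Uniform(−0.5, 0.5) voxels per axis) applied to the continuous
model before voxelization — the idealized "same patient, 15 minutes later"
setting.

**What the generator does not emulate:** lung anatomy (vessels, airways,
pleural contact), reconstruction kernels and dose-dependent noise texture,
respiratory motion, segmentation variability (masks are exact by
construction), and any baseline association between texture and mutation
status. Passing pipeline tests therefore demonstrates that the machinery
recovers signals it was given and is stable under re-scan noise — not that
the specific features are clinically predictive.

## Delta table, selection, statistics

Delta = pre − post, cell-wise after alignment by subject id; labels must
agree. The coefficient of variation is sample std / |mean|, undefined
(excluded from ranking) when |mean| < 1e−12 — relevant because delta
values can be negative. Selection: rank by CV, keep the top 15, then
while any pair has |ρ| above 0.95 remove, from the worst pair, the feature
with the larger mean absolute correlation to the remaining candidates
(ties: lower CV, then lexicographically later name); Volume and
Max_Diameter are kept out of the ranking pool and appended for comparison.
"Mean correlation higher than 0.95" admits several readings; this
worst-pair/most-redundant-first rule is reproducible and order-invariant
(columns are sorted before ranking). Spearman is the default pruning
statistic, Pearson available by config. The selector is an sklearn
transformer (`fit`/`transform`/`get_params`), so it composes with
pipelines and model selection.

AUC uses the Mann–Whitney identity with ties counted 1/2; p-values are
exact (enumeration) for tie-free problems with n₊·n₋ ≤ 400 and
tie-corrected normal otherwise, with the method recorded per result. The
exact and normal p agree to < 0.01 at cohort-scale grids (n₊·n₋ ≳ 100);
at very small samples the normal approximation inherently deviates more.
AUC is reported directionally (can be < 0.5) with a sign field. No
multiple-testing correction is applied in the headline screen (the
selected panel is small by design); a Benjamini–Hochberg column is
emitted, explicitly labelled supplementary.

ICC uses the Shrout–Fleiss single-measure ANOVA closed forms with k = 2
replicates; ICC(1,1) (one-way random effects) is the default for
test–retest under one protocol, with ICC(2,1)/ICC(3,1) selectable and the
estimator label recorded in every output. A table constant in both
columns has no defined ICC and is reported as NaN and excluded from
summary means. The implementation is cross-checked against pingouin in
the test suite.

## Pipeline and problem sizes

`run_study` chains cohort → (optional resampling) → extraction → delta →
selection → AUC screening (selected panel at pre, post and delta, the
three-panel presentation) → correlation matrix, and writes reports only
after every stage succeeds; failures carry the stage name. Outputs embed
the seed, a config hash and the package version. The default study runs
20 + 20 subjects on 64³ 1-mm grids and 20 test–retest pairs — sizes chosen
so a full study, including 183-feature extraction on 80 volumes, completes
in about a minute on one CPU while leaving every statistical contrast
comfortably detectable.

## Known limitations

- Laws/Gabor are 2D per-slice by design; no 3D texture-energy variants.
- The exact composition of the 183-feature catalogue and the external
  Laws numbering are conventions of this package (alias-mappable), not a
  canonical standard.
- The sigmoid "offset"/"slope" definitions (B + A/2, |sA|/4) are one
  parameterization of margin density and sharpness; others exist.
- GLCM binning (32 equal-width bins over the masked range) makes texture
  statistics invariant to affine intensity rescaling but sensitive to
  outlier-driven range changes.
- No inter-timepoint registration: features are computed per scan, which
  matches the delta-of-features design but cannot localize change.
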