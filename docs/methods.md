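# Methods

`epiquant` implements the quantitative chain used to study how NANOG and SOX2
partition the post-implantation mouse epiblast: per-nucleus immunofluorescence
quantification of 3D confocal stacks, a threshold–correlation statistic linking
regional SOX2 levels to explant pluripotency, a stage-wise blocked correlation
screen for co-regulated genes, and a partial information decomposition of what
gene pairs say about *Sox2*. Every stage is exercised on synthetic data with
planted ground truth; this note records the models, the defaults and why, the
numerical choices, and what the synthetic data does and does not establish.

## Depth-attenuation correction

Detected fluorescence in a cleared whole-mount embryo decays approximately
exponentially with imaging depth. Each channel carries an attenuation constant
`k` (per micron); a voxel recorded at depth `d` is corrected as

    corrected = recorded / exp(-k · d),      d = z_index · Δz

with depth measured in microns from the first acquired plane. Defaults are the
constants typical for this preparation: 0.001 (Alexa488), 0.009 (Alexa568),
0.002 (Alexa647) and 0.014 (DAPI). The formula's depth unit is fixed here as
microns — the magnitudes of `k` only make sense as per-micron rates — and a
`depth_offset_um` parameter covers stacks whose first plane is not the sample
surface. Correction precedes segmentation and feature extraction by default;
`quantify-stack --segment-uncorrected` segments the raw nuclear channel
instead and corrects only the intensities, for preparations where amplified
deep-stack noise harms the mask more than attenuation does.

## Segmentation and features

The built-in segmenter is deliberately classical so that its behaviour is
fully reproducible: Gaussian smoothing (σ = 1 voxel), Otsu threshold,
removal of objects below `min_size` voxels, Euclidean distance transform
(anisotropy-aware), light smoothing of the distance map (σ = 1 voxel, which
removes the integer plateaus that would otherwise seed spurious watershed
markers), peak markers separated by at least `min_distance_um` (set near the
expected nucleus radius; default 4 µm), and marker-based watershed. A
`2d-per-slice` mode segments each plane independently and relabels, mirroring
per-slice pipelines. Label volumes from any external model (e.g. a trained
deep-learning segmenter) can be supplied via `labels_from_array`/`read_labels`
and flow through the identical feature extraction, and `filter_labels`
(min/max voxel count) stands in for manual curation, which cannot be
automated.

Per nucleus we record voxel count, boundary measure (2-D perimeter per slice
label; exposed voxel-face surface area in 3-D, both in microns), an
eccentricity in [0, 1) from the second-moment ellipsoid
(`sqrt(1 − λ_min/λ_max)` of the coordinate covariance eigenvalues), and the
average nuclear intensity (ANI) — the arithmetic mean of each channel over
the nucleus's voxels. ANI is permutation-invariant over voxels and linear in
global intensity scaling.

## Gating, contours, colony classes, G-test

Positivity gates are derived from an internally controlled negative region of
the same embryo. The statistic of the negative ANI population is selectable:
99th percentile (default; linearly interpolated), maximum (exact for small
negative samples), or mean + 3 SD. Records strictly above the gate are
positive.

Two-channel ANI scatter is summarised by equal-probability contours: a
Gaussian KDE (Silverman bandwidth) on a 256×256 grid, with one level per mass
fraction f ∈ {s, 2s, …} (s = 0.05 or 0.10, hence 19 or 9 levels); the level
for f is the density whose super-level cells hold fraction f of total grid
mass, so grid granularity bounds the enclosed-mass error. Points in cells
below the outermost level are reported as outliers, matching
flow-cytometry-style contour plots. KDE was chosen over histogram contouring
because "equal probability" constrains the mass semantics, not the estimator.

Explant colonies are classed by their count of GFP⁺ foci: ≤ 2 (excluded as
indistinguishable from debris), 3–7, and > 7. Percentages are taken over all
scored colonies — excluded colonies stay in the denominator, which reproduces
per-class percentages of analysed colonies; a different convention can be
applied downstream since raw counts are kept. Class proportions are compared
with the likelihood-ratio goodness-of-fit test G = 2 Σ O_i ln(O_i/E_i)
(0 ln 0 = 0), referred to χ² with k − 1 degrees of freedom; expected values
given as proportions are rescaled to the observed total, making G invariant
to their scaling.

## Threshold scan

For a candidate SOX2 ANI threshold τ, each embryo region contributes the
percentage of its imaged cells strictly above τ; this vector is correlated
across regions with the observed percentage of GFP⁺ colonies, and the curve
of signed squared Pearson coefficients r·|r| over τ peaks at the SOX2 level
that best predicts colony reactivation. The signed square keeps the
direction of the association visible (a "+0.835"-style quantity); plain r²
is a flag away. Ties at the threshold are broken strictly (`>`): ANIs are
effectively continuous and the choice is immaterial.

The default threshold grid is the pooled unique ANI values (argmax exact on
the data); recovery analyses use a uniform 25-point grid over the pooled
range — about 2.5 grid points per region when ten regions are assayed, which
matches the resolution the region design can support. The null is built by
recomputing the curve after uniformly permuting the colony percentages over
regions (unrestricted permutations, not derangements; 21 iterations by
default) and summarising per-threshold mean and SD (ddof = 1). The observed
peak is judged against the null mean ± 3 SD at the peak's τ. Because the
peak is a maximum over correlated thresholds, its excursion above the
pointwise null is slightly anti-conservative; with 21 iterations the planted
relationship still clears + 3 SD by a wide margin while threshold-independent
data stays within ± 3 SD in roughly 93% of runs.

## Gene screen

Cells from the same mouse are correlated, so pooling them inflates
correlations; ranks are therefore formed within mouse-of-origin blocks.
Per-block Spearman coefficients ρ_b (average ranks for ties) are combined as
Σ (n_b − 1) ρ_b / Σ (n_b − 1); blocks with fewer than 4 observations, or in
which either variable is constant, carry no usable rank information and are
dropped. Two-sided p-values come from within-block permutations (default
1000), which keeps the inference assumption-light and exactly testable; in
the vectorised screen the anchor is permuted within blocks and the same
permutations serve every gene, valid per gene under the null and computable
as one matrix product per stage × anchor.

Benjamini–Hochberg correction (`q_(i) = min_{j≥i} m·p_(j)/j`, capped at 1)
is applied across genes within each (stage, anchor) stratum — per-stage
correction is the faithful reading of a screen run "at each embryonic
stage" — with a global-correction flag. A gene is called Nanog-correlated
when, in at least `min_stages` (default 2) stages, it is significant
(q < 0.05) with ρ > 0 against *Nanog* **and** significant with ρ < 0 against
*Sox2* in the same stage; Sox2-correlated genes satisfy the mirrored rule.
Requiring the two anchor conditions to coincide per stage is the stricter of
the two readings of "at ≥ 2 timepoints"; `same_stage=False` relaxes it. The
two result sets are disjoint by construction (a gene qualifying for both —
possible only with opposite-signed significance in different stages — is
called for neither, with a warning).

## Information decomposition

Continuous expression is discretised per variable with Bayesian blocks: cell
edges are the mid-points between consecutive distinct values (plus the data
extremes), and dynamic programming maximises
Σ_k N_k (ln N_k − ln T_k) − ncp_prior · #blocks over all contiguous
segmentations (N_k points, T_k width). The penalty defaults to the standard
false-alarm calibration `4 − ln(73.53 · p0 · n^(−0.478))` with p0 = 0.05.
The DP is O(n²) in distinct values and matches exhaustive search over all
2^(n−1) segmentations on every tested instance. Constant input yields a
single ε-width block. Note that for well-separated clusters the optimum
brackets the empty gap with its own sparse block (two interior edges), which
is the correct maximum of this fitness. Discretisation uses half-open bins
[e_i, e_{i+1}) with the last bin closed; out-of-span values clamp to the end
bins with a warning.

Mutual information is the plug-in estimator in bits, no bias correction
(matching simple estimators; a shuffle-baseline is available but off by
default — plug-in bias is visible in the shuffled-target checks as a small
positive floor). The two-source decomposition follows Williams–Beer:
specific information I(Z=z; A) = Σ_a p(a|z) log₂(p(z|a)/p(z)), redundancy
R = Σ_z p(z) min(I(Z=z;X), I(Z=z;Y)), unique terms U_X = I(X;Z) − R and
U_Y = I(Y;Z) − R, and synergy closes the budget S = I(X,Y;Z) − R − U_X − U_Y,
so additivity holds to machine precision by construction and all components
are non-negative with R ≤ min(I(X;Z), I(Y;Z)). Batch mode decomposes each
panel gene against a fixed co-source and target ("does this gene add unique
or synergistic information about *Sox2* beyond, say, *Tbxt*?"); a
joint-source flag concatenates the panel's codes into one source instead.

## Synthetic data: what it emulates

The generators define the study conditions; their defaults are fixed and are
not tuned per analysis.

**Embryo stacks** — 64³ voxels at 1 µm isotropic spacing, 50 non-overlapping
solid ellipsoidal nuclei (base radius 3–5 µm, axis ratios in [1, 1.5];
simple shapes keep volume and eccentricity analytic). Along the
anterior–posterior axis, per-nucleus SOX2 follows S_max·σ(−(a−x0)/w) and
NANOG the mirrored logistic (x0 = 0.5, w = 0.1, maxima 1000), reproducing
the anticorrelated gradient; DAPI is constant at 1000. Recorded voxels are
attenuated by exp(−k·depth) per channel and then receive additive Gaussian
noise, clipped at zero (noise_sd 100 ≈ SNR 10 for the criteria runs).
Placement uses bounded rejection sampling and reports the achieved count on
failure. Not modelled: PSF blur, spectral bleed-through, Poisson photon
statistics, chromatin texture — so segmentation results here bound the
easy-case behaviour of the classical baseline, not its performance on real
stacks.

**Explant assays** — ten regions whose mean SOX2 ANI is graded linearly from
20 to 80 (SD 10, truncated at zero), 200 imaged cells per region. A planted
threshold τ* = 46.6 drives colony outcome through an identity link: a colony
of 15 cells drawn from its region's distribution has foci count
Binomial(15, fraction of its cells above τ*). Identity is the minimal link
consistent with a threshold relationship and is recoverable. Fifteen cells
per colony makes the "> 7 foci" high class transition at rate one-half, i.e.
symmetric about τ*, so the scan's argmax is unbiased; 40 colonies per region
is a typical explant yield. A `flat_rate` option severs the τ* dependence
for null calibration.

**Expression matrices** — five stages E6.5–E7.5, two mice per stage, 200
cells per mouse. Each cell's latent AP score enters through a Gaussian
copula; *Nanog* couples to it with Spearman 0.9 (increasing) and *Sox2*
−0.9, and planted genes load on the latent so that their population Spearman
against the matching anchor is `effect_rho` (default 0.5; the bivariate-
normal conversion r = 2 sin(πρ/6) calibrates the loadings, verified
empirically to ± 0.1 over seeds). Null genes are independent. Per-(mouse,
gene) intercepts (SD 0.5) distort pooled correlations but not within-mouse
ones — exactly the confound the blocking removes. Values are continuous
log-scale intensities, not counts: the screen is rank-based, so the marginal
family is immaterial, but count-specific phenomena (dropout, depth) are out
of scope.

## Problem sizes and determinism

The standard verification runs use: one 64³ stack (50 nuclei) for the
round-trip, de-biasing and segmentation checks; 25 generator seeds for
threshold recovery and 25 for null calibration (21-iteration nulls); 10
seeds × 522 genes × 5 stages for the screen (1000 permutations, vectorised);
1000 random joints for PID additivity; and 100 draws at n ≤ 12 against the
exhaustive Bayesian-blocks oracle. Every generator and every stochastic
routine takes an explicit seed and is bit-reproducible given it.

## Known limitations

- The classical segmenter under-performs trained models on crowded or
  textured nuclei; it is a baseline and a plug-in point, not a replacement.
- Plug-in MI is positively biased at small n; comparisons between PID rows
  at equal n are safe, absolute values near zero are not.
- The peak-vs-pointwise-null comparison in the threshold scan is mildly
  anti-conservative (see above); treat ± 3 SD as a screen, not a calibrated
  test.
- Williams–Beer redundancy is the only PID measure implemented; other
  lattices (pointwise, minimal-synergy) can disagree on the same joint.
- The explant generator's identity link is one of many monotone links
  consistent with a threshold mechanism; only threshold location, not link
  shape, is treated as recoverable truth.
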