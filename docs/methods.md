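# Methods

## The measurement model

NAD(P)H autofluorescence in a pixel is treated as a two-species mixture:
free coenzyme with a fixed lifetime τ_free = 0.45 ns and enzyme-bound
coenzyme with a variable lifetime τ_bound (2.5–4 ns depending on the
enzyme). Under pulsed excitation with period T (default 12.5 ns, i.e.
an 80 MHz two-photon source; the repetition rate is configurable and
every geometric quantity is parameterized by ω = 2π·harmonic/T), the
periodic decay of a mono-exponential species has the exact
first-harmonic phasor

    g = 1 / (1 + (ωτ)²),   s = ωτ g,

which lies on the universal semicircle. The transform is linear in
intensity, so a free/bound mixture lies on the chord between the two
pure phasors, at a position equal to the bound intensity fraction
α_bound. The decomposition inverts this geometry per pixel with the
free anchor fixed; no curve fitting is involved, which is what makes
the method usable at ~20–30 photons/pixel.

**Discretization.** The transform uses bin-center timestamps on
histograms of N bins per period. Because photon counts are bin
integrals, the discrete coefficients equal the continuous ones times a
common factor ≈ sinc(ωΔt/2); the factor cancels in τ = s/(ωg), leaving
a relative lifetime bias below 1e-4 at N = 256. Tests bound the
semicircle deviation at 3e-5 and the end-to-end noise-free recovery
error at 1e-3.

**Quality control.** Shot noise scatters pixel phasors outside the
physical chord. Pixels beyond the semicircle or past the bound anchor
are clamped to α_bound ∈ [0, 1] and flagged `clamped`; pixels whose
chord has no physical second intersection (s ≤ 0 side), or with zero
photons, are flagged `invalid` and excluded from per-cell statistics.
Clamping rather than discarding keeps per-cell means unbiased under
symmetric noise; QC fractions are reported per image.

**ORR.** Both channels are acquired at one excitation wavelength, so
the FAD channel contains a constant fraction α of NAD(P)H signal and
the observed ratio is the true ratio plus α. The per-cell ORR is the
mitochondrial FAD/NAD(P)H sum ratio minus the cytoplasmic/nuclear one,
which cancels α exactly (verified to 1e-12 in tests). No FAD lifetime
decomposition is performed; FAD contributes intensity only.

## Segmentation

Cells are masked by NAD(P)H photon count strictly above a threshold
(default 2 photons; low-power live imaging leaves a nearly photon-free
background), with holes filled. Touching cells are split by watershed
on the negated distance transform. Markers are the distance-transform
local maxima restricted to the eroded mask (3×3 cross, one iteration,
configurable): erosion alone cannot disconnect two substantially
overlapping cell bodies, while each body retains its own distance peak,
so peak-seeded markers separate exactly the configurations a
morphologist would call two cells. Peaks closer than a plausible cell
radius (default 10 px) are merged to avoid oversplitting ragged masks.
Components outside a size window (defaults derived from a 6–20 µm cell
diameter at the configured pixel size) are removed as debris or clumps.

Within each cell, background-subtracted FAD intensity (background =
mean FAD outside the global cell mask) is Otsu-thresholded; bright
pixels are mitochondria, the remainder is the pooled
cytoplasmic/nuclear compartment (no nuclear segmentation). Cells with
constant FAD or a one-sided split are flagged and excluded from
compartment features only.

## Feature library

The registry enumerates 210 features: three per-pixel channels
(NAD(P)H intensity, α_bound, τ_bound) × two regions × 20 statistics,
ORR statistics in mitochondria plus the corrected per-cell ORR,
compartmentalization `(m − c)/(m + c)` of all 20 statistics for the
three channels, and nine morphology features. Statistics per region:

* strength — mean, median, 10th/90th percentiles (linear-interpolation
  percentile convention);
* distribution — SD, variance, skewness and excess kurtosis (Fisher;
  undefined below 3 pixels), entropy (bits) and uniformity on a 16-bin
  min–max histogram, IQR;
* texture — GLCM (contrast, difference variance, difference entropy,
  inverse difference moment, energy, correlation) and GLRLM (gray-level
  variance, run-length variance, short-run emphasis), computed on the
  region quantized to 16 gray levels by min–max scaling, distance 1,
  four directions aggregated and symmetrized. Regions under 9 pixels or
  quantizing to one gray level are flagged degenerate (undefined rather
  than zero — a constant region has no texture support).

Morphology: area (µm²), major/minor axis lengths, circularity 4πA/P²
(≈0.9 for a rasterized disk due to digital perimeter overestimation),
eccentricity, solidity, mito and cyto areas, and mito dispersity —
connected mitochondrial components per unit mitochondrial area, a
fragmentation measure; "dispersity" has no canonical definition, so the
registry entry is swappable.

Missingness is explicit: uncomputable features are NaN and listed per
cell, and downstream stages refuse rows with silent NaNs.

## Feature selection

Two gates, each required in **both** of two independent differentiation
datasets: (i) single-feature logistic regression trained on a
stratified 60% split, F1 on the held-out 40% strictly above 0.6 with
the stem class positive (sklearn defaults, moderate L2; a constant
feature falls back to the majority rule and is flagged); (ii) trending
index of population-level stage means strictly above 0.5 in magnitude.
By default the TI sign must also agree across datasets — a feature
rising in one model and falling in the other does not report the same
biology; the literal threshold-only rule is available by switching
`require_ti_sign_match` off. Surviving features are grouped into
knowledge-graph leaves (channel × region × statistic family, plus
morphology and compartmentalization stems); a leaf is retained when at
least half its members passed, and emits its canonical member
(average > median > variance priority). Subset quality is benchmarked
by an RBF-SVM ROC on a stratified 70/30 split, AUC by the trapezoid
rule.

## MOB score

Representative features are normalized by a robust scaler fitted on a
training reference — the stem population in differentiation studies,
all cells in paired-daughter studies — mapping the training median to 0
and the quartiles to ±1 (x → (x − median)/((q3 − q1)/2)). The half-IQR
convention is used because it pins both quartiles to ±1 exactly; the
common full-IQR convention (quartiles → ±0.5) is switchable. Outliers
are removed by DBSCAN on robustly standardized features; when eps is
not supplied it is taken from the sorted k-distance curve
(k = min_samples = 5): genuine outliers sit beyond a large gap in that
curve, so eps is the largest-gap midpoint when the gap exceeds 3× the
median k-distance and just above the maximum otherwise (no-outlier
regime — nothing is removed from a clean cluster). Conditions are
shuffled and trimmed to equal n without replacement.

The score is the first latent variable of a 3-dimensional
maximum-likelihood linear factor model (EM), requiring at least 5 cells
per feature. The EM noise variances start at the standard unit values:
a zero start is an absorbing fixed point of the M-step (features pinned
at zero residual variance dominate the latent posterior and the fit
stalls in a degenerate optimum), so zero initialization is accepted via
a parameter but not the default. LV1's sign is arbitrary; it is
anchored so that a named feature known to be elevated in stem cells
(mitochondrial τ_bound average by default) carries positive weight,
which orients unlabeled datasets reproducibly. Feature weights are
Pearson correlations between LV1 and the scaled features.

The stem/differentiated threshold is the equal-posterior point between
the means of a two-component Gaussian mixture fit to the scores (closed
form via the log-density quadratic; midpoint for equal weights and
variances). A threshold is only reported when the mixture density has a
genuine antimode — its value at the threshold must dip below the value
at both component means. A two-component fit to unimodal data yields
well-separated means with the mixture mode between them, so a
means-distance test alone cannot detect collapse; the antimode test
can, and it flags exactly the unimodal cases in simulation.

## Division analysis

Parents are imaged on micropattern sites before division; post-division
cells are assigned to the nearest site within a radius. Sites with two
cells become paired-daughter records; crowded sites (a second division)
are excluded and counted. ΔMOB is the absolute sibling score
difference — the sign has no meaning between unordered siblings. The
symmetric/asymmetric threshold is the same mixture machinery as above,
EM-initialized at the 25th/75th ΔMOB percentiles; classification
requires a threshold fitted on the same dataset or supplied explicitly.
Inheritance is the Pearson correlation between parent and daughter
scores with a zero-slope p value; each daughter contributes one point,
and confidence intervals use the effective sample size
2N/(1 + ρ_sib) because siblings share a pair midpoint. Post-division
dynamics are summarized per pattern as mean trajectories and
above-threshold fractions, compared by Mann–Whitney per timepoint;
condition screens report per-condition ΔMOB summaries, asymmetric
fractions and one-way ANOVA across conditions.

## Synthetic data: what it emulates, and what it does not

The scene generator emulates the photon physics that limits real
acquisitions: exact bin-integral expectations of periodic
two-exponential decays, Poisson sampling at configurable rates (default
~25 photons/pixel in cells, ~0.2 background), disk-shaped cells, and
punctate mitochondria whose FAD rate is elevated by a contrast factor
(default 5×) — the handle the Otsu split relies on. The instrument
response is ideal (real phasor systems correct for theirs internally),
optics are ignored (no PSF, no spectral bleed beyond the additive ORR
model, no photobleaching), cells are geometrically simple, and lifetime
truth is constant within a cell. Passing tests therefore demonstrate
correctness of the computational chain under controlled truth — not
robustness to optical artifacts, motion, or biological heterogeneity
within cells.

Population tables draw per-cell features from Gaussians around stage
means (monotone for informative features); division tables enforce the
requested parent–daughter correlation through a variance budget: the
signed sibling half-gap contributes E[δ²]/4 to daughter variance, so
the pair-midpoint residual is shrunk accordingly, and specs with
r² + E[δ²]/4 > 1 are rejected as infeasible.

## Benchmark conditions (`mobflim.benchmarks`)

* Calibration inversion: ideal 2.5 ns decay, 1024 bins, 12.5 ns period.
* Lifetime recovery: nine r = 14 px cells (α = 0.5, τ_bound = 3.4 ns) in
  a 192×192 scene. Noise-free condition (expected histograms, empty
  background): every per-cell mean within 1e-3 relative. At 25
  photons/pixel the per-cell means are averaged over the nine cells
  before comparison: a single ~600-pixel cell mean carries 5–10%
  Poisson estimator noise at that budget, larger than the method's
  bias, and the scene average isolates the latter.
* Selection power: 10 informative features stepping 1.5 noise-SD per
  stage (alternating direction) + 10 pure-noise features, 4 stages,
  200 cells/stage, two datasets.
* Latent recovery: one-factor data, 11 features, n = 500, loadings
  U(0.5, 1.5), noise SD 0.3.
* Division recovery: 500 divisions, gap modes 0.3/2.0 (SD 0.2), 30%
  asymmetric, inheritance 0.8.
* Binning robustness: two 320×320 scenes of 16 cells whose radius,
  α_bound, τ_bound and NAD(P)H rate all follow one latent level;
  native vs 2×2-binned processing, five representative features, the
  model fitted on native cells, binned cells normalized against their
  own population (independent acquisitions are scaled independently)
  and scored with the same loadings; cells matched by centroid.

## Known limitations

Higher harmonics are not computed; FAD lifetimes are not decomposed;
vendor file formats are not read (convert to TIFF stacks first); no 3D
segmentation or through-mitosis tracking; the texture parameter choices
(16 levels, distance 1) follow common radiomics defaults and are fixed
in the registry manifest rather than exposed per-call.
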