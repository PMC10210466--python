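# Methods

## Imaging arm

### Segmentation model

Cell segmentation operates on the *composite* image — the element-wise
sum of the fluorescence channels — so that the foreground decision does
not depend on any single channel's brightness. Nuclear counter-stains
(Hoechst, PI) are excluded from the composite by default because the
composite is meant to capture cytoplasmic sensor signal; fields that
contain only counter-stains fall back to summing what is present.

The chain is: median filter (window 7×7) → Gaussian smoothing (σ = 1 px)
→ intensity threshold → morphological closing (disc, radius 3 px) →
removal of connected components smaller than 5000 px → 8-connected
labelling. The median window, Gaussian σ and area cutoff are the
pipeline's standard operating values; all are parameters of
`CellSegmenter`. Two choices were genuinely open:

* **Threshold.** The original workflow used a manually selected
  threshold, whose numeric value is not knowable from a manual
  protocol. The default here is Otsu's method on the preprocessed
  composite — a reproducible automatic stand-in — with a fixed value
  accepted wherever fidelity to a particular manual choice matters.
* **Closing element and connectivity.** A disc of radius 3 px and
  8-connectivity. The disc is small enough not to bridge neighbouring
  cells at realistic spacings; connectivity is stated once and tested.

An all-background segmentation is legal and is flagged with an
`EmptyMaskWarning`; empty-mask summaries are reported as missing (NaN),
never as zero, so empty fields cannot bias condition means toward zero.

Intensity summaries are computed per field of view (the acquisition
unit); a per-component mode reuses the same extraction core for
dot-per-cell style analyses. The colocalization score is the mean over
the mask of the per-pixel TagRFP×eGFP product (intensity² units). It is
symmetric in its two channels, homogeneous of degree one in each, and
exactly zero when either channel is null — the acid-quenched-GFP limit.

### Viability detection

Nuclei are detected on the Hoechst channel by a Laplacian-of-Gaussian
response at σ = 6 px. The LoG is built from separable sampled Gaussian
kernels in which the second-derivative kernel is corrected to exact
zero sum, so a constant intensity offset produces an exactly zero
response and the detection count is invariant under global offsets.
Local maxima above a threshold are accepted greedily in decreasing
response order subject to a minimum pairwise Euclidean distance
(10 px); ties are broken by row-major scan order, making detection
fully deterministic. The default response threshold is 10% of the
field's maximum response — scale-free, hence robust to exposure
changes — and overridable.

PI positivity is judged by the mean PI intensity in a disc of radius σ
around each detection rather than at the single detected pixel; the
disc average buys noise robustness at negligible cost in specificity
for nucleus-sized objects. Viability is 100 × live/total per field and
is undefined (missing) when nothing was detected.

### Condition comparisons

Group comparisons of per-field (or per-cell) readouts use Welch's
two-sample t-test, two-sided, as implemented in scipy; the statistic,
Welch–Satterthwaite df and p-value are returned.

## Proteomics arm

### Processing order and parameters

The chain is: log2 normalization → proteotypic filter → outlier-replicate
removal → imputation → moderated testing. Outliers are removed *before*
imputation so that imputed values can never rescue a failing replicate.
Key parameters, with defaults and rationale:

* `min_peptides = 2` — the conventional proteotypic-evidence floor for a
  confident identification ("enough proteotypic peptides" is otherwise
  undefined).
* `min_correlation = 0.8` — a replicate is excluded when its median
  Pearson correlation (pairwise-complete proteins) with its
  same-condition peers falls below this; the rule is deterministic and
  auditable, and a hard floor always retains the best two replicates of
  a condition. A manual exclusion list is also accepted.
* Imputation: missing label-free intensities are predominantly censored
  at the detection limit, so each missing entry is drawn from
  Normal(m, sd²) with m the global minimum of the present log2 values
  and sd = 0.3 log2 units by default; the draw is seeded and present
  values are never altered.

### Moderated test

Per-protein variances are pooled across all conditions (residual df
d_g = Σ(n_c − 1), NaN-aware). The prior (d₀, s₀²) is estimated by
matching the first two moments of log s²_g to the log
scaled-inverse-χ² distribution: with
e_g = log s²_g − ψ(d_g/2) + log(d_g/2), the model gives
E[e] = log s₀² + ψ(d₀/2) − log(d₀/2) and
Var[e] = ψ′(d_g/2) + ψ′(d₀/2); the trigamma equation is inverted by
Newton iteration. When the observed dispersion is at or below the
theoretical floor, d₀ is reported as infinite and s₀² as the plain mean
of the sample variances. The implementation agrees with the reference R
implementation of the empirical-Bayes moderated t-test to ~10⁻⁶
relative error on fixed data (checked in the test suite), and matches
its two closed-form limits — classical pooled t at d₀ = 0, fixed-variance
z at d₀ = ∞ — to 10⁻¹⁰.

Fold changes are treatment minus control throughout, so "enriched after
treatment" means positive log2FC. Comparisons are treatment-vs-control
only; no all-pairs mode exists. Volcano classification defaults to
adjusted p < 0.05 and |log2FC| > 1, both configurable and recorded with
the output. BH adjustment is the step-up rule
adj₍ᵢ₎ = min₍j≥i₎ p₍ⱼ₎·m/j capped at 1, with an explicit floor at the
raw p to guard the adjusted ≥ raw invariant against last-ulp rounding.

### ORA and overlap reporting

Term enrichment uses the upper-tail hypergeometric probability
P(X ≥ k) with term members intersected with the user-supplied universe,
BH-adjusted across terms. Reference-list overlap deduplicates and
case-normalizes identifiers and reports 100 × |query ∩ reference| /
|query| rounded half-up to one decimal. Half-up is stated explicitly
because common binary-float rounding ("banker's") differs on exact
halves; at the published list sizes 2028/2538 gives 79.9% and 2349/2538
gives 92.6% (92.553…, which a different rounding convention would print
as 92.5%).

## Synthetic data

### Fields

Cells are rendered as discs with a 2-px cosine-tapered edge: smooth
enough to exercise thresholding realistically while keeping the
ground-truth mask (the flat-top hard disc) analytic, so within-mask
intensities equal the recorded per-cell means exactly in the noiseless
limit. Noise is additive Gaussian clipped at zero — the simplest model
that exercises the median/Gaussian preprocessing. Debris discs are
capped at radius 35 px so their area stays below the 5000-px component
cutoff; they carry cytoplasmic-channel signal only and are placed clear
of cells, so they cross the intensity threshold and must be removed by
the area rule alone. Placement is rejection sampling under the spacing
constraints with bounded retries (a `PlacementError` otherwise). All
randomness flows from one seeded generator per call; a fixed seed is
bit-reproducible.

Default flux fields are 640×640 px with five cells of radius 42–52 px
(hard-disc area comfortably above the cutoff), base intensity 100,
background 10, noise sd 20 — per-channel SNR 5. Default viability
fields are 512×512 px with fifty nuclei of radius 7–10 px spaced at
least 25 px (2.5× the detector's minimum distance), Hoechst base 100,
PI base 120 on the dead subset against a PI threshold of 50, and 10%
dead. Exactly round(dead_fraction × n_cells) cells are dead.

What the generator does *not* emulate: optics (PSF, channel
bleed-through), 3-D stacks, time-lapse, touching or overlapping cells,
intensity gradients across the field. Passing recovery tests therefore
demonstrates the correctness of the operators under their stated
assumptions, not robustness to every real-microscope artefact.

### Matrices

Per-protein variances are drawn from scaled-inv-χ²(d₀ = 4,
s₀² = 0.0625) — noise sd around 0.25 log2 units, typical of replicate
label-free data — baselines from N(25, 2²) on the log2 scale (the
MaxLFQ intensity range), three replicates per condition, 10%
differential proteins at ±1 log2 unit. Missingness is Bernoulli with
probability logistic(−1.5·(value − 20)), concentrating at low
abundance so minimum-anchored imputation is the appropriate
counterpart; the overall missing rate at the defaults is ~2%.
Proteotypic-peptide counts are 1 + Poisson(2.5), leaving a small
fraction below the evidence floor for the filter to remove. The
generator writes raw-scale intensities (2^log2) so the pipeline's own
normalization is always exercised.

## Problem sizes and numerical checks

The automated checks run the imaging recoveries on ten fields per
setting and the statistical calibrations on 2000-protein matrices
(twenty null seeds for type-I calibration; ten seeds for FDR and effect
recovery), sizes at which the binomial noise on the reported fractions
is well inside the stated bands. Null p-value calibration is assessed
on complete matrices (missingness disabled) to isolate the statistic's
calibration from imputation variance; the FDR and effect-recovery
checks run the full chain including missingness and imputation.
Tolerances used in tests: exact identities at 10⁻¹⁰–10⁻¹² relative
error; Monte-Carlo quantities at 2–3 standard errors of the simulated
estimate.

## Known limitations

* Touching cells are segmented as one component (no instance
  segmentation or watershed splitting); per-cell mode then reports
  merged objects.
* The outlier-replicate rule assumes at least two honest replicates per
  condition; with two replicates a disagreement cannot be attributed.
* Imputation treats all missingness as left-censored; values missing at
  random at high abundance are pulled toward the dataset minimum.
* The prior fit assumes a common residual-df structure is meaningful;
  with very few proteins (< 10 usable variances) it refuses to
  estimate.
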