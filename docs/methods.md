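# Methods

## The question and the three indices

Hemispheric asymmetry in cortical morphometry is usually quantified pairwise:
a homologous pair of regions is compared, region by region. But if male/female
differences in asymmetry are *global* — involving the proportional structure
among many regions across hemispheres rather than the size of any single pair —
pairwise statistics will understate them. This package implements and compares
three per-region asymmetry indices over bilateral tables of 34 cortical ROIs
(FreeSurfer `aparc` parcels) for four gray-matter measures (volume mm³, surface
area mm², thickness mm, mean curvature mm⁻¹).

For atlas-ordered left/right values `a_L`, `a_R` (34-vectors per subject):

**Distance index (DI).** For ROI *i*, build the vector of absolute differences
between that ROI and every other ipsilateral ROI, once per hemisphere:

    V_L = [ |a_{i,L} − a_{j,L}| : j ≠ i ]     (33 entries)
    V_R = [ |a_{i,R} − a_{j,R}| : j ≠ i ]

and let *r* be their Pearson correlation. Then `DI_i = 1 − |r|`. DI is 0 when
the hemispheres are proportional (the inter-ROI difference structure is
preserved, whatever the overall left/right size ratio) and grows as that
structure decorrelates. It is invariant to a common rescaling of both
hemispheres and blind to a uniform proportional offset between them.

**Laterality index (LI).** `LI_i = |(a_{i,L} − a_{i,R}) / (a_{i,L} + a_{i,R})|`
— the classic weighted pairwise asymmetry, as a magnitude.

**Subtraction index (SI).** `SI_i = |a_{i,L} − a_{i,R}|`, in measure units.

All three are magnitudes; which hemisphere is larger is deliberately not
encoded. Downstream, the indices feed (i) random-forest sex classification,
(ii) an image-quality robustness analysis, and (iii) group contrasts and
point-biserial sex correlations.

### Numerical choices for the indices

- The difference vector for ROI *i* uses all 33 partners `j ≠ i`. A
  triangular variant (`j > i`, giving shorter vectors for later ROIs) is
  available behind `distance_index(..., mode="upper")`; entries whose vector
  has fewer than 3 elements are undefined there.
- `DI = 1 − |r|` with the absolute value taken *before* subtraction, keeping
  DI in [0, 1]; rounding can push `|r|` infinitesimally above 1, so DI is
  clamped into [0, 1].
- Pearson *r* is the sum-of-products over the root of the sums of squares of
  centered vectors; degrees-of-freedom conventions cancel in *r*.
- Undefined entries — zero variance in either difference vector (DI), a zero
  denominator (LI) — are NaN, counted in a QC report, and excluded pairwise
  downstream. They are never zero-filled.
- Mean curvature can be negative; raw values are used as-is, so LI may exceed
  1 with mixed signs. Such values are counted in QC, not clipped, because the
  same formula is applied to every measure.

## Synthetic cohort generator

No generative model of hemispheric asymmetry accompanies these indices, so
the generator operationalizes the two distinct ways hemispheres can differ,
with an independent knob for each. For subject *s* of sex *g* and ROI *i*
with template magnitude `m_i`:

    a_{i,L} = m_i · exp(u_s) + ε_i      u_s ~ N(0, subject_scale_sd²)
                                        ε_i ~ N(0, (roi_noise_cv · m_i)²)
    a_{i,R} = a_{i,L} · (1 + δ_{i,g}) + ζ_i
                                        ζ_i ~ N(0, (σ_g · m_i)²)

- `σ_g` (**coherence noise**, dimensionless CV) perturbs the inter-ROI
  difference structure across hemispheres and is the DI-driving knob; to
  second order, subject-mean DI scales with σ².
- `δ_{i,g}` (**pairwise shift**, fractional) moves LI (≈ δ/2 for small δ) and
  SI (≈ δ·m_i) but, being proportional, leaves DI untouched up to the
  noise-to-spread leakage discussed below.
- `exp(u_s)` models head-size variation; `ε` is ROI-level measurement noise.

Template magnitudes span the ranges FreeSurfer tables show (volumes
7×10²–2.4×10⁴ mm³, areas 2.5×10²–5×10³ mm², thickness 2–3 mm, curvature
0.1–0.2 mm⁻¹), with a fixed permutation so magnitude rank is not confounded
with atlas order. Positive-valued measures are floored at `10⁻³·m_i`; a
configuration producing >1% non-positive draws is rejected.

Defaults — the study condition used throughout the analysis scripts and the
acceptance runs — are 396 males / 430 females, ages uniform 19–26, all
right-handed, `subject_scale_sd = 0.08`, `roi_noise_cv = 0.02`,
`σ_male = 0.02, σ_female = 0.01` (males globally more asymmetric), `δ ≡ 0`.
`SimulationConfig.null()` is the matched no-effect configuration
(`σ = 0.015` both sexes). IQMs are Gaussian per sex with shifted means and,
for EFC, a female SD about a third of the male one (female EFC values are
characteristically homogeneous); IQMs are independent of morphometry, so
robustness verdicts under the default configuration reflect sampling noise
only, not genuine quality sensitivity.

What the generator does **not** emulate: empirical ROI mean/covariance
structure, cross-measure correlation within subject, spatially structured
(neighbor-correlated) asymmetry, non-Gaussian IQM tails, or any real
morphometry–quality coupling (an optional linkage would live in the IQM
block). Passing tests therefore demonstrate the statistical machinery and
the indices' contrast under controlled conditions — not claims about any
particular empirical dataset.

## Classification

Per (index, measure): predictors are the 34 per-ROI index values plus age
(35 columns); rows with any undefined value are dropped. A stratified 80/20
split is followed by a 500-tree random forest (bagging; scikit-learn). The
one tunable hyperparameter, the feature-subset size per split (`mtry`), can
be grid-searched with 10-fold cross-validation *on the training partition
only* — tuning on test data would leak; by default the `sqrt(p)` heuristic
is used. Evaluation reports the 2×2 confusion matrix (target on columns,
prediction on rows, male first), accuracy, Cohen's Kappa computed from the
matrix via `(p_o − p_e)/(1 − p_e)`, the no-information rate (majority-class
prevalence of the test set), and the one-sided exact binomial tail
`P(X ≥ correct | n, p = NIR)`. Kappa's conventional qualitative bands are
attached as labels only. Predictor ranking uses permutation importance on
the held-out partition (out-of-bag permutation is not natively available in
the implementation stack; held-out permutation is the standard unbiased
variant), with impurity importance retained for comparison; ties break
alphabetically for determinism.

## Robustness analysis

For each of five image-quality metrics — CJV, CNR, EFC, INU, WM2MAX — the
`n` lowest and `n` highest subjects *per sex* form the lower and upper
subsamples (`n = 80` by default, `n = 35` for EFC via a per-metric override;
ties break by subject id). Selecting extremes within sex matches the metric
levels across sexes by construction; achieved per-sex means are reported so
matching quality is auditable. Within each subsample, the male and female
per-ROI mean profiles of each (index, measure) are compared by a paired
t-test across the 34 ROI pairs. Tiers: `*` p < 0.001, `x` 0.001 ≤ p < 0.05,
`ns` otherwise (boundaries exact). Verdicts: *robust* if both levels are
significant, *quality-sensitive* if only one level is (the preferred level
is lower for CJV/EFC, upper for CNR/INU/WM2MAX), *not-robust* if neither.
Rows with > 20% undefined ROI means are flagged unreliable.

## Group statistics

The whole-cohort contrast is the same ROI-paired t-test applied to the full
male and female mean profiles, with a reported direction (sign of the mean
male−female difference). Sex correlations are per-ROI point-biserial
(Pearson against male = 0 / female = 1), averaged over defined ROIs; because
higher male asymmetry yields negative *r* under this coding, the absolute
grand mean is the headline and the signed value is retained. The hemisphere
contrast pairs the left and right hemispheres' raw-value sex-correlation
profiles across ROIs. Degenerate paired tests (zero-variance differences)
return t = 0, p = 1 when the profiles are identical and a signed infinite t
with p = 0 otherwise, flagged rather than overflowing. No multiple-testing
correction is applied in the headline tables (each tier stands alone), and
p-values are two-sided throughout since direction is reported separately.

## Calibration caveat: the ROI-paired t-test and DI

The ROI-paired t-test treats the 34 per-ROI group-mean differences as an
i.i.d. sample. That premise holds to a good approximation for SI, whose
per-ROI values are functions of disjoint inputs (measured null rejection
rate ≈ 3–5% at α = 0.05), is mildly violated for LI (shared subject scale
factor; ≈ 10%), and fails structurally for DI: all 34 DI values of a subject
are computed from the same 68 numbers, giving a mean cross-ROI correlation
of ≈ 0.6 and a null rejection rate near 50%. The DI inflation persists under
every generator variant (with or without subject scaling, with noise scaled
to subject size), so it is a property of the statistic, not of the
simulation. Consequences drawn here: the null-calibration check in the test
suite is asserted on SI, where the test's assumptions hold; DI group
differences should be read as descriptive (or tested at the subject level —
e.g. a Welch t-test on subject-mean DI, which is exactly calibrated since
subjects are independent — as the regime-separation test does). DI contrast
p-values in pipeline outputs are computed with the ROI-paired test for
fidelity to the analysis design, with this caveat.

A second, smaller interaction: because coherence noise is added *after* the
pairwise shift (`a_R = a_L(1+δ) + ζ`), a between-group δ difference changes
the noise-to-spread ratio by `((1+δ_F)/(1+δ_M))²` and hence leaks into DI at
second order. With realistic few-percent shifts the DI effect is ~20× smaller
(Cohen's d ≈ 0.1 vs ≈ 2–3 for LI/SI), which is what the regime-separation
test quantifies.

## Problem sizes and determinism

The analysis scripts and the acceptance script use the full default cohort
(826 subjects, four measures, twelve index tables, twelve forests). The test
suite uses smaller cohorts chosen for statistical adequacy: 200 replicate
null cohorts of 60/sex for calibration, 20 seeded cohorts of 400/sex for
effect recovery, 10 cohorts of 200/sex for regime separation. Every source
of randomness descends from a single integer seed (NumPy `default_rng`;
scikit-learn `random_state`), and the full pipeline's CSV outputs are
byte-identical across reruns with the same seed.

## Known limitations

- The generator's independence simplifications (above) mean robustness
  verdicts under the shipped configurations exercise the machinery, not
  realistic quality confounding.
- Atlas naming: the 34-parcel FreeSurfer `aparc` label set is treated as
  canonical; variant label spellings are normalized onto it and the atlas
  name is recorded in the run manifest.
- The ROI-paired t-test calibration caveat above applies to any correlated
  index, DI most of all.
- LI > 1 (mixed-sign curvature) is reported, flagged, and left to the
  analyst; no sign-aware curvature variant is provided.
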