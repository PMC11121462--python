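# Methods

## Scope and data model

One record is a honey sample: an opaque id, a declared botanical type
(acacia, honeydew, linden, monofloral, polyfloral, sunflower), one of six
Serbian regions, a harvest year (2018–2023), and nine measurements —
glucose, fructose, sucrose [g/100 g], 5-HMF [mg/kg], moisture [%], free
acidity [meq/kg], diastase activity [Schade/DN], insoluble matter [%], and
electrical conductivity [mS/cm]. Sucrose and 5-HMF determinations below
the limit of quantification are reported as "<0.50"; they are stored at
the LOQ (0.50) with a censoring flag, and descriptive statistics use the
stored value as-is. This substitution convention is an assumption: survey
tables that print a sucrose mean of 0.46 ± 0.61 alongside "<0.50" cells
show that sub-LOQ raw values entered the original computations, but the
raw values themselves are unrecoverable, so the LOQ-substituted value is
the only reproducible choice.

Sugar limits are standardised on g/100 g (≡ % m/m). Regulatory texts
occasionally print these limits with a mg/kg unit; that reading is treated
as a typographical slip, since the same sources report all sugar data in
g/100 g.

## Threshold policy

All limits live in one `ThresholdPolicy` object (defaults in parentheses,
overridable from a flat YAML file):

| limit | default | unit | applies to |
|---|---|---|---|
| econd_flower_max | 0.8 | mS/cm | honeydew reclassification cut |
| econd_low_flag | 0.1 | mS/cm | suspiciously low conductivity |
| sugar_sum_min_blossom | 60 | g/100 g | glucose+fructose floor, flower honey |
| sugar_sum_min_honeydew | 45 | g/100 g | floor for honeydew (and blends) |
| sucrose_max_default | 5 | g/100 g | all types except exceptions |
| sucrose_max_exception | 10 | g/100 g | acacia (configurable set) |
| hmf_max | 40 | mg/kg | 5-HMF ceiling |
| acidity_max | 50 | meq/kg | free acidity ceiling |
| diastase_min | 8 | DN | diastase floor |
| moisture_max | 20 | % | moisture ceiling |
| insoluble_max | 0.1 (0.5 pressed) | % | insoluble matter ceiling |
| blend_econd_min | 0.70 | mS/cm | lower edge of the blend band |

Every comparison is a strict inequality — a value exactly at a limit is
compliant — mirroring the "higher than / lower than" phrasing of the
regulatory texts. A conductivity exactly at 0.8 mS/cm leaves the declared
type unchanged for the same reason.

Grading: sucrose, 5-HMF, acidity, and diastase deviations are
adulteration-grade (they are the four parameters that adulteration
predominantly disturbs); low sugar sum, high moisture, low conductivity,
and high insoluble matter are suspect-grade. Adulteration-grade codes
dominate: a sample carrying both kinds is counted once, in the
adulterated tier, which makes the two tiers disjoint. The blend flag
(low-sum flower honey with sum ≥ 45 and conductivity in [0.70, 0.8)) is
informational only and never changes a grade; 0.70 was chosen because
documented blend examples cluster at 0.71–0.76 mS/cm.

## Statistics

* Sample SD uses the n−1 denominator; this is forced by the
  confidence-interval audit: the closed form x̄ ± t(0.975, n−1)·s/√n
  reproduces all 161 printed CI pairs of the reference descriptive tables
  to two decimals (within ±0.01, the slack attributable to the tables'
  own rounding of x̄ and s).
* Quantiles use linear interpolation between order statistics ("type 7",
  the numpy/spreadsheet default); the source tables do not state a rule.
* One-way ANOVA is the classical between/within decomposition with
  df = (k−1, N−k); an all-constant input returns F = 0, p = 1, flagged
  degenerate.
* Tukey pairwise p-values come from the studentized-range distribution
  with the Tukey–Kramer standard error for unequal n. The compact letter
  display uses the insert-and-absorb algorithm (split every letter column
  containing both members of a significant pair, absorb subset columns),
  processed in a deterministic order. Letters are derived from pairwise
  tests only, so they can in principle disagree with the omnibus F.
* Kruskal–Wallis uses average ranks with the standard tie correction and
  a chi-square reference with k−1 df; an exhaustive brute-force oracle
  validates it on all two-group splits up to N = 8.
* The correlation matrix reports raw (unadjusted) two-sided p-values with
  stars at 0.05/0.01/0.001, matching the reporting convention of survey
  correlation tables; no multiplicity correction is applied by design.

## Synthetic data

### Realistic generator

Each type×parameter cell is a truncated normal with the published per-type
mean, SD, minimum, and maximum (54 embedded constants); sampling is
inverse-CDF on the truncated interval, so a fixed seed reproduces the
table bit-identically and `sd = 0` degenerates to a constant. Censored
cells are generated from a floor of 0 and re-censored at the LOQ on
output; the all-censored monofloral sucrose cell is a synthetic stand-in
confined to [0, 0.49].

Dependence is a Gaussian copula. The embedded 9×9 target is the published
pooled Pearson matrix of the survey (609 samples); its strong entry is
acidity–conductivity, r = 0.570, consistent with honeydew honey being high
in both organic acids and minerals. Because the generator pools six types
with different means, a pooled Pearson target has a between-type-means
component that a naive copula would miss; the latent correlation is
therefore calibrated per pair by first-order moment matching: with
per-type truncated means m_t, SDs s_t, latent linearity c_t = corr(X, Z)
(computed by Gauss–Hermite quadrature), and type weights w_t, the pooled
covariance is `between + ρ·Σ w_t c_tj c_tk s_tj s_tk` and ρ is solved per
pair, clipped to ±0.985, and the matrix repaired to the nearest positive
definite correlation. At n = 5000 the empirical pooled acid–EC correlation
lands within ±0.02–0.05 of 0.570.

Honeydew conductivity is generated on [0.82, 1.80] and every other type at
most 0.79, so generated tables are stable under reclassification.

What the generator does **not** emulate: per-type (within-class)
correlation structure beyond what the single pooled-calibrated latent
matrix implies, quartile shapes (only mean/SD/min/max are matched), any
year×region×type interaction (labels are drawn independently from the
survey margins), and measurement error structure. Tests that pass on this
generator therefore validate the pipeline's arithmetic and the stated
marginal/pooled-dependence conditions — not performance on real honey.

### Fixture

`build_fixture(seed)` constructs 609 records with a known deviation
inventory: 111 special records (9 conductivity in-moves, 16 out-moves, 5
sucrose violators of which 4 also miss the sugar floor, 12 5-HMF, 1
acidity at 61.26 meq/kg, 4 diastase, 2 moisture, 9 low-conductivity, 53
suspect-grade low-sum records including 3 blend profiles at 0.76/0.71/0.73
mS/cm) and 498 baseline records drawn independently per parameter from the
marginals clipped to the compliant region. Declared-type counts (218
acacia, 36 honeydew, 36 linden, 8 monofloral, 288 polyfloral, 23
sunflower) are chosen so that the conductivity rule lands exactly on the
survey's final counts (213/29/34/8/302/23); the declared honeydew count of
36 is arithmetic (29 final = declared − 16 out + 9 in), not a published
figure. Region and year margins match the survey (the joint distribution
is filled from quotas and is not meaningful). The deviation categories are
mutually disjoint across samples, so the grade accounting is exact:
22 adulterated + 64 suspect = 86 non-conforming = 14.1 % of 609.

## Classifier

Architecture 8-12-6: eight min-max-scaled inputs (5-HMF excluded, as its
information is already in the adulteration screen and it is not a marker
of botanical origin), 12 logistic hidden units, softmax output over the
six types, 186 parameters. Loss is mean categorical cross-entropy plus a
small L2 penalty on the weight matrices (default 1e-4, biases exempt) —
the standard ridge default for a network of this size fitted to a few
hundred records; without it, training to convergence demonstrably
overfits (deeper BFGS runs *reduce* minority-class test recall).

Training: scaling parameters are fitted on the 70 % training split and
stored with the model (a constant feature maps to 0). A stratified 20 %
validation subset is carved from the training split; each of the 10
random restarts (weights uniform in ±0.5 scaled by 1/√fan-in) runs BFGS
(Wolfe line search, iteration cap 500, gradient tolerance 1e-6) and keeps
the iterate with the lowest validation loss (early stopping, which in
practice stops after one to two hundred iterations); the restart with the
lowest validation loss wins. Setting `val_fraction = 0` recovers plain
training-loss selection at full cap. Everything is deterministic given
the split and init seeds; prediction is argmax with first-index
tie-breaking. The split is stratified by class by default to guarantee
the 8-sample monofloral class appears in training; `stratify=False`
reproduces a plain random split.

On generator-default tables the model reaches roughly 78–85 % test
accuracy. Honeydew — whose conductivity is disjoint from every other
class by construction — is recognised at 100 % in most runs, but not in
every run: the copula occasionally draws a honeydew sample that is
flower-like in all seven other features, and with only ~20 honeydew
training records the network does not always extrapolate the conductivity
rule to such points (observed minima 77.8–88.9 % = 1–2 of 9 test records
missed). The Bayes rule (EC > 0.8) is perfect by construction, so this is
an estimation limit at n = 609, not a separability limit; it is the main
caveat on classifier results from this generator.

## Numerical conventions and degenerate inputs

* Percentages are rounded half-up to one decimal at presentation; all
  computation keeps full precision.
* CSV floats are written in shortest round-trip (`repr`) form so
  read→write→read is byte-identical.
* Empty tables are rejected before any stage runs; a single-value group
  leaves its CI flagged undefined; an all-tied Kruskal–Wallis input and an
  all-constant ANOVA input return flagged degenerate results rather than
  raising.
* The logistic is evaluated in the numerically stable split form and the
  softmax with max-subtraction; probabilities sum to 1 within 1e-9 for
  arbitrary weights.

## Known limitations

* The audit is threshold-based only; it cannot detect adulteration that
  keeps all parameters within limits (no isotope, NMR, or syrup-marker
  assays).
* The fixture's per-sample narrative details (which region/year carries
  which violation) follow the documented inventory where stated and are
  otherwise filled deterministically; only the counts are contractual.
* Statistical results on synthetic tables validate implementation
  correctness, not real-data effect sizes; real-survey F/H statistics and
  per-class recognition rates depend on data that were never deposited.
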