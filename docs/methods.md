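# Methods

## Problem and model

Great cormorants are sexually monomorphic in plumage; sex is assigned from
linear measurements (mm): wing length, bill length, maximum and minimum
bill depth, tarsus length (total head length is accepted in the input
schema but excluded from default analyses). The statistical model is the
classical two-group linear discriminant: within each sex, measurements are
multivariate normal with a common covariance matrix, and the canonical axis
**b** ∝ S_W⁻¹(x̄_M − x̄_F) carries all between-group structure. Everything
downstream — Wilks' lambda, partial F, Mahalanobis classification, the
grey zone — is exact under that model and degrades gracefully under the
mild non-normality typical of real biometric data.

## Conventions of the fitted discriminant function

Software packages differ in how they normalise and centre canonical
functions, so the conventions used here are stated explicitly:

- **Scale**: pooled within-group variance of scores is 1 (within-group SD
  units).
- **Orientation**: male score mean > female score mean, so D > 0 suggests
  a male.
- **Constant**: the *size-weighted* mean of all case scores is 0. With
  unequal group sizes this puts the cut D = 0 off-centre between the group
  score means — evaluating the shipped wing+bill preset at the two sex
  means gives ≈ +1.217 (male) and −1.713 (female), the asymmetry expected
  when males outnumber females in the fitting sample. Consequence: the
  sign rule at D = 0 and the equal-priors Mahalanobis rule (cut at the
  *midpoint* of the group score means) coincide exactly only when
  n_M = n_F; with unequal n they differ for scores between the two cuts.
  Tests of the identity use balanced samples.
- **Standardized coefficients** are b_j × pooled within-group SD of
  variable j, comparing the contribution of predictors on a common scale.

## Stepwise selection

Backward-stepwise on Wilks' lambda Λ = |W|/|T|, partial
F = (Λ_without/Λ_with − 1)(n − g − p + 1)/(g − 1) with g = 2 and p the
size of the larger model. Defaults 3.84 (enter) and 2.71 (remove) are the
0.95 and 0.90 points of χ²₁ — the conventional settings for this analysis.
Each step removes the weakest included variable if its F < 2.71, otherwise
re-enters the strongest excluded variable if its F ≥ 3.84 (re-entry can be
disabled), otherwise stops. Listwise deletion over the variables under
evaluation at each step; both lambdas in any one comparison are computed
on the same case set, which guarantees Λ_with ≤ Λ_without. Exact F ties
remove the later-listed variable (deterministic). If every variable is
removed the run fails with the selection trace attached.

Two statistical facts worth knowing when reading selection outcomes:
a variable with no group effect and no correlation with the kept variables
has a null-F(1, n−p−1) partial F, so it survives removal with probability
P(F ≥ 2.71) ≈ 0.10 per fit — occasional retention of a useless variable is
expected behaviour of the criterion, not a defect; and a variable with *no
marginal* sex difference but correlated with a dimorphic trait can be a
genuine suppressor and is then legitimately retained.

## Classification, accuracy, grey zone

Cases are assigned by squared Mahalanobis distance d²_s to each sex
centroid over the model's variables, posterior ∝ prior × exp(−d²/2),
equal priors by default (configurable; reports flag non-default priors).
Accuracy is resubstitution (the training cases re-classified), per sex and
case-weighted overall; leave-one-out is deliberately not part of the main
pipeline. Grey-zone thresholds for a per-sex error target e: t_F is the
e-quantile of male scores, t_M the (1−e)-quantile of female scores, with
linear interpolation between order statistics; if t_F ≥ t_M (near-separable
samples) the zone collapses to empty. D = 0 exactly is reported unsexed
under the plain sign rule.

## Prediction ellipses

The bivariate region for one new observation:
(x − x̄)ᵀS⁻¹(x − x̄) ≤ (2(n−1)(n+1)/(n(n−2)))·F_{level; 2, n−2} — a
prediction region, not a confidence region for the mean and not the plain
χ² data ellipse; the scale constant tends to χ²₂(level) = 5.991 at
level 0.95 as n → ∞. Boundary membership counts as inside.

## Synthetic populations

`synthetic_data` draws each sex × age group from a multivariate normal
with Σ_ij = ρ_ij (CV_i μ_i)(CV_j μ_j); non-positive draws are redrawn
(negligible at realistic CVs). The shipped defaults encode the published
sex-specific means and CVs, per-sex totals 218 M / 139 F (split
juvenile:adult 222:157 as in the source sample), and
missing-completely-at-random rates per measurement chosen so expected
non-missing counts match the published per-measurement sample sizes.
Between-measurement correlation is not published; the default is a uniform
ρ = 0.5, a realistic value for skeletal size traits that produces genuine
multivariate overlap without degenerate separation. Ages share one
distribution within sex by default (matching the finding of no adult–
juvenile differences); an additive adult offset per measurement is
configurable to test detection of such differences.

What the generator does **not** emulate: between-observer measurement
error, moult state, body mass, non-normal tails or age-mixture structure,
and any missingness mechanism beyond MCAR. Passing tests therefore
demonstrate correctness of the *procedures* under the stated model, not
the exact published accuracies, which depend on the original specimens.
Published figures requiring the deposited raw data (the exact Table-style
accuracies, the −1.256/0.916 grey-zone thresholds, the 38% unsexed and
29%/22% ellipse-overlap fractions) are checked structurally (signs,
calibration, monotonicity), not numerically — though on the default seed
the synthetic pipeline lands close (e.g. 37% unsexed, same selected
variable set).

## Numerical choices

- Pooled-variance t-test by default (the variance screen precedes it, as
  in the classical workflow); Welch available via `pooled=False`.
- Covariance solves use `numpy.linalg.solve` on the pooled S_W with a
  condition-number guard: warn above 10⁸, refuse above 10¹² naming the
  offending variable set.
- Wilks' lambda via sign-checked log-determinants (slogdet) for stability.
- Model serialization uses JSON with full float repr: round trips are
  bit-exact, and the file doubles as the sexing-rule exchange format.
- Report-layer rounding only (V and SDI to 0.1, t to 0.01, percentages to
  0.1); full precision internally and in `report.json`.
- Problem sizes in the test suite (e.g. 5 000/sex for moment recovery,
  20 000/sex for Bayes-accuracy recovery, 200 replicates × 10⁴ probes for
  ellipse coverage, 100 replicates for stepwise behaviour) were chosen so
  sampling error sits comfortably below each assertion's tolerance while
  the whole suite stays fast.

## Known limitations

- Equations transfer across populations only to the extent that size
  distributions match; the cross-validation table quantifies, not removes,
  that risk (subspecies mixture shifts bill dimensions in particular).
- Resubstitution accuracy is optimistic relative to out-of-sample
  accuracy; with n ≥ 100/sex and ≤ 3 predictors the optimism is small but
  not zero.
- The grey-zone quantile convention (linear interpolation) is one of
  several; with n ≥ 10³ scores the choice moves thresholds by far less
  than sampling error.
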