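# Methods notes

This note records the statistical conventions the package implements, the
choices made where the literature leaves the definition open, what the
synthetic-data generator does and does not emulate, and the resulting
limitations. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Instrument selection and harmonization

Candidates are filtered in a fixed order — p-value, minor-allele frequency,
per-SNP F statistic, LD clumping — so the instrument-strength filter is
evaluated only on association-significant SNPs and audit trails are
reproducible. Defaults: p < 1e-5 (5e-5 via the `sparse` flag for SNP-poor
exposures), MAF ≥ 0.01, F ≥ 10 with the exclusion rule read strictly as
F < 10 (a SNP at exactly 10 is retained), greedy clumping at r² < 0.001 in
a ±10,000 kb window with ties on p broken by SNP id. Records lacking a
frequency pass the MAF filter with a warning rather than being dropped,
since many released summary files omit frequency and silent removal would
bias instrument counts. LD comes from a user-supplied r² table; a missing
pair is treated as r² = 0 with a warning, matching the assumption that
unrecorded pairs are unlinked. Positions are 1-based.

Harmonization aligns outcome effects to the exposure's effect allele:
same-order alleles are kept, swapped alleles negate the outcome beta and
mirror its frequency, strand-complement matches are complemented first.
Palindromic (A/T, C/G) variants are oriented by frequency agreement when
both frequencies lie outside 0.42–0.58 and dropped as ambiguous otherwise —
the conservative standard practice; the window is configurable. The
procedure is idempotent and a double allele swap is an exact identity.

## Estimators

- **Wald ratio** β_Y/β_X with first-order SE σ_Y/|β_X|; a second-order
  variant adding the exposure-uncertainty term is available by flag.
- **IVW**: weighted regression through the origin with weights σ_Y⁻².
  The default is the multiplicative random-effects model — the fixed-effects
  SE inflated by max(1, √(Q/(J−1))) — with plain fixed effects selectable.
  The floor at 1 prevents anti-conservative deflation under homogeneity.
  P-values are normal.
- **MR-Egger**: instruments oriented so every exposure beta is
  non-negative, then WLS with intercept. Residual variance is floored at 1
  and inference uses t with J−2 df. The intercept is the pleiotropy test.
- **Weighted median**: ratios sorted, weights (σ_Y/|β_X|)⁻² normalized,
  the estimate interpolates the cumulative weight midpoints at probability
  0.5. SEs by parametric bootstrap (betas resampled from their normal
  sampling distributions; default 1000 draws, explicit seed).
- **Mode estimators**: normal-kernel density over the ratios with
  bandwidth h = φ · 0.9 · min(sd, mad/0.6745) · J^(−1/5) (φ = 1 by
  default), evaluated on a 512-point grid spanning the ratios ± 3h;
  uniform (simple) or inverse-variance (weighted) kernel weights. The grid
  and bandwidth rule have no canonical published definition, so they are
  pinned here and fully configurable; identical ratios short-circuit to
  the common ratio. Bootstrap SEs as above.

All estimators are exactly equivariant to rescaling of either trait's
betas and SEs, and with homogeneous ratios IVW (both models), the weighted
median and the Wald ratio coincide; the test suite asserts both, plus
agreement with an independent weighted-least-squares oracle to 1e-10.

## Sensitivity battery

Cochran's Q uses first-order ratio weights; the radial decomposition
reports per-SNP contributions (summing exactly to Q) with Bonferroni
chi-square(1) flags at α/J. MR-PRESSO follows the
simulate-and-compare construction: observed statistic
Σ w_j (β_Yj − β̂_(−j) β_Xj)² with leave-one-out IVW expectations, Monte
Carlo replicates drawn at the observed SEs, p-values estimated as
(1 + count)/(1 + n_sim) so they are never zero, per-SNP outlier tests
Bonferroni-scaled by J, and a distortion p defined as the two-sided tail
of |IVW_all − IVW_without_outliers| under the simulated null (the
reference implementation's distortion bootstrap is not published as
closed-form pseudocode; this variant is documented and deterministic).
When every SNP is flagged the distortion test is undefined and reported as
such. The Steiger test sums per-SNP variance explained r² = z²/(z²+n−2)
per trait and compares Fisher-transformed √(Σr²) with the independent-
samples normal approximation; ties report a statistic of 0, p = 1 and
direction not-correct with a note. For binary outcomes on the log-odds
scale this r² is an approximation and is flagged as such here.
Leave-one-out recomputes IVW J times and raises a flag when any omission
flips the effect sign or moves the p-value across α. Alpha defaults to
0.05 throughout.

## Mediation

The decomposition is the product of coefficients: mediated effect E×F,
direct effect C′ = C − E×F, proportion (E×F)/C, all exact identities on
the result object. The SE of E×F is first-order delta,
√(E²σ_F² + F²σ_E²), with z = 1.96 for 95% intervals — the convention that
reproduces published mediation tables from their printed leg CIs to within
rounding (verified in the acceptance checks).

Two proportion intervals are reported. `ci_proportion` divides the
mediated-effect CI bounds by the total-effect point estimate (bounds
swapped when C < 0); this matches how published mediation tables print the
interval but conditions on C, so it undercovers when the total effect
carries real sampling noise. `ci_proportion_delta` propagates var(E),
var(F) and var(C) through the ratio jointly (covariances between legs are
negligible by design here because each leg's noise comes from a different
GWAS draw). Simulation-based coverage claims in the tests therefore use
the delta interval; worked-example reproduction uses the table convention.
A proportion outside [−1, 1] (inconsistent mediation) is allowed and
flagged.

In `two_step_mediation`, the mediator → outcome leg selects instruments
from the mediator GWAS and then applies per-SNP Steiger filtering against
the exposure: a SNP is kept only if it explains more variance in the
mediator than in the exposure. Without this, any SNP acting on the
mediator through the exposure masquerades as a mediator instrument and the
F leg converges to C/E instead of F; filtering mediator instruments for
exposure association is the corresponding standard practice in mediation
MR. The reverse-causation screen (outcome → exposure MR, filtered the same
way) is always computed and recorded on the result; "negative reverse MR"
is interpreted by default as a non-significant reverse estimate, with the
literal negative-sign reading selectable (`reverse_rule="negative"`) since
the phrase is ambiguous. A screen with no surviving reverse instruments
passes vacuously, with a note. The library always returns the full
decomposition; the report layer and CLI withhold results that fail the
screen.

## Synthetic-data generator

The generator emulates what two-sample MR consumes after QC: independent
instruments (no LD — the post-clumping regime), standardized per-allele
effects, observed betas drawn normally around truth with SE = 1/√n
(optionally 1/√(2·maf·(1−maf)·n)), p-values from the z statistic, and
non-palindromic allele pairs by default (strand-ambiguous SNPs are
presumed removed upstream; a flag re-enables them to exercise the
harmonizer). Two instrument blocks are drawn: exposure instruments
γ ~ N(0, γ_sd²) and direct mediator instruments δ ~ N(0, δ_sd²). The
mediator block is essential: if every mediator-associated SNP acted
through the exposure, the mediator → outcome effect would be
unidentifiable by univariable MR. Defaults γ_sd = δ_sd = 0.05 on the
standardized scale (≈0.25% variance explained per SNP — realistic for
well-instrumented molecular traits), n = 100,000 per GWAS, 100 SNPs per
block, E = 0.3, F = 0.2, C′ = 0.1.

Pleiotropy modes act on the exposure block: `balanced` draws zero-mean
SNP → mediator and SNP → outcome effects; `directional` centers them at
`pleiotropy_mean` aligned with the exposure-increasing allele (an
allele-agnostic mean would be cancelled by estimator orientation and no
method could detect it); `inside_violating` correlates the outcome-side
effect with instrument strength (r ≈ 0.7), breaking the InSiDE
assumption. In the trio design the Egger intercept under directional
pleiotropy converges to pleiotropy_mean·(1+F) because the mediator
pathway forwards the mediator-side pleiotropy into the outcome; the tests
assert that value. Outliers offset the outcome effect of the
`n_outlier_snps` *strongest* exposure instruments by ±outlier_scale
outcome-SEs: injecting into the strongest instruments makes outlier-
recovery experiments measure detection rather than instrument selection.

What the generator does not emulate, and what passing tests therefore do
not show: LD between instruments (no clumping stress test on realistic
panels), binary-outcome log-odds generation with case-control imbalance,
sample overlap between cohorts, winner's-curse-scale selection bias at
marginal instrument strength, or population stratification. Conclusions
about real GWAS behavior under those features need real data.

## Problem sizes and numerical conventions

The calibration experiments run at sizes chosen to make their Monte-Carlo
error small relative to the acceptance bands while keeping the whole suite
fast: 2000 null pairs (50 candidate instruments each) for IVW null
calibration, 100 trios for mediated-proportion recovery, 50 replicates for
outlier sensitivity, 200 for the MR-PRESSO null rate and the screening
false-positive rate. All stochastic procedures take explicit seeds and are
bit-reproducible; child seeds are derived via `numpy.random.SeedSequence`.
P-values are floored at the smallest positive double so the (0, 1]
contract holds; Monte-Carlo p-values use (1 + count)/(1 + n_sim). Degenerate
inputs are defined rather than accidental: a single instrument falls back
to the Wald ratio with a note, identical ratios give Q = 0 and a zero-width
mode bandwidth returns the common ratio, and an empty selection returns a
structured no-instruments status instead of raising deep in the stack.

## Known limitations

- No multivariable MR: the direct effect is C − E×F, not a
  multivariable-adjusted estimate, and one mediator is handled per model.
- Steiger r² for binary traits uses the z-based approximation on the
  log-odds scale.
- The LD interface consumes precomputed r²; the package never computes LD
  from genotypes and never fetches remote data.
- The mode estimators' bandwidth rule is a pinned convention, not a
  published standard; results at very small J are sensitive to it.
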