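# mrmediate

Two-sample Mendelian randomization (MR) with two-step mediation, for
epidemiologists and statistical geneticists who work from GWAS summary
statistics. The package covers the full analytic chain used in
metabolite / immune-phenotype / disease mediation studies: instrument
selection and harmonization, five causal-effect estimators, a sensitivity
battery, the product-of-coefficients mediation decomposition with
delta-method intervals, bidirectional screening of exposure–outcome pairs,
and a synthetic summary-statistics generator so every stage can be
validated end to end without external data.

## The model

Each genetic instrument j contributes a per-allele association with the
exposure (β̂<sub>Xj</sub>, σ<sub>Xj</sub>) and with the outcome
(β̂<sub>Yj</sub>, σ<sub>Yj</sub>), taken from two independent GWAS.
Under the instrumental-variable assumptions the per-SNP Wald ratio
β̂<sub>Yj</sub>/β̂<sub>Xj</sub> estimates the causal effect, and the
inverse-variance-weighted (IVW) estimator

&nbsp;&nbsp;&nbsp;&nbsp;β̂ = Σ<sub>j</sub> β̂<sub>Xj</sub> β̂<sub>Yj</sub> σ<sub>Yj</sub>⁻² / Σ<sub>j</sub> β̂<sub>Xj</sub>² σ<sub>Yj</sub>⁻²

is the weighted regression of outcome on exposure effects through the
origin. MR-Egger adds a free intercept (average directional pleiotropy);
the weighted median and the simple/weighted mode estimators are robust to
up to half the weight, or the plurality, coming from invalid instruments.

For mediation, a two-step design estimates E (exposure → mediator) and
F (mediator → outcome) alongside the total effect C (exposure → outcome):

- mediated effect `E×F`, with delta-method SE `√(E²σ_F² + F²σ_E²)`,
- direct effect `C′ = C − E×F`,
- mediated proportion `(E×F)/C`, reported as a percentage.

Diagnostics: Cochran's Q and its per-SNP (radial) decomposition, the
MR-Egger intercept test, simulation-based MR-PRESSO (global, per-SNP
outlier and distortion tests), the Steiger directionality test, and
leave-one-out IVW.

## Worked example

Simulate a trio with known structure (E = 0.3, F = 0.2, C′ = 0.1, so the
true total effect is 0.16 and the true mediated proportion 37.5%), then run
the two-step mediation:

```sh
mrmediate simulate --out demo --seed 7 --n-snps 100
mrmediate mediate --exposure demo/exposure.tsv --mediator demo/mediator.tsv \
    --outcome demo/outcome.tsv --out demo/med --seed 1
```

The printed `MediationResult` (abridged) for this seed:

| quantity | estimate | true value |
| --- | --- | --- |
| total effect C (IVW, 68 SNPs) | 0.1685 (se 0.0072) | 0.16 |
| step E (IVW, 68 SNPs) | 0.2922 (se 0.0075) | 0.30 |
| step F (IVW, 81 SNPs) | 0.2124 (se 0.0070) | 0.20 |
| mediated effect E×F | 0.0621, 95% CI (0.0570, 0.0671) | 0.06 |
| direct effect C′ | 0.1064 | 0.10 |
| mediated proportion | 36.8%, delta CI (32.5%, 41.2%) | 37.5% |

The reverse-causation screen (outcome → exposure MR) passed, so the result
appears in `demo/med/mediation.tsv`; a result failing the screen is
computed but withheld from the table and listed in the run log. The same
decomposition is available programmatically through
`mrmediate.two_step_mediation`, and single pairs through `mrmediate.run_pair`
/ the `mrmediate mr` and `mrmediate screen` commands.

Summary-statistics files are plain TSV with header
`SNP, chrom, pos, effect_allele, other_allele, eaf, beta, se, pval, n`;
aliased headers are handled with a column map.

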