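"""Synthetic GWAS summary statistics for exposure-mediator-outcome trios.

The generator emulates the statistical structure two-sample MR assumes
after quality control: independent (post-clumping) instruments with
standardized per-allele effects, sampling noise matching the stated GWAS
sample sizes (SE = 1/sqrt(n), optionally allele-frequency scaled), an
exposure -> mediator -> outcome causal chain with known coefficients,
optional horizontal pleiotropy (balanced, directional, or correlated with
instrument strength, i.e. violating the InSiDE assumption), and optional
injected outlier SNPs.

Two instrument blocks are generated: SNPs acting on the exposure (effects
gamma ~ N(0, gamma_sd^2)) and SNPs acting directly on the mediator
(delta ~ N(0, delta_sd^2)); the latter identify the mediator -> outcome
leg, which is otherwise confounded by the exposure pathway.  Effects are on
a standardized continuous scale; LD is not simulated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import stats

from .sumstats import VariantAssociation, write_sumstats

__all__ = ["SyntheticTrioConfig", "TrioData", "generate_trio", "generate_null_grid"]

# non-palindromic ordered allele pairs; strand-ambiguous variants are assumed
# already excluded by upstream QC (include_palindromic re-enables them)
_PAIRS = [
    ("A", "G"), ("G", "A"), ("A", "C"), ("C", "A"),
    ("T", "G"), ("G", "T"), ("T", "C"), ("C", "T"),
]
_PAIRS_PALINDROMIC = _PAIRS + [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass
class SyntheticTrioConfig:
    """Study conditions for one synthetic trio.

    ``n_snps`` instruments act on the exposure and ``n_snps_mediator``
    (default: same) act directly on the mediator.  Structural coefficients:
    E_true (exposure -> mediator), F_true (mediator -> outcome), Cprime_true
    (direct exposure -> outcome); the total effect is derived,
    C = Cprime + E*F.  ``gamma_sd``/``delta_sd`` are per-SNP standardized
    effect spreads (default 0.05, i.e. ~0.25% variance explained per SNP, a
    realistic figure for strongly instrumented molecular traits).
    ``outlier_scale`` is the size of the injected outcome-effect offset in
    outcome-SE units; outliers are injected into the strongest exposure
    instruments so they are guaranteed to enter the analysis set.
    """

    n_snps: int = 100
    n_snps_mediator: int | None = None
    n_exposure: int = 100_000
    n_mediator: int = 100_000
    n_outcome: int = 100_000
    gamma_sd: float = 0.05
    delta_sd: float = 0.05
    E_true: float = 0.3
    F_true: float = 0.2
    Cprime_true: float = 0.1
    pleiotropy_mode: str = "none"  # none | balanced | directional | inside_violating
    pleiotropy_sd: float = 0.02
    pleiotropy_mean: float = 0.0
    n_outlier_snps: int = 0
    outlier_scale: float = 10.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    se_model: str = "simple"  # simple: 1/sqrt(n); af: 1/sqrt(2 maf (1-maf) n)
    include_palindromic: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        for name in ("n_exposure", "n_mediator", "n_outcome"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be >= 2")
        lo, hi = self.maf_range
        if not (0 < lo < hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.pleiotropy_mode not in ("none", "balanced", "directional", "inside_violating"):
            raise ValueError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        if self.se_model not in ("simple", "af"):
            raise ValueError(f"unknown se_model {self.se_model!r}")

    @property
    def C_true(self) -> float:
        """Total effect, derived: Cprime + E*F."""
        return self.Cprime_true + self.E_true * self.F_true

    @property
    def proportion_true(self) -> float | None:
        """Mediated proportion implied by the coefficients; None when C = 0."""
        if self.C_true == 0:
            return None
        return self.E_true * self.F_true / self.C_true


@dataclass
class TrioData:
    """Three summary-statistics tables plus the latent truth record."""

    exposure: list[VariantAssociation]
    mediator: list[VariantAssociation]
    outcome: list[VariantAssociation]
    truth: dict = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_sumstats(self.exposure, outdir / "exposure.tsv")
        write_sumstats(self.mediator, outdir / "mediator.tsv")
        write_sumstats(self.outcome, outdir / "outcome.tsv")
        with open(outdir / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=2, sort_keys=True)
            fh.write("\n")


def _records(ids, chroms, poss, eas, oas, eafs, beta, se, ns):
    pvals = 2.0 * stats.norm.sf(np.abs(beta / se))
    pvals = np.clip(pvals, 5e-324, 1.0)
    return [
        VariantAssociation(
            snp_id=ids[i],
            chrom=chroms[i],
            pos=int(poss[i]),
            effect_allele=eas[i],
            other_allele=oas[i],
            eaf=float(eafs[i]),
            beta=float(beta[i]),
            se=float(se[i]),
            pval=float(pvals[i]),
            n=int(ns),
        )
        for i in range(len(ids))
    ]


def generate_trio(cfg: SyntheticTrioConfig) -> TrioData:
    """Generate one exposure/mediator/outcome trio of summary tables.

    Identical configs (including seed) yield bit-identical tables.  The
    truth record stores every latent per-SNP effect and the structural
    coefficients.
    """
    rng = np.random.default_rng(cfg.seed)
    j_exp = cfg.n_snps
    j_med = cfg.n_snps_mediator if cfg.n_snps_mediator is not None else cfg.n_snps
    j = j_exp + j_med

    # variant annotations: one SNP per mb on chr1, independent by construction
    ids = [f"rs{100000 + i}" for i in range(j)]
    chroms = ["1"] * j
    poss = 1_000_000 * (1 + np.arange(j))
    pairs = _PAIRS_PALINDROMIC if cfg.include_palindromic else _PAIRS
    pick = rng.integers(0, len(pairs), size=j)
    eas = [pairs[k][0] for k in pick]
    oas = [pairs[k][1] for k in pick]
    eafs = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=j)

    # latent per-SNP effects
    gamma = np.zeros(j)
    gamma[:j_exp] = rng.normal(0.0, cfg.gamma_sd, size=j_exp)
    delta = np.zeros(j)
    delta[j_exp:] = rng.normal(0.0, cfg.delta_sd, size=j_med)

    alpha = np.zeros(j)  # SNP -> mediator pleiotropy (exposure block)
    theta = np.zeros(j)  # SNP -> outcome pleiotropy (exposure block)
    blk = slice(0, j_exp)
    if cfg.pleiotropy_mode == "balanced":
        alpha[blk] = rng.normal(0.0, cfg.pleiotropy_sd, size=j_exp)
        theta[blk] = rng.normal(0.0, cfg.pleiotropy_sd, size=j_exp)
    elif cfg.pleiotropy_mode == "directional":
        # directional pleiotropy is aligned with the exposure-increasing
        # allele (sign of gamma); otherwise instrument orientation during
        # estimation would average it away
        orient = np.sign(gamma[blk])
        alpha[blk] = orient * cfg.pleiotropy_mean + rng.normal(
            0.0, cfg.pleiotropy_sd, size=j_exp
        )
        theta[blk] = orient * cfg.pleiotropy_mean + rng.normal(
            0.0, cfg.pleiotropy_sd, size=j_exp
        )
    elif cfg.pleiotropy_mode == "inside_violating":
        # pleiotropy correlated (r ~ 0.7) with instrument strength
        noise = rng.normal(0.0, 1.0, size=j_exp)
        std_gamma = gamma[blk] / cfg.gamma_sd
        theta[blk] = cfg.pleiotropy_mean + cfg.pleiotropy_sd * (
            0.7 * std_gamma + np.sqrt(1 - 0.7**2) * noise
        )
        alpha[blk] = rng.normal(0.0, cfg.pleiotropy_sd, size=j_exp)

    # structural chain (per-SNP true associations)
    a_true = cfg.E_true * gamma + alpha + delta
    b_true = cfg.C_true * gamma + cfg.F_true * (alpha + delta) + theta

    if cfg.se_model == "simple":
        se_exp = np.full(j, cfg.n_exposure**-0.5)
        se_med = np.full(j, cfg.n_mediator**-0.5)
        se_out = np.full(j, cfg.n_outcome**-0.5)
    else:
        scale = 1.0 / np.sqrt(2.0 * eafs * (1.0 - eafs))
        se_exp = scale * cfg.n_exposure**-0.5
        se_med = scale * cfg.n_mediator**-0.5
        se_out = scale * cfg.n_outcome**-0.5

    # outliers: offset the outcome effect of the strongest exposure instruments
    outlier_ids: list[str] = []
    if cfg.n_outlier_snps > 0:
        strongest = np.argsort(-np.abs(gamma[:j_exp]))[: cfg.n_outlier_snps]
        signs = rng.choice([-1.0, 1.0], size=cfg.n_outlier_snps)
        b_true = b_true.copy()
        b_true[strongest] += signs * cfg.outlier_scale * se_out[strongest]
        outlier_ids = [ids[i] for i in strongest]

    beta_exp = rng.normal(gamma, se_exp)
    beta_med = rng.normal(a_true, se_med)
    beta_out = rng.normal(b_true, se_out)

    truth = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(cfg).items()
        },
        "C_true": cfg.C_true,
        "proportion_true": cfg.proportion_true,
        "snp_ids": ids,
        "gamma": gamma.tolist(),
        "delta": delta.tolist(),
        "alpha": alpha.tolist(),
        "theta": theta.tolist(),
        "a_true": a_true.tolist(),
        "b_true": b_true.tolist(),
        "outlier_ids": outlier_ids,
    }
    return TrioData(
        exposure=_records(ids, chroms, poss, eas, oas, eafs, beta_exp, se_exp, cfg.n_exposure),
        mediator=_records(ids, chroms, poss, eas, oas, eafs, beta_med, se_med, cfg.n_mediator),
        outcome=_records(ids, chroms, poss, eas, oas, eafs, beta_out, se_out, cfg.n_outcome),
        truth=truth,
    )


def generate_null_grid(
    n_exposures: int,
    n_outcomes: int,
    cfg: SyntheticTrioConfig | None = None,
    seed: int = 0,
) -> list[tuple[list[VariantAssociation], list[VariantAssociation], dict]]:
    """Independent null exposure-outcome pairs (all structural coefficients 0).

    Returns ``n_exposures * n_outcomes`` tuples ``(exposure_records,
    outcome_records, truth)``; each pair draws fresh instruments and noise
    from a child seed of ``seed``.  Supports false-positive accounting for
    the screening stage.
    """
    if n_exposures < 1 or n_outcomes < 1:
        raise ValueError("counts must be >= 1")
    base = cfg or SyntheticTrioConfig()
    n_pairs = n_exposures * n_outcomes
    children = np.random.SeedSequence(seed).spawn(n_pairs)
    pairs = []
    for child in children:
        sub = SyntheticTrioConfig(
            **{
                **asdict(base),
                "E_true": 0.0,
                "F_true": 0.0,
                "Cprime_true": 0.0,
                "n_snps_mediator": 0,
                "maf_range": tuple(base.maf_range),
                "seed": int(child.generate_state(1)[0] % (2**31)),
            }
        )
        trio = generate_trio(sub)
        pairs.append((trio.exposure, trio.outcome, trio.truth))
    return pairs
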