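"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from mrmediate import HarmonizedInstrumentSet, VariantAssociation


def make_variant(
    snp_id="rs1",
    effect_allele="A",
    other_allele="G",
    beta=0.1,
    se=0.01,
    pval=1e-8,
    eaf=0.3,
    chrom="1",
    pos=1_000_000,
    n=100_000,
) -> VariantAssociation:
    return VariantAssociation(
        snp_id=snp_id,
        effect_allele=effect_allele,
        other_allele=other_allele,
        beta=beta,
        se=se,
        pval=pval,
        eaf=eaf,
        chrom=chrom,
        pos=pos,
        n=n,
    )


def make_hset(bx, sx, by, sy, **kwargs) -> HarmonizedInstrumentSet:
    bx = np.asarray(bx, dtype=float)
    return HarmonizedInstrumentSet(
        exposure_name=kwargs.get("exposure_name", "X"),
        outcome_name=kwargs.get("outcome_name", "Y"),
        snp_ids=[f"rs{i}" for i in range(bx.size)],
        beta_exp=bx,
        se_exp=np.asarray(sx, dtype=float),
        beta_out=np.asarray(by, dtype=float),
        se_out=np.asarray(sy, dtype=float),
    )


def random_hset(seed: int, j: int = 8, true_beta: float = 0.3) -> HarmonizedInstrumentSet:
    """A homogeneous random instrument set with noise around a true effect."""
    rng = np.random.default_rng(seed)
    bx = rng.uniform(0.05, 0.5, j) * rng.choice([-1, 1], j)
    sx = rng.uniform(0.005, 0.02, j)
    sy = rng.uniform(0.01, 0.05, j)
    by = true_beta * bx + rng.normal(0, sy)
    return make_hset(bx, sx, by, sy)


@pytest.fixture
def homogeneous_set() -> HarmonizedInstrumentSet:
    """Five instruments whose Wald ratios are all exactly 0.4."""
    bx = np.array([0.1, 0.2, -0.3, 0.15, 0.25])
    sx = np.full(5, 0.01)
    by = 0.4 * bx
    sy = np.array([0.01, 0.02, 0.01, 0.03, 0.02])
    return make_hset(bx, sx, by, sy)
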