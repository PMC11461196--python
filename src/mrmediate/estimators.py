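"""Causal-effect estimators for two-sample MR on harmonized summary statistics.

All estimators consume a :class:`~mrmediate.sumstats.HarmonizedInstrumentSet`
with J aligned instruments and return an :class:`MREstimate`.  The inverse-
variance-weighted (IVW) estimator is the primary method; MR-Egger, the
weighted median and the two mode estimators serve as pleiotropy-robust
cross-checks.  The IVW default is the multiplicative random-effects model
with the residual inflation floored at 1; the fixed-effects variant is
available via ``model="fixed"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .sumstats import (
    HarmonizedInstrumentSet,
    InsufficientInstrumentsError,
    NoInstrumentsError,
)

__all__ = [
    "MREstimate",
    "wald_ratio",
    "ivw",
    "egger",
    "weighted_median",
    "mode_estimate",
    "all_estimates",
]

_Z975 = float(stats.norm.ppf(0.975))
_P_FLOOR = 5e-324  # smallest subnormal double; keeps pval in (0, 1]


@dataclass
class MREstimate:
    """One method's causal-effect estimate with uncertainty."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snps: int
    notes: str = ""

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "nsnp": self.n_snps,
            "beta": self.beta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "pval": self.pval,
            "notes": self.notes,
        }


def _normal_estimate(method, beta, se, n_snps, notes=""):
    beta = float(beta)
    se = float(se)
    if se > 0:
        p = 2.0 * stats.norm.sf(abs(beta) / se)
    else:
        p = _P_FLOOR if beta != 0 else 1.0
    return MREstimate(
        method=method,
        beta=beta,
        se=se,
        ci_low=beta - _Z975 * se,
        ci_high=beta + _Z975 * se,
        pval=float(min(max(p, _P_FLOOR), 1.0)),
        n_snps=n_snps,
        notes=notes,
    )


def wald_ratio(
    bx: float, sx: float, by: float, sy: float, second_order: bool = False
) -> MREstimate:
    """Single-SNP causal estimate by/bx with delta-method SE.

    First-order SE is ``sy/|bx|``; ``second_order=True`` adds the exposure
    uncertainty term ``by^2 sx^2 / bx^4``.
    """
    if bx == 0:
        raise ZeroDivisionError("wald ratio undefined for bx = 0")
    beta = by / bx
    if second_order:
        se = float(np.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4))
    else:
        se = sy / abs(bx)
    return _normal_estimate("wald", beta, se, 1)


def _ivw_fixed(bx, by, sy):
    w = sy**-2.0
    denom = float(np.sum(w * bx * bx))
    beta = float(np.sum(w * bx * by)) / denom
    se = denom**-0.5
    return beta, se


def _cochran_q(bx, by, sy, beta):
    # residual weighted sum of squares of the through-origin fit; identical to
    # the ratio-form Q with first-order weights
    return float(np.sum((by - beta * bx) ** 2 / sy**2))


def ivw(set_: HarmonizedInstrumentSet, model: str = "mre") -> MREstimate:
    """Inverse-variance-weighted estimate: WLS of beta_out on beta_exp through
    the origin with weights se_out^-2.

    ``model="mre"`` (default) inflates the fixed-effects SE by
    ``max(1, sqrt(Q/(J-1)))``; ``model="fixed"`` uses the fixed-effects SE.
    A single instrument falls back to the Wald ratio with a note.
    """
    if model not in ("fixed", "mre"):
        raise ValueError(f"unknown IVW model {model!r}")
    j = len(set_)
    if j == 0:
        raise NoInstrumentsError("IVW requires at least one instrument")
    if j == 1:
        est = wald_ratio(set_.beta_exp[0], set_.se_exp[0], set_.beta_out[0], set_.se_out[0])
        est.method = "ivw"
        est.notes = "single-SNP Wald fallback"
        return est
    beta, se = _ivw_fixed(set_.beta_exp, set_.beta_out, set_.se_out)
    notes = ""
    if model == "mre":
        q = _cochran_q(set_.beta_exp, set_.beta_out, set_.se_out, beta)
        inflation = max(1.0, np.sqrt(q / (j - 1)))
        se *= inflation
        notes = f"multiplicative random effects, inflation {inflation:.4g}"
    return _normal_estimate("ivw", beta, se, j, notes)


def egger(set_: HarmonizedInstrumentSet) -> tuple[MREstimate, MREstimate]:
    """MR-Egger: WLS of beta_out on beta_exp with a free intercept.

    Instruments are oriented so every exposure beta is non-negative; the
    slope estimates the causal effect and the intercept the average
    directional pleiotropy.  Residual variance is floored at 1 and p-values
    use a t distribution with J-2 degrees of freedom.
    """
    j = len(set_)
    if j < 3:
        raise InsufficientInstrumentsError(f"MR-Egger requires >= 3 instruments, got {j}")
    sign = np.where(set_.beta_exp < 0, -1.0, 1.0)
    bx = set_.beta_exp * sign
    by = set_.beta_out * sign
    sy = set_.se_out
    w = sy**-2.0
    x = np.column_stack([np.ones(j), bx])
    xtwx = x.T @ (w[:, None] * x)
    xtwy = x.T @ (w * by)
    coef = np.linalg.solve(xtwx, xtwy)
    resid = by - x @ coef
    sigma2 = max(1.0, float(np.sum(w * resid**2)) / (j - 2))
    cov = sigma2 * np.linalg.inv(xtwx)
    intercept, slope = float(coef[0]), float(coef[1])
    se_int, se_slope = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    df = j - 2
    tcrit = float(stats.t.ppf(0.975, df))

    def _t_estimate(method, beta, se):
        p = 2.0 * stats.t.sf(abs(beta) / se, df) if se > 0 else (1.0 if beta == 0 else _P_FLOOR)
        return MREstimate(
            method=method,
            beta=beta,
            se=se,
            ci_low=beta - tcrit * se,
            ci_high=beta + tcrit * se,
            pval=float(min(max(p, _P_FLOOR), 1.0)),
            n_snps=j,
        )

    return _t_estimate("egger_slope", slope, se_slope), _t_estimate(
        "egger_intercept", intercept, se_int
    )


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios, kind="stable")
    r = ratios[order]
    w = weights[order] / float(np.sum(weights))
    midpoints = np.cumsum(w) - w / 2.0
    return float(np.interp(0.5, midpoints, r))


def _bootstrap_se(set_, point_fn, n_boot, seed):
    rng = np.random.default_rng(seed)
    j = len(set_)
    est = np.empty(n_boot)
    for b in range(n_boot):
        bx = rng.normal(set_.beta_exp, set_.se_exp)
        by = rng.normal(set_.beta_out, set_.se_out)
        est[b] = point_fn(bx, by, set_.se_out)
    return float(np.std(est, ddof=1))


def weighted_median(
    set_: HarmonizedInstrumentSet, n_boot: int = 1000, seed: int = 0
) -> MREstimate:
    """Weighted median of per-SNP Wald ratios.

    Ratios are weighted by the inverse variance of the ratio (first order,
    ``(se_out/|beta_exp|)^-2``); the estimate interpolates the weighted
    cumulative midpoints at probability 0.5.  Consistent when valid
    instruments carry at least half the weight.  SE by parametric bootstrap.
    """
    j = len(set_)
    if j < 3:
        raise InsufficientInstrumentsError(
            f"weighted median requires >= 3 instruments, got {j}"
        )

    def point(bx, by, sy):
        ratios = by / bx
        weights = (sy / np.abs(bx)) ** -2.0
        return _weighted_median_point(ratios, weights)

    beta = point(set_.beta_exp, set_.beta_out, set_.se_out)
    se = _bootstrap_se(set_, point, n_boot, seed)
    return _normal_estimate("weighted_median", beta, se, j)


def _mode_point(bx, by, sy, weighted, bandwidth_factor):
    ratios = by / bx
    j = ratios.size
    if weighted:
        w = (sy / np.abs(bx)) ** -2.0
    else:
        w = np.ones(j)
    w = w / np.sum(w)
    sd = float(np.std(ratios, ddof=1)) if j > 1 else 0.0
    mad = float(np.median(np.abs(ratios - np.median(ratios))))
    spread = min(sd, mad / 0.6745) if mad > 0 else sd
    h = bandwidth_factor * 0.9 * spread * j ** (-1.0 / 5.0)
    if h <= 0:
        return float(ratios[0])
    grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, 512)
    dens = np.exp(-0.5 * ((grid[:, None] - ratios[None, :]) / h) ** 2) @ w
    return float(grid[int(np.argmax(dens))])


def mode_estimate(
    set_: HarmonizedInstrumentSet,
    weighted: bool = False,
    bandwidth_factor: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> MREstimate:
    """Simple- or weighted-mode estimate: the argmax of a normal-kernel
    density over per-SNP Wald ratios.

    Bandwidth ``h = bandwidth_factor * 0.9 * min(sd, mad/0.6745) * J^(-1/5)``
    evaluated on a 512-point grid spanning the ratios +- 3h.  Identical
    ratios (zero bandwidth) return the common ratio.  SE by parametric
    bootstrap.
    """
    j = len(set_)
    if j < 3:
        raise InsufficientInstrumentsError(
            f"mode estimator requires >= 3 instruments, got {j}"
        )

    def point(bx, by, sy):
        return _mode_point(bx, by, sy, weighted, bandwidth_factor)

    beta = point(set_.beta_exp, set_.beta_out, set_.se_out)
    se = _bootstrap_se(set_, point, n_boot, seed)
    method = "weighted_mode" if weighted else "simple_mode"
    return _normal_estimate(method, beta, se, j)


def all_estimates(
    set_: HarmonizedInstrumentSet,
    n_boot: int = 1000,
    seed: int = 0,
    ivw_model: str = "mre",
) -> dict[str, MREstimate]:
    """Run every estimator the instrument count permits.

    Returns a dict keyed by method tag; bootstrap-based methods derive
    distinct child seeds from ``seed``.
    """
    j = len(set_)
    if j == 0:
        raise NoInstrumentsError("no instruments")
    out: dict[str, MREstimate] = {}
    out["ivw"] = ivw(set_, model=ivw_model)
    if j >= 3:
        slope, intercept = egger(set_)
        out["egger_slope"] = slope
        out["egger_intercept"] = intercept
        ss = np.random.SeedSequence(seed).spawn(3)
        seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss]
        out["weighted_median"] = weighted_median(set_, n_boot=n_boot, seed=seeds[0])
        out["simple_mode"] = mode_estimate(set_, weighted=False, n_boot=n_boot, seed=seeds[1])
        out["weighted_mode"] = mode_estimate(set_, weighted=True, n_boot=n_boot, seed=seeds[2])
    return out
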