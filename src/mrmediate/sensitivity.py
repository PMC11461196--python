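"""Heterogeneity, pleiotropy, outlier and directionality diagnostics.

Each diagnostic is implemented from its definition on a harmonized
instrument set: Cochran's Q with first-order ratio weights, radial per-SNP Q
decomposition, the MR-Egger intercept, a simulation-based MR-PRESSO (global,
per-SNP outlier and distortion tests), the Steiger directionality test and
leave-one-out IVW.  Monte-Carlo p-values use the (1 + count)/(1 + n_sim)
estimator so they never reach zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import MREstimate, _ivw_fixed, ivw
from .sumstats import HarmonizedInstrumentSet, InsufficientInstrumentsError

__all__ = [
    "cochran_q",
    "radial_outliers",
    "egger_intercept_test",
    "mr_presso",
    "steiger",
    "leave_one_out",
    "funnel_scatter_export",
    "sensitivity_report",
    "PressoResult",
    "SteigerResult",
    "LeaveOneOutResult",
    "SensitivityReport",
]


def _ratio_weights(set_: HarmonizedInstrumentSet):
    ratios = set_.beta_out / set_.beta_exp
    weights = (set_.se_out / np.abs(set_.beta_exp)) ** -2.0
    return ratios, weights


def cochran_q(set_: HarmonizedInstrumentSet) -> tuple[float, int, float]:
    """Cochran's Q heterogeneity statistic with J-1 degrees of freedom.

    Q = sum_j w_j (ratio_j - beta_ivw_fixed)^2 with first-order ratio
    weights; equal to the weighted residual sum of squares of the fixed
    IVW fit.
    """
    j = len(set_)
    if j < 2:
        raise InsufficientInstrumentsError("Cochran's Q requires >= 2 instruments")
    ratios, w = _ratio_weights(set_)
    beta_fixed, _ = _ivw_fixed(set_.beta_exp, set_.beta_out, set_.se_out)
    q = float(np.sum(w * (ratios - beta_fixed) ** 2))
    df = j - 1
    pval = float(stats.chi2.sf(q, df))
    return q, df, max(pval, 5e-324)


def radial_outliers(set_: HarmonizedInstrumentSet, alpha: float = 0.05) -> pd.DataFrame:
    """Per-SNP contributions to Cochran's Q with Bonferroni outlier flags.

    Each contribution Q_j is referred to a chi-square(1) upper tail; a SNP is
    flagged when that tail probability falls below alpha/J.  Contributions
    sum exactly to Cochran's Q.
    """
    j = len(set_)
    if j < 3:
        raise InsufficientInstrumentsError("radial analysis requires >= 3 instruments")
    ratios, w = _ratio_weights(set_)
    beta_fixed, _ = _ivw_fixed(set_.beta_exp, set_.beta_out, set_.se_out)
    q_j = w * (ratios - beta_fixed) ** 2
    pvals = stats.chi2.sf(q_j, 1)
    return pd.DataFrame(
        {
            "snp_id": set_.snp_ids,
            "q_contribution": q_j,
            "pval": pvals,
            "outlier": pvals < alpha / j,
        }
    )


def egger_intercept_test(set_: HarmonizedInstrumentSet) -> tuple[float, float, float]:
    """MR-Egger intercept, SE and t(J-2) p-value (directional pleiotropy)."""
    from .estimators import egger

    _, intercept = egger(set_)
    return intercept.beta, intercept.se, intercept.pval


@dataclass
class PressoResult:
    global_rss: float
    global_pval: float
    outlier_ids: list[str]
    outlier_pvals: dict[str, float]
    distortion_pval: float | None
    n_sim: int

    @property
    def has_outliers(self) -> bool:
        return bool(self.outlier_ids)


def mr_presso(
    set_: HarmonizedInstrumentSet,
    n_sim: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> PressoResult:
    """MR-PRESSO: simulation-based global, outlier and distortion tests.

    The observed statistic is the weighted residual sum of squares
    ``sum_j w_j (by_j - beta_(-j) bx_j)^2`` where ``beta_(-j)`` is the fixed
    IVW estimate excluding SNP j.  ``n_sim`` replicate datasets are drawn
    with ``bx* ~ N(bx, sx)`` and ``by* ~ N(beta_(-j) bx, sy)`` and the same
    statistic recomputed; the global p is the Monte-Carlo tail.  Per-SNP
    outlier p-values compare each observed squared residual with its
    simulated distribution, Bonferroni-scaled by J.  When outliers are
    flagged, the distortion p is the two-sided Monte-Carlo tail of the
    difference between IVW with and without the flagged SNPs.
    """
    j = len(set_)
    if j < 4:
        raise InsufficientInstrumentsError("MR-PRESSO requires >= 4 instruments")
    rng = np.random.default_rng(seed)
    bx, sx = set_.beta_exp, set_.se_exp
    by, sy = set_.beta_out, set_.se_out
    w = sy**-2.0

    s1 = float(np.sum(w * bx * by))
    s2 = float(np.sum(w * bx * bx))
    beta_loo = (s1 - w * bx * by) / (s2 - w * bx * bx)
    res_obs = w * (by - beta_loo * bx) ** 2
    rss_obs = float(np.sum(res_obs))

    bx_s = rng.normal(bx, sx, size=(n_sim, j))
    by_s = rng.normal(beta_loo * bx, sy, size=(n_sim, j))
    s1_s = np.sum(w * bx_s * by_s, axis=1, keepdims=True)
    s2_s = np.sum(w * bx_s * bx_s, axis=1, keepdims=True)
    beta_loo_s = (s1_s - w * bx_s * by_s) / (s2_s - w * bx_s * bx_s)
    res_s = w * (by_s - beta_loo_s * bx_s) ** 2
    rss_s = np.sum(res_s, axis=1)

    global_pval = (1.0 + float(np.sum(rss_s >= rss_obs))) / (1.0 + n_sim)
    p_snp = (1.0 + np.sum(res_s >= res_obs[None, :], axis=0)) / (1.0 + n_sim)
    flagged = np.minimum(p_snp * j, 1.0) < alpha
    outlier_ids = [set_.snp_ids[i] for i in np.flatnonzero(flagged)]

    distortion_pval = None
    if outlier_ids and not np.all(flagged):
        keep = ~flagged
        beta_all, _ = _ivw_fixed(bx, by, sy)
        beta_wo, _ = _ivw_fixed(bx[keep], by[keep], sy[keep])
        d_obs = beta_all - beta_wo
        beta_all_s = (s1_s[:, 0]) / (s2_s[:, 0])
        s1_keep = np.sum((w * bx_s * by_s)[:, keep], axis=1)
        s2_keep = np.sum((w * bx_s * bx_s)[:, keep], axis=1)
        beta_wo_s = s1_keep / s2_keep
        d_s = beta_all_s - beta_wo_s
        distortion_pval = (1.0 + float(np.sum(np.abs(d_s) >= abs(d_obs)))) / (1.0 + n_sim)

    return PressoResult(
        global_rss=rss_obs,
        global_pval=global_pval,
        outlier_ids=outlier_ids,
        outlier_pvals={set_.snp_ids[i]: float(p_snp[i]) for i in range(j)},
        distortion_pval=distortion_pval,
        n_sim=n_sim,
    )


@dataclass
class SteigerResult:
    correct_direction: bool
    pval: float
    r2_exposure: float
    r2_outcome: float
    note: str = ""


def variance_explained(beta: float, se: float, n: int) -> float:
    """Per-SNP variance explained from a z-score: z^2 / (z^2 + n - 2)."""
    z2 = (beta / se) ** 2
    return z2 / (z2 + n - 2)


def steiger(
    set_: HarmonizedInstrumentSet, n_exposure: int, n_outcome: int
) -> SteigerResult:
    """Steiger directionality test.

    Sums per-SNP variance explained across instruments for each trait;
    the causal direction is supported when the instruments explain more
    variance in the exposure than the outcome.  The p-value uses the
    normal approximation on Fisher-transformed correlations from the two
    (independent) samples.  A tie yields statistic 0, p = 1 and the
    direction reported as not-correct with a note.
    """
    if n_exposure is None or n_outcome is None:
        raise ValueError("Steiger test requires sample sizes for both traits")
    zx2 = (set_.beta_exp / set_.se_exp) ** 2
    zy2 = (set_.beta_out / set_.se_out) ** 2
    r2x = float(np.sum(zx2 / (zx2 + n_exposure - 2)))
    r2y = float(np.sum(zy2 / (zy2 + n_outcome - 2)))
    rx = np.sqrt(min(r2x, 1.0 - 1e-12))
    ry = np.sqrt(min(r2y, 1.0 - 1e-12))
    if rx == ry:
        return SteigerResult(False, 1.0, r2x, r2y, note="tie: equal variance explained")
    z = (np.arctanh(rx) - np.arctanh(ry)) / np.sqrt(
        1.0 / (n_exposure - 3) + 1.0 / (n_outcome - 3)
    )
    pval = float(min(max(2.0 * stats.norm.sf(abs(z)), 5e-324), 1.0))
    return SteigerResult(r2x > r2y, pval, r2x, r2y)


@dataclass
class LeaveOneOutResult:
    estimates: list[tuple[str, MREstimate]]
    influential: bool
    details: list[str] = field(default_factory=list)


def leave_one_out(
    set_: HarmonizedInstrumentSet, alpha: float = 0.05, model: str = "mre"
) -> LeaveOneOutResult:
    """J IVW estimates, each omitting one SNP.

    Flags the set as influenced by a single SNP when any omission flips the
    sign of the estimate or moves its p-value across ``alpha`` relative to
    the full-set estimate.
    """
    j = len(set_)
    if j < 3:
        raise InsufficientInstrumentsError("leave-one-out requires >= 3 instruments")
    full = ivw(set_, model=model)
    out: list[tuple[str, MREstimate]] = []
    details: list[str] = []
    influential = False
    for i in range(j):
        keep = np.ones(j, dtype=bool)
        keep[i] = False
        est = ivw(set_.subset(keep), model=model)
        out.append((set_.snp_ids[i], est))
        if np.sign(est.beta) != np.sign(full.beta) and full.beta != 0:
            influential = True
            details.append(f"{set_.snp_ids[i]}: omission flips effect sign")
        if (est.pval < alpha) != (full.pval < alpha):
            influential = True
            details.append(f"{set_.snp_ids[i]}: omission moves p across {alpha}")
    return LeaveOneOutResult(out, influential, details)


def funnel_scatter_export(
    set_: HarmonizedInstrumentSet, estimates: dict[str, MREstimate] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Plot-data tables for funnel and scatter diagnostics (no rendering).

    Returns ``(funnel, scatter, lines)``: per-SNP (ratio, precision) pairs,
    per-SNP harmonized effects, and one fitted line per estimate (Egger
    keeps its intercept; all other methods pass through the origin).
    """
    estimates = estimates or {}
    if len(set_):
        ratios, weights = _ratio_weights(set_)
        funnel = pd.DataFrame(
            {"snp_id": set_.snp_ids, "ratio": ratios, "precision": np.sqrt(weights)}
        )
    else:
        funnel = pd.DataFrame(columns=["snp_id", "ratio", "precision"])
    scatter = pd.DataFrame(
        {
            "snp_id": set_.snp_ids,
            "beta_exposure": set_.beta_exp,
            "se_exposure": set_.se_exp,
            "beta_outcome": set_.beta_out,
            "se_outcome": set_.se_out,
        }
    )
    intercept = estimates.get("egger_intercept")
    rows = []
    for method, est in estimates.items():
        if method == "egger_intercept":
            continue
        b0 = intercept.beta if (method == "egger_slope" and intercept) else 0.0
        rows.append({"method": method, "slope": est.beta, "intercept": b0})
    lines = pd.DataFrame(rows, columns=["method", "slope", "intercept"])
    return funnel, scatter, lines


@dataclass
class SensitivityReport:
    """Bundle of diagnostics for one exposure-outcome pair."""

    q: float | None = None
    q_df: int | None = None
    q_pval: float | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_pval: float | None = None
    radial: list[dict] = field(default_factory=list)
    presso_global_pval: float | None = None
    presso_outliers: list[str] = field(default_factory=list)
    presso_distortion_pval: float | None = None
    steiger_correct_direction: bool | None = None
    steiger_pval: float | None = None
    steiger_note: str = ""
    loo_influential: bool | None = None
    loo: list[dict] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    def to_json(self, **kwargs) -> str:
        return json.dumps(asdict(self), **kwargs)


def sensitivity_report(
    set_: HarmonizedInstrumentSet,
    n_exposure: int | None = None,
    n_outcome: int | None = None,
    n_sim: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> SensitivityReport:
    """Run the full diagnostic battery, skipping (with a note) any component
    the instrument count or missing sample sizes do not permit."""
    rep = SensitivityReport()
    j = len(set_)
    if j >= 2:
        rep.q, rep.q_df, rep.q_pval = cochran_q(set_)
    else:
        rep.notes.append("cochran_q: not computed (J < 2)")
    if j >= 3:
        rep.egger_intercept, rep.egger_intercept_se, rep.egger_intercept_pval = (
            egger_intercept_test(set_)
        )
        rep.radial = radial_outliers(set_, alpha=alpha).to_dict("records")
        loo = leave_one_out(set_, alpha=alpha)
        rep.loo_influential = loo.influential
        rep.loo = [
            {"omitted": snp, **est.to_dict()} for snp, est in loo.estimates
        ]
    else:
        rep.notes.append("egger/radial/leave-one-out: not computed (J < 3)")
    if j >= 4:
        presso = mr_presso(set_, n_sim=n_sim, seed=seed, alpha=alpha)
        rep.presso_global_pval = presso.global_pval
        rep.presso_outliers = presso.outlier_ids
        rep.presso_distortion_pval = presso.distortion_pval
    else:
        rep.notes.append("mr_presso: not computed (J < 4)")
    if n_exposure is not None and n_outcome is not None:
        st = steiger(set_, n_exposure, n_outcome)
        rep.steiger_correct_direction = st.correct_direction
        rep.steiger_pval = st.pval
        rep.steiger_note = st.note
    else:
        rep.notes.append("steiger: not computed (sample sizes unavailable)")
    return rep
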