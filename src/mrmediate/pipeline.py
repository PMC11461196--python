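"""Pair-level orchestration: bidirectional MR, pair classification,
multiple-testing adjustment and report export.

A "pair" is one exposure-outcome combination; the screen runs MR in both
directions with the full sensitivity battery, classifies each pair from the
significance of the two IVW estimates, excludes pairs whose MR-PRESSO
global test indicates horizontal pleiotropy, and annotates heterogeneity.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from . import __version__
from .estimators import MREstimate, all_estimates, egger, ivw, mode_estimate, weighted_median
from .mediation import MediationResult
from .sensitivity import SensitivityReport, funnel_scatter_export, sensitivity_report, variance_explained
from .sumstats import (
    HarmonizedInstrumentSet,
    InstrumentSelection,
    InstrumentSelectionConfig,
    LDMatrix,
    VariantAssociation,
    harmonize,
    select_instruments,
)

__all__ = [
    "LegResult",
    "PairResult",
    "PairClassification",
    "run_mr",
    "run_pair",
    "classify_pair",
    "adjust_pvalues",
    "report",
]


@dataclass
class LegResult:
    """One direction of MR for one pair."""

    exposure_name: str
    outcome_name: str
    status: str  # "ok" | "no-instruments"
    selection: InstrumentSelection | None = None
    hset: HarmonizedInstrumentSet | None = None
    estimates: dict[str, MREstimate] = field(default_factory=dict)
    sensitivity: SensitivityReport | None = None

    @property
    def estimate(self) -> MREstimate | None:
        """The primary (requested-method) estimate, IVW unless overridden."""
        return self._primary

    _primary: MREstimate | None = None


def _steiger_keep(
    candidates: Sequence[VariantAssociation],
    other_tables: Sequence[Sequence[VariantAssociation]],
) -> list[VariantAssociation]:
    """Keep candidates that explain more variance in the leg's exposure than
    in each comparison trait; SNPs that cannot be evaluated (missing from a
    comparison table or lacking n) are kept."""
    others = [{r.snp_id: r for r in tab} for tab in other_tables]
    kept = []
    for rec in candidates:
        if rec.n is None:
            kept.append(rec)
            continue
        r2_here = variance_explained(rec.beta, rec.se, rec.n)
        ok = True
        for table in others:
            o = table.get(rec.snp_id)
            if o is None or o.n is None:
                continue
            if variance_explained(o.beta, o.se, o.n) >= r2_here:
                ok = False
                break
        if ok:
            kept.append(rec)
    return kept


_METHOD_KEY = {
    "ivw": "ivw",
    "egger": "egger_slope",
    "weighted_median": "weighted_median",
    "simple_mode": "simple_mode",
    "weighted_mode": "weighted_mode",
}


def run_mr(
    exposure: Sequence[VariantAssociation],
    outcome: Sequence[VariantAssociation],
    cfg: InstrumentSelectionConfig | None = None,
    method: str = "ivw",
    seed: int = 0,
    sparse: bool = False,
    ld: LDMatrix | None = None,
    steiger_filter_vs: Sequence[Sequence[VariantAssociation]] | None = None,
    all_methods: bool = False,
    sensitivity: bool = False,
    n_sim: int = 1000,
    n_boot: int = 1000,
    alpha: float = 0.05,
    ivw_model: str = "mre",
    exposure_name: str = "exposure",
    outcome_name: str = "outcome",
) -> LegResult:
    """One MR leg: select instruments from the exposure table, optionally
    Steiger-filter them against other traits, harmonize against the outcome
    table, estimate, and (optionally) run the sensitivity battery."""
    cfg = cfg or InstrumentSelectionConfig()
    if method not in _METHOD_KEY:
        raise ValueError(f"unknown method {method!r}")
    selection = select_instruments(exposure, cfg, ld=ld, sparse=sparse)
    instruments = selection.instruments
    if steiger_filter_vs and instruments:
        instruments = _steiger_keep(instruments, steiger_filter_vs)
    leg = LegResult(exposure_name, outcome_name, "ok", selection=selection)
    if not instruments:
        leg.status = "no-instruments"
        return leg
    hset = harmonize(
        instruments,
        outcome,
        palindrome_eaf_window=cfg.palindrome_eaf_window,
        exposure_name=exposure_name,
        outcome_name=outcome_name,
    )
    if len(hset) == 0:
        leg.status = "no-instruments"
        return leg
    leg.hset = hset
    if all_methods:
        leg.estimates = all_estimates(hset, n_boot=n_boot, seed=seed, ivw_model=ivw_model)
    else:
        if method == "ivw" or len(hset) < 3:
            leg.estimates = {"ivw": ivw(hset, model=ivw_model)}
        elif method == "egger":
            slope, intercept = egger(hset)
            leg.estimates = {"egger_slope": slope, "egger_intercept": intercept}
        elif method == "weighted_median":
            leg.estimates = {"weighted_median": weighted_median(hset, n_boot=n_boot, seed=seed)}
        else:
            leg.estimates = {
                _METHOD_KEY[method]: mode_estimate(
                    hset, weighted=(method == "weighted_mode"), n_boot=n_boot, seed=seed
                )
            }
    key = _METHOD_KEY[method]
    leg._primary = leg.estimates.get(key, leg.estimates.get("ivw"))
    if sensitivity:
        n_exp = _median_n(instruments)
        n_out = _median_n(outcome)
        leg.sensitivity = sensitivity_report(
            hset, n_exposure=n_exp, n_outcome=n_out, n_sim=n_sim, seed=seed, alpha=alpha
        )
    return leg


def _median_n(records: Sequence[VariantAssociation]) -> int | None:
    ns = [r.n for r in records if r.n is not None]
    return int(np.median(ns)) if ns else None


@dataclass
class PairResult:
    exposure_name: str
    outcome_name: str
    forward: LegResult
    reverse: LegResult


@dataclass
class PairClassification:
    exposure: str
    outcome: str
    category: str  # none | forward_only | reverse_only | bidirectional | not-estimable
    mediation_candidate: bool
    forward_pval: float | None
    reverse_pval: float | None
    excluded_reason: str | None = None
    heterogeneity: bool = False


def run_pair(
    exposure: Sequence[VariantAssociation],
    outcome: Sequence[VariantAssociation],
    cfg: InstrumentSelectionConfig | None = None,
    alpha: float = 0.05,
    seed: int = 0,
    sparse_forward: bool = False,
    sparse_reverse: bool = False,
    n_sim: int = 1000,
    n_boot: int = 1000,
    exposure_name: str = "exposure",
    outcome_name: str = "outcome",
    sensitivity: bool = True,
    steiger_filter: bool = False,
) -> PairResult:
    """Bidirectional MR for one pair: all estimators plus the sensitivity
    battery in each direction.

    ``steiger_filter=True`` drops, in each direction, candidate instruments
    that explain more variance in the target trait than in the trait they
    instrument (per-SNP Steiger filtering), so a purely forward causal
    signal is not re-detected as a spurious reverse effect.
    """
    cfg = cfg or InstrumentSelectionConfig()
    s_fwd, s_rev = [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(seed).spawn(2)
    ]
    forward = run_mr(
        exposure,
        outcome,
        cfg=cfg,
        seed=s_fwd,
        sparse=sparse_forward,
        steiger_filter_vs=[outcome] if steiger_filter else None,
        all_methods=True,
        sensitivity=sensitivity,
        n_sim=n_sim,
        n_boot=n_boot,
        alpha=alpha,
        exposure_name=exposure_name,
        outcome_name=outcome_name,
    )
    reverse = run_mr(
        outcome,
        exposure,
        cfg=cfg,
        seed=s_rev,
        sparse=sparse_reverse,
        steiger_filter_vs=[exposure] if steiger_filter else None,
        all_methods=True,
        sensitivity=sensitivity,
        n_sim=n_sim,
        n_boot=n_boot,
        alpha=alpha,
        exposure_name=outcome_name,
        outcome_name=exposure_name,
    )
    return PairResult(exposure_name, outcome_name, forward, reverse)


def classify_pair(
    forward: LegResult, reverse: LegResult, alpha: float = 0.05
) -> PairClassification:
    """Classify a pair from the significance of its two IVW estimates.

    ``bidirectional`` iff both directions are significant at ``alpha``
    (strict <); a pair whose forward MR-PRESSO global p < alpha is excluded
    as horizontally pleiotropic; heterogeneity (Cochran's Q p < alpha) is
    annotated but not exclusionary.  A pair is a mediation candidate when
    the forward effect is significant and the reverse is not.
    """
    p_fwd = forward.estimate.pval if forward.status == "ok" else None
    p_rev = reverse.estimate.pval if reverse.status == "ok" else None
    if p_fwd is None and p_rev is None:
        category = "not-estimable"
    else:
        fwd_sig = p_fwd is not None and p_fwd < alpha
        rev_sig = p_rev is not None and p_rev < alpha
        category = {
            (True, True): "bidirectional",
            (True, False): "forward_only",
            (False, True): "reverse_only",
            (False, False): "none",
        }[(fwd_sig, rev_sig)]
    excluded = None
    if (
        forward.sensitivity is not None
        and forward.sensitivity.presso_global_pval is not None
        and forward.sensitivity.presso_global_pval < alpha
    ):
        excluded = "presso-pleiotropy"
    het = bool(
        forward.sensitivity is not None
        and forward.sensitivity.q_pval is not None
        and forward.sensitivity.q_pval < alpha
    )
    return PairClassification(
        exposure=forward.exposure_name,
        outcome=forward.outcome_name,
        category=category,
        mediation_candidate=(
            category in ("forward_only",) and excluded is None
        ),
        forward_pval=p_fwd,
        reverse_pval=p_rev,
        excluded_reason=excluded,
        heterogeneity=het,
    )


def adjust_pvalues(pvals: Sequence[float], method: str = "none") -> np.ndarray:
    """Multiple-testing adjustment: identity, Bonferroni, or Benjamini-
    Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must be in (0, 1]")
    if method == "none":
        return p.copy()
    if method == "bonferroni":
        return np.minimum(p * p.size, 1.0)
    if method == "bh":
        return multipletests(p, method="fdr_bh")[1]
    raise ValueError(f"unknown adjustment method {method!r}")


_FLOAT_FMT = "%.10g"


def _estimate_rows(pair: PairResult):
    for direction, leg in (("forward", pair.forward), ("reverse", pair.reverse)):
        for est in leg.estimates.values():
            yield {
                "exposure": leg.exposure_name,
                "outcome": leg.outcome_name,
                "direction": direction,
                **est.to_dict(),
            }


def report(
    results: dict,
    outdir: str | Path,
    config: dict | None = None,
    seed: int | None = None,
) -> dict[str, Path]:
    """Write a tidy result bundle.

    ``results`` may hold ``pairs`` (list of PairResult), ``classifications``
    (list of PairClassification) and ``mediations`` (list of
    MediationResult).  Emits per-method estimates TSV, a mediation table
    shaped like a published forest-plot table (mediation results failing the
    reverse-causation screen are withheld from the table and listed in the
    log), sensitivity JSON, funnel/scatter plot data and a run log.
    Reruns with the same inputs, config and seed are byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    pairs: list[PairResult] = results.get("pairs", [])
    rows = [row for pair in pairs for row in _estimate_rows(pair)]
    est_cols = [
        "exposure", "outcome", "direction", "method", "nsnp",
        "beta", "se", "ci_low", "ci_high", "pval", "notes",
    ]
    est_df = pd.DataFrame(rows, columns=est_cols)
    path = outdir / "estimates.tsv"
    est_df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    written["estimates"] = path

    mediations: list[MediationResult] = results.get("mediations", [])
    reported = [m for m in mediations if m.reverse_screen_passed]
    withheld = [m for m in mediations if not m.reverse_screen_passed]
    med_cols = [
        "exposure", "mediator", "outcome", "total_effect", "total_ci_low",
        "total_ci_high", "direct_effect_A", "direct_A_ci_low",
        "direct_A_ci_high", "direct_effect_B", "direct_B_ci_low",
        "direct_B_ci_high", "mediated_effect", "mediated_ci_low",
        "mediated_ci_high", "mediated_pval", "direct_effect",
        "proportion_pct", "proportion_ci_low_pct", "proportion_ci_high_pct",
        "reverse_screen_passed",
    ]
    med_df = pd.DataFrame([m.to_table_row() for m in reported], columns=med_cols)
    path = outdir / "mediation.tsv"
    med_df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    written["mediation"] = path

    sens = {}
    for pair in pairs:
        for direction, leg in (("forward", pair.forward), ("reverse", pair.reverse)):
            if leg.sensitivity is not None:
                key = f"{leg.exposure_name}->{leg.outcome_name} ({direction})"
                sens[key] = json.loads(leg.sensitivity.to_json())
    path = outdir / "sensitivity.json"
    with open(path, "w") as fh:
        json.dump(sens, fh, indent=2, sort_keys=True)
        fh.write("\n")
    written["sensitivity"] = path

    funnel_frames, scatter_frames, line_frames = [], [], []
    for pair in pairs:
        leg = pair.forward
        if leg.hset is not None:
            funnel, scatter, lines = funnel_scatter_export(leg.hset, leg.estimates)
            for frame in (funnel, scatter, lines):
                frame.insert(0, "exposure", leg.exposure_name)
                frame.insert(1, "outcome", leg.outcome_name)
            funnel_frames.append(funnel)
            scatter_frames.append(scatter)
            line_frames.append(lines)
    for name, frames, cols in (
        ("funnel", funnel_frames, ["exposure", "outcome", "snp_id", "ratio", "precision"]),
        (
            "scatter",
            scatter_frames,
            ["exposure", "outcome", "snp_id", "beta_exposure", "se_exposure",
             "beta_outcome", "se_outcome"],
        ),
        ("scatter_lines", line_frames, ["exposure", "outcome", "method", "slope", "intercept"]),
    ):
        frame = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=cols)
        path = outdir / f"{name}.tsv"
        frame.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
        written[name] = path

    classifications = results.get("classifications", [])
    if classifications:
        cls_df = pd.DataFrame([vars(c) for c in classifications])
        path = outdir / "classifications.tsv"
        cls_df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
        written["classifications"] = path

    log = {
        "package": "mrmediate",
        "version": __version__,
        "seed": seed,
        "config": config or {},
        "n_pairs": len(pairs),
        "n_mediations_reported": len(reported),
        "mediations_withheld_by_reverse_screen": [
            f"{m.exposure_name}|{m.mediator_name}|{m.outcome_name}" for m in withheld
        ],
    }
    path = outdir / "run_log.json"
    with open(path, "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
        fh.write("\n")
    written["log"] = path
    return written
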