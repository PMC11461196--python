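"""Two-step mediation MR: decompose a total causal effect into direct and
mediator-carried components with delta-method uncertainty.

Notation follows the standard mediation decomposition: C is the total effect
of the exposure on the outcome, E the effect of the exposure on the
mediator, F the effect of the mediator on the outcome.  The mediated effect
is E*F, the direct effect C' = C - E*F, and the mediated proportion
(E*F)/C.  The 95% interval for E*F uses the first-order delta method,
se(EF) = sqrt(E^2 se_F^2 + F^2 se_E^2), with critical value 1.96.

Two proportion intervals are reported: ``ci_proportion`` divides the
mediated-effect CI bounds by the total-effect point estimate (the convention
used in published mediation-MR tables; it conditions on C), and
``ci_proportion_delta`` propagates the uncertainty of E, F and C jointly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats

from .estimators import MREstimate
from .sumstats import InstrumentSelectionConfig

__all__ = [
    "MediationResult",
    "MediationError",
    "mediated_effect",
    "delta_se_product",
    "product_estimate",
    "mediated_proportion",
    "two_step_mediation",
]

_Z95 = 1.96
_P_FLOOR = 5e-324


class MediationError(ValueError):
    """A mediation leg could not be estimated (names the failing leg)."""


def mediated_effect(E: float, F: float) -> float:
    """Mediated (indirect) effect: the product E * F."""
    return E * F


def delta_se_product(E: float, se_E: float, F: float, se_F: float) -> float:
    """First-order delta-method SE of the product E*F:
    sqrt(E^2 se_F^2 + F^2 se_E^2)."""
    if se_E < 0 or se_F < 0:
        raise ValueError("standard errors must be non-negative")
    return float(np.sqrt(E**2 * se_F**2 + F**2 * se_E**2))


def product_estimate(
    E: float, se_E: float, F: float, se_F: float
) -> tuple[float, float, tuple[float, float], float]:
    """Mediated effect with delta-method SE, 95% CI and two-sided p."""
    ef = mediated_effect(E, F)
    se = delta_se_product(E, se_E, F, se_F)
    ci = (ef - _Z95 * se, ef + _Z95 * se)
    if se > 0:
        p = float(min(max(2.0 * stats.norm.sf(abs(ef) / se), _P_FLOOR), 1.0))
    else:
        p = 1.0 if ef == 0 else _P_FLOOR
    return ef, se, ci, p


def mediated_proportion(
    EF: float, ci_EF: tuple[float, float], C: float
) -> tuple[float, tuple[float, float]]:
    """Mediated proportion EF/C with its interval ci_EF/C.

    Bounds are swapped when C < 0 so low <= high.  A proportion outside
    [-1, 1] is allowed but flagged with a warning (inconsistent mediation).
    """
    if C == 0:
        raise ZeroDivisionError("mediated proportion undefined for total effect C = 0")
    prop = EF / C
    lo, hi = ci_EF[0] / C, ci_EF[1] / C
    if lo > hi:
        lo, hi = hi, lo
    if abs(prop) > 1:
        warnings.warn(
            f"mediated proportion {prop:.3g} outside [-1, 1]: inconsistent mediation",
            stacklevel=2,
        )
    return prop, (lo, hi)


@dataclass
class MediationResult:
    """C / E / F decomposition with intervals.

    Invariants (held exactly as computed): ``mediated_EF == step_E.beta *
    step_F.beta``, ``direct_Cprime == total_C.beta - mediated_EF``,
    ``proportion == mediated_EF / total_C.beta``.
    """

    exposure_name: str
    mediator_name: str
    outcome_name: str
    total_C: MREstimate
    step_E: MREstimate
    step_F: MREstimate
    mediated_EF: float
    se_EF: float
    ci_EF: tuple[float, float]
    pval_mediated: float
    direct_Cprime: float
    proportion: float
    ci_proportion: tuple[float, float]
    ci_proportion_delta: tuple[float, float]
    reverse_screen_passed: bool = True
    reverse_pval: float | None = None
    reverse_beta: float | None = None
    notes: list[str] = field(default_factory=list)

    @property
    def proportion_pct(self) -> float:
        return 100.0 * self.proportion

    def to_json(self, **kwargs) -> str:
        d = asdict(self)
        return json.dumps(d, default=str, **kwargs)

    def to_table_row(self) -> dict:
        """One row shaped like a published mediation table."""
        return {
            "exposure": self.exposure_name,
            "mediator": self.mediator_name,
            "outcome": self.outcome_name,
            "total_effect": self.total_C.beta,
            "total_ci_low": self.total_C.ci_low,
            "total_ci_high": self.total_C.ci_high,
            "direct_effect_A": self.step_E.beta,
            "direct_A_ci_low": self.step_E.ci_low,
            "direct_A_ci_high": self.step_E.ci_high,
            "direct_effect_B": self.step_F.beta,
            "direct_B_ci_low": self.step_F.ci_low,
            "direct_B_ci_high": self.step_F.ci_high,
            "mediated_effect": self.mediated_EF,
            "mediated_ci_low": self.ci_EF[0],
            "mediated_ci_high": self.ci_EF[1],
            "mediated_pval": self.pval_mediated,
            "direct_effect": self.direct_Cprime,
            "proportion_pct": self.proportion_pct,
            "proportion_ci_low_pct": 100.0 * self.ci_proportion[0],
            "proportion_ci_high_pct": 100.0 * self.ci_proportion[1],
            "reverse_screen_passed": self.reverse_screen_passed,
        }


def assemble_mediation(
    total_C: MREstimate,
    step_E: MREstimate,
    step_F: MREstimate,
    exposure_name: str = "exposure",
    mediator_name: str = "mediator",
    outcome_name: str = "outcome",
    reverse_screen_passed: bool = True,
    reverse_pval: float | None = None,
    reverse_beta: float | None = None,
    notes: list[str] | None = None,
) -> MediationResult:
    """Assemble a MediationResult from the three leg estimates.

    Used both by :func:`two_step_mediation` and when the legs were computed
    separately (composition identity: the assembled result is a pure
    function of the three estimates).
    """
    E, F, C = step_E.beta, step_F.beta, total_C.beta
    ef, se_ef, ci_ef, p_med = product_estimate(E, step_E.se, F, step_F.se)
    prop, ci_prop = mediated_proportion(ef, ci_ef, C)
    # full first-order delta for the ratio EF/C, including var(C)
    se_prop = float(
        np.sqrt(
            (F / C) ** 2 * step_E.se**2
            + (E / C) ** 2 * step_F.se**2
            + (ef / C**2) ** 2 * total_C.se**2
        )
    )
    ci_prop_delta = (prop - _Z95 * se_prop, prop + _Z95 * se_prop)
    return MediationResult(
        exposure_name=exposure_name,
        mediator_name=mediator_name,
        outcome_name=outcome_name,
        total_C=total_C,
        step_E=step_E,
        step_F=step_F,
        mediated_EF=ef,
        se_EF=se_ef,
        ci_EF=ci_ef,
        pval_mediated=p_med,
        direct_Cprime=C - ef,
        proportion=prop,
        ci_proportion=ci_prop,
        ci_proportion_delta=ci_prop_delta,
        reverse_screen_passed=reverse_screen_passed,
        reverse_pval=reverse_pval,
        reverse_beta=reverse_beta,
        notes=list(notes or []),
    )


def two_step_mediation(
    exposure_stats,
    mediator_stats,
    outcome_stats,
    cfg: InstrumentSelectionConfig | None = None,
    estimator: str = "ivw",
    seed: int = 0,
    alpha: float = 0.05,
    reverse_rule: str = "nonsignificant",
    mediator_filter: bool = True,
    exposure_name: str = "exposure",
    mediator_name: str = "mediator",
    outcome_name: str = "outcome",
) -> MediationResult:
    """Two-step mediation MR from three summary-statistics tables.

    Runs three MR legs, each with its own instrument selection and
    harmonization: C (exposure -> outcome), E (exposure -> mediator) and
    F (mediator -> outcome).  With ``mediator_filter=True`` (default) the
    mediator-leg instruments are Steiger-filtered against the exposure so
    SNPs acting on the mediator through the exposure do not masquerade as
    mediator instruments.

    A reverse-causation screen (outcome -> exposure MR, Steiger-filtered the
    same way) is always computed; ``reverse_rule`` decides when it passes:
    ``"nonsignificant"`` requires the reverse IVW p >= alpha,
    ``"negative"`` requires a negative reverse point estimate.  The screen's
    verdict is recorded on the result (``reverse_screen_passed``); the
    reporting layer withholds mediation results that fail it.

    Raises :class:`MediationError` naming the leg when C, E or F lacks
    instruments.
    """
    from .pipeline import run_mr  # local import: pipeline imports this module

    cfg = cfg or InstrumentSelectionConfig()
    seeds = [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(seed).spawn(4)
    ]
    notes: list[str] = []

    legs = {}
    leg_plan = {
        "total (exposure->outcome)": (exposure_stats, outcome_stats, None, seeds[0]),
        "step E (exposure->mediator)": (exposure_stats, mediator_stats, None, seeds[1]),
        "step F (mediator->outcome)": (
            mediator_stats,
            outcome_stats,
            exposure_stats if mediator_filter else None,
            seeds[2],
        ),
    }
    for name, (exp, out, filt, s) in leg_plan.items():
        leg = run_mr(
            exp,
            out,
            cfg=cfg,
            method=estimator,
            seed=s,
            steiger_filter_vs=[filt] if filt is not None else None,
        )
        if leg.status != "ok":
            raise MediationError(f"{name}: no instruments after selection")
        legs[name] = leg

    reverse = run_mr(
        outcome_stats,
        exposure_stats,
        cfg=cfg,
        method="ivw",
        seed=seeds[3],
        steiger_filter_vs=[exposure_stats] if mediator_filter else None,
    )
    if reverse.status != "ok":
        passed = True
        rev_p = None
        rev_b = None
        notes.append("reverse screen: no reverse instruments; screen passes vacuously")
    else:
        rev_p = reverse.estimate.pval
        rev_b = reverse.estimate.beta
        if reverse_rule == "nonsignificant":
            passed = rev_p >= alpha
        elif reverse_rule == "negative":
            passed = rev_b < 0
        else:
            raise ValueError(f"unknown reverse_rule {reverse_rule!r}")
        if not passed:
            notes.append(
                f"reverse screen failed (rule={reverse_rule}, "
                f"beta={rev_b:.4g}, p={rev_p:.3g})"
            )

    return assemble_mediation(
        total_C=legs["total (exposure->outcome)"].estimate,
        step_E=legs["step E (exposure->mediator)"].estimate,
        step_F=legs["step F (mediator->outcome)"].estimate,
        exposure_name=exposure_name,
        mediator_name=mediator_name,
        outcome_name=outcome_name,
        reverse_screen_passed=passed,
        reverse_pval=rev_p,
        reverse_beta=rev_b,
        notes=notes,
    )
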