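"""Shared result containers for effect estimates."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class EffectEstimate:
    """One comparison-by-visit treatment effect with Wald inference.

    ``scale`` is "difference" for identity-scale outcomes and "ratio" for
    exponentiated (log-scale) effects — geometric-mean ratios, prevalence
    or risk ratios, odds ratios, incidence-rate ratios, with the specific
    flavour recorded in ``label``.
    """
    comparison: tuple
    visit: int | None
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    ci_level: float
    p_unadjusted: float
    p_adjusted: float | None = None
    scale: str = "difference"
    label: str | None = None
    estimable: bool = True

    def __post_init__(self):
        if self.estimable and not np.isnan(self.estimate):
            if not (self.ci_low <= self.estimate <= self.ci_high):
                raise ValueError("confidence interval must contain the "
                                 "estimate")
            if self.scale == "ratio" and self.ci_low < 0:
                raise ValueError("ratio-scale CI must be positive")

    def to_dict(self) -> dict:
        return {
            "comparison": "_vs_".join(self.comparison),
            "visit": self.visit, "estimate": self.estimate, "se": self.se,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "ci_level": self.ci_level, "p_unadjusted": self.p_unadjusted,
            "p_adjusted": self.p_adjusted, "scale": self.scale,
            "label": self.label, "estimable": self.estimable,
        }


def wald_effect(comparison, visit, est, se, ci_level, log_scale=False,
                label=None) -> EffectEstimate:
    """Build an EffectEstimate from a point estimate and SE on the linear
    (possibly log) scale, using the normal reference."""
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    lo, hi = est - z * se, est + z * se
    if se > 0:
        p = 2.0 * stats.norm.sf(abs(est) / se)
    else:
        p = np.nan
    if log_scale:
        est, lo, hi = np.exp(est), np.exp(lo), np.exp(hi)
        scale = "ratio"
    else:
        scale = "difference"
    return EffectEstimate(
        comparison=tuple(comparison), visit=visit, estimate=float(est),
        se=float(se), ci_low=float(lo), ci_high=float(hi),
        ci_level=float(ci_level), p_unadjusted=float(p), scale=scale,
        label=label)


def non_estimable(comparison, visit, ci_level, label=None) -> EffectEstimate:
    return EffectEstimate(
        comparison=tuple(comparison), visit=visit, estimate=float("nan"),
        se=float("nan"), ci_low=float("nan"), ci_high=float("nan"),
        ci_level=ci_level, p_unadjusted=float("nan"), label=label,
        estimable=False)
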