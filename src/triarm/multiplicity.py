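"""Serial gatekeeping and Hochberg multiplicity control.

The decision tree for the primary outcome, at overall two-sided level
alpha (default 5%):

* each primary hypothesis (iron vs placebo, MNPs vs placebo) is tested at
  alpha/2 (Bonferroni);
* the head-to-head comparison (iron vs MNPs) is tested only if at least
  one primary is rejected — at alpha/2 if exactly one was rejected, at
  the full alpha if both were;
* if neither primary is rejected the head-to-head hypothesis is untested:
  its estimate is reported with a 95% CI and the p-value is suppressed.

Confidence levels always match the assigned test level (CI level =
1 − assigned alpha). Adjusted p-values are the smallest overall alpha at
which the full procedure rejects the hypothesis, so "rejected at overall
alpha" and "adjusted p ≤ alpha" coincide for every alpha.

Key-secondary endpoints form one Hochberg family per pairwise comparison,
tested at the level used for that comparison's primary test, and only
when the corresponding primary null was rejected (the gate). Month-3 and
month-12 procedures run independently.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

DEFAULT_ALPHA = 0.05
PRIMARY_LABELS = ("iron_vs_placebo", "mnp_vs_placebo")
HEAD_TO_HEAD = "iron_vs_mnp"


@dataclass
class HypothesisDecision:
    label: str
    p_unadjusted: float
    assigned_alpha: float | None     # None when the gate never opened
    rejected: bool
    p_adjusted: float | None         # None when suppressed
    ci_level: float

    def to_dict(self):
        return self.__dict__.copy()


@dataclass
class MultiplicityOutcome:
    decisions: dict = field(default_factory=dict)
    overall_alpha: float = DEFAULT_ALPHA
    trace: list = field(default_factory=list)

    def __getitem__(self, label) -> HypothesisDecision:
        return self.decisions[label]

    @property
    def any_rejection(self) -> bool:
        return any(d.rejected for d in self.decisions.values())

    def to_json(self) -> str:
        return json.dumps({
            "overall_alpha": self.overall_alpha,
            "decisions": {k: d.to_dict() for k, d in self.decisions.items()},
            "trace": self.trace,
        }, indent=2)


def _validate(p):
    p = float(p)
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value {p} outside [0, 1]")
    return p


def gatekeeper_primary(p_iron: float, p_mnp: float, p_head_to_head: float,
                       overall_alpha: float = DEFAULT_ALPHA
                       ) -> MultiplicityOutcome:
    """Run the primary-outcome gatekeeping tree on three p-values."""
    p_iron, p_mnp, p_hh = map(_validate, (p_iron, p_mnp, p_head_to_head))
    alpha = float(overall_alpha)
    half = alpha / 2.0
    trace = []

    rej_iron = p_iron <= half
    rej_mnp = p_mnp <= half
    trace.append(f"primary tests at alpha/2 = {half:g}: "
                 f"iron_vs_placebo {'rejected' if rej_iron else 'retained'} "
                 f"(p={p_iron:g}), mnp_vs_placebo "
                 f"{'rejected' if rej_mnp else 'retained'} (p={p_mnp:g})")

    adj_iron, adj_mnp, adj_hh = adjusted_pvalues(p_iron, p_mnp, p_hh)
    decisions = {
        "iron_vs_placebo": HypothesisDecision(
            "iron_vs_placebo", p_iron, half, bool(rej_iron), adj_iron,
            1.0 - half),
        "mnp_vs_placebo": HypothesisDecision(
            "mnp_vs_placebo", p_mnp, half, bool(rej_mnp), adj_mnp,
            1.0 - half),
    }
    n_rejected = int(rej_iron) + int(rej_mnp)
    if n_rejected == 0:
        trace.append("gate closed: head-to-head untested; estimate with "
                     "95% CI, p-value suppressed")
        decisions[HEAD_TO_HEAD] = HypothesisDecision(
            HEAD_TO_HEAD, p_hh, None, False, None, 0.95)
    else:
        hh_alpha = alpha if n_rejected == 2 else half
        rej_hh = p_hh <= hh_alpha
        trace.append(f"gate open ({n_rejected} primary rejection(s)): "
                     f"head-to-head tested at {hh_alpha:g} and "
                     f"{'rejected' if rej_hh else 'retained'} (p={p_hh:g})")
        decisions[HEAD_TO_HEAD] = HypothesisDecision(
            HEAD_TO_HEAD, p_hh, hh_alpha, bool(rej_hh), adj_hh,
            1.0 - hh_alpha)
    return MultiplicityOutcome(decisions=decisions, overall_alpha=alpha,
                               trace=trace)


def adjusted_pvalues(p_iron: float, p_mnp: float, p_head_to_head: float):
    """Smallest-rejecting overall alpha for each hypothesis.

    Primaries reduce to a Bonferroni doubling, min(1, 2p). For the
    head-to-head hypothesis the gate must be open: with exactly one
    primary rejected the test level is alpha/2, with both it is alpha.
    The minimum over the two regimes gives the adjusted p (capped at 1);
    monotone in every argument.
    """
    p_iron, p_mnp, p_hh = map(_validate, (p_iron, p_mnp, p_head_to_head))
    adj_iron = min(1.0, 2.0 * p_iron)
    adj_mnp = min(1.0, 2.0 * p_mnp)

    a_lo, a_hi = sorted((2.0 * p_iron, 2.0 * p_mnp))  # gate-opening alphas
    candidates = []
    # regime 1: only the stronger primary rejected -> level alpha/2
    c1 = max(a_lo, 2.0 * p_hh)
    if c1 < a_hi:
        candidates.append(c1)
    # regime 2: both primaries rejected -> level alpha
    candidates.append(max(a_hi, p_hh))
    adj_hh = min(1.0, min(candidates))
    return adj_iron, adj_mnp, adj_hh


def hochberg_family(p_values, family_alpha: float, gate_open: bool = True):
    """Step-up Hochberg decisions and adjusted p-values for one family.

    Rejects every hypothesis with p at or below the largest p_(j)
    satisfying p_(j) <= family_alpha/(m - j + 1). Adjusted p of the i-th
    ordered hypothesis is min over j >= i of (m - j + 1) * p_(j), capped at
    1 and enforced monotone. Ties are broken by original index. When the
    gate is closed the family is untested: all hypotheses reported as not
    rejected with adjusted p suppressed (None).
    """
    p_values = [(_validate(p)) for p in p_values]
    m = len(p_values)
    if m == 0:
        return [], []
    if not gate_open:
        return [False] * m, [None] * m
    order = sorted(range(m), key=lambda i: (p_values[i], i))
    sorted_p = [p_values[i] for i in order]
    # adjusted p, from the largest down, enforcing monotonicity
    adj_sorted = [None] * m
    running = 1.0
    for j in range(m - 1, -1, -1):
        running = min(running, (m - j) * sorted_p[j])
        adj_sorted[j] = min(1.0, running)
    # step-up rejection: find the largest j with p_(j) <= alpha/(m-j)
    reject_upto = -1
    for j in range(m - 1, -1, -1):
        if sorted_p[j] <= family_alpha / (m - j):
            reject_upto = j
            break
    rejected = [False] * m
    adjusted = [None] * m
    for rank, i in enumerate(order):
        rejected[i] = rank <= reject_upto
        adjusted[i] = adj_sorted[rank]
    return rejected, adjusted


def key_secondary_decisions(primary_outcome: MultiplicityOutcome,
                            family_pvalues: dict) -> dict:
    """Run one Hochberg family per pairwise comparison.

    ``family_pvalues`` maps comparison label -> {endpoint: p}. Each family
    is tested at the level assigned to that comparison's primary test, and
    only when the primary null for that comparison was rejected.
    """
    out = {}
    for comparison, endpoint_ps in family_pvalues.items():
        primary = primary_outcome[comparison]
        gate_open = primary.rejected
        alpha = primary.assigned_alpha if primary.assigned_alpha else 0.0
        labels = list(endpoint_ps)
        rejected, adjusted = hochberg_family(
            [endpoint_ps[k] for k in labels],
            family_alpha=alpha if gate_open else 0.0,
            gate_open=gate_open)
        out[comparison] = {
            label: HypothesisDecision(
                label=f"{comparison}:{label}",
                p_unadjusted=endpoint_ps[label],
                assigned_alpha=(alpha if gate_open else None),
                rejected=rej,
                p_adjusted=adj,
                ci_level=(1.0 - alpha) if gate_open else 0.95,
            )
            for label, rej, adj in zip(labels, rejected, adjusted)
        }
    return out
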