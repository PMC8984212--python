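"""Simulation configuration for synthetic three-arm trials.

The defaults encode the trial design this package emulates: 1100 children
per arm, a Bayley-III-like cognitive composite with SD 15 measured at
baseline, month 3 and month 12, 1:1:1 stratified permuted-block
randomisation by union (3 levels) and sex (2 levels), and 20% loss to
follow-up.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import yaml

ARMS = ("iron", "mnp", "placebo")
UNIONS = ("Bhulta", "Golakandail", "Rupganj")
SEXES = ("female", "male")
VISITS = (0, 1, 2)  # baseline, month 3, month 12
VISIT_DAYS = (0, 90, 365)

#: continuous outcomes measured at every visit
CONTINUOUS_OUTCOMES = (
    "cognitive", "language", "motor",
    "haemoglobin", "ferritin", "crp",
    "laz", "waz", "wlz", "head_circumference",
)
#: outcomes simulated on the natural-log scale (positive, right-skewed labs)
LOGNORMAL_OUTCOMES = ("ferritin", "crp")

MORBIDITY_TYPES = (
    "fever", "diarrhoea", "bloody_stool", "vomiting", "cough", "other",
)

INTERVENTION_DAYS = 90      # day 0 .. day 90
STUDY_DAYS = 365
N_WEEKLY_REPORTS = 13       # intervention period
N_MONTHLY_REPORTS = 9       # extended follow-up


def exchangeable_cov(sd: float, rho: float, k: int = 3) -> np.ndarray:
    """Compound-symmetric covariance with common SD and correlation."""
    s = np.full(k, float(sd))
    c = np.full((k, k), rho) + (1.0 - rho) * np.eye(k)
    return np.outer(s, s) * c


def _default_visit_means() -> dict:
    # Composite scores on the standardised scale (mean 100, SD 15); labs on
    # their natural scales; log-normal outcomes give the log-scale mean.
    return {
        "cognitive": (100.0, 100.0, 100.0),
        "language": (100.0, 100.0, 100.0),
        "motor": (100.0, 100.0, 100.0),
        "haemoglobin": (105.0, 108.0, 112.0),
        "ferritin": (np.log(20.0), np.log(18.0), np.log(16.0)),
        "crp": (np.log(1.5), np.log(1.5), np.log(1.5)),
        "laz": (-1.2, -1.3, -1.4),
        "waz": (-1.0, -1.1, -1.2),
        "wlz": (-0.5, -0.55, -0.6),
        "head_circumference": (44.0, 45.5, 47.5),
    }


def _default_covariance() -> dict:
    return {
        "cognitive": exchangeable_cov(15.0, 0.4),
        "language": exchangeable_cov(15.0, 0.4),
        "motor": exchangeable_cov(15.0, 0.4),
        "haemoglobin": exchangeable_cov(12.0, 0.4),
        "ferritin": exchangeable_cov(0.7, 0.4),
        "crp": exchangeable_cov(0.9, 0.2),
        "laz": exchangeable_cov(1.0, 0.7),
        "waz": exchangeable_cov(1.0, 0.7),
        "wlz": exchangeable_cov(1.0, 0.6),
        "head_circumference": exchangeable_cov(1.4, 0.6),
    }


def _default_morbidity_rates() -> dict:
    # events per child per reporting occasion, shared across arms
    return {
        "fever": 0.25, "diarrhoea": 0.15, "bloody_stool": 0.01,
        "vomiting": 0.08, "cough": 0.30, "other": 0.10,
    }


@dataclass
class DropoutSpec:
    """Loss-to-follow-up mechanism.

    ``mechanism`` is MCAR (each child drops independently with probability
    ``rate``) or MAR (a logistic model on baseline covariates, with intercept
    calibrated so the marginal rate is approximately ``rate``).
    ``monotone=True`` makes month-3 dropouts also missing at month 12.
    """
    mechanism: str = "MCAR"
    rate: float = 0.20
    mar_predictors: dict = field(default_factory=dict)  # name -> coefficient
    monotone: bool = True

    def __post_init__(self):
        if self.mechanism not in ("MCAR", "MAR"):
            raise ValueError(f"unknown dropout mechanism {self.mechanism!r}")
        if not 0.0 <= self.rate <= 1.0:
            raise ValueError("dropout rate must lie in [0, 1]")


@dataclass
class SimConfig:
    """Full parameterisation of one synthetic trial."""
    n_per_arm: int = 1100
    strata_weights: dict = field(default_factory=dict)  # (union, sex) -> prob
    block_size: int = 6
    visit_means: dict = field(default_factory=_default_visit_means)
    # per outcome: {arm: (shift at visit 1, shift at visit 2)}; additive on
    # the analysis scale (log scale for log-normal outcomes)
    effects: dict = field(default_factory=dict)
    within_child_covariance: dict = field(default_factory=_default_covariance)
    morbidity_rates: dict = field(default_factory=_default_morbidity_rates)
    morbidity_rate_ratio: dict = field(default_factory=dict)  # arm -> ratio
    morbidity_dispersion: float | None = None  # neg-binomial size; None = Poisson
    # daily intake probability ~ Beta(a, b) per child, plus a point mass of
    # children with no intake data at all
    adherence_beta: tuple = (8.0, 2.0)
    prob_no_intake_data: float = 0.02
    dropout: DropoutSpec = field(default_factory=DropoutSpec)
    violation_rates: dict = field(default_factory=lambda: {
        "consent_withdrawn_all_data": 0.003,
        "never_dosed": 0.01,
        "improper_unblinding": 0.002,
        "eligibility_violation": 0.005,
    })
    death_rate: float = 0.004
    seed: int = 0
    # skip morbidity/adherence/registry detail for speed in large simulation
    # studies; outcomes, allocation and covariates are always generated
    light: bool = False

    def __post_init__(self):
        if self.block_size % 3 != 0 or self.block_size <= 0:
            raise ValueError(
                f"block_size must be a positive multiple of 3 (one slot per "
                f"arm per sub-block); got {self.block_size}"
            )
        if self.n_per_arm <= 0:
            raise ValueError("n_per_arm must be positive")
        if not self.strata_weights:
            cells = [(u, s) for u in UNIONS for s in SEXES]
            self.strata_weights = {c: 1.0 / len(cells) for c in cells}
        total = sum(self.strata_weights.values())
        if not np.isclose(total, 1.0):
            raise ValueError("strata_weights must sum to 1")
        for name, cov in self.within_child_covariance.items():
            cov = np.asarray(cov, dtype=float)
            if cov.shape != (3, 3):
                raise ValueError(f"covariance for {name!r} must be 3x3")
            if np.min(np.linalg.eigvalsh(cov)) <= 0:
                raise ValueError(
                    f"within-child covariance for {name!r} is not "
                    f"positive-definite"
                )
            self.within_child_covariance[name] = cov
        for key, p in self.violation_rates.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"violation rate {key} outside [0, 1]")

    def arm_effect(self, outcome: str, arm: str) -> tuple:
        """(visit-1, visit-2) additive shift for ``arm`` on ``outcome``."""
        per_arm = self.effects.get(outcome, {})
        return tuple(per_arm.get(arm, (0.0, 0.0)))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["within_child_covariance"] = {
            k: np.asarray(v).tolist()
            for k, v in d["within_child_covariance"].items()
        }
        d["strata_weights"] = {
            f"{u}|{s}": w for (u, s), w in d["strata_weights"].items()
        }
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "strata_weights" in raw:
            raw["strata_weights"] = {
                tuple(k.split("|")): v for k, v in raw["strata_weights"].items()
            }
        if "dropout" in raw and isinstance(raw["dropout"], dict):
            raw["dropout"] = DropoutSpec(**raw["dropout"])
        return cls(**raw)
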