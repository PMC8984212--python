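"""Tidy in-memory container for child-level trial data.

A :class:`TrialDataset` bundles four tidy tables:

``children``
    one row per randomised child: allocation, stratification cells,
    household covariates, participation interval and status flags;
``outcomes``
    one row per child-visit with one column per outcome (missing values are
    ``NaN``), plus the actual assessment day;
``morbidity``
    one row per reporting occasion (13 weekly during the intervention,
    9 monthly in extended follow-up) with event counts per infection type
    and clinic-visit / hospitalisation indicators;
``intake``
    one row per child-day over the 90-day intervention with the indicator
    that both syrup and sachet were taken (absent in light simulations;
    ``children.intake_days`` always carries the per-child total).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

SCHEMA_VERSION = "1"

REQUIRED_CHILD_COLUMNS = (
    "child_id", "arm", "union", "sex",
)


@dataclass
class TrialDataset:
    children: pd.DataFrame
    outcomes: pd.DataFrame
    morbidity: pd.DataFrame | None = None
    intake: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = [c for c in REQUIRED_CHILD_COLUMNS
                   if c not in self.children.columns]
        if missing:
            raise ValueError(f"children table lacks columns {missing}")
        if self.children["child_id"].duplicated().any():
            raise ValueError("child_id values are not unique")
        if self.children["arm"].isna().any():
            raise ValueError("every randomised child must carry an arm")
        if "visit" in self.outcomes.columns:
            bad = set(self.outcomes["visit"].unique()) - {0, 1, 2}
            if bad:
                raise ValueError(f"visit indices outside {{0,1,2}}: {bad}")

    @property
    def n_children(self) -> int:
        return len(self.children)

    def copy(self) -> "TrialDataset":
        return TrialDataset(
            children=self.children.copy(),
            outcomes=self.outcomes.copy(),
            morbidity=None if self.morbidity is None else self.morbidity.copy(),
            intake=None if self.intake is None else self.intake.copy(),
            meta=dict(self.meta),
        )

    def analysis_table(self, population: pd.Series | None = None) -> pd.DataFrame:
        """Child-visit table joined with child-level covariates.

        ``population`` is an optional boolean Series indexed by child_id
        restricting the rows (e.g. an ITT or per-protocol flag).
        """
        tab = self.outcomes.merge(self.children, on="child_id", how="left")
        if population is not None:
            keep = population[population].index
            tab = tab[tab["child_id"].isin(keep)]
        return tab.reset_index(drop=True)

    # ---------------------------------------------------------------- I/O
    def write(self, directory) -> None:
        """Write the dataset as CSV files plus a JSON sidecar."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.children.to_csv(directory / "children.csv", index=False)
        self.outcomes.to_csv(directory / "outcomes.csv", index=False)
        if self.morbidity is not None:
            self.morbidity.to_csv(directory / "morbidity.csv", index=False)
        if self.intake is not None:
            self.intake.to_csv(directory / "intake.csv", index=False)
        sidecar = {"schema_version": SCHEMA_VERSION, **self.meta}
        (directory / "dataset.json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def read(cls, directory) -> "TrialDataset":
        directory = Path(directory)
        meta = {}
        sidecar = directory / "dataset.json"
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            meta.pop("schema_version", None)
        morbidity = intake = None
        if (directory / "morbidity.csv").exists():
            morbidity = pd.read_csv(directory / "morbidity.csv")
        if (directory / "intake.csv").exists():
            intake = pd.read_csv(directory / "intake.csv")
        return cls(
            children=pd.read_csv(directory / "children.csv"),
            outcomes=pd.read_csv(directory / "outcomes.csv"),
            morbidity=morbidity,
            intake=intake,
            meta=meta,
        )
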