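"""The model input bundle: one directory of CSV tables plus a JSON manifest.

A bundle is the package's stand-in for the study's parameter table: per
pathology the national prevalence, severity split, cost baskets, burden
and productivity inputs, plus the expert-elicitation panels for the six
severity-transition questions and the scenario defaults. Serialization is
deliberately plain (CSV + JSON, floats written at full precision) so a
bundle round-trips losslessly and a regenerated bundle is byte-identical
under the same seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .burden import ProductivityParameters
from .cohort import MortalityParameter
from .costing import COST_CATEGORIES, CostBasket, CostItem
from .elicitation import ExpertJudgement, panels_from_frame, panels_to_frame
from .states import LIVING_STATES, HealthState

__all__ = [
    "SCHEMA_VERSION",
    "TRANSITION_QUESTIONS",
    "question_states",
    "PathologyParameters",
    "ParameterBundle",
    "validate_bundle",
]

SCHEMA_VERSION = "1"

#: the six elicited severity transitions; each living row's remaining
#: (diagonal) probability is the complement of its two elicited exits
TRANSITION_QUESTIONS = (
    "mild_to_moderate",
    "mild_to_severe",
    "moderate_to_mild",
    "moderate_to_severe",
    "severe_to_mild",
    "severe_to_moderate",
)

_STATE_BY_NAME = {s.name.lower(): s for s in HealthState}


def question_states(question_id: str) -> tuple[HealthState, HealthState]:
    """Map a question id like ``mild_to_moderate`` to its state pair."""
    frm, _, to = question_id.partition("_to_")
    try:
        return _STATE_BY_NAME[frm], _STATE_BY_NAME[to]
    except KeyError:
        raise ValueError(f"unknown transition question {question_id!r}") from None


@dataclass(frozen=True)
class PathologyParameters:
    """Everything the model needs about one pathology.

    ``depression_background_cases`` is the national pool of depression
    cases to which the attributable fraction applies; the exposure
    prevalence itself is recomputed at evaluation time as pathology
    prevalence x (moderate + severe) severity share, so that PSA draws of
    prevalence and split stay coherent with the attribution.
    """

    name: str
    prevalence: float
    severity_split: tuple[float, float, float]
    baskets: Mapping[HealthState, CostBasket]
    duration_years: float = 1.0
    disability_weight: float = 0.1
    pain_domain_fraction: float = 1.0
    depression_relative_risk: float = 1.0
    depression_background_cases: float = 0.0
    anxiety_proportion: float = 0.0
    depression_cost_per_case_clp: float = 0.0
    anxiety_cost_per_case_clp: float = 0.0
    productivity: ProductivityParameters = field(default_factory=ProductivityParameters)

    def __post_init__(self) -> None:
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError(f"{self.name}: prevalence must lie in [0, 1]")
        split = np.asarray(self.severity_split, dtype=float)
        if split.shape != (3,) or np.any(split < 0) or abs(split.sum() - 1.0) > 1e-9:
            raise ValueError(f"{self.name}: severity_split must sum to 1")
        if self.duration_years <= 0:
            raise ValueError(f"{self.name}: duration_years must be positive")
        for prop in ("disability_weight", "pain_domain_fraction", "anxiety_proportion"):
            v = getattr(self, prop)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{self.name}: {prop} must lie in [0, 1]")
        if self.depression_relative_risk < 0:
            raise ValueError(f"{self.name}: depression_relative_risk must be >= 0")
        object.__setattr__(self, "severity_split", tuple(split))
        object.__setattr__(self, "baskets", dict(self.baskets))


@dataclass(frozen=True)
class ParameterBundle:
    population_size: float
    mortality: MortalityParameter
    pathologies: Mapping[str, PathologyParameters]
    panels: Mapping[str, Sequence[ExpertJudgement]]
    scenario_defaults: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.population_size < 0:
            raise ValueError("population_size must be non-negative")
        object.__setattr__(self, "pathologies", dict(self.pathologies))
        object.__setattr__(self, "panels", {k: list(v) for k, v in self.panels.items()})

    # ------------------------------------------------------------------ I/O

    def to_dir(self, path: str | Path) -> Path:
        """Write the bundle as CSV tables plus ``manifest.json``."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)

        manifest = {
            "schema_version": SCHEMA_VERSION,
            "population_size": self.population_size,
            "mortality_annual_per_1000": self.mortality.annual_per_1000,
            "pathology_order": list(self.pathologies),
            "question_order": list(self.panels),
            "scenario_defaults": self.scenario_defaults,
            "meta": self.meta,
        }
        (path / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )

        rows = []
        for p in self.pathologies.values():
            rows.append(
                {
                    "pathology": p.name,
                    "prevalence": p.prevalence,
                    "split_mild": p.severity_split[0],
                    "split_moderate": p.severity_split[1],
                    "split_severe": p.severity_split[2],
                    "duration_years": p.duration_years,
                    "disability_weight": p.disability_weight,
                    "pain_domain_fraction": p.pain_domain_fraction,
                    "depression_relative_risk": p.depression_relative_risk,
                    "depression_background_cases": p.depression_background_cases,
                    "anxiety_proportion": p.anxiety_proportion,
                    "depression_cost_per_case_clp": p.depression_cost_per_case_clp,
                    "anxiety_cost_per_case_clp": p.anxiety_cost_per_case_clp,
                }
            )
        pd.DataFrame(rows).to_csv(path / "pathologies.csv", index=False)

        basket_rows = [
            {
                "pathology": p.name,
                "state": state.name.lower(),
                "resource": item.resource,
                "category": item.category,
                "unit_price_clp": item.unit_price_clp,
                "monthly_quantity": item.monthly_quantity,
                "user_fraction": item.user_fraction,
            }
            for p in self.pathologies.values()
            for state in LIVING_STATES
            if state in p.baskets
            for item in p.baskets[state].items
        ]
        pd.DataFrame(basket_rows).to_csv(path / "cost_baskets.csv", index=False)

        prod_rows = [
            {
                "pathology": p.name,
                "leave_episodes": p.productivity.leave_episodes,
                "mean_days_per_episode": p.productivity.mean_days_per_episode,
                "daily_wage_clp": p.productivity.daily_wage_clp,
                "system_paid_fraction": p.productivity.system_paid_fraction,
                "structural_zero": p.productivity.structural_zero,
            }
            for p in self.pathologies.values()
        ]
        pd.DataFrame(prod_rows).to_csv(path / "productivity.csv", index=False)

        panels_to_frame(self.panels).to_csv(path / "elicitation.csv", index=False)
        return path

    @classmethod
    def from_dir(cls, path: str | Path) -> "ParameterBundle":
        path = Path(path)
        manifest = json.loads((path / "manifest.json").read_text())
        if manifest.get("schema_version") != SCHEMA_VERSION:
            raise ValueError(
                f"unsupported bundle schema {manifest.get('schema_version')!r}"
            )
        pat = pd.read_csv(path / "pathologies.csv", float_precision="round_trip").set_index("pathology", drop=False)
        baskets = pd.read_csv(path / "cost_baskets.csv", float_precision="round_trip")
        prod = pd.read_csv(path / "productivity.csv", float_precision="round_trip").set_index("pathology")
        panels = panels_from_frame(pd.read_csv(path / "elicitation.csv", float_precision="round_trip"))
        panels = {q: panels[q] for q in manifest["question_order"]}

        pathologies: dict[str, PathologyParameters] = {}
        for name in manifest["pathology_order"]:
            row = pat.loc[name]
            prow = prod.loc[name]
            pbaskets: dict[HealthState, CostBasket] = {}
            for state in LIVING_STATES:
                sdf = baskets[
                    (baskets["pathology"] == name)
                    & (baskets["state"] == state.name.lower())
                ]
                if len(sdf):
                    pbaskets[state] = CostBasket(
                        state=state,
                        items=tuple(
                            CostItem(
                                resource=r.resource,
                                category=r.category,
                                unit_price_clp=r.unit_price_clp,
                                monthly_quantity=r.monthly_quantity,
                                user_fraction=r.user_fraction,
                            )
                            for r in sdf.itertuples()
                        ),
                    )
            pathologies[name] = PathologyParameters(
                name=name,
                prevalence=row["prevalence"],
                severity_split=(
                    row["split_mild"], row["split_moderate"], row["split_severe"]
                ),
                baskets=pbaskets,
                duration_years=row["duration_years"],
                disability_weight=row["disability_weight"],
                pain_domain_fraction=row["pain_domain_fraction"],
                depression_relative_risk=row["depression_relative_risk"],
                depression_background_cases=row["depression_background_cases"],
                anxiety_proportion=row["anxiety_proportion"],
                depression_cost_per_case_clp=row["depression_cost_per_case_clp"],
                anxiety_cost_per_case_clp=row["anxiety_cost_per_case_clp"],
                productivity=ProductivityParameters(
                    leave_episodes=prow["leave_episodes"],
                    mean_days_per_episode=prow["mean_days_per_episode"],
                    daily_wage_clp=prow["daily_wage_clp"],
                    system_paid_fraction=prow["system_paid_fraction"],
                    structural_zero=bool(prow["structural_zero"]),
                ),
            )
        return cls(
            population_size=manifest["population_size"],
            mortality=MortalityParameter(manifest["mortality_annual_per_1000"]),
            pathologies=pathologies,
            panels=panels,
            scenario_defaults=manifest.get("scenario_defaults", {}),
            meta=manifest.get("meta", {}),
        )


# -------------------------------------------------------------- validation

def validate_bundle(bundle_or_path) -> list[str]:
    """Check every bundle invariant; return a list of all violations.

    Accepts an in-memory :class:`ParameterBundle` or a bundle directory.
    Directory validation works on the raw tables, so a broken bundle is
    fully reported rather than failing at the first dataclass constructor.
    """
    if isinstance(bundle_or_path, ParameterBundle):
        # in-memory bundles were validated at construction; re-check the
        # cross-cutting invariants anyway
        violations: list[str] = []
        for name, p in bundle_or_path.pathologies.items():
            if abs(sum(p.severity_split) - 1.0) > 1e-9:
                violations.append(f"pathology {name}: severity_split does not sum to 1")
        for qid, panel in bundle_or_path.panels.items():
            if not panel:
                violations.append(f"question {qid}: empty expert panel")
        return violations

    path = Path(bundle_or_path)
    violations = []
    manifest_path = path / "manifest.json"
    if not manifest_path.exists():
        return [f"missing file: {manifest_path}"]
    try:
        manifest = json.loads(manifest_path.read_text())
    except json.JSONDecodeError as exc:
        return [f"manifest.json unreadable: {exc}"]

    for fname in ("pathologies.csv", "cost_baskets.csv", "productivity.csv",
                  "elicitation.csv"):
        if not (path / fname).exists():
            violations.append(f"missing file: {fname}")
    if violations:
        return violations

    if manifest.get("mortality_annual_per_1000", 0) < 0:
        violations.append("manifest: mortality_annual_per_1000 must be non-negative")
    if manifest.get("population_size", 0) < 0:
        violations.append("manifest: population_size must be non-negative")

    pat = pd.read_csv(path / "pathologies.csv", float_precision="round_trip")
    for row in pat.itertuples():
        if not 0.0 <= row.prevalence <= 1.0:
            violations.append(f"pathology {row.pathology}: prevalence outside [0, 1]")
        split_sum = row.split_mild + row.split_moderate + row.split_severe
        if abs(split_sum - 1.0) > 1e-9:
            violations.append(
                f"pathology {row.pathology}: severity split sums to {split_sum:g}, not 1"
            )
        for col in ("disability_weight", "pain_domain_fraction", "anxiety_proportion"):
            if not 0.0 <= getattr(row, col) <= 1.0:
                violations.append(f"pathology {row.pathology}: {col} outside [0, 1]")
        if row.depression_relative_risk < 0:
            violations.append(
                f"pathology {row.pathology}: depression_relative_risk negative"
            )

    baskets = pd.read_csv(path / "cost_baskets.csv", float_precision="round_trip")
    for i, row in enumerate(baskets.itertuples()):
        where = f"basket row {i} ({row.pathology}/{row.state}/{row.resource})"
        if row.category not in COST_CATEGORIES:
            violations.append(f"{where}: unknown category {row.category!r}")
        if row.unit_price_clp < 0:
            violations.append(f"{where}: negative unit price")
        if row.monthly_quantity < 0:
            violations.append(f"{where}: negative monthly quantity")
        if not 0.0 <= row.user_fraction <= 1.0:
            violations.append(f"{where}: user_fraction outside [0, 1]")

    prod = pd.read_csv(path / "productivity.csv", float_precision="round_trip")
    for row in prod.itertuples():
        if min(row.leave_episodes, row.mean_days_per_episode, row.daily_wage_clp) < 0:
            violations.append(f"productivity {row.pathology}: negative input")
        if not 0.0 <= row.system_paid_fraction <= 1.0:
            violations.append(
                f"productivity {row.pathology}: system_paid_fraction outside [0, 1]"
            )

    elic = pd.read_csv(path / "elicitation.csv", float_precision="round_trip")
    for (qid, eid), edf in elic.groupby(["question_id", "expert_id"], sort=False):
        grid = edf["bin_midpoint"].to_numpy()
        weights = edf["weight"].to_numpy()
        where = f"elicitation {qid}/expert {eid}"
        if np.any(np.diff(grid) <= 0):
            violations.append(f"{where}: grid not strictly increasing")
        if np.any(weights < 0):
            violations.append(f"{where}: negative weight")
        elif abs(weights.sum() - 1.0) > 1e-9:
            violations.append(f"{where}: weights sum to {weights.sum():.12g}, not 1")

    for key, value in manifest.get("scenario_defaults", {}).items():
        if key in ("undiagnosed_mild", "undiagnosed_moderate") and not 0 <= value <= 1:
            violations.append(f"scenario_defaults.{key}: outside [0, 1]")
    return violations
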