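"""Single-trait genetic gains and multi-trait selection-index gains.

Candidates are ranked by a selection index SI = sum_i w_i * EBV_i with weights
in [0, 1] summing to 1 over the trait panel; the top fraction (default 5%) is
selected and each trait's genetic gain is the mean EBV of the selected trees,
expressed as a percentage of that trait's phenotypic mean.  By default each
trait's EBVs are standardized to unit variance before weighting (otherwise the
weights are scale-dependent); ``raw_scale=True`` combines EBVs on their raw
trait scales.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SelectionScenario",
    "GainReport",
    "default_scenarios",
    "single_trait_gain",
    "select_by_index",
    "index_gains",
    "compare_scenarios",
]


@dataclass
class SelectionScenario:
    name: str
    weights: dict[str, float]  # trait -> weight, sum to 1
    proportion: float = 0.05

    def __post_init__(self) -> None:
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"scenario {self.name!r}: weights sum to {total}, not 1")
        if any(not 0.0 <= w <= 1.0 for w in self.weights.values()):
            raise ValueError(f"scenario {self.name!r}: weights must be in [0, 1]")
        if not 0.0 < self.proportion < 1.0:
            raise ValueError("selection proportion must be in (0, 1)")


@dataclass
class GainReport:
    scenario: str
    method: str
    gains_pct: dict[str, float]
    selected: list[str] = field(repr=False)


def default_scenarios(proportion: float = 0.05) -> list[SelectionScenario]:
    """The five height-priority multi-trait scenarios."""
    return [
        SelectionScenario("S1", {"height": 1.0}, proportion),
        SelectionScenario("S2", {"height": 0.8, "resistance": 0.2}, proportion),
        SelectionScenario("S3", {"height": 0.8, "resilience": 0.2}, proportion),
        SelectionScenario(
            "S4", {"height": 0.6, "wood_density": 0.2, "resistance": 0.2}, proportion
        ),
        SelectionScenario(
            "S5", {"height": 0.6, "wood_density": 0.2, "resilience": 0.2}, proportion
        ),
    ]


def _n_selected(n: int, proportion: float) -> int:
    m = math.ceil(proportion * n)
    if m < 1:
        raise ValueError("selection proportion picks no trees")
    return m


def single_trait_gain(
    ebvs: pd.Series, phenotypic_mean: float, proportion: float = 0.05
) -> float:
    """Gain% = 100 * mean(EBV of the top trees by EBV) / phenotypic mean."""
    if phenotypic_mean == 0:
        raise ValueError(
            "phenotypic mean is zero; report absolute gain instead of a percentage"
        )
    m = _n_selected(len(ebvs), proportion)
    top = _rank(ebvs).head(m)
    return float(100.0 * top.mean() / phenotypic_mean)


def _rank(scores: pd.Series) -> pd.Series:
    """Descending score, ties broken by ascending tree id (deterministic)."""
    df = scores.rename("score").rename_axis("tree").reset_index()
    df = df.sort_values(["score", "tree"], ascending=[False, True], kind="mergesort")
    return df.set_index("tree")["score"]


def select_by_index(
    ebv_table: pd.DataFrame,
    scenario: SelectionScenario,
    standardize: bool = True,
) -> list[str]:
    """Rank by SI and return the selected tree ids."""
    for trait in scenario.weights:
        if trait not in ebv_table.columns:
            raise ValueError(f"no EBVs for trait {trait!r}")
        missing = ebv_table[ebv_table[trait].isna()].index.tolist()
        if missing:
            raise ValueError(f"missing {trait} EBVs for trees {missing[:5]}")
    si = pd.Series(0.0, index=ebv_table.index)
    for trait, w in scenario.weights.items():
        col = ebv_table[trait]
        if standardize:
            sd = col.std()
            if sd > 0:
                col = col / sd
        si = si + w * col
    m = _n_selected(len(ebv_table), scenario.proportion)
    return list(_rank(si).head(m).index)


def index_gains(
    ebv_table: pd.DataFrame,
    scenario: SelectionScenario,
    phenotypic_means: dict[str, float],
    method: str = "GBLUP",
    standardize: bool = True,
) -> GainReport:
    """Per-trait gain (% of phenotypic mean) under index selection."""
    selected = select_by_index(ebv_table, scenario, standardize=standardize)
    gains = {}
    for trait in ebv_table.columns:
        mean = phenotypic_means.get(trait)
        if mean is None or mean == 0:
            continue
        gains[trait] = float(100.0 * ebv_table.loc[selected, trait].mean() / mean)
    return GainReport(scenario.name, method, gains, selected)


def compare_scenarios(
    ebv_table: pd.DataFrame,
    scenarios: list[SelectionScenario],
    phenotypic_means: dict[str, float],
    method: str = "GBLUP",
    standardize: bool = True,
    include_single_trait: bool = True,
) -> pd.DataFrame:
    """Gains table, one row per scenario (plus single-trait reference rows)."""
    names = [s.name for s in scenarios]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate scenario names: {names}")
    rows = []
    if include_single_trait:
        gains = {
            trait: single_trait_gain(
                ebv_table[trait].dropna(), phenotypic_means[trait], scenarios[0].proportion
            )
            for trait in ebv_table.columns
            if trait in phenotypic_means and phenotypic_means[trait] != 0
        }
        rows.append({"scenario": "single_trait", "method": method, **gains})
    reports = [
        index_gains(ebv_table, s, phenotypic_means, method, standardize) for s in scenarios
    ]
    for rep in reports:
        rows.append({"scenario": rep.scenario, "method": rep.method, **rep.gains_pct})
    out = pd.DataFrame(rows)
    # overlap of selected sets between scenarios
    overlap = {
        (a.scenario, b.scenario): len(set(a.selected) & set(b.selected))
        for i, a in enumerate(reports)
        for b in reports[i + 1 :]
    }
    out.attrs["selected_overlap"] = overlap
    return out
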