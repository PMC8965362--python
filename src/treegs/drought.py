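"""Lloret components of drought response computed per tree from BAI series.

Around a stated drought year d, with a pre-drought window of ``pre`` years and a
post-drought window of ``post`` years:

    resistance          = BAI_d / mean(BAI_{d-pre..d-1})
    recovery            = mean(BAI_{d+1..d+post}) / BAI_d
    resilience          = mean(BAI_{d+1..d+post}) / mean(BAI_{d-pre..d-1})
    relative resilience = resilience - resistance

Resistance quantifies the growth loss in the drought year, recovery the
subsequent rebound, resilience the return to pre-drought growth.  When the
post-drought window is unusable (truncated series, or a stand intervention such
as thinning confounds post-drought growth) only resistance is reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dendro import RingSeries

__all__ = ["DroughtResponse", "lloret_components", "batch_components", "summarize_components"]

COMPONENT_NAMES = ("resistance", "recovery", "resilience", "relative_resilience")


@dataclass
class DroughtResponse:
    tree_id: str
    drought_year: int
    resistance: float
    recovery: float | None
    resilience: float | None
    relative_resilience: float | None
    pre: int
    post: int

    def as_dict(self) -> dict:
        return {
            "tree": self.tree_id,
            "drought_year": self.drought_year,
            "resistance": self.resistance,
            "recovery": self.recovery,
            "resilience": self.resilience,
            "relative_resilience": self.relative_resilience,
        }


def lloret_components(
    series: RingSeries,
    drought_year: int,
    pre: int = 2,
    post: int = 3,
    post_valid: bool = True,
) -> DroughtResponse:
    """Compute the four components for one tree.

    The pre-drought window is mandatory; if the post window is unavailable
    (series ends early or ``post_valid`` is False) only resistance is returned
    and the post-drought components are marked absent.
    """
    if pre < 1 or post < 1:
        raise ValueError("pre and post windows must be >= 1 year")
    if series.kind not in ("bai", "index"):
        raise ValueError("drought components are computed on BAI (or index) series")
    pre_vals = series.window(drought_year - pre, drought_year - 1)
    d_val = series.value_in(drought_year)
    if d_val == 0:
        raise ValueError(f"{series.tree_id}: zero growth in drought year {drought_year}")
    pre_mean = float(np.mean(pre_vals))
    resistance = d_val / pre_mean

    have_post = post_valid and series.last_year >= drought_year + post
    if not have_post:
        return DroughtResponse(
            series.tree_id, drought_year, resistance, None, None, None, pre, post
        )
    post_mean = float(np.mean(series.window(drought_year + 1, drought_year + post)))
    recovery = post_mean / d_val
    resilience = post_mean / pre_mean
    return DroughtResponse(
        series.tree_id,
        drought_year,
        resistance,
        recovery,
        resilience,
        resilience - resistance,
        pre,
        post,
    )


def batch_components(
    series_set: list[RingSeries],
    drought_year: int,
    pre: int = 2,
    post: int = 3,
    post_valid: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One row per tree; per-tree failures are collected into a rejects table."""
    rows, rejects = [], []
    for s in series_set:
        try:
            rows.append(
                lloret_components(s, drought_year, pre=pre, post=post, post_valid=post_valid).as_dict()
            )
        except (KeyError, ValueError) as exc:
            rejects.append({"tree": s.tree_id, "error": str(exc)})
    table = pd.DataFrame(
        rows,
        columns=["tree", "drought_year", *COMPONENT_NAMES[:1], "recovery", "resilience", "relative_resilience"],
    )
    return table, pd.DataFrame(rejects, columns=["tree", "error"])


def summarize_components(table: pd.DataFrame) -> pd.DataFrame:
    """Mean, SD and CV% (100*SD/mean) per component, as in trait-summary tables."""
    rows = []
    for comp in COMPONENT_NAMES:
        vals = table[comp].dropna()
        if vals.empty:
            continue
        mean, sd = float(vals.mean()), float(vals.std())
        rows.append(
            {
                "trait": comp,
                "n": len(vals),
                "mean": mean,
                "sd": sd,
                "cv_pct": 100.0 * sd / mean if mean != 0 else np.inf,
            }
        )
    return pd.DataFrame(rows)
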