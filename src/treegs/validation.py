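"""Family-stratified cross-validation of ABLUP/GBLUP predictions.

Individuals are dealt round-robin into k folds within each family (so each fold
holds roughly 1/k of every family), the model is refit on the training trees of
each repeat x fold with the held-out phenotypes removed — held-out trees stay
in K so their breeding values are predicted purely through relationships — and
predictive ability (PA) is the Pearson correlation between the held-out
phenotypes and their predicted breeding values.  Predictive accuracy rescales
PA by the (GBLUP) heritability: PACC = PA / sqrt(h2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluation import ConvergenceError, ModelSpec, fit_univariate
from .relatedness import RelationshipMatrix

__all__ = ["CVResult", "make_folds", "cross_validate"]


@dataclass
class CVResult:
    trait: str
    method: str  # ABLUP | GBLUP
    folds: pd.DataFrame  # repeat, fold, n_test, pa
    pa_mean: float
    pa_sd: float
    pacc: float | None  # filled once a reference h2 is supplied
    h2_reference: float | None
    n_failed: int

    def with_reference_h2(self, h2: float) -> "CVResult":
        """PACC = PA / sqrt(h2), with h2 taken from the (GBLUP) full-data fit."""
        return CVResult(
            self.trait,
            self.method,
            self.folds,
            self.pa_mean,
            self.pa_sd,
            self.pa_mean / np.sqrt(h2),
            h2,
            self.n_failed,
        )


def make_folds(
    phenotypes: pd.DataFrame,
    k: int = 10,
    stratify_by: str = "family",
    seed: int = 0,
    id_column: str = "id",
) -> pd.Series:
    """Deal individuals round-robin into k folds within each stratum.

    Within each family the individuals are shuffled and dealt so fold sizes
    within a family differ by at most one; fold numbering starts at a rotating
    offset so small families do not all land in the low folds.
    """
    if k < 2:
        raise ValueError("need at least 2 folds")
    rng = np.random.default_rng(seed)
    assignment = pd.Series(-1, index=phenotypes[id_column], dtype=int)
    start = 0
    for _, grp in phenotypes.groupby(stratify_by, sort=True):
        ids = grp[id_column].to_numpy()
        rng.shuffle(ids)
        for j, tree in enumerate(ids):
            assignment[tree] = (start + j) % k
        start = (start + len(ids)) % k
    return assignment.rename("fold")


def cross_validate(
    phenotypes: pd.DataFrame,
    trait: str,
    K: RelationshipMatrix,
    method: str,
    k: int = 10,
    repeats: int = 10,
    seed: int = 0,
    spec: ModelSpec | None = None,
) -> CVResult:
    """Repeated k-fold CV; PA per held-out fold, aggregated as mean +/- SD."""
    spec = spec or ModelSpec(traits=(trait,))
    df = phenotypes.dropna(subset=[trait]).reset_index(drop=True)
    rows = []
    n_failed = 0
    for rep in range(repeats):
        folds = make_folds(df, k=k, seed=seed * 10007 + rep, id_column=spec.id_column)
        fold_of = df[spec.id_column].map(folds)
        for fold in range(k):
            test = df[fold_of == fold]
            train = df[fold_of != fold]
            if test.empty:
                continue
            try:
                fit = fit_univariate(train, trait, K, spec)
            except (ConvergenceError, ValueError):
                n_failed += 1
                continue
            pred = fit.ebv.loc[test[spec.id_column], "ebv"].to_numpy()
            obs = test[trait].to_numpy(float)
            if np.std(pred) == 0 or np.std(obs) == 0:
                n_failed += 1
                continue
            pa = float(np.corrcoef(obs, pred)[0, 1])
            rows.append({"repeat": rep, "fold": fold, "n_test": len(test), "pa": pa})
    folds_df = pd.DataFrame(rows, columns=["repeat", "fold", "n_test", "pa"])
    if folds_df.empty:
        raise RuntimeError(f"every CV fold failed for trait {trait!r}")
    return CVResult(
        trait=trait,
        method=method,
        folds=folds_df,
        pa_mean=float(folds_df["pa"].mean()),
        pa_sd=float(folds_df["pa"].std()),
        pacc=None,
        h2_reference=None,
        n_failed=n_failed,
    )
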