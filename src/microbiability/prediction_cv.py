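"""Part-whole (LR) cross-validation of microbiome-based predictions.

Accuracy of microbial predictions is measured by refitting the model with
the phenotypes of a hold-out set removed (the animals stay in A and M, so
their m_hat remains defined through the covariance with the rest) and
correlating the partial predictions m_hat_p with the whole-data predictions
m_hat_w over the held-out animals.  Two designs: random hold-out subsets
(e.g. 50 animals, 20 replicates) and leave-one-group-out over a grouping
factor such as contemporary group.  Variance components stay fixed at their
whole-data values for every partial refit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .mixed_models import BlupSolution, FitError, ModelSpec, blup_solve
from .preprocess import RelationshipMatrix

__all__ = ["CvDesign", "PredictionAccuracy", "make_design", "lr_accuracy"]


@dataclass
class CvDesign:
    kind: str                      # "random" | "group"
    folds: list                    # list of held-out id lists
    fold_names: list
    seed: Optional[int] = None
    group_factor: Optional[str] = None


@dataclass
class PredictionAccuracy:
    per_fold: pd.DataFrame         # fold, quantity, r, n_holdout
    summary: pd.DataFrame          # quantity, mean, sd

    def mean(self, quantity: str) -> float:
        row = self.summary[self.summary["quantity"] == quantity]
        return float(row["mean"].iloc[0])

    def sd(self, quantity: str) -> float:
        row = self.summary[self.summary["quantity"] == quantity]
        return float(row["sd"].iloc[0])


def make_design(kind: str, phenotypes: pd.DataFrame,
                n_holdout: int = 50, n_replicates: int = 20,
                seed: int = 0, group_factor: str = "cg",
                trait: Optional[str] = None) -> CvDesign:
    """Hold-out folds over the phenotyped animals.

    ``random``: ``n_replicates`` independent draws of ``n_holdout`` animals
    without replacement within a replicate.  ``group``: one fold per level
    of ``group_factor`` (a partition of the animals).
    """
    ids = phenotypes["id"]
    if trait is not None:
        ids = ids[np.isfinite(phenotypes[trait].to_numpy(float))]
    ids = list(ids)
    if kind == "random":
        if n_holdout >= len(ids):
            raise FitError("hold-out size must leave at least one "
                           "phenotyped animal")
        rng = np.random.default_rng(seed)
        folds = [list(rng.choice(ids, size=n_holdout, replace=False))
                 for _ in range(n_replicates)]
        names = [f"rep{i}" for i in range(n_replicates)]
        return CvDesign(kind="random", folds=folds, fold_names=names, seed=seed)
    if kind == "group":
        if group_factor not in phenotypes.columns:
            raise FitError(f"grouping column {group_factor!r} not found")
        groups = phenotypes.set_index("id")[group_factor]
        levels = sorted(groups.unique())
        if len(levels) < 2:
            raise FitError("group design needs at least 2 levels")
        folds = [[i for i in ids if groups[i] == lev] for lev in levels]
        folds = [f for f in folds if f]
        if any(len(f) == len(ids) for f in folds):
            raise FitError("a fold would hold out every phenotyped animal")
        return CvDesign(kind="group", folds=folds,
                        fold_names=[str(lev) for lev in levels],
                        group_factor=group_factor)
    raise FitError(f"unknown design kind {kind!r}")


def lr_accuracy(design: CvDesign, spec: ModelSpec, phenotypes: pd.DataFrame,
                A: Optional[RelationshipMatrix], M: RelationshipMatrix,
                variances: dict,
                whole: Optional[BlupSolution] = None) -> PredictionAccuracy:
    """LR part-whole accuracy for m_hat (and a_hat + m_hat under Model 4).

    For each fold the held-out animals' phenotypes are set missing, the MME
    are re-solved at the whole-data variance components, and the Pearson
    correlation between partial and whole predictions is computed over the
    held-out animals only.
    """
    if not spec.include_microbiome:
        raise FitError("LR accuracy is defined for models with a microbial term")
    trait = spec.traits[0]
    if whole is None:
        whole = blup_solve(spec, phenotypes, A, M, variances)

    rows = []
    for name, fold in zip(design.fold_names, design.folds):
        part_pheno = phenotypes.copy()
        mask = part_pheno["id"].isin(fold)
        part_pheno.loc[mask, trait] = np.nan
        partial = blup_solve(spec, part_pheno, A, M, variances)
        held = [i for i in fold if i in whole.m.index]
        if len(held) == 0:
            rows.append({"fold": name, "quantity": "r_m", "r": 1.0,
                         "n_holdout": 0})
            continue
        unstable = len(held) < 3
        if unstable:
            warnings.warn(f"fold {name}: only {len(held)} held-out animals; "
                          "correlation flagged unstable")
        mp = partial.m.loc[held].to_numpy(float)
        mw = whole.m.loc[held].to_numpy(float)
        rows.append({"fold": name, "quantity": "r_m",
                     "r": _safe_corr(mp, mw), "n_holdout": len(held),
                     "unstable": unstable})
        if spec.include_genetic:
            ap = partial.a.loc[held].to_numpy(float)
            aw = whole.a.loc[held].to_numpy(float)
            rows.append({"fold": name, "quantity": "r_am",
                         "r": _safe_corr(ap + mp, aw + mw),
                         "n_holdout": len(held), "unstable": unstable})
    per_fold = pd.DataFrame(rows)
    summary = (per_fold.groupby("quantity")["r"]
               .agg(["mean", "std"]).rename(columns={"std": "sd"})
               .reset_index())
    return PredictionAccuracy(per_fold=per_fold, summary=summary)


def _safe_corr(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 2 or np.std(x) == 0 or np.std(y) == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])
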