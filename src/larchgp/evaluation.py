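"""Cross-validated predictive ability.

Predictive ability (PA) is the Pearson correlation between predicted
genetic values of validation trees and their phenotypes adjusted for block
effects, assessed under a 10-fold cross-validation scheme with 10
replicates.  The benchmark model predicts additive breeding values
(GBLUP-A); "optimal" genomic models (GS-GBLUP, GS-RKHS) keep only the
genetic terms with a non-negligible variance share and are scored on total
genetic value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import RelationshipMatrix
from .mixed_model import (
    GENETIC_LABELS,
    MixedModelFit,
    build_model,
    fit_reml,
    heritability,
    predict_genetic_values,
)
from .rkhs import (
    GibbsConfig,
    fit_gibbs,
    predict_genetic_values_rkhs,
)

__all__ = [
    "FoldPlan",
    "CVResult",
    "adjust_phenotypes",
    "make_folds",
    "predictive_ability",
    "select_optimal_terms",
    "run_cv",
    "compare_pa",
]


@dataclass
class FoldPlan:
    replicate: int
    fold: int
    validation_ids: np.ndarray
    training_ids: np.ndarray
    seed: int


def adjust_phenotypes(
    pheno: pd.DataFrame, trait: str, block_col: str = "block"
) -> pd.Series:
    """Phenotypes minus the OLS block means: y_adj = y - (mu + block-hat).

    With a single block this reduces to centring.  Estimated once on all
    phenotyped individuals; the adjustment defines the evaluation target,
    not a training-set quantity.
    """
    keep = pheno[~pheno[trait].isna()]
    y = keep[trait].to_numpy(dtype=float)
    blocks = keep[block_col].astype(str)
    fitted = blocks.map(keep.groupby(blocks)[trait].mean()).to_numpy(dtype=float)
    return pd.Series(y - fitted, index=keep["id"].to_numpy(dtype=object))


def make_folds(
    ids: Sequence[str], k: int = 10, replicates: int = 10, seed: int = 0
) -> list[FoldPlan]:
    """Seeded k-fold partitions, repeated; fold sizes differ by at most one."""
    ids = np.asarray(ids, dtype=object)
    if k > len(ids):
        raise ValueError(f"k={k} exceeds {len(ids)} individuals")
    plans = []
    for rep in range(1, replicates + 1):
        rep_seed = int(np.random.default_rng([seed, rep]).integers(2**31))
        rng = np.random.default_rng(rep_seed)
        perm = rng.permutation(len(ids))
        folds = np.array_split(perm, k)
        for f, val_idx in enumerate(folds, start=1):
            mask = np.zeros(len(ids), dtype=bool)
            mask[val_idx] = True
            plans.append(
                FoldPlan(
                    replicate=rep,
                    fold=f,
                    validation_ids=ids[mask],
                    training_ids=ids[~mask],
                    seed=rep_seed,
                )
            )
    return plans


def predictive_ability(
    predicted: pd.Series, adjusted: pd.Series, validation_ids: Sequence[str]
) -> float | None:
    """Pearson r over validation individuals with both values present.

    Returns None (undefined) with fewer than 3 overlapping individuals or a
    zero-variance vector; such folds are excluded from summaries.
    """
    common = [i for i in validation_ids if i in predicted.index and i in adjusted.index]
    if len(common) < 3:
        return None
    a = predicted.loc[common].to_numpy(dtype=float)
    b = adjusted.loc[common].to_numpy(dtype=float)
    if np.std(a) == 0 or np.std(b) == 0:
        return None
    return float(np.corrcoef(a, b)[0, 1])


def select_optimal_terms(
    fit: MixedModelFit, negligible_threshold: float = 0.05
) -> set[str]:
    """Genetic terms whose variance share clears the threshold.

    The additive term is always retained, so the optimal model never loses
    its breeding-value component.
    """
    est = heritability(fit)
    keep = {
        lab
        for lab in fit.genetic_labels
        if est.proportions[lab] >= negligible_threshold
    }
    keep.add("a")
    return keep


@dataclass
class CVResult:
    model: str  # GBLUP-A | GS-GBLUP | GS-RKHS (or custom)
    trait: str
    scores: pd.DataFrame  # columns: replicate, fold, pa (NaN where undefined)
    n_skipped: int = 0

    def fold_pas(self) -> np.ndarray:
        return self.scores["pa"].dropna().to_numpy()

    @property
    def mean_pa(self) -> float:
        return float(np.nanmean(self.scores["pa"]))

    @property
    def median_pa(self) -> float:
        return float(np.nanmedian(self.scores["pa"]))

    def replicate_means(self) -> pd.Series:
        return self.scores.groupby("replicate")["pa"].mean()


def run_cv(
    model: str,
    trait: str,
    pheno: pd.DataFrame,
    matrices: Mapping[str, RelationshipMatrix],
    folds: Sequence[FoldPlan],
    include: set[str] | None = None,
    gibbs_config: GibbsConfig | None = None,
    reml_kwargs: dict | None = None,
) -> CVResult:
    """Cross-validated predictive ability for one model/trait pair.

    *matrices* maps term labels to relationship matrices or kernels built on
    **all** individuals.  Validation phenotypes are masked before each
    training fit.  GBLUP-A scores additive BLUPs; every other model scores
    total genetic value.  Folds whose fit fails to converge are skipped and
    counted.
    """
    adjusted = adjust_phenotypes(pheno, trait)
    if include is None:
        include = {"plot", "a"} if model == "GBLUP-A" else {"plot", *matrices}
    which = "additive_only" if model == "GBLUP-A" else "total_genetic"
    is_rkhs = model.upper().endswith("RKHS")
    reml_kwargs = dict(reml_kwargs or {})
    rows = []
    n_skipped = 0
    for plan in folds:
        masked = pheno.copy()
        masked.loc[masked["id"].isin(plan.validation_ids), trait] = np.nan
        spec = build_model(masked, trait, matrices, include, name=model)
        try:
            if is_rkhs:
                cfg = gibbs_config or GibbsConfig()
                cfg = GibbsConfig(
                    n_iter=cfg.n_iter,
                    burn_in=cfg.burn_in,
                    thin=cfg.thin,
                    prior_df=cfg.prior_df,
                    seed=int(
                        np.random.default_rng(
                            [cfg.seed, plan.replicate, plan.fold]
                        ).integers(2**31)
                    ),
                )
                samples = fit_gibbs(spec, cfg)
                pred = predict_genetic_values_rkhs(
                    samples, matrices, list(plan.validation_ids), which
                )
            else:
                fit = fit_reml(spec, **reml_kwargs)
                if not fit.converged:
                    n_skipped += 1
                    rows.append(
                        {"replicate": plan.replicate, "fold": plan.fold, "pa": np.nan}
                    )
                    continue
                pred = predict_genetic_values(
                    fit, matrices, list(plan.validation_ids), which
                )
        except (np.linalg.LinAlgError, FloatingPointError):
            n_skipped += 1
            rows.append({"replicate": plan.replicate, "fold": plan.fold, "pa": np.nan})
            continue
        pa = predictive_ability(pred, adjusted, plan.validation_ids)
        rows.append(
            {
                "replicate": plan.replicate,
                "fold": plan.fold,
                "pa": np.nan if pa is None else pa,
            }
        )
    return CVResult(model=model, trait=trait, scores=pd.DataFrame(rows), n_skipped=n_skipped)


def _stars(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def compare_pa(a: CVResult, b: CVResult) -> dict:
    """Paired two-sided t-test on fold-level PAs, with a Wilcoxon companion.

    Folds are matched by (replicate, fold); significance stars follow the
    0.05 / 0.01 convention.  Identical results give p = 1 ('ns'); a
    constant nonzero shift is treated as exactly significant.
    """
    merged = a.scores.merge(
        b.scores, on=["replicate", "fold"], suffixes=("_a", "_b"), validate="one_to_one"
    )
    if len(merged) != len(a.scores) or len(merged) != len(b.scores):
        raise ValueError("fold plans of the two CV results do not match")
    merged = merged.dropna(subset=["pa_a", "pa_b"])
    d = merged["pa_a"].to_numpy() - merged["pa_b"].to_numpy()
    if len(d) < 2:
        raise ValueError("fewer than 2 matched folds with defined PA")
    if np.allclose(d, 0.0):
        p_t, t_stat, p_w = 1.0, 0.0, 1.0
    elif np.std(d, ddof=1) == 0:
        # constant nonzero shift: difference is deterministic
        p_t, t_stat, p_w = 0.0, np.inf * np.sign(d.mean()), 0.0
    else:
        t_stat, p_t = stats.ttest_rel(merged["pa_a"], merged["pa_b"])
        try:
            _, p_w = stats.wilcoxon(d)
        except ValueError:
            p_w = np.nan
    return {
        "model_a": a.model,
        "model_b": b.model,
        "trait": a.trait,
        "n_pairs": int(len(d)),
        "mean_diff": float(np.mean(d)),
        "t": float(t_stat),
        "p_ttest": float(p_t),
        "p_wilcoxon": float(p_w),
        "stars": _stars(float(p_t)),
    }
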