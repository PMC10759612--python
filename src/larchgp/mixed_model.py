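"""Multi-kernel linear mixed model fitted by REML.

One generic machine covers every model family used in the analysis:
pedigree-based individual-tree models (additive, additive + dominance) and
genomic models with additive, dominance, imprinting and additive-by-additive
epistatic terms, i.e.

    y = X beta + Z_p p + Z_a a + Z_d d + Z_i i + Z_e e + eps

with X an intercept plus block dummies, p ~ N(0, I sigma2_p) at the plot
level, each genetic term ~ N(0, K sigma2) for its relationship matrix K,
and eps ~ N(0, I sigma2_eps).

Variance components are estimated by maximising the restricted likelihood
with average-information (AI) updates, step-halving, and an EM fallback;
all components are constrained above a small positive floor.  Writing
V = sum_k theta_k C_k with C_k = Z_k K_k Z_k' (C = I for the residual),

    score_k = -1/2 [tr(P C_k) - y' P C_k P y]
    AI_kl   =  1/2  y' P C_k P C_l P y
    P       = V^-1 - V^-1 X (X' V^-1 X)^-1 X' V^-1

and the EM update theta_k <- theta_k + theta_k^2 (y'P C_k P y - tr(P C_k))/n
never decreases the restricted likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data import RelationshipMatrix

__all__ = [
    "ModelSpec",
    "MixedModelFit",
    "HeritabilityEstimate",
    "build_model",
    "fit_reml",
    "information_criteria",
    "compare_models",
    "heritability",
    "extract_blups",
    "predict_genetic_values",
]

GENETIC_LABELS = ("a", "d", "i", "e")


def _component(label: str) -> str:
    """Genetic component of a term label ('a_h5' -> 'a')."""
    return label.split("_")[0]

# default mapping from relationship-matrix kind to model term
_KIND_TO_LABEL = {
    "ped_A": "a",
    "gen_A": "a",
    "ped_D": "d",
    "gen_D": "d",
    "gen_I": "i",
    "gen_AA": "e",
}


@dataclass
class RandomTerm:
    label: str
    K: np.ndarray           # level-covariance (q x q); identity for plot
    Z: np.ndarray           # incidence (n x q)
    level_ids: np.ndarray   # labels of the q levels

    @property
    def C(self) -> np.ndarray:
        return self.Z @ self.K @ self.Z.T


@dataclass
class ModelSpec:
    trait: str
    y: np.ndarray
    X: np.ndarray
    fixed_labels: list[str]
    terms: list[RandomTerm]
    ids: np.ndarray  # phenotyped individuals, aligned with y rows
    name: str = "model"

    def __post_init__(self) -> None:
        labels = [t.label for t in self.terms]
        if len(set(labels)) != len(labels):
            raise ValueError("random-term labels must be unique")
        for t in self.terms:
            if t.K.shape[0] != t.Z.shape[1]:
                raise ValueError(
                    f"term {t.label!r}: covariance dimension {t.K.shape[0]} "
                    f"does not match incidence level count {t.Z.shape[1]}"
                )

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def labels(self) -> list[str]:
        return [t.label for t in self.terms]


def build_model(
    pheno: pd.DataFrame,
    trait: str,
    matrices: Sequence[RelationshipMatrix] | Mapping[str, RelationshipMatrix],
    include: Iterable[str],
    name: str | None = None,
    block_col: str = "block",
    plot_col: str = "plot",
) -> ModelSpec:
    """Assemble design matrices for one trait/model combination.

    ``include`` lists the random genetic terms ('a', 'd', 'i', 'e'); the
    plot term is added whenever ``'plot'`` is included (default model forms
    always carry it — pass it explicitly).  Relationship matrices may be
    given as a mapping label -> matrix or a sequence, in which case kinds
    map to labels (ped_A/gen_A -> a, ped_D/gen_D -> d, gen_I -> i,
    gen_AA -> e, kernels via their ``meta['component']``).
    """
    include = set(include)
    if isinstance(matrices, Mapping):
        by_label = dict(matrices)
    else:
        by_label = {}
        for mat in matrices:
            if mat.kind == "kernel":
                lab = mat.meta.get("component")
                if lab is None:
                    raise ValueError("kernel matrix needs meta['component']")
            else:
                lab = _KIND_TO_LABEL[mat.kind]
            by_label[lab] = mat

    keep = pheno[~pheno[trait].isna()].reset_index(drop=True)
    if keep.empty:
        raise ValueError(f"no phenotyped individuals for trait {trait!r}")
    blocks = keep[block_col].astype(str)
    if blocks.nunique() < 2:
        raise ValueError("need at least 2 blocks for the fixed design")
    ids = keep["id"].to_numpy(dtype=object)
    y = keep[trait].to_numpy(dtype=float)

    block_levels = sorted(blocks.unique())
    X = np.column_stack(
        [np.ones(len(keep))]
        + [(blocks == b).to_numpy(float) for b in block_levels[1:]]
    )
    fixed_labels = ["intercept"] + [f"block[{b}]" for b in block_levels[1:]]

    terms: list[RandomTerm] = []
    if "plot" in include:
        plots = keep[plot_col].astype(str)
        levels = sorted(plots.unique())
        Z = np.column_stack([(plots == p).to_numpy(float) for p in levels])
        terms.append(
            RandomTerm("plot", np.eye(len(levels)), Z, np.array(levels, dtype=object))
        )
    for lab in sorted(include - {"plot"}):
        if lab not in by_label:
            raise ValueError(f"term {lab!r} requested but no matching matrix given")
        K = by_label[lab].subset(ids)
        terms.append(RandomTerm(lab, K.values, np.eye(len(ids)), ids))
    return ModelSpec(
        trait=trait,
        y=y,
        X=X,
        fixed_labels=fixed_labels,
        terms=terms,
        ids=ids,
        name=name or "+".join([t.label for t in terms]),
    )


@dataclass
class MixedModelFit:
    spec_name: str
    trait: str
    variances: dict[str, float]      # term label -> sigma^2, plus 'residual'
    beta: pd.Series
    blups: dict[str, pd.Series]      # term label -> BLUPs at term levels
    logL: float
    rho: int
    n: int
    aic: float
    bic: float
    cov_variances: pd.DataFrame      # inverse-AI asymptotic covariance
    converged: bool
    n_iter: int
    floor: float
    at_floor: list[str]
    ids: np.ndarray
    Py: np.ndarray                   # P y at the optimum (for prediction)

    @property
    def genetic_labels(self) -> list[str]:
        return [k for k in self.variances if _component(k) in GENETIC_LABELS]


def _reml_loglik(
    y: np.ndarray, X: np.ndarray, V: np.ndarray
) -> tuple[float, np.ndarray]:
    """Restricted log-likelihood and the projection matrix P."""
    n, p = X.shape
    L = np.linalg.cholesky(V)
    logdetV = 2.0 * float(np.sum(np.log(np.diag(L))))
    Vinv = np.linalg.inv(V)
    XtVinv = X.T @ Vinv
    XtVinvX = XtVinv @ X
    sign, logdetXVX = np.linalg.slogdet(XtVinvX)
    if sign <= 0:
        raise np.linalg.LinAlgError("X'V^-1X is singular; check the fixed design")
    P = Vinv - XtVinv.T @ np.linalg.solve(XtVinvX, XtVinv)
    yPy = float(y @ P @ y)
    logL = -0.5 * ((n - p) * np.log(2.0 * np.pi) + logdetV + logdetXVX + yPy)
    return logL, P


def fit_reml(
    spec: ModelSpec,
    tolerance: float = 1e-8,
    max_iter: int = 200,
    floor: float | None = None,
    algorithm: str = "AI-with-EM-fallback",
    start: Sequence[float] | None = None,
    rho_includes_fixed: bool = False,
    bic_variant: str = "standard",
) -> MixedModelFit:
    """Estimate variance components by REML.

    ``algorithm`` is one of ``"AI"``, ``"EM"`` or ``"AI-with-EM-fallback"``
    (default; one EM warm-up iteration, then AI with step-halving, falling
    back to EM whenever an AI step will not increase the likelihood).
    Components are constrained above ``floor`` (default 1e-6 * var(y));
    components held at the floor still count in the parameter count rho.
    Non-convergence is flagged, not fatal.
    """
    if algorithm not in ("AI", "EM", "AI-with-EM-fallback"):
        raise ValueError(f"unknown algorithm {algorithm!r}")
    y, X = spec.y, spec.X
    n, p = X.shape
    if n <= p:
        raise ValueError("more fixed effects than observations")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("singular fixed-effect design")
    Cs = [t.C for t in spec.terms] + [np.eye(n)]
    n_levels = np.array([t.Z.shape[1] for t in spec.terms] + [n], dtype=float)
    labels = spec.labels + ["residual"]
    k = len(Cs)
    vary = float(np.var(y, ddof=1)) if n > 1 else 1.0
    if floor is None:
        floor = 1e-6 * vary
    theta = (
        np.asarray(start, dtype=float)
        if start is not None
        else np.full(k, vary / k)
    )
    theta = np.maximum(theta, floor)

    def build_V(th: np.ndarray) -> np.ndarray:
        V = np.zeros((n, n))
        for c, t in zip(Cs, th):
            V += t * c
        return V

    logL, P = _reml_loglik(y, X, build_V(theta))
    converged = False
    AI = np.eye(k)
    it = 0
    for it in range(1, max_iter + 1):
        Py = P @ y
        PC = [P @ c for c in Cs]
        trPC = np.array([float(np.trace(pc)) for pc in PC])
        CPy = [c @ Py for c in Cs]
        yPCPy = np.array([float(Py @ cpy) for cpy in CPy])
        score = -0.5 * (trPC - yPCPy)
        PCPy = [P @ cpy for cpy in CPy]
        AI = 0.5 * np.array([[float(a @ c) for c in CPy] for a in PCPy])
        # symmetrize (a'P c vs c'P a are equal analytically)
        AI = 0.5 * (AI + AI.T)

        em_theta = np.maximum(theta + theta**2 * (yPCPy - trPC) / n_levels, floor)
        # active-set treatment of the positivity constraint: a component EM is
        # driving to zero converges only asymptotically, so park it at the
        # floor once it is close and still has a downhill gradient
        snap = (em_theta < 10.0 * floor) & (score < 0)
        em_theta[snap] = floor

        free = theta > floor * (1.0 + 1e-12)
        at_floor_push = ~free & (score < 0)  # held at floor, gradient points down
        use_em = algorithm == "EM" or (algorithm == "AI-with-EM-fallback" and it == 1)
        new_theta = None
        if not use_em:
            # active-set Newton step: components pinned at the floor with a
            # downhill gradient are excluded from the AI solve, otherwise
            # they corrupt the direction for the free components
            free_idx = np.where(~at_floor_push)[0]
            delta = None
            if len(free_idx) > 0:
                sub = AI[np.ix_(free_idx, free_idx)]
                try:
                    delta = np.zeros(k)
                    delta[free_idx] = np.linalg.solve(
                        sub + 1e-12 * np.eye(len(free_idx)), score[free_idx]
                    )
                except np.linalg.LinAlgError:
                    delta = None
            if delta is not None:
                step = 1.0
                for _ in range(10):
                    cand = np.maximum(theta + step * delta, floor)
                    cand[at_floor_push] = floor
                    try:
                        cand_logL, cand_P = _reml_loglik(y, X, build_V(cand))
                    except np.linalg.LinAlgError:
                        step *= 0.5
                        continue
                    if cand_logL >= logL - 1e-10:
                        new_theta, new_logL, new_P = cand, cand_logL, cand_P
                        break
                    step *= 0.5
            if new_theta is None and algorithm == "AI":
                # AI failed outright this iteration; take the EM step anyway
                # to keep the trajectory moving (still reported as AI fit)
                use_em = True
        if new_theta is None:
            cand = em_theta
            cand_logL, cand_P = _reml_loglik(y, X, build_V(cand))
            new_theta, new_logL, new_P = cand, cand_logL, cand_P
            if algorithm == "EM" and it % 10 == 0:
                # EM approaches a boundary only asymptotically (O(1/t));
                # test the constrained boundary directly and jump there
                # when it does not lower the restricted likelihood
                for kk in range(k):
                    if (new_theta[kk] > floor and score[kk] < 0
                            and new_theta[kk] < 1e-2 * vary):
                        trial = new_theta.copy()
                        trial[kk] = floor
                        try:
                            t_logL, t_P = _reml_loglik(y, X, build_V(trial))
                        except np.linalg.LinAlgError:
                            continue
                        if t_logL >= new_logL:
                            new_theta, new_logL, new_P = trial, t_logL, t_P

        denom = np.maximum(np.abs(theta), 1e-4 * vary)
        rel_change = float(np.max(np.abs(new_theta - theta) / denom))
        dlogL = new_logL - logL
        theta, logL, P = new_theta, new_logL, new_P
        # converged at a likelihood plateau or when parameters stop moving;
        # components parked at the floor no longer block convergence.  Pure EM
        # crawls near boundaries with tiny logL steps, so the plateau rule
        # only applies to AI-driven fits.
        plateau = algorithm != "EM" and it > 1 and abs(dlogL) < 1e-9 * max(1.0, abs(logL))
        if rel_change < tolerance or plateau:
            converged = True
            break

    # final quantities at the optimum
    Py = P @ y
    V = build_V(theta)
    Vinv = np.linalg.inv(V)
    XtVinvX = X.T @ Vinv @ X
    beta = np.linalg.solve(XtVinvX, X.T @ (Vinv @ y))
    blups: dict[str, pd.Series] = {}
    for t, th in zip(spec.terms, theta[:-1]):
        u = th * (t.K @ (t.Z.T @ Py))
        blups[t.label] = pd.Series(u, index=t.level_ids)
    try:
        cov = np.linalg.inv(AI)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(AI)
    rho = k + (p if rho_includes_fixed else 0)
    aic = -2.0 * logL + 2.0 * rho
    bic = _bic(logL, rho, n, bic_variant)
    return MixedModelFit(
        spec_name=spec.name,
        trait=spec.trait,
        variances=dict(zip(labels, map(float, theta))),
        beta=pd.Series(beta, index=spec.fixed_labels),
        blups=blups,
        logL=float(logL),
        rho=rho,
        n=n,
        aic=float(aic),
        bic=float(bic),
        cov_variances=pd.DataFrame(cov, index=labels, columns=labels),
        converged=converged,
        n_iter=it,
        floor=float(floor),
        at_floor=[lab for lab, th in zip(labels, theta) if th <= floor * (1 + 1e-9)],
        ids=spec.ids,
        Py=Py,
    )


def _bic(logL: float, rho: int, n: int, variant: str) -> float:
    if variant == "standard":
        return -2.0 * logL + np.log(n) * rho
    if variant == "paper":
        # doubled penalty, as sometimes printed: -2 logL + 2 log(n) rho
        return -2.0 * logL + 2.0 * np.log(n) * rho
    raise ValueError(f"unknown bic_variant {variant!r}")


def information_criteria(
    fit: MixedModelFit, bic_variant: str = "standard"
) -> tuple[float, float]:
    """AIC = -2 logL + 2 rho; BIC with a selectable penalty variant."""
    aic = -2.0 * fit.logL + 2.0 * fit.rho
    return aic, _bic(fit.logL, fit.rho, fit.n, bic_variant)


def compare_models(fits: Sequence[MixedModelFit], threshold: float = 2.0) -> pd.DataFrame:
    """AIC/BIC ranking; models within *threshold* of the best AIC are tied."""
    traits = {f.trait for f in fits}
    ns = {f.n for f in fits}
    if len(traits) > 1 or len(ns) > 1:
        raise ValueError("fits compare only within one trait and sample size")
    df = pd.DataFrame(
        {
            "model": [f.spec_name for f in fits],
            "logL": [f.logL for f in fits],
            "rho": [f.rho for f in fits],
            "AIC": [f.aic for f in fits],
            "BIC": [f.bic for f in fits],
            "converged": [f.converged for f in fits],
        }
    )
    df["delta_AIC"] = df["AIC"] - df["AIC"].min()
    df["tied_with_best"] = df["delta_AIC"] <= threshold
    df["rank"] = df["AIC"].rank(method="min").astype(int)
    return df.sort_values("AIC").reset_index(drop=True)


@dataclass
class HeritabilityEstimate:
    h2: float | None
    H2: float
    se_h2: float | None
    se_H2: float
    sigma_g2: float
    sigma_P2: float
    proportions: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-8:
            raise ValueError(f"variance proportions sum to {total}, not 1")


def heritability(fit: MixedModelFit) -> HeritabilityEstimate:
    """Narrow- and broad-sense heritability with delta-method SEs.

    h2 = sigma2_a / sigma2_P and H2 = sigma2_g / sigma2_P, where sigma2_g
    sums exactly the genetic terms present in the fit and sigma2_P sums
    every variance component (plot and residual included).  SEs use the
    inverse-AI covariance of the components.
    """
    labels = list(fit.variances)
    theta = np.array([fit.variances[lab] for lab in labels])
    total = float(theta.sum())
    genetic = [_component(lab) in GENETIC_LABELS for lab in labels]
    sigma_g2 = float(theta[np.array(genetic)].sum())
    cov = fit.cov_variances.loc[labels, labels].to_numpy()

    def ratio_se(num_mask: np.ndarray) -> float:
        num = float(theta[num_mask].sum())
        # d(num/total)/d theta_k = (1{k in num} * total - num) / total^2
        grad = (num_mask.astype(float) * total - num) / total**2
        return float(np.sqrt(max(grad @ cov @ grad, 0.0)))

    gen_mask = np.array(genetic)
    H2 = sigma_g2 / total
    se_H2 = ratio_se(gen_mask)
    a_mask = np.array([_component(lab) == "a" for lab in labels])
    if a_mask.any():
        h2 = float(theta[a_mask].sum()) / total
        se_h2 = ratio_se(a_mask)
    else:
        h2, se_h2 = None, None
    proportions = {lab: float(v) / total for lab, v in zip(labels, theta)}
    return HeritabilityEstimate(
        h2=h2,
        H2=H2,
        se_h2=se_h2,
        se_H2=se_H2,
        sigma_g2=sigma_g2,
        sigma_P2=total,
        proportions=proportions,
    )


def extract_blups(fit: MixedModelFit, which: str = "additive_only") -> pd.Series:
    """Per-individual genetic values from a fit.

    ``additive_only`` returns the additive BLUPs; ``total_genetic`` sums the
    BLUPs of every genetic term present.
    """
    if which == "additive_only":
        gen = [v for lab, v in fit.blups.items() if _component(lab) == "a"]
        if not gen:
            raise ValueError("fit has no additive term")
    elif which == "total_genetic":
        gen = [v for lab, v in fit.blups.items() if _component(lab) in GENETIC_LABELS]
        if not gen:
            raise ValueError("fit has no genetic terms")
    else:
        raise ValueError(f"unknown which {which!r}")
    out = gen[0].copy()
    for s in gen[1:]:
        out = out.add(s)
    return out


def predict_genetic_values(
    fit: MixedModelFit,
    matrices: Mapping[str, RelationshipMatrix],
    individuals: Sequence[str],
    which: str = "additive_only",
) -> pd.Series:
    """BLUP prediction for individuals outside the training fit.

    Uses u_new = sigma2_k K_{new,train} P y per term, the standard kriging
    extension of the mixed-model BLUP; *matrices* must cover training and
    requested individuals.
    """
    if which == "additive_only":
        want = [lab for lab in fit.variances if _component(lab) == "a"]
    elif which == "total_genetic":
        want = [lab for lab in fit.variances if _component(lab) in GENETIC_LABELS]
    else:
        raise ValueError(f"unknown which {which!r}")
    total = np.zeros(len(individuals))
    for lab in want:
        if lab not in matrices:
            raise ValueError(f"no relationship matrix supplied for term {lab!r}")
        K = matrices[lab]
        missing = set(individuals) - set(K.ids)
        if missing:
            raise ValueError(f"individuals absent from {lab!r} matrix: {sorted(missing)[:5]}")
        Kvt = K.cross(individuals, list(fit.ids))
        total = total + fit.variances[lab] * (Kvt @ fit.Py)
    return pd.Series(total, index=list(individuals))
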