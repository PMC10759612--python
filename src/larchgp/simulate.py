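"""Synthetic open-pollinated progeny-trial generator.

Emulates a single-site larch progeny trial: maternal parents crossed to an
unobserved pollen pool, nominal half-sib families laid out in a randomized
complete block design on a square planting grid, and phenotypes assembled
from additive, dominance, imprinting and additive-by-additive epistatic
genetic values plus block, plot and residual effects.

Genetic values are drawn as zero-mean multivariate normals whose
covariances are the *realized* genomic relationship matrices of the
simulated genotypes (sigma^2_a * G_A and so on), so the estimation models
downstream are correctly specified and parameter recovery is a clean test.
A per-marker-effect generator is available behind ``effect_model`` for
robustness studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .data import UNKNOWN, GenotypeMatrix, Pedigree
from .kinship import epistatic_matrix, genomic_matrix

__all__ = [
    "SimulationConfig",
    "SimulatedTruth",
    "FieldLayout",
    "simulate_founders",
    "simulate_op_pedigree",
    "simulate_field_layout",
    "simulate_phenotypes",
    "inject_missingness",
    "simulate_dataset",
    "SimulatedDataset",
]

GENETIC_COMPONENTS = ("additive", "dominance", "imprinting", "epistasis")
ALL_COMPONENTS = GENETIC_COMPONENTS + ("plot", "residual")


@dataclass
class SimulationConfig:
    """Study conditions for one simulated progeny trial.

    Defaults mirror the trial being emulated: 66 open-pollinated families
    of 9-12 trees (~661 total), a pollen pool of 97 fathers, 11,333 SNPs
    with minimum MAF 0.05 and 17.7% missingness, five complete blocks with
    five-tree row plots on a 2 x 2 m grid.
    """

    n_families: int = 66
    progeny_per_family: tuple[int, int] = (9, 12)
    n_maternal_parents: int = 66
    n_pollen_parents: int = 97
    n_snps: int = 11333
    maf_min: float = 0.05
    missing_rate: float = 0.177
    n_blocks: int = 5
    plot_size: int = 5
    grid_spacing: float = 2.0
    variance_shares: Mapping[str, float] = field(
        default_factory=lambda: {
            "additive": 0.25,
            "dominance": 0.05,
            "imprinting": 0.05,
            "epistasis": 0.15,
            "plot": 0.05,
            "residual": 0.45,
        }
    )
    total_phenotypic_variance: float = 1.0
    block_effect_sd: float = 0.5
    trait_name: str = "Y"
    effect_model: str = "gaussian_process"  # or "marker_effects"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 1 or self.n_snps < 1:
            raise ValueError("need at least one family and one SNP")
        if self.n_maternal_parents < self.n_families:
            raise ValueError("each family needs its own maternal parent")
        if self.n_maternal_parents < 2 or self.n_pollen_parents < 2:
            raise ValueError("need at least two parents in each pool")
        if not 0.0 < self.maf_min <= 0.5:
            raise ValueError("maf_min must be in (0, 0.5]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        lo, hi = self.progeny_per_family
        if not 1 <= lo <= hi:
            raise ValueError("invalid progeny_per_family range")
        if lo < self.n_blocks:
            raise ValueError(
                "progeny per family must be >= n_blocks so every family "
                "appears in every block"
            )
        shares = dict(self.variance_shares)
        unknown = set(shares) - set(ALL_COMPONENTS)
        if unknown:
            raise ValueError(f"unknown variance components {sorted(unknown)}")
        for name in ALL_COMPONENTS:
            shares.setdefault(name, 0.0)
        vals = np.array([shares[c] for c in ALL_COMPONENTS])
        if (vals < 0).any():
            raise ValueError("variance shares must be nonnegative")
        if abs(vals.sum() - 1.0) > 1e-12:
            raise ValueError(f"variance shares sum to {vals.sum()}, not 1")
        self.variance_shares = shares
        if self.total_phenotypic_variance <= 0:
            raise ValueError("total_phenotypic_variance must be positive")
        if self.effect_model not in ("gaussian_process", "marker_effects"):
            raise ValueError(f"unknown effect_model {self.effect_model!r}")

    def component_variances(self) -> dict[str, float]:
        return {
            c: self.variance_shares[c] * self.total_phenotypic_variance
            for c in ALL_COMPONENTS
        }


@dataclass
class SimulatedTruth:
    """Ground truth recorded for parameter-recovery checks."""

    true_variances: dict[str, float]
    true_genetic_values: dict[str, np.ndarray]  # keys a, d, i, e per individual
    true_block_effects: dict[str, float]
    true_plot_effects: dict[str, float]
    individual_ids: np.ndarray

    def total_genetic(self) -> np.ndarray:
        return sum(self.true_genetic_values.values())


@dataclass
class FieldLayout:
    """Tree positions: columns id, family, block, plot, row, col."""

    table: pd.DataFrame
    grid_spacing: float

    def __post_init__(self) -> None:
        required = {"id", "family", "block", "plot", "row", "col"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"layout missing columns {sorted(missing)}")
        coords = list(zip(self.table["row"], self.table["col"]))
        if len(set(coords)) != len(coords):
            raise ValueError("grid coordinates are not unique")


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    # separate deterministic stream per stage so stages stay independently callable
    return np.random.default_rng([config.seed, stage])


# ---------------------------------------------------------------------------
# Founders
# ---------------------------------------------------------------------------

def simulate_founders(config: SimulationConfig) -> GenotypeMatrix:
    """Phased founder genotypes for the maternal and pollen-pool parents.

    Per-locus allele frequencies are uniform on [maf_min, 0.5] and founder
    genotypes are in Hardy-Weinberg proportions; loci that come out
    monomorphic are redrawn so every locus segregates.
    """
    rng = _rng(config, 1)
    n = config.n_maternal_parents + config.n_pollen_parents
    m = config.n_snps
    maternal = np.empty((n, m), dtype=np.int8)
    paternal = np.empty((n, m), dtype=np.int8)
    pending = np.arange(m)
    for _ in range(1000):
        if len(pending) == 0:
            break
        p = rng.uniform(config.maf_min, 0.5, size=len(pending))
        a1 = (rng.random((n, len(pending))) < p).astype(np.int8)
        a2 = (rng.random((n, len(pending))) < p).astype(np.int8)
        dose = a1 + a2
        poly = (dose.sum(axis=0) > 0) & (dose.sum(axis=0) < 2 * n)
        cols = pending[poly]
        maternal[:, cols] = a1[:, poly]
        paternal[:, cols] = a2[:, poly]
        pending = pending[~poly]
    else:  # pragma: no cover - astronomically unlikely at sane configs
        raise RuntimeError("could not draw polymorphic founder loci")
    ids = [f"M{k + 1:03d}" for k in range(config.n_maternal_parents)] + [
        f"P{k + 1:03d}" for k in range(config.n_pollen_parents)
    ]
    snp_ids = np.array([f"snp{j + 1:05d}" for j in range(m)], dtype=object)
    return GenotypeMatrix(
        np.array(ids, dtype=object),
        snp_ids,
        (maternal + paternal).astype(float),
        maternal,
        paternal,
    )


# ---------------------------------------------------------------------------
# Mating and Mendelian transmission
# ---------------------------------------------------------------------------

def _gamete(geno: GenotypeMatrix, row: int, rng: np.random.Generator) -> np.ndarray:
    pick = rng.random(geno.n_snps) < 0.5
    return np.where(pick, geno.maternal[row], geno.paternal[row]).astype(np.int8)


def simulate_op_pedigree(
    config: SimulationConfig, founders: GenotypeMatrix
) -> tuple[Pedigree, GenotypeMatrix]:
    """Open-pollinated families with known dams and pollen-pool sires.

    Each progeny's sire is drawn uniformly from the pollen pool (panmixia),
    emulating the situation after paternity reconstruction: the returned
    pedigree is the full-sib view; ``pedigree.op_view()`` hides the sires.
    Progeny genotypes are Mendelian gametes with the maternal allele
    recorded first, so parental origin is known exactly.
    """
    if founders.maternal is None:
        raise ValueError("founders must be phased")
    rng = _rng(config, 2)
    dam_ids = [f"M{k + 1:03d}" for k in range(config.n_families)]
    pollen_ids = [f"P{k + 1:03d}" for k in range(config.n_pollen_parents)]
    pos = {iid: k for k, iid in enumerate(founders.ids)}
    for iid in dam_ids + pollen_ids:
        if iid not in pos:
            raise ValueError(f"parent {iid!r} missing from founder genotypes")
    lo, hi = config.progeny_per_family
    fam_sizes = rng.integers(lo, hi + 1, size=config.n_families)
    records = [
        {"id": iid, "dam": UNKNOWN, "sire": UNKNOWN} for iid in founders.ids
    ]
    prog_ids, mats, pats = [], [], []
    for f, dam in enumerate(dam_ids):
        for k in range(fam_sizes[f]):
            sire = pollen_ids[rng.integers(0, config.n_pollen_parents)]
            iid = f"F{f + 1:02d}_{k + 1:02d}"
            records.append({"id": iid, "dam": dam, "sire": sire})
            prog_ids.append(iid)
            mats.append(_gamete(founders, pos[dam], rng))
            pats.append(_gamete(founders, pos[sire], rng))
    maternal = np.vstack(mats)
    paternal = np.vstack(pats)
    progeny = GenotypeMatrix(
        np.array(prog_ids, dtype=object),
        founders.snp_ids.copy(),
        (maternal + paternal).astype(float),
        maternal,
        paternal,
    )
    return Pedigree(pd.DataFrame(records)), progeny


# ---------------------------------------------------------------------------
# Field layout
# ---------------------------------------------------------------------------

def simulate_field_layout(config: SimulationConfig, pedigree: Pedigree) -> FieldLayout:
    """Randomized complete block layout on a square planting grid.

    Each family's progeny are spread over all blocks (so the design is a
    complete block design); within a block a family's trees form contiguous
    row plots of at most ``plot_size`` trees.  Positions are filled
    row-major, blocks stacked as horizontal bands of the same grid.
    """
    rng = _rng(config, 3)
    prog = pedigree.records[pedigree.records["dam"] != UNKNOWN]
    if prog.empty:
        raise ValueError("pedigree contains no progeny")
    fam_members: dict[str, list[str]] = {}
    for rec in prog.itertuples(index=False):
        fam_members.setdefault(rec.dam, []).append(rec.id)
    n_trees = len(prog)
    n_cols = int(np.ceil(np.sqrt(n_trees)))
    # split every family round-robin over blocks after a shuffle
    per_block: list[list[tuple[str, str]]] = [[] for _ in range(config.n_blocks)]
    for fam, members in fam_members.items():
        members = list(members)
        rng.shuffle(members)
        if len(members) < config.n_blocks:
            raise ValueError(
                f"family {fam!r} has {len(members)} trees < {config.n_blocks} blocks"
            )
        for k, iid in enumerate(members):
            per_block[k % config.n_blocks].append((fam, iid))
    rows = []
    next_row = 0
    for b in range(config.n_blocks):
        # group by family, random plot order within block
        by_fam: dict[str, list[str]] = {}
        for fam, iid in per_block[b]:
            by_fam.setdefault(fam, []).append(iid)
        plots: list[tuple[str, list[str]]] = []
        for fam in sorted(by_fam):
            members = by_fam[fam]
            for k in range(0, len(members), config.plot_size):
                label = f"B{b + 1}_{fam}_P{k // config.plot_size + 1}"
                plots.append((label, members[k:k + config.plot_size]))
        order = rng.permutation(len(plots))
        slot = 0
        for idx in order:
            label, members = plots[idx]
            for iid in members:
                fam = label.split("_")[1]
                rows.append(
                    {
                        "id": iid,
                        "family": fam,
                        "block": b + 1,
                        "plot": label,
                        "row": next_row + slot // n_cols,
                        "col": slot % n_cols,
                    }
                )
                slot += 1
        next_row += int(np.ceil(slot / n_cols))
    return FieldLayout(pd.DataFrame(rows), config.grid_spacing)


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def _bend_and_chol(values: np.ndarray) -> np.ndarray:
    """Cholesky factor, ridging the diagonal if numerically indefinite."""
    import warnings

    ridge = 1e-8 * float(np.mean(np.diag(values)))
    work = values + 1e-10 * np.eye(len(values))
    for _ in range(60):
        try:
            return np.linalg.cholesky(work)
        except np.linalg.LinAlgError:
            warnings.warn("sampling covariance bent with a small ridge")
            work[np.diag_indices_from(work)] += ridge
            ridge *= 2.0
    raise np.linalg.LinAlgError("could not bend sampling covariance")


def simulate_phenotypes(
    config: SimulationConfig,
    genotypes: GenotypeMatrix,
    layout: FieldLayout,
) -> tuple[pd.DataFrame, SimulatedTruth]:
    """Assemble phenotypes: y = block + plot + a + d + i + e + residual.

    Genetic components are multivariate normal with covariances
    sigma^2_c * G_c built from the (complete, phased) genotypes; block
    effects are fixed draws, plot and residual effects i.i.d. normal.
    The grand mean is zero.
    """
    if genotypes.missing_mask.any():
        raise ValueError("phenotype simulation needs complete genotypes")
    rng = _rng(config, 4)
    table = layout.table.set_index("id").loc[genotypes.ids].reset_index()
    n = genotypes.n_individuals
    variances = config.component_variances()

    values: dict[str, np.ndarray] = {}
    if config.effect_model == "gaussian_process":
        g_a = genomic_matrix(genotypes, "A")
        mats = {
            "additive": g_a,
            "dominance": genomic_matrix(genotypes, "D"),
            "imprinting": genomic_matrix(genotypes, "I"),
            "epistasis": epistatic_matrix(g_a),
        }
        for comp in GENETIC_COMPONENTS:
            var = variances[comp]
            if var <= 0:
                values[comp] = np.zeros(n)
                continue
            # standardize to unit mean diagonal so the nominal sigma^2 is the
            # realized per-individual variance (the imprinting matrix in its
            # published scaling has mean diagonal well above 1)
            work = mats[comp].values
            scale = float(np.mean(np.diag(work)))
            if scale <= 0:
                values[comp] = np.zeros(n)
                continue
            L = _bend_and_chol(work / scale)
            values[comp] = np.sqrt(var) * (L @ rng.standard_normal(n))
    else:  # per-marker effects, scaled to the target component variance
        oriented = genotypes.orient_minor()
        from .kinship import (
            marker_matrix_additive,
            marker_matrix_dominance,
            marker_matrix_imprinting,
        )

        builders = {
            "additive": marker_matrix_additive,
            "dominance": marker_matrix_dominance,
            "imprinting": marker_matrix_imprinting,
        }
        for comp in ("additive", "dominance", "imprinting"):
            var = variances[comp]
            if var <= 0:
                values[comp] = np.zeros(n)
                continue
            M = builders[comp](oriented)
            raw = M @ rng.standard_normal(M.shape[1])
            sd = raw.std()
            values[comp] = np.sqrt(var) * raw / (sd if sd > 0 else 1.0)
        var = variances["epistasis"]
        if var <= 0:
            values["epistasis"] = np.zeros(n)
        else:
            M = marker_matrix_additive(oriented)
            # pairwise products of a random subset of loci
            k = min(M.shape[1], 500)
            cols = rng.choice(M.shape[1], size=k, replace=False)
            prod = M[:, cols[: k // 2]] * M[:, cols[k // 2: 2 * (k // 2)]]
            raw = prod @ rng.standard_normal(prod.shape[1])
            sd = raw.std()
            values["epistasis"] = np.sqrt(var) * raw / (sd if sd > 0 else 1.0)

    block_levels = sorted(int(b) for b in table["block"].unique())
    block_eff = {
        b: float(rng.normal(0.0, config.block_effect_sd)) for b in block_levels
    }
    plot_levels = sorted(table["plot"].unique())
    plot_sd = np.sqrt(variances["plot"])
    plot_eff = {p: float(rng.normal(0.0, plot_sd)) for p in plot_levels}
    resid = rng.normal(0.0, np.sqrt(variances["residual"]), size=n)

    y = (
        np.array([block_eff[int(b)] for b in table["block"]])
        + np.array([plot_eff[p] for p in table["plot"]])
        + sum(values[c] for c in GENETIC_COMPONENTS)
        + resid
    )
    pheno = table[["id", "family", "block", "plot", "row", "col"]].copy()
    pheno[config.trait_name] = y
    truth = SimulatedTruth(
        true_variances=variances,
        true_genetic_values={
            "a": values["additive"],
            "d": values["dominance"],
            "i": values["imprinting"],
            "e": values["epistasis"],
        },
        true_block_effects=block_eff,
        true_plot_effects=plot_eff,
        individual_ids=genotypes.ids.copy(),
    )
    return pheno, truth


# ---------------------------------------------------------------------------
# Missingness
# ---------------------------------------------------------------------------

def inject_missingness(
    genotypes: GenotypeMatrix, rate: float, seed: int
) -> GenotypeMatrix:
    """Mask entries missing-completely-at-random at the given rate."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("missing rate must be in [0, 1)")
    out = genotypes.copy()
    if rate == 0.0:
        return out
    rng = np.random.default_rng(seed)
    mask = rng.random(out.dosage.shape) < rate
    out.dosage[mask] = np.nan
    if out.maternal is not None:
        out.maternal[mask] = -1
        out.paternal[mask] = -1
    return out


# ---------------------------------------------------------------------------
# One-call bundle
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    config: SimulationConfig
    founders: GenotypeMatrix
    pedigree_fs: Pedigree
    pedigree_op: Pedigree
    genotypes_complete: GenotypeMatrix  # progeny, fully observed and phased
    genotypes_observed: GenotypeMatrix  # progeny after missingness injection
    layout: FieldLayout
    phenotypes: pd.DataFrame
    truth: SimulatedTruth


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Run every stage under one seed and return the full bundle."""
    founders = simulate_founders(config)
    pedigree, progeny = simulate_op_pedigree(config, founders)
    layout = simulate_field_layout(config, pedigree)
    pheno, truth = simulate_phenotypes(config, progeny, layout)
    observed = inject_missingness(
        progeny, config.missing_rate, int(np.random.default_rng([config.seed, 5]).integers(2**31))
    )
    return SimulatedDataset(
        config=config,
        founders=founders,
        pedigree_fs=pedigree,
        pedigree_op=pedigree.op_view(),
        genotypes_complete=progeny,
        genotypes_observed=observed,
        layout=layout,
        phenotypes=pheno,
        truth=truth,
    )
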