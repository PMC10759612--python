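"""Relationship-structure construction.

Pedigree-based additive (numerator) and dominance matrices via the tabular
method, and genomic additive / dominance / imprinting matrices from centred
marker matrices, plus the Hadamard additive-by-additive epistatic matrix.

Marker coding counts the minor allele (A2).  With p_j the observed minor
allele frequency at locus j the marker matrices are

    M_A: dosage - 2 p_j
    M_D: -2 p_j^2 (A1A1), 2 p_j (1 - p_j) (het), -2 (1 - p_j)^2 (A2A2)
    M_I: 0 (homozygotes), +1 (maternal A1 / paternal A2),
         -1 (maternal A2 / paternal A1)

and the genomic matrices are

    G_A  = M_A M_A' / (2 sum_j p_j (1 - p_j))
    G_D  = M_D M_D' / sum_j (2 p_j (1 - p_j))^2
    G_I  = M_I M_I' / sum_j (2 p_j (1 - p_j))^2
    G_AA = G_A # G_A          (entrywise square; PSD by the Schur theorem)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import UNKNOWN, GenotypeMatrix, Pedigree, RelationshipMatrix

__all__ = [
    "FilterReport",
    "filter_snps",
    "impute_random",
    "pedigree_additive",
    "pedigree_dominance",
    "marker_matrix_additive",
    "marker_matrix_dominance",
    "marker_matrix_imprinting",
    "resolve_phase",
    "genomic_matrix",
    "epistatic_matrix",
]


# ---------------------------------------------------------------------------
# SNP filtering and imputation
# ---------------------------------------------------------------------------

@dataclass
class FilterReport:
    n_input: int
    n_removed_maf: int
    n_removed_call_rate: int
    n_kept: int


def filter_snps(
    genotypes: GenotypeMatrix,
    maf_min: float = 0.05,
    call_rate_min: float = 0.40,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Drop loci with observed MAF below *maf_min* or call rate below
    *call_rate_min*; returns the filtered matrix and per-rule counts."""
    call = genotypes.call_rate()
    maf = genotypes.minor_allele_freq()
    low_call = call < call_rate_min
    # loci with no calls have undefined MAF; they fail the call-rate rule
    low_maf = np.where(np.isnan(maf), False, maf < maf_min) & ~low_call
    keep = ~(low_call | low_maf)
    if not keep.any():
        raise ValueError(
            f"all {genotypes.n_snps} loci removed "
            f"(maf<{maf_min}: {int(low_maf.sum())}, "
            f"call rate<{call_rate_min}: {int(low_call.sum())})"
        )
    report = FilterReport(
        n_input=genotypes.n_snps,
        n_removed_maf=int(low_maf.sum()),
        n_removed_call_rate=int(low_call.sum()),
        n_kept=int(keep.sum()),
    )
    out = GenotypeMatrix(
        genotypes.ids.copy(),
        genotypes.snp_ids[keep],
        genotypes.dosage[:, keep],
        None if genotypes.maternal is None else genotypes.maternal[:, keep],
        None if genotypes.paternal is None else genotypes.paternal[:, keep],
        None if genotypes.imputed is None else genotypes.imputed[:, keep],
    )
    return out, report


def impute_random(genotypes: GenotypeMatrix, seed: int) -> GenotypeMatrix:
    """Fill missing dosages with Binomial(2, p_j) draws.

    p_j is the observed allele-2 frequency among non-missing calls at the
    locus, so imputation reproduces the observed allele frequencies in
    expectation.  Observed entries are never altered; imputed entries are
    flagged.  Phase of imputed entries stays unknown.
    """
    missing = genotypes.missing_mask
    out = genotypes.copy()
    if not missing.any():
        if out.imputed is None:
            out.imputed = np.zeros_like(missing)
        return out
    freq = genotypes.allele2_freq()
    bad = np.isnan(freq)
    if bad.any():
        raise ValueError(
            f"{int(bad.sum())} loci have no observed calls; filter before imputing"
        )
    rng = np.random.default_rng(seed)
    draws = rng.binomial(2, np.broadcast_to(freq, missing.shape)[missing])
    out.dosage[missing] = draws
    out.imputed = missing if out.imputed is None else (out.imputed | missing)
    return out


# ---------------------------------------------------------------------------
# Pedigree-based matrices (tabular method)
# ---------------------------------------------------------------------------

def pedigree_additive(pedigree: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix A by the tabular method.

    A_ii = 1 + A_{dam,sire}/2; A_ij = (A_{j,dam(i)} + A_{j,sire(i)})/2 with
    unknown parents contributing zero.
    """
    ids = pedigree.ids
    n = len(ids)
    pos = {iid: k for k, iid in enumerate(ids)}
    dam_idx = np.full(n, -1)
    sire_idx = np.full(n, -1)
    for k, row in enumerate(pedigree.records.itertuples(index=False)):
        if row.dam != UNKNOWN and row.dam in pos:
            dam_idx[k] = pos[row.dam]
        if row.sire != UNKNOWN and row.sire in pos:
            sire_idx[k] = pos[row.sire]
    A = np.zeros((n, n))
    for i in range(n):
        d, s = dam_idx[i], sire_idx[i]
        if i > 0:
            row = np.zeros(i)
            if d >= 0:
                row += A[d, :i]
            if s >= 0:
                row += A[s, :i]
            A[i, :i] = A[:i, i] = 0.5 * row
        A[i, i] = 1.0 + (0.5 * A[d, s] if d >= 0 and s >= 0 else 0.0)
    return RelationshipMatrix("ped_A", A, ids)


def pedigree_dominance(
    pedigree: Pedigree, additive: RelationshipMatrix | None = None
) -> RelationshipMatrix:
    """Pedigree dominance matrix.

    D_ij = (A_{s(i)s(j)} A_{d(i)d(j)} + A_{s(i)d(j)} A_{d(i)s(j)}) / 4 for
    i != j, D_ii = 1; any unknown parent zeroes the entry.
    """
    if additive is None:
        additive = pedigree_additive(pedigree)
    if additive.kind != "ped_A":
        raise ValueError("additive matrix must be pedigree-based (ped_A)")
    ids = pedigree.ids
    if not np.array_equal(additive.ids, ids):
        raise ValueError("additive matrix ids do not match pedigree")
    n = len(ids)
    pos = {iid: k for k, iid in enumerate(ids)}
    dam = np.array(
        [pos.get(r.dam, -1) if r.dam != UNKNOWN else -1
         for r in pedigree.records.itertuples(index=False)]
    )
    sire = np.array(
        [pos.get(r.sire, -1) if r.sire != UNKNOWN else -1
         for r in pedigree.records.itertuples(index=False)]
    )
    A = additive.values
    D = np.eye(n)
    known = (dam >= 0) & (sire >= 0)
    idx = np.where(known)[0]
    for a_pos, i in enumerate(idx):
        for j in idx[a_pos + 1:]:
            v = 0.25 * (
                A[sire[i], sire[j]] * A[dam[i], dam[j]]
                + A[sire[i], dam[j]] * A[dam[i], sire[j]]
            )
            D[i, j] = D[j, i] = v
    return RelationshipMatrix("ped_D", D, ids)


# ---------------------------------------------------------------------------
# Marker matrices
# ---------------------------------------------------------------------------

def _checked_dosage(genotypes: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    dosage = genotypes.dosage
    if np.isnan(dosage).any():
        raise ValueError("missing dosages present; impute before building marker matrices")
    p = genotypes.allele2_freq()
    return dosage, p


def marker_matrix_additive(genotypes: GenotypeMatrix) -> np.ndarray:
    """Centred additive coding: dosage - 2 p_j (columns sum to zero)."""
    dosage, p = _checked_dosage(genotypes)
    return dosage - 2.0 * p


def marker_matrix_dominance(genotypes: GenotypeMatrix) -> np.ndarray:
    dosage, p = _checked_dosage(genotypes)
    q = 1.0 - p
    hom1 = np.broadcast_to(-2.0 * p**2, dosage.shape)
    het = np.broadcast_to(2.0 * p * q, dosage.shape)
    hom2 = np.broadcast_to(-2.0 * q**2, dosage.shape)
    return np.select([dosage == 0, dosage == 1], [hom1, het], default=hom2)


def marker_matrix_imprinting(genotypes: GenotypeMatrix) -> np.ndarray:
    """Parent-of-origin coding: +1 maternal-A1/paternal-A2 heterozygote,
    -1 for the reciprocal, 0 for homozygotes and unresolved phase."""
    if not genotypes.is_phased:
        raise ValueError(
            "imprinting matrix needs parental-origin genotypes; run "
            "resolve_phase (or simulate phased data) first"
        )
    dosage, _ = _checked_dosage(genotypes)
    m, p = genotypes.maternal, genotypes.paternal
    out = np.zeros_like(dosage)
    known = (m >= 0) & (p >= 0)
    out[known & (m == 0) & (p == 1)] = 1.0
    out[known & (m == 1) & (p == 0)] = -1.0
    return out


def resolve_phase(genotypes: GenotypeMatrix, pedigree: Pedigree) -> GenotypeMatrix:
    """Best-effort parental-origin assignment from dam genotypes.

    A heterozygous progeny whose dam is genotyped homozygous inherits the
    dam's allele maternally; the paternal allele follows.  Homozygotes are
    trivially phased.  Heterozygotes with a heterozygous, missing or
    ungenotyped dam stay unresolved (phase code -1) and contribute zero to
    the imprinting coding.  The phasing rate is stored in a report on the
    returned matrix.
    """
    out = genotypes.copy()
    n, m = out.dosage.shape
    if out.maternal is None:
        out.maternal = np.full((n, m), -1, dtype=np.int8)
        out.paternal = np.full((n, m), -1, dtype=np.int8)
    pos = {iid: k for k, iid in enumerate(out.ids)}
    dam_row = np.full(n, -1)
    for rec in pedigree.records.itertuples(index=False):
        if rec.id in pos and rec.dam != UNKNOWN and rec.dam in pos:
            dam_row[pos[rec.id]] = pos[rec.dam]
    dosage = out.dosage
    obs = ~np.isnan(dosage)
    # homozygotes: phase is trivial
    for val, allele in ((0.0, 0), (2.0, 1)):
        mask = obs & (dosage == val)
        out.maternal[mask] = allele
        out.paternal[mask] = allele
    het = obs & (dosage == 1.0)
    unresolved_before = het & (out.maternal < 0)
    for i in range(n):
        d = dam_row[i]
        if d < 0:
            continue
        row_het = unresolved_before[i]
        dam_dos = dosage[d]
        dam_hom0 = row_het & (dam_dos == 0.0)
        dam_hom2 = row_het & (dam_dos == 2.0)
        out.maternal[i, dam_hom0] = 0
        out.paternal[i, dam_hom0] = 1
        out.maternal[i, dam_hom2] = 1
        out.paternal[i, dam_hom2] = 0
    n_het = int(het.sum())
    n_unres = int((het & (out.maternal < 0)).sum())
    out_meta = {
        "n_heterozygous": n_het,
        "n_resolved": n_het - n_unres,
        "phasing_rate": 1.0 if n_het == 0 else (n_het - n_unres) / n_het,
    }
    out.phase_report = out_meta  # type: ignore[attr-defined]
    return out


# ---------------------------------------------------------------------------
# Genomic matrices
# ---------------------------------------------------------------------------

_MARKER_BUILDERS = {
    "A": marker_matrix_additive,
    "D": marker_matrix_dominance,
    "I": marker_matrix_imprinting,
}


def genomic_matrix(genotypes: GenotypeMatrix, kind: str) -> RelationshipMatrix:
    """Genomic relationship matrix of the requested kind ('A', 'D' or 'I').

    Loci are re-oriented so the counted allele is minor before coding; the
    denominator is 2*sum p(1-p) for the additive matrix and sum (2p(1-p))^2
    for dominance and imprinting.
    """
    if kind not in _MARKER_BUILDERS:
        raise ValueError(f"kind must be one of {sorted(_MARKER_BUILDERS)}, got {kind!r}")
    oriented = genotypes.orient_minor()
    M = _MARKER_BUILDERS[kind](oriented)
    p = oriented.allele2_freq()
    het = 2.0 * p * (1.0 - p)
    denom = het.sum() if kind == "A" else (het**2).sum()
    if denom <= 0:
        raise ValueError("all loci monomorphic: zero genomic-matrix denominator")
    G = (M @ M.T) / denom
    return RelationshipMatrix(f"gen_{kind}", G, genotypes.ids.copy())


def epistatic_matrix(additive: RelationshipMatrix) -> RelationshipMatrix:
    """First-order additive-by-additive matrix: Hadamard square of G_A."""
    if additive.kind != "gen_A":
        raise ValueError(f"epistatic matrix requires gen_A input, got {additive.kind!r}")
    return RelationshipMatrix(
        "gen_AA", additive.values * additive.values, additive.ids.copy()
    )
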