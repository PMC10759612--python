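"""Core data containers: genotypes, pedigrees and relationship matrices.

Genotypes are stored as allele-2 dosages (0/1/2) with ``nan`` marking
missing calls.  When parental origin is known the maternal and paternal
alleles are carried alongside as 0/1 codes (allele 2 = 1), with -1 for
cells whose phase is unknown or missing.  Phased entries always collapse
to the unordered dosage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["GenotypeMatrix", "Pedigree", "RelationshipMatrix"]


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs dosage matrix with optional parental-origin phase.

    Parameters
    ----------
    ids : sequence of str
        Individual identifiers (rows).
    snp_ids : sequence of str
        Marker identifiers (columns).
    dosage : ndarray of float, shape (n, m)
        Count of the A2 allele in {0, 1, 2}; ``nan`` marks missing calls.
    maternal, paternal : ndarray of int8, optional
        Allele carried on the maternal / paternal gamete (0 = A1, 1 = A2);
        -1 where the parental origin is unknown or the call is missing.
    imputed : ndarray of bool, optional
        Flags entries filled in by imputation.
    """

    ids: np.ndarray
    snp_ids: np.ndarray
    dosage: np.ndarray
    maternal: np.ndarray | None = None
    paternal: np.ndarray | None = None
    imputed: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.ids), len(self.snp_ids)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.ids)} ids x {len(self.snp_ids)} snps"
            )
        if self.maternal is not None:
            self.maternal = np.asarray(self.maternal, dtype=np.int8)
            self.paternal = np.asarray(self.paternal, dtype=np.int8)
            self._check_phase_consistency()

    def _check_phase_consistency(self) -> None:
        m, p = self.maternal, self.paternal
        known = (m >= 0) & (p >= 0)
        collapsed = (m + p).astype(float)
        obs = ~np.isnan(self.dosage)
        bad = known & obs & (collapsed != self.dosage)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"phased alleles disagree with dosage at ({self.ids[i]}, "
                f"{self.snp_ids[j]})"
            )

    # -- basic properties -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def is_phased(self) -> bool:
        return self.maternal is not None

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosage)

    def call_rate(self) -> np.ndarray:
        """Fraction of individuals with an observed call, per locus."""
        return 1.0 - np.isnan(self.dosage).mean(axis=0)

    def allele2_freq(self) -> np.ndarray:
        """Observed frequency of the A2 (dosage-counted) allele per locus."""
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-missing locus
            return np.nanmean(self.dosage, axis=0) / 2.0

    def minor_allele_freq(self) -> np.ndarray:
        p = self.allele2_freq()
        return np.minimum(p, 1.0 - p)

    # -- transforms -------------------------------------------------------
    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.ids.copy(),
            self.snp_ids.copy(),
            self.dosage.copy(),
            None if self.maternal is None else self.maternal.copy(),
            None if self.paternal is None else self.paternal.copy(),
            None if self.imputed is None else self.imputed.copy(),
        )

    def orient_minor(self) -> "GenotypeMatrix":
        """Flip loci so the counted (A2) allele is the minor allele.

        Makes the observed p_j the minor-allele frequency at every locus,
        which keeps the genomic-matrix denominators well defined.
        """
        out = self.copy()
        flip = out.allele2_freq() > 0.5
        out.dosage[:, flip] = 2.0 - out.dosage[:, flip]
        if out.maternal is not None:
            for arr in (out.maternal, out.paternal):
                block = arr[:, flip]
                known = block >= 0
                block[known] = 1 - block[known]
                arr[:, flip] = block
        return out

    def unphased(self) -> "GenotypeMatrix":
        """Drop parental-origin information, keeping dosages."""
        return GenotypeMatrix(self.ids.copy(), self.snp_ids.copy(), self.dosage.copy())

    def subset(self, individuals: Sequence[str]) -> "GenotypeMatrix":
        index = {iid: k for k, iid in enumerate(self.ids)}
        rows = np.array([index[i] for i in individuals])
        return GenotypeMatrix(
            np.asarray(individuals, dtype=object),
            self.snp_ids.copy(),
            self.dosage[rows],
            None if self.maternal is None else self.maternal[rows],
            None if self.paternal is None else self.paternal[rows],
            None if self.imputed is None else self.imputed[rows],
        )


UNKNOWN = "NA"


@dataclass
class Pedigree:
    """Ordered pedigree records; parents must precede offspring.

    Unknown parents are coded with the string ``"NA"``.  The open-pollinated
    view of a reconstructed pedigree has all sires unknown; the full-sib view
    carries the assigned sires.
    """

    records: pd.DataFrame  # columns: id, dam, sire

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.records, copy=True)
        required = {"id", "dam", "sire"}
        if not required.issubset(df.columns):
            raise ValueError(f"pedigree needs columns {sorted(required)}")
        df = df[["id", "dam", "sire"]].astype(str)
        df[["dam", "sire"]] = df[["dam", "sire"]].replace(
            {"nan": UNKNOWN, "None": UNKNOWN, "": UNKNOWN}
        )
        self.records = df.reset_index(drop=True)
        self._validate_order()

    def _validate_order(self) -> None:
        seen: set[str] = set()
        ids = set(self.records["id"])
        for row in self.records.itertuples(index=False):
            if row.id in seen:
                raise ValueError(f"duplicate pedigree id {row.id!r}")
            for parent in (row.dam, row.sire):
                if parent == UNKNOWN:
                    continue
                if parent == row.id:
                    raise ValueError(f"{row.id!r} is its own parent")
                if parent in ids and parent not in seen:
                    raise ValueError(
                        f"parent {parent!r} of {row.id!r} is listed after its "
                        "offspring; pedigree must be topologically ordered"
                    )
            seen.add(row.id)

    @property
    def ids(self) -> np.ndarray:
        return self.records["id"].to_numpy(dtype=object)

    def parents_of(self, iid: str) -> tuple[str, str]:
        row = self.records.loc[self.records["id"] == iid]
        if row.empty:
            raise KeyError(iid)
        return str(row["dam"].iloc[0]), str(row["sire"].iloc[0])

    def op_view(self) -> "Pedigree":
        """Open-pollinated view: sires replaced by unknown."""
        df = self.records.copy()
        df["sire"] = UNKNOWN
        return Pedigree(df)


_VALID_KINDS = ("ped_A", "ped_D", "gen_A", "gen_D", "gen_I", "gen_AA", "kernel")


@dataclass
class RelationshipMatrix:
    """Labeled symmetric covariance-structure matrix with a kind tag."""

    kind: str
    values: np.ndarray
    ids: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in _VALID_KINDS:
            raise ValueError(f"unknown relationship kind {self.kind!r}")
        self.values = np.asarray(self.values, dtype=float)
        self.ids = np.asarray(self.ids, dtype=object)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix dimensions do not match id list")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("relationship matrix is not symmetric (1e-10)")
        # exact symmetry downstream
        self.values = 0.5 * (self.values + self.values.T)

    @property
    def n(self) -> int:
        return len(self.ids)

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values)[0])

    def bend(self, floor: float = 1e-10, ridge_scale: float = 1e-8) -> "RelationshipMatrix":
        """Ridge the diagonal until the smallest eigenvalue clears *floor*.

        Finite-sample dominance/imprinting matrices can be numerically
        indefinite; REML needs them (at least) positive semidefinite.
        """
        values = self.values.copy()
        ridge = ridge_scale * float(np.mean(np.diag(values)))
        if ridge <= 0:
            ridge = ridge_scale
        bent = False
        for _ in range(60):
            if np.linalg.eigvalsh(values)[0] >= floor:
                break
            values[np.diag_indices_from(values)] += ridge
            ridge *= 2.0
            bent = True
        meta = dict(self.meta)
        if bent:
            meta["bent"] = True
        return RelationshipMatrix(self.kind, values, self.ids.copy(), meta)

    def subset(self, individuals: Sequence[str]) -> "RelationshipMatrix":
        index = {iid: k for k, iid in enumerate(self.ids)}
        rows = np.array([index[i] for i in individuals])
        return RelationshipMatrix(
            self.kind,
            self.values[np.ix_(rows, rows)],
            np.asarray(individuals, dtype=object),
            dict(self.meta),
        )

    def cross(self, rows: Sequence[str], cols: Sequence[str]) -> np.ndarray:
        """Rectangular block linking *rows* to *cols* (e.g. validation x training)."""
        index = {iid: k for k, iid in enumerate(self.ids)}
        r = np.array([index[i] for i in rows])
        c = np.array([index[i] for i in cols])
        return self.values[np.ix_(r, c)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)
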