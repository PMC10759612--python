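"""Readers and writers for the plain-text interchange formats.

Genotypes travel as a tab-delimited individuals x SNPs matrix whose cells
are phased codes ("0|1"; maternal allele first), unordered dosages
("0"/"1"/"2"), or "." for missing.  Pedigrees and phenotypes are CSV,
relationship matrices labeled CSV, simulation truth JSON.  A minimal VCF
writer/reader (GT field, "|" phased) is provided for interoperability.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data import UNKNOWN, GenotypeMatrix, Pedigree, RelationshipMatrix
from .simulate import SimulatedTruth

__all__ = [
    "write_genotypes",
    "read_genotypes",
    "write_vcf",
    "read_vcf",
    "write_pedigree",
    "read_pedigree",
    "write_relationship",
    "read_relationship",
    "write_truth",
    "read_truth",
]


def _cell(dosage: float, m: int, p: int) -> str:
    if np.isnan(dosage):
        return "."
    if m >= 0 and p >= 0:
        return f"{m}|{p}"
    return str(int(dosage))


def write_genotypes(geno: GenotypeMatrix, path: str | Path) -> None:
    path = Path(path)
    mat = geno.maternal if geno.maternal is not None else np.full(geno.dosage.shape, -1)
    pat = geno.paternal if geno.paternal is not None else np.full(geno.dosage.shape, -1)
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(map(str, geno.snp_ids)) + "\n")
        for i, iid in enumerate(geno.ids):
            cells = [_cell(geno.dosage[i, j], mat[i, j], pat[i, j])
                     for j in range(geno.n_snps)]
            fh.write(str(iid) + "\t" + "\t".join(cells) + "\n")


def read_genotypes(path: str | Path) -> GenotypeMatrix:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        snp_ids = header[1:]
        ids, rows_d, rows_m, rows_p = [], [], [], []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            ids.append(parts[0])
            d = np.empty(len(snp_ids))
            m = np.full(len(snp_ids), -1, dtype=np.int8)
            p = np.full(len(snp_ids), -1, dtype=np.int8)
            for j, cell in enumerate(parts[1:]):
                if cell == ".":
                    d[j] = np.nan
                elif "|" in cell:
                    a, b = cell.split("|")
                    m[j], p[j] = int(a), int(b)
                    d[j] = m[j] + p[j]
                else:
                    d[j] = float(cell)
            rows_d.append(d)
            rows_m.append(m)
            rows_p.append(p)
    maternal = np.vstack(rows_m)
    paternal = np.vstack(rows_p)
    phased = (maternal >= 0).any()
    return GenotypeMatrix(
        np.array(ids, dtype=object),
        np.array(snp_ids, dtype=object),
        np.vstack(rows_d),
        maternal if phased else None,
        paternal if phased else None,
    )


def write_vcf(geno: GenotypeMatrix, path: str | Path) -> None:
    """Minimal VCF 4.2 with GT only; phased entries use '|'."""
    path = Path(path)
    mat = geno.maternal if geno.maternal is not None else np.full(geno.dosage.shape, -1)
    pat = geno.paternal if geno.paternal is not None else np.full(geno.dosage.shape, -1)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, geno.ids))
            + "\n"
        )
        for j, snp in enumerate(geno.snp_ids):
            gts = []
            for i in range(geno.n_individuals):
                d = geno.dosage[i, j]
                if np.isnan(d):
                    gts.append("./.")
                elif mat[i, j] >= 0 and pat[i, j] >= 0:
                    gts.append(f"{mat[i, j]}|{pat[i, j]}")
                else:
                    d = int(d)
                    gts.append("0/0" if d == 0 else ("0/1" if d == 1 else "1/1"))
            fh.write(
                f"1\t{j + 1}\t{snp}\tA\tC\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a VCF (GT field) via cyvcf2; honours '|' as phased."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = np.array(vcf.samples, dtype=object)
    snp_ids, dosages, mats, pats = [], [], [], []
    for var in vcf:
        snp_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        n = len(ids)
        d = np.empty(n)
        m = np.full(n, -1, dtype=np.int8)
        p = np.full(n, -1, dtype=np.int8)
        for i, (a, b, phased) in enumerate(
            (g[0], g[1], g[2]) for g in var.genotypes
        ):
            if a < 0 or b < 0:
                d[i] = np.nan
            else:
                d[i] = a + b
                if phased:
                    m[i], p[i] = a, b
                elif a == b:
                    m[i], p[i] = a, b
        dosages.append(d)
        mats.append(m)
        pats.append(p)
    maternal = np.vstack(mats).T
    paternal = np.vstack(pats).T
    phased_any = (maternal >= 0).any()
    return GenotypeMatrix(
        ids,
        np.array(snp_ids, dtype=object),
        np.vstack(dosages).T,
        maternal if phased_any else None,
        paternal if phased_any else None,
    )


def write_pedigree(ped: Pedigree, path: str | Path, op_view: bool = False) -> None:
    df = (ped.op_view() if op_view else ped).records
    df.to_csv(path, index=False)


def read_pedigree(path: str | Path) -> Pedigree:
    return Pedigree(pd.read_csv(path, dtype=str, keep_default_na=False).replace("", UNKNOWN))


def write_relationship(mat: RelationshipMatrix, path: str | Path) -> None:
    df = mat.to_frame()
    df.index.name = f"kind={mat.kind}"
    df.to_csv(path)


def read_relationship(path: str | Path, kind: str | None = None) -> RelationshipMatrix:
    df = pd.read_csv(path, index_col=0)
    if kind is None:
        name = df.index.name or ""
        kind = name.removeprefix("kind=") if name.startswith("kind=") else "kernel"
    return RelationshipMatrix(kind, df.to_numpy(), np.array(df.columns, dtype=object))


def write_truth(truth: SimulatedTruth, path: str | Path) -> None:
    payload = {
        "true_variances": truth.true_variances,
        "true_genetic_values": {
            k: v.tolist() for k, v in truth.true_genetic_values.items()
        },
        "true_block_effects": truth.true_block_effects,
        "true_plot_effects": truth.true_plot_effects,
        "individual_ids": truth.individual_ids.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def read_truth(path: str | Path) -> SimulatedTruth:
    payload = json.loads(Path(path).read_text())
    return SimulatedTruth(
        true_variances=payload["true_variances"],
        true_genetic_values={
            k: np.asarray(v) for k, v in payload["true_genetic_values"].items()
        },
        true_block_effects=payload["true_block_effects"],
        true_plot_effects=payload["true_plot_effects"],
        individual_ids=np.array(payload["individual_ids"], dtype=object),
    )
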