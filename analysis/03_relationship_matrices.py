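"""Genotype QC and relationship-matrix construction.

Reads the simulated trial, applies the SNP filters (minimum MAF 0.05, 40%
call rate), random-imputes remaining gaps, resolves parental origin from dam
genotypes, and builds every relationship structure used downstream:
pedigree A and D (OP and reconstructed full-sib views) and genomic G_A, G_D,
G_I and the Hadamard G_AA.  Writes the matrices plus a summary of their
diagonals/off-diagonals to results/.

Usage: python analysis/03_relationship_matrices.py [--data DIR] [--out DIR] [--seed N]
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from larchgp import io as lio
from larchgp.kinship import (
    epistatic_matrix,
    filter_snps,
    genomic_matrix,
    impute_random,
    pedigree_additive,
    pedigree_dominance,
    resolve_phase,
)


def summarize(name, mat):
    v = mat.values
    off = v[np.triu_indices(len(v), 1)]
    return {"matrix": name, "n": mat.n, "diag_mean": np.diag(v).mean(),
            "offdiag_mean": off.mean(), "offdiag_sd": off.std(),
            "min_eigenvalue": mat.min_eigenvalue()}


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", default="results/data")
    ap.add_argument("--out", default="results")
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    data = Path(args.data)
    geno = lio.read_genotypes(data / "genotypes.tsv")
    ped_fs = lio.read_pedigree(data / "pedigree_fs.csv")
    ped_op = lio.read_pedigree(data / "pedigree_op.csv")

    filtered, report = filter_snps(geno, maf_min=0.05, call_rate_min=0.40)
    print(f"SNP filters: {report.n_input} in, {report.n_removed_maf} below MAF, "
          f"{report.n_removed_call_rate} below call rate, {report.n_kept} kept")
    imputed = impute_random(filtered, seed=args.seed + 300)
    phased = resolve_phase(imputed, ped_fs)
    print(f"parental origin resolved for {phased.phase_report['phasing_rate']:.1%} "
          f"of heterozygous calls via homozygous dams")

    ids = list(phased.ids)
    mats = {
        "ped_A_op": pedigree_additive(ped_op).subset(ids),
        "ped_A_fs": pedigree_additive(ped_fs).subset(ids),
        "gen_A": genomic_matrix(phased, "A"),
        "gen_D": genomic_matrix(phased, "D"),
        "gen_I": genomic_matrix(phased, "I"),
    }
    mats["ped_D_fs"] = pedigree_dominance(ped_fs).subset(ids)
    mats["gen_AA"] = epistatic_matrix(mats["gen_A"])

    out = Path(args.out)
    (out / "matrices").mkdir(parents=True, exist_ok=True)
    rows = []
    for name, mat in mats.items():
        lio.write_relationship(mat, out / "matrices" / f"{name}.csv")
        rows.append(summarize(name, mat))
    summary = pd.DataFrame(rows).round(4)
    summary.to_csv(out / "matrix_summary.csv", index=False)
    print("\nrelationship-matrix summary:")
    print(summary.to_string(index=False))


if __name__ == "__main__":
    main()
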