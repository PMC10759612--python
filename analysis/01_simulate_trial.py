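"""Generate the emulated open-pollinated progeny trial.

Produces a scaled-down trial (default 20 families, ~210 trees, 1,000 SNPs
with 17.7% missingness) and writes genotypes, both pedigree views, the field
layout with phenotypes, and the simulation ground truth under results/data/.
Pass --full for the full emulated shape (66 families, ~690 trees, 11,333
SNPs; several minutes and ~100 MB of text).

Usage: python analysis/01_simulate_trial.py [--seed N] [--out DIR] [--full]
"""

import argparse
from pathlib import Path

from larchgp import io as lio
from larchgp.simulate import SimulationConfig, simulate_dataset


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", default="results/data")
    ap.add_argument("--full", action="store_true")
    args = ap.parse_args()

    if args.full:
        cfg = SimulationConfig(seed=args.seed)
    else:
        cfg = SimulationConfig(
            n_families=20, progeny_per_family=(9, 12), n_maternal_parents=20,
            n_pollen_parents=30, n_snps=1000, seed=args.seed,
        )
    sim = simulate_dataset(cfg)
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    lio.write_genotypes(sim.genotypes_observed, out / "genotypes.tsv")
    lio.write_pedigree(sim.pedigree_fs, out / "pedigree_fs.csv")
    lio.write_pedigree(sim.pedigree_fs, out / "pedigree_op.csv", op_view=True)
    sim.phenotypes.to_csv(out / "phenotypes.csv", index=False)
    lio.write_truth(sim.truth, out / "truth.json")

    miss = sim.genotypes_observed.missing_mask.mean()
    print(f"simulated {sim.genotypes_observed.n_individuals} trees in "
          f"{cfg.n_families} OP families, {cfg.n_snps} SNPs "
          f"({miss:.1%} missing), {cfg.n_blocks} blocks")
    print(f"variance shares: {dict(cfg.variance_shares)}")
    print(f"wrote dataset to {out}/")


if __name__ == "__main__":
    main()
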