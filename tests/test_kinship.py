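import numpy as np
import pandas as pd
import pytest

from larchgp.data import GenotypeMatrix, Pedigree
from larchgp.kinship import (
    epistatic_matrix,
    filter_snps,
    genomic_matrix,
    impute_random,
    marker_matrix_additive,
    marker_matrix_dominance,
    marker_matrix_imprinting,
    pedigree_additive,
    pedigree_dominance,
    resolve_phase,
)


def geno_from_dosage(dosage, ids=None, snps=None):
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    ids = ids or [f"i{k}" for k in range(n)]
    snps = snps or [f"s{j}" for j in range(m)]
    return GenotypeMatrix(np.array(ids, dtype=object), np.array(snps, dtype=object), dosage)


class TestFilter:
    def test_enumerated_toy(self):
        # 10 individuals, 5 loci: locus0 monomorphic (MAF 0), locus1 30% called,
        # loci 2-4 clean -> 3 survive
        n = 10
        dosage = np.ones((n, 5))
        dosage[:, 0] = 0.0                     # monomorphic
        dosage[: n - 3, 1] = np.nan            # 30% call rate
        dosage[:5, 2] = 0.0
        dosage[:5, 3] = 2.0
        dosage[:3, 4] = 0.0
        out, report = filter_snps(geno_from_dosage(dosage), maf_min=0.05, call_rate_min=0.40)
        assert out.n_snps == 3
        assert report.n_removed_maf == 1
        assert report.n_removed_call_rate == 1

    def test_maf_threshold_boundary(self):
        # MAF 0.049 < 0.05 removed; one clean locus kept so the call succeeds
        n = 1000
        dosage = np.zeros((n, 2))
        dosage[:98, 0] = 1.0     # p = 0.049
        dosage[: n // 2, 1] = 1.0
        out, _ = filter_snps(geno_from_dosage(dosage), maf_min=0.05)
        assert list(out.snp_ids) == ["s1"]

    def test_all_removed_raises(self):
        with pytest.raises(ValueError, match="all .* removed"):
            filter_snps(geno_from_dosage(np.zeros((6, 2))))


class TestImpute:
    def test_identity_without_missing(self):
        g = geno_from_dosage([[0, 1], [2, 1], [1, 0]])
        out = impute_random(g, seed=1)
        assert np.array_equal(out.dosage, g.dosage)

    def test_binomial_mean(self):
        # locus with observed p = 0.3; 10,000 missing entries imputed
        n = 10100
        dosage = np.full((n, 1), np.nan)
        obs = np.array([0.0] * 49 + [1.0] * 42 + [2.0] * 9)  # p = 60/200 = 0.3
        dosage[:100, 0] = obs[:100]
        g = geno_from_dosage(dosage)
        p = g.allele2_freq()[0]
        out = impute_random(g, seed=5)
        imputed = out.dosage[100:, 0]
        se = np.sqrt(2 * p * (1 - p) / len(imputed))
        assert abs(imputed.mean() - 2 * p) < 3 * se
        assert out.imputed[100:, 0].all() and not out.imputed[:100, 0].any()

    def test_fully_missing_locus_raises(self):
        dosage = np.full((4, 1), np.nan)
        with pytest.raises(ValueError, match="no observed calls"):
            impute_random(geno_from_dosage(dosage), seed=0)


class TestPedigreeMatrices:
    @pytest.fixture
    def family(self):
        # founders f1..f4 unrelated; c1, c2 full sibs; c3 maternal half sib of c1;
        # g1 = offspring of c1 x f4 (grandchild of f1/f2)
        return Pedigree(pd.DataFrame({
            "id":   ["f1", "f2", "f3", "f4", "c1", "c2", "c3", "g1"],
            "dam":  ["NA", "NA", "NA", "NA", "f1", "f1", "f1", "c1"],
            "sire": ["NA", "NA", "NA", "NA", "f2", "f2", "f3", "f4"],
        }))

    def test_tabular_values(self, family):
        A = pedigree_additive(family).to_frame()
        assert A.loc["f1", "c1"] == pytest.approx(0.5)    # parent-offspring
        assert A.loc["c1", "c2"] == pytest.approx(0.5)    # full sibs
        assert A.loc["c1", "c3"] == pytest.approx(0.25)   # half sibs
        assert A.loc["c1", "g1"] == pytest.approx(0.5)    # parent-offspring
        assert A.loc["c2", "g1"] == pytest.approx(0.25)   # aunt/uncle
        assert A.loc["f1", "g1"] == pytest.approx(0.25)   # grandparent
        assert np.allclose(np.diag(A.to_numpy()), 1.0)    # no inbreeding here

    def test_offspring_of_full_sib_by_unrelated_mates(self):
        # children of two full sibs, each mated to an unrelated founder: 0.125
        ped = Pedigree(pd.DataFrame({
            "id":   ["f1", "f2", "m1", "m2", "s1", "s2", "k1", "k2"],
            "dam":  ["NA", "NA", "NA", "NA", "f1", "f1", "s1", "s2"],
            "sire": ["NA", "NA", "NA", "NA", "f2", "f2", "m1", "m2"],
        }))
        A = pedigree_additive(ped).to_frame()
        assert A.loc["k1", "k2"] == pytest.approx(0.125)

    def test_dominance_values(self, family):
        D = pedigree_dominance(family).to_frame()
        assert D.loc["c1", "c2"] == pytest.approx(0.25)   # full sibs
        assert D.loc["f1", "c1"] == pytest.approx(0.0)    # parent-offspring
        assert D.loc["c1", "c3"] == pytest.approx(0.0)    # half sibs
        assert np.allclose(np.diag(D.to_numpy()), 1.0)

    def test_op_view_half_sib_quarter(self, family):
        A = pedigree_additive(family.op_view()).to_frame()
        assert A.loc["c1", "c2"] == pytest.approx(0.25)   # sires hidden -> HS

    def test_unordered_pedigree_rejected(self):
        with pytest.raises(ValueError, match="topologically"):
            Pedigree(pd.DataFrame({
                "id": ["kid", "mum"], "dam": ["mum", "NA"], "sire": ["NA", "NA"]
            }))


class TestMarkerMatrices:
    def test_additive_coding(self):
        # locus p=0.5: hom A1A1 -> -1; locus p=0.1: het -> 0.8
        g = geno_from_dosage([[0, 1], [2, 0], [1, 0], [1, 0], [0, 0],
                              [0, 0], [0, 0], [0, 0], [0, 0], [0, 1]])
        p = g.allele2_freq()
        assert p[0] == pytest.approx(0.2) and p[1] == pytest.approx(0.1)
        M = marker_matrix_additive(g)
        assert M[1, 0] == pytest.approx(2 - 0.4)
        assert M[0, 1] == pytest.approx(1 - 0.2)

    def test_column_sums_exactly_zero(self, tiny_sim):
        M = marker_matrix_additive(tiny_sim.genotypes_complete.orient_minor())
        assert np.allclose(M.sum(axis=0), 0.0, atol=1e-9)

    def test_dominance_coding(self):
        g = geno_from_dosage([[0], [1], [2], [1]])
        p = g.allele2_freq()[0]  # 0.5
        M = marker_matrix_dominance(g)
        assert M[0, 0] == pytest.approx(-2 * p**2)        # -0.5
        assert M[1, 0] == pytest.approx(2 * p * (1 - p))  # +0.5
        assert M[2, 0] == pytest.approx(-2 * (1 - p) ** 2)

    def test_dominance_hwe_expectation_zero(self):
        # p^2*(-2q^2) + 2pq*(2pq) + q^2*(-2p^2) = 0 for any p
        for p in (0.1, 0.2, 0.35, 0.5):
            q = 1 - p
            expect = q**2 * (-2 * p**2) + 2 * p * q * (2 * p * q) + p**2 * (-2 * q**2)
            assert expect == pytest.approx(0.0, abs=1e-12)

    def test_dominance_p02_hom_entry(self):
        g = geno_from_dosage([[2], [0], [0], [0], [0],
                              [1], [1], [0], [0], [0]])
        assert g.allele2_freq()[0] == pytest.approx(0.2)
        M = marker_matrix_dominance(g)
        assert M[0, 0] == pytest.approx(-2 * 0.8**2)  # -1.28

    def test_imprinting_toy(self):
        # 3 individuals x 2 loci with known parental origin
        maternal = np.array([[0, 1], [1, 0], [0, 0]], dtype=np.int8)
        paternal = np.array([[1, 1], [0, 0], [0, 1]], dtype=np.int8)
        g = GenotypeMatrix(
            np.array(["x", "y", "z"], dtype=object),
            np.array(["s0", "s1"], dtype=object),
            (maternal + paternal).astype(float),
            maternal,
            paternal,
        )
        M = marker_matrix_imprinting(g)
        assert np.array_equal(M, [[1, 0], [-1, 0], [0, 1]])

    def test_imprinting_antisymmetry(self, tiny_sim):
        g = tiny_sim.genotypes_complete
        M = marker_matrix_imprinting(g)
        swapped = GenotypeMatrix(
            g.ids.copy(), g.snp_ids.copy(), g.dosage.copy(),
            g.paternal.copy(), g.maternal.copy(),
        )
        assert np.array_equal(marker_matrix_imprinting(swapped), -M)

    def test_imprinting_requires_phase(self):
        with pytest.raises(ValueError, match="resolve_phase"):
            marker_matrix_imprinting(geno_from_dosage([[1], [1]]))


class TestResolvePhase:
    def test_dam_homozygous_resolves(self):
        ped = Pedigree(pd.DataFrame({
            "id": ["mum", "kid"], "dam": ["NA", "mum"], "sire": ["NA", "NA"]
        }))
        g = geno_from_dosage([[0.0], [1.0]], ids=["mum", "kid"])
        out = resolve_phase(g, ped)
        assert out.maternal[1, 0] == 0 and out.paternal[1, 0] == 1

    def test_dam_heterozygous_unresolved(self):
        ped = Pedigree(pd.DataFrame({
            "id": ["mum", "kid"], "dam": ["NA", "mum"], "sire": ["NA", "NA"]
        }))
        g = geno_from_dosage([[1.0], [1.0]], ids=["mum", "kid"])
        out = resolve_phase(g, ped)
        assert out.maternal[1, 0] == -1
        M = marker_matrix_imprinting(out)
        assert M[1, 0] == 0.0

    def test_phasing_rate_counting(self, tiny_sim):
        # phasing rate must equal the fraction of het sites whose dam is
        # genotyped homozygous (counting oracle)
        founders, prog = tiny_sim.founders, tiny_sim.genotypes_complete
        combined_ids = np.concatenate([founders.ids, prog.ids])
        dosage = np.vstack([founders.dosage, prog.dosage])
        g = GenotypeMatrix(combined_ids, founders.snp_ids.copy(), dosage.copy())
        out = resolve_phase(g, tiny_sim.pedigree_op)
        pos = {iid: k for k, iid in enumerate(combined_ids)}
        dam_of = dict(zip(tiny_sim.pedigree_op.records["id"],
                          tiny_sim.pedigree_op.records["dam"]))
        n_het = n_resolvable = 0
        for iid in combined_ids:
            dam = dam_of.get(str(iid), "NA")
            i = pos[iid]
            het = dosage[i] == 1.0
            n_het += het.sum()
            if dam != "NA":
                dam_hom = np.isin(dosage[pos[dam]], (0.0, 2.0))
                n_resolvable += (het & dam_hom).sum()
        report = out.phase_report
        assert report["n_heterozygous"] == n_het
        assert report["n_resolved"] == n_resolvable


class TestGenomicMatrices:
    def test_one_locus_hand_example(self):
        # two individuals, dosages (2, 0), observed p = 0.5:
        # M_A = (+1, -1), denom = 2*0.25 = 0.5, G_A = [[2,-2],[-2,2]]
        g = geno_from_dosage([[2.0], [0.0]])
        G = genomic_matrix(g, "A")
        assert np.allclose(G.values, [[2.0, -2.0], [-2.0, 2.0]])

    def test_diagonal_mean_near_one_under_hwe(self, rng):
        n, m = 500, 1500
        p = rng.uniform(0.1, 0.5, size=m)
        dosage = rng.binomial(2, p, size=(n, m)).astype(float)
        G = genomic_matrix(geno_from_dosage(dosage), "A")
        assert abs(np.diag(G.values).mean() - 1.0) < 0.02

    def test_imprinting_matrix_zero_for_homozygous_population(self):
        maternal = np.array([[0, 1], [1, 1], [0, 0]], dtype=np.int8)
        g = GenotypeMatrix(
            np.array(list("abc"), dtype=object),
            np.array(["s0", "s1"], dtype=object),
            (2 * maternal).astype(float), maternal, maternal.copy(),
        )
        G = genomic_matrix(g, "I")
        assert np.allclose(G.values, 0.0)

    def test_monomorphic_denominator_error(self):
        with pytest.raises(ValueError, match="denominator"):
            genomic_matrix(geno_from_dosage([[0.0], [0.0]]), "A")

    def test_symmetry_and_labels(self, tiny_sim):
        for kind in ("A", "D", "I"):
            G = genomic_matrix(tiny_sim.genotypes_complete, kind)
            assert np.allclose(G.values, G.values.T, atol=1e-10)
            assert np.array_equal(G.ids, tiny_sim.genotypes_complete.ids)

    def test_genomic_regresses_on_pedigree(self):
        # off-diagonal G_A regressed on pedigree A has slope ~1 at 5,000 loci
        from larchgp.simulate import SimulationConfig, simulate_dataset

        cfg = SimulationConfig(
            n_families=12, progeny_per_family=(9, 12), n_maternal_parents=12,
            n_pollen_parents=10, n_snps=5000, n_blocks=3, missing_rate=0.0, seed=21,
        )
        sim = simulate_dataset(cfg)
        ids = list(sim.genotypes_complete.ids)
        G = genomic_matrix(sim.genotypes_complete, "A").values
        A = pedigree_additive(sim.pedigree_fs).subset(ids).values
        iu = np.triu_indices(len(ids), 1)
        g, a = G[iu], A[iu]
        slope = np.polyfit(a, g, 1)[0]
        assert abs(slope - 1.0) < 0.1


class TestEpistatic:
    def test_entrywise_square(self, rng):
        B = rng.standard_normal((5, 8))
        G = B @ B.T
        from larchgp.data import RelationshipMatrix

        ga = RelationshipMatrix("gen_A", G, np.array(list("abcde"), dtype=object))
        gaa = epistatic_matrix(ga)
        assert np.allclose(gaa.values, G * G)

    def test_schur_psd(self, rng):
        from larchgp.data import RelationshipMatrix

        for _ in range(100):
            B = rng.standard_normal((6, 6))
            G = B @ B.T
            ga = RelationshipMatrix("gen_A", G, np.array(list("abcdef"), dtype=object))
            assert epistatic_matrix(ga).min_eigenvalue() >= -1e-8

    def test_requires_gen_a(self, rng):
        from larchgp.data import RelationshipMatrix

        B = rng.standard_normal((4, 6))
        gd = RelationshipMatrix("gen_D", B @ B.T, np.array(list("abcd"), dtype=object))
        with pytest.raises(ValueError, match="gen_A"):
            epistatic_matrix(gd)
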