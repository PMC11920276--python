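import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import build_a_matrix_oracle
from xokit.genome import SnpPanel
from xokit.pedigree import Pedigree
from xokit.quantgen import (
    CHI2_MEDIAN_1DF,
    _AnimalModel,
    a_matrix,
    a_matrix_inverse,
    bonferroni_threshold,
    genomic_control,
    grm,
    mlm_loco_gwas,
    reml_animal_model,
)
from xokit.simulate import simulate_pedigree, simulate_phenotypes_direct


class TestAMatrixInverse:
    def test_founders_identity(self):
        ped = Pedigree(pd.DataFrame(
            {"id": [1, 2, 3], "sire": 0, "dam": 0, "sex": ["M", "F", "F"]}
        ))
        np.testing.assert_allclose(a_matrix_inverse(ped).toarray(), np.eye(3))

    def test_trio_closed_form(self, trio_pedigree):
        Ainv = a_matrix_inverse(trio_pedigree).toarray()
        expected = np.array([[1.5, 0.5, -1.0], [0.5, 1.5, -1.0], [-1.0, -1.0, 2.0]])
        np.testing.assert_allclose(Ainv, expected)
        # dense-inverse oracle on the directly built A
        A = np.array([[1, 0, 0.5], [0, 1, 0.5], [0.5, 0.5, 1]])
        np.testing.assert_allclose(Ainv, np.linalg.inv(A), atol=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_pedigree_dense_inverse_oracle(self, seed):
        ped = simulate_pedigree(4, 8, 3, 2, seed)
        assert len(ped) <= 200
        A = build_a_matrix_oracle(ped)  # independent pairwise recursion
        Ainv = a_matrix_inverse(ped).toarray()
        np.testing.assert_allclose(Ainv @ A, np.eye(len(ped)), atol=1e-8)

    def test_inbred_pedigree_needs_inbreeding_rules(self):
        # full-sib mating: offspring of two full sibs is inbred (F = 1/4)
        df = pd.DataFrame({
            "id": [1, 2, 3, 4, 5],
            "sire": [0, 0, 1, 1, 3],
            "dam": [0, 0, 2, 2, 4],
            "sex": ["M", "F", "M", "F", "M"],
        })
        ped = Pedigree(df)
        A = build_a_matrix_oracle(ped)
        assert A[4, 4] == pytest.approx(1.25)
        Ainv = a_matrix_inverse(ped, inbreeding=True).toarray()
        np.testing.assert_allclose(Ainv @ A, np.eye(5), atol=1e-10)

    def test_package_a_matrix_agrees_with_oracle(self):
        ped = simulate_pedigree(3, 5, 2, 2, 7)
        np.testing.assert_allclose(a_matrix(ped), build_a_matrix_oracle(ped), atol=1e-12)


class TestREML:
    def test_null_va_recovery(self):
        h2s = []
        for seed in range(6):
            ped = simulate_pedigree(10, 100, 2, 1, seed)
            fids = [int(i) for i in ped.non_founders()]
            rec, _ = simulate_phenotypes_direct(
                ped, V_A=0.0, V_PE=0.5, V_E=4.0, n_records_per_fid=4, fids=fids, seed=seed
            )
            vc = reml_animal_model(rec, ped, repeated=True, compute_se=False)
            h2s.append(vc.h2)
        assert np.median(h2s) < 0.02

    def test_h2_03_single_record_recovery(self):
        h2s = []
        for seed in range(6):
            ped = simulate_pedigree(40, 400, 5, 1, seed)
            fids = [int(i) for i in ped.non_founders()]
            rec, _ = simulate_phenotypes_direct(
                ped, V_A=3.0, V_PE=0.0, V_E=7.0, n_records_per_fid=1, fids=fids, seed=seed
            )
            vc = reml_animal_model(rec, ped, repeated=False, compute_se=False)
            h2s.append(vc.h2)
        assert np.median(h2s) == pytest.approx(0.3, abs=0.08)

    def test_repeated_records_recovery(self):
        h2s, pe2s = [], []
        for seed in range(6):
            ped = simulate_pedigree(20, 150, 2, 1, seed)
            fids = [int(i) for i in ped.non_founders()]
            rec, _ = simulate_phenotypes_direct(
                ped, V_A=1.0, V_PE=1.0, V_E=8.0, n_records_per_fid=10, fids=fids, seed=seed
            )
            vc = reml_animal_model(rec, ped, repeated=True, compute_se=False)
            h2s.append(vc.h2)
            pe2s.append(vc.pe2)
        assert np.median(h2s) == pytest.approx(0.10, abs=0.04)
        assert np.median(pe2s) == pytest.approx(0.10, abs=0.04)

    def test_em_steps_monotone_restricted_likelihood(self):
        ped = simulate_pedigree(5, 30, 3, 1, 13)
        fids = [int(i) for i in ped.non_founders()]
        rec, _ = simulate_phenotypes_direct(
            ped, V_A=1.0, V_PE=0.5, V_E=2.0, n_records_per_fid=4, fids=fids, seed=13
        )
        model = _AnimalModel(rec, ped, repeated=True)
        sA, sPE, sE = 0.1, 0.1, 3.0  # deliberately poor start
        ll = model.restricted_loglik(sA, sPE, sE)
        for _ in range(15):
            sA, sPE, sE = model.em_step(sA, sPE, sE)
            ll_new = model.restricted_loglik(sA, sPE, sE)
            assert ll_new >= ll - 1e-8
            ll = ll_new

    def test_se_reported(self):
        ped = simulate_pedigree(10, 80, 3, 1, 5)
        fids = [int(i) for i in ped.non_founders()]
        rec, _ = simulate_phenotypes_direct(
            ped, V_A=2.0, V_PE=0.0, V_E=3.0, n_records_per_fid=1, fids=fids, seed=5
        )
        vc = reml_animal_model(rec, ped, repeated=False)
        assert vc.se.get("V_A", 0) > 0 and vc.se.get("h2", 0) > 0
        assert 0 <= vc.h2 <= 1 and vc.h2 + vc.pe2 <= 1

    def test_unknown_fid_errors(self, trio_pedigree):
        rec = pd.DataFrame({"fid": [99], "record": [1], "y": [1.0]})
        with pytest.raises(ValueError, match="absent"):
            reml_animal_model(rec, trio_pedigree)

    def test_empty_records_error(self, trio_pedigree):
        with pytest.raises(ValueError, match="no phenotype"):
            reml_animal_model(pd.DataFrame(columns=["fid", "y"]), trio_pedigree)


def _founder_genotypes(n_ind, n_snp, seed, freqs=None):
    rng = np.random.default_rng(seed)
    if freqs is None:
        freqs = rng.uniform(0.1, 0.5, n_snp)
    g = rng.binomial(2, freqs, (n_ind, n_snp))
    ids = [f"s{j}" for j in range(n_snp)]
    return pd.DataFrame(g, index=range(1, n_ind + 1), columns=ids), freqs


def _panel(n_snp, n_chrom=18):
    per = n_snp // n_chrom
    chrom = np.repeat(np.arange(1, n_chrom + 1), per)
    bp = np.tile(np.arange(1, per + 1) * 1_000_000, n_chrom)
    return SnpPanel(chrom=chrom, bp=bp.astype(np.int64),
                    ids=np.array([f"s{j}" for j in range(per * n_chrom)], dtype=object))


class TestGRM:
    def test_duplicate_individuals(self):
        geno, _ = _founder_genotypes(20, 50, 1)
        geno.iloc[1] = geno.iloc[0]
        K = grm(geno)
        assert K[0, 1] == pytest.approx(K[0, 0])
        assert K[1, 0] == pytest.approx(K[1, 1])

    def test_diagonal_near_one_for_founders(self):
        geno, _ = _founder_genotypes(100, 2000, 2)
        K = grm(geno)
        assert np.mean(np.diag(K)) == pytest.approx(1.0, abs=0.05)
        np.testing.assert_allclose(K, K.T)

    def test_loco_exclusion_bookkeeping(self):
        n_snp = 180
        geno, _ = _founder_genotypes(30, n_snp, 3)
        panel = _panel(n_snp)
        kept = (panel.chrom != 4).sum()
        assert n_snp - kept == panel.markers_on(4).size
        K_full, K_loco = grm(geno), grm(geno, panel, exclude_chromosome=4)
        assert not np.allclose(K_full, K_loco)

    def test_too_few_markers(self):
        geno, _ = _founder_genotypes(10, 3, 4)
        geno.iloc[:, :] = 0
        with pytest.raises(ValueError, match="fewer than 2"):
            grm(geno)


@pytest.fixture(scope="module")
def null_gwas():
    """Pure-noise phenotype on 10,000 simulated SNPs (one seeded run)."""
    n_ind, n_snp = 300, 10_008
    geno, _ = _founder_genotypes(n_ind, n_snp, 5)
    panel = _panel(n_snp)
    rng = np.random.default_rng(6)
    pheno = pd.DataFrame({"fid": geno.index, "y": rng.normal(0, 1, n_ind)})
    return mlm_loco_gwas(pheno, geno, panel)


class TestGwas:
    def test_null_pvalues_uniform(self, null_gwas):
        ks = stats.kstest(null_gwas["p_raw"], "uniform")
        assert ks.pvalue > 0.01

    def test_null_lambda_near_one(self, null_gwas):
        assert 0.9 <= null_gwas["lambda_gc"].iloc[0] <= 1.1

    def test_null_type_one_error(self, null_gwas):
        rate = (null_gwas["p_raw"] < 0.05).mean()
        assert 0.035 <= rate <= 0.065

    def test_output_schema_sorted(self, null_gwas):
        assert list(null_gwas["chrom"]) == sorted(null_gwas["chrom"])
        assert ((null_gwas["maf"] > 0) & (null_gwas["maf"] <= 0.5)).all()
        assert ((null_gwas["p_raw"] > 0) & (null_gwas["p_raw"] <= 1)).all()
        assert (null_gwas["se"] > 0).all()

    def _qtl_sim(self, seed, beta=-1.0, n_ind=400, n_snp=360):
        geno, freqs = _founder_genotypes(n_ind, n_snp, seed)
        panel = _panel(n_snp)
        causal = 45  # chromosome 3
        rng = np.random.default_rng(seed + 1)
        dosage = geno.iloc[:, causal].to_numpy(dtype=float)
        if freqs[causal] > 0.5:
            dosage = 2 - dosage
        y = beta * dosage + rng.normal(0, 1.0, n_ind)
        pheno = pd.DataFrame({"fid": geno.index, "y": y})
        return geno, panel, pheno, causal, dosage

    def test_planted_qtl_top_hit_and_sign(self):
        geno, panel, pheno, causal, _ = self._qtl_sim(7)
        res = mlm_loco_gwas(pheno, geno, panel)
        top = res.loc[res["p_raw"].idxmin()]
        assert top["marker"] == f"s{causal}"
        assert top["beta"] < 0

    def test_scale_equivariance(self):
        geno, panel, pheno, causal, _ = self._qtl_sim(8)
        res1 = mlm_loco_gwas(pheno, geno, panel, gc_correct=False)
        pheno2 = pheno.assign(y=2 * pheno["y"])
        res2 = mlm_loco_gwas(pheno2, geno, panel, gc_correct=False)
        np.testing.assert_allclose(res2["beta"], 2 * res1["beta"], rtol=1e-8)
        np.testing.assert_allclose(res2["se"], 2 * res1["se"], rtol=1e-8)
        np.testing.assert_allclose(res2["p_raw"], res1["p_raw"], rtol=1e-6)

    def test_monomorphic_skipped(self):
        geno, panel, pheno, *_ = self._qtl_sim(9, n_ind=100, n_snp=180)
        geno.iloc[:, 10] = 0
        res = mlm_loco_gwas(pheno, geno, panel)
        assert "s10" not in set(res["marker"])
        assert ("s10", "monomorphic") in res.attrs["skipped"]

    def test_covariate_accepted(self):
        geno, panel, pheno, causal, dosage = self._qtl_sim(10, n_ind=150, n_snp=180)
        pheno = pheno.assign(cc=dosage * 0.5 + 1.0)
        res = mlm_loco_gwas(pheno, geno, panel, covariates=["cc"])
        assert len(res) > 0

    def test_loco_relieves_proximal_contamination(self):
        # causal SNP chi2 with LOCO GRM >= with full GRM in most replicates
        from xokit.quantgen import _reml_single_kernel

        wins = 0
        for seed in range(10):
            geno, panel, pheno, causal, dosage = self._qtl_sim(
                100 + seed, beta=-0.7, n_ind=200, n_snp=360
            )
            y = pheno["y"].to_numpy()
            X = np.ones((len(y), 1))
            chi2 = {}
            for label, K in (
                ("loco", grm(geno, panel, exclude_chromosome=3)),
                ("full", grm(geno)),
            ):
                sg, se_, d, U = _reml_single_kernel(y, X, K)
                w = sg * d + se_
                yt, Xt = U.T @ y, U.T @ X
                xt = U.T @ dosage
                Xs = np.column_stack([Xt, xt])
                A = (Xs / w[:, None]).T @ Xs
                cov = np.linalg.inv(A)
                b = cov @ ((Xs / w[:, None]).T @ yt)
                chi2[label] = (b[-1] / np.sqrt(cov[-1, -1])) ** 2
            if chi2["loco"] >= chi2["full"]:
                wins += 1
        assert wins >= 8


class TestGenomicControl:
    def test_calibration_point(self):
        lam, p = genomic_control(np.full(101, 0.4549))
        assert lam == pytest.approx(1.0, abs=1e-3)

    def test_scale_property(self):
        rng = np.random.default_rng(1)
        chi2 = rng.chisquare(1, 1001)
        lam1, _ = genomic_control(chi2)
        lam2, _ = genomic_control(2 * chi2)
        assert lam2 == pytest.approx(2 * lam1)

    def test_null_simulation(self):
        rng = np.random.default_rng(2)
        chi2 = rng.chisquare(1, 10_000)
        lam, p = genomic_control(chi2)
        assert 0.9 <= lam <= 1.1

    def test_no_correction_when_deflated(self):
        chi2 = np.full(11, 0.1)  # lambda < 1
        lam, p = genomic_control(chi2)
        assert lam < 1
        np.testing.assert_allclose(p, stats.chi2.sf(chi2, 1))

    def test_empty_errors(self):
        with pytest.raises(ValueError, match="empty"):
            genomic_control(np.array([]))


class TestBonferroni:
    def test_paper_snp_count(self):
        thr = bonferroni_threshold(0.05, 524_587)
        assert f"{thr:.2e}" == "9.53e-08"

    def test_identity(self):
        assert bonferroni_threshold(0.05, 1) == 0.05

    def test_arithmetic(self):
        assert bonferroni_threshold(0.05, 5) == pytest.approx(0.01)

    def test_invalid(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.0, 10)
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)
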