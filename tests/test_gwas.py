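"""LMM engine: GRM/PC oracles, REML limits and recovery, GLS exactness,
allele symmetry and genomic-control behavior."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from igwas.config import SimConfig
from igwas.gwas import (
    Kinship, LmmWorkspace, assoc_scan, compute_grm, compute_pcs,
    genomic_inflation, reml_fit_null, run_endophenotype_gwas,
)
from igwas.synthetic import GenotypePanel, simulate_genotypes


def _panel_from_dosages(dosages, chrom=None, stride=5000):
    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    chrom = np.array(chrom if chrom is not None else ["1"] * m)
    pos = np.empty(m, dtype=np.int64)
    for c in np.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        pos[idx] = 1 + np.arange(len(idx)) * stride
    p = dosages.mean(axis=0) / 2
    return GenotypePanel(dosages=dosages, chrom=chrom, pos=pos,
                         ref=np.array(["A"] * m), alt=np.array(["C"] * m),
                         maf=np.minimum(p, 1 - p))


class TestGrm:
    def test_one_snp_closed_form(self):
        panel = _panel_from_dosages([[0], [2]])
        K = compute_grm(panel, maf_filter=0.0)
        assert np.allclose(K.values, [[2, -2], [-2, 2]])

    def test_duplicated_subject_matches_diagonal(self, small_panel):
        d = np.vstack([small_panel.dosages, small_panel.dosages[:1]])
        panel = _panel_from_dosages(d)
        K = compute_grm(panel).values
        n = small_panel.n_subjects
        assert K[0, n] == pytest.approx(K[0, 0], abs=1e-12)

    def test_matches_two_loop_oracle(self, small_panel):
        from igwas.gwas import standardized_dosages

        K = compute_grm(small_panel).values
        Z, keep = standardized_dosages(small_panel, 0.01)
        n, M = Z.shape
        ref = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                ref[i, j] = sum(Z[i, k] * Z[j, k] for k in range(M)) / M
        assert np.max(np.abs(K - ref)) < 1e-10

    def test_monomorphic_only_panel_rejected(self):
        panel = _panel_from_dosages(np.zeros((5, 3)))
        with pytest.raises(ValueError):
            compute_grm(panel)


class TestPcs:
    def test_rank_one_recovers_generator(self, rng):
        v = rng.standard_normal(30)
        K = Kinship(values=np.outer(v, v), n_snps=1)
        pc1 = compute_pcs(K, k=1)[:, 0]
        cos = abs(pc1 @ v / np.linalg.norm(v))
        assert cos == pytest.approx(1.0, abs=1e-10)

    def test_eigenvalues_match_dense_oracle(self, small_panel):
        K = compute_grm(small_panel)
        pcs = compute_pcs(K, k=5)
        lam_ref, U_ref = np.linalg.eigh(K.values)
        top = U_ref[:, np.argsort(lam_ref)[::-1][:5]]
        for j in range(5):
            assert abs(abs(pcs[:, j] @ top[:, j]) - 1.0) < 1e-8

    def test_sign_convention(self, small_panel):
        pcs = compute_pcs(compute_grm(small_panel), k=4)
        for j in range(4):
            assert pcs[np.argmax(np.abs(pcs[:, j])), j] > 0

    def test_k_too_large_rejected(self, small_panel):
        with pytest.raises(ValueError):
            compute_pcs(compute_grm(small_panel), k=small_panel.n_subjects)


class TestReml:
    def test_null_variance_reduces_to_ols(self, small_panel, rng):
        n = small_panel.n_subjects
        K = compute_grm(small_panel)
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = X @ [0.5, 1.0] + rng.standard_normal(n)   # no genetic component
        sg2, se2, _ = reml_fit_null(y, X, K)
        assert sg2 < 0.05 * se2
        ws = LmmWorkspace.build(small_panel, loco=False)
        tab = assoc_scan(y, X, ws)
        # compare against plain OLS per SNP
        for j in range(0, small_panel.n_snps, 7):
            if tab.flag[j] != "ok":
                continue
            g = small_panel.dosages[:, j].astype(float)
            A = np.column_stack([X, g])
            coef, res_ss, *_ = np.linalg.lstsq(A, y, rcond=None)
            assert tab.beta[j] == pytest.approx(coef[-1], abs=2e-4)

    def test_recovers_variance_components(self):
        cfg = SimConfig(n_subjects=500, n_snps=800, ld_block_size=1,
                        within_block_r=0.0, seed=21)
        panel = simulate_genotypes(cfg)
        K = compute_grm(panel)
        lam, U = K.eig()
        ests = []
        for s in range(20):
            r = np.random.default_rng(300 + s)
            g = U @ (r.standard_normal(500) * np.sqrt(0.5 * lam))
            y = g + r.standard_normal(500) * np.sqrt(0.5)
            sg2, se2, _ = reml_fit_null(y, np.ones((500, 1)), K)
            ests.append((sg2, se2))
        mean = np.mean(ests, axis=0)
        assert abs(mean[0] - 0.5) < 0.15
        assert abs(mean[1] - 0.5) < 0.15

    def test_optimum_beats_random_ratios(self, small_panel, rng):
        from igwas.gwas import _reml_neg_loglik

        n = small_panel.n_subjects
        K = compute_grm(small_panel)
        lam, U = K.eig()
        y = rng.standard_normal(n)
        X = np.ones((n, 1))
        _, _, ll = reml_fit_null(y, X, K)
        ty, tX = U.T @ y, U.T @ X
        for lr in rng.uniform(-10, 10, 20):
            assert ll >= -_reml_neg_loglik(lr, lam, ty, tX) - 1e-7

    def test_rank_deficient_covariates_rejected(self, small_panel, rng):
        n = small_panel.n_subjects
        X = np.column_stack([np.ones(n), np.ones(n)])
        with pytest.raises(ValueError):
            reml_fit_null(rng.standard_normal(n), X, compute_grm(small_panel))


class TestAssocScan:
    def test_matches_dense_gls_oracle(self, rng):
        cfg = SimConfig(n_subjects=20, n_snps=30, ld_block_size=5,
                        within_block_r=0.5, seed=3)
        panel = simulate_genotypes(cfg)
        y = rng.standard_normal(20)
        X = np.column_stack([np.ones(20), rng.standard_normal(20)])
        ws = LmmWorkspace.build(panel, loco=False)
        tab = assoc_scan(y, X, ws)
        sg2, se2, _ = reml_fit_null(y, X, ws.K)
        V = sg2 * ws.K.values + se2 * np.eye(20)
        Vi = np.linalg.inv(V)
        P = Vi - Vi @ X @ np.linalg.inv(X.T @ Vi @ X) @ X.T @ Vi
        for j in range(panel.n_snps):
            if tab.flag[j] != "ok":
                continue
            g = panel.dosages[:, j].astype(float)
            gPg = g @ P @ g
            assert tab.beta[j] == pytest.approx(g @ P @ y / gPg, abs=1e-8)
            assert tab.se[j] == pytest.approx(1 / np.sqrt(gPg), abs=1e-8)
            assert tab.chi2[j] == pytest.approx((g @ P @ y) ** 2 / gPg, abs=1e-8)

    def test_allele_swap_flips_beta_preserves_chi2(self, rng):
        cfg = SimConfig(n_subjects=80, n_snps=20, seed=6)
        panel = simulate_genotypes(cfg)
        y = rng.standard_normal(80)
        X = np.ones((80, 1))
        swapped = _panel_from_dosages(2 - panel.dosages,
                                      chrom=list(panel.chrom))
        t1 = assoc_scan(y, X, LmmWorkspace.build(panel, loco=False))
        t2 = assoc_scan(y, X, LmmWorkspace.build(swapped, loco=False))
        ok = (t1.flag == "ok") & (t2.flag == "ok")
        assert np.allclose(t1.beta[ok], -t2.beta[ok], atol=1e-10)
        assert np.allclose(t1.chi2[ok], t2.chi2[ok], atol=1e-10)

    def test_monomorphic_snp_flagged(self, rng):
        d = rng.integers(0, 3, (30, 4))
        d[:, 2] = 1
        panel = _panel_from_dosages(d)
        tab = assoc_scan(rng.standard_normal(30), np.ones((30, 1)),
                         LmmWorkspace.build(panel, maf_filter=0.01, loco=False))
        assert tab.flag[2] == "monomorphic"
        assert tab.beta[2] == 0.0 and tab.pvalue[2] == 1.0


class TestRunGwas:
    def _inputs(self, small_panel, small_subjects, rng, d_traits=3):
        ids = [str(s) for s in small_panel.subject_ids]
        traits = pd.DataFrame(rng.standard_normal((len(ids), d_traits)),
                              index=ids,
                              columns=[f"e{j}" for j in range(d_traits)])
        covars = pd.DataFrame({
            "id": ids,
            "age": [s.age for s in small_subjects],
            "sex": [s.sex for s in small_subjects],
        })
        return traits, covars

    def test_table_shape_and_identical_eyes(self, small_panel, small_subjects,
                                            rng):
        traits, covars = self._inputs(small_panel, small_subjects, rng)
        left, right = run_endophenotype_gwas(traits, traits, covars,
                                             small_panel, n_pcs=4)
        assert len(left) == 3 * small_panel.n_snps
        pd.testing.assert_frame_equal(
            left.drop(columns="eye"), right.drop(columns="eye"))

    def test_subject_mismatch_lists_offenders(self, small_panel,
                                              small_subjects, rng):
        traits, covars = self._inputs(small_panel, small_subjects, rng)
        bad = traits.rename(index={traits.index[0]: "INTRUDER"})
        with pytest.raises(ValueError, match="INTRUDER"):
            run_endophenotype_gwas(bad, bad, covars, small_panel)


class TestGenomicInflation:
    def test_all_half_is_one(self):
        assert genomic_inflation([0.5] * 10) == pytest.approx(1.0, abs=1e-9)

    def test_scale_equivariance(self, rng):
        chi2 = stats.chi2.rvs(1, size=1001, random_state=7)
        p1 = stats.chi2.sf(chi2, 1)
        p2 = stats.chi2.sf(2 * chi2, 1)
        assert genomic_inflation(p2) == pytest.approx(
            2 * genomic_inflation(p1), rel=1e-9)

    def test_uniform_pvalues_near_one(self, rng):
        p = rng.uniform(0, 1, 10_000)
        assert 0.95 < genomic_inflation(p) < 1.05

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            genomic_inflation([])
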