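"""Dual-eye selection, clumping, LD scores, LDSC, descriptives, catalog."""

import numpy as np
import pandas as pd
import pytest

from igwas.postprocess import (
    Locus, SelectedVariant, catalog_range_query, clump_loci,
    compute_ld_scores, endophenotype_descriptives, intersect_eyes,
    ld_r2_matrix, ldsc_h2, ldsc_rg, pairwise_hits,
)
from igwas.synthetic import GenotypePanel
from igwas.config import SimConfig
from igwas.synthetic import simulate_genotypes


def _assoc_table(snps, traits, pvals, eye="left"):
    rows = []
    for i, s in enumerate(snps):
        for j, t in enumerate(traits):
            rows.append((s, "1", (i + 1) * 1000, t, eye, pvals[i][j]))
    return pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "trait",
                                       "eye", "pvalue"])


class TestIntersectEyes:
    def test_both_pass_selected_with_smaller_p(self):
        left = _assoc_table(["s1"], ["t"], [[1e-9]])
        right = _assoc_table(["s1"], ["t"], [[2e-8]], eye="right")
        sel = intersect_eyes(left, right)
        assert len(sel) == 1
        assert sel[0].reported_p == 1e-9

    def test_one_eye_fails_not_selected(self):
        left = _assoc_table(["s1"], ["t"], [[1e-9]])
        right = _assoc_table(["s1"], ["t"], [[6e-8]], eye="right")
        assert intersect_eyes(left, right) == []

    def test_universe_mismatch_rejected(self):
        left = _assoc_table(["s1"], ["t"], [[0.5]])
        right = _assoc_table(["s2"], ["t"], [[0.5]], eye="right")
        with pytest.raises(ValueError, match="s1"):
            intersect_eyes(left, right)

    def test_matches_double_loop_oracle(self, rng):
        snps = [f"s{i}" for i in range(30)]
        traits = [f"t{j}" for j in range(4)]
        pl = 10 ** -rng.uniform(0, 12, (30, 4))
        pr = 10 ** -rng.uniform(0, 12, (30, 4))
        left = _assoc_table(snps, traits, pl)
        right = _assoc_table(snps, traits, pr, eye="right")
        thr = 1e-7
        sel = {v.snp_id: v.reported_p for v in intersect_eyes(left, right, thr)}
        expected = {}
        for i, s in enumerate(snps):
            ml, mr = min(pl[i]), min(pr[i])
            if ml < thr and mr < thr:
                expected[s] = min(ml, mr)
        assert sel == pytest.approx(expected)

    def test_monotone_in_threshold(self, rng):
        snps = [f"s{i}" for i in range(20)]
        pl = 10 ** -rng.uniform(0, 10, (20, 2))
        pr = 10 ** -rng.uniform(0, 10, (20, 2))
        left = _assoc_table(snps, ["a", "b"], pl)
        right = _assoc_table(snps, ["a", "b"], pr, eye="right")
        loose = {v.snp_id for v in intersect_eyes(left, right, 1e-4)}
        tight = {v.snp_id for v in intersect_eyes(left, right, 1e-6)}
        assert tight <= loose


class TestPairwiseHits:
    def test_trait_significant_one_eye_excluded(self):
        left = _assoc_table(["s1"], ["a", "b"], [[1e-9, 0.5]])
        right = _assoc_table(["s1"], ["a", "b"], [[1e-9, 1e-9]], eye="right")
        hits = pairwise_hits(left, right)
        assert list(hits.trait) == ["a"]

    def test_matches_double_loop_oracle(self, rng):
        snps = [f"s{i}" for i in range(15)]
        traits = ["a", "b", "c"]
        pl = 10 ** -rng.uniform(0, 10, (15, 3))
        pr = 10 ** -rng.uniform(0, 10, (15, 3))
        hits = pairwise_hits(_assoc_table(snps, traits, pl),
                             _assoc_table(snps, traits, pr, eye="right"),
                             threshold=1e-6)
        got = set(zip(hits.snp_id, hits.trait))
        expected = {(s, t) for i, s in enumerate(snps)
                    for j, t in enumerate(traits)
                    if pl[i][j] < 1e-6 and pr[i][j] < 1e-6}
        assert got == expected


def _toy_panel(positions, chroms, dosages):
    dosages = np.asarray(dosages, dtype=np.int8)
    p = dosages.mean(axis=0) / 2
    return GenotypePanel(
        dosages=dosages, chrom=np.asarray(chroms, dtype=str),
        pos=np.asarray(positions, dtype=np.int64),
        ref=np.array(["A"] * dosages.shape[1]),
        alt=np.array(["C"] * dosages.shape[1]),
        maf=np.minimum(p, 1 - p),
    )


def _variants(panel, idx):
    return [SelectedVariant(
        snp_id=str(panel.snp_ids[i]), chrom=str(panel.chrom[i]),
        pos=int(panel.pos[i]), min_p_left=1e-9, min_p_right=1e-9,
        best_trait_left="t", best_trait_right="t") for i in idx]


class TestLdMatrix:
    def test_duplicated_column_r2_one(self, rng):
        d = rng.integers(0, 3, (50, 1))
        panel = _toy_panel([1, 2], ["1", "1"], np.hstack([d, d]))
        r2 = ld_r2_matrix(panel, [0, 1])
        assert r2[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_independent_snps_near_zero(self):
        cfg = SimConfig(n_subjects=5000, n_snps=20, ld_block_size=1,
                        within_block_r=0.0, seed=17)
        panel = simulate_genotypes(cfg)
        r2 = ld_r2_matrix(panel, list(range(20)))
        off = r2[np.triu_indices(20, k=1)]
        assert off.mean() < 0.01

    def test_matches_textbook_formula(self, small_panel):
        idx = list(range(0, 30, 3))
        r2 = ld_r2_matrix(small_panel, idx)
        D = small_panel.dosages[:, idx].astype(float)
        ref = np.corrcoef(D.T) ** 2
        assert np.max(np.abs(r2 - ref)) < 1e-12

    def test_monomorphic_set_to_zero_with_warning(self):
        d = np.array([[1, 1], [2, 1], [0, 1]])
        panel = _toy_panel([1, 2], ["1", "1"], d)
        with pytest.warns(UserWarning, match="monomorphic"):
            r2 = ld_r2_matrix(panel, [0, 1])
        assert r2[0, 1] == 0.0


class TestClumping:
    def test_far_apart_low_ld_two_loci(self, rng):
        d = rng.integers(0, 3, (100, 2))
        panel = _toy_panel([1, 300_001], ["1", "1"], d)
        loci = clump_loci(_variants(panel, [0, 1]), panel)
        assert len(loci) == 2

    def test_chain_merges_transitively(self, rng):
        d = rng.integers(0, 3, (100, 3))
        panel = _toy_panel([1, 200_001, 400_001], ["1"] * 3, d)
        loci = clump_loci(_variants(panel, [0, 1, 2]), panel)
        assert len(loci) == 1
        assert sorted(loci[0].members) == sorted(panel.snp_ids)

    def test_distinct_chromosomes_never_merge(self, rng):
        d = rng.integers(0, 3, (100, 3))
        panel = _toy_panel([1, 1, 1], ["1", "2", "3"], d)
        loci = clump_loci(_variants(panel, [0, 1, 2]), panel)
        assert len(loci) == 3

    def test_equals_transitive_closure_oracle(self, rng):
        import networkx as nx

        for rep in range(200):
            r = np.random.default_rng(rep)
            m = int(r.integers(2, 12))
            n = 60
            d = r.integers(0, 3, (n, m))
            # random duplicated columns create high-LD links
            for _ in range(m // 3):
                a, b = r.integers(0, m, 2)
                d[:, b] = d[:, a]
            chroms = r.choice(["1", "2"], size=m)
            positions = np.sort(r.integers(1, 2_000_000, size=m))
            panel = _toy_panel(positions, chroms, d)
            panel.snp_ids = np.array([f"v{j}" for j in range(m)])
            variants = _variants(panel, range(m))
            loci = clump_loci(variants, panel, r2_threshold=0.2,
                              dist_threshold=250_000)
            # oracle: explicit graph + connected components
            G = nx.Graph()
            G.add_nodes_from(range(m))
            r2 = ld_r2_matrix(panel, list(range(m)))
            for i in range(m):
                for j in range(i + 1, m):
                    if chroms[i] == chroms[j] and (
                            r2[i, j] > 0.2
                            or abs(int(positions[i]) - int(positions[j])) <= 250_000):
                        G.add_edge(i, j)
            expected = {frozenset(panel.snp_ids[list(c)])
                        for c in nx.connected_components(G)}
            got = {frozenset(l.members) for l in loci}
            assert got == expected

    def test_lead_snp_is_smallest_p(self, rng):
        d = rng.integers(0, 3, (50, 2))
        panel = _toy_panel([1, 1001], ["1", "1"], d)
        vs = _variants(panel, [0, 1])
        vs[1].min_p_left = 1e-12
        loci = clump_loci(vs, panel)
        assert loci[0].lead_snp == vs[1].snp_id
        assert loci[0].min_p == 1e-12

    def test_order_invariance(self, rng):
        d = rng.integers(0, 3, (60, 5))
        panel = _toy_panel([1, 100_001, 600_001, 700_001, 1_500_001],
                           ["1"] * 5, d)
        vs = _variants(panel, range(5))
        a = clump_loci(vs, panel)
        b = clump_loci(vs[::-1], panel)
        assert [l.members for l in a] == [l.members for l in b]


class TestLdScores:
    def test_window_zero_gives_one(self, small_panel):
        l = compute_ld_scores(small_panel, window_bp=0)
        assert np.allclose(l, 1.0)

    def test_independent_snps_near_one(self):
        cfg = SimConfig(n_subjects=4000, n_snps=30, ld_block_size=1,
                        within_block_r=0.0, seed=19)
        panel = simulate_genotypes(cfg)
        l = compute_ld_scores(panel)
        assert np.all(np.abs(l - 1.0) < 0.1)

    def test_matches_windowed_double_loop(self, small_panel):
        window = 30_000
        l = compute_ld_scores(small_panel, window_bp=window)
        for j in range(0, small_panel.n_snps, 5):
            acc = 0.0
            for k in range(small_panel.n_snps):
                if small_panel.chrom[j] != small_panel.chrom[k]:
                    continue
                if abs(int(small_panel.pos[j]) - int(small_panel.pos[k])) > window:
                    continue
                acc += ld_r2_matrix(small_panel, [j, k])[0, 1]
            assert l[j] == pytest.approx(acc, abs=1e-12)


class TestLdsc:
    def test_noiseless_line_recovered_exactly(self, rng):
        l = rng.uniform(1, 5, 500)
        N, M = 1000.0, 500.0
        res = ldsc_h2(1 + N * 0.3 * l / M, l, N, M)
        assert res.estimate == pytest.approx(0.3, abs=1e-10)
        assert res.intercept == pytest.approx(1.0, abs=1e-10)

    def test_null_simulation_near_zero(self):
        l = np.random.default_rng(0).uniform(1, 5, 2000)
        ests = [ldsc_h2(np.random.default_rng(s).standard_normal(2000) ** 2,
                        l, 1000, 2000).estimate for s in range(20)]
        assert abs(np.mean(ests)) < 0.05

    def test_constant_ld_scores_rejected(self):
        with pytest.raises(ValueError):
            ldsc_h2(np.ones(100), np.ones(100), 100, 100)

    def test_rg_of_identical_stats_is_one(self, rng):
        l = rng.uniform(1, 8, 1500)
        N, M = 1000.0, 1500.0
        z = rng.standard_normal(1500) * np.sqrt(1 + N * 0.3 * l / M)
        h2 = ldsc_h2(z ** 2, l, N, M).estimate
        res = ldsc_rg(z, z, l, N, N, M, h2, h2)
        assert res.estimate == pytest.approx(1.0, abs=1e-9)

    def test_rg_independent_traits_near_zero(self):
        l = np.random.default_rng(0).uniform(1, 5, 2000)
        vals = []
        for s in range(20):
            r = np.random.default_rng(1000 + s)
            z1, z2 = r.standard_normal((2, 2000))
            vals.append(ldsc_rg(z1, z2, l, 1000, 1000, 2000, 0.3, 0.3).estimate)
        assert abs(np.mean(vals)) < 0.1

    def test_rg_shared_effects_high(self):
        l = np.random.default_rng(0).uniform(1, 8, 2000)
        N, M = 2000.0, 2000.0
        vals = []
        for s in range(20):
            r = np.random.default_rng(2000 + s)
            shared = r.standard_normal(2000) * np.sqrt(N * 0.3 * l / M)
            z1 = shared + r.standard_normal(2000)
            z2 = shared + r.standard_normal(2000)
            h2_1 = ldsc_h2(z1 ** 2, l, N, M).estimate
            h2_2 = ldsc_h2(z2 ** 2, l, N, M).estimate
            vals.append(ldsc_rg(z1, z2, l, N, N, M, h2_1, h2_2).estimate)
        assert np.mean(vals) > 0.8

    def test_nonpositive_h2_rejected(self):
        with pytest.raises(ValueError):
            ldsc_rg(np.ones(10), np.ones(10), np.arange(10.0), 1, 1, 10, 0.0, 0.3)


class TestDescriptives:
    def test_matrix_symmetric_unit_diagonal(self, rng):
        rep = endophenotype_descriptives(rng.standard_normal((200, 6)))
        A = rep["abs_corr"]
        assert np.allclose(A, A.T)
        assert np.allclose(np.diag(A), 1.0)

    def test_duplicated_trait_detected(self, rng):
        v = rng.standard_normal((100, 3))
        v[:, 2] = v[:, 0]
        rep = endophenotype_descriptives(v)
        assert rep["abs_corr"][0, 2] == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_traits_low_correlation(self, rng):
        rep = endophenotype_descriptives(rng.standard_normal((5000, 8)))
        A = rep["abs_corr"].copy()
        np.fill_diagonal(A, 0.0)
        assert A.mean() < 0.03

    def test_report_written_as_tsv_and_figure(self, rng, tmp_path):
        from igwas.postprocess import write_descriptives

        rep = endophenotype_descriptives(rng.standard_normal((80, 5)))
        write_descriptives(rep, tmp_path / "desc")
        assert (tmp_path / "desc_abs_corr.tsv").exists()
        assert (tmp_path / "desc_abs_corr.png").exists()

    def test_constant_trait_warned(self, rng):
        v = rng.standard_normal((50, 3))
        v[:, 1] = 2.0
        with pytest.warns(UserWarning, match="constant"):
            rep = endophenotype_descriptives(v)
        assert rep["abs_corr"][0, 1] == 0.0


class TestCatalogQuery:
    def _loci(self):
        return [Locus(chrom="1", start=1_000_000, end=1_100_000,
                      members=["a"], lead_snp="a", min_p=1e-9)]

    def test_boundary_is_closed(self):
        cat = pd.DataFrame({"chrom": ["1"], "pos": [750_000],
                            "trait": ["eye color"]})
        hits = catalog_range_query(self._loci(), cat, flank=250_000)
        assert len(hits) == 1    # exactly at start - flank

    def test_empty_catalog(self):
        cat = pd.DataFrame({"chrom": [], "pos": [], "trait": []})
        assert len(catalog_range_query(self._loci(), cat)) == 0

    def test_matches_interval_scan_oracle(self, rng):
        loci = [Locus(chrom=str(c), start=int(s), end=int(s + 50_000),
                      members=["x"], lead_snp="x", min_p=1e-9)
                for c, s in zip(rng.integers(1, 3, 10),
                                rng.integers(1, 5_000_000, 10))]
        cat = pd.DataFrame({
            "chrom": rng.integers(1, 3, 200).astype(str),
            "pos": rng.integers(1, 6_000_000, 200),
            "trait": ["t"] * 200,
        })
        hits = catalog_range_query(loci, cat, flank=100_000)
        expected = 0
        for lo in loci:
            for _, row in cat.iterrows():
                if (str(row.chrom) == lo.chrom
                        and lo.start - 100_000 <= row.pos <= lo.end + 100_000):
                    expected += 1
        assert len(hits) == expected

    def test_build_mismatch_refused(self):
        cat = pd.DataFrame({"chrom": ["1"], "pos": [1], "trait": ["t"]})
        cat.attrs["build_mismatch"] = True
        with pytest.raises(ValueError, match="build"):
            catalog_range_query(self._loci(), cat)
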