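"""Expression preprocessing, coexpression modules, metabolite clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest

from phenodyn import (SimConfig, affinity_propagation, bicor, bicor_matrix,
                      coexpression_modules, filter_genes,
                      gen_omics_and_behavior, gen_parcel_sessions,
                      metab_normalize, nuisance_regress, pick_soft_power,
                      project_eigengenes, size_factors, tom_similarity, vst)


def df(mat, prefix="g"):
    mat = np.asarray(mat, dtype=float)
    return pd.DataFrame(mat, index=[f"{prefix}{i}" for i in range(mat.shape[0])],
                        columns=[f"s{j}" for j in range(mat.shape[1])])


class TestSizeFactors:
    def test_doubled_session(self):
        rng = np.random.default_rng(0)
        base = rng.integers(1, 100, size=20).astype(float)
        counts = df(np.column_stack([base, 2 * base]))
        f = size_factors(counts)
        assert f.iloc[1] / f.iloc[0] == pytest.approx(2.0)

    def test_toy_matches_hand_median_of_ratios(self):
        counts = df([[10, 20, 30],
                     [4, 8, 4],
                     [100, 50, 100],
                     [1, 1, 1]])
        f = size_factors(counts)
        mat = counts.values.astype(float)
        geo = np.exp(np.mean(np.log(mat), axis=1))
        for j in range(3):
            expect = np.median(mat[:, j] / geo)
            assert f.iloc[j] == pytest.approx(expect, abs=1e-12)

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(1)
        counts = df(rng.integers(1, 500, size=(30, 4)))
        f1 = size_factors(counts)
        f2 = size_factors(counts.iloc[::-1])
        np.testing.assert_allclose(f1.values, f2.values)

    def test_session_scaling_property(self):
        # median-of-ratios factors are relative: scaling one session by c
        # multiplies its factor by c relative to the others (a global
        # rescaling of every session leaves the factors unchanged)
        rng = np.random.default_rng(2)
        counts = df(rng.integers(1, 500, size=(30, 4)))
        f1 = size_factors(counts)
        scaled = counts.astype(float).copy()
        scaled.iloc[:, 0] *= 3.0
        f2 = size_factors(scaled)
        ratio1 = f1.iloc[0] / f1.iloc[1]
        ratio2 = f2.iloc[0] / f2.iloc[1]
        assert ratio2 == pytest.approx(3.0 * ratio1, rel=1e-12)
        f3 = size_factors(counts * 3)
        np.testing.assert_allclose(f3.values, f1.values, rtol=1e-12)

    def test_no_common_gene_errors(self):
        counts = df([[0, 5], [5, 0]])
        with pytest.raises(ValueError, match="pseudocount"):
            size_factors(counts)


class TestFilterGenes:
    def test_inclusive_boundaries(self):
        counts = df([[3, 4, 5],      # mean 4.0 -> kept
                     [3, 4, 4],      # mean ~3.67 -> removed
                     [10, 10, 10]])
        out = filter_genes(counts, use_normalized=False)
        assert "g0" in out.index and "g2" in out.index
        assert "g1" not in out.index
        assert out.attrs["removed"]["below"] == 1

    def test_small_rna_removed_regardless_of_mean(self):
        counts = df([[100, 100], [50, 50]])
        flags = pd.Series([True, False], index=counts.index)
        out = filter_genes(counts, small_rna=flags, use_normalized=False)
        assert "g0" not in out.index
        assert out.attrs["removed"]["small_rna"] == 1

    def test_high_expression_removed(self):
        counts = df([[20000, 20000], [50, 50]])
        out = filter_genes(counts, use_normalized=False)
        assert "g0" not in out.index
        assert out.attrs["removed"]["above"] == 1

    def test_generator_bookkeeping_matches_exactly(self):
        cfg = SimConfig(n_parcels=10, n_networks=2, n_sessions=30,
                        timepoints_per_session=20, n_genes=500,
                        n_gene_modules=5, small_rna_frac=0.1,
                        extreme_mean_frac=0.05, seed=23)
        _, truth = gen_parcel_sessions(cfg)
        genes, _, _ = gen_omics_and_behavior(cfg, truth)
        out = filter_genes(genes)
        assert out.attrs["removed"] == truth.filter_counts

    def test_empty_result_errors(self):
        counts = df([[1, 1], [2, 2]])
        with pytest.raises(ValueError):
            filter_genes(counts, min_mean=100, use_normalized=False)


@pytest.fixture(scope="module")
def nb_counts():
    rng = np.random.default_rng(3)
    mu = np.exp(rng.uniform(np.log(5), np.log(500), size=400))
    alpha = 0.2
    lam = rng.gamma(1 / alpha, alpha * mu[:, None], size=(400, 50))
    return df(rng.poisson(lam))


class TestVst:

    def test_strictly_monotone_in_counts(self, nb_counts):
        out = vst(nb_counts, pd.Series(1.0, index=nb_counts.columns))
        col = nb_counts.values[:, 0]
        tcol = out.values[:, 0]
        order = np.argsort(col)
        distinct = np.diff(col[order]) > 0
        assert np.all(np.diff(tcol[order])[distinct] > 0)

    def test_variance_stabilized_versus_raw_log(self, nb_counts):
        out = vst(nb_counts)
        sd_t = out.values.std(axis=1, ddof=1)
        assert sd_t.max() / max(sd_t.min(), 1e-12) < 3.0
        # raw log (with tiny offset standing in for log of 0) is far worse
        raw = np.log2(nb_counts.values + 1e-6)
        sd_raw = raw.std(axis=1, ddof=1)
        assert sd_raw.max() / sd_raw.min() > 3.0

    def test_large_count_limit_is_log2(self, nb_counts):
        out = vst(nb_counts, pd.Series(1.0, index=nb_counts.columns))
        a0 = out.attrs["dispersion_a0"]
        assert a0 > 0
        x1, x2 = 50_000.0, 200_000.0
        a1 = out.attrs["dispersion_a1"]

        def f(x):
            return np.log2((1 + a1 + 2 * a0 * x
                            + 2 * np.sqrt(a0 * x * (1 + a1 + a0 * x))) / (4 * a0))

        diff = f(x2) - f(x1)
        assert diff == pytest.approx(np.log2(x2 / x1), rel=0.05)

    def test_degenerate_fit_falls_back(self):
        # sub-Poisson toy data force a0 <= 0
        rng = np.random.default_rng(4)
        counts = df(100 + rng.integers(0, 3, size=(50, 30)))
        with pytest.warns(RuntimeWarning, match="shifted log"):
            out = vst(counts, pd.Series(1.0, index=counts.columns))
        assert out.attrs["vst_fallback"]


class TestNuisanceRegress:
    def test_residuals_orthogonal_to_covariates(self):
        rng = np.random.default_rng(5)
        x = df(rng.standard_normal((40, 20)))
        cov = rng.standard_normal(20)
        resid = nuisance_regress(x, cov, n_pcs=3)
        for row in resid.values[:10]:
            assert abs(np.corrcoef(row, cov)[0, 1]) < 1e-10

    def test_feature_equal_to_covariate_vanishes(self):
        rng = np.random.default_rng(6)
        cov = rng.standard_normal(20)
        mat = rng.standard_normal((10, 20))
        mat[0] = 2.0 * cov + 1.0
        resid = nuisance_regress(df(mat), cov, n_pcs=0)
        assert np.max(np.abs(resid.values[0])) < 1e-10

    def test_planted_signal_survives(self):
        rng = np.random.default_rng(7)
        n_sess = 48
        factor = rng.standard_normal(n_sess)
        cov = rng.standard_normal(n_sess)
        mat = 0.8 * factor[None, :] + 0.3 * rng.standard_normal((60, n_sess))
        mat[:10] += 0.5 * cov[None, :]
        resid = nuisance_regress(df(mat), cov, n_pcs=0)
        keep_corr = [abs(np.corrcoef(resid.values[i], factor)[0, 1])
                     for i in range(20, 60)]
        assert np.mean(keep_corr) >= 0.9

    def test_collinear_design_errors(self):
        rng = np.random.default_rng(8)
        cov = np.column_stack([np.ones(20), np.ones(20) * 2])
        with pytest.raises(ValueError, match="collinear"):
            nuisance_regress(df(rng.standard_normal((10, 20))), cov, n_pcs=0)


class TestBicor:
    def test_identity(self):
        x = np.random.default_rng(9).standard_normal(50)
        val, fallback = bicor(x, x)
        assert val == pytest.approx(1.0)
        assert not fallback

    def test_gaussian_consistency_with_pearson(self):
        rng = np.random.default_rng(10)
        n = 1000
        x = rng.standard_normal(n)
        y = 0.6 * x + np.sqrt(1 - 0.36) * rng.standard_normal(n)
        val, _ = bicor(x, y)
        assert abs(val - np.corrcoef(x, y)[0, 1]) < 0.05

    def test_outlier_robustness(self):
        closer = 0
        n_rep = 200
        for i in range(n_rep):
            rng = np.random.default_rng(1000 + i)
            n = 50
            x = rng.standard_normal(n)
            y = 0.6 * x + 0.8 * rng.standard_normal(n)
            x[0], y[0] = 10.0, -10.0  # one 10-SD contaminating pair
            b, _ = bicor(x, y)
            p = np.corrcoef(x, y)[0, 1]
            if abs(b - 0.6) < abs(p - 0.6):
                closer += 1
        assert closer >= 0.9 * n_rep

    def test_zero_mad_pearson_fallback(self):
        x = np.array([1.0, 1.0, 1.0, 1.0, 9.0])
        y = np.array([0.1, 0.4, 0.2, 0.3, 5.0])
        val, fallback = bicor(x, y)
        assert fallback
        assert val == pytest.approx(np.corrcoef(x, y)[0, 1])

    def test_matrix_agrees_with_pairwise(self):
        rng = np.random.default_rng(11)
        mat = rng.standard_normal((6, 40))
        c = bicor_matrix(mat)
        for i in range(6):
            for j in range(i + 1, 6):
                val, _ = bicor(mat[i], mat[j])
                assert c[i, j] == pytest.approx(val, abs=1e-10)


class TestSoftPower:
    def test_returns_smallest_passing_power(self):
        rng = np.random.default_rng(12)
        # module-structured expression yields a usable similarity matrix
        factor = rng.standard_normal((4, 60))
        load = rng.uniform(0.4, 0.9, 200)
        mem = np.arange(200) % 4
        mat = load[:, None] * factor[mem] + 0.6 * rng.standard_normal((200, 60))
        sim = bicor_matrix(mat)
        power, diag = pick_soft_power(sim, r2_target=0.8)
        passing = diag[diag["signed_r2"] >= 0.8]
        if len(passing):
            assert power == int(passing["power"].iloc[0])
        else:
            assert power == int(diag.loc[diag["signed_r2"].idxmax(), "power"])

    def test_identity_matrix_fallback_path(self):
        power, diag = pick_soft_power(np.eye(30))
        assert 1 <= power <= 20
        assert len(diag) == 20

    def test_diagnostics_report_complete(self):
        rng = np.random.default_rng(13)
        sim = np.clip(rng.uniform(-1, 1, (40, 40)), -1, 1)
        sim = (sim + sim.T) / 2
        np.fill_diagonal(sim, 1.0)
        _, diag = pick_soft_power(sim, powers=range(1, 11))
        assert list(diag["power"]) == list(range(1, 11))


class TestTom:
    def test_four_node_toy_matches_hand_formula(self):
        a = np.array([
            [0.0, 0.8, 0.3, 0.0],
            [0.8, 0.0, 0.5, 0.2],
            [0.3, 0.5, 0.0, 0.6],
            [0.0, 0.2, 0.6, 0.0],
        ])
        tom = tom_similarity(a)
        k = a.sum(axis=1)
        for i in range(4):
            for j in range(4):
                if i == j:
                    assert tom[i, j] == 1.0
                    continue
                shared = sum(a[i, u] * a[u, j] for u in range(4))
                expect = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
                assert tom[i, j] == pytest.approx(expect, abs=1e-12)

    def test_bounds(self):
        rng = np.random.default_rng(14)
        a = rng.uniform(0, 1, (20, 20))
        a = (a + a.T) / 2
        tom = tom_similarity(a)
        assert np.all(tom >= 0) and np.all(tom <= 1)


def jaccard(a, b):
    a, b = set(a), set(b)
    return len(a & b) / len(a | b)


class TestCoexpressionModules:
    def test_planted_modules_recovered(self):
        cfg = SimConfig(n_parcels=10, n_networks=2, n_sessions=48,
                        timepoints_per_session=20, n_genes=600,
                        n_gene_modules=5, small_rna_frac=0.0,
                        extreme_mean_frac=0.0, seed=31)
        _, truth = gen_parcel_sessions(cfg)
        genes, _, _ = gen_omics_and_behavior(cfg, truth)
        stab = vst(filter_genes(genes))
        # covariate-only nuisance regression: with only five modules the top
        # expression components are the module factors themselves, so PC
        # removal would strip the biology it is meant to protect
        resid = nuisance_regress(stab, genes.attrs["rin"].values, n_pcs=0)
        power, _ = pick_soft_power(bicor_matrix(resid.values))
        modules = coexpression_modules(resid, power=power, min_module=30)

        membership = truth.gene_module_membership
        planted = {m: set(genes.index[membership == m])
                   for m in range(cfg.n_gene_modules)}
        recovered = 0
        matched_eigen = 0
        for m, members in planted.items():
            best, best_mod = 0.0, None
            for mod in modules.module_ids:
                found = set(modules.membership.index[modules.membership == mod])
                j = jaccard(members & set(resid.index), found)
                if j > best:
                    best, best_mod = j, mod
            if best >= 0.7:
                recovered += 1
                eig = modules.eigengenes.loc[best_mod].values
                factor = truth.gene_module_factors[m]
                if abs(np.corrcoef(eig, factor)[0, 1]) >= 0.9:
                    matched_eigen += 1
        assert recovered >= 4
        assert matched_eigen >= 4

    def test_identical_profiles_full_variance_explained(self):
        rng = np.random.default_rng(15)
        base = rng.standard_normal(30)
        mat = np.tile(base, (40, 1))
        modules = coexpression_modules(df(mat), power=2, min_module=10)
        assert len(modules.module_ids) >= 1
        m = modules.module_ids[0]
        assert modules.variance_explained[m] == pytest.approx(1.0)

    def test_no_module_all_grey(self):
        rng = np.random.default_rng(16)
        mat = rng.standard_normal((40, 30))
        with pytest.warns(RuntimeWarning):
            modules = coexpression_modules(df(mat), power=8, min_module=50)
        assert (modules.membership == 0).all()


class TestProjectEigengenes:
    def _modules(self, seed=17):
        rng = np.random.default_rng(seed)
        factor = rng.standard_normal((3, 40))
        mem = np.arange(150) % 3
        mat = 0.9 * factor[mem] + 0.4 * rng.standard_normal((150, 40))
        x = df(mat)
        return x, coexpression_modules(x, power=6, min_module=20), factor

    def test_self_projection_reproduces_eigengenes(self):
        # matching nuisance settings (none here): projecting onto the
        # defining dataset must reproduce the eigengenes up to sign
        x, modules, _ = self._modules()
        scores, overlap = project_eigengenes(x, modules, n_pcs=0)
        assert np.all(overlap.values == 1.0)
        for m in modules.module_ids:
            r = np.corrcoef(scores.loc[m], modules.eigengenes.loc[m])[0, 1]
            assert abs(r) > 0.999

    def test_second_cohort_shares_latents(self):
        x, modules, factor = self._modules()
        rng = np.random.default_rng(18)
        mem = np.arange(150) % 3
        mat2 = 0.9 * factor[mem] + 0.4 * rng.standard_normal((150, 40))
        scores, _ = project_eigengenes(df(mat2), modules, n_pcs=0)
        hits = 0
        for m in modules.module_ids:
            best = max(abs(np.corrcoef(scores.loc[m], factor[k])[0, 1])
                       for k in range(3))
            hits += best >= 0.8
        assert hits == len(modules.module_ids)

    def test_shuffled_ids_trigger_overlap_warning(self):
        x, modules, _ = self._modules()
        shuffled = x.copy()
        shuffled.index = [f"other{i}" for i in range(len(x))]
        with pytest.warns(RuntimeWarning, match="skipped"):
            scores, overlap = project_eigengenes(shuffled, modules)
        assert len(scores) == 0


class TestMetabNormalize:
    def test_session_mean_one(self):
        rng = np.random.default_rng(19)
        peaks = df(np.exp(rng.standard_normal((30, 6))), prefix="m")
        out = metab_normalize(peaks)
        np.testing.assert_allclose(out.values.mean(axis=0), 1.0)

    def test_session_scaling_invariance(self):
        rng = np.random.default_rng(20)
        peaks = df(np.exp(rng.standard_normal((30, 3))), prefix="m")
        out1 = metab_normalize(peaks)
        scaled = peaks.copy()
        scaled.iloc[:, 1] *= 10.0
        out2 = metab_normalize(scaled)
        np.testing.assert_allclose(out1.values, out2.values, rtol=1e-12)

    def test_toy_hand_arithmetic(self):
        peaks = df([[2.0, 8.0], [4.0, 4.0], [6.0, 12.0]], prefix="m")
        out = metab_normalize(peaks)
        np.testing.assert_allclose(out.values[:, 0], [2 / 4, 4 / 4, 6 / 4])
        np.testing.assert_allclose(out.values[:, 1], [8 / 8, 4 / 8, 12 / 8])

    def test_nonpositive_errors(self):
        with pytest.raises(ValueError):
            metab_normalize(df([[1.0, -2.0]], prefix="m"))


def neg_sq_dist(points):
    d = points[:, None, :] - points[None, :, :]
    return -np.square(d).sum(axis=2)


class TestAffinityPropagation:
    def test_single_point_self_exemplar(self):
        ex, labels = affinity_propagation(np.array([[0.0]]))
        assert ex.tolist() == [0] and labels.tolist() == [0]

    def test_two_blobs_recovered(self):
        rng = np.random.default_rng(21)
        pts = np.vstack([rng.normal(0, 0.3, (15, 2)),
                         rng.normal(6, 0.3, (15, 2))])
        ex, labels = affinity_propagation(neg_sq_dist(pts), seed=0)
        assert np.unique(labels).size == 2
        assert np.unique(labels[:15]).size == 1
        assert np.unique(labels[15:]).size == 1

    def test_exemplars_self_assigned_partition(self):
        rng = np.random.default_rng(22)
        pts = rng.standard_normal((20, 3))
        ex, labels = affinity_propagation(neg_sq_dist(pts), seed=0)
        assert np.all(labels >= 0)
        for k, e in enumerate(ex):
            assert labels[e] == k

    def test_small_n_matches_exhaustive_exemplar_search(self):
        rng = np.random.default_rng(23)
        pts = rng.standard_normal((8, 2))
        sim = neg_sq_dist(pts)
        pref = float(np.median(sim))
        ex, labels = affinity_propagation(sim, seed=0)

        def net_similarity(exemplars):
            total = sum(pref for _ in exemplars)
            for i in range(8):
                if i in exemplars:
                    continue
                total += max(sim[i, e] for e in exemplars)
            return total

        ap_net = net_similarity(set(ex.tolist()))
        best = -np.inf
        for k in range(1, 9):
            for combo in itertools.combinations(range(8), k):
                best = max(best, net_similarity(set(combo)))
        assert ap_net >= best - 0.01 * abs(best)
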