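import numpy as np
import pytest
from scipy import stats

from qkforest import assoc, kinship, simdata
from qkforest.assoc import ModelSpec
from qkforest.popstruct import AdmixtureQ

from conftest import make_markers


# ---------------------------------------------------------------------------
# independent oracles

def brute_force_gls_scan(M, y, X0, K, lam_grid=None):
    """Dense GLS/REML oracle: per marker, grid-REML over lambda with direct
    O(n^3) likelihood evaluations, then GLS Wald F for the marker effect."""
    n = len(y)
    if lam_grid is None:
        lam_grid = np.logspace(-5, 5, 200)
    pvals = np.empty(M.shape[1])
    for j in range(M.shape[1]):
        X = np.column_stack([X0, M[:, j]])
        best_ll, best_lam = -np.inf, None
        for lam in lam_grid:
            V = lam * K + np.eye(n)
            Vi = np.linalg.inv(V)
            XtVi = X.T @ Vi
            XtViX = XtVi @ X
            beta = np.linalg.solve(XtViX, XtVi @ y)
            r = y - X @ beta
            p = X.shape[1]
            s2 = float(r @ Vi @ r) / (n - p)
            sign, ld = np.linalg.slogdet(V)
            _, ldx = np.linalg.slogdet(XtViX)
            ll = -0.5 * ((n - p) * np.log(2 * np.pi * s2) + ld + ldx
                         + (n - p))
            if ll > best_ll:
                best_ll, best_lam = ll, lam
        V = best_lam * K + np.eye(n)
        Vi = np.linalg.inv(V)
        XtViX = X.T @ Vi @ X
        beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
        r = y - X @ beta
        p = X.shape[1]
        s2 = float(r @ Vi @ r) / (n - p)
        se2 = s2 * np.linalg.inv(XtViX)[-1, -1]
        F = beta[-1] ** 2 / se2
        pvals[j] = stats.f.sf(F, 1, n - p)
    return pvals


def brute_force_reml_loglik(y, X, K, lam):
    """Direct REML log-likelihood at given lambda (profiled over sigma_e2)."""
    n, p = X.shape
    V = lam * K + np.eye(n)
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    r = y - X @ beta
    s2 = float(r @ Vi @ r) / (n - p)
    _, ld = np.linalg.slogdet(V)
    _, ldx = np.linalg.slogdet(XtViX)
    _, ldxx = np.linalg.slogdet(X.T @ X)
    return -0.5 * ((n - p) * np.log(2 * np.pi * s2) + ld + ldx - ldxx + (n - p))


def brute_force_bh(p):
    """Step-up definition: adj_i = min over j with p_j >= p_i of m*p_j/rank_j."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        adj[i] = running
    return adj


def random_structured(seed, n=60, m=25, sigma_g2=0.4):
    cfg = simdata.SimConfig(n_accessions=n, n_subpops=2, fst=0.3,
                            admix_alpha=0.2, n_markers=m, sigma_g2=sigma_g2,
                            sigma_e2=0.6, pop_effects=[0.5, -0.5], seed=seed)
    Q, P = simdata.simulate_population(cfg)
    markers = simdata.simulate_markers(Q, P, seed=seed + 1)
    keep = (markers.allele_freq > 0.1) & (markers.allele_freq < 0.9)
    markers = markers.subset(keep)
    K = kinship.kinship_freq_corrected(markers)
    from qkforest.simdata import _psd_sqrt
    L, _ = _psd_sqrt(K.values)
    Kpsd = L @ L.T
    pheno, _ = simdata.simulate_phenotypes(markers, Q, Kpsd, cfg)
    return markers, pheno.values[:, 0], Q, Kpsd


class TestModelSpec:
    def test_flags(self):
        assert not ModelSpec(1).uses_Q and not ModelSpec(1).uses_K
        assert ModelSpec(2).uses_Q and not ModelSpec(2).uses_K
        assert not ModelSpec(3).uses_Q and ModelSpec(3).uses_K
        assert ModelSpec(4).uses_Q and ModelSpec(4).uses_K

    def test_invalid(self):
        with pytest.raises(ValueError):
            ModelSpec(5)
        with pytest.raises(ValueError):
            ModelSpec(1, vc_strategy="bogus")


class TestScanNaive:
    def test_balanced_symmetric_y_gives_zero_beta(self):
        m = make_markers([[0], [0], [1], [1]])
        y = np.array([-1.0, 1.0, -1.0, 1.0])  # identical class means
        res = assoc.scan_naive(m, y)
        assert res.effect[0] == pytest.approx(0.0, abs=1e-12)
        assert res.p_raw[0] == pytest.approx(1.0)

    def test_equivalence_with_pooled_t_test(self, rng):
        scores = (rng.random((40, 10)) < 0.5).astype(np.int8)
        scores[0, :] = 1 - scores[1, :]  # keep all polymorphic
        m = make_markers(scores)
        y = rng.standard_normal(40)
        res = assoc.scan_naive(m, y)
        for j in range(10):
            g0, g1 = y[scores[:, j] == 0], y[scores[:, j] == 1]
            t, p = stats.ttest_ind(g1, g0, equal_var=True)
            assert res.p_raw[j] == pytest.approx(p, abs=1e-12)
            assert np.sqrt(res.stat[j]) == pytest.approx(abs(t), rel=1e-10)

    def test_perfect_marker(self):
        m = make_markers([[0], [0], [1], [1]])
        y = m.scores[:, 0].astype(float)
        res = assoc.scan_naive(m, y)
        assert res.r2[0] == pytest.approx(1.0)
        assert res.p_raw[0] <= np.finfo(float).tiny

    def test_monomorphic_flagged_untestable(self):
        m = make_markers([[1, 0], [1, 1], [1, 0]])
        res = assoc.scan_naive(m, np.array([1.0, 2.0, 3.0]))
        assert res.untestable[0] and np.isnan(res.p_raw[0])
        assert not res.untestable[1]


class TestScanQ:
    def test_constant_q_equals_naive(self, rng):
        scores = (rng.random((30, 8)) < 0.5).astype(np.int8)
        scores[0] = 1 - scores[1]
        m = make_markers(scores)
        y = rng.standard_normal(30)
        Q = AdmixtureQ(memberships=np.tile([0.5, 0.5], (30, 1)),
                       accession_ids=m.accession_ids)
        res_q = assoc.scan_q(m, y, Q)
        res_n = assoc.scan_naive(m, y)
        np.testing.assert_allclose(res_q.p_raw, res_n.p_raw, atol=1e-12)

    def test_marker_collinear_with_q_untestable(self):
        memb = np.array([[0.0, 1.0]] * 5 + [[1.0, 0.0]] * 5)
        Q = AdmixtureQ(memberships=memb, accession_ids=[str(i) for i in range(10)])
        scores = np.column_stack([memb[:, 0].astype(int),
                                  [0, 1, 0, 1, 0, 1, 0, 1, 0, 1]])
        m = make_markers(scores.astype(np.int8))
        res = assoc.scan_q(m, np.arange(10, dtype=float), Q)
        assert res.untestable[0]
        assert not res.untestable[1]

    def test_matches_general_linear_hypothesis_oracle(self, rng):
        # GLH oracle: full-model OLS with explicit F = (RSS0-RSS1)/(RSS1/df)
        markers, y, Q, _ = random_structured(seed=101)
        res = assoc.scan_q(markers, y, Q)
        X0 = np.column_stack([np.ones(len(y)), Q.memberships[:, :-1]])
        for j in range(markers.n_markers):
            X1 = np.column_stack([X0, markers.scores[:, j]])
            b0, rss0 = np.linalg.lstsq(X0, y, rcond=None)[0], None
            rss0 = float(((y - X0 @ b0) ** 2).sum())
            b1 = np.linalg.lstsq(X1, y, rcond=None)[0]
            rss1 = float(((y - X1 @ b1) ** 2).sum())
            df = len(y) - X1.shape[1]
            F = (rss0 - rss1) / (rss1 / df)
            p = stats.f.sf(F, 1, df)
            assert res.p_raw[j] == pytest.approx(p, abs=1e-10)


class TestFitVC:
    def test_null_recovery(self):
        # sigma_g2 = 0 truth: estimated heritability should collapse
        hits = 0
        reps = 40
        for r in range(reps):
            rng = np.random.default_rng(200 + r)
            n = 100
            A = rng.standard_normal((n, 5))
            K = A @ A.T / 5
            d = np.sqrt(np.diag(K))
            K = K / np.outer(d, d)
            y = rng.standard_normal(n)
            vc = assoc.fit_vc(y, np.ones((n, 1)), K)
            h2 = vc.sigma_g2 / (vc.sigma_g2 + vc.sigma_e2)
            hits += h2 <= 0.05
        assert hits / reps >= 0.9

    def test_scale_equivariance(self):
        markers, y, Q, K = random_structured(seed=55)
        X = np.ones((len(y), 1))
        vc1 = assoc.fit_vc(y, X, K)
        vc2 = assoc.fit_vc(2 * y, X, K)
        assert vc2.sigma_g2 == pytest.approx(4 * vc1.sigma_g2, rel=1e-6, abs=1e-12)
        assert vc2.sigma_e2 == pytest.approx(4 * vc1.sigma_e2, rel=1e-6)
        assert vc2.lam == pytest.approx(vc1.lam, rel=1e-6)

    def test_optimum_dominates_brute_force_grid(self):
        markers, y, Q, K = random_structured(seed=77)
        X = np.ones((len(y), 1))
        vc = assoc.fit_vc(y, X, K)
        for lam in np.logspace(-4, 4, 25):
            ll_direct = brute_force_reml_loglik(y, X, K, lam)
            ll_opt = brute_force_reml_loglik(y, X, K, vc.lam)
            assert ll_opt >= ll_direct - 1e-6

    def test_spectral_equals_direct_loglik_shape(self):
        # spectral and direct REML agree up to a lambda-free constant
        markers, y, Q, K = random_structured(seed=88)
        X = np.ones((len(y), 1))
        from qkforest.assoc import _reml_loglik, _reml_spectral
        xi, eta, r = _reml_spectral(y, X, K)
        lams = [0.01, 0.1, 1.0, 10.0]
        diffs = [_reml_loglik(l, xi, eta, r) - brute_force_reml_loglik(y, X, K, l)
                 for l in lams]
        assert np.ptp(diffs) < 1e-6

    def test_non_psd_rejected(self):
        K = np.eye(10)
        K[0, 1] = K[1, 0] = 2.0
        with pytest.raises(ValueError, match="PSD"):
            assoc.fit_vc(np.random.default_rng(0).standard_normal(10),
                         np.ones((10, 1)), K)


class TestScanMixed:
    def test_identity_k_reduces_to_naive_and_q(self):
        markers, y, Q, _ = random_structured(seed=31)
        n = len(y)
        I = np.eye(n)
        res3 = assoc.scan_mixed(markers, y, I)
        res1 = assoc.scan_naive(markers, y)
        np.testing.assert_allclose(res3.p_raw, res1.p_raw, atol=1e-8)
        res4 = assoc.scan_mixed(markers, y, I, Q=Q)
        res2 = assoc.scan_q(markers, y, Q)
        np.testing.assert_allclose(res4.p_raw, res2.p_raw, atol=1e-8)

    def test_matches_brute_force_gls_oracle(self):
        markers, y, Q, K = random_structured(seed=47, n=50, m=22)
        res = assoc.scan_mixed(markers, y, K, Q=Q, vc_strategy="per-marker")
        X0 = np.column_stack([np.ones(len(y)), Q.memberships[:, :-1]])
        p_oracle = brute_force_gls_scan(markers.scores.astype(float), y, X0, K)
        dlog = np.abs(np.log10(res.p_raw) - np.log10(p_oracle))
        assert np.nanmax(dlog) <= 0.05

    def test_power_at_fdr(self):
        # strong planted effect detected at FDR <= 0.05 in most replicates
        detected = 0
        reps = 30
        for r in range(reps):
            cfg = simdata.SimConfig(n_accessions=200, n_subpops=2, fst=0.2,
                                    admix_alpha=0.3, n_markers=60,
                                    causal_effects={5: 1.0}, sigma_g2=0.5,
                                    sigma_e2=0.5, seed=900 + r)
            Q, P = simdata.simulate_population(cfg)
            markers = simdata.simulate_markers(Q, P, seed=901 + r)
            if not 0.1 < markers.allele_freq[5] < 0.9:
                detected += 1  # skip degenerate draw (count as neutral)
                continue
            K = kinship.kinship_freq_corrected(
                markers.subset((markers.allele_freq > 0)
                               & (markers.allele_freq < 1)))
            pheno, _ = simdata.simulate_phenotypes(markers, Q, K.values, cfg)
            keep = (markers.allele_freq > 0.1) & (markers.allele_freq < 0.9)
            idx5 = int(keep[:5].sum())
            res = assoc.scan_mixed(markers.subset(keep), pheno.values[:, 0],
                                   K, Q=Q)
            padj = assoc.adjust_fdr(res.p_raw)
            detected += padj[idx5] <= 0.05
        assert detected / reps >= 0.8


class TestVarianceExplained:
    def test_perfect_marker_is_one(self):
        m = make_markers([[0], [1], [0], [1]])
        res = assoc.scan_naive(m, m.scores[:, 0].astype(float))
        assert assoc.variance_explained(res)[0] == pytest.approx(1.0)

    def test_independent_marker_near_zero_never_negative(self, rng):
        scores = (rng.random((500, 5)) < 0.5).astype(np.int8)
        res = assoc.scan_naive(make_markers(scores), rng.standard_normal(500))
        r2 = assoc.variance_explained(res)
        assert np.all(r2 >= 0) and np.all(r2 < 0.05)

    def test_orthogonal_additivity(self):
        # orthogonal balanced predictors: incremental R2 sums to full-model R2
        x1 = np.array([0, 0, 1, 1, 0, 0, 1, 1], dtype=np.int8)
        x2 = np.array([0, 1, 0, 1, 0, 1, 0, 1], dtype=np.int8)
        y = 1.0 * x1 + 2.0 * x2 + np.array([0.1, -0.1] * 4)
        m = make_markers(np.column_stack([x1, x2]))
        res = assoc.scan_naive(m, y)
        X = np.column_stack([np.ones(8), x1, x2])
        b = np.linalg.lstsq(X, y, rcond=None)[0]
        rss = float(((y - X @ b) ** 2).sum())
        tss = float(((y - y.mean()) ** 2).sum())
        full_r2 = 1 - rss / tss
        assert res.r2.sum() == pytest.approx(full_r2, abs=1e-10)


class TestAdjustFDR:
    def test_single_p_unchanged(self):
        assert assoc.adjust_fdr(np.array([0.2]))[0] == pytest.approx(0.2)

    def test_step_up_arithmetic(self):
        adj = assoc.adjust_fdr(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_matches_brute_force(self, rng):
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 40))
            np.testing.assert_array_equal(assoc.adjust_fdr(p), brute_force_bh(p))

    def test_nan_propagates(self):
        adj = assoc.adjust_fdr(np.array([0.01, np.nan, 0.5]))
        assert np.isnan(adj[1]) and np.isfinite(adj[0])


class TestAdjustResampling:
    def test_single_marker_equals_permutation_p(self, rng):
        scores = (rng.random((30, 1)) < 0.5).astype(np.int8)
        m = make_markers(scores)
        y = rng.standard_normal(30)
        res = assoc.adjust_resampling(m, y, ModelSpec(1), n_perm=300, seed=5)
        # with one marker maxT is the plain permutation p of that marker
        assert 0 < res.p_adj[0] <= 1
        assert res.p_adj[0] >= res.p_raw[0]

    def test_adjusted_geq_raw_and_monotone(self):
        markers, y, Q, K = random_structured(seed=61)
        res = assoc.adjust_resampling(markers, y, ModelSpec(4), n_perm=200,
                                      seed=2, Q=Q, K=K)
        ok = ~res.untestable
        assert np.all(res.p_adj[ok] >= res.p_raw[ok] - 1e-12)
        order = np.argsort(res.p_raw[ok])
        assert np.all(np.diff(res.p_adj[ok][order]) >= -1e-12)

    def test_seeded_determinism(self):
        markers, y, Q, K = random_structured(seed=62)
        r1 = assoc.adjust_resampling(markers, y, ModelSpec(2), n_perm=150,
                                     seed=9, Q=Q)
        r2 = assoc.adjust_resampling(markers, y, ModelSpec(2), n_perm=150,
                                     seed=9, Q=Q)
        np.testing.assert_array_equal(r1.p_adj, r2.p_adj)

    def test_small_n_perm_warns(self, rng):
        m = make_markers((rng.random((20, 3)) < 0.5).astype(np.int8))
        with pytest.warns(UserWarning, match="n_perm"):
            assoc.adjust_resampling(m, rng.standard_normal(20), ModelSpec(1),
                                    n_perm=50)


class TestSummarizeSubpops:
    def test_identical_group_means(self):
        y = np.tile([1.0, 2.0, 3.0], 4)
        pheno = simdata.PhenotypeTable(values=y, accession_ids=[str(i) for i in range(12)],
                                       trait_names=["t"])
        labels = np.repeat(["a", "b", "c", "d"], 3)
        tbl = assoc.summarize_subpops(pheno, labels)
        assert tbl["anova_F"].iloc[0] <= 1e-10

    def test_two_groups_equals_t_test(self, rng):
        y = rng.standard_normal(20)
        labels = np.array(["x"] * 10 + ["y"] * 10)
        pheno = simdata.PhenotypeTable(values=y, accession_ids=[str(i) for i in range(20)],
                                       trait_names=["t"])
        tbl = assoc.summarize_subpops(pheno, labels)
        _, p = stats.ttest_ind(y[:10], y[10:], equal_var=True)
        assert tbl["anova_p"].iloc[0] == pytest.approx(p, abs=1e-12)

    def test_lsd_hand_formula(self):
        y = np.array([1.0, 2.0, 3.0, 4.0, 10.0, 11.0, 12.0, 13.0])
        labels = np.array(["a"] * 4 + ["b"] * 4)
        pheno = simdata.PhenotypeTable(values=y, accession_ids=[str(i) for i in range(8)],
                                       trait_names=["t"])
        tbl = assoc.summarize_subpops(pheno, labels, alpha=0.05)
        mse = (np.var(y[:4], ddof=1) * 3 + np.var(y[4:], ddof=1) * 3) / 6
        lsd = stats.t.ppf(0.975, 6) * np.sqrt(mse * (1 / 4 + 1 / 4))
        assert tbl["lsd"].iloc[0] == pytest.approx(lsd, abs=1e-12)
        assert tbl["significant"].iloc[0]

    def test_small_group_dropped(self, rng):
        y = rng.standard_normal(11)
        labels = np.array(["a"] * 5 + ["b"] * 5 + ["c"])
        pheno = simdata.PhenotypeTable(values=y, accession_ids=[str(i) for i in range(11)],
                                       trait_names=["t"])
        with pytest.warns(UserWarning, match="dropping"):
            tbl = assoc.summarize_subpops(pheno, labels)
        assert set(tbl["group_a"]) | set(tbl["group_b"]) == {"a", "b"}


def test_type_one_error_ordering_under_confounding():
    """Naive model inflated; Q-corrected models calibrated; K-only ~ naive."""
    rates = {1: [], 2: [], 3: [], 4: []}
    reps = 6
    for r in range(reps):
        cfg = simdata.SimConfig(n_accessions=150, n_subpops=4, fst=0.25,
                                admix_alpha=0.5, n_markers=120,
                                pop_effects=[1.0, 0.3, -0.3, -1.0],
                                sigma_g2=0.0, sigma_e2=1.0, seed=3000 + r)
        Q, P = simdata.simulate_population(cfg)
        markers = simdata.simulate_markers(Q, P, seed=3100 + r)
        pheno, _ = simdata.simulate_phenotypes(markers, Q, np.eye(150), cfg)
        y = pheno.values[:, 0]
        keep = (markers.allele_freq > 0.1) & (markers.allele_freq < 0.9)
        mk = markers.subset(keep)
        K = kinship.kinship_freq_corrected(mk)
        res = {
            1: assoc.scan_naive(mk, y),
            2: assoc.scan_q(mk, y, Q),
            3: assoc.scan_mixed(mk, y, K),
            4: assoc.scan_mixed(mk, y, K, Q=Q),
        }
        for mdl, scan in res.items():
            p = scan.p_raw[~scan.untestable]
            rates[mdl].append((p < 0.05).mean())
    means = {mdl: np.mean(v) for mdl, v in rates.items()}
    assert means[1] > 0.10  # > 2x nominal
    assert means[2] < 0.10
    assert means[4] < 0.10
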