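import numpy as np
import pytest

import ordidim as od
from ordidim.ega import (
    EGAConfig,
    detect_communities,
    glasso_ebic_select,
    louvain_communities,
    select_network,
    unidimensionality_adjust,
)
from ordidim.generate import discretize, sample_normal, threshold_table


def block_sigma(n_blocks, block_size, within, between=0.0):
    p = n_blocks * block_size
    S = np.full((p, p), between)
    for b in range(n_blocks):
        sl = slice(b * block_size, (b + 1) * block_size)
        S[sl, sl] = within
    np.fill_diagonal(S, 1.0)
    return S


def factor_data(m, k, primary, cross, rho, n, seed, categories=4):
    c = od.ConditionSpec(n=n, m=m, k=k, primary_level=primary, cross_level=cross,
                         rho=rho, categories=categories, dist_type="normal")
    return od.generate_dataset(c, np.random.default_rng(seed))


class TestGlassoEbicSelect:
    def test_identity_gives_empty_network(self):
        net = glasso_ebic_select(np.eye(6), 1000)
        assert net.n_edges == 0
        assert np.all(net.W == 0)

    def test_gamma_zero_reduces_to_bic(self):
        S = block_sigma(2, 3, 0.4, 0.1)
        n = 500
        net0 = glasso_ebic_select(S, n, gamma=0.0)
        net5 = glasso_ebic_select(S, n, gamma=0.5)
        merged = net0.ebic_grid.merge(net5.ebic_grid, on="lam", suffixes=("_0", "_5"))
        # EBIC(gamma) - BIC = 4 * gamma * E * log p at every grid point
        extra = 4 * 0.5 * merged["n_edges_5"] * np.log(S.shape[0])
        assert np.allclose(merged["ebic_5"] - merged["ebic_0"], extra)
        assert np.isfinite(net0.ebic_grid["ebic"]).all()
        assert net0.ebic_value == pytest.approx(net0.ebic_grid["ebic"].min())

    def test_two_variable_case_matches_brute_force(self):
        """EBIC scan using a generic penalized-likelihood optimizer (oracle)."""
        from scipy.optimize import minimize

        S = np.array([[1.0, 0.5], [0.5, 1.0]])
        n = 1000
        lam_max = 0.5
        lams = np.exp(np.linspace(np.log(lam_max), np.log(0.1 * lam_max), 100))

        def fit_at(lam):
            def obj(theta):
                K = np.array([[theta[0], theta[2]], [theta[2], theta[1]]])
                w = np.linalg.eigvalsh(K)
                if w[0] <= 1e-10:
                    return 1e10
                return (-np.log(w).sum() + np.trace(S @ K) + 2 * lam * abs(theta[2]))

            best = None
            for start in ([1.0, 1.0, 0.0], [1.4, 1.4, -0.6]):
                r = minimize(obj, start, method="Nelder-Mead",
                             options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
                if best is None or r.fun < best.fun:
                    best = r
            return np.array([[best.x[0], best.x[2]], [best.x[2], best.x[1]]])

        best_ebic, best_w = np.inf, None
        for lam in lams:
            K = fit_at(lam)
            E = int(abs(K[0, 1]) > 1e-4)
            k12 = K[0, 1] if E else 0.0
            ll = 0.5 * n * (np.linalg.slogdet(K)[1] - np.trace(S @ K))
            ebic = -2 * ll + E * np.log(n) + 4 * E * 0.5 * np.log(2)
            if ebic < best_ebic:
                best_ebic = ebic
                best_w = -k12 / np.sqrt(K[0, 0] * K[1, 1])
        net = glasso_ebic_select(S, n)
        assert net.W[0, 1] == pytest.approx(best_w, abs=5e-3)

    def test_partial_correlation_transform_properties(self):
        S = block_sigma(2, 4, 0.5, -0.15)
        net = glasso_ebic_select(S, 2000)
        assert np.abs(net.W).max() <= 1.0
        assert np.allclose(np.diag(net.W), 0.0)
        # recompute K at the selected lambda to compare signs
        from ordidim._glasso import glasso_path

        Ks, _ = glasso_path(S, np.array([net.lambda_selected]), 1e-4, 200, 1e-7, 200)
        K = Ks[0]
        mask = np.abs(K) > 1e-8
        np.fill_diagonal(mask, False)
        assert np.all(np.sign(net.W[mask]) == -np.sign(K[mask]))

    def test_larger_gamma_never_denser(self):
        S = block_sigma(2, 5, 0.35, 0.1)
        sparse = glasso_ebic_select(S, 300, gamma=1.0)
        dense = glasso_ebic_select(S, 300, gamma=0.0)
        assert sparse.n_edges <= dense.n_edges

    def test_matches_reference_solver(self):
        """Cross-check precision path points against sklearn's graphical lasso."""
        import warnings

        from sklearn.covariance import graphical_lasso as sk_glasso

        from ordidim._glasso import glasso_path

        rng = np.random.default_rng(2)
        A = rng.standard_normal((8, 8))
        S = A @ A.T
        d = np.sqrt(np.diag(S))
        S = S / np.outer(d, d)
        lams = np.array([0.4, 0.2, 0.1, 0.05])
        Ks, _ = glasso_path(S, lams, 1e-6, 500, 1e-9, 500)
        for i, lam in enumerate(lams):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, K_ref = sk_glasso(S, alpha=lam, tol=1e-8, max_iter=1000)
            assert np.abs(Ks[i] - K_ref).max() < 0.02


class TestDetectCommunities:
    def test_disconnected_blocks(self):
        W = block_sigma(2, 5, 0.3, 0.0)
        np.fill_diagonal(W, 0.0)
        labels = detect_communities(W)
        assert np.unique(labels).size == 2
        assert np.unique(labels[:5]).size == 1 and np.unique(labels[5:]).size == 1

    def test_empty_network_gives_singletons(self):
        labels = detect_communities(np.zeros((7, 7)))
        assert np.array_equal(labels, np.arange(7))

    def test_block_diagonal_parameter_recovery(self):
        # within-block correlation 0.49 (loadings 0.7), orthogonal blocks
        S = block_sigma(2, 5, 0.49)
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = sample_normal(S, 1000, rng)
            d = discretize(X, threshold_table(4, False))
            net = select_network(od.polychoric_matrix(d.values), 1000)
            labels = detect_communities(net)
            ok = (np.unique(labels).size == 2
                  and np.unique(labels[:5]).size == 1
                  and np.unique(labels[5:]).size == 1)
            hits += ok
        assert hits == 20


class TestGammaStepdown:
    def test_stepdown_connects_weak_network(self):
        data = factor_data(2, 10, "low", "low", 0.6, 300, seed=1)
        S = od.polychoric_matrix(data)
        fixed = glasso_ebic_select(S, 300, gamma=0.5)
        stepped = select_network(S, 300)
        assert fixed.n_edges == 0  # EBIC at gamma=0.5 prefers the empty network here
        assert stepped.n_edges > 0
        assert stepped.gamma < 0.5
        assert stepped.isolated_nodes().size == 0

    def test_no_stepdown_when_connected(self):
        data = factor_data(2, 5, "high", "low", 0.0, 300, seed=2)
        net = select_network(od.polychoric_matrix(data), 300)
        assert net.gamma == 0.5


class TestUnidimensionalityAdjust:
    def test_louvain_gate_accepts_one_factor(self):
        hits = 0
        for seed in range(20):
            data = factor_data(1, 5, "high", "low", 0.0, 1000, seed=seed)
            is_uni, nf = unidimensionality_adjust(data, np.random.default_rng(seed))
            hits += is_uni and nf == 1
        assert hits == 20

    def test_louvain_gate_defers_two_factors(self):
        data = factor_data(2, 10, "high", "low", 0.6, 300, seed=3)
        is_uni, nf = unidimensionality_adjust(data, np.random.default_rng(0))
        assert (is_uni, nf) == (False, None)

    def test_expand_accepts_one_factor(self):
        cfg = EGAConfig(uni_method="expand")
        hits = 0
        reps = 40
        for seed in range(reps):
            data = factor_data(1, 5, "high", "low", 0.0, 1000, seed=seed)
            is_uni, nf = unidimensionality_adjust(
                data, np.random.default_rng(seed), cfg
            )
            hits += is_uni and nf == 1
        assert hits / reps >= 0.95

    def test_expand_defers_orthogonal_two_factors(self):
        cfg = EGAConfig(uni_method="expand")
        hits = 0
        reps = 40
        for seed in range(reps):
            data = factor_data(2, 5, "high", "low", 0.0, 1000, seed=seed)
            is_uni, _ = unidimensionality_adjust(data, np.random.default_rng(seed), cfg)
            hits += not is_uni
        assert hits / reps >= 0.95

    def test_expand_augments_four_items(self):
        from ordidim.ega import _simulated_unidim_block

        block = _simulated_unidim_block(300, 5, True, np.random.default_rng(0))
        assert block.shape == (300, 4)
        assert block.min() >= 1 and block.max() <= 5


class TestEgaNfactors:
    def test_strong_four_factor_recovery(self):
        hits = 0
        reps = 40
        for seed in range(reps):
            data = factor_data(4, 5, "high", "low", 0.0, 1000, seed=seed)
            res = od.ega_nfactors(data, np.random.default_rng(seed))
            hits += res.n_factors == 4
        assert hits / reps >= 0.95

    def test_oblique_two_factor_recovery(self):
        hits = 0
        reps = 20
        for seed in range(reps):
            data = factor_data(2, 10, "high", "low", 0.6, 300, seed=seed)
            res = od.ega_nfactors(data, np.random.default_rng(seed))
            hits += res.n_factors == 2
        assert hits / reps >= 0.95

    def test_one_factor_via_adjustment(self):
        data = factor_data(1, 5, "high", "low", 0.0, 1000, seed=11)
        res = od.ega_nfactors(data, np.random.default_rng(1))
        assert res.n_factors == 1
        assert res.unidimensional_branch

    def test_independent_items_overfactor_without_gate(self):
        rng = np.random.default_rng(21)
        values = rng.integers(1, 5, size=(500, 6))
        data = od.OrdinalDataset(values=values)
        cfg = EGAConfig(uni_method="none", gamma_step=0.0)
        res = od.ega_nfactors(data, np.random.default_rng(0), cfg)
        assert res.n_factors == 6  # singleton communities, counted as overfactoring

    def test_louvain_communities_on_blocks(self):
        labels = louvain_communities(block_sigma(3, 5, 0.6, 0.05))
        assert np.unique(labels).size == 3

    def test_network_export(self):
        data = factor_data(2, 5, "high", "low", 0.0, 600, seed=4)
        res = od.ega_nfactors(data, np.random.default_rng(0))
        edges = res.network.edge_list()
        assert (edges["weight"].abs() > 0).all()
        assert len(edges) == res.network.n_edges
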