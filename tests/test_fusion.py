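"""Sparse CCA, low-rank multimodal fusion and the CONCAT baseline."""

import numpy as np
import pandas as pd
import pytest

from respifuse import (FeatureTable, LowRankFusion, SparseCCA, concat_fuse)
from respifuse.errors import (AlignmentError, DegenerateSolutionError,
                              DivergenceError, SchemaError)
from respifuse.fusion import _augment, outer_product_features


def classical_cca_rho(X, Y, k):
    """Brute-force classical CCA correlations via the generalized
    eigenproblem on explicit covariance matrices."""
    n = X.shape[0]
    Xs = (X - X.mean(0)) / X.std(0)
    Ys = (Y - Y.mean(0)) / Y.std(0)
    Sxx, Syy = Xs.T @ Xs / n, Ys.T @ Ys / n
    Sxy = Xs.T @ Ys / n
    M = np.linalg.solve(Sxx, Sxy) @ np.linalg.solve(Syy, Sxy.T)
    ev = np.sqrt(np.clip(np.sort(np.linalg.eigvals(M).real)[::-1], 0, None))
    return ev[:k]


def _tables(X, Y, labels=None):
    n = X.shape[0]
    ids = [f"s{i:03d}" for i in range(n)]
    labels = labels if labels is not None else np.r_[np.ones(n // 2, int),
                                                    np.zeros(n - n // 2, int)]
    tX = FeatureTable(pd.DataFrame(X, index=ids,
                                   columns=[f"x{j}" for j in range(X.shape[1])]),
                      labels)
    tY = FeatureTable(pd.DataFrame(Y, index=ids,
                                   columns=[f"y{j}" for j in range(Y.shape[1])]),
                      labels)
    return tX, tY


def planted_instance(seed=42, n=500, p=9, q=9):
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n)
    X = rng.standard_normal((n, p))
    Y = rng.standard_normal((n, q))
    a = np.zeros(p)
    a[[0, 3, 7]] = [1.0, -0.8, 0.6]
    b = np.zeros(q)
    b[[1, 4, 5]] = [0.9, 0.7, -0.5]
    X += np.outer(z, a)
    Y += np.outer(z, b)
    return X, Y, a, b


class TestSparseCCA:
    def test_identical_blocks_have_unit_correlation(self, rng):
        X = rng.standard_normal((60, 4))
        tX, _ = _tables(X, X)
        tY, _ = _tables(X, X)
        model = SparseCCA(n_components=1).fit(tX, tX)
        assert model.rho_[0] == pytest.approx(1.0, abs=1e-6)

    def test_unpenalized_fit_matches_classical_cca_oracle(self, rng):
        X = rng.standard_normal((200, 5))
        Y = rng.standard_normal((200, 4))
        Y[:, 0] += 0.8 * X[:, 1]
        tX, tY = _tables(X, Y)
        model = SparseCCA(n_components=2).fit(tX, tY)
        oracle = classical_cca_rho(X, Y, 2)
        assert np.abs(model.rho_ - oracle).max() < 1e-6

    def test_planted_support_recovery(self):
        X, Y, a_true, b_true = planted_instance()
        tX, tY = _tables(X, Y)
        model = SparseCCA(lam1=0.15, lam2=0.15, n_components=1).fit(tX, tY)
        a, b = model.a_[:, 0], model.b_[:, 0]
        assert set(np.flatnonzero(np.abs(a) > 1e-12)) == {0, 3, 7}
        assert set(np.flatnonzero(np.abs(b) > 1e-12)) == {1, 4, 5}
        assert abs(a @ (a_true / np.linalg.norm(a_true))) > 0.9
        assert abs(b @ (b_true / np.linalg.norm(b_true))) > 0.9

    def test_penalty_path_sparsity_monotone(self, rng):
        X = rng.standard_normal((80, 6))
        Y = rng.standard_normal((80, 6))
        Y[:, 0] += 0.5 * X[:, 0]
        tX, tY = _tables(X, Y)
        counts = [SparseCCA(lam1=lam, n_components=1).fit(tX, tY)
                  .nonzero_counts()[0]
                  for lam in (0.0, 0.05, 0.1, 0.15, 0.2, 0.25, 0.3)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_overwhelming_penalty_raises_named_error(self, rng):
        X = rng.standard_normal((50, 4))
        tX, tY = _tables(X, rng.standard_normal((50, 4)))
        with pytest.raises(DegenerateSolutionError, match="lambda1"):
            SparseCCA(lam1=5.0, n_components=1).fit(tX, tY)

    def test_objective_ascends_at_zero_penalty(self, rng):
        X = rng.standard_normal((100, 6))
        Y = rng.standard_normal((100, 5))
        Y[:, 2] += 0.4 * X[:, 1]
        tX, tY = _tables(X, Y)
        model = SparseCCA(n_components=1).fit(tX, tY)
        history = model.objective_history_[0]
        assert np.all(np.diff(history) >= -1e-10)

    def test_transform_width_and_rho_reproduction(self, rng):
        X = rng.standard_normal((120, 5))
        Y = rng.standard_normal((120, 4))
        Y[:, 1] += X[:, 0]
        tX, tY = _tables(X, Y)
        model = SparseCCA(n_components=2).fit(tX, tY)
        cflc = model.transform(tX, tY)
        assert cflc.values.shape[1] == 4  # 2 columns per component
        assert cflc.role == "CFLC"
        u, v = cflc.values[:, 0], cflc.values[:, 1]
        assert abs(np.corrcoef(u, v)[0, 1] - model.rho_[0]) < 1e-6

    def test_zero_variance_column_contributes_nothing(self, rng):
        X = rng.standard_normal((80, 4))
        X[:, 2] = 7.0  # constant
        Y = rng.standard_normal((80, 3))
        Y[:, 0] += X[:, 0]
        tX, tY = _tables(X, Y)
        cflc = SparseCCA(n_components=1).fit_transform(tX, tY)
        X2 = X.copy()
        X2[:, 2] = -3.0  # different constant, same information
        tX2, _ = _tables(X2, Y)
        cflc2 = SparseCCA(n_components=1).fit_transform(tX2, tY)
        assert np.allclose(cflc.values, cflc2.values, atol=1e-8)

    def test_column_mismatch_rejected(self, rng):
        X = rng.standard_normal((40, 3))
        tX, tY = _tables(X, rng.standard_normal((40, 3)))
        model = SparseCCA(n_components=1).fit(tX, tY)
        with pytest.raises(SchemaError):
            model.transform(tY, tX)


class TestLowRankFusion:
    def test_gradients_match_finite_differences(self, rng):
        r, h, n = 2, 3, 25
        Zc = _augment(rng.standard_normal((n, 2)))
        Zl = _augment(rng.standard_normal((n, 2)))
        y = rng.integers(0, 2, n).astype(float)
        Wc = rng.normal(0, 0.5, (r, h, 3))
        Wl = rng.normal(0, 0.5, (r, h, 3))
        v = rng.normal(0, 0.5, h)
        c = 0.1
        _, dWc, dWl, dv, dc = LowRankFusion.loss_and_grads(Wc, Wl, v, c,
                                                           Zc, Zl, y)
        eps = 1e-5
        for arr, grad in ((Wc, dWc), (Wl, dWl), (v, dv)):
            flat = arr.reshape(-1)
            gflat = np.asarray(grad).reshape(-1)
            for idx in rng.choice(flat.size, size=min(6, flat.size),
                                  replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                lp = LowRankFusion.loss_and_grads(Wc, Wl, v, c, Zc, Zl, y)[0]
                flat[idx] = orig - eps
                lm = LowRankFusion.loss_and_grads(Wc, Wl, v, c, Zc, Zl, y)[0]
                flat[idx] = orig
                numeric = (lp - lm) / (2 * eps)
                assert abs(numeric - gflat[idx]) < 1e-3 * max(1.0, abs(numeric))

    def test_full_rank_factorization_reproduces_tensor_fusion(self, rng):
        """A full-rank decomposition of an explicit weight tensor yields an
        LMF whose h equals the TFN output exactly."""
        W = rng.standard_normal((4, 3, 5))
        model = LowRankFusion.from_tensor(W)
        Zc = rng.standard_normal((20, 3))
        Zl = rng.standard_normal((20, 5))
        h_lmf = LowRankFusion.forward_h(model.W_c_, model.W_l_, Zc, Zl)
        h_tfn = np.einsum("np,kpq,nq->nk", Zc, W, Zl)
        assert np.abs(h_lmf - h_tfn).max() < 1e-10

    def test_trained_tfn_oracle_reproduced_at_full_rank(self, rng):
        """Tiny instance (d1 = d2 = 2, n = 50): the convex TFN logistic fit
        defines the oracle; its weight tensor, refactored at full rank,
        reproduces the oracle's fusion output within 1e-4."""
        from sklearn.linear_model import LogisticRegression

        n = 50
        Xc = rng.standard_normal((n, 2))
        Xl = rng.standard_normal((n, 2))
        y = (Xc[:, 0] * Xl[:, 0] + 0.3 * rng.standard_normal(n) > 0).astype(int)
        Zc, Zl = _augment(Xc), _augment(Xl)
        tfn_features = outer_product_features(Zc, Zl)
        oracle = LogisticRegression(C=1e6, max_iter=5000).fit(tfn_features, y)
        W = oracle.coef_.reshape(1, 3, 3)
        model = LowRankFusion.from_tensor(W)
        h = LowRankFusion.forward_h(model.W_c_, model.W_l_, Zc, Zl)[:, 0]
        logits_oracle = tfn_features @ oracle.coef_[0]
        assert np.abs(h - logits_oracle).max() < 1e-4

    def test_rank_one_scalar_output_is_product_of_affine_forms(self, rng):
        model = LowRankFusion(rank=1, h_dim=1)
        wc = rng.standard_normal((1, 1, 3))
        wl = rng.standard_normal((1, 1, 4))
        Zc = _augment(rng.standard_normal((15, 2)))
        Zl = _augment(rng.standard_normal((15, 3)))
        h = LowRankFusion.forward_h(wc, wl, Zc, Zl)[:, 0]
        assert np.allclose(h, (Zc @ wc[0, 0]) * (Zl @ wl[0, 0]), atol=1e-12)

    def test_zero_inputs_give_constant_fusion_rows(self, rng):
        n = 30
        Xc = np.zeros((n, 3))
        Xl = np.zeros((n, 2))
        tc, tl = _tables(Xc, Xl)
        model = LowRankFusion(rank=2, h_dim=4, n_steps=50).fit(tc, tl)
        h = model.transform(tc, tl).values
        assert np.allclose(h, h[0], atol=1e-12)

    def test_divergence_raises_actionable_error(self, rng):
        Xc = 100 * rng.standard_normal((40, 3))
        Xl = 100 * rng.standard_normal((40, 3))
        tc, tl = _tables(Xc, Xl)
        with pytest.raises(DivergenceError, match="learning rate"):
            LowRankFusion(rank=2, h_dim=2, learning_rate=1e12,
                          n_steps=50).fit(tc, tl)

    def test_training_reduces_loss_on_learnable_signal(self, rng):
        n = 200
        Xc = rng.standard_normal((n, 3))
        Xl = rng.standard_normal((n, 3))
        labels = (Xc[:, 0] + Xl[:, 0] > 0).astype(int)
        tc, tl = _tables(Xc, Xl, labels)
        model = LowRankFusion(rank=2, h_dim=4, n_steps=500).fit(tc, tl)
        assert model.loss_history_[-1] < model.loss_history_[0]


class TestConcat:
    def test_widths_add(self, rng):
        tabs = []
        for j, w in enumerate((9, 9, 7)):
            X = rng.standard_normal((12, w))
            ids = [f"s{i:03d}" for i in range(12)]
            tabs.append(FeatureTable(
                pd.DataFrame(X, index=ids,
                             columns=[f"m{j}_{k}" for k in range(w)]),
                np.r_[np.ones(6, int), np.zeros(6, int)]))
        fused = concat_fuse(tabs)
        assert fused.values.shape[1] == 25
        assert fused.role == "concat"
        assert fused.provenance["widths"] == [9, 9, 7]

    def test_single_table_identity(self, rng, table_factory):
        t = table_factory(rng.standard_normal((8, 3)), np.r_[1, 1, 1, 1, 0, 0, 0, 0])
        fused = concat_fuse([t])
        assert np.array_equal(fused.values, t.values)

    def test_misaligned_ids_rejected(self, rng):
        X = rng.standard_normal((6, 2))
        labels = np.r_[1, 1, 1, 0, 0, 0]
        a = FeatureTable(pd.DataFrame(X, index=[f"a{i}" for i in range(6)],
                                      columns=["p", "q"]), labels)
        b = FeatureTable(pd.DataFrame(X, index=[f"b{i}" for i in range(6)],
                                      columns=["r", "s"]), labels)
        with pytest.raises(AlignmentError):
            concat_fuse([a, b])
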