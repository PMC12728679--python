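"""Feature-level fusion: sparse CCA, low-rank multimodal fusion and
early-fusion concatenation.

**Sparse CCA.**  Given the fiber-frequency block X (FFr) and the
audio-rhythm block Y (ARh), sparse CCA maximizes ``corr(Xa, Yb)`` under L1
penalties on the canonical directions,

    max_{a,b}  aᵀ Sxy b / sqrt(aᵀ Sxx a · bᵀ Syy b)  −  λ1‖a‖₁ − λ2‖b‖₁.

The solver alternates ridge-stabilized penalized regressions: hold ``b``
fixed, regress the variate ``Yb`` on X, soft-threshold, renormalize to unit
variate variance, then swap.  With λ = 0 this is exactly power iteration on
the whitened cross-covariance, so it converges to the classical CCA
solution; components beyond the first are found by deflating the fitted
canonical variates out of both blocks.  The per-subject fusion product
("clinical features", CFLC) concatenates the pair of canonical variate
scores for each component.

**Low-rank multimodal fusion (LMF).**  The exact tensor-fusion (TFN)
counterpart scores the outer product of bias-augmented modality vectors,
``h_k = z_cᵀ W_k z_l``.  LMF replaces each ``W_k`` by a rank-r sum of
modality-specific factors so that

    h = Σ_{i=1..r} (W_CFLC⁽ⁱ⁾ z_CFLC) ⊙ (W_LMLC⁽ⁱ⁾ z_LMLC),

with ⊙ the elementwise product.  Factors are trained by full-batch
gradient descent on a logistic proxy loss over the class labels, then
frozen; ``h`` is emitted as the fused feature table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (AlignmentError, ConfigurationError,
                     DegenerateSolutionError, DivergenceError, SchemaError)
from .records import FeatureTable


class FusedFeatureTable(FeatureTable):
    """FeatureTable carrying a fusion role tag and provenance."""

    def __init__(self, frame, labels=None, role: str = "concat",
                 provenance: dict | None = None):
        super().__init__(frame, labels)
        if role not in ("CFLC", "LMLC", "h", "concat"):
            raise ConfigurationError(f"unknown fusion role {role!r}")
        self.role = role
        self.provenance = provenance or {}


def _standardize_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale = np.where(scale > 0, scale, 1.0)  # zero-variance columns drop out
    return mean, scale


def _soft_threshold(v: np.ndarray, lam: float) -> np.ndarray:
    return np.sign(v) * np.maximum(np.abs(v) - lam, 0.0)


# ---------------------------------------------------------------------------
# Sparse CCA
# ---------------------------------------------------------------------------

@dataclass
class SparseCCA:
    """Sparse canonical correlation analysis with L1-penalized directions.

    Parameters
    ----------
    lam1, lam2 : float
        Soft-threshold penalties on the (unit-norm) X- and Y-side
        directions; 0 recovers classical CCA.
    n_components : int
        Number of canonical pairs, found by deflation.
    ridge : float
        Tikhonov stabilizer added to the within-block covariances.
    """

    lam1: float = 0.0
    lam2: float = 0.0
    n_components: int = 2
    max_iter: int = 500
    tol: float = 1e-6
    ridge: float = 1e-8

    def __post_init__(self) -> None:
        if self.lam1 < 0 or self.lam2 < 0:
            raise ConfigurationError("penalties must be non-negative")
        if self.n_components < 1:
            raise ConfigurationError("n_components must be >= 1")
        self.a_: np.ndarray | None = None
        self.b_: np.ndarray | None = None
        self.rho_: np.ndarray | None = None
        self.objective_history_: list[np.ndarray] = []
        self._x_names: list[str] = []
        self._y_names: list[str] = []

    # -- fitting -----------------------------------------------------------
    def fit(self, X: FeatureTable, Y: FeatureTable) -> "SparseCCA":
        X.align_check(Y)
        self._x_names = X.feature_names
        self._y_names = Y.feature_names
        Xv, Yv = X.values, Y.values
        self._x_mean, self._x_scale = _standardize_fit(Xv)
        self._y_mean, self._y_scale = _standardize_fit(Yv)
        Xs = (Xv - self._x_mean) / self._x_scale
        Ys = (Yv - self._y_mean) / self._y_scale

        n, p = Xs.shape
        q = Ys.shape[1]
        k_max = min(self.n_components, p, q)
        A = np.zeros((p, k_max))
        B = np.zeros((q, k_max))
        rho = np.zeros(k_max)
        self.objective_history_ = []

        Xd, Yd = Xs.copy(), Ys.copy()
        for k in range(k_max):
            a, b, r, history = self._fit_one(Xd, Yd)
            A[:, k], B[:, k], rho[k] = a, b, r
            self.objective_history_.append(np.asarray(history))
            # deflate the fitted canonical variates out of both blocks
            u = Xd @ a
            v = Yd @ b
            for Z, w in ((Xd, u), (Yd, v)):
                denom = float(w @ w)
                if denom > 0:
                    Z -= np.outer(w, (w @ Z) / denom)

        self.a_, self.b_, self.rho_ = A, B, rho
        return self

    def _fit_one(self, Xs, Ys):
        n, p = Xs.shape
        Sxx = Xs.T @ Xs / n + self.ridge * np.eye(p)
        Syy = Ys.T @ Ys / n + self.ridge * np.eye(Ys.shape[1])
        Sxy = Xs.T @ Ys / n

        # deterministic init: leading singular directions of the
        # cross-covariance
        U, _, Vt = np.linalg.svd(Sxy, full_matrices=False)
        a = U[:, 0]
        b = Vt[0]

        def _corr(a, b):
            u, v = Xs @ a, Ys @ b
            su, sv = np.sqrt(u @ u), np.sqrt(v @ v)
            return float(u @ v / (su * sv)) if su > 0 and sv > 0 else 0.0

        history = [abs(_corr(a, b))]
        for _ in range(self.max_iter):
            a_old, b_old = a, b
            a = self._update(Sxx, Sxy @ b, self.lam1, "lambda1")
            b = self._update(Syy, Sxy.T @ a, self.lam2, "lambda2")
            history.append(abs(_corr(a, b)))
            if (np.linalg.norm(a - a_old) < self.tol
                    and np.linalg.norm(b - b_old) < self.tol):
                break

        # sign convention: largest-|.| coefficient of a is positive
        if a[np.argmax(np.abs(a))] < 0:
            a, b = -a, -b
        rho = _corr(a, b)
        # report unit-l2 directions; rho is normalization-invariant
        return a / np.linalg.norm(a), b / np.linalg.norm(b), rho, history

    def _update(self, S, target, lam, name):
        w = np.linalg.solve(S, target)
        norm = np.linalg.norm(w)
        if norm == 0:
            raise DegenerateSolutionError(f"direction collapsed ({name}={lam})")
        w = _soft_threshold(w / norm, lam)
        norm = np.linalg.norm(w)
        if norm == 0:
            raise DegenerateSolutionError(
                f"{name}={lam} zeroes every coefficient; lower the penalty")
        return w / norm

    # -- application -------------------------------------------------------
    def transform(self, X: FeatureTable, Y: FeatureTable) -> FusedFeatureTable:
        """Per-subject CFLC: (X·a_k, Y·b_k) concatenated over components."""
        if self.a_ is None:
            raise RuntimeError("SparseCCA is not fitted")
        if X.feature_names != self._x_names or Y.feature_names != self._y_names:
            raise SchemaError("transform columns differ from the fitted blocks")
        X.align_check(Y)
        Xs = (X.values - self._x_mean) / self._x_scale
        Ys = (Y.values - self._y_mean) / self._y_scale
        cols, names = [], []
        for k in range(self.a_.shape[1]):
            cols += [Xs @ self.a_[:, k], Ys @ self.b_[:, k]]
            names += [f"cflc{k + 1}_x", f"cflc{k + 1}_y"]
        frame = pd.DataFrame(np.column_stack(cols), index=X.subject_ids,
                             columns=names)
        return FusedFeatureTable(frame, X.labels, role="CFLC",
                                 provenance={"lam1": self.lam1,
                                             "lam2": self.lam2,
                                             "n_components": self.a_.shape[1]})

    def fit_transform(self, X: FeatureTable, Y: FeatureTable) -> FusedFeatureTable:
        return self.fit(X, Y).transform(X, Y)

    def nonzero_counts(self) -> tuple[int, int]:
        return (int(np.sum(np.abs(self.a_[:, 0]) > 1e-12)),
                int(np.sum(np.abs(self.b_[:, 0]) > 1e-12)))


def select_scca_penalties(X: FeatureTable, Y: FeatureTable,
                          grid: tuple[float, ...] = (0.0, 0.05, 0.1, 0.2, 0.3),
                          n_folds: int = 5, seed: int = 0
                          ) -> tuple[float, float]:
    """Pick (λ1, λ2) = (λ, λ) by k-fold CV, maximizing the first-component
    validation correlation."""
    rng = np.random.default_rng(seed)
    n = X.n_subjects
    order = rng.permutation(n)
    folds = np.array_split(order, n_folds)
    best, best_lam = -np.inf, grid[0]
    for lam in grid:
        corrs = []
        for f in folds:
            train = np.setdiff1d(order, f)
            try:
                model = SparseCCA(lam1=lam, lam2=lam, n_components=1)
                model.fit(X.subset_rows(train), Y.subset_rows(train))
                z = model.transform(X.subset_rows(f), Y.subset_rows(f))
                u, v = z.values[:, 0], z.values[:, 1]
                if u.std() > 0 and v.std() > 0:
                    corrs.append(abs(np.corrcoef(u, v)[0, 1]))
            except DegenerateSolutionError:
                corrs.append(-np.inf)
        score = float(np.mean(corrs)) if corrs else -np.inf
        if score > best:
            best, best_lam = score, lam
    return best_lam, best_lam


# ---------------------------------------------------------------------------
# Low-rank multimodal fusion
# ---------------------------------------------------------------------------

def _augment(X: np.ndarray) -> np.ndarray:
    """Bias-augmented modality input Z = [x; 1]."""
    return np.hstack([X, np.ones((X.shape[0], 1))])


def outer_product_features(Zc: np.ndarray, Zl: np.ndarray) -> np.ndarray:
    """Explicit tensor-fusion features: flattened z_c ⊗ z_l per subject."""
    return np.einsum("np,nq->npq", Zc, Zl).reshape(Zc.shape[0], -1)


@dataclass
class LowRankFusion:
    """LMF model: rank-r factor stacks per modality, trained on a logistic
    proxy loss and then frozen as a feature map.

    ``W_c``/``W_l`` have shape (rank, h_dim, block_dim + 1): slice ``i`` is
    the factor matrix applied to the bias-augmented modality input.
    """

    rank: int = 4
    h_dim: int = 8
    learning_rate: float = 0.01
    n_steps: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rank < 1 or self.h_dim < 1:
            raise ConfigurationError("rank and h_dim must be >= 1")
        self.W_c_: np.ndarray | None = None
        self.W_l_: np.ndarray | None = None
        self.readout_: np.ndarray | None = None
        self.intercept_: float = 0.0
        self.loss_history_: np.ndarray | None = None
        self.fitted_: bool = False

    # -- core forward/backward (static so tests can probe them) ------------
    @staticmethod
    def forward_h(W_c: np.ndarray, W_l: np.ndarray, Zc: np.ndarray,
                  Zl: np.ndarray) -> np.ndarray:
        A = np.einsum("rhp,np->nrh", W_c, Zc)
        B = np.einsum("rhq,nq->nrh", W_l, Zl)
        return np.sum(A * B, axis=1)

    @staticmethod
    def loss_and_grads(W_c, W_l, v, c, Zc, Zl, y):
        """Mean logistic loss and exact gradients for every parameter.

        Overflow is tolerated: a diverging parameter scale surfaces as a
        non-finite loss, which :meth:`fit` converts into a clear error.
        """
        A = np.einsum("rhp,np->nrh", W_c, Zc)
        B = np.einsum("rhq,nq->nrh", W_l, Zl)
        H = np.sum(A * B, axis=1)
        logits = H @ v + c
        # numerically stable BCE
        loss = float(np.mean(np.maximum(logits, 0) - logits * y
                             + np.log1p(np.exp(-np.abs(logits)))))
        g = (1.0 / (1.0 + np.exp(-logits)) - y) / y.size
        Gh = g[:, None] * v[None, :]
        dWc = np.einsum("nrh,np->rhp", Gh[:, None, :] * B, Zc)
        dWl = np.einsum("nrh,nq->rhq", Gh[:, None, :] * A, Zl)
        dv = H.T @ g
        dc = float(g.sum())
        return loss, dWc, dWl, dv, dc

    # -- fitting -----------------------------------------------------------
    def fit(self, cflc: FeatureTable, lmlc: FeatureTable,
            labels=None) -> "LowRankFusion":
        cflc.align_check(lmlc)
        y = np.asarray(cflc.labels if labels is None else labels, float)
        self._c_names = cflc.feature_names
        self._l_names = lmlc.feature_names
        self._c_mean, self._c_scale = _standardize_fit(cflc.values)
        self._l_mean, self._l_scale = _standardize_fit(lmlc.values)
        Zc = _augment((cflc.values - self._c_mean) / self._c_scale)
        Zl = _augment((lmlc.values - self._l_mean) / self._l_scale)

        rng = np.random.default_rng(self.seed)
        scale = 1.0 / np.sqrt(self.rank)
        W_c = rng.normal(0, scale, (self.rank, self.h_dim, Zc.shape[1]))
        W_l = rng.normal(0, scale, (self.rank, self.h_dim, Zl.shape[1]))
        v = rng.normal(0, 0.1, self.h_dim)
        c = 0.0

        history = np.empty(self.n_steps)
        lr = self.learning_rate
        for step in range(self.n_steps):
            with np.errstate(over="ignore", invalid="ignore"):
                loss, dWc, dWl, dv, dc = self.loss_and_grads(W_c, W_l, v, c,
                                                             Zc, Zl, y)
            if not np.isfinite(loss):
                raise DivergenceError(
                    "LMF training diverged; lower the learning rate")
            history[step] = loss
            W_c -= lr * dWc
            W_l -= lr * dWl
            v -= lr * dv
            c -= lr * dc

        self.W_c_, self.W_l_ = W_c, W_l
        self.readout_, self.intercept_ = v, c
        self.loss_history_ = history
        self.fitted_ = True
        return self

    @classmethod
    def from_tensor(cls, W: np.ndarray) -> "LowRankFusion":
        """Exact factorization of an explicit weight tensor W of shape
        (h_dim, p, q): per output dimension, an SVD supplies rank-r factors
        reproducing ``h_k = z_cᵀ W_k z_l`` to float precision."""
        h_dim, p, q = W.shape
        rank = min(p, q)
        model = cls(rank=rank, h_dim=h_dim)
        W_c = np.zeros((rank, h_dim, p))
        W_l = np.zeros((rank, h_dim, q))
        for k in range(h_dim):
            U, s, Vt = np.linalg.svd(W[k], full_matrices=False)
            for i in range(rank):
                W_c[i, k] = np.sqrt(s[i]) * U[:, i]
                W_l[i, k] = np.sqrt(s[i]) * Vt[i]
        model.W_c_, model.W_l_ = W_c, W_l
        model.readout_ = np.zeros(h_dim)
        model.fitted_ = True
        model._c_mean = model._l_mean = None  # raw-input mode
        return model

    # -- application -------------------------------------------------------
    def _prepare(self, cflc: FeatureTable, lmlc: FeatureTable):
        if getattr(self, "_c_mean", None) is None:
            return _augment(cflc.values), _augment(lmlc.values)
        if (cflc.feature_names != self._c_names
                or lmlc.feature_names != self._l_names):
            raise SchemaError("transform columns differ from the fitted blocks")
        Zc = _augment((cflc.values - self._c_mean) / self._c_scale)
        Zl = _augment((lmlc.values - self._l_mean) / self._l_scale)
        return Zc, Zl

    def transform(self, cflc: FeatureTable, lmlc: FeatureTable
                  ) -> FusedFeatureTable:
        if not self.fitted_:
            raise RuntimeError("LowRankFusion is not fitted")
        cflc.align_check(lmlc)
        Zc, Zl = self._prepare(cflc, lmlc)
        H = self.forward_h(self.W_c_, self.W_l_, Zc, Zl)
        frame = pd.DataFrame(H, index=cflc.subject_ids,
                             columns=[f"h{i + 1}" for i in range(self.h_dim)])
        return FusedFeatureTable(frame, cflc.labels, role="h",
                                 provenance={"rank": self.rank,
                                             "h_dim": self.h_dim})

    def fit_transform(self, cflc: FeatureTable, lmlc: FeatureTable,
                      labels=None) -> FusedFeatureTable:
        return self.fit(cflc, lmlc, labels).transform(cflc, lmlc)


# ---------------------------------------------------------------------------
# Early fusion
# ---------------------------------------------------------------------------

def concat_fuse(tables: list[FeatureTable]) -> FusedFeatureTable:
    """Column-wise concatenation of aligned tables (early fusion)."""
    if not tables:
        raise AlignmentError("no tables to concatenate")
    first = tables[0]
    for t in tables[1:]:
        first.align_check(t)
    frame = pd.concat([t.frame for t in tables], axis=1)
    if frame.columns.duplicated().any():
        raise SchemaError("duplicate feature names across concatenated tables")
    return FusedFeatureTable(frame, first.labels, role="concat",
                             provenance={"widths": [t.frame.shape[1]
                                                    for t in tables]})
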