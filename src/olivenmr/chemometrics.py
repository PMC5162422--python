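"""Latent-variable models and validation.

PCA by singular-value decomposition, multi-class PLS-DA by NIPALS with
per-component deflation, binary OPLS-DA with sequential orthogonal filtering,
Q2 by k-fold cross-validation (default 7-fold, seeded shuffle then contiguous
blocks), a response permutation test, and S-line covariance/correlation
loadings for the orthogonally filtered models.

Conventions: standard deviation uses denominator n-1; each PCA loading
vector is oriented so its largest-magnitude entry is positive; NIPALS runs
at tolerance 1e-10 for at most 500 iterations with a deterministic start
(response column of maximal variance).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "PCAModel",
    "DummyResponse",
    "PLSDAModel",
    "OPLSDAModel",
    "PermutationResult",
    "SLine",
    "fit_pca",
    "select_ncomp_by_cumvar",
    "select_ncomp_by_q2",
    "encode_classes",
    "fit_plsda",
    "fit_oplsda",
    "q2_crossval",
    "permutation_test",
    "sline",
]

_NIPALS_TOL = 1e-10
_NIPALS_MAX_ITER = 500


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PCAModel:
    """PCA of a (column-centered) data matrix.

    scores = centered X projected on ``loadings``; explained variance
    fractions are singular-value energies relative to the total.
    """

    column_means: np.ndarray
    loadings: np.ndarray  # buckets x k
    scores: np.ndarray  # samples x k
    explained_variance_fraction: np.ndarray
    cumulative_R2X: np.ndarray
    singular_values: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.column_means) @ self.loadings


def fit_pca(X: np.ndarray, k: int) -> PCAModel:
    """Fit a k-component PCA via SVD of the centered matrix."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if not 1 <= k <= min(n - 1, p):
        raise ValueError(f"fit_pca: k must be in [1, {min(n - 1, p)}]")
    means = X.mean(axis=0)
    Xc = X - means
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size and s[0] > 0 else 0
    if k > rank:
        raise ValueError(f"fit_pca: k={k} exceeds the matrix rank {rank}")
    total = float(np.sum(s**2))
    explained = s**2 / total
    loadings = vt[:k].T.copy()
    # sign convention: largest-magnitude entry of each loading positive
    for j in range(k):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] = -loadings[:, j]
    scores = Xc @ loadings
    return PCAModel(
        column_means=means,
        loadings=loadings,
        scores=scores,
        explained_variance_fraction=explained[:k],
        cumulative_R2X=np.cumsum(explained[:k]),
        singular_values=s[:k],
    )


def select_ncomp_by_cumvar(model: PCAModel, threshold: float) -> int:
    """Smallest k whose cumulative explained variance reaches ``threshold``."""
    if not 0 < threshold <= 1:
        raise ValueError("select_ncomp_by_cumvar: threshold must be in (0, 1]")
    hit = np.flatnonzero(model.cumulative_R2X >= threshold - 1e-12)
    return int(hit[0]) + 1 if hit.size else model.n_components


# ---------------------------------------------------------------------------
# class encoding


@dataclass
class DummyResponse:
    """Class membership as a 0/1 indicator matrix (columns = sorted class
    names); two-class problems also expose a single 0/1 column."""

    class_labels: list[str]
    classes: list[str]
    indicator: np.ndarray
    binary_column: np.ndarray | None

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def response_matrix(self) -> np.ndarray:
        """Matrix handed to the regression: single column for 2 classes."""
        if self.binary_column is not None:
            return self.binary_column[:, None]
        return self.indicator


def encode_classes(labels: Sequence[str], min_class_size: int = 1) -> DummyResponse:
    """Encode per-sample class names as a dummy (indicator) response.

    ``min_class_size=2`` rejects singleton classes, which cannot survive
    cross-validation; the default accepts any non-empty class.
    """
    labels = [str(x) for x in labels]
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("encode_classes: at least 2 classes required")
    counts = {c: labels.count(c) for c in classes}
    small = [c for c, n in counts.items() if n < min_class_size]
    if small:
        raise ValueError(f"encode_classes: singleton/undersized class(es) {small}")
    index = {c: j for j, c in enumerate(classes)}
    indicator = np.zeros((len(labels), len(classes)))
    for i, lab in enumerate(labels):
        indicator[i, index[lab]] = 1.0
    binary = indicator[:, 0].copy() if len(classes) == 2 else None
    return DummyResponse(
        class_labels=labels, classes=classes, indicator=indicator, binary_column=binary
    )


def _as_response(Y) -> np.ndarray:
    if isinstance(Y, DummyResponse):
        return Y.response_matrix()
    Y = np.asarray(Y, dtype=float)
    return Y[:, None] if Y.ndim == 1 else Y


# ---------------------------------------------------------------------------
# PLS-DA (NIPALS)


@dataclass
class PLSDAModel:
    """NIPALS PLS-DA decomposition with cumulative fit statistics."""

    x_mean: np.ndarray
    y_mean: np.ndarray
    x_weights: np.ndarray  # p x k, unit norm
    x_loadings: np.ndarray  # p x k
    x_scores: np.ndarray  # n x k
    y_loadings: np.ndarray  # c x k
    r2x_per_component: np.ndarray
    R2X: float
    R2Y: float
    r2y_cumulative: np.ndarray

    @property
    def n_components(self) -> int:
        return self.x_weights.shape[1]

    def coefficients(self) -> np.ndarray:
        W, P, Q = self.x_weights, self.x_loadings, self.y_loadings
        return W @ np.linalg.solve(P.T @ W, Q.T)

    def predict(self, X: np.ndarray) -> np.ndarray:
        Xc = np.asarray(X, dtype=float) - self.x_mean
        return Xc @ self.coefficients() + self.y_mean


def fit_plsda(
    X: np.ndarray,
    Y,
    n_components: int,
    tol: float = _NIPALS_TOL,
    max_iter: int = _NIPALS_MAX_ITER,
) -> PLSDAModel:
    """Fit PLS-DA by NIPALS with X (and Y) deflation per component.

    X and the response are centered internally. Components maximize the
    covariance between X scores and the class-indicator response.
    """
    X = np.asarray(X, dtype=float)
    Y = _as_response(Y)
    n, p = X.shape
    if Y.shape[0] != n:
        raise ValueError("fit_plsda: X and Y row counts differ")
    x_mean, y_mean = X.mean(axis=0), Y.mean(axis=0)
    E, F = X - x_mean, Y - y_mean
    ssx, ssy = float(np.sum(E**2)), float(np.sum(F**2))
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    Q = np.zeros((Y.shape[1], n_components))
    r2x = np.zeros(n_components)
    r2y_cum = np.zeros(n_components)
    for a in range(n_components):
        u = F[:, int(np.argmax(F.var(axis=0)))].copy()
        if np.allclose(u, 0):
            raise ValueError(f"fit_plsda: response fully deflated at component {a + 1}")
        for _ in range(max_iter):
            w = E.T @ u
            norm = np.linalg.norm(w)
            if norm == 0:
                raise ValueError(f"fit_plsda: degenerate weight at component {a + 1}")
            w /= norm
            t = E @ w
            q = F.T @ t / (t @ t)
            u_new = F @ q / (q @ q)
            if np.linalg.norm(u_new - u) <= tol * max(np.linalg.norm(u_new), 1e-300):
                u = u_new
                break
            u = u_new
        else:
            raise RuntimeError(
                f"fit_plsda: NIPALS did not converge in {max_iter} iterations"
            )
        t = E @ w
        pvec = E.T @ t / (t @ t)
        q = F.T @ t / (t @ t)
        E = E - np.outer(t, pvec)
        F = F - np.outer(t, q)
        W[:, a], P[:, a], T[:, a], Q[:, a] = w, pvec, t, q
        r2x[a] = (t @ t) * (pvec @ pvec) / ssx
        r2y_cum[a] = 1.0 - float(np.sum(F**2)) / ssy
    return PLSDAModel(
        x_mean=x_mean,
        y_mean=y_mean,
        x_weights=W,
        x_loadings=P,
        x_scores=T,
        y_loadings=Q,
        r2x_per_component=r2x,
        R2X=float(np.sum(r2x)),
        R2Y=float(r2y_cum[-1]),
        r2y_cumulative=r2y_cum,
    )


# ---------------------------------------------------------------------------
# OPLS-DA (binary)


@dataclass
class OPLSDAModel:
    """One predictive component plus sequential orthogonal components.

    Orthogonal components carry structured variation uncorrelated with the
    (binary) response; the predictive component is fitted on the filtered
    matrix. Variance fractions are relative to the centered training matrix.
    """

    x_mean: np.ndarray
    y_mean: float
    predictive_weights: np.ndarray  # p
    predictive_loadings: np.ndarray  # p
    predictive_scores: np.ndarray  # n
    y_loading: float
    ortho_weights: np.ndarray  # p x n_ortho
    ortho_loadings: np.ndarray  # p x n_ortho
    ortho_scores: np.ndarray  # n x n_ortho
    predictive_variance_fraction: float
    ortho_variance_fractions: np.ndarray
    R2X: float
    R2Y: float

    @property
    def n_ortho(self) -> int:
        return self.ortho_weights.shape[1]

    def _filter(self, Xc: np.ndarray) -> np.ndarray:
        for i in range(self.n_ortho):
            t_o = Xc @ self.ortho_weights[:, i]
            Xc = Xc - np.outer(t_o, self.ortho_loadings[:, i])
        return Xc

    def predict(self, X: np.ndarray) -> np.ndarray:
        Xc = self._filter(np.asarray(X, dtype=float) - self.x_mean)
        t = Xc @ self.predictive_weights
        return t * self.y_loading + self.y_mean


def fit_oplsda(X: np.ndarray, y, n_ortho: int) -> OPLSDAModel:
    """Fit a binary OPLS-DA with ``n_ortho`` orthogonal components.

    Each round removes the part of the X loading orthogonal to the current
    predictive weight; the predictive component is then a single PLS
    component on the filtered matrix. With ``n_ortho = 0`` this reduces
    exactly to one-component PLS-DA.
    """
    X = np.asarray(X, dtype=float)
    if isinstance(y, DummyResponse):
        if y.binary_column is None:
            raise ValueError("fit_oplsda: response must be binary")
        y = y.binary_column
    y = np.asarray(y, dtype=float).ravel()
    if n_ortho < 0:
        raise ValueError("fit_oplsda: n_ortho must be nonnegative")
    if len(set(np.round(y, 12))) != 2:
        raise ValueError("fit_oplsda: response must take exactly two values")
    n, p = X.shape
    x_mean, y_mean = X.mean(axis=0), float(y.mean())
    E, yc = X - x_mean, y - y_mean
    ssx, ssy = float(np.sum(E**2)), float(yc @ yc)
    Wo = np.zeros((p, n_ortho))
    Po = np.zeros((p, n_ortho))
    To = np.zeros((n, n_ortho))
    ortho_frac = np.zeros(n_ortho)
    for i in range(n_ortho):
        w = E.T @ yc
        norm = np.linalg.norm(w)
        if norm == 0:
            raise ValueError("fit_oplsda: response uncorrelated with the data")
        w /= norm
        t = E @ w
        pvec = E.T @ t / (t @ t)
        w_o = pvec - (w @ pvec) * w
        norm_o = np.linalg.norm(w_o)
        if norm_o <= 1e-12 * np.linalg.norm(pvec):
            raise ValueError(
                f"fit_oplsda: n_ortho={n_ortho} too large; no orthogonal "
                f"variation left after {i} component(s)"
            )
        w_o /= norm_o
        t_o = E @ w_o
        p_o = E.T @ t_o / (t_o @ t_o)
        E = E - np.outer(t_o, p_o)
        Wo[:, i], Po[:, i], To[:, i] = w_o, p_o, t_o
        ortho_frac[i] = (t_o @ t_o) * (p_o @ p_o) / ssx
    w = E.T @ yc
    norm = np.linalg.norm(w)
    if norm == 0:
        raise ValueError("fit_oplsda: response uncorrelated with the data")
    w /= norm
    t = E @ w
    pvec = E.T @ t / (t @ t)
    q = float(yc @ t / (t @ t))
    resid = yc - t * q
    pred_frac = (t @ t) * (pvec @ pvec) / ssx
    return OPLSDAModel(
        x_mean=x_mean,
        y_mean=y_mean,
        predictive_weights=w,
        predictive_loadings=pvec,
        predictive_scores=t,
        y_loading=q,
        ortho_weights=Wo,
        ortho_loadings=Po,
        ortho_scores=To,
        predictive_variance_fraction=float(pred_frac),
        ortho_variance_fractions=ortho_frac,
        R2X=float(pred_frac + ortho_frac.sum()),
        R2Y=1.0 - float(resid @ resid) / ssy,
    )


# ---------------------------------------------------------------------------
# cross-validation and permutation testing


def _fold_indices(n: int, folds: int, seed: int) -> list[np.ndarray]:
    """Seeded shuffle, then contiguous blocks."""
    order = np.random.default_rng(seed).permutation(n)
    return [blk for blk in np.array_split(order, folds) if blk.size]


def _check_classes_survive(Y: np.ndarray, train: np.ndarray) -> None:
    # only meaningful for 0/1 class-indicator responses
    if not np.isin(np.round(Y, 12), (0.0, 1.0)).all():
        return
    Yt = Y[train]
    if Y.shape[1] == 1:
        if np.unique(Yt).size < np.unique(Y).size:
            raise ValueError("q2_crossval: a fold emptied one of the classes")
    elif np.any(Yt.sum(axis=0) < 1):
        raise ValueError("q2_crossval: a fold emptied one of the classes")


def q2_crossval(
    X: np.ndarray,
    Y,
    *,
    n_components: int = 1,
    n_ortho: int | None = None,
    folds: int = 7,
    seed: int = 0,
    rescale: str | None = None,
) -> float:
    """Cross-validated predictive ability Q2 = 1 - PRESS/TSS.

    Folds are contiguous blocks of a seeded shuffle. A PLS-DA with
    ``n_components`` is refitted per fold, or an OPLS-DA with ``n_ortho``
    orthogonal components when ``n_ortho`` is given. TSS is the total sum of
    squares of the response about its global mean. With ``rescale="pareto"``
    the per-bucket Pareto parameters are re-estimated inside each training
    fold and applied to the held-out block (no leakage).
    """
    X = np.asarray(X, dtype=float)
    Y = _as_response(Y)
    n = X.shape[0]
    if folds < 2:
        raise ValueError("q2_crossval: folds must be at least 2")
    folds = min(folds, n)
    tss = float(np.sum((Y - Y.mean(axis=0)) ** 2))
    press = 0.0
    for test in _fold_indices(n, folds, seed):
        train = np.setdiff1d(np.arange(n), test)
        if train.size < 2:
            raise ValueError("q2_crossval: training fold too small")
        _check_classes_survive(Y, train)
        Xtr, Xte = X[train], X[test]
        if rescale == "pareto":
            mean = Xtr.mean(axis=0)
            sd = Xtr.std(axis=0, ddof=1)
            div = np.where(sd > 0, np.sqrt(sd), 1.0)
            Xtr = (Xtr - mean) / div
            Xte = (Xte - mean) / div
        elif rescale is not None:
            raise ValueError(f"q2_crossval: unknown rescale option {rescale!r}")
        if n_ortho is None:
            model = fit_plsda(Xtr, Y[train], n_components)
        else:
            model = fit_oplsda(Xtr, Y[train].ravel(), n_ortho)
        pred = model.predict(Xte)
        press += float(np.sum((Y[test] - np.atleast_2d(pred).reshape(Y[test].shape)) ** 2))
    return 1.0 - press / tss


def select_ncomp_by_q2(
    X: np.ndarray,
    Y,
    max_components: int,
    *,
    folds: int = 7,
    seed: int = 0,
) -> int:
    """Smallest adequate PLS-DA order: stop when adding a component lowers Q2."""
    best_k, best_q2 = 1, -np.inf
    for k in range(1, max_components + 1):
        q2 = q2_crossval(X, Y, n_components=k, folds=folds, seed=seed)
        if q2 <= best_q2:
            break
        best_k, best_q2 = k, q2
    return best_k


@dataclass
class PermutationResult:
    """Response-permutation null distribution of Q2."""

    observed_Q2: float
    permuted_Q2: np.ndarray
    empirical_p: float


def permutation_test(
    X: np.ndarray,
    Y,
    n_perm: int = 400,
    seed: int = 0,
    *,
    n_components: int = 1,
    n_ortho: int | None = None,
    folds: int = 7,
) -> PermutationResult:
    """Permute the response rows and recompute Q2 each time.

    empirical_p = (1 + #{permuted >= observed}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("permutation_test: n_perm must be at least 1")
    Y = _as_response(Y)
    observed = q2_crossval(
        X, Y, n_components=n_components, n_ortho=n_ortho, folds=folds, seed=seed
    )
    rng = np.random.default_rng(seed)
    permuted = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(Y.shape[0])
        permuted[i] = q2_crossval(
            X, Y[perm], n_components=n_components, n_ortho=n_ortho, folds=folds, seed=seed
        )
    p = (1 + int(np.sum(permuted >= observed))) / (n_perm + 1)
    return PermutationResult(observed_Q2=observed, permuted_Q2=permuted, empirical_p=p)


# ---------------------------------------------------------------------------
# S-line


@dataclass
class SLine:
    """Per-bucket covariance and correlation with the predictive score."""

    covariance: np.ndarray
    correlation: np.ndarray  # NaN where the bucket has zero variance


def sline(model: OPLSDAModel, X: np.ndarray) -> SLine:
    """S-line loadings of a fitted OPLS-DA on its training matrix."""
    X = np.asarray(X, dtype=float)
    t = model.predictive_scores
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    tc = t - t.mean()
    cov = Xc.T @ tc / (n - 1)
    sx = Xc.std(axis=0, ddof=1)
    st = tc.std(ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.where(sx > 0, cov / (sx * st), np.nan)
    return SLine(covariance=cov, correlation=corr)
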