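"""Penalized discriminant analysis (PDA) for flattened morphometric maps.

Maps are vectorized into an n x 6120 design (raster order: section, then
degree), a "p >> n" problem with strong spatial autocorrelation.  PDA is
realized as penalized optimal scoring: class indicators are regressed on
the centered design with a quadratic roughness penalty

    Omega = L^T L,   L = graph Laplacian of the 17 x 360 cylinder grid
                        (periodic in the degree dimension only),

and discriminant directions are read off the optimal-scoring eigenproblem.
Model complexity is summarized by the effective degrees of freedom
df(lambda) = trace of the penalized smoother, which decreases
monotonically in lambda.  The regularization weight is selected by
repeated stratified k-fold cross-validation: among all lambdas whose mean
CV error does not exceed the minimum upper 95% prediction bound, the one
with the lowest df is chosen.

All n x n computations go through the Gram matrix G = Xc A^-1 Xc^T with
A = lambda*Omega + eps*I, so cross-validation refits cost O(n^3) rather
than O(p^3).  For the standard cylinder-grid penalty, A^-1 is applied
spectrally (DCT along sections, FFT along degrees); arbitrary sparse
penalties fall back to a sparse LU factorization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from scipy import fft as sfft
from scipy import stats
from scipy.linalg import eigh, solve
from scipy.sparse.linalg import splu

GRID_SHAPE = (17, 360)


# --------------------------------------------------------------------------
# penalty


class CylinderPenalty:
    """Roughness penalty Omega = L^T L on a sections x degrees cylinder grid.

    L is the combinatorial graph Laplacian with 4-neighbour connectivity,
    periodic in the degree dimension and free at the proximal/distal ends.
    The constant map spans its null space.  Supports fast application of
    (lambda*Omega + eps*I)^-1 through the DCT-II / FFT eigenbasis.
    """

    def __init__(self, shape: tuple[int, int] = GRID_SHAPE):
        self.shape = tuple(shape)
        m, n = self.shape
        # eigenvalues of the path Laplacian (DCT-II basis) and cycle Laplacian (DFT basis)
        self._ev_path = 2.0 - 2.0 * np.cos(np.pi * np.arange(m) / m)
        self._ev_cycle = 2.0 - 2.0 * np.cos(2.0 * np.pi * np.arange(n // 2 + 1) / n)
        self._ev_lap = self._ev_path[:, None] + self._ev_cycle[None, :]

    @property
    def n_features(self) -> int:
        return self.shape[0] * self.shape[1]

    def matrix(self) -> sp.csr_matrix:
        """Explicit sparse Omega (for oracles and small problems)."""
        m, n = self.shape
        path = sp.diags([np.r_[1.0, [2.0] * (m - 2), 1.0] if m > 1 else [0.0]], [0]) - sp.diags(
            [np.ones(m - 1), np.ones(m - 1)], [-1, 1]
        )
        cyc = sp.diags([2.0 * np.ones(n)], [0]) - sp.diags(
            [np.ones(n - 1), np.ones(n - 1)], [-1, 1]
        )
        cyc = cyc.tolil()
        cyc[0, n - 1] -= 1.0
        cyc[n - 1, 0] -= 1.0
        lap = sp.kron(sp.identity(m), cyc.tocsr()) + sp.kron(path, sp.identity(n))
        return (lap.T @ lap).tocsr()

    def solve(self, lam: float, eps: float, rhs: np.ndarray) -> np.ndarray:
        """Apply (lam*Omega + eps*I)^-1 to rows of ``rhs`` (n, p)."""
        m, n = self.shape
        r = rhs.reshape(-1, m, n)
        t = sfft.dct(r, type=2, axis=1, norm="ortho")
        f = np.fft.rfft(t, axis=2, norm="ortho")
        denom = lam * self._ev_lap**2 + eps
        f = f / denom[None, :, :]
        t = np.fft.irfft(f, n=n, axis=2, norm="ortho")
        out = sfft.idct(t, type=2, axis=1, norm="ortho")
        return out.reshape(rhs.shape)


def penalty_matrix(n_sections: int = 17, n_degrees: int = 360) -> sp.csr_matrix:
    """Sparse roughness penalty Omega = L^T L for the cylinder grid."""
    return CylinderPenalty((n_sections, n_degrees)).matrix()


def flatten_maps(maps: Sequence[np.ndarray]) -> np.ndarray:
    """Stack (sections x degrees) maps into an n x p design, raster order."""
    arrs = [np.asarray(m, dtype=float) for m in maps]
    shape = arrs[0].shape
    if any(a.shape != shape for a in arrs):
        raise ValueError("all maps must share one shape")
    return np.stack([a.ravel() for a in arrs])


# --------------------------------------------------------------------------
# gram machinery


def _default_eps(x: np.ndarray) -> float:
    return 1e-8 * float(np.sum(x * x)) / x.shape[1]


class _PenalizedGram:
    """G = X A^-1 X^T and W = A^-1 X^T for A = lam*Omega + eps*I."""

    def __init__(self, x: np.ndarray, lam: float, penalty, eps: float):
        n, p = x.shape
        if lam < 0:
            raise ValueError("lambda must be >= 0")
        if lam == 0 and eps == 0:
            raise ValueError(
                "singular system: with p > n the unpenalized problem is "
                "ill-posed; use lambda > 0 (or a positive ridge eps)"
            )
        self.x = x
        self.lam, self.eps = lam, eps
        if isinstance(penalty, CylinderPenalty) and penalty.n_features == p:
            self.w = penalty.solve(lam, eps, x).T  # (p, n)
        else:
            if penalty is None:
                a = sp.identity(p, format="csc") * eps
                if lam > 0:
                    raise ValueError("penalty required when lambda > 0")
            else:
                omega = sp.csc_matrix(penalty)
                a = (lam * omega + eps * sp.identity(p)).tocsc()
            self.w = splu(a).solve(x.T)
        self.g = x @ self.w


def _centered_gram(g: np.ndarray, train_idx: np.ndarray) -> np.ndarray:
    """Gram of the design centered on the mean of the training rows."""
    n = g.shape[0]
    w = np.zeros(n)
    w[train_idx] = 1.0 / len(train_idx)
    gw = g @ w
    c = float(w @ gw)
    return g - gw[:, None] - gw[None, :] + c


def _indicator(codes: np.ndarray, k: int) -> np.ndarray:
    y = np.zeros((len(codes), k))
    y[np.arange(len(codes)), codes] = 1.0
    return y


def _os_eig(gtt: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Optimal-scoring eigenproblem on a (centered) training Gram block.

    The squared-error loss is averaged over the training rows (the
    effective penalty is m * lambda * Omega), so the fit is invariant to
    duplicating every observation.  Returns (C, theta, alphas, Z): ridge
    coefficients in the Gram parameterization, optimal scores per class,
    canonical eigenvalues, and training discriminant scores (unscaled).
    """
    m, k = y.shape
    c = solve(m * np.eye(m) + gtt, y, assume_a="pos")
    yhat = gtt @ c
    mm = y.T @ yhat
    counts = y.sum(axis=0)
    d = 1.0 / np.sqrt(counts)
    ms = (mm * d[:, None]) * d[None, :]
    ms = 0.5 * (ms + ms.T)
    evals, vecs = eigh(ms)
    order = np.argsort(evals)[::-1][: k - 1]
    alphas = np.clip(evals[order], 0.0, 1.0 - 1e-12)
    theta = vecs[:, order] * d[:, None]
    z = yhat @ theta
    return c, theta, alphas, z


def _scale_and_orient(
    z: np.ndarray, codes: np.ndarray, k: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unit pooled within-class sd per discriminant + deterministic sign.

    The sign is fixed so the last class's centroid does not sit below the
    first class's centroid on each discriminant (ties leave the sign).
    Returns (scale, signs, centroids) with centroids already scaled/signed.
    """
    m, q = z.shape
    cent = np.stack([z[codes == j].mean(axis=0) for j in range(k)])
    resid = z - cent[codes]
    denom = max(m - k, 1)
    s = np.sqrt((resid**2).sum(axis=0) / denom)
    fallback = z.std(axis=0, ddof=0)
    s = np.where(s > 1e-12 * np.maximum(fallback, 1.0), s, np.where(fallback > 0, fallback, 1.0))
    signs = np.where(cent[-1] - cent[0] >= 0, 1.0, -1.0)
    cent = cent * signs / s
    return s, signs, cent


@dataclass
class PDAModel:
    """A fitted penalized discriminant model."""

    classes_: list
    lam: float
    eps: float
    mean_: np.ndarray  # (p,) training column means
    coef_: np.ndarray  # (p, K-1) discriminant loadings
    centroids_: np.ndarray  # (K, K-1) training group centroids in discriminant space
    eigvals_: np.ndarray  # canonical eigenvalues per discriminant
    df_: float  # effective degrees of freedom of the penalized smoother
    grid_shape: tuple[int, int] = GRID_SHAPE
    training_errors_: int = 0
    n_train_: int = 0

    @property
    def n_discriminants(self) -> int:
        return self.coef_.shape[1]


def fit_pda(
    x: np.ndarray,
    labels: Sequence,
    lam: float,
    penalty=None,
    eps: float | None = None,
    grid_shape: tuple[int, int] = GRID_SHAPE,
) -> PDAModel:
    """Fit penalized optimal-scoring discriminant functions.

    ``penalty`` is a :class:`CylinderPenalty`, a sparse/dense p x p
    matrix, or None (defaults to the cylinder-grid penalty when p matches
    ``grid_shape``).  ``eps`` is a small ridge added for invertibility
    (default 1e-8 of the mean column energy).  Discriminants are ordered
    by decreasing canonical eigenvalue and scaled to unit pooled
    within-class standard deviation on the training scores.
    """
    x = np.asarray(x, dtype=float)
    n, p = x.shape
    labels = np.asarray(labels)
    classes = sorted(np.unique(labels).tolist())
    k = len(classes)
    if n < k:
        raise ValueError("need at least one observation per class")
    codes = np.array([classes.index(v) for v in labels])
    if penalty is None and p == grid_shape[0] * grid_shape[1]:
        penalty = CylinderPenalty(grid_shape)
    if eps is None:
        eps = _default_eps(x)
    gram = _PenalizedGram(x, lam, penalty, eps)
    all_idx = np.arange(n)
    gc = _centered_gram(gram.g, all_idx)
    y = _indicator(codes, k)
    c, theta, alphas, z = _os_eig(gc, y)
    s, signs, centroids = _scale_and_orient(z, codes, k)
    ct = c @ theta  # (n, K-1)
    wc = gram.w - (gram.w @ np.full(n, 1.0 / n))[:, None]
    coef = (wc @ ct) * (signs / s)[None, :]
    zs = z * (signs / s)[None, :]
    dists = ((zs[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    pred = dists.argmin(axis=1)
    gvals = np.clip(np.linalg.eigvalsh(gc), 0.0, None)
    df = float(np.sum(gvals / (n + gvals)))
    return PDAModel(
        classes_=classes,
        lam=float(lam),
        eps=float(eps),
        mean_=x.mean(axis=0),
        coef_=coef,
        centroids_=centroids,
        eigvals_=alphas,
        df_=df,
        grid_shape=tuple(grid_shape),
        training_errors_=int((pred != codes).sum()),
        n_train_=n,
    )


def effective_df(
    lam: float,
    penalty,
    x: np.ndarray,
    eps: float | None = None,
) -> float:
    """Effective degrees of freedom: trace of the penalized smoother.

    df = trace[ Xc (Xc^T Xc + n*(lam*Omega + eps*I))^-1 Xc^T ], computed
    from the eigenvalues of the centered Gram matrix (the penalty scales
    with n because the loss is per-sample averaged).  Continuous and
    monotone non-increasing in lambda; df(0+) <= min(n-1, p) and df(inf)
    tends to the dimension of Omega's null space.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if eps is None:
        eps = _default_eps(x)
    gram = _PenalizedGram(x, lam, penalty, eps)
    gc = _centered_gram(gram.g, np.arange(n))
    gvals = np.clip(np.linalg.eigvalsh(gc), 0.0, None)
    return float(np.sum(gvals / (n + gvals)))


def project(model: PDAModel, x: np.ndarray) -> np.ndarray:
    """Project observations onto the discriminant functions."""
    x = np.asarray(x, dtype=float)
    return (x - model.mean_) @ model.coef_


def classify(model: PDAModel, x: np.ndarray) -> np.ndarray:
    """Nearest-centroid classification in discriminant space.

    Distance ties break deterministically toward the first class in
    sorted class order.
    """
    scores = project(model, x)
    d = ((scores[:, None, :] - model.centroids_[None, :, :]) ** 2).sum(axis=2)
    return np.asarray(model.classes_, dtype=object)[d.argmin(axis=1)]


def misclassification_count(model: PDAModel, x: np.ndarray, labels: Sequence) -> int:
    pred = classify(model, x)
    return int(np.sum(pred != np.asarray(labels, dtype=object)))


@dataclass
class LoadingMap:
    values: np.ndarray  # (sections, degrees) signed loadings
    sign: np.ndarray  # +1 / -1 map
    boundary: np.ndarray  # zero-crossing boundary pixels (bool)


def loading_map(model: PDAModel, which: int = 1) -> LoadingMap:
    """Reshape a discriminant's coefficients to the map grid.

    A positive loading means a larger property value at that pixel
    increases the observation's score on that discriminant.  The boundary
    marks pixels whose sign differs from a 4-neighbour (wrapping in the
    degree dimension).
    """
    if not 1 <= which <= model.n_discriminants:
        raise ValueError(f"which must be in 1..{model.n_discriminants}")
    vals = model.coef_[:, which - 1].reshape(model.grid_shape)
    sign = np.where(vals >= 0, 1, -1)
    boundary = np.zeros(model.grid_shape, dtype=bool)
    boundary |= sign != np.roll(sign, 1, axis=1)
    boundary |= sign != np.roll(sign, -1, axis=1)
    boundary[1:] |= sign[1:] != sign[:-1]
    boundary[:-1] |= sign[:-1] != sign[1:]
    return LoadingMap(values=vals, sign=sign, boundary=boundary)


# --------------------------------------------------------------------------
# train/test split and cross-validation


def split_train_test(
    labels: Sequence, per_group_train: int = 12, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Random per-group train/test assignment, deterministic given seed."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train, test = [], []
    for cls in sorted(np.unique(labels).tolist()):
        idx = np.where(labels == cls)[0]
        if len(idx) < per_group_train:
            raise ValueError(
                f"group {cls!r} has {len(idx)} members; needs >= {per_group_train}"
            )
        perm = rng.permutation(idx)
        train.extend(perm[:per_group_train].tolist())
        test.extend(perm[per_group_train:].tolist())
    return np.sort(np.array(train, dtype=int)), np.sort(np.array(test, dtype=int))


def make_folds(codes: np.ndarray, n_folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Stratified folds with exactly one member per class per fold.

    Requires every class to have exactly ``n_folds`` members; the folds
    partition all rows.
    """
    folds = [[] for _ in range(n_folds)]
    for cls in np.unique(codes):
        idx = np.where(codes == cls)[0]
        if len(idx) != n_folds:
            raise ValueError(
                f"stratified folds need exactly {n_folds} members per class; "
                f"class {cls} has {len(idx)}"
            )
        perm = rng.permutation(idx)
        for f in range(n_folds):
            folds[f].append(perm[f])
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def _cv_errors_for_gram(
    g: np.ndarray, codes: np.ndarray, k: int, fold_sets: list[list[np.ndarray]]
) -> np.ndarray:
    """Mean CV error per repeat for one lambda's Gram matrix."""
    n = g.shape[0]
    y_all = _indicator(codes, k)
    errs = np.zeros(len(fold_sets))
    for r, folds in enumerate(fold_sets):
        wrong = 0
        for fold in folds:
            test_mask = np.zeros(n, dtype=bool)
            test_mask[fold] = True
            tr = np.where(~test_mask)[0]
            gc = _centered_gram(g, tr)
            c, theta, _, z = _os_eig(gc[np.ix_(tr, tr)], y_all[tr])
            s, signs, centroids = _scale_and_orient(z, codes[tr], k)
            zs = (gc[np.ix_(fold, tr)] @ (c @ theta)) * (signs / s)[None, :]
            d = ((zs[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
            wrong += int(np.sum(d.argmin(axis=1) != codes[fold]))
        errs[r] = wrong / n
    return errs


@dataclass
class LambdaSelection:
    lambda_: float
    df_: float
    lambda_grid: np.ndarray
    df_grid: np.ndarray
    mean_error: np.ndarray
    upper_band: np.ndarray
    admissible: np.ndarray
    errors: np.ndarray = field(repr=False)  # (repeats, n_lambda)
    repeats: int = 0


def default_lambda_grid(x: np.ndarray, penalty: CylinderPenalty | None = None, num: int = 25) -> np.ndarray:
    """Logarithmic lambda grid auto-scaled to the data/penalty spectrum.

    The initial scale balances the data energy against trace(Omega); the
    bounds are then expanded until the effective df sweeps (almost) its
    whole range, from near min(n-1, p) down to near the dimension of
    Omega's null space, so the CV selection can explore all complexities.
    """
    x = np.asarray(x, dtype=float)
    if penalty is None:
        penalty = CylinderPenalty(GRID_SHAPE)
    # trace(Omega) = sum of squared Laplacian eigenvalues over the grid
    tr_omega = float(np.sum(penalty._ev_lap[:, 1:] ** 2)) * 2 + float(
        np.sum(penalty._ev_lap[:, 0] ** 2)
    )
    xc = x - x.mean(axis=0)
    lam0 = float(np.sum(xc * xc)) / max(tr_omega, 1e-300)
    eps = _default_eps(x)
    df_max = min(x.shape[0] - 1, x.shape[1])
    lo = hi = lam0
    for _ in range(20):
        if effective_df(hi, penalty, x, eps) <= 2.0:
            break
        hi *= 10.0
    for _ in range(20):
        if effective_df(lo, penalty, x, eps) >= 0.995 * df_max:
            break
        lo /= 10.0
    return np.logspace(np.log10(lo), np.log10(hi), num)


def select_lambda(
    x: np.ndarray,
    labels: Sequence,
    penalty=None,
    lambda_grid: np.ndarray | None = None,
    n_folds: int = 12,
    repeats: int = 100,
    seed: int = 0,
    eps: float | None = None,
    grid_shape: tuple[int, int] = GRID_SHAPE,
) -> LambdaSelection:
    """Select the regularization weight by repeated stratified k-fold CV.

    For each lambda the mean CV misclassification rate over all repeats
    and its approximate 95% prediction band (mean +/- t * sd across the
    repeat means) are computed; lambdas whose mean error does not exceed
    the minimum upper band are admissible, and the admissible lambda with
    the lowest effective df is chosen.  Fold assignments are drawn once
    per repeat and shared across the grid; deterministic given ``seed``.
    """
    x = np.asarray(x, dtype=float)
    n, p = x.shape
    labels = np.asarray(labels)
    classes = sorted(np.unique(labels).tolist())
    k = len(classes)
    codes = np.array([classes.index(v) for v in labels])
    if penalty is None and p == grid_shape[0] * grid_shape[1]:
        penalty = CylinderPenalty(grid_shape)
    if lambda_grid is None:
        lambda_grid = default_lambda_grid(x, penalty if isinstance(penalty, CylinderPenalty) else None)
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    if eps is None:
        eps = _default_eps(x)
    if repeats < 2:
        import warnings

        warnings.warn("fewer than 2 repeats: the prediction band is degenerate")
    rng = np.random.default_rng(seed)
    fold_sets = [make_folds(codes, n_folds, rng) for _ in range(repeats)]

    all_idx = np.arange(n)
    errors = np.zeros((repeats, len(lambda_grid)))
    dfs = np.zeros(len(lambda_grid))
    for j, lam in enumerate(lambda_grid):
        gram = _PenalizedGram(x, float(lam), penalty, eps)
        gvals = np.clip(np.linalg.eigvalsh(_centered_gram(gram.g, all_idx)), 0.0, None)
        dfs[j] = np.sum(gvals / (n + gvals))
        errors[:, j] = _cv_errors_for_gram(gram.g, codes, k, fold_sets)

    mean_err = errors.mean(axis=0)
    if repeats > 1:
        sd = errors.std(axis=0, ddof=1)
        tq = stats.t.ppf(0.975, repeats - 1)
        upper = mean_err + tq * sd
    else:
        upper = mean_err.copy()
    if np.all(mean_err >= 1.0 - 1e-12):
        raise ValueError("lambda selection failed: every lambda misclassifies everything")
    threshold = float(np.min(upper))
    admissible = mean_err <= threshold + 1e-12
    cand = np.where(admissible)[0]
    best = cand[np.argmin(dfs[cand])]
    return LambdaSelection(
        lambda_=float(lambda_grid[best]),
        df_=float(dfs[best]),
        lambda_grid=lambda_grid,
        df_grid=dfs,
        mean_error=mean_err,
        upper_band=upper,
        admissible=admissible,
        errors=errors,
        repeats=repeats,
    )
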