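"""PLS1 regression, OLS for index models, and grouped k-fold
cross-validation with R2/RMSE.

The PLS1 fit is the NIPALS sequence on centered data: for each latent
variable the weight vector is X'y (normalized), scores t = Xw, loadings
p = X't/t't, q = y't/t't, then X and y are deflated.  Coefficients on the
original predictor scale are recovered as B = W (P'W)^{-1} q, so the
fitted model is exactly the linear form y = a0 + sum_i a_i x_i and
predictions via the latent scores and via the coefficients agree to
machine precision.  With as many latent variables as the design rank,
PLS1 predictions coincide with ordinary least squares.

Cross-validation is grouped: all leaves of one seedling share a fold, so
twin leaves can never leak between training and validation.  R2 is
1 - SS_res/SS_tot on the pooled out-of-fold predictions.  The number of
latent variables is chosen by an inner CV with the one-standard-error
parsimony rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import FitError, ParameterError, ShapeError


@dataclass
class PLSModel:
    """Fitted PLS1 (or degenerate OLS) model on the original scale."""

    x_means: np.ndarray
    y_mean: float
    n_lv: int
    coefficients: np.ndarray
    intercept: float
    method: str = "pls1"

    def predict(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        if X.shape[1] != self.coefficients.size:
            raise ShapeError(
                f"model has {self.coefficients.size} predictors, got {X.shape[1]}"
            )
        return self.intercept + X @ self.coefficients


@dataclass
class CVResult:
    """Pooled out-of-fold accuracy for one recipe."""

    r2_cv: float
    rmse_cv: float
    fold_assignments: np.ndarray
    per_fold: list
    k: int
    seed: int
    predictions: np.ndarray = field(default=None, repr=False)


def _center(X, y):
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != y.size:
        raise ShapeError(f"{X.shape[0]} rows of X but {y.size} responses")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise FitError("missing or non-finite values in the design")
    xm = X.mean(axis=0)
    return X - xm, y - y.mean(), xm, float(y.mean())


def _nipals_path(Xc, yc, max_lv):
    """Weights/loadings for 1..max_lv components; returns per-component
    coefficient vectors on the centered scale."""
    n, p = Xc.shape
    W = np.zeros((p, max_lv))
    P = np.zeros((p, max_lv))
    q = np.zeros(max_lv)
    Xd = Xc.copy()
    yd = yc.copy()
    a = 0
    for a in range(max_lv):
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if nw < 1e-12:
            break
        w /= nw
        t = Xd @ w
        tt = float(t @ t)
        if tt < 1e-12:
            break
        W[:, a] = w
        P[:, a] = Xd.T @ t / tt
        q[a] = float(yd @ t) / tt
        Xd -= np.outer(t, P[:, a])
        yd -= q[a] * t
        a += 1
    n_fit = a
    coefs = []
    for k in range(1, n_fit + 1):
        Wk, Pk, qk = W[:, :k], P[:, :k], q[:k]
        # B = W (P'W)^{-1} q
        beta = Wk @ np.linalg.solve(Pk.T @ Wk, qk)
        coefs.append(beta)
    return coefs


def fit_pls1(X, y, n_lv: int) -> PLSModel:
    """NIPALS PLS1 with ``n_lv`` latent variables.

    If the design supports fewer components than requested, the count is
    reduced with a warning.
    """
    if n_lv < 1:
        raise ParameterError("n_lv must be >= 1")
    Xc, yc, xm, ym = _center(X, y)
    cap = min(Xc.shape[0] - 1, Xc.shape[1])
    if n_lv > cap:
        warnings.warn(f"n_lv={n_lv} exceeds rank cap {cap}; reduced")
        n_lv = max(cap, 1)
    coefs = _nipals_path(Xc, yc, n_lv)
    if not coefs:
        # X carries no covariance with y at all; constant model
        beta = np.zeros(Xc.shape[1])
        return PLSModel(xm, ym, 0, beta, ym)
    if len(coefs) < n_lv:
        warnings.warn(f"NIPALS stopped at {len(coefs)} component(s)")
    beta = coefs[-1]
    return PLSModel(xm, ym, len(coefs), beta, ym - float(xm @ beta))


def predict(model: PLSModel, X) -> np.ndarray:
    """Linear-form prediction a0 + X @ a."""
    return model.predict(X)


def fit_linear(X, y) -> PLSModel:
    """Ordinary least squares for one-to-a-few index columns."""
    Xc, yc, xm, ym = _center(X, y)
    n, p = Xc.shape
    if n <= p:
        raise FitError(f"OLS needs n > p, got n={n}, p={p}")
    rank = np.linalg.matrix_rank(Xc)
    if rank < p:
        raise FitError(f"rank-deficient design (rank {rank} < {p} columns)")
    beta, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
    return PLSModel(xm, ym, p, beta, ym - float(xm @ beta), method="ols")


# ---------------------------------------------------------------------------
# folds and metrics
# ---------------------------------------------------------------------------

def r2_score(y_true, y_pred) -> float:
    y_true = np.asarray(y_true, float)
    y_pred = np.asarray(y_pred, float)
    ss_res = float(((y_true - y_pred) ** 2).sum())
    ss_tot = float(((y_true - y_true.mean()) ** 2).sum())
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0


def rmse(y_true, y_pred) -> float:
    d = np.asarray(y_true, float) - np.asarray(y_pred, float)
    return float(np.sqrt((d**2).mean()))


def grouped_folds(group_ids, k: int, seed: int, strata=None) -> np.ndarray:
    """Per-sample fold ids with whole groups (seedlings) in one fold.

    Groups are shuffled (optionally within strata such as treatment) with
    the given seed and dealt cyclically, so fold sizes are balanced and
    the assignment is deterministic.
    """
    group_ids = np.asarray(group_ids)
    uniq = pd_unique(group_ids)
    if k < 2:
        raise ParameterError("k must be >= 2")
    if k > uniq.size:
        raise ParameterError(f"k={k} exceeds {uniq.size} groups")
    rng = np.random.default_rng(seed)
    fold_of_group = {}
    if strata is None:
        strata = np.zeros(group_ids.size)
    strata = np.asarray(strata)
    stratum_of_group = {g: strata[np.flatnonzero(group_ids == g)[0]] for g in uniq}
    offset = 0
    for s in pd_unique(np.array([stratum_of_group[g] for g in uniq])):
        members = [g for g in uniq if stratum_of_group[g] == s]
        order = rng.permutation(len(members))
        for j, gi in enumerate(order):
            fold_of_group[members[gi]] = (offset + j) % k
        offset += len(members)
    return np.array([fold_of_group[g] for g in group_ids], dtype=int)


def pd_unique(values: np.ndarray) -> np.ndarray:
    """Order-preserving unique."""
    _, idx = np.unique(values, return_index=True)
    return values[np.sort(idx)]


def choose_n_lv(X, y, k_folds: int = 5, max_lv: int | None = None,
                seed: int = 0, groups=None) -> int:
    """Latent-variable count minimizing inner-CV RMSE, then relaxed to the
    smallest count within one standard error of that minimum."""
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, float)
    n, p = X.shape
    cap = min(n - 1, p)
    max_lv = min(max_lv or min(20, p), cap)
    if groups is None:
        groups = np.arange(n)
    folds = grouped_folds(groups, min(k_folds, np.unique(groups).size), seed)
    k = folds.max() + 1
    sq_err = np.full((k, max_lv), np.nan)
    for f in range(k):
        tr = folds != f
        te = ~tr
        Xc, yc, xm, ym = _center(X[tr], y[tr])
        coefs = _nipals_path(Xc, yc, min(max_lv, tr.sum() - 1))
        for a, beta in enumerate(coefs):
            pred = ym + (X[te] - xm) @ beta
            sq_err[f, a] = ((y[te] - pred) ** 2).mean()
        # pad truncated paths with the last available component
        for a in range(len(coefs), max_lv):
            sq_err[f, a] = sq_err[f, len(coefs) - 1] if coefs else ((y[te] - ym) ** 2).mean()
    fold_rmse = np.sqrt(sq_err)
    mean_rmse = fold_rmse.mean(axis=0)
    best = int(np.nanargmin(mean_rmse))
    se = fold_rmse[:, best].std(ddof=1) / np.sqrt(k)
    threshold = mean_rmse[best] + se
    for a in range(max_lv):
        if mean_rmse[a] <= threshold:
            return a + 1
    return best + 1


def kfold_cv(recipe, spectra, k: int = 5, seed: int = 0) -> CVResult:
    """Grouped k-fold CV of a full modeling recipe on a SpectraSet.

    ``recipe`` must expose ``clone() -> recipe``, ``fit(train_spectra)``
    and ``predict(spectra) -> array``; every fitted statistic (transform
    context, band screening, PCA rotation, PLS coefficients) is
    re-estimated inside each training fold.
    """
    y = spectra.chlorophyll
    groups = spectra.records["seedling_id"].to_numpy()
    strata = spectra.records["treatment"].to_numpy()
    folds = grouped_folds(groups, k, seed, strata=strata)
    preds = np.empty_like(y)
    per_fold = []
    for f in range(k):
        train = spectra.subset(folds != f)
        test = spectra.subset(folds == f)
        fitted = recipe.clone()
        fitted.fit(train)
        p = fitted.predict(test)
        preds[folds == f] = p
        per_fold.append({"fold": f, "n": test.n_leaves,
                         "rmse": rmse(test.chlorophyll, p)})
    return CVResult(
        r2_cv=r2_score(y, preds),
        rmse_cv=rmse(y, preds),
        fold_assignments=folds,
        per_fold=per_fold,
        k=k,
        seed=seed,
        predictions=preds,
    )
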