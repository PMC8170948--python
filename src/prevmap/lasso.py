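"""L1-penalized logistic regression with the composite lambda rule.

The shrinkage parameter is chosen to minimize k-fold cross-validated
misclassification error plus one standard error, or such that at least
``min_predictors`` predictors are retained — whichever of the two candidate
fits contains MORE nonzero predictors.  This guards the sparsity-inducing
1-SE rule against selecting a model too small to capture medication-use
signal for rare outcomes.

Predictors are standardized internally for fitting (the penalty applies on
the standardized scale, the usual convention); coefficients are always
reported on the original column scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from . import _solver
from .errors import InputError
from .features import FeatureMatrix

__all__ = [
    "LassoPath",
    "CvCurve",
    "SelectedFit",
    "fit_lasso_logit_path",
    "auto_lambda_grid",
    "cv_misclassification",
    "select_lambda",
    "predict_probabilities",
    "lasso_logit_cv",
    "kkt_violations",
]


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, FeatureMatrix):
        return X.data
    if isinstance(X, pd.DataFrame):
        return X
    raise InputError("X must be a FeatureMatrix or a pandas DataFrame")


@dataclass
class LassoPath:
    """Coefficient path over a decreasing lambda grid (original scale)."""

    lambda_grid: np.ndarray
    coefs: np.ndarray  # (n_lambda, n_columns)
    intercepts: np.ndarray
    nnz: np.ndarray
    columns: list[str]
    kkt_viol: np.ndarray  # achieved stationarity violation per lambda

    def coefs_at(self, index: int) -> pd.Series:
        return pd.Series(self.coefs[index], index=self.columns)


@dataclass
class CvCurve:
    """Cross-validated misclassification error along a lambda grid."""

    lambda_grid: np.ndarray
    mean_error: np.ndarray
    se_error: np.ndarray  # sd over folds / sqrt(k)
    k: int
    seed: int
    fold_errors: np.ndarray | None = None  # (k, n_lambda)


@dataclass
class SelectedFit:
    """The fit at the selected lambda."""

    lambda_: float
    branch: str  # "one_se" | "min_predictors"
    intercept: float
    coefficients: pd.Series
    nnz: int

    @property
    def columns(self) -> list[str]:
        return list(self.coefficients.index)

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("name,value\n")
            fh.write(f"_lambda,{self.lambda_!r}\n")
            fh.write(f"_branch,{self.branch}\n")
            fh.write(f"_intercept,{self.intercept!r}\n")
            fh.write(f"_nnz,{self.nnz}\n")
            for name, coef in self.coefficients.items():
                fh.write(f"{name},{coef!r}\n")

    @classmethod
    def from_csv(cls, path) -> "SelectedFit":
        df = pd.read_csv(path, dtype={"name": str, "value": str})
        meta = dict(zip(df["name"], df["value"]))
        coef_rows = df[~df["name"].str.startswith("_")]
        coefs = pd.Series(
            [float(v) for v in coef_rows["value"]], index=list(coef_rows["name"])
        )
        return cls(
            lambda_=float(meta["_lambda"]),
            branch=meta["_branch"],
            intercept=float(meta["_intercept"]),
            coefficients=coefs,
            nnz=int(meta["_nnz"]),
        )


def _validate_xy(X: pd.DataFrame, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    Xv = X.to_numpy(float)
    if not np.all(np.isfinite(Xv)):
        raise InputError("design matrix contains non-finite values")
    y = np.asarray(y, float).ravel()
    if y.size != Xv.shape[0]:
        raise InputError("X and y are not aligned")
    classes = np.unique(y)
    if not np.isin(classes, (0.0, 1.0)).all():
        raise InputError("y must be 0/1")
    if classes.size < 2:
        raise InputError("y has a single class; cannot fit a logistic model")
    return Xv, y


def _standardize(Xv: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    mu = Xv.mean(axis=0)
    sd = Xv.std(axis=0)
    free = sd > 0
    sd_safe = np.where(free, sd, 1.0)
    Xs = (Xv - mu) / sd_safe
    Xs[:, ~free] = 0.0
    return Xs, mu, sd_safe, free


def auto_lambda_grid(
    X, y, n_lambda: int = 100, lambda_min_ratio: float = 1e-2
) -> np.ndarray:
    """Decreasing log-spaced grid from the critical lambda (all slopes zero)."""
    Xv, y = _validate_xy(_as_frame(X), y)
    Xs, _, _, free = _standardize(Xv)
    ybar = y.mean()
    g = Xs.T @ (ybar - y) / y.size
    lam_max = float(np.max(np.abs(g[free]))) if free.any() else 0.0
    if lam_max <= 0:
        raise InputError("all predictors are constant; no penalization path exists")
    # nudge the top of the grid above the critical value so the null model
    # is exact there despite floating-point rounding of the score
    lam_max *= 1.0 + 1e-6
    return np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)


def fit_lasso_logit_path(
    X,
    y,
    lambda_grid: np.ndarray | None = None,
    n_lambda: int = 100,
    lambda_min_ratio: float = 1e-2,
    kkt_tol: float = _solver.KKT_TOL,
) -> LassoPath:
    """Fit the penalized logistic path; see the module docstring.

    With ``lambda_grid=None`` an automatic grid is built from the smallest
    lambda that zeroes all slopes, descending geometrically over
    ``n_lambda`` points.
    """
    frame = _as_frame(X)
    Xv, y = _validate_xy(frame, y)
    if lambda_grid is None:
        lambda_grid = auto_lambda_grid(frame, y, n_lambda, lambda_min_ratio)
    lambda_grid = np.asarray(lambda_grid, float)
    if lambda_grid.size == 0 or np.any(lambda_grid <= 0):
        raise InputError("lambda grid must be non-empty and strictly positive")
    order = np.argsort(-lambda_grid, kind="stable")
    lambdas = lambda_grid[order]

    Xs, mu, sd, free = _standardize(Xv)
    Xt = np.ascontiguousarray(Xs.T)
    B, b0s, nnz, viols = _solver.fit_path(
        Xt, y, lambdas, free, kkt_tol, 60, 2000, 40
    )
    # back to the caller's grid order and the original column scale
    inv = np.empty_like(order)
    inv[order] = np.arange(order.size)
    B = B[inv]
    b0s = b0s[inv]
    nnz = nnz[inv]
    viols = viols[inv]
    coefs = B / sd
    intercepts = b0s - coefs @ mu
    return LassoPath(
        lambda_grid=lambda_grid,
        coefs=coefs,
        intercepts=intercepts,
        nnz=nnz,
        columns=list(frame.columns),
        kkt_viol=viols,
    )


def kkt_violations(path: LassoPath, X, y) -> np.ndarray:
    """Recompute the stationarity violation at every grid point.

    For each lambda, on the standardized predictor scale: the score of the
    penalized objective must vanish within tolerance at active coordinates
    (|grad_j + lambda sign(beta_j)|) and be dominated by lambda at inactive
    ones (max(|grad_j| - lambda, 0)); the intercept score must vanish.
    """
    frame = _as_frame(X)
    Xv, y = _validate_xy(frame, y)
    Xs, mu, sd, free = _standardize(Xv)
    out = np.zeros(path.lambda_grid.size)
    for k, lam in enumerate(path.lambda_grid):
        beta_std = path.coefs[k] * sd
        b0_std = path.intercepts[k] + path.coefs[k] @ mu
        eta = b0_std + Xs @ beta_std
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
        r = p - y
        g = Xs.T @ r / y.size
        viol = abs(r.mean())
        active = (beta_std != 0) & free
        inactive = (beta_std == 0) & free
        if active.any():
            viol = max(viol, np.max(np.abs(g[active] + lam * np.sign(beta_std[active]))))
        if inactive.any():
            viol = max(viol, max(np.max(np.abs(g[inactive])) - lam, 0.0))
        out[k] = viol
    return out


def cv_misclassification(
    X,
    y,
    lambda_grid: np.ndarray | None = None,
    k: int = 10,
    threshold: float = 0.5,
    seed: int = 0,
    **path_kwargs,
) -> CvCurve:
    """k-fold cross-validated misclassification error along the path.

    Folds are stratified by outcome so both classes appear in every
    training split (re-drawn with a fresh shuffle in the unlikely event a
    split still loses a class; error after 10 attempts).
    """
    frame = _as_frame(X)
    Xv, y = _validate_xy(frame, y)
    n = y.size
    if k < 2:
        raise InputError("k must be >= 2")
    if n < k:
        raise InputError("need at least k observations")
    if lambda_grid is None:
        lambda_grid = auto_lambda_grid(frame, y, **{
            kk: vv for kk, vv in path_kwargs.items()
            if kk in ("n_lambda", "lambda_min_ratio")
        })
    lambda_grid = np.asarray(lambda_grid, float)
    cut = np.log(threshold / (1.0 - threshold))

    folds = None
    for attempt in range(10):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=(seed + attempt) % (2**31))
        candidate = list(skf.split(Xv, y))
        ok = all(np.unique(y[tr]).size == 2 for tr, _ in candidate)
        if ok:
            folds = candidate
            break
        warnings.warn("a CV training split lost a class; refolding")
    if folds is None:
        raise InputError("could not build CV folds with both classes in every split")

    errors = np.empty((k, lambda_grid.size))
    for f, (tr, te) in enumerate(folds):
        sub = fit_lasso_logit_path(
            frame.iloc[tr], y[tr], lambda_grid=lambda_grid,
            **{kk: vv for kk, vv in path_kwargs.items() if kk == "kkt_tol"},
        )
        eta = Xv[te] @ sub.coefs.T + sub.intercepts  # (n_te, K)
        pred = (eta > cut).astype(float)
        errors[f] = (pred != y[te][:, None]).mean(axis=0)
    return CvCurve(
        lambda_grid=lambda_grid,
        mean_error=errors.mean(axis=0),
        se_error=errors.std(axis=0, ddof=1) / np.sqrt(k),
        k=k,
        seed=seed,
        fold_errors=errors,
    )


def select_lambda(
    cv: CvCurve, path: LassoPath, min_predictors: int = 10
) -> SelectedFit:
    """Apply the composite selection rule.

    Candidate A (``one_se``): the largest lambda whose mean CV error is
    within one standard error of the minimum.  Candidate B
    (``min_predictors``): the largest lambda whose fit retains at least
    ``min_predictors`` nonzero predictors (the smallest grid lambda, with a
    warning, if none does).  The candidate whose fit has more nonzero
    predictors wins; ties go to the larger lambda.
    """
    if cv.lambda_grid.size == 0:
        raise InputError("empty lambda grid")
    if cv.lambda_grid.size != path.lambda_grid.size or not np.allclose(
        cv.lambda_grid, path.lambda_grid
    ):
        raise InputError("CV curve and path do not share a lambda grid")
    order = np.argsort(-cv.lambda_grid, kind="stable")  # descending
    lam = cv.lambda_grid[order]
    mean = cv.mean_error[order]
    se = cv.se_error[order]
    nnz = path.nnz[order]

    i_min = int(np.argmin(mean))
    thresh = mean[i_min] + se[i_min]
    i_1se = int(np.nonzero(mean <= thresh)[0][0])  # largest lambda within 1 SE

    reach = np.nonzero(nnz >= min_predictors)[0]
    if reach.size:
        i_10 = int(reach[0])
    else:
        warnings.warn(
            f"no lambda on the grid retains >= {min_predictors} predictors; "
            "falling back to the smallest grid lambda"
        )
        i_10 = lam.size - 1

    if nnz[i_1se] > nnz[i_10]:
        i_sel, branch = i_1se, "one_se"
    elif nnz[i_10] > nnz[i_1se]:
        i_sel, branch = i_10, "min_predictors"
    else:  # equal nonzero counts: the larger lambda, labelled one_se on a tie
        i_sel = min(i_1se, i_10)
        branch = "one_se" if i_sel == i_1se else "min_predictors"

    k = order[i_sel]
    coefs = path.coefs_at(k)
    return SelectedFit(
        lambda_=float(path.lambda_grid[k]),
        branch=branch,
        intercept=float(path.intercepts[k]),
        coefficients=coefs,
        nnz=int(path.nnz[k]),
    )


def predict_probabilities(fit: SelectedFit, X) -> np.ndarray:
    """Inverse-logit of the fit's linear predictor, per row of X."""
    frame = _as_frame(X)
    missing = [c for c in fit.columns if c not in frame.columns]
    extra = [c for c in frame.columns if c not in fit.coefficients.index]
    if missing or extra:
        raise InputError(
            f"column mismatch between fit and X; missing={missing!r} extra={extra!r}"
        )
    Xv = frame[fit.columns].to_numpy(float)
    eta = fit.intercept + Xv @ fit.coefficients.to_numpy()
    return 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))


def lasso_logit_cv(
    X,
    y,
    k: int = 10,
    threshold: float = 0.5,
    min_predictors: int = 10,
    seed: int = 0,
    n_lambda: int = 100,
    lambda_min_ratio: float = 1e-2,
    kkt_tol: float = _solver.KKT_TOL,
    cv_kkt_tol: float = _solver.CV_KKT_TOL,
) -> tuple[SelectedFit, LassoPath, CvCurve]:
    """Full procedure: path fit, k-fold CV, composite lambda selection.

    Fold fits use the looser ``cv_kkt_tol``: they only feed the
    misclassification curve, which is insensitive to coefficient precision
    far below the fold-to-fold noise.
    """
    frame = _as_frame(X)
    grid = auto_lambda_grid(frame, y, n_lambda=n_lambda, lambda_min_ratio=lambda_min_ratio)
    path = fit_lasso_logit_path(frame, y, lambda_grid=grid, kkt_tol=kkt_tol)
    cv = cv_misclassification(
        frame, y, lambda_grid=grid, k=k, threshold=threshold, seed=seed,
        kkt_tol=cv_kkt_tol,
    )
    fit = select_lambda(cv, path, min_predictors=min_predictors)
    return fit, path, cv
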