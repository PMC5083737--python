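"""Sparse penalized multinomial logistic regression.

Implements the three-class softmax model in the symmetric (reference-free)
parameterization, fitted by proximal gradient descent with backtracking on

    F(b0, B) = -(1/n) * log-likelihood + lambda * Penalty(B)

where Penalty is the Lasso ell_1 norm sum_jk |beta_jk| or the group-Lasso
sum over features of the row norm ||beta_j.||_2 (a feature enters or leaves
the model for all classes jointly).  Intercepts are never penalized; the
penalty resolves the softmax identifiability redundancy.  Features are
standardized internally and coefficients returned on the original scale.

A full regularization path is fitted with warm starts from lambda_max (the
analytically smallest lambda at which the penalized solution is the null
model) down four decades, and the tuning parameter is chosen by stratified
K-fold cross-validation on either held-out deviance or misclassification.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CLASS_ORDER = ("CP", "IPMN", "PC")

N_LAMBDA_DEFAULT = 100
LAMBDA_DECADES_DEFAULT = 4.0
TOL_DEFAULT = 1e-7
MAX_ITER_DEFAULT = 5000


# ---------------------------------------------------------------------------
# model primitives

def _one_hot(y: np.ndarray, classes: tuple[str, ...]) -> np.ndarray:
    index = {c: k for k, c in enumerate(classes)}
    unknown = set(np.unique(y)) - set(classes)
    if unknown:
        raise ValueError(f"unknown class labels: {sorted(unknown)}")
    Y = np.zeros((len(y), len(classes)))
    for i, label in enumerate(y):
        Y[i, index[label]] = 1.0
    return Y


def softmax(scores: np.ndarray) -> np.ndarray:
    s = scores - scores.max(axis=1, keepdims=True)
    e = np.exp(s)
    return e / e.sum(axis=1, keepdims=True)


def _nll_from_scores(scores: np.ndarray, Y: np.ndarray) -> float:
    s = scores - scores.max(axis=1, keepdims=True)
    log_z = np.log(np.exp(s).sum(axis=1))
    return float(-np.mean((s * Y).sum(axis=1) - log_z))


def penalty_value(B: np.ndarray, kind: str) -> float:
    if kind == "lasso":
        return float(np.abs(B).sum())
    if kind == "group_lasso":
        return float(np.linalg.norm(B, axis=1).sum())
    raise ValueError(f"unknown penalty kind {kind!r}")


def _prox(B: np.ndarray, threshold: float, kind: str) -> np.ndarray:
    if kind == "lasso":
        return np.sign(B) * np.maximum(np.abs(B) - threshold, 0.0)
    norms = np.linalg.norm(B, axis=1, keepdims=True)
    scale = np.maximum(1.0 - threshold / np.maximum(norms, 1e-300), 0.0)
    return B * scale


# ---------------------------------------------------------------------------
# single-lambda solver (on standardized design with leading intercept column)

def _kkt_from_grad(G: np.ndarray, W: np.ndarray, lam: float, kind: str) -> float:
    """Max stationarity violation given the smooth gradient at W."""
    res = float(np.abs(G[0]).max())
    Gb, B = G[1:], W[1:]
    if kind == "lasso":
        active = B != 0
        if active.any():
            res = max(res, float(np.abs(Gb[active] + lam * np.sign(B[active])).max()))
        if (~active).any():
            res = max(res, float(np.maximum(np.abs(Gb[~active]) - lam, 0.0).max()))
    else:
        norms = np.linalg.norm(B, axis=1)
        act = norms > 0
        if act.any():
            res = max(
                res,
                float(np.abs(Gb[act] + lam * B[act] / norms[act, None]).max()),
            )
        if (~act).any():
            res = max(
                res,
                float(np.maximum(np.linalg.norm(Gb[~act], axis=1) - lam, 0.0).max()),
            )
    return res


KKT_TOL_DEFAULT = 1e-4


def _fit_single(
    Xa: np.ndarray,
    Y: np.ndarray,
    lam: float,
    kind: str,
    W0: np.ndarray,
    step0: float,
    tol: float = TOL_DEFAULT,
    max_iter: int = MAX_ITER_DEFAULT,
    kkt_tol: float = KKT_TOL_DEFAULT,
    record_objective: bool = False,
) -> tuple[np.ndarray, list[float]]:
    """Proximal gradient with backtracking; monotone in the objective.

    ``Xa`` carries a leading all-ones column; row 0 of the weight matrix is
    the (unpenalized) intercept row.  A FISTA extrapolation is attempted
    each iteration but discarded whenever it would increase the objective,
    preserving monotone descent while keeping the acceleration.  Iteration
    stops once the relative objective change falls below ``tol`` and the
    penalized stationarity (KKT) residual falls below ``kkt_tol``.
    """
    n = Xa.shape[0]
    W = W0.copy()
    scores = Xa @ W
    f = _nll_from_scores(scores, Y)
    obj = f + lam * penalty_value(W[1:], kind)
    history = [obj] if record_objective else []
    t = step0
    W_prev = W.copy()
    momentum = 0.0

    for it in range(max_iter):
        # extrapolated point (monotone-safeguarded FISTA)
        if momentum > 0.0:
            V = W + momentum * (W - W_prev)
        else:
            V = W
        scores_v = Xa @ V
        P = softmax(scores_v)
        G = Xa.T @ (P - Y) / n
        f_v = _nll_from_scores(scores_v, Y)

        while True:
            Wn = V - t * G
            Wn[1:] = _prox(Wn[1:], t * lam, kind)
            D = Wn - V
            f_n = _nll_from_scores(Xa @ Wn, Y)
            if f_n <= f_v + (G * D).sum() + (D * D).sum() / (2 * t) + 1e-12:
                break
            t *= 0.5
            if t < 1e-18:
                break
        obj_n = f_n + lam * penalty_value(Wn[1:], kind)

        if obj_n > obj and momentum > 0.0:
            # extrapolation overshot: plain proximal step from W instead
            scores_w = Xa @ W
            P = softmax(scores_w)
            G = Xa.T @ (P - Y) / n
            f_w = _nll_from_scores(scores_w, Y)
            while True:
                Wn = W - t * G
                Wn[1:] = _prox(Wn[1:], t * lam, kind)
                D = Wn - W
                f_n = _nll_from_scores(Xa @ Wn, Y)
                if f_n <= f_w + (G * D).sum() + (D * D).sum() / (2 * t) + 1e-12:
                    break
                t *= 0.5
                if t < 1e-18:
                    break
            obj_n = f_n + lam * penalty_value(Wn[1:], kind)
            momentum = 0.0
        else:
            momentum = min(0.95, (it + 1.0) / (it + 4.0))

        if obj_n > obj:  # cannot decrease further at machine precision
            if record_objective:
                history.append(obj)
            break
        W_prev, W = W, Wn
        small_change = abs(obj - obj_n) <= tol * max(1.0, abs(obj))
        obj = obj_n
        if record_objective:
            history.append(obj)
        if small_change:
            Gw = Xa.T @ (softmax(Xa @ W) - Y) / n
            if _kkt_from_grad(Gw, W, lam, kind) <= kkt_tol:
                break
        t = min(t * 1.1, step0 * 4)
    return W, history


# ---------------------------------------------------------------------------
# standardization and path

@dataclass(frozen=True)
class Standardization:
    mean: np.ndarray
    scale: np.ndarray
    kept: np.ndarray  # indices of non-constant columns retained for fitting

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X[:, self.kept] - self.mean) / self.scale


def _standardize(X: np.ndarray) -> Standardization:
    mean = X.mean(axis=0)
    scale = X.std(axis=0, ddof=0)
    kept = np.flatnonzero(scale > 0)
    if len(kept) < X.shape[1]:
        warnings.warn(
            f"dropping {X.shape[1] - len(kept)} constant feature(s) before fitting",
            stacklevel=3,
        )
    return Standardization(mean=mean[kept], scale=scale[kept], kept=kept)


def lambda_max(Xs: np.ndarray, Y: np.ndarray, kind: str) -> float:
    """Smallest lambda whose penalized solution is the null model.

    At the intercept-only optimum the predicted probabilities equal the
    empirical class frequencies; lambda_max is the norm of the null-model
    gradient dual to the penalty (max |g_jk| for the Lasso, max row
    ||g_j.||_2 for the group Lasso).
    """
    n = Xs.shape[0]
    p_null = Y.mean(axis=0, keepdims=True)
    G = Xs.T @ (p_null - Y) / n
    if kind == "lasso":
        return float(np.abs(G).max())
    if kind == "group_lasso":
        return float(np.linalg.norm(G, axis=1).max())
    raise ValueError(f"unknown penalty kind {kind!r}")


def default_lambda_path(
    lam_max: float,
    n_lambdas: int = N_LAMBDA_DEFAULT,
    decades: float = LAMBDA_DECADES_DEFAULT,
) -> np.ndarray:
    return np.logspace(np.log10(lam_max), np.log10(lam_max) - decades, n_lambdas)


def _validate_xy(X: np.ndarray, y: np.ndarray) -> None:
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in feature matrix")
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate labels: need samples from >= 2 classes")
    if X.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    if X.shape[0] != len(y):
        raise ValueError("X and y length mismatch")


@dataclass
class PathFit:
    """Coefficients along a regularization path.

    ``weights_std`` holds (p_kept+1) x K matrices on the standardized scale
    (intercept row first); ``intercepts``/``coefs`` are mapped back to the
    original feature scale with dropped (constant) columns reinserted as
    zeros.
    """

    lambdas: np.ndarray
    intercepts: list[np.ndarray]
    coefs: list[np.ndarray]
    weights_std: list[np.ndarray]
    standardization: Standardization
    classes: tuple[str, ...]
    penalty_kind: str
    n_features: int


def _to_original_scale(
    W: np.ndarray, std: Standardization, n_features: int
) -> tuple[np.ndarray, np.ndarray]:
    b0_std, B_std = W[0], W[1:]
    B = np.zeros((n_features, W.shape[1]))
    B[std.kept] = B_std / std.scale[:, None]
    b0 = b0_std - (B_std * (std.mean / std.scale)[:, None]).sum(axis=0)
    return b0, B


def fit_path(
    X: np.ndarray,
    y: np.ndarray,
    penalty_kind: str = "lasso",
    lambdas: np.ndarray | None = None,
    classes: tuple[str, ...] = CLASS_ORDER,
    tol: float = TOL_DEFAULT,
    max_iter: int = MAX_ITER_DEFAULT,
    kkt_tol: float = KKT_TOL_DEFAULT,
) -> PathFit:
    """Fit the penalized model along a (default 100-point) lambda path.

    Warm starts run from lambda_max downward; the first path point is the
    exact null model (all coefficients zero, intercepts the log class
    frequencies).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    _validate_xy(X, y)
    Y = _one_hot(y, classes)
    std = _standardize(X)
    Xs = std.transform(X)
    n = Xs.shape[0]
    Xa = np.hstack([np.ones((n, 1)), Xs])

    lam_max = lambda_max(Xs, Y, penalty_kind)
    if lambdas is None:
        lambdas = default_lambda_path(lam_max)
    lambdas = np.asarray(lambdas, dtype=float)
    if len(lambdas) > 1 and np.any(np.diff(lambdas) >= 0):
        raise ValueError("lambda path must be strictly decreasing")

    # Lipschitz bound for the softmax NLL gradient: 0.5 * ||Xa||_2^2 / n
    spectral = np.linalg.norm(Xa, 2)
    step0 = 1.0 / (0.5 * spectral**2 / n)

    freqs = Y.mean(axis=0)
    b0_null = np.log(np.maximum(freqs, 1e-12))
    b0_null -= b0_null.mean()  # symmetric parameterization
    W = np.zeros((Xa.shape[1], len(classes)))
    W[0] = b0_null

    fit = PathFit(
        lambdas=lambdas,
        intercepts=[],
        coefs=[],
        weights_std=[],
        standardization=std,
        classes=classes,
        penalty_kind=penalty_kind,
        n_features=X.shape[1],
    )
    for lam in lambdas:
        W, _ = _fit_single(
            Xa, Y, lam, penalty_kind, W, step0, tol=tol, max_iter=max_iter,
            kkt_tol=kkt_tol,
        )
        b0, B = _to_original_scale(W, std, X.shape[1])
        fit.weights_std.append(W.copy())
        fit.intercepts.append(b0)
        fit.coefs.append(B)
    return fit


def kkt_residual(path: PathFit, X: np.ndarray, y: np.ndarray, index: int) -> float:
    """Maximum violation of the penalized stationarity conditions at one
    path point, on the standardized scale (used to certify solutions)."""
    X = np.asarray(X, dtype=float)
    Y = _one_hot(np.asarray(y), path.classes)
    std = path.standardization
    Xs = std.transform(X)
    Xa = np.hstack([np.ones((len(Xs), 1)), Xs])
    W = path.weights_std[index]
    lam = path.lambdas[index]
    P = softmax(Xa @ W)
    G = Xa.T @ (P - Y) / len(Xs)
    res = float(np.abs(G[0]).max())  # intercept gradient must vanish
    Gb, B = G[1:], W[1:]
    if path.penalty_kind == "lasso":
        active = B != 0
        if active.any():
            res = max(res, float(np.abs(Gb[active] + lam * np.sign(B[active])).max()))
        if (~active).any():
            res = max(res, float(np.maximum(np.abs(Gb[~active]) - lam, 0.0).max()))
    else:
        norms = np.linalg.norm(B, axis=1)
        for j in range(B.shape[0]):
            if norms[j] > 0:
                res = max(
                    res,
                    float(np.abs(Gb[j] + lam * B[j] / norms[j]).max()),
                )
            else:
                res = max(res, float(max(np.linalg.norm(Gb[j]) - lam, 0.0)))
    return res


# ---------------------------------------------------------------------------
# cross-validation

def stratified_folds(
    y: np.ndarray, folds: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Class-stratified fold assignment: per-class shuffle + round-robin."""
    assignments = [[] for _ in range(folds)]
    offset = 0
    for cls in np.unique(y):
        idx = np.flatnonzero(np.asarray(y) == cls)
        rng.shuffle(idx)
        for k, i in enumerate(idx):
            assignments[(k + offset) % folds].append(i)
        offset += len(idx)
    return [np.array(sorted(a), dtype=int) for a in assignments]


def _held_out_scores(path: PathFit, X: np.ndarray) -> list[np.ndarray]:
    Xs = path.standardization.transform(np.asarray(X, dtype=float))
    Xa = np.hstack([np.ones((len(Xs), 1)), Xs])
    return [softmax(Xa @ W) for W in path.weights_std]


def cv_select_lambda(
    X: np.ndarray,
    y: np.ndarray,
    penalty_kind: str = "lasso",
    criterion: str = "deviance",
    folds: int = 5,
    seed: int = 0,
    lambdas: np.ndarray | None = None,
    classes: tuple[str, ...] = CLASS_ORDER,
    tol: float = TOL_DEFAULT,
    max_iter: int = MAX_ITER_DEFAULT,
) -> tuple[float, pd.DataFrame]:
    """Stratified K-fold CV over the lambda path.

    criterion "deviance" minimizes the mean held-out multinomial deviance
    (-2 log-likelihood per sample); "accuracy" minimizes the mean held-out
    misclassification rate.  Ties break toward larger lambda (the sparser
    model).  A fold layout whose training part loses a class is redrawn up
    to 10 times before erroring.
    """
    if criterion not in {"deviance", "accuracy"}:
        raise ValueError(f"unknown criterion {criterion!r}")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(y) < folds:
        raise ValueError("need at least as many samples as folds")
    _validate_xy(X, y)

    if lambdas is None:
        Y = _one_hot(y, classes)
        std = _standardize(X)
        lambdas = default_lambda_path(lambda_max(std.transform(X), Y, penalty_kind))

    rng = np.random.default_rng(seed)
    n_classes_total = len(np.unique(y))
    for attempt in range(10):
        fold_idx = stratified_folds(y, folds, rng)
        ok = all(
            len(np.unique(np.delete(y, test))) == n_classes_total for test in fold_idx
        )
        if ok:
            break
    else:
        raise ValueError("could not build folds keeping every class in training")

    Yfull = _one_hot(y, classes)
    dev = np.zeros((folds, len(lambdas)))
    err = np.zeros((folds, len(lambdas)))
    for k, test in enumerate(fold_idx):
        train = np.setdiff1d(np.arange(len(y)), test)
        path = fit_path(
            X[train], y[train], penalty_kind, lambdas=lambdas, classes=classes,
            tol=tol, max_iter=max_iter,
        )
        probs = _held_out_scores(path, X[test])
        Yt = Yfull[test]
        for m, P in enumerate(probs):
            p_true = np.clip((P * Yt).sum(axis=1), 1e-12, None)
            dev[k, m] = float(-2.0 * np.mean(np.log(p_true)))
            err[k, m] = float(np.mean(P.argmax(axis=1) != Yt.argmax(axis=1)))

    curve = pd.DataFrame(
        {
            "lambda": lambdas,
            "cv_deviance": dev.mean(axis=0),
            "cv_error_rate": err.mean(axis=0),
        }
    )
    scores = curve["cv_deviance" if criterion == "deviance" else "cv_error_rate"].to_numpy()
    best = scores.min()
    selected = float(lambdas[int(np.flatnonzero(scores <= best + 1e-12)[0])])
    return selected, curve


# ---------------------------------------------------------------------------
# fitted-model container

@dataclass
class ModelFit:
    """A fitted penalized multinomial model at one selected lambda."""

    class_order: tuple[str, ...]
    penalty_kind: str
    intercepts: np.ndarray
    coef: np.ndarray  # p x K, original feature scale
    lambda_selected: float
    lambda_path: np.ndarray
    cv_criterion: str | None
    feature_names: list[str] | None = None
    cv_curve: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def selected_features(self) -> np.ndarray:
        """Indices of features with any nonzero coefficient."""
        return np.flatnonzero(np.any(self.coef != 0.0, axis=1))

    def to_json(self) -> str:
        payload = {
            "class_order": list(self.class_order),
            "penalty_kind": self.penalty_kind,
            "intercepts": self.intercepts.tolist(),
            "coef": self.coef.tolist(),
            "lambda_selected": self.lambda_selected,
            "lambda_path": np.asarray(self.lambda_path).tolist(),
            "cv_criterion": self.cv_criterion,
            "feature_names": self.feature_names,
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ModelFit":
        payload = json.loads(text)
        return cls(
            class_order=tuple(payload["class_order"]),
            penalty_kind=payload["penalty_kind"],
            intercepts=np.array(payload["intercepts"]),
            coef=np.array(payload["coef"]),
            lambda_selected=payload["lambda_selected"],
            lambda_path=np.array(payload["lambda_path"]),
            cv_criterion=payload["cv_criterion"],
            feature_names=payload["feature_names"],
        )


def fit_cv(
    X: np.ndarray,
    y: np.ndarray,
    penalty_kind: str = "lasso",
    criterion: str = "deviance",
    folds: int = 5,
    seed: int = 0,
    classes: tuple[str, ...] = CLASS_ORDER,
    feature_names: list[str] | None = None,
    tol: float = TOL_DEFAULT,
    max_iter: int = MAX_ITER_DEFAULT,
) -> ModelFit:
    """Cross-validate lambda, then refit on all data at the selection."""
    lam, curve = cv_select_lambda(
        X, y, penalty_kind, criterion, folds=folds, seed=seed, classes=classes,
        tol=tol, max_iter=max_iter,
    )
    lambdas = curve["lambda"].to_numpy()
    path = fit_path(X, y, penalty_kind, lambdas=lambdas, classes=classes,
                    tol=tol, max_iter=max_iter)
    idx = int(np.flatnonzero(lambdas == lam)[0])
    return ModelFit(
        class_order=classes,
        penalty_kind=penalty_kind,
        intercepts=path.intercepts[idx],
        coef=path.coefs[idx],
        lambda_selected=lam,
        lambda_path=lambdas,
        cv_criterion=criterion,
        feature_names=list(feature_names) if feature_names is not None else None,
        cv_curve=curve,
    )


def predict_proba(model: ModelFit, X: np.ndarray) -> np.ndarray:
    """Class probabilities (softmax of affine scores); rows sum to 1."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.coef.shape[0]:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match model ({model.coef.shape[0]})"
        )
    return softmax(model.intercepts + X @ model.coef)
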