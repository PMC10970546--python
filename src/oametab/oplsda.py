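"""OPLS-DA: orthogonal projections to latent structures discriminant analysis.

For a binary class vector y (coded -1/+1 and centered) and an autoscaled
matrix X, O-PLS splits X-variation into a part correlated with y (one
predictive component, enough for two classes) and parts orthogonal to it.
Each orthogonal component is found by taking the current predictive
loading p, removing its projection on the predictive weight w
(``w_ortho = p - (w'p) w``), and deflating X by the resulting orthogonal
score/loading pair; the predictive component is then refit on the filtered
matrix.

Model quality is summarized by R2Y (training variance of y explained),
Q2Y (1 - PRESS/SS from stratified k-fold cross-validation with all
scaling re-estimated inside each training fold), CV-ANOVA (an F-test of
cross-validated residuals against total variation), and a label
permutation test. Variable influence uses VIP scores from the predictive
component, with jackknife confidence intervals over the CV training
subsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "OplsDaModel",
    "CvResult",
    "CvAnovaResult",
    "PermutationSummary",
    "fit_oplsda",
    "predict",
    "cross_validate",
    "cv_anova",
    "permutation_test",
    "vip_scores",
    "select_variables",
]

_MAX_AUTO_ORTHO = 5
_AUTO_Q2_GAIN = 0.01


def _encode_y(y) -> np.ndarray:
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"y must have exactly 2 classes, found {len(classes)}")
    return np.where(y == classes[1], 1.0, -1.0), classes


def _autoscale_fit(X: np.ndarray):
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        j = int(np.flatnonzero(sd == 0)[0])
        raise ValueError(f"variable {j} has zero variance; remove before fitting")
    return mean, sd


def _fit_core(Xs: np.ndarray, yc: np.ndarray, n_ortho: int):
    """O-PLS on already-scaled X and centered y. Returns raw arrays."""
    n, p = Xs.shape
    if n_ortho >= min(n, p):
        raise ValueError(f"n_ortho={n_ortho} >= rank bound {min(n, p)}")
    Xf = Xs.copy()
    W_o = np.zeros((p, n_ortho))
    P_o = np.zeros((p, n_ortho))
    T_o = np.zeros((n, n_ortho))
    for k in range(n_ortho):
        w = Xf.T @ yc
        norm = np.linalg.norm(w)
        if norm == 0:
            raise ValueError("X carries no y-covariance; cannot extract components")
        w /= norm
        t = Xf @ w
        p_load = Xf.T @ t / (t @ t)
        w_o = p_load - (w @ p_load) * w
        norm_o = np.linalg.norm(w_o)
        if norm_o < 1e-12:
            raise ValueError(
                f"no orthogonal variation left after {k} component(s); "
                f"reduce n_ortho"
            )
        w_o /= norm_o
        t_o = Xf @ w_o
        p_o = Xf.T @ t_o / (t_o @ t_o)
        Xf = Xf - np.outer(t_o, p_o)
        W_o[:, k], P_o[:, k], T_o[:, k] = w_o, p_o, t_o
    w = Xf.T @ yc
    norm = np.linalg.norm(w)
    if norm == 0:
        raise ValueError("X carries no y-covariance; cannot extract components")
    w /= norm
    t = Xf @ w
    p_load = Xf.T @ t / (t @ t)
    q = (yc @ t) / (t @ t)
    return {"w": w, "p": p_load, "t": t, "q": q, "W_o": W_o, "P_o": P_o, "T_o": T_o}


@dataclass
class OplsDaModel:
    """A fitted two-class OPLS-DA model."""

    classes: np.ndarray  # classes[0] -> -1, classes[1] -> +1
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    weights: np.ndarray  # predictive weight w, unit norm
    loadings: np.ndarray  # predictive loading p
    scores: np.ndarray  # predictive score t (training samples)
    y_loading: float  # q
    ortho_weights: np.ndarray  # p_vars x n_ortho
    ortho_loadings: np.ndarray
    ortho_scores: np.ndarray  # n_samples x n_ortho
    n_ortho: int
    r2y: float
    variable_ids: list = field(default_factory=list)


def fit_oplsda(X, y, n_ortho: int | str = 0, variable_ids=None) -> OplsDaModel:
    """Fit OPLS-DA with ``n_ortho`` orthogonal components.

    ``n_ortho="auto"`` adds orthogonal components (up to 5) while the
    7-fold cross-validated Q2Y improves by more than 0.01.

    X is autoscaled (mean 0, unit variance per variable) internally; y may
    be any two-valued vector and is coded -1/+1 then centered.
    """
    X = np.asarray(X, dtype=float)
    yc_raw, classes = _encode_y(y)
    counts = np.bincount((yc_raw > 0).astype(int))
    if counts.min() < 2:
        raise ValueError("need at least 2 samples per class")
    if np.isnan(X).any():
        raise ValueError("X contains missing values; impute before fitting")

    if n_ortho == "auto":
        n_ortho = _auto_n_ortho(X, y)

    mean, sd = _autoscale_fit(X)
    Xs = (X - mean) / sd
    y_mean = yc_raw.mean()
    yc = yc_raw - y_mean

    core = _fit_core(Xs, yc, int(n_ortho))
    y_hat = core["t"] * core["q"]
    ss_tot = float(yc @ yc)
    r2y = 1.0 - float((yc - y_hat) @ (yc - y_hat)) / ss_tot
    return OplsDaModel(
        classes=classes,
        x_mean=mean,
        x_sd=sd,
        y_mean=float(y_mean),
        weights=core["w"],
        loadings=core["p"],
        scores=core["t"],
        y_loading=float(core["q"]),
        ortho_weights=core["W_o"],
        ortho_loadings=core["P_o"],
        ortho_scores=core["T_o"],
        n_ortho=int(n_ortho),
        r2y=r2y,
        variable_ids=list(variable_ids) if variable_ids is not None else [],
    )


def predict(model: OplsDaModel, X) -> np.ndarray:
    """Continuous predictions of the centered -1/+1 class variable."""
    X = np.asarray(X, dtype=float)
    Xs = (X - model.x_mean) / model.x_sd
    for k in range(model.n_ortho):
        t_o = Xs @ model.ortho_weights[:, k]
        Xs = Xs - np.outer(t_o, model.ortho_loadings[:, k])
    return (Xs @ model.weights) * model.y_loading + model.y_mean


def _stratified_folds(y01: np.ndarray, folds: int, rng: np.random.Generator):
    """Deal each class round-robin into folds after a seeded shuffle."""
    assign = np.empty(len(y01), dtype=int)
    for cls in (0, 1):
        idx = np.flatnonzero(y01 == cls)
        rng.shuffle(idx)
        assign[idx] = np.arange(len(idx)) % folds
    return assign


@dataclass
class CvResult:
    q2y: float
    y_pred: np.ndarray  # out-of-fold continuous predictions (centered scale)
    press: float
    ss_tot: float
    fold_assignment: np.ndarray
    n_ortho: int


def cross_validate(X, y, n_ortho: int = 0, folds: int = 7, seed: int = 0) -> CvResult:
    """Stratified k-fold CV with no information leakage.

    Scaling parameters and the model are re-estimated inside every
    training fold; Q2Y = 1 - PRESS/SS with SS the total centered sum of
    squares of the -1/+1 class variable. Folds leaving a single class in
    a training split are re-dealt with a fresh sub-seed (max 10 attempts).
    """
    X = np.asarray(X, dtype=float)
    yc_raw, _ = _encode_y(y)
    y01 = (yc_raw > 0).astype(int)
    folds = min(folds, len(y01))
    rng = np.random.default_rng(seed)
    for _attempt in range(10):
        assign = _stratified_folds(y01, folds, rng)
        ok = all(
            len(np.unique(y01[assign != k])) == 2 for k in range(folds)
        )
        if ok:
            break
    else:
        raise ValueError("could not build folds with both classes in training")

    y_mean_all = yc_raw.mean()
    yc_all = yc_raw - y_mean_all
    y_pred = np.empty_like(yc_raw)
    for k in range(folds):
        train, test = assign != k, assign == k
        if not test.any():
            continue
        model = fit_oplsda(X[train], yc_raw[train], n_ortho=n_ortho)
        y_pred[test] = predict(model, X[test]) - y_mean_all
    press = float((yc_all - y_pred) @ (yc_all - y_pred))
    ss_tot = float(yc_all @ yc_all)
    return CvResult(
        q2y=1.0 - press / ss_tot,
        y_pred=y_pred,
        press=press,
        ss_tot=ss_tot,
        fold_assignment=assign,
        n_ortho=int(n_ortho),
    )


def _auto_n_ortho(X, y, folds: int = 7, seed: int = 0) -> int:
    best_q2 = cross_validate(X, y, n_ortho=0, folds=folds, seed=seed).q2y
    n_ortho = 0
    for k in range(1, _MAX_AUTO_ORTHO + 1):
        try:
            q2 = cross_validate(X, y, n_ortho=k, folds=folds, seed=seed).q2y
        except ValueError:
            break
        if q2 > best_q2 + _AUTO_Q2_GAIN:
            best_q2, n_ortho = q2, k
        else:
            break
    return n_ortho


@dataclass
class CvAnovaResult:
    f_statistic: float
    df_model: int
    df_residual: int
    p_value: float


def cv_anova(cv: CvResult, y, model: OplsDaModel) -> CvAnovaResult:
    """F-test of cross-validated residuals against total variation.

    F = ((SS_tot - PRESS)/A) / (PRESS/(N - A - 1)) with A the total number
    of fitted components (predictive + orthogonal); the difference is
    floored at zero so a worthless model gives F = 0, p = 1.
    """
    yc_raw, _ = _encode_y(y)
    n = len(yc_raw)
    a = 1 + model.n_ortho
    d2 = n - a - 1
    if d2 <= 0:
        raise ValueError(f"too few samples (N={n}) for {a} components in CV-ANOVA")
    explained = max(cv.ss_tot - cv.press, 0.0)
    f = (explained / a) / (cv.press / d2) if cv.press > 0 else np.inf
    p = float(stats.f.sf(f, a, d2)) if np.isfinite(f) else 0.0
    return CvAnovaResult(f_statistic=float(f), df_model=a, df_residual=d2, p_value=p)


@dataclass
class PermutationSummary:
    n_iterations: int
    observed_r2y: float
    observed_q2y: float
    permuted_r2y: np.ndarray
    permuted_q2y: np.ndarray
    y_correlations: np.ndarray  # |corr| of each permuted y with original
    p_q2: float  # (1 + #{permuted Q2 >= observed}) / (n + 1)
    r2_intercept: float
    q2_intercept: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "correlation": self.y_correlations,
                "r2y": self.permuted_r2y,
                "q2y": self.permuted_q2y,
            }
        )


def permutation_test(
    X,
    y,
    n_ortho: int = 0,
    n_iterations: int = 1000,
    seed: int = 0,
    folds: int = 7,
) -> PermutationSummary:
    """Label-permutation validation with identical model settings.

    Each iteration permutes y, refits the model and its cross-validation,
    and records R2Y/Q2Y together with |corr(y_perm, y)|. The intercepts
    of the least-squares lines of R2Y and Q2Y on |correlation| (observed
    point included at correlation 1) summarize the permutation plot; the
    add-one estimator keeps p_Q2 >= 1/(n+1), so an identical permutation
    can never drive p to zero.
    """
    import warnings as _warnings

    if n_iterations < 20:
        _warnings.warn(
            f"only {n_iterations} permutations: p-value resolution is "
            f">= {1.0 / (n_iterations + 1):.3f}"
        )
    X = np.asarray(X, dtype=float)
    yc_raw, _ = _encode_y(y)
    rng = np.random.default_rng(seed)

    observed_model = fit_oplsda(X, yc_raw, n_ortho=n_ortho)
    observed_cv = cross_validate(X, yc_raw, n_ortho=n_ortho, folds=folds,
                                 seed=int(rng.integers(2**31 - 1)))
    r2s = np.empty(n_iterations)
    q2s = np.empty(n_iterations)
    corrs = np.empty(n_iterations)
    for i in range(n_iterations):
        y_perm = rng.permutation(yc_raw)
        corrs[i] = abs(float(np.corrcoef(y_perm, yc_raw)[0, 1]))
        r2s[i] = fit_oplsda(X, y_perm, n_ortho=n_ortho).r2y
        q2s[i] = cross_validate(
            X, y_perm, n_ortho=n_ortho, folds=folds,
            seed=int(rng.integers(2**31 - 1)),
        ).q2y
    p_q2 = (1 + int(np.sum(q2s >= observed_cv.q2y))) / (n_iterations + 1)

    xs = np.append(corrs, 1.0)
    r2_line = np.polynomial.polynomial.polyfit(xs, np.append(r2s, observed_model.r2y), 1)
    q2_line = np.polynomial.polynomial.polyfit(xs, np.append(q2s, observed_cv.q2y), 1)
    return PermutationSummary(
        n_iterations=n_iterations,
        observed_r2y=observed_model.r2y,
        observed_q2y=observed_cv.q2y,
        permuted_r2y=r2s,
        permuted_q2y=q2s,
        y_correlations=corrs,
        p_q2=p_q2,
        r2_intercept=float(r2_line[0]),
        q2_intercept=float(q2_line[0]),
    )


def vip_scores(
    X, y, model: OplsDaModel, folds: int = 7, seed: int = 0
) -> pd.DataFrame:
    """VIP scores on the predictive component with jackknife intervals.

    For a single predictive component VIP_j = sqrt(p) * |w_j| (w unit
    norm), which guarantees sum(VIP^2) equals the number of variables.
    Confidence intervals come from a jackknife over the k CV training
    subsets: mean +/- t_{0.975, k-1} * jackknife SE. Ranks (1 = most
    discriminant) follow the full-model VIP, ties broken by variable id.
    """
    X = np.asarray(X, dtype=float)
    yc_raw, _ = _encode_y(y)
    n, p = X.shape
    vip_full = np.sqrt(p) * np.abs(model.weights)

    cv = cross_validate(X, yc_raw, n_ortho=model.n_ortho, folds=folds, seed=seed)
    k = int(cv.fold_assignment.max()) + 1
    vip_k = np.empty((k, p))
    for fold in range(k):
        train = cv.fold_assignment != fold
        sub = fit_oplsda(X[train], yc_raw[train], n_ortho=model.n_ortho)
        vip_k[fold] = np.sqrt(p) * np.abs(sub.weights)
    vbar = vip_k.mean(axis=0)
    se = np.sqrt((k - 1) / k * ((vip_k - vbar) ** 2).sum(axis=0))
    t_crit = stats.t.ppf(0.975, df=k - 1)

    ids = model.variable_ids if model.variable_ids else [str(j) for j in range(p)]
    order = np.lexsort((np.asarray(ids, dtype=object), -vip_full))
    ranks = np.empty(p, dtype=int)
    ranks[order] = np.arange(1, p + 1)
    return pd.DataFrame(
        {
            "vip": vip_full,
            "ci_lower": vbar - t_crit * se,
            "ci_upper": vbar + t_crit * se,
            "rank": ranks,
        },
        index=pd.Index(ids, name="variable"),
    )


def select_variables(vip_table: pd.DataFrame, top_n: int = 30) -> list[str]:
    """Variables ranked in the top ``top_n`` whose VIP CI excludes zero."""
    keep = (vip_table["rank"] <= top_n) & (vip_table["ci_lower"] > 0)
    return list(vip_table.index[keep])
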