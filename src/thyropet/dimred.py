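"""Per-training-split dimensionality reduction of the radiomic feature set.

With ~214 features and ~84 patients the feature matrix is wide; the workflow
is: z-standardise on training statistics, greedily drop features until no
retained pair correlates above |r| = 0.9, fit a maximum-likelihood factor
model with one factor per ten training subjects (varimax-rotated), and project
cases onto regression (Thomson) factor scores. Test cases never touch the
fit: standardisation means/sds, the retained set, loadings and score weights
all come from the training split alone. The Kaiser–Meyer–Olkin statistic
diagnoses sampling adequacy of the retained correlation matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import FactorAnalysis


def n_factors_rule(n_train: int) -> int:
    """One factor per ten training subjects, at least one."""
    return max(n_train // 10, 1)


@dataclass
class Standardiser:
    """Column-wise z-scoring with training-split statistics."""

    mean: pd.Series
    sd: pd.Series

    @classmethod
    def fit(cls, frame: pd.DataFrame) -> "Standardiser":
        sd = frame.std(ddof=1)
        return cls(mean=frame.mean(), sd=sd.where(sd > 0, 1.0))

    def transform(self, frame: pd.DataFrame) -> pd.DataFrame:
        return (frame[self.mean.index] - self.mean) / self.sd


def redundancy_filter(train_features: pd.DataFrame, threshold: float = 0.9) -> list[str]:
    """Greedy redundancy filtering on the training correlation matrix.

    Constant (zero-variance) features are removed first with a warning (their
    correlation is undefined). Then, while any retained pair has
    |Pearson r| > threshold, the feature with the most super-threshold
    partners is dropped; ties break deterministically on the feature name.
    """
    if len(train_features) < 2:
        raise ValueError("need at least two cases to correlate features")
    cols = list(train_features.columns)
    constant = [c for c in cols if train_features[c].nunique() <= 1]
    if constant:
        warnings.warn(f"removed {len(constant)} constant feature(s)", stacklevel=2)
    retained = [c for c in cols if c not in set(constant)]
    corr = train_features[retained].corr().abs().to_numpy()
    np.fill_diagonal(corr, 0.0)
    sort_keys = np.array([str(n) for n in retained])  # tie-break on name only
    alive = np.ones(len(retained), dtype=bool)
    while True:
        sub = corr[np.ix_(alive, alive)]
        over = sub > threshold
        counts = over.sum(axis=1)
        if counts.max(initial=0) == 0:
            break
        idx_alive = np.flatnonzero(alive)
        order = np.lexsort((sort_keys[idx_alive], -counts))  # most partners, then name
        alive[idx_alive[order[0]]] = False
    return [retained[i] for i in np.flatnonzero(alive)]


def _varimax(loadings: np.ndarray, tol: float = 1e-10, max_iter: int = 500) -> np.ndarray:
    """Kaiser varimax rotation (orthogonal)."""
    p, k = loadings.shape
    if k < 2:
        return loadings.copy()
    rotation = np.eye(k)
    var_old = 0.0
    for _ in range(max_iter):
        lam = loadings @ rotation
        u, s, vt = np.linalg.svd(
            loadings.T @ (lam**3 - (lam * (lam**2).sum(axis=0)) / p)
        )
        rotation = u @ vt
        var_new = s.sum()
        if var_new - var_old < tol * max(var_new, 1.0):
            break
        var_old = var_new
    return loadings @ rotation


@dataclass
class FactorModel:
    """Fitted factor-analysis model with projection weights.

    ``loadings`` is (features x factors) on the retained, standardised
    features; ``score_weights`` are the Thomson regression weights
    ``Sigma^{-1} Lambda`` with ``Sigma = Lambda Lambda' + Psi`` the
    model-implied correlation matrix.
    """

    retained_feature_names: list[str]
    loadings: np.ndarray
    uniquenesses: np.ndarray
    score_weights: np.ndarray
    n_factors: int
    kmo: float
    standardiser: Standardiser
    rotation: str = "varimax"

    @property
    def communalities(self) -> np.ndarray:
        return (self.loadings**2).sum(axis=1)

    def to_dict(self) -> dict:
        return {
            "retained_feature_names": self.retained_feature_names,
            "loadings": self.loadings.tolist(),
            "uniquenesses": self.uniquenesses.tolist(),
            "score_weights": self.score_weights.tolist(),
            "n_factors": self.n_factors,
            "kmo": self.kmo,
            "rotation": self.rotation,
        }

    def top_loading_features(self, k: int = 3) -> list[list[str]]:
        """Per factor, the k features with the largest |loading|."""
        out = []
        names = np.array(self.retained_feature_names)
        for f in range(self.n_factors):
            order = np.argsort(-np.abs(self.loadings[:, f]))[:k]
            out.append(list(names[order]))
        return out


def compute_kmo(train_features: pd.DataFrame, ridge: float | None = None) -> float:
    """Kaiser–Meyer–Olkin sampling-adequacy statistic on the correlation matrix.

    KMO = sum r^2 / (sum r^2 + sum partial^2) over off-diagonal entries, with
    partial correlations from the inverse correlation matrix. If the matrix is
    singular, the smallest ridge λ from {1e-6, 1e-5, ...} restoring positive
    definiteness is added (and noted via warning).
    """
    corr = np.corrcoef(np.asarray(train_features, dtype=float), rowvar=False)
    corr = np.atleast_2d(corr)
    p = corr.shape[0]
    ridges = [0.0, 1e-6, 1e-5, 1e-4, 1e-3, 1e-2] if ridge is None else [ridge]
    inv = None
    for lam in ridges:
        reg = corr + lam * np.eye(p)
        try:
            np.linalg.cholesky(reg)
            inv = np.linalg.inv(reg)
            if lam > 0:
                warnings.warn(f"KMO: correlation matrix regularised with ridge {lam}", stacklevel=2)
            break
        except np.linalg.LinAlgError:
            continue
    if inv is None:
        raise ValueError("correlation matrix singular even after regularisation")
    d = np.sqrt(np.diag(inv))
    partial = -inv / np.outer(d, d)
    off = ~np.eye(p, dtype=bool)
    r2 = (corr[off] ** 2).sum()
    a2 = (partial[off] ** 2).sum()
    return float(r2 / (r2 + a2))


def fit_factor_model(
    train_features: pd.DataFrame,
    n_factors: int | None = None,
    threshold: float = 0.9,
    prefiltered: bool = False,
) -> FactorModel:
    """Redundancy-filter and fit the ML factor model on a training split.

    ``n_factors`` defaults to the one-per-ten-subjects rule. Factors are
    varimax-rotated, ordered by explained variance, and sign-fixed so each
    factor's largest-magnitude loading is positive.
    """
    n_train = len(train_features)
    if n_factors is None:
        n_factors = n_factors_rule(n_train)
    if n_factors < 1:
        raise ValueError("need at least one factor")
    if n_train <= n_factors:
        raise ValueError("need more cases than factors")

    standardiser = Standardiser.fit(train_features)
    z = standardiser.transform(train_features)
    retained = list(z.columns) if prefiltered else redundancy_filter(z, threshold)
    z = z[retained]
    # re-standardise the retained block so the FA covariance is a correlation
    standardiser = Standardiser.fit(train_features[retained])
    z = standardiser.transform(train_features[retained])

    fa = FactorAnalysis(n_components=n_factors, svd_method="lapack", max_iter=5000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fa.fit(z.to_numpy())
    loadings = fa.components_.T  # (features x factors)
    uniq = np.clip(fa.noise_variance_, 1e-6, None)
    if np.any(fa.noise_variance_ < 1e-6):
        warnings.warn("Heywood case: uniquenesses bounded below at 1e-6", stacklevel=2)

    loadings = _varimax(loadings)
    # order factors by explained variance, fix signs deterministically
    order = np.argsort(-(loadings**2).sum(axis=0), kind="stable")
    loadings = loadings[:, order]
    for f in range(loadings.shape[1]):
        j = np.argmax(np.abs(loadings[:, f]))
        if loadings[j, f] < 0:
            loadings[:, f] = -loadings[:, f]

    sigma = loadings @ loadings.T + np.diag(uniq)
    score_weights = np.linalg.solve(sigma, loadings)
    kmo = compute_kmo(z)
    return FactorModel(
        retained_feature_names=retained,
        loadings=loadings,
        uniquenesses=uniq,
        score_weights=score_weights,
        n_factors=n_factors,
        kmo=kmo,
        standardiser=standardiser,
    )


def project_scores(model: FactorModel, features: pd.DataFrame) -> np.ndarray:
    """Thomson regression factor scores for (train or test) cases.

    Features are standardised with the training means/sds; missing retained
    columns raise.
    """
    missing = [c for c in model.retained_feature_names if c not in features.columns]
    if missing:
        raise ValueError(f"missing feature columns: {missing[:5]}")
    z = model.standardiser.transform(features[model.retained_feature_names])
    return z.to_numpy() @ model.score_weights
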