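"""PCA and PLS-DA ordination with VIP scores and cross-validated Q2.

PCA follows the usual SVD route on centered (optionally unit-variance
scaled) data, with orthonormal loadings and a fixed sign convention (the
largest-magnitude loading of each component is positive). PLS-DA fits a
NIPALS partial-least-squares regression of 0/1-coded class membership on
the scaled feature matrix; per-feature variable-importance-in-projection
(VIP) scores satisfy mean(VIP^2) = 1, and features with VIP > 0.9 are
flagged as discriminative. Predictive accuracy Q2Y = 1 - PRESS/TSS comes
from k-fold cross-validation (k = 7 by default, a common chemometrics
choice) with a seeded partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA as _SKPCA
from sklearn.model_selection import StratifiedKFold

from .containers import FeatureTable

DEFAULT_VIP_THRESHOLD = 0.9
DEFAULT_CV_FOLDS = 7


@dataclass
class OrdinationResult:
    """Scores/loadings of a PCA or PLS-DA fit.

    ``explained_variance`` holds per-component proportions (PCA);
    ``r2x``/``r2y``/``q2y`` and ``vip`` are populated for PLS-DA fits.
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance: np.ndarray
    method: str
    mean_: np.ndarray = field(default=None, repr=False)
    scale_: np.ndarray = field(default=None, repr=False)
    r2x: float | None = None
    r2y: float | None = None
    q2y: float | None = None
    vip: pd.Series | None = None
    vip_threshold: float = DEFAULT_VIP_THRESHOLD
    dropped_features: list[str] = field(default_factory=list)

    @property
    def discriminative_ids(self) -> list[str]:
        if self.vip is None:
            return []
        return list(self.vip.index[self.vip > self.vip_threshold])


def _prepare(values: pd.DataFrame, scale: str) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str], list[str]]:
    """Center (and optionally scale) a samples x features matrix.

    Zero-variance features are dropped under scaling (returned separately).
    """
    X = values.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    dropped: list[str] = []
    cols = list(values.columns)
    if scale in ("unit-variance", "pareto"):
        keep = sd > 0
        dropped = [c for c, k in zip(cols, keep) if not k]
        cols = [c for c, k in zip(cols, keep) if k]
        X = X[:, keep]
        sd = sd[keep]
    mean = X.mean(axis=0)
    if scale == "unit-variance":
        denom = sd
    elif scale == "pareto":
        denom = np.sqrt(sd)
    elif scale == "none":
        denom = np.ones_like(mean)
    else:
        raise ValueError(f"unknown scaling {scale!r}")
    return (X - mean) / denom, mean, denom, cols, dropped


def pca(
    table: FeatureTable, scale: str = "none", n_components: int | None = None
) -> OrdinationResult:
    """Principal component analysis of a feature table.

    Loadings are orthonormal, scores = centered data x loadings, and signs
    are fixed so the largest-magnitude loading per component is positive.
    """
    if table.n_samples < 2 or table.n_features < 2:
        raise ValueError("need at least 2 samples and 2 features")
    Xc, mean, denom, cols, dropped = _prepare(table.values, scale)
    max_comp = min(table.n_samples - 1, len(cols))
    if n_components is None:
        n_components = max_comp
    if n_components > max_comp:
        raise ValueError(f"n_components must be <= {max_comp}")
    fit = _SKPCA(n_components=n_components, svd_solver="full").fit(Xc)
    load = fit.components_.T  # features x components
    scores = Xc @ load
    # sign convention: largest-magnitude loading positive
    for k in range(load.shape[1]):
        j = np.argmax(np.abs(load[:, k]))
        if load[j, k] < 0:
            load[:, k] *= -1
            scores[:, k] *= -1
    comps = [f"PC{k + 1}" for k in range(n_components)]
    return OrdinationResult(
        scores=pd.DataFrame(scores, index=table.sample_ids, columns=comps),
        loadings=pd.DataFrame(load, index=cols, columns=comps),
        explained_variance=fit.explained_variance_ratio_.copy(),
        method="pca",
        mean_=mean,
        scale_=denom,
        dropped_features=dropped,
    )


def _vip_scores(pls: PLSRegression, feature_ids: list[str]) -> pd.Series:
    W = pls.x_weights_  # columns unit-norm
    T = pls.x_scores_
    Q = pls.y_loadings_
    ssy = (Q.ravel() ** 2) * (T**2).sum(axis=0)
    p = W.shape[0]
    vip = np.sqrt(p * (W**2 * (ssy / ssy.sum())).sum(axis=1))
    return pd.Series(vip, index=feature_ids, name="vip")


def plsda_vip(
    table: FeatureTable,
    labels,
    n_components: int = 2,
    cv_folds: int = DEFAULT_CV_FOLDS,
    scale: str = "unit-variance",
    vip_threshold: float = DEFAULT_VIP_THRESHOLD,
    seed: int = 0,
) -> OrdinationResult:
    """PLS-DA of a binary grouping with VIP scores and cross-validated Q2Y.

    ``labels`` is a binary class per sample (any two values). Both classes
    need >= 3 samples.
    """
    y_raw = pd.Series(list(labels), index=table.sample_ids)
    classes = sorted(y_raw.unique())
    if len(classes) != 2:
        raise ValueError("PLS-DA requires exactly two classes")
    y = (y_raw == classes[1]).to_numpy(dtype=float)
    if min((y == 0).sum(), (y == 1).sum()) < 3:
        raise ValueError("each class needs at least 3 samples")

    Xs, mean, denom, cols, dropped = _prepare(table.values, scale)
    n_components = min(n_components, Xs.shape[0] - 1, len(cols))
    pls = PLSRegression(n_components=n_components, scale=False)
    yc = y - y.mean()
    pls.fit(Xs, yc)

    ss_x = (Xs**2).sum()
    Xhat = pls.x_scores_ @ pls.x_loadings_.T
    r2x = float(1 - ((Xs - Xhat) ** 2).sum() / ss_x)
    yhat = pls.predict(Xs).ravel()
    tss = (yc**2).sum()
    r2y = float(1 - ((yc - yhat) ** 2).sum() / tss)

    # cross-validated Q2: PRESS from per-fold refits on the scaled matrix
    folds = min(cv_folds, int((y == 0).sum()), int((y == 1).sum()))
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    press = 0.0
    for tr, te in cv.split(Xs, y):
        sub = PLSRegression(n_components=min(n_components, len(tr) - 1), scale=False)
        sub.fit(Xs[tr], yc[tr])
        pred = sub.predict(Xs[te]).ravel()
        press += ((yc[te] - pred) ** 2).sum()
    q2y = float(1 - press / tss)

    comps = [f"LV{k + 1}" for k in range(n_components)]
    return OrdinationResult(
        scores=pd.DataFrame(pls.x_scores_, index=table.sample_ids, columns=comps),
        loadings=pd.DataFrame(pls.x_loadings_, index=cols, columns=comps),
        explained_variance=np.array(
            [(pls.x_scores_[:, k] ** 2).sum() / ss_x for k in range(n_components)]
        ),
        method="plsda",
        mean_=mean,
        scale_=denom,
        r2x=r2x,
        r2y=r2y,
        q2y=q2y,
        vip=_vip_scores(pls, cols),
        vip_threshold=vip_threshold,
        dropped_features=dropped,
    )
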