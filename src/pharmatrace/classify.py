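"""Origin classification: discriminant analysis of principal components
(DAPC), kernel discriminant analysis (KDA), leave-one-out cross-validation
and held-out membership prediction.

DAPC centers the feature matrix, projects onto the smallest number of
principal components reaching the target cumulative variance (~90 % by
default, capped so the subsequent LDA stays solvable), and fits a linear
discriminant with equal class priors on the retained scores.  KDA performs
kernel Fisher discriminant analysis with a radial-basis kernel
(median-pairwise-distance bandwidth by default) and Gaussian posteriors on
distances to class means in the discriminant space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

__all__ = [
    "DiscriminantModel",
    "MembershipPrediction",
    "fit_dapc",
    "fit_kda",
    "loocv",
    "predict_membership",
    "median_heuristic_bandwidth",
]


@dataclass
class DiscriminantModel:
    kind: str  # 'dapc' | 'kda'
    classes: list
    feature_names: list
    center: np.ndarray
    scale: np.ndarray | None = None
    # dapc
    rotation: np.ndarray | None = None  # features x retained PCs
    n_pcs: int | None = None
    explained: float | None = None
    lda: LinearDiscriminantAnalysis | None = None
    # kda
    bandwidth: float | None = None
    train_x: np.ndarray | None = None
    alphas: np.ndarray | None = None  # n_train x n_axes
    class_means_: np.ndarray | None = None  # classes x n_axes
    axis_var: np.ndarray | None = None

    def _prepare(self, queries: pd.DataFrame) -> np.ndarray:
        cols = list(queries.columns)
        missing = [f for f in self.feature_names if f not in cols]
        overlap = [f for f in self.feature_names if f in cols]
        if not overlap:
            raise ValueError("queries share no features with the model")
        if missing:
            warnings.warn(
                f"{len(missing)} model feature(s) absent from queries; imputed as 0",
                stacklevel=3,
            )
        x = np.zeros((len(queries), len(self.feature_names)))
        for j, f in enumerate(self.feature_names):
            if f in queries.columns:
                x[:, j] = queries[f].to_numpy(float)
        x = x - self.center
        if self.scale is not None:
            x = x / self.scale
        return x


@dataclass
class MembershipPrediction:
    posteriors: pd.DataFrame  # query x class, rows sum to 1
    assigned: pd.Series
    tie: pd.Series

    def for_sample(self, sid) -> pd.Series:
        return self.posteriors.loc[sid]


def _as_frame(features) -> pd.DataFrame:
    if isinstance(features, pd.DataFrame):
        return features
    return pd.DataFrame(np.asarray(features, float))


def fit_dapc(
    features, labels, var_target: float = 0.90, scale: bool = False
) -> DiscriminantModel:
    """Fit a DAPC model: PCA to ~``var_target`` cumulative variance, then
    LDA with equal priors on the retained PC scores."""
    x_df = _as_frame(features)
    labels = np.asarray(labels)
    if not 0 < var_target <= 1:
        raise ValueError("var_target must lie in (0, 1]")
    classes = sorted(pd.unique(labels))
    if len(classes) < 2:
        raise ValueError("need >= 2 classes")
    sizes = pd.Series(labels).value_counts()
    if (sizes < 2).any():
        raise ValueError(f"every class needs >= 2 samples: {sizes.to_dict()}")
    x = x_df.to_numpy(float)
    n, p = x.shape
    center = x.mean(axis=0)
    xc = x - center
    sd = None
    if scale:
        sd = xc.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        xc = xc / sd
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    var = s**2
    keep_rank = var > var[0] * 1e-12 if len(var) else np.zeros(0, bool)
    var = var[keep_rank]
    vt = vt[keep_rank]
    cum = np.cumsum(var) / var.sum()
    k = int(np.searchsorted(cum, var_target - 1e-12) + 1)
    k = min(k, max(1, n - len(classes)))  # keep the within-class scatter nonsingular
    if k == 0:
        raise ValueError("no principal components retained")
    rotation = vt[:k].T
    scores = xc @ rotation
    lda = LinearDiscriminantAnalysis(priors=np.full(len(classes), 1 / len(classes)))
    lda.fit(scores, labels)
    return DiscriminantModel(
        kind="dapc",
        classes=list(lda.classes_),
        feature_names=list(x_df.columns),
        center=center,
        scale=sd,
        rotation=rotation,
        n_pcs=k,
        explained=float(cum[k - 1]),
        lda=lda,
    )


def median_heuristic_bandwidth(x: np.ndarray) -> float:
    d = pdist(x)
    d = d[d > 0]
    if len(d) == 0:
        return 1.0
    return float(np.median(d))


def fit_kda(features, labels, bandwidth: float | None = None, reg: float = 1e-6
            ) -> DiscriminantModel:
    """Kernel Fisher discriminant analysis with an RBF kernel.

    Solves the generalized eigenproblem of between-class vs regularized
    within-class scatter in the kernel-induced space; posteriors come from
    a Gaussian model on distances to class means along the discriminant
    axes (pooled per-axis within-class variance, equal priors).
    """
    x_df = _as_frame(features)
    labels = np.asarray(labels)
    classes = sorted(pd.unique(labels))
    if len(classes) < 2:
        raise ValueError("need >= 2 classes")
    x = x_df.to_numpy(float)
    center = x.mean(axis=0)
    xc = x - center
    if bandwidth is None:
        bandwidth = median_heuristic_bandwidth(xc)
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    n = len(xc)
    gamma = 1.0 / (2.0 * bandwidth**2)
    sq = ((xc[:, None, :] - xc[None, :, :]) ** 2).sum(-1)
    k_mat = np.exp(-gamma * sq)

    m_tot = k_mat.mean(axis=1)
    m_between = np.zeros((n, n))
    n_within = np.zeros((n, n))
    for c in classes:
        idx = np.where(labels == c)[0]
        k_c = k_mat[:, idx]
        m_c = k_c.mean(axis=1)
        diff = m_c - m_tot
        m_between += len(idx) * np.outer(diff, diff)
        center_mat = np.eye(len(idx)) - np.full((len(idx), len(idx)), 1.0 / len(idx))
        n_within += k_c @ center_mat @ k_c.T
    n_within += reg * np.trace(k_mat) / n * np.eye(n) + reg * np.eye(n)

    vals, vecs = np.linalg.eig(np.linalg.solve(n_within, m_between))
    order = np.argsort(vals.real)[::-1]
    n_axes = len(classes) - 1
    alphas = vecs[:, order[:n_axes]].real
    proj = k_mat @ alphas
    # normalize axes to unit pooled within-class variance
    for j in range(n_axes):
        sw = 0.0
        for c in classes:
            idx = labels == c
            sw += proj[idx, j].var(ddof=0) * idx.sum()
        sd = np.sqrt(sw / n) if sw > 0 else 1.0
        alphas[:, j] /= sd if sd > 0 else 1.0
    proj = k_mat @ alphas
    class_means = np.stack([proj[labels == c].mean(axis=0) for c in classes])
    pooled = np.zeros(n_axes)
    for c in classes:
        idx = labels == c
        pooled += ((proj[idx] - proj[idx].mean(axis=0)) ** 2).sum(axis=0)
    axis_var = np.maximum(pooled / max(n - len(classes), 1), 1e-12)
    return DiscriminantModel(
        kind="kda",
        classes=classes,
        feature_names=list(x_df.columns),
        center=center,
        bandwidth=float(bandwidth),
        train_x=xc,
        alphas=alphas,
        class_means_=class_means,
        axis_var=axis_var,
    )


def predict_membership(model: DiscriminantModel, queries) -> MembershipPrediction:
    """Posterior class membership for query samples.

    Missing model features are imputed as zero with a warning; exact
    posterior ties are broken to the lexicographically first class and
    flagged.
    """
    q_df = _as_frame(queries)
    x = model._prepare(q_df)
    if model.kind == "dapc":
        scores = x @ model.rotation
        post = model.lda.predict_proba(scores)
    elif model.kind == "kda":
        gamma = 1.0 / (2.0 * model.bandwidth**2)
        sq = ((x[:, None, :] - model.train_x[None, :, :]) ** 2).sum(-1)
        k_q = np.exp(-gamma * sq)
        proj = k_q @ model.alphas
        log_like = np.zeros((len(x), len(model.classes)))
        for ci in range(len(model.classes)):
            d2 = (proj - model.class_means_[ci]) ** 2 / model.axis_var
            log_like[:, ci] = -0.5 * d2.sum(axis=1)
        log_like -= log_like.max(axis=1, keepdims=True)
        post = np.exp(log_like)
        post /= post.sum(axis=1, keepdims=True)
    else:
        raise ValueError(f"unknown model kind {model.kind!r}")
    posteriors = pd.DataFrame(post, index=q_df.index, columns=model.classes)
    top = posteriors.max(axis=1)
    tie = (posteriors.apply(lambda r: (np.isclose(r, r.max(), atol=1e-9)).sum(), axis=1) > 1)
    assigned = posteriors.idxmax(axis=1)  # idxmax takes the first (lexicographic) on ties
    return MembershipPrediction(posteriors=posteriors, assigned=assigned, tie=tie)


def loocv(
    fitter: Callable[[pd.DataFrame, np.ndarray], DiscriminantModel],
    features,
    labels,
) -> tuple[pd.DataFrame, float]:
    """Leave-one-out cross-validation of a fitter.

    ``fitter(train_features, train_labels)`` must return a model usable by
    :func:`predict_membership`; any feature selection belonging to the
    fitter is therefore re-run inside every fold, so the held-out sample
    never influences its own prediction.  Folds that would empty a class
    are flagged and excluded from the accuracy.
    """
    x_df = _as_frame(features)
    labels = np.asarray(labels)
    n = len(x_df)
    classes = pd.unique(labels)
    if n < len(classes) + 1:
        raise ValueError("need at least #classes + 1 samples for LOOCV")
    rows = []
    correct = used = 0
    for i in range(n):
        train_idx = np.arange(n) != i
        train_labels = labels[train_idx]
        if len(pd.unique(train_labels)) < len(classes):
            warnings.warn(
                f"fold {x_df.index[i]!r} would empty a class; excluded from accuracy",
                stacklevel=2,
            )
            rows.append({"sample": x_df.index[i], "true": labels[i], "predicted": None,
                         "correct": None})
            continue
        model = fitter(x_df.iloc[train_idx], train_labels)
        pred = predict_membership(model, x_df.iloc[[i]])
        got = pred.assigned.iloc[0]
        ok = bool(got == labels[i])
        rows.append(
            {
                "sample": x_df.index[i],
                "true": labels[i],
                "predicted": got,
                "correct": ok,
                **{f"p_{c}": pred.posteriors.iloc[0][c] for c in model.classes},
            }
        )
        used += 1
        correct += ok
    if used == 0:
        raise ValueError("no usable LOOCV folds")
    return pd.DataFrame(rows).set_index("sample"), correct / used
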