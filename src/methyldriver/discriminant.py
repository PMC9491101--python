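"""Two-class regularized linear discriminant analysis and ROC evaluation.

The discriminant direction is w = S_lambda^-1 (mu_pos - mu_neg) with
S_lambda = (1 - lambda) * S_pooled + lambda * diag(S_pooled): shrinkage
toward the diagonal keeps the pooled covariance invertible when features
approach or exceed samples, and lambda = 1 degrades gracefully to diagonal
LDA.  "auto" picks lambda by a Schafer-Strimmer-style estimate of the
optimal diagonal-target intensity.  AUC is computed by the rank method and
equals the Mann-Whitney U statistic over score pairs with ties counted 1/2.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import linalg, stats


@dataclass
class DiscriminantModel:
    features: list[str]
    positive: str
    negative: str
    mu_pos: np.ndarray
    mu_neg: np.ndarray
    w: np.ndarray
    intercept: float
    shrinkage: float
    priors: dict[str, float]

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "features": self.features,
                "positive": self.positive,
                "negative": self.negative,
                "mu_pos": self.mu_pos.tolist(),
                "mu_neg": self.mu_neg.tolist(),
                "w": self.w.tolist(),
                "intercept": self.intercept,
                "shrinkage": self.shrinkage,
                "priors": self.priors,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "DiscriminantModel":
        p = Path(str(text_or_path))
        text = p.read_text() if p.exists() else str(text_or_path)
        d = json.loads(text)
        return cls(
            features=d["features"], positive=d["positive"], negative=d["negative"],
            mu_pos=np.array(d["mu_pos"]), mu_neg=np.array(d["mu_neg"]),
            w=np.array(d["w"]), intercept=d["intercept"],
            shrinkage=d["shrinkage"], priors=d["priors"],
        )


@dataclass
class RocResult:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


def split_train_test(
    labels: pd.Series, train_fraction: float = 0.7, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Class-stratified random split; per-class train count = round(f * n)."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    classes = sorted(labels.unique())
    if len(classes) < 2:
        raise ValueError("split requires two classes")
    rng = np.random.default_rng(seed)
    train: list[str] = []
    test: list[str] = []
    for cls in classes:
        ids = sorted(labels.index[labels == cls])
        if len(ids) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 samples")
        perm = rng.permutation(len(ids))
        n_train = int(np.floor(train_fraction * len(ids) + 0.5))
        train.extend(ids[i] for i in perm[:n_train])
        test.extend(ids[i] for i in perm[n_train:])
    return train, test


def _auto_shrinkage(W: np.ndarray, S: np.ndarray) -> float:
    """Schafer-Strimmer intensity toward the diagonal target.

    ``W`` holds class-centered observations (features x n); the estimate is
    lambda* = sum_{i != j} Var(s_ij) / sum_{i != j} s_ij^2, clipped to [0, 1].
    """
    n = W.shape[1]
    if n < 4:
        return 1.0
    P = (W @ W.T) / n  # mean of cross-products
    W2 = W * W
    Q = (W2 @ W2.T) / n  # mean of squared cross-products
    var_s = n**2 / (n - 1) ** 3 * (Q - P**2)
    off = ~np.eye(S.shape[0], dtype=bool)
    denom = float((S[off] ** 2).sum())
    if denom <= 0:
        return 1.0
    lam = float(var_s[off].sum()) / denom
    # conditioning floor: as features approach or exceed the sample count the
    # sample covariance turns near-singular and the plug-in estimate alone
    # leaves the weight vector estimation-noise dominated
    p = W.shape[0]
    return float(np.clip(max(lam, p / (p + n)), 0.0, 1.0))


def fit_lda(
    X: pd.DataFrame,
    labels: pd.Series,
    positive: str,
    shrinkage: float | str = "auto",
) -> DiscriminantModel:
    """Fit the two-class shrinkage LDA on a feature x sample matrix."""
    labels = labels.loc[X.columns]
    classes = sorted(labels.unique())
    if len(classes) != 2 or positive not in classes:
        raise ValueError("fit_lda requires exactly two classes including the positive one")
    negative = next(c for c in classes if c != positive)
    pos_ids = list(labels.index[labels == positive])
    neg_ids = list(labels.index[labels == negative])
    if len(pos_ids) < 2 or len(neg_ids) < 2:
        raise ValueError("each class needs at least 2 samples")

    Xp = X[pos_ids].to_numpy()
    Xn = X[neg_ids].to_numpy()
    mu_p = Xp.mean(axis=1)
    mu_n = Xn.mean(axis=1)
    W = np.hstack([Xp - mu_p[:, None], Xn - mu_n[:, None]])
    n = W.shape[1]
    S = (W @ W.T) / (n - 2)

    lam = _auto_shrinkage(W, S) if shrinkage == "auto" else float(shrinkage)
    if not 0.0 <= lam <= 1.0:
        raise ValueError("shrinkage must be in [0, 1] or 'auto'")
    diag = np.diag(np.diag(S))
    S_lam = (1.0 - lam) * S + lam * diag
    if lam > 0:
        # a zero-variance feature leaves a zero on the diagonal even after
        # shrinkage; floor it so shrunk fits degrade gracefully (its class
        # means are equal too, so its weight becomes 0)
        d = np.diag(S_lam).copy()
        floor = 1e-12 * max(float(d.max()), 1.0)
        np.fill_diagonal(S_lam, np.maximum(d, floor))
    try:
        c, low = linalg.cho_factor(S_lam)
        w = linalg.cho_solve((c, low), mu_p - mu_n)
    except linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "pooled covariance is singular (e.g. a constant feature with "
            "shrinkage 0); use shrinkage > 0 or 'auto'"
        ) from exc

    prior_p = len(pos_ids) / (len(pos_ids) + len(neg_ids))
    intercept = float(-0.5 * w @ (mu_p + mu_n) + np.log(prior_p / (1 - prior_p)))
    return DiscriminantModel(
        features=list(X.index), positive=positive, negative=negative,
        mu_pos=mu_p, mu_neg=mu_n, w=w, intercept=intercept, shrinkage=lam,
        priors={positive: prior_p, negative: 1 - prior_p},
    )


def score(model: DiscriminantModel, X: pd.DataFrame) -> pd.Series:
    """Scalar discriminant score per sample; affine in every feature."""
    missing = [f for f in model.features if f not in X.index]
    if missing:
        raise ValueError(f"matrix lacks model feature(s): {missing}")
    extra = set(X.index) - set(model.features)
    if extra:
        warnings.warn(f"{len(extra)} extra feature row(s) ignored")
    vals = X.loc[model.features].to_numpy()
    return pd.Series(model.w @ vals + model.intercept, index=X.columns)


def roc_auc(scores: pd.Series | np.ndarray, labels: pd.Series | np.ndarray, positive: str) -> RocResult:
    """ROC curve and rank-method AUC with ties shared as 1/2."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels) == positive
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires both classes present")
    ranks = stats.rankdata(s)
    auc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    # one point per distinct threshold
    distinct = np.r_[np.nonzero(np.diff(s_sorted))[0], len(s_sorted) - 1]
    tps = np.cumsum(y_sorted)[distinct]
    fps = np.cumsum(~y_sorted)[distinct]
    thresholds = np.r_[np.inf, s_sorted[distinct]]
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    return RocResult(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=float(auc))
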