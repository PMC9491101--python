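"""Iterated, stability-voted recursive feature elimination.

One RFE run ranks features by standardized discriminant weight, scores each
candidate subset size by cross-validated AUC, and keeps the size maximizing
it (ties -> smallest).  ``stability_select`` repeats the run with distinct
resampling seeds and keeps features appearing in at least ``vote`` of the
optimal subsets.  ``irfe`` reapplies stability selection to the surviving
submatrix until the panel stops shrinking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .discriminant import DiscriminantModel, fit_lda, roc_auc, score


@dataclass
class RfeRunResult:
    sizes: list[int]
    cv_auc: list[float]
    selected: list[str]
    ranking: list[str]


@dataclass
class StabilityPanel:
    n_runs: int
    vote: int
    counts: dict[str, int]
    survivors: list[str]
    generation: int
    history: list[int]
    converged: bool
    diagnostic: str = ""


def default_size_grid(n_features: int) -> list[int]:
    """Powers of 2 capped at the feature count, plus the full size."""
    sizes = []
    s = 1
    while s < n_features:
        sizes.append(s)
        s *= 2
    sizes.append(n_features)
    return sizes


def rank_features(model: DiscriminantModel, X: pd.DataFrame) -> list[str]:
    """Features by decreasing |w_i| * sd(feature_i); ties lexicographic."""
    sd = X.loc[model.features].std(axis=1, ddof=1).to_numpy()
    importance = np.abs(model.w) * sd
    order = sorted(range(len(model.features)), key=lambda i: (-importance[i], model.features[i]))
    return [model.features[i] for i in order]


def _stratified_folds(labels: pd.Series, folds: int, rng: np.random.Generator) -> list[list[str]]:
    assignments: list[list[str]] = [[] for _ in range(folds)]
    for cls in sorted(labels.unique()):
        ids = sorted(labels.index[labels == cls])
        perm = rng.permutation(len(ids))
        for pos, i in enumerate(perm):
            assignments[pos % folds].append(ids[i])
    return assignments


def rfe_once(
    X: pd.DataFrame,
    labels: pd.Series,
    positive: str,
    size_grid: list[int] | None = None,
    folds: int = 5,
    seed: int = 0,
    shrinkage: float | str = "auto",
) -> RfeRunResult:
    """One backward-elimination run scored by k-fold cross-validated AUC."""
    n_features = X.shape[0]
    grid = sorted(size_grid) if size_grid is not None else default_size_grid(n_features)
    if any(s < 1 or s > n_features for s in grid):
        raise ValueError(f"size grid must lie within [1, {n_features}]")
    labels = labels.loc[X.columns]
    rng = np.random.default_rng(seed)
    folds_ids = _stratified_folds(labels, folds, rng)

    auc_by_size = {s: [] for s in grid}
    for f in range(folds):
        test_ids = folds_ids[f]
        train_ids = [s for g in range(folds) if g != f for s in folds_ids[g]]
        y_test = labels.loc[test_ids]
        if y_test.nunique() < 2:
            continue
        full = fit_lda(X[train_ids], labels.loc[train_ids], positive, shrinkage)
        ranking = rank_features(full, X[train_ids])
        for s in grid:
            feats = ranking[:s]
            m = fit_lda(X.loc[feats, train_ids], labels.loc[train_ids], positive, shrinkage)
            sc = score(m, X.loc[feats, test_ids])
            auc_by_size[s].append(roc_auc(sc, y_test, positive).auc)

    mean_auc = [float(np.mean(auc_by_size[s])) if auc_by_size[s] else 0.5 for s in grid]
    best = max(mean_auc)
    best_size = next(s for s, a in zip(grid, mean_auc) if a >= best - 1e-12)

    final = fit_lda(X, labels, positive, shrinkage)
    ranking = rank_features(final, X)
    return RfeRunResult(
        sizes=list(grid), cv_auc=mean_auc, selected=ranking[:best_size], ranking=ranking
    )


def stability_select(
    X: pd.DataFrame,
    labels: pd.Series,
    positive: str,
    n_runs: int = 100,
    vote: int = 50,
    seed: int = 0,
    size_grid: list[int] | None = None,
    folds: int = 5,
    shrinkage: float | str = "auto",
) -> StabilityPanel:
    """One generation: count feature occurrences over repeated RFE runs."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if not 1 <= vote <= n_runs:
        raise ValueError(f"vote must be in [1, n_runs={n_runs}]")
    run_seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=n_runs)
    counts: dict[str, int] = {f: 0 for f in X.index}
    for rs in run_seeds:
        res = rfe_once(X, labels, positive, size_grid=size_grid, folds=folds,
                       seed=int(rs), shrinkage=shrinkage)
        for f in res.selected:
            counts[f] += 1
    survivors = sorted(f for f, c in counts.items() if c >= vote)
    diag = "" if survivors else "no feature reached the vote threshold"
    return StabilityPanel(
        n_runs=n_runs, vote=vote, counts=counts, survivors=survivors,
        generation=1, history=[X.shape[0], len(survivors)],
        converged=False, diagnostic=diag,
    )


def irfe(
    X: pd.DataFrame,
    labels: pd.Series,
    positive: str,
    n_runs: int = 100,
    vote: int = 50,
    seed: int = 0,
    folds: int = 5,
    shrinkage: float | str = "auto",
) -> StabilityPanel:
    """Iterate stability selection until the panel stops strictly shrinking.

    The panel size is a non-negative integer that strictly decreases until
    the loop stops, so termination is guaranteed.  If a generation yields an
    empty survivor set, the previous generation's panel is returned with
    ``converged=False`` and a diagnostic.
    """
    if X.shape[0] < 2:
        if X.shape[0] == 1:
            return StabilityPanel(
                n_runs=n_runs, vote=vote, counts={X.index[0]: n_runs},
                survivors=list(X.index), generation=1,
                history=[1, 1], converged=True,
            )
        raise ValueError("irfe requires at least 1 feature")
    seed_stream = np.random.default_rng(seed).integers(0, 2**31 - 1, size=X.shape[0] + 1)
    current = list(X.index)
    history = [len(current)]
    last_panel: StabilityPanel | None = None
    generation = 0
    while True:
        generation += 1
        panel = stability_select(
            X.loc[current], labels, positive, n_runs=n_runs, vote=vote,
            seed=int(seed_stream[generation - 1]), folds=folds, shrinkage=shrinkage,
        )
        size = len(panel.survivors)
        if size == 0:
            prev = last_panel or panel
            return StabilityPanel(
                n_runs=n_runs, vote=vote, counts=prev.counts,
                survivors=list(current) if last_panel else [],
                generation=generation, history=history + [0], converged=False,
                diagnostic="survivor set became empty; previous panel returned",
            )
        history.append(size)
        if size >= len(current):
            return StabilityPanel(
                n_runs=n_runs, vote=vote, counts=panel.counts,
                survivors=panel.survivors, generation=generation,
                history=history, converged=True,
            )
        current = panel.survivors
        last_panel = panel
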