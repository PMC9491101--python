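"""Random-panel AUC nulls, group-wise comparisons and panel correlations.

The null contrasts an observed panel AUC against B validation AUCs of
randomly drawn same-size panels using a one-tailed one-sample t-test
(upper tail: observed exceeds the null mean).  An empirical percentile of
the observed AUC among the null AUCs is reported alongside as a
calibration diagnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from scipy import stats

from .core_io import MethylationMatrix
from .discriminant import fit_lda, roc_auc, score


@dataclass
class NullAucDistribution:
    k: int
    B: int
    null_aucs: np.ndarray
    observed_auc: float
    t: float
    p: float  # upper-tail t p-value with B - 1 df
    empirical_p: float  # fraction of null AUCs >= observed


@dataclass
class CorrelationReport:
    panel: list[str]
    strata: dict[str, pd.DataFrame]  # stratum -> pairwise r matrix
    p_values: dict[str, pd.DataFrame]
    baseline_mean_abs_r: float | None = None


def null_t_test(null_aucs: np.ndarray, observed: float) -> tuple[float, float]:
    """Upper-tailed one-sample t of B null AUCs against the observed AUC."""
    null_aucs = np.asarray(null_aucs, float)
    B = null_aucs.size
    if B < 2:
        raise ValueError("need at least 2 null AUCs")
    sd = null_aucs.std(ddof=1)
    if sd == 0:
        warnings.warn("null AUC distribution has zero variance")
        return (np.inf, 0.0) if observed > null_aucs[0] else (-np.inf, 1.0)
    t = (observed - null_aucs.mean()) / (sd / np.sqrt(B))
    return float(t), float(stats.t.sf(t, B - 1))


def random_panel_null(
    X_train: pd.DataFrame,
    labels_train: pd.Series,
    X_valid: pd.DataFrame,
    labels_valid: pd.Series,
    positive: str,
    k: int,
    observed_auc: float,
    B: int = 100,
    seed: int = 0,
    shrinkage: float | str = "auto",
) -> NullAucDistribution:
    """B random k-feature panels: fit on train, AUC on validation, t-test."""
    if k > X_train.shape[0]:
        raise ValueError("panel size k exceeds available features")
    if B < 2:
        raise ValueError("B must be >= 2")
    rng = np.random.default_rng(seed)
    features = list(X_train.index)
    aucs = np.empty(B)
    for b in range(B):
        panel = [features[i] for i in rng.choice(len(features), size=k, replace=False)]
        model = fit_lda(X_train.loc[panel], labels_train, positive, shrinkage)
        sc = score(model, X_valid.loc[panel])
        aucs[b] = roc_auc(sc, labels_valid.loc[X_valid.columns], positive).auc
    t, p = null_t_test(aucs, observed_auc)
    empirical = float((aucs >= observed_auc).mean())
    return NullAucDistribution(
        k=k, B=B, null_aucs=aucs, observed_auc=observed_auc, t=t, p=p,
        empirical_p=empirical,
    )


def group_compare(
    values: pd.Series,
    groups: pd.Series,
    pairs: list[tuple[str, str]] | None = None,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Wilcoxon rank-sum p per requested group pair on one feature."""
    groups = groups.loc[values.index]
    available = sorted(groups.unique())
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(available) for b in available[i + 1:]]
    rows = []
    for g1, g2 in pairs:
        for g in (g1, g2):
            if g not in available:
                raise ValueError(f"unknown group label {g!r}")
        x = values[groups == g1].to_numpy()
        y = values[groups == g2].to_numpy()
        if len(x) < 2 or len(y) < 2:
            raise ValueError(f"groups {g1!r}/{g2!r} need at least 2 samples each")
        p = float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
        rows.append({"group1": g1, "group2": g2, "n1": len(x), "n2": len(y),
                     "p": p, "significant": p < alpha})
    return pd.DataFrame(rows)


def panel_correlations(
    X: MethylationMatrix | pd.DataFrame,
    strata: pd.Series,
    panel: list[str],
) -> CorrelationReport:
    """Per-stratum pairwise Pearson r (with two-sided p) among panel features."""
    df = X.data if isinstance(X, MethylationMatrix) else X
    missing = [f for f in panel if f not in df.index]
    if missing:
        raise ValueError(f"panel feature(s) absent from matrix: {missing}")
    report_r: dict[str, pd.DataFrame] = {}
    report_p: dict[str, pd.DataFrame] = {}
    for stratum in sorted(strata.unique()):
        ids = [s for s in df.columns if s in strata.index and strata[s] == stratum]
        sub = df.loc[panel, ids]
        k = len(panel)
        r = np.full((k, k), np.nan)
        p = np.full((k, k), np.nan)
        np.fill_diagonal(r, 1.0)
        np.fill_diagonal(p, 0.0)
        for i in range(k):
            for j in range(i + 1, k):
                xi = sub.iloc[i].to_numpy()
                xj = sub.iloc[j].to_numpy()
                if xi.std() == 0 or xj.std() == 0:
                    continue  # undefined for constant features; stays missing
                rr, pp = stats.pearsonr(xi, xj)
                r[i, j] = r[j, i] = rr
                p[i, j] = p[j, i] = pp
        report_r[stratum] = pd.DataFrame(r, index=panel, columns=panel)
        report_p[stratum] = pd.DataFrame(p, index=panel, columns=panel)
    return CorrelationReport(panel=list(panel), strata=report_r, p_values=report_p)


@dataclass
class RandomPanelCorrelationBaseline:
    k: int
    repeats: int
    mean_sorted_abs_r: np.ndarray  # mean over repeats of sorted |off-diagonal r|
    mean_abs_r: float


def random_panel_correlation_baseline(
    X: MethylationMatrix | pd.DataFrame,
    k: int,
    repeats: int = 100,
    seed: int = 0,
) -> RandomPanelCorrelationBaseline:
    """Average |off-diagonal r| profile of random k-feature panels."""
    df = X.data if isinstance(X, MethylationMatrix) else X
    if k > df.shape[0]:
        raise ValueError("k exceeds available features")
    rng = np.random.default_rng(seed)
    n_off = k * (k - 1) // 2
    acc = np.zeros(n_off)
    iu = np.triu_indices(k, 1)
    for _ in range(repeats):
        idx = rng.choice(df.shape[0], size=k, replace=False)
        corr = np.corrcoef(df.iloc[idx].to_numpy())
        vals = np.abs(corr[iu])
        acc += np.sort(vals)[::-1]
    mean_sorted = acc / repeats
    return RandomPanelCorrelationBaseline(
        k=k, repeats=repeats, mean_sorted_abs_r=mean_sorted,
        mean_abs_r=float(mean_sorted.mean()),
    )
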