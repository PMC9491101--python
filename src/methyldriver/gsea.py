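"""Single-gene GSEA over correlation-ranked methylation clusters.

All clusters are ranked by the Pearson correlation of their methylation
with a target cluster; a weighted Kolmogorov-Smirnov running sum yields the
enrichment score (ES) per gene set, normalized to NES against gene-set
permutations of matching sign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import GeneSet, MethylationMatrix


@dataclass
class RankedList:
    """Features sorted by descending metric; target excluded from the list."""

    features: list[str]
    metric: np.ndarray
    target: str

    def __post_init__(self) -> None:
        if len(self.features) != len(self.metric):
            raise ValueError("features and metric must align")


@dataclass
class EnrichmentResult:
    set_name: str
    es: float
    nes: float
    p: float
    p_is_upper_bound: bool
    leading_edge: list[str]
    n_perm: int


def rank_by_correlation(
    X: MethylationMatrix | pd.DataFrame,
    target: str,
    samples: list[str] | None = None,
) -> RankedList:
    """Pearson r of every other cluster with the target, sorted descending.

    Ties break lexicographically by feature ID so the order is total and
    deterministic.
    """
    df = X.data if isinstance(X, MethylationMatrix) else X
    if target not in df.index:
        raise ValueError(f"target cluster {target!r} absent from matrix")
    if samples is not None:
        df = df[samples]
    if df.shape[1] < 3:
        raise ValueError("need at least 3 samples to rank by correlation")
    t = df.loc[target].to_numpy()
    if t.std() == 0:
        raise ValueError("target cluster is constant; correlation undefined")
    others = df.drop(index=target)
    vals = others.to_numpy()
    tc = t - t.mean()
    vc = vals - vals.mean(axis=1, keepdims=True)
    denom = np.sqrt((vc**2).sum(axis=1)) * np.sqrt((tc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (vc @ tc) / denom
    r = np.where(np.isfinite(r), r, 0.0)  # constant rows rank neutrally
    order = sorted(range(len(r)), key=lambda i: (-r[i], others.index[i]))
    return RankedList(
        features=[others.index[i] for i in order],
        metric=np.array([r[i] for i in order]),
        target=target,
    )


def enrichment_score(
    ranked: RankedList, gene_set: GeneSet | set[str], weight: float = 1.0
) -> tuple[float, np.ndarray]:
    """Weighted-KS enrichment score and the full running sum.

    At member positions the sum rises by |metric|^weight normalized over the
    set; elsewhere it falls by 1/(N - set size).  ES is the running-sum value
    of maximal absolute deviation, sign retained.
    """
    members = set(gene_set.members) if isinstance(gene_set, GeneSet) else set(gene_set)
    in_set = np.array([f in members for f in ranked.features])
    n_hit = int(in_set.sum())
    if n_hit == 0:
        raise ValueError("gene set has no members in the ranked list")
    n = len(ranked.features)
    if n_hit == n:
        raise ValueError("gene set covers the entire ranked list")
    w = np.abs(ranked.metric) ** weight
    hit_w = np.where(in_set, w, 0.0)
    total = hit_w.sum()
    if total == 0:  # all member metrics are exactly zero: fall back to equal weights
        hit_w = in_set.astype(float)
        total = hit_w.sum()
    steps = hit_w / total - (~in_set) / (n - n_hit)
    running = np.cumsum(steps)
    idx = int(np.argmax(np.abs(running)))
    return float(running[idx]), running


def _leading_edge(ranked: RankedList, members: set[str], running: np.ndarray, es: float) -> list[str]:
    idx = int(np.argmax(np.abs(running)))
    if es >= 0:
        return [f for f in ranked.features[: idx + 1] if f in members]
    return [f for f in ranked.features[idx:] if f in members]


def nes_and_p(
    ranked: RankedList,
    gene_set: GeneSet,
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
) -> EnrichmentResult:
    """Gene-set permutation NES and nominal p, deterministic per seed.

    NES = ES / mean(|permuted ES| of matching sign); p is the fraction of
    same-sign permuted scores at least as extreme as the observed ES.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    members = set(gene_set.members)
    present = [f for f in ranked.features if f in members]
    es, running = enrichment_score(ranked, gene_set, weight)
    rng = np.random.default_rng(seed)
    n = len(ranked.features)
    n_hit = len(present)
    perm_es = np.empty(n_perm)
    features = np.array(ranked.features)
    for b in range(n_perm):
        idx = rng.choice(n, size=n_hit, replace=False)
        perm_es[b], _ = enrichment_score(ranked, set(features[idx]), weight)

    same_sign = perm_es >= 0 if es >= 0 else perm_es < 0
    n_same = int(same_sign.sum())
    if n_same == 0:
        nes = float("nan")
        p = 1.0 / n_perm
        upper_bound = True
    else:
        pool = np.abs(perm_es[same_sign])
        nes = float(es / pool.mean()) if pool.mean() > 0 else float("nan")
        p = float((pool >= abs(es)).sum() / n_same)
        upper_bound = False
        if p == 0.0:
            p = 1.0 / n_same
            upper_bound = True
    return EnrichmentResult(
        set_name=gene_set.name, es=es, nes=nes, p=p, p_is_upper_bound=upper_bound,
        leading_edge=_leading_edge(ranked, members, running, es), n_perm=n_perm,
    )


def top_sets_report(results: list[EnrichmentResult], n: int = 10) -> list[EnrichmentResult]:
    """Top-n results by NES descending; NaN NES last; ties by set name."""
    def key(r: EnrichmentResult):
        nes = r.nes if np.isfinite(r.nes) else -np.inf
        return (-nes, r.set_name)

    return sorted(results, key=key)[:n]
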