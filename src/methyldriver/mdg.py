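"""Methylation-driven gene (MDG) calling.

A gene is called methylation-driven when (a) a univariate Gaussian mixture
fitted to its disease-sample beta values has a component whose mean differs
from the normal-reference mean by at least ``dm_min`` with a significant
rank-sum test, and (b) its methylation inversely predicts its own
expression (Pearson r below ``r_max`` with a significant p).  Probes of a
gene are first grouped into correlated clusters; calling operates on
cluster-level betas (mean of member probes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .core_io import (
    ClusterDefinition,
    ExpressionMatrix,
    MethylationMatrix,
    ProbeAnnotation,
    SampleMetadata,
    aggregate_clusters,
)

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class Thresholds:
    """MDG-calling thresholds (all configurable)."""

    dm_min: float = 0.10  # minimum |component mean - normal mean|
    r_max: float = -0.3  # maximum methylation-expression Pearson r
    alpha: float = 0.01  # significance level for both tests
    r_cluster: float = 0.4  # minimum average within-cluster probe correlation


@dataclass
class MixtureFit:
    """A BIC-selected univariate Gaussian mixture fit."""

    k: int
    means: np.ndarray
    variances: np.ndarray
    weights: np.ndarray
    responsibilities: np.ndarray  # k x n
    log_likelihood: float
    bic_by_k: dict[int, float]
    n_iter: int
    converged: bool
    ll_trace: np.ndarray | None = None

    def assignments(self) -> np.ndarray:
        """Hard component assignment per sample (argmax responsibility)."""
        return np.argmax(self.responsibilities, axis=0)


@dataclass
class ComponentEvidence:
    component: int
    dm: float  # component mean - normal mean
    p: float  # rank-sum p, component-assigned disease vs normal
    n_assigned: int


@dataclass
class ClusterCall:
    """Driver evidence for one methylation cluster."""

    cluster: ClusterDefinition
    fit: MixtureFit
    normal_mean: float
    components: list[ComponentEvidence]
    r: float  # methylation-expression Pearson r on disease samples
    r_p: float
    is_driver: bool


@dataclass
class MdgCallResult:
    """Per-gene call: cluster definitions and per-cluster driver evidence."""

    gene: str
    clusters: list[ClusterDefinition]
    calls: list[ClusterCall]

    @property
    def is_driver(self) -> bool:
        return any(c.is_driver for c in self.calls)

    @property
    def driver_clusters(self) -> list[ClusterDefinition]:
        return [c.cluster for c in self.calls if c.is_driver]


# ---------------------------------------------------------------------------
# probe clustering
# ---------------------------------------------------------------------------


def cluster_probes(
    probe_betas: pd.DataFrame, gene: str, r_cluster: float = 0.4
) -> list[ClusterDefinition]:
    """Group a gene's probes into correlated clusters.

    Average-linkage hierarchical clustering on 1 - Pearson r, cut so that
    merged probes keep average correlation >= ``r_cluster``.  Constant probe
    rows cannot be correlated and become singleton clusters (warning).
    Cluster numbering follows probe order of first appearance; a gene whose
    probes form a single cluster is named by the bare gene symbol.
    """
    probe_ids = list(probe_betas.index)
    if not probe_ids:
        raise ValueError(f"gene {gene!r} has no probes")
    values = probe_betas.to_numpy()
    variable = values.std(axis=1) > 0
    if not variable.all():
        warnings.warn(
            f"gene {gene}: {int((~variable).sum())} constant probe row(s) "
            "placed in singleton clusters"
        )

    groups: list[list[str]] = []
    var_ids = [p for p, ok in zip(probe_ids, variable) if ok]
    if len(var_ids) == 1:
        groups.append([var_ids[0]])
    elif len(var_ids) > 1:
        sub = values[variable]
        corr = np.corrcoef(sub)
        dist = np.clip(1.0 - corr, 0.0, 2.0)
        np.fill_diagonal(dist, 0.0)
        z = linkage(squareform(dist, checks=False), method="average")
        labels = fcluster(z, t=1.0 - r_cluster, criterion="distance")
        by_label: dict[int, list[str]] = {}
        for pid, lab in zip(var_ids, labels):
            by_label.setdefault(int(lab), []).append(pid)
        groups.extend(by_label.values())
    groups.extend([[p] for p, ok in zip(probe_ids, variable) if not ok])

    # deterministic numbering by first-appearance probe order
    order = {p: i for i, p in enumerate(probe_ids)}
    groups.sort(key=lambda g: min(order[p] for p in g))
    if len(groups) == 1:
        return [ClusterDefinition(gene, gene, tuple(groups[0]))]
    return [
        ClusterDefinition(f"{gene}-Cluster{k + 1}", gene, tuple(g))
        for k, g in enumerate(groups)
    ]


# ---------------------------------------------------------------------------
# mixture fitting
# ---------------------------------------------------------------------------


def _em_fit(x: np.ndarray, k: int, tol: float, max_iter: int):
    n = x.size
    # deterministic quantile-based initialization
    means = np.quantile(x, (np.arange(k) + 0.5) / k)
    variances = np.full(k, max(x.var(), 1e-6))
    weights = np.full(k, 1.0 / k)
    ll_old = -np.inf
    resp = np.full((k, n), 1.0 / k)
    converged = False
    it = 0
    trace = []
    for it in range(1, max_iter + 1):
        # E-step in log space
        log_comp = (
            np.log(np.maximum(weights, 1e-300))[:, None]
            - 0.5 * (_LOG2PI + np.log(variances))[:, None]
            - 0.5 * (x[None, :] - means[:, None]) ** 2 / variances[:, None]
        )
        log_norm = np.logaddexp.reduce(log_comp, axis=0)
        resp = np.exp(log_comp - log_norm[None, :])
        ll = float(log_norm.sum())
        trace.append(ll)
        # M-step
        nk = np.maximum(resp.sum(axis=1), 1e-10)
        means = (resp @ x) / nk
        variances = np.maximum((resp @ x**2) / nk - means**2, 1e-6)
        weights = nk / n
        if abs(ll - ll_old) < tol:
            converged = True
            ll_old = ll
            break
        ll_old = ll
    return means, variances, weights, resp, ll_old, it, converged, np.array(trace)


def fit_beta_value_mixture(
    values: np.ndarray,
    k_candidates: tuple[int, ...] = (1, 2, 3),
    tol: float = 1e-6,
    max_iter: int = 500,
) -> MixtureFit:
    """EM-fit Gaussian mixtures on beta values; return the BIC-minimizing K.

    Initialization is quantile-based and therefore deterministic; the
    log-likelihood is non-decreasing across EM iterations, and convergence
    is declared when it changes by less than ``tol``.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 10:
        raise ValueError("mixture fitting requires at least 10 values")
    if np.nanmin(x) < 0 or np.nanmax(x) > 1:
        raise ValueError("beta values must lie in [0, 1]")
    if x.var() < 1e-12:
        raise ValueError("degenerate distribution: zero variance")

    best: MixtureFit | None = None
    best_bic = np.inf
    bic_by_k: dict[int, float] = {}
    for k in sorted(k_candidates):
        means, variances, weights, resp, ll, it, conv, trace = _em_fit(x, k, tol, max_iter)
        bic = -2.0 * ll + (3 * k - 1) * np.log(x.size)
        bic_by_k[k] = float(bic)
        # strictly smaller BIC wins; ties keep the smaller K
        if bic < best_bic:
            best_bic = bic
            best = MixtureFit(
                k=k, means=means, variances=variances, weights=weights,
                responsibilities=resp, log_likelihood=ll, bic_by_k=bic_by_k,
                n_iter=it, converged=conv, ll_trace=trace,
            )
    assert best is not None
    best.bic_by_k = bic_by_k
    return best


# ---------------------------------------------------------------------------
# driver calling
# ---------------------------------------------------------------------------


def _ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    if x.size == 0 or y.size == 0:
        return float("nan")
    try:
        return float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
    except ValueError:  # all-identical values
        return 1.0


def call_driver(
    gene: str,
    cluster: ClusterDefinition,
    disease_beta: np.ndarray,
    normal_beta: np.ndarray,
    disease_expr: np.ndarray,
    thresholds: Thresholds | None = None,
) -> ClusterCall:
    """Evaluate the MDG criteria for one cluster-level beta vector.

    ``disease_beta`` and ``disease_expr`` must be aligned to the same
    disease samples.  All evidence is returned regardless of the flag.
    """
    th = thresholds or Thresholds()
    disease_beta = np.asarray(disease_beta, float)
    normal_beta = np.asarray(normal_beta, float)
    disease_expr = np.asarray(disease_expr, float)
    if normal_beta.size < 3:
        raise ValueError("call_driver requires at least 3 normal samples")
    if disease_beta.size != disease_expr.size:
        raise ValueError("disease methylation and expression must be sample-aligned")

    fit = fit_beta_value_mixture(disease_beta)
    normal_mean = float(normal_beta.mean())
    hard = fit.assignments()
    components = []
    for k in range(fit.k):
        assigned = disease_beta[hard == k]
        components.append(
            ComponentEvidence(
                component=k,
                dm=float(fit.means[k] - normal_mean),
                p=_ranksum_p(assigned, normal_beta),
                n_assigned=int(assigned.size),
            )
        )

    if disease_beta.std() > 0 and disease_expr.std() > 0:
        r, r_p = stats.pearsonr(disease_beta, disease_expr)
    else:
        r, r_p = float("nan"), 1.0

    dm_ok = any(
        abs(c.dm) >= th.dm_min and np.isfinite(c.p) and c.p < th.alpha
        for c in components
    )
    corr_ok = np.isfinite(r) and r < th.r_max and r_p < th.alpha
    return ClusterCall(
        cluster=cluster,
        fit=fit,
        normal_mean=normal_mean,
        components=components,
        r=float(r),
        r_p=float(r_p),
        is_driver=bool(dm_ok and corr_ok),
    )


def call_all(
    meth: MethylationMatrix,
    expr: ExpressionMatrix,
    meta: SampleMetadata,
    annotation: ProbeAnnotation,
    thresholds: Thresholds | None = None,
    disease_classes: tuple[str, ...] = ("cancer",),
    normal_classes: tuple[str, ...] = ("normal", "adjacent"),
) -> tuple[list[MdgCallResult], MethylationMatrix]:
    """Call drivers gene by gene and extract the driver-cluster matrix.

    Probes are grouped per gene (clusters computed on all tissue samples),
    aggregated to cluster betas, and each cluster is evaluated against the
    normal reference.  Returns the per-gene calls plus the cluster-level
    methylation matrix restricted to driver clusters over all input samples
    (the "MDGs data" handed to the classifier stages).
    """
    th = thresholds or Thresholds()
    disease_ids = [s for s in meth.sample_ids if s in meta.data.index and meta.data.loc[s, "tissue_class"] in disease_classes]
    normal_ids = [s for s in meth.sample_ids if s in meta.data.index and meta.data.loc[s, "tissue_class"] in normal_classes]
    if len(normal_ids) < 3:
        raise ValueError("call_all requires at least 3 normal-reference samples")

    by_gene: dict[str, list[str]] = {}
    n_skipped = 0
    for p in meth.feature_ids:
        if p not in annotation:
            n_skipped += 1
            continue
        by_gene.setdefault(annotation.gene_of(p), []).append(p)
    if n_skipped:
        warnings.warn(f"{n_skipped} probe(s) without annotation were skipped")

    results: list[MdgCallResult] = []
    driver_defs: list[ClusterDefinition] = []
    for gene, probes in by_gene.items():
        if gene not in expr.data.index:
            warnings.warn(f"gene {gene} absent from expression matrix; skipped")
            continue
        defs = cluster_probes(meth.data.loc[probes], gene, r_cluster=th.r_cluster)
        cluster_mat = aggregate_clusters(meth, defs)
        e_dis = expr.data.loc[gene, disease_ids].to_numpy()
        calls = []
        for d in defs:
            beta = cluster_mat.data.loc[d.cluster_id]
            try:
                calls.append(
                    call_driver(
                        gene, d,
                        beta[disease_ids].to_numpy(),
                        beta[normal_ids].to_numpy(),
                        e_dis,
                        th,
                    )
                )
            except ValueError as exc:  # degenerate cluster distribution
                warnings.warn(f"cluster {d.cluster_id}: {exc}; not called")
        res = MdgCallResult(gene=gene, clusters=defs, calls=calls)
        results.append(res)
        driver_defs.extend(res.driver_clusters)

    if driver_defs:
        mdg_matrix = aggregate_clusters(meth, driver_defs)
    else:
        mdg_matrix = MethylationMatrix(
            pd.DataFrame(np.empty((0, len(meth.sample_ids))), index=[], columns=meth.sample_ids)
        )
    return results, mdg_matrix


def driver_table(results: list[MdgCallResult]) -> pd.DataFrame:
    """Flat per-cluster evidence table (gene, cluster, K, best DM, p, r, flag)."""
    rows = []
    for res in results:
        for call in res.calls:
            best = max(call.components, key=lambda c: abs(c.dm), default=None)
            rows.append(
                {
                    "gene": res.gene,
                    "cluster_id": call.cluster.cluster_id,
                    "n_probes": len(call.cluster.probe_ids),
                    "k": call.fit.k,
                    "dm": best.dm if best else np.nan,
                    "dm_p": best.p if best else np.nan,
                    "r": call.r,
                    "r_p": call.r_p,
                    "is_driver": call.is_driver,
                }
            )
    return pd.DataFrame(rows)
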