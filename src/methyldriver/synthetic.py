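"""Seeded generator of multi-stage methylation cohorts with planted drivers.

Emulates the statistical structure of array-based colorectal methylation
studies: beta-distributed probe values in [0, 1]; a minority of driver genes
whose methylation shifts from the adenoma stage onward (normal and
cancer-adjacent tissue indistinguishable, shift growing through low- and
high-grade adenoma, plateauing across cancer stages I-IV) with inversely
coupled expression; a planted minimal panel of driver clusters that
additionally share a latent sample-level factor so their betas correlate
across samples; and cfDNA modeled as a stage-dependent mixture of tumor and
leukocyte background signal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import (
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    MethylationMatrix,
    ProbeAnnotation,
    SampleMetadata,
)

#: tissue classes x stage combinations generated for the tissue cohort
CLASS_KEYS = (
    "normal", "adjacent", "adenoma_low", "adenoma_high",
    "cancer_I", "cancer_II", "cancer_III", "cancer_IV",
)

#: default per-stage cfDNA tumor fractions (healthy plasma carries none;
#: fractions stay negligible until the heavy tumor-DNA shedding of stage IV)
DEFAULT_STAGE_FRACTIONS = {"none": 0.0, "0": 0.01, "I": 0.01, "II": 0.02, "III": 0.05, "IV": 0.40}

_HYPER_BASE = (0.25, 0.45)
_HYPO_BASE = (0.55, 0.75)
_NULL_BASE = (0.10, 0.90)
_MEAN_CLIP = (0.02, 0.98)


def _default_n_per_class() -> dict[str, int]:
    return {
        "normal": 40, "adjacent": 40, "adenoma_low": 30, "adenoma_high": 30,
        "cancer_I": 30, "cancer_II": 30, "cancer_III": 30, "cancer_IV": 30,
    }


def _default_effect_profile() -> dict[str, float]:
    return {"adenoma_low": 0.08, "adenoma_high": 0.13, "cancer": 0.16}


def _default_n_cfdna() -> dict[str, int]:
    return {"healthy": 40, "0": 20, "I": 20, "II": 20, "III": 20, "IV": 20}


@dataclass
class CohortSpec:
    """All knobs of the synthetic cohort; defaults are the study conditions.

    ``effect_profile`` gives the mean beta shift of driver genes per class
    (hyper drivers shift up, hypo drivers down); it must be monotone
    non-decreasing from low-grade adenoma to cancer and is zero for normal
    and cancer-adjacent tissue.  ``panel_effect_scale`` multiplies the shift
    for the planted panel genes — the panel is planted as the most
    discriminative minimal subset.  ``panel_loading`` is the latent-factor
    loading lambda; pairwise panel correlation is ~ lambda^2.  Beta noise is
    parameterized by mean/precision (a = mu*phi, b = (1-mu)*phi).

    ``driver_heterogeneity_sd`` is the SD of a per-sample, gene-level
    biological offset applied to driver genes in shifted classes (scaled by
    the class effect), mimicking the partial-penetrance spread that makes
    disease-tissue methylation broad or bimodal while normals stay tight.
    ``driver_comethylation`` is the fraction of that heterogeneity shared
    across ordinary drivers through one disease-severity factor — concerted
    hyper/hypomethylation across loci (the methylator-phenotype structure),
    which caps how much a stack of ordinary drivers adds over a few of
    them.  The planted panel instead uses the smaller
    ``panel_heterogeneity_sd`` tied to its own latent factor; together these
    make the panel *minimal*: a single panel cluster is informative but
    insufficient, the four jointly separate the classes and dominate any
    same-size set of ordinary drivers.
    """

    n_per_class: dict[str, int] = field(default_factory=_default_n_per_class)
    n_genes: int = 2000
    probes_per_gene: tuple[int, int] = (1, 3)
    n_driver_genes: int = 100
    n_panel_clusters: int = 4
    effect_profile: dict[str, float] = field(default_factory=_default_effect_profile)
    panel_effect_scale: float = 1.25
    driver_heterogeneity_sd: float = 0.145
    panel_heterogeneity_sd: float = 0.09
    driver_comethylation: float = 0.6
    hyper_fraction: float = 0.7
    panel_loading: float = 0.5
    probe_offset_sd: float = 0.02
    phi_tissue: float = 50.0
    phi_cfdna: float = 100.0
    expression_baseline_mean: float = 8.0
    expression_baseline_sd: float = 1.0
    expression_slope: float = 6.0
    expression_noise_sd: float = 0.5
    n_cfdna_per_group: dict[str, int] = field(default_factory=_default_n_cfdna)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.n_per_class.values()):
            raise ValueError("all class counts must be positive")
        if set(self.n_per_class) != set(CLASS_KEYS):
            raise ValueError(f"n_per_class must cover exactly {CLASS_KEYS}")
        if not (0 < self.n_driver_genes <= self.n_genes):
            raise ValueError("n_driver_genes must be in [1, n_genes]")
        if not (0 < self.n_panel_clusters <= self.n_driver_genes):
            raise ValueError("n_panel_clusters must be in [1, n_driver_genes]")
        lo, hi, can = (
            self.effect_profile["adenoma_low"],
            self.effect_profile["adenoma_high"],
            self.effect_profile["cancer"],
        )
        if not (0 <= lo <= hi <= can):
            raise ValueError("effect_profile must be monotone non-decreasing from adenoma onward")
        if not 0 <= self.hyper_fraction <= 1:
            raise ValueError("hyper_fraction must be in [0, 1]")
        if not 0 <= self.panel_loading < 1:
            raise ValueError("panel_loading must be in [0, 1)")
        margin = 3 * self.probe_offset_sd
        max_shift = can * self.panel_effect_scale
        if _HYPER_BASE[1] + margin + max_shift >= 1 or _HYPO_BASE[0] - margin - max_shift <= 0:
            raise ValueError("effect profile pushes driver means outside (0, 1)")

    def class_shift(self, class_key: str) -> float:
        """Driver mean-beta shift (before direction/scale) for one class."""
        if class_key in ("normal", "adjacent"):
            return 0.0
        if class_key.startswith("cancer"):
            return self.effect_profile["cancer"]
        return self.effect_profile[class_key]


@dataclass
class GroundTruth:
    """What was planted: drivers, panel, true means, cfDNA fractions."""

    driver_directions: dict[str, int]  # gene -> +1 hyper / -1 hypo
    driver_class_means: pd.DataFrame  # driver genes x CLASS_KEYS, gene-level true means
    panel_genes: list[str]
    panel_cluster_ids: list[str]
    stage_fractions: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_STAGE_FRACTIONS))
    probe_class_means: pd.DataFrame | None = None  # probes x CLASS_KEYS (for cfDNA draws)
    probe_gene: pd.Series | None = None

    def __post_init__(self) -> None:
        if not set(self.panel_genes) <= set(self.driver_directions):
            raise ValueError("planted panel must be a subset of driver genes")

    @property
    def driver_genes(self) -> list[str]:
        return list(self.driver_directions)

    def to_json(self) -> str:
        return json.dumps(
            {
                "driver_directions": self.driver_directions,
                "panel_genes": self.panel_genes,
                "panel_cluster_ids": self.panel_cluster_ids,
                "stage_fractions": self.stage_fractions,
            },
            indent=2,
        )


def generate_tissue_cohort(
    spec: CohortSpec,
) -> tuple[MethylationMatrix, ExpressionMatrix, SampleMetadata, ProbeAnnotation, GroundTruth]:
    """Generate the multi-stage tissue cohort defined by ``spec``.

    Non-driver probes draw from a beta distribution with a class-independent
    mean; driver probes shift by class according to the effect profile;
    planted-panel probes share one latent sample factor through a Gaussian
    copula, preserving exact beta marginals while inducing cross-panel
    correlation ~ loading^2.
    """
    rng = np.random.default_rng(spec.seed)

    genes = [f"G{i:04d}" for i in range(spec.n_genes)]
    lo, hi = spec.probes_per_gene
    n_probes_per_gene = rng.integers(lo, hi + 1, size=spec.n_genes)
    probe_gene: list[str] = []
    for g, k in zip(genes, n_probes_per_gene):
        probe_gene.extend([g] * int(k))
    probes = [f"cg{i + 1:08d}" for i in range(len(probe_gene))]
    probe_gene_s = pd.Series(probe_gene, index=probes, name="gene")

    driver_idx = rng.choice(spec.n_genes, size=spec.n_driver_genes, replace=False)
    driver_genes = [genes[i] for i in sorted(driver_idx)]
    directions = {
        g: (1 if rng.random() < spec.hyper_fraction else -1) for g in driver_genes
    }
    panel_pick = rng.choice(spec.n_driver_genes, size=spec.n_panel_clusters, replace=False)
    panel_genes = sorted(driver_genes[i] for i in panel_pick)

    # gene baseline means: hyper drivers start low, hypo drivers start high
    base_mean = {}
    for g in genes:
        if g in directions:
            a, b = _HYPER_BASE if directions[g] == 1 else _HYPO_BASE
        else:
            a, b = _NULL_BASE
        base_mean[g] = rng.uniform(a, b)

    probe_offsets = rng.normal(0.0, spec.probe_offset_sd, size=len(probes))

    # probe x class matrix of true means
    class_means = np.empty((len(probes), len(CLASS_KEYS)))
    for j, ck in enumerate(CLASS_KEYS):
        shift = spec.class_shift(ck)
        for i, p in enumerate(probes):
            g = probe_gene[i]
            d = directions.get(g, 0)
            scale = spec.panel_effect_scale if g in panel_genes else 1.0
            mu = base_mean[g] + probe_offsets[i] + d * scale * shift
            class_means[i, j] = mu
    class_means = np.clip(class_means, *_MEAN_CLIP)
    probe_class_means = pd.DataFrame(class_means, index=probes, columns=list(CLASS_KEYS))

    # samples, in fixed class order
    sample_ids: list[str] = []
    sample_class: list[str] = []
    for ck in CLASS_KEYS:
        for r in range(spec.n_per_class[ck]):
            sample_ids.append(f"T_{ck}_{r:03d}")
            sample_class.append(ck)
    n_samples = len(sample_ids)
    class_col = {ck: j for j, ck in enumerate(CLASS_KEYS)}
    mu = class_means[:, [class_col[ck] for ck in sample_class]]  # probes x samples

    # one latent sample-level factor shared by the planted panel: it drives
    # both the biological heterogeneity of panel genes (below) and the
    # technical-noise copula (further below), so panel clusters correlate
    # ~ loading^2 in every tissue class
    lam = spec.panel_loading
    factor = rng.standard_normal(n_samples)

    # per-sample gene-level biological heterogeneity of driver methylation,
    # scaled by the class effect so normals stay tight and a zero effect
    # profile yields a pure null generator
    cancer_shift = spec.effect_profile["cancer"]
    if cancer_shift > 0:
        shift_frac = np.array([spec.class_shift(ck) for ck in sample_class]) / cancer_shift
        severity = rng.standard_normal(n_samples)  # shared disease-severity factor
        rho = spec.driver_comethylation
        gene_eta: dict[str, np.ndarray] = {}
        for g in driver_genes:
            if g in panel_genes:
                # the panel factor couples betas positively whatever the
                # direction of the mean shift (co-methylation level swings
                # are same-signed); direction acts on the mean only
                z = lam * factor + np.sqrt(1.0 - lam**2) * rng.standard_normal(n_samples)
                gene_eta[g] = z * spec.panel_heterogeneity_sd * shift_frac
            else:
                z = np.sqrt(rho) * severity + np.sqrt(1.0 - rho) * rng.standard_normal(n_samples)
                gene_eta[g] = directions[g] * z * spec.driver_heterogeneity_sd * shift_frac
        eta = np.zeros_like(mu)
        for i, g in enumerate(probe_gene):
            if g in gene_eta:
                eta[i] = gene_eta[g]
        mu = np.clip(mu + eta, *_MEAN_CLIP)

    a = mu * spec.phi_tissue
    b = (1.0 - mu) * spec.phi_tissue

    values = rng.beta(a, b)

    # planted panel: the same latent factor through a Gaussian copula on the
    # beta marginals of panel probes
    panel_probe_mask = probe_gene_s.isin(panel_genes).to_numpy()
    if panel_probe_mask.any():
        eps = rng.standard_normal((int(panel_probe_mask.sum()), n_samples))
        z = lam * factor[None, :] + np.sqrt(1.0 - lam**2) * eps
        u = stats.norm.cdf(z)
        values[panel_probe_mask] = stats.beta.ppf(
            u, a[panel_probe_mask], b[panel_probe_mask]
        )

    meth = MethylationMatrix(pd.DataFrame(values, index=probes, columns=sample_ids))

    # expression: drivers inversely coupled to their gene-level methylation
    gene_meth = (
        meth.data.groupby(probe_gene_s.reindex(meth.data.index)).mean().reindex(genes)
    )
    baselines = rng.normal(
        spec.expression_baseline_mean, spec.expression_baseline_sd, size=spec.n_genes
    )
    noise = rng.normal(0.0, spec.expression_noise_sd, size=(spec.n_genes, n_samples))
    slopes = np.array([spec.expression_slope if g in directions else 0.0 for g in genes])
    expr_values = baselines[:, None] - slopes[:, None] * gene_meth.to_numpy() + noise
    expr = ExpressionMatrix(pd.DataFrame(expr_values, index=genes, columns=sample_ids))

    tissue_class = [ck.split("_")[0] if ck.startswith("cancer") else ck for ck in sample_class]
    stage = [ck.split("_")[1] if ck.startswith("cancer") else "none" for ck in sample_class]
    meta = SampleMetadata(
        pd.DataFrame(
            {"tissue_class": tissue_class, "stage": stage, "cohort": "synthetic-tissue"},
            index=sample_ids,
        )
    )
    annot = ProbeAnnotation(probe_gene_s.copy())

    drv_means = probe_class_means.groupby(probe_gene_s).mean().reindex(driver_genes)
    truth = GroundTruth(
        driver_directions=directions,
        driver_class_means=drv_means,
        panel_genes=panel_genes,
        # under the caller's naming rule a gene whose probes form one cluster
        # is named by the bare gene symbol; panel genes are built that way
        panel_cluster_ids=list(panel_genes),
        probe_class_means=probe_class_means,
        probe_gene=probe_gene_s,
    )
    return meth, expr, meta, annot, truth


_STAGE_TO_CLASS = {"0": "cancer_I", "I": "cancer_I", "II": "cancer_II", "III": "cancer_III", "IV": "cancer_IV"}


def generate_cfdna_cohort(
    spec: CohortSpec,
    truth: GroundTruth,
    fractions: dict[str, float] | None = None,
) -> tuple[MethylationMatrix, SampleMetadata]:
    """cfDNA betas as a tumor-fraction mixture.

    Each cfDNA sample of stage ``s`` draws, per probe,
    ``f_s * Beta(tumor mean, phi_tissue) + (1 - f_s) * Beta(normal mean,
    phi_cfdna)``; healthy plasma uses ``f = 0``.  The leukocyte background
    mean equals the normal-tissue mean.
    """
    if truth.probe_class_means is None:
        raise ValueError("ground truth lacks probe-level class means")
    fractions = dict(truth.stage_fractions if fractions is None else fractions)
    for st, f in fractions.items():
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"tumor fraction for stage {st!r} outside [0, 1]: {f}")

    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 977]))
    probes = list(truth.probe_class_means.index)
    bg_mu = truth.probe_class_means["normal"].to_numpy()

    sample_ids: list[str] = []
    stages: list[str] = []
    cols: list[np.ndarray] = []
    for group, n in spec.n_cfdna_per_group.items():
        stage = "none" if group == "healthy" else group
        f = fractions.get(stage, fractions.get(group, 0.0))
        tumor_mu = (
            truth.probe_class_means[_STAGE_TO_CLASS[stage]].to_numpy()
            if stage != "none"
            else bg_mu
        )
        tumor = rng.beta(tumor_mu * spec.phi_tissue, (1 - tumor_mu) * spec.phi_tissue, size=(n, len(probes)))
        bg = rng.beta(bg_mu * spec.phi_cfdna, (1 - bg_mu) * spec.phi_cfdna, size=(n, len(probes)))
        mixed = f * tumor + (1 - f) * bg
        for r in range(n):
            sample_ids.append(f"CF_{group}_{r:03d}")
            stages.append(stage)
            cols.append(mixed[r])

    meth = MethylationMatrix(
        pd.DataFrame(np.column_stack(cols), index=probes, columns=sample_ids)
    )
    meta = SampleMetadata(
        pd.DataFrame(
            {"tissue_class": "cfdna", "stage": stages, "cohort": "synthetic-cfdna"},
            index=sample_ids,
        )
    )
    return meth, meta


def synthesize_gene_sets(
    universe: list[str],
    planted_members: list[str],
    n_random: int = 20,
    set_size: int = 10,
    seed: int = 0,
) -> GeneSetCollection:
    """A GMT-style collection: one planted co-methylation set + random sets."""
    rng = np.random.default_rng(seed)
    sets = [
        GeneSet(
            "PLANTED_COMETHYLATION",
            "clusters sharing the planted latent factor",
            tuple(planted_members),
        )
    ]
    for i in range(n_random):
        members = rng.choice(universe, size=min(set_size, len(universe)), replace=False)
        sets.append(GeneSet(f"RANDOM_SET_{i:02d}", "random background set", tuple(sorted(members))))
    return GeneSetCollection(sets)
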