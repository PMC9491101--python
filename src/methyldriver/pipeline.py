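"""End-to-end pipeline: simulate -> call MDGs -> classify -> iRFE -> nulls
-> correlations -> single-gene GSEA -> cfDNA evaluation.

A single config (YAML-serializable) drives every stage; one master seed
deterministically derives all stage seeds, so a rerun with an identical
config reproduces every artifact byte for byte (timestamps appear only in
logs, never in outputs).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import core_io, gsea, mdg, panel_stats, synthetic
from .irfe import irfe as run_irfe
from .core_io import MethylationMatrix, SampleMetadata
from .discriminant import DiscriminantModel, fit_lda, roc_auc, score, split_train_test

log = logging.getLogger("methyldriver")

STAGE_ORDER = (
    "simulate", "mdg", "discriminant", "irfe", "null_auc", "correlate", "gsea", "cfdna",
)


@dataclass
class PipelineConfig:
    outdir: str = "methyldriver_run"
    seed: int = 0
    stages: dict[str, bool] = field(default_factory=lambda: {s: True for s in STAGE_ORDER})
    inputs: dict[str, str] = field(default_factory=dict)  # paths when a stage is disabled
    cohort: dict = field(default_factory=dict)  # CohortSpec overrides
    thresholds: dict = field(default_factory=dict)  # Thresholds overrides
    train_fraction: float = 0.7
    irfe_runs: int = 100
    irfe_vote: int = 50
    irfe_folds: int = 5
    null_b: int = 100
    corr_repeats: int = 100
    gsea_n_perm: int = 1000
    gsea_n_random_sets: int = 20
    gsea_set_size: int = 10
    stage_fractions: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for s in self.stages:
            if s not in STAGE_ORDER:
                raise ValueError(f"unknown stage {s!r}")
        self.stages = {s: self.stages.get(s, True) for s in STAGE_ORDER}
        self.validate()

    def validate(self) -> None:
        on = self.stages
        if not on["simulate"] and on["mdg"]:
            needed = {"meth", "expr", "meta", "annot"} - set(self.inputs)
            if needed:
                raise ValueError(f"mdg enabled without simulate: missing input paths {sorted(needed)}")
        if not on["mdg"] and any(on[s] for s in ("discriminant", "irfe", "null_auc", "correlate", "gsea")):
            if "mdg_matrix" not in self.inputs or "meta" not in self.inputs:
                raise ValueError(
                    "downstream stages enabled without the mdg stage: provide "
                    "'mdg_matrix' and 'meta' input paths"
                )
        if on["cfdna"] and not on["simulate"] and "cfdna" not in self.inputs:
            raise ValueError("cfdna stage enabled without simulate: missing 'cfdna' input path")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def non_default_params(self) -> dict:
        ref = asdict(PipelineConfig(outdir=self.outdir))
        cur = asdict(self)
        return {k: v for k, v in cur.items() if ref.get(k) != v}


@dataclass
class StageReport:
    stage: str
    inputs_digest: str
    params: dict
    metrics: dict
    status: str = "ok"

    def as_dict(self) -> dict:
        return asdict(self)


def _digest(df: pd.DataFrame) -> str:
    h = hashlib.sha256()
    h.update(",".join(map(str, df.index)).encode())
    h.update(",".join(map(str, df.columns)).encode())
    h.update(np.ascontiguousarray(df.to_numpy(float)).tobytes())
    return h.hexdigest()[:16]


def cfdna_evaluate(
    model: DiscriminantModel,
    cfdna: MethylationMatrix,
    meta: SampleMetadata,
    alpha: float = 0.01,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply a tissue-trained model unchanged to cfDNA, stage by stage.

    Returns a per-stage AUC table (each stage group vs healthy cfDNA) and a
    per-panel-feature, per-stage Wilcoxon rank-sum p table.  Stages with
    fewer than 2 samples are skipped with a warning.
    """
    missing = [f for f in model.features if f not in cfdna.data.index]
    if missing:
        raise ValueError(f"cfDNA matrix lacks model feature(s): {missing}")
    stages_s = meta.stage().loc[[s for s in cfdna.sample_ids if s in meta.data.index]]
    healthy = list(stages_s.index[stages_s == "none"])
    if len(healthy) < 2:
        raise ValueError("need at least 2 healthy cfDNA samples")
    sc_all = score(model, cfdna.data)

    auc_rows = []
    p_rows = []
    for st in [s for s in core_io.STAGES if s != "none"]:
        ids = list(stages_s.index[stages_s == st])
        if len(ids) == 0:
            continue
        if len(ids) < 2:
            log.warning("cfDNA stage %s has < 2 samples; skipped", st)
            continue
        labels = pd.Series(
            ["case"] * len(ids) + ["healthy"] * len(healthy), index=ids + healthy
        )
        auc = roc_auc(sc_all.loc[ids + healthy], labels, "case").auc
        auc_rows.append({"stage": st, "n_case": len(ids), "n_healthy": len(healthy), "auc": auc})
        for f in model.features:
            res = panel_stats.group_compare(
                cfdna.data.loc[f, ids + healthy], labels, [("case", "healthy")], alpha
            )
            p_rows.append({"stage": st, "feature": f, "p": res["p"].iloc[0],
                           "significant": bool(res["significant"].iloc[0])})
    return pd.DataFrame(auc_rows), pd.DataFrame(p_rows)


def _tissue_labels(meta: SampleMetadata, samples: list[str]) -> pd.Series:
    """cancer vs normal-like (healthy normal + cancer-adjacent) labels."""
    cls = meta.tissue_class().loc[samples]
    lab = cls.map(lambda c: "cancer" if c == "cancer" else ("normal" if c in ("normal", "adjacent") else None))
    return lab.dropna()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all enabled stages in order; return and write the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage_seeds = np.random.SeedSequence(config.seed).generate_state(16) % (2**31 - 1)
    reports: list[StageReport] = []
    manifest = {"config": asdict(config), "non_default_params": config.non_default_params(),
                "stages": []}

    state: dict = {}
    current_stage = "setup"
    try:
        # ------------------------------------------------------------- simulate
        current_stage = "simulate"
        if config.stages["simulate"]:
            spec = synthetic.CohortSpec(**{**config.cohort, "seed": int(stage_seeds[0])})
            meth, expr, meta, annot, truth = synthetic.generate_tissue_cohort(spec)
            fractions = dict(truth.stage_fractions)
            fractions.update(config.stage_fractions)
            truth.stage_fractions = fractions
            cfdna_m, cfdna_meta = synthetic.generate_cfdna_cohort(spec, truth, fractions)
            core_io.write_matrix(meth, outdir / "methylation.tsv")
            core_io.write_matrix(expr, outdir / "expression.tsv")
            core_io.write_metadata(meta, outdir / "samples.tsv")
            core_io.write_annotation(annot, outdir / "annotation.tsv")
            core_io.write_matrix(cfdna_m, outdir / "cfdna.tsv")
            core_io.write_metadata(cfdna_meta, outdir / "cfdna_samples.tsv")
            (outdir / "ground_truth.json").write_text(truth.to_json())
            state.update(meth=meth, expr=expr, meta=meta, annot=annot, truth=truth,
                         cfdna=cfdna_m, cfdna_meta=cfdna_meta)
            reports.append(StageReport(
                "simulate", _digest(meth.data),
                {"seed": int(stage_seeds[0]), "n_genes": spec.n_genes,
                 "n_driver_genes": spec.n_driver_genes},
                {"n_probes": len(meth.feature_ids), "n_samples": len(meth.sample_ids),
                 "n_cfdna": len(cfdna_m.sample_ids)},
            ))
        elif config.stages["mdg"] or config.stages["cfdna"]:
            if "meth" in config.inputs:
                state["meth"] = core_io.read_matrix(config.inputs["meth"], "methylation")
                state["expr"] = core_io.read_matrix(config.inputs["expr"], "expression")
                state["annot"] = core_io.read_annotation(config.inputs["annot"])
            if "meta" in config.inputs:
                state["meta"] = core_io.read_metadata(config.inputs["meta"])
            if "cfdna" in config.inputs:
                state["cfdna"] = core_io.read_matrix(config.inputs["cfdna"], "methylation")
                state["cfdna_meta"] = core_io.read_metadata(config.inputs["cfdna_meta"])
            state["truth"] = None

        # ------------------------------------------------------------------ mdg
        current_stage = "mdg"
        if config.stages["mdg"]:
            th = mdg.Thresholds(**config.thresholds)
            results, mdg_matrix = mdg.call_all(
                state["meth"], state["expr"], state["meta"], state["annot"], th
            )
            table = mdg.driver_table(results)
            table.to_csv(outdir / "driver_table.tsv", sep="\t", index=False)
            core_io.write_matrix(mdg_matrix, outdir / "mdg_matrix.tsv")
            driver_defs = [d for r in results for d in r.driver_clusters]
            pd.DataFrame(
                [{"cluster_id": d.cluster_id, "gene": d.gene, "probes": ",".join(d.probe_ids)}
                 for d in driver_defs]
            ).to_csv(outdir / "driver_clusters.tsv", sep="\t", index=False)
            state.update(mdg_results=results, mdg_matrix=mdg_matrix, driver_defs=driver_defs)
            metrics = {
                "n_genes_called": len(results),
                "n_driver_genes": int(sum(r.is_driver for r in results)),
                "n_driver_clusters": len(driver_defs),
            }
            truth = state.get("truth")
            if truth is not None:
                called = {r.gene for r in results if r.is_driver}
                planted = set(truth.driver_genes)
                metrics["sensitivity"] = len(called & planted) / len(planted)
                n_null = len(results) - len(planted)
                metrics["false_driver_rate"] = len(called - planted) / max(n_null, 1)
            reports.append(StageReport(
                "mdg", _digest(state["meth"].data), asdict(th), metrics))
        elif any(config.stages[s] for s in ("discriminant", "irfe", "null_auc", "correlate", "gsea")):
            state["mdg_matrix"] = core_io.read_matrix(config.inputs["mdg_matrix"], "methylation")
            if "meta" not in state:
                state["meta"] = core_io.read_metadata(config.inputs["meta"])

        # --------------------------------------------------------- discriminant
        current_stage = "discriminant"
        if config.stages["discriminant"]:
            X = state["mdg_matrix"].data
            labels = _tissue_labels(state["meta"], list(X.columns))
            X = X[labels.index]
            train_ids, test_ids = split_train_test(
                labels, config.train_fraction, int(stage_seeds[1])
            )
            model = fit_lda(X[train_ids], labels.loc[train_ids], "cancer")
            test_auc = roc_auc(
                score(model, X[test_ids]), labels.loc[test_ids], "cancer"
            ).auc
            model.to_json(outdir / "lda_model.json")
            state.update(X=X, labels=labels, train_ids=train_ids, test_ids=test_ids)
            reports.append(StageReport(
                "discriminant", _digest(X),
                {"train_fraction": config.train_fraction, "seed": int(stage_seeds[1]),
                 "shrinkage": model.shrinkage},
                {"n_features": X.shape[0], "n_train": len(train_ids),
                 "n_test": len(test_ids), "test_auc": test_auc},
            ))

        # ----------------------------------------------------------------- irfe
        current_stage = "irfe"
        if config.stages["irfe"]:
            X, labels = state["X"], state["labels"]
            train_ids, test_ids = state["train_ids"], state["test_ids"]
            panel = run_irfe(
                X[train_ids], labels.loc[train_ids], "cancer",
                n_runs=config.irfe_runs, vote=config.irfe_vote,
                seed=int(stage_seeds[2]), folds=config.irfe_folds,
            )
            panel_model = fit_lda(
                X.loc[panel.survivors, train_ids], labels.loc[train_ids], "cancer"
            )
            holdout_auc = roc_auc(
                score(panel_model, X.loc[panel.survivors, test_ids]),
                labels.loc[test_ids], "cancer",
            ).auc
            (outdir / "panel.json").write_text(json.dumps({
                "survivors": panel.survivors, "history": panel.history,
                "generations": panel.generation, "converged": panel.converged,
                "counts": panel.counts, "holdout_auc": holdout_auc,
            }, indent=2))
            panel_model.to_json(outdir / "panel_model.json")
            state.update(panel=panel, panel_model=panel_model, holdout_auc=holdout_auc)
            reports.append(StageReport(
                "irfe", _digest(X[train_ids]),
                {"n_runs": config.irfe_runs, "vote": config.irfe_vote,
                 "seed": int(stage_seeds[2])},
                {"panel": panel.survivors, "history": panel.history,
                 "converged": panel.converged, "holdout_auc": holdout_auc},
            ))

        # ------------------------------------------------------------- null_auc
        current_stage = "null_auc"
        if config.stages["null_auc"]:
            X, labels = state["X"], state["labels"]
            null = panel_stats.random_panel_null(
                X[state["train_ids"]], labels.loc[state["train_ids"]],
                X[state["test_ids"]], labels.loc[state["test_ids"]],
                "cancer", k=len(state["panel"].survivors),
                observed_auc=state["holdout_auc"], B=config.null_b,
                seed=int(stage_seeds[3]),
            )
            reports.append(StageReport(
                "null_auc", _digest(X), {"B": config.null_b, "k": null.k},
                {"observed_auc": null.observed_auc, "null_mean": float(null.null_aucs.mean()),
                 "t": null.t, "p": null.p, "empirical_p": null.empirical_p},
            ))

        # ------------------------------------------------------------ correlate
        current_stage = "correlate"
        if config.stages["correlate"]:
            X = state["X"]
            strata = state["meta"].tissue_class().loc[X.columns]
            strata = strata[strata.isin(["cancer", "adjacent"])]
            report = panel_stats.panel_correlations(
                X[strata.index], strata, state["panel"].survivors
            )
            baseline = panel_stats.random_panel_correlation_baseline(
                X[strata.index], k=len(state["panel"].survivors),
                repeats=config.corr_repeats, seed=int(stage_seeds[4]),
            )
            iu = np.triu_indices(len(report.panel), 1)
            metrics = {
                "baseline_mean_abs_r": baseline.mean_abs_r,
                "panel_mean_abs_r": {
                    st: float(np.nanmean(np.abs(m.to_numpy()[iu])))
                    for st, m in report.strata.items()
                },
                # stratum-matched baselines: random same-size panels drawn
                # within each stratum, comparable to the per-stratum panel r
                "baseline_mean_abs_r_by_stratum": {
                    st: panel_stats.random_panel_correlation_baseline(
                        X[strata.index[strata == st]],
                        k=len(state["panel"].survivors),
                        repeats=config.corr_repeats, seed=int(stage_seeds[4]),
                    ).mean_abs_r
                    for st in sorted(strata.unique())
                },
            }
            for st, m in report.strata.items():
                m.to_csv(outdir / f"panel_correlation_{st}.tsv", sep="\t")
            reports.append(StageReport(
                "correlate", _digest(X), {"repeats": config.corr_repeats}, metrics))

        # ----------------------------------------------------------------- gsea
        current_stage = "gsea"
        if config.stages["gsea"]:
            X = state["mdg_matrix"].data
            universe = list(X.index)
            truth = state.get("truth")
            planted = (
                [c for c in truth.panel_cluster_ids if c in universe]
                if truth is not None else list(state["panel"].survivors)
            )
            sets = synthetic.synthesize_gene_sets(
                universe, planted, n_random=config.gsea_n_random_sets,
                set_size=config.gsea_set_size, seed=int(stage_seeds[5]),
            )
            core_io.write_gmt(sets, outdir / "gene_sets.gmt")
            target = sorted(state["panel"].survivors)[0]
            ranked = gsea.rank_by_correlation(X, target)
            results = [
                gsea.nes_and_p(ranked, s, n_perm=config.gsea_n_perm,
                               seed=int(stage_seeds[6]))
                for s in sets
            ]
            top = gsea.top_sets_report(results, 10)
            pd.DataFrame(
                [{"set": r.set_name, "es": r.es, "nes": r.nes, "p": r.p} for r in top]
            ).to_csv(outdir / "gsea_top10.tsv", sep="\t", index=False)
            planted_res = next(r for r in results if r.set_name == "PLANTED_COMETHYLATION")
            reports.append(StageReport(
                "gsea", _digest(X),
                {"target": target, "n_perm": config.gsea_n_perm},
                {"top_set": top[0].set_name, "top_nes": top[0].nes,
                 "planted_set_nes": planted_res.nes, "planted_set_p": planted_res.p},
            ))

        # ---------------------------------------------------------------- cfdna
        current_stage = "cfdna"
        if config.stages["cfdna"]:
            cf_cluster = core_io.aggregate_clusters(
                state["cfdna"],
                [d for d in state["driver_defs"] if d.cluster_id in state["panel"].survivors]
                if "driver_defs" in state else [],
            ) if "driver_defs" in state else state["cfdna"]
            auc_table, p_table = cfdna_evaluate(
                state["panel_model"], cf_cluster, state["cfdna_meta"]
            )
            auc_table.to_csv(outdir / "cfdna_auc.tsv", sep="\t", index=False)
            p_table.to_csv(outdir / "cfdna_feature_p.tsv", sep="\t", index=False)
            reports.append(StageReport(
                "cfdna", _digest(cf_cluster.data), {},
                {"stage_auc": {row["stage"]: row["auc"] for _, row in auc_table.iterrows()}},
            ))
    except Exception as exc:
        failed_stage = current_stage
        manifest["stages"] = [r.as_dict() for r in reports]
        manifest["status"] = "failed"
        manifest["failed_stage"] = failed_stage
        manifest["error"] = str(exc)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"pipeline failed at stage {failed_stage!r}: {exc}") from exc

    manifest["stages"] = [r.as_dict() for r in reports]
    manifest["status"] = "ok"
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
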