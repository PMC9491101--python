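"""Shared fixtures: small cohorts for unit tests, the full study-scale
cohort (generated once per session) for the end-to-end recovery checks."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

from methyldriver.discriminant import fit_lda, roc_auc, score, split_train_test
from methyldriver.irfe import irfe
from methyldriver.mdg import call_all
from methyldriver.synthetic import CohortSpec, generate_tissue_cohort


def cancer_vs_normal_labels(meta) -> pd.Series:
    cls = meta.tissue_class()
    lab = cls.map(
        lambda c: "cancer" if c == "cancer" else ("normal" if c in ("normal", "adjacent") else None)
    )
    return lab.dropna()


@pytest.fixture(scope="session")
def small_cohort():
    """A 150-gene / 15-driver cohort: fast, same structure as the default."""
    spec = CohortSpec(n_genes=150, n_driver_genes=15, seed=7)
    return spec, generate_tissue_cohort(spec)


@pytest.fixture(scope="session")
def study_cohort():
    """The default study-scale cohort (2000 genes / 100 drivers), seed 1."""
    spec = CohortSpec(seed=1)
    return spec, generate_tissue_cohort(spec)


@pytest.fixture(scope="session")
def study_mdg(study_cohort):
    """Driver calls and the driver-cluster matrix on the study cohort."""
    _, (meth, expr, meta, annot, _) = study_cohort
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        results, matrix = call_all(meth, expr, meta, annot)
    return results, matrix


@pytest.fixture(scope="session")
def study_panel(study_cohort, study_mdg):
    """70/30 split, iRFE panel and its held-out panel model on the study cohort."""
    _, (_, _, meta, _, _) = study_cohort
    _, matrix = study_mdg
    labels = cancer_vs_normal_labels(meta)
    X = matrix.data[labels.index]
    train_ids, test_ids = split_train_test(labels, 0.7, seed=1)
    panel = irfe(X[train_ids], labels.loc[train_ids], "cancer", n_runs=100, vote=50, seed=1)
    model = fit_lda(X.loc[panel.survivors, train_ids], labels.loc[train_ids], "cancer")
    holdout_auc = roc_auc(
        score(model, X.loc[panel.survivors, test_ids]), labels.loc[test_ids], "cancer"
    ).auc
    return {
        "X": X, "labels": labels, "train_ids": train_ids, "test_ids": test_ids,
        "panel": panel, "model": model, "holdout_auc": holdout_auc,
    }
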