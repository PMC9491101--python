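"""Probe clustering, mixture EM, and driver calling."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest

from methyldriver.core_io import MethylationMatrix
from methyldriver.mdg import (
    Thresholds,
    call_all,
    call_driver,
    cluster_probes,
    fit_beta_value_mixture,
)
from methyldriver.core_io import ClusterDefinition


def _rows(values, probes):
    return pd.DataFrame(values, index=probes)


class TestClusterProbes:
    def test_single_probe_single_cluster(self):
        defs = cluster_probes(_rows([[0.1, 0.2, 0.3]], ["p1"]), "G")
        assert len(defs) == 1
        assert defs[0].cluster_id == "G" and defs[0].probe_ids == ("p1",)

    def test_highly_correlated_pair_merges(self):
        rng = np.random.default_rng(0)
        base = rng.random(50)
        x = base + rng.normal(0, 0.05, 50)
        y = base + rng.normal(0, 0.05, 50)
        defs = cluster_probes(_rows([x, y], ["p1", "p2"]), "G", r_cluster=0.4)
        assert len(defs) == 1 and set(defs[0].probe_ids) == {"p1", "p2"}

    def test_two_pairs_match_brute_force_partition(self):
        rng = np.random.default_rng(1)
        f1, f2 = rng.random(60), rng.random(60)
        rows = np.array([
            f1 + rng.normal(0, 0.1, 60),
            f1 + rng.normal(0, 0.1, 60),
            f2 + rng.normal(0, 0.1, 60),
            f2 + rng.normal(0, 0.1, 60),
        ])
        probes = ["pa", "pb", "pc", "pd"]
        defs = cluster_probes(_rows(rows, probes), "G", r_cluster=0.4)
        got = {frozenset(d.probe_ids) for d in defs}

        # oracle: exhaustive search over partitions of 4 probes maximizing
        # total within-cluster correlation, subject to mean within r >= 0.4
        corr = np.corrcoef(rows)
        idx = {p: i for i, p in enumerate(probes)}

        def partitions(items):
            if not items:
                yield []
                return
            first, rest = items[0], items[1:]
            for part in partitions(rest):
                for i, block in enumerate(part):
                    yield part[:i] + [[first] + block] + part[i + 1:]
                yield [[first]] + part

        def mean_r(block):
            pairs = list(itertools.combinations(block, 2))
            if not pairs:
                return 1.0
            return float(np.mean([corr[idx[a], idx[b]] for a, b in pairs]))

        best, best_score = None, -np.inf
        for part in partitions(probes):
            if all(mean_r(b) >= 0.4 for b in part):
                score = sum(mean_r(b) * (len(b) > 1) * len(b) for b in part)
                if score > best_score:
                    best, best_score = part, score
        assert got == {frozenset(b) for b in best}

    def test_naming_by_first_appearance(self):
        rng = np.random.default_rng(2)
        rows = rng.random((3, 40))  # independent -> three singleton clusters
        defs = cluster_probes(_rows(rows, ["p1", "p2", "p3"]), "G", r_cluster=0.4)
        assert [d.cluster_id for d in defs] == ["G-Cluster1", "G-Cluster2", "G-Cluster3"]

    def test_constant_probe_goes_to_singleton_with_warning(self):
        rng = np.random.default_rng(3)
        rows = np.vstack([np.full(30, 0.5), rng.random(30)])
        with pytest.warns(UserWarning, match="constant"):
            defs = cluster_probes(_rows(rows, ["pc", "pv"]), "G")
        assert {d.probe_ids for d in defs} == {("pc",), ("pv",)}


class TestMixtureFit:
    def test_single_component_recovery(self):
        rng = np.random.default_rng(0)
        x = np.clip(rng.normal(0.3, 0.03, 200), 0, 1)
        fit = fit_beta_value_mixture(x)
        assert fit.k == 1
        assert abs(fit.means[0] - 0.3) < 0.01

    def test_two_component_recovery(self):
        rng = np.random.default_rng(1)
        x = np.clip(np.r_[rng.normal(0.2, 0.05, 100), rng.normal(0.7, 0.05, 100)], 0, 1)
        fit = fit_beta_value_mixture(x)
        assert fit.k == 2
        means = np.sort(fit.means)
        assert abs(means[0] - 0.2) < 0.03 and abs(means[1] - 0.7) < 0.03
        assert np.all(np.abs(fit.weights - 0.5) < 0.1)

    def test_bic_selects_truth_at_large_n(self):
        rng = np.random.default_rng(4)
        x = np.clip(np.r_[rng.normal(0.25, 0.05, 250), rng.normal(0.65, 0.05, 250)], 0, 1)
        assert fit_beta_value_mixture(x).k == 2

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_em_likelihood_monotone(self, seed):
        rng = np.random.default_rng(seed)
        x = np.clip(rng.beta(2, 3, 80), 0, 1)
        fit = fit_beta_value_mixture(x, k_candidates=(2,))
        assert np.all(np.diff(fit.ll_trace) >= -1e-8)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="at least 10"):
            fit_beta_value_mixture(np.linspace(0, 1, 5))
        with pytest.raises(ValueError, match="degenerate"):
            fit_beta_value_mixture(np.full(20, 0.4))
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            fit_beta_value_mixture(np.linspace(-0.2, 0.5, 20))


def _driver_vectors(rng, n_dis=80, n_nor=60, shift=0.25, slope=6.0):
    normal = np.clip(rng.normal(0.3, 0.05, n_nor), 0, 1)
    disease = np.clip(rng.normal(0.3 + shift, 0.08, n_dis), 0, 1)
    expr = 8.0 - slope * disease + rng.normal(0, 0.5, n_dis)
    return disease, normal, expr


class TestCallDriver:
    def test_planted_hypermethylated_driver_is_called(self):
        rng = np.random.default_rng(0)
        disease, normal, expr = _driver_vectors(rng)
        cd = ClusterDefinition("G", "G", ("p",))
        call = call_driver("G", cd, disease, normal, expr)
        assert call.is_driver
        assert max(abs(c.dm) for c in call.components) > 0.1
        assert call.r < -0.3

    def test_null_gene_not_called(self):
        rng = np.random.default_rng(1)
        normal = np.clip(rng.normal(0.4, 0.05, 60), 0, 1)
        disease = np.clip(rng.normal(0.4, 0.05, 80), 0, 1)
        expr = rng.normal(8, 1, 80)
        call = call_driver("G", ClusterDefinition("G", "G", ("p",)), disease, normal, expr)
        assert not call.is_driver

    def test_positively_coupled_gene_fails_inverse_filter(self):
        rng = np.random.default_rng(2)
        disease, normal, _ = _driver_vectors(rng)
        expr_pos = 2.0 + 6.0 * disease + rng.normal(0, 0.5, disease.size)
        call = call_driver("G", ClusterDefinition("G", "G", ("p",)), disease, normal, expr_pos)
        assert call.r > 0.3
        assert not call.is_driver

    def test_requires_three_normals(self):
        rng = np.random.default_rng(3)
        disease, _, expr = _driver_vectors(rng)
        with pytest.raises(ValueError, match="3 normal"):
            call_driver("G", ClusterDefinition("G", "G", ("p",)), disease, np.array([0.3, 0.4]), expr)

    def test_dm_invariant_to_sample_order(self):
        rng = np.random.default_rng(4)
        disease, normal, expr = _driver_vectors(rng)
        call1 = call_driver("G", ClusterDefinition("G", "G", ("p",)), disease, normal, expr)
        perm = rng.permutation(disease.size)
        call2 = call_driver("G", ClusterDefinition("G", "G", ("p",)), disease[perm], normal[::-1], expr[perm])
        dm1 = sorted(c.dm for c in call1.components)
        dm2 = sorted(c.dm for c in call2.components)
        np.testing.assert_allclose(dm1, dm2, atol=1e-9)


class TestCallAll:
    def test_recovers_planted_drivers_on_small_cohort(self, small_cohort):
        _, (meth, expr, meta, annot, truth) = small_cohort
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            results, matrix = call_all(meth, expr, meta, annot)
        called = {r.gene for r in results if r.is_driver}
        planted = set(truth.driver_genes)
        sens = len(called & planted) / len(planted)
        fdr_rate = len(called - planted) / (len(results) - len(planted))
        assert sens >= 0.9
        assert fdr_rate <= 0.05
        assert set(matrix.sample_ids) == set(meth.sample_ids)

    def test_impossible_threshold_yields_no_drivers(self, small_cohort):
        _, (meth, expr, meta, annot, _) = small_cohort
        sub_probes = meth.feature_ids[:80]
        sub = MethylationMatrix(meth.data.loc[sub_probes])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            results, matrix = call_all(sub, expr, meta, annot, Thresholds(dm_min=1.0))
        assert sum(r.is_driver for r in results) == 0
        assert matrix.data.shape[0] == 0

    def test_null_cohort_respects_alpha(self):
        from methyldriver.synthetic import CohortSpec, generate_tissue_cohort
        spec = CohortSpec(
            n_genes=200, n_driver_genes=20, seed=31,
            effect_profile={"adenoma_low": 0.0, "adenoma_high": 0.0, "cancer": 0.0},
            expression_slope=0.0,
        )
        meth, expr, meta, annot, _ = generate_tissue_cohort(spec)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            results, _ = call_all(meth, expr, meta, annot)
        rate = sum(r.is_driver for r in results) / len(results)
        assert rate <= 0.02  # alpha = 0.01 on two joint filters, plus slack
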