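"""I/O round-trips, NA handling, PCA screening and beta aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from methyldriver.core_io import (
    ClusterDefinition,
    GeneSet,
    GeneSetCollection,
    MethylationMatrix,
    aggregate_clusters,
    drop_na_probes,
    gene_level_methylation,
    pca_outlier_screen,
    read_gmt,
    read_matrix,
    write_gmt,
    write_matrix,
)
from methyldriver.panels import panel_cluster_definitions, panel_probe_table


def _mm(values, probes=None, samples=None) -> MethylationMatrix:
    values = np.asarray(values, float)
    probes = probes or [f"cg{i:08d}" for i in range(values.shape[0])]
    samples = samples or [f"S{j}" for j in range(values.shape[1])]
    return MethylationMatrix(pd.DataFrame(values, index=probes, columns=samples))


class TestReadWrite:
    def test_round_trip_preserves_values_exactly(self, tmp_path):
        rng = np.random.default_rng(0)
        m = _mm(rng.random((5, 4)))
        path = tmp_path / "m.tsv"
        write_matrix(m, path)
        back = read_matrix(path, "methylation")
        pd.testing.assert_frame_equal(m.data, back.data)

    def test_expression_round_trip_allows_negatives(self, tmp_path):
        df = pd.DataFrame([[1.5, -2.25], [0.0, 8.125]], index=["g1", "g2"], columns=["a", "b"])
        path = tmp_path / "e.csv"
        df.to_csv(path)
        back = read_matrix(path, "expression")
        pd.testing.assert_frame_equal(df.astype(float), back.data)

    def test_beta_out_of_range_names_offender(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("id\tS1\tS2\ncg1\t0.5\t0.7\ncg2\t1.2\t0.3\n")
        with pytest.raises(ValueError, match="cg2"):
            read_matrix(path, "methylation")

    def test_duplicate_ids_rejected(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text("id\tS1\tS2\ncg1\t0.5\t0.7\ncg1\t0.2\t0.3\n")
        with pytest.raises(ValueError, match="cg1"):
            read_matrix(path, "methylation")
        path.write_text("id\tS1\tS1\ncg1\t0.5\t0.7\n")
        with pytest.raises(ValueError, match="S1"):
            read_matrix(path, "methylation")

    def test_na_tokens_parse_as_missing(self, tmp_path):
        path = tmp_path / "na.tsv"
        path.write_text("id\tS1\tS2\ncg1\t0.5\tNA\ncg2\t0.2\t0.3\n")
        m = read_matrix(path, "methylation")
        assert m.n_missing() == 1
        kept = drop_na_probes(m)
        assert kept.feature_ids == ["cg2"]


class TestDropNaProbes:
    def test_probe_with_single_na_removed(self):
        m = _mm([[0.1, 0.2], [0.3, np.nan], [0.5, 0.6]])
        out = drop_na_probes(m)
        assert out.feature_ids == [m.feature_ids[0], m.feature_ids[2]]
        assert out.sample_ids == m.sample_ids

    def test_complete_matrix_unchanged(self):
        m = _mm(np.full((3, 2), 0.5))
        pd.testing.assert_frame_equal(drop_na_probes(m).data, m.data)

    def test_matches_independent_row_scan(self):
        rng = np.random.default_rng(42)
        values = rng.random((100, 20))
        na_rows = rng.choice(100, size=10, replace=False)
        for i in na_rows:
            values[i, rng.integers(0, 20)] = np.nan
        m = _mm(values)
        out = drop_na_probes(m)
        # independent oracle: per-row python scan
        expected = [
            pid for pid, row in zip(m.feature_ids, values)
            if not any(np.isnan(v) for v in row)
        ]
        assert out.feature_ids == expected
        assert len(out.feature_ids) == 90

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        values = rng.random((20, 5))
        values[rng.integers(0, 20, 4), 0] = np.nan
        once = drop_na_probes(_mm(values))
        twice = drop_na_probes(once)
        pd.testing.assert_frame_equal(once.data, twice.data)

    def test_all_probes_missing_is_an_error(self):
        m = _mm([[np.nan, 0.2], [0.3, np.nan]])
        with pytest.raises(ValueError, match="no complete probes"):
            drop_na_probes(m)


class TestPcaOutlierScreen:
    def test_identical_samples_flag_nothing(self):
        m = _mm(np.tile(np.linspace(0.1, 0.9, 10)[:, None], (1, 6)))
        kept, flagged = pca_outlier_screen(m, k_sd=3.0)
        assert flagged == []
        assert kept == m.sample_ids

    def test_planted_outlier_is_the_only_flag(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0.5, 0.02, size=(50, 21))
        base[:, 20] += 10 * 0.02  # one sample shifted by 10 within-feature SDs
        m = _mm(np.clip(base, 0, 1))
        _, flagged = pca_outlier_screen(m, k_sd=3.0)
        assert flagged == [m.sample_ids[20]]

    def test_infinite_threshold_flags_nothing(self):
        rng = np.random.default_rng(1)
        m = _mm(rng.random((30, 8)))
        kept, flagged = pca_outlier_screen(m, k_sd=np.inf)
        assert flagged == [] and kept == m.sample_ids

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(2)
        base = rng.normal(0.5, 0.05, size=(40, 12))
        base[:, 3] += 0.5
        m = _mm(np.clip(base, 0, 1))
        _, flagged = pca_outlier_screen(m, k_sd=3.0)
        perm = rng.permutation(12)
        m2 = MethylationMatrix(m.data.iloc[:, perm])
        _, flagged2 = pca_outlier_screen(m2, k_sd=3.0)
        assert set(flagged) == set(flagged2)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="3 samples"):
            pca_outlier_screen(_mm(np.full((4, 2), 0.5)))


class TestAggregation:
    def test_published_panel_probes_collapse_to_four_clusters(self):
        table = panel_probe_table()
        rng = np.random.default_rng(0)
        m = _mm(rng.random((5, 3)), probes=list(table["probe_id"]))
        out = aggregate_clusters(m, panel_cluster_definitions())
        assert len(out.feature_ids) == 4
        assert len(m.feature_ids) == 5
        np.testing.assert_allclose(
            out.data.loc["ADHFE1-Cluster1"],
            m.data.loc[["cg01988129", "cg08090772"]].mean(axis=0),
        )

    def test_two_probe_cluster_is_the_mean(self):
        m = _mm([[0.2, 0.8], [0.4, 0.6]], probes=["p1", "p2"])
        out = aggregate_clusters(m, [ClusterDefinition("c", "G", ("p1", "p2"))])
        np.testing.assert_allclose(out.data.loc["c"], [0.3, 0.7])

    def test_single_probe_cluster_copies_the_row(self):
        m = _mm([[0.25, 0.75]], probes=["p1"])
        out = aggregate_clusters(m, [ClusterDefinition("G", "G", ("p1",))])
        np.testing.assert_array_equal(out.data.loc["G"], m.data.loc["p1"])

    def test_absent_probe_named_in_error(self):
        m = _mm([[0.5]], probes=["p1"])
        with pytest.raises(ValueError, match=r"cX.*pMissing|pMissing"):
            aggregate_clusters(m, [ClusterDefinition("cX", "G", ("pMissing",))])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_cluster_mean_contained_in_member_range(self, seed):
        rng = np.random.default_rng(seed)
        m = _mm(rng.random((6, 4)))
        defs = [
            ClusterDefinition("a", "G1", tuple(m.feature_ids[:3])),
            ClusterDefinition("b", "G2", tuple(m.feature_ids[3:])),
        ]
        out = aggregate_clusters(m, defs)
        for d in defs:
            member = m.data.loc[list(d.probe_ids)]
            assert (out.data.loc[d.cluster_id] >= member.min(axis=0) - 1e-12).all()
            assert (out.data.loc[d.cluster_id] <= member.max(axis=0) + 1e-12).all()

    def test_gene_level_mean_of_clusters(self):
        m = _mm([[0.1, 0.3], [0.5, 0.7]], probes=["c1", "c2"])
        defs = [ClusterDefinition("c1", "G", ("x",)), ClusterDefinition("c2", "G", ("y",))]
        out = gene_level_methylation(m, defs)
        np.testing.assert_allclose(out.data.loc["G"], [0.3, 0.5])

    def test_gene_level_matches_brute_force(self):
        rng = np.random.default_rng(5)
        m = _mm(rng.random((6, 3)), probes=[f"c{i}" for i in range(6)])
        defs = [
            ClusterDefinition(f"c{i}", f"G{i % 2}", (f"p{i}",)) for i in range(6)
        ]
        out = gene_level_methylation(m, defs)
        for g in ("G0", "G1"):
            members = [d.cluster_id for d in defs if d.gene == g]
            np.testing.assert_allclose(
                out.data.loc[g], m.data.loc[members].mean(axis=0)
            )

    def test_all_single_cluster_genes_pass_through(self):
        m = _mm([[0.2, 0.4]], probes=["c1"])
        out = gene_level_methylation(m, [ClusterDefinition("c1", "G", ("p",))])
        np.testing.assert_array_equal(out.data.loc["G"], m.data.loc["c1"])


class TestGmt:
    def test_minimal_line(self, tmp_path):
        path = tmp_path / "s.gmt"
        path.write_text("S1\tdesc\tg1\tg2\n")
        coll = read_gmt(path)
        assert len(coll) == 1
        assert coll["S1"].members == ("g1", "g2")

    def test_duplicate_set_name_rejected(self, tmp_path):
        path = tmp_path / "s.gmt"
        path.write_text("S1\td\tg1\nS1\td\tg2\n")
        with pytest.raises(ValueError, match="S1"):
            read_gmt(path)

    def test_short_line_reports_line_number(self, tmp_path):
        path = tmp_path / "s.gmt"
        path.write_text("S1\td\tg1\nS2\tonly-two-fields\n")
        with pytest.raises(ValueError, match="line 2"):
            read_gmt(path)

    def test_blank_lines_skipped_and_round_trip(self, tmp_path):
        rng = np.random.default_rng(9)
        sets = [
            GeneSet(f"S{i:02d}", f"d{i}", tuple(f"g{j}" for j in rng.choice(100, 5, replace=False)))
            for i in range(50)
        ]
        path = tmp_path / "many.gmt"
        write_gmt(GeneSetCollection(sets), path)
        text = path.read_text().replace("S25", "S25")  # keep content; add blank line
        path.write_text(text + "\n\n")
        back = read_gmt(path)
        assert len(back) == 50
        for s in sets:
            assert back[s.name].members == s.members
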