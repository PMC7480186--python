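import numpy as np
import pandas as pd
import pytest
from scipy import stats

from crossde.io import MICROARRAY, RNASEQ
from crossde.normalize import normalize_study
from crossde.de import run_de
from crossde.simulate import (
    SimulationConfig,
    generate_dual_study,
    generate_gene_sets,
    generate_ppi,
    write_simulation,
)


class TestConfigValidation:
    def test_bad_proportion_rejected(self):
        with pytest.raises(ValueError, match="de_fraction"):
            SimulationConfig(de_fraction=1.5)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="lfc_mean"):
            SimulationConfig(lfc_mean=float("nan"))

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="group_sizes"):
            SimulationConfig(group_sizes=(1, 5, 5, 5))


class TestDualStudy:
    def test_deterministic_under_seed(self):
        cfg = SimulationConfig(n_genes=300, group_sizes=(4, 4, 4, 4), seed=7)
        a1, r1, t1 = generate_dual_study(cfg)
        a2, r2, t2 = generate_dual_study(cfg)
        pd.testing.assert_frame_equal(a1.values, a2.values)
        pd.testing.assert_frame_equal(r1.values, r2.values)
        pd.testing.assert_frame_equal(t1, t2)

    def test_structure_and_metadata(self, small_simulation, small_config):
        array_study, rnaseq_study, truth = small_simulation
        assert array_study.platform == MICROARRAY
        assert rnaseq_study.platform == RNASEQ
        assert list(array_study.gene_ids) == list(rnaseq_study.gene_ids) == list(truth.index)
        assert (array_study.values.to_numpy() >= 0).all()
        assert rnaseq_study.values.dtypes.eq(np.int64).all()
        n_ac, n_actl, n_rc, n_rctl = small_config.group_sizes
        assert (array_study.samples["group"] == "case").sum() == n_ac
        assert (rnaseq_study.samples["group"] == "control").sum() == n_rctl
        assert set(array_study.samples["study"]) == {"array_study"}

    def test_truth_bookkeeping(self, small_simulation, small_config):
        *_, truth = small_simulation
        n_de = truth["is_de"].sum()
        expected = small_config.de_fraction * small_config.n_genes
        assert abs(n_de - expected) <= 3 * np.sqrt(expected)
        de = truth[truth["is_de"]]
        assert (de[["true_lfc_array", "true_lfc_rnaseq"]].abs().sum(axis=1) > 0).all()
        assert (truth.loc[~truth["is_de"], ["true_lfc_array", "true_lfc_rnaseq"]] == 0).all().all()
        discordant = (np.sign(de["true_lfc_array"]) != np.sign(de["true_lfc_rnaseq"])).mean()
        p = small_config.discordant_fraction
        assert abs(discordant - p) <= 3 * np.sqrt(p * (1 - p) / len(de)) + 1 / len(de)

    def test_mean_effect_size_near_configured(self, default_simulation):
        *_, truth = default_simulation
        de = truth[truth["is_de"]]
        mean_abs = de["true_lfc_array"].abs().mean()
        se = SimulationConfig().lfc_sd / np.sqrt(len(de))
        assert abs(mean_abs - SimulationConfig().lfc_mean) <= 3 * se + 0.01

    def test_null_case_has_no_de_and_uniform_p(self):
        cfg = SimulationConfig(n_genes=10_000, group_sizes=(10, 10, 8, 12),
                               de_fraction=0.0, dropout_fraction=0.0, seed=11)
        array_study, rnaseq_study, truth = generate_dual_study(cfg)
        assert truth["is_de"].sum() == 0
        for study in (array_study, rnaseq_study):
            de = run_de(normalize_study(study))
            assert stats.kstest(de["p"], "uniform").pvalue > 0.01

    def test_dropout_genes_mostly_absent(self, small_simulation, small_config):
        array_study, rnaseq_study, truth = small_simulation
        n_drop = round(small_config.dropout_fraction * small_config.n_genes)
        zero_frac = ((array_study.values == 0).sum(axis=1) + (rnaseq_study.values == 0).sum(axis=1)) / (
            array_study.n_samples + rnaseq_study.n_samples
        )
        assert (zero_frac > 0.8).sum() >= n_drop


class TestGeneSets:
    def test_forced_size(self):
        universe = [f"g{i}" for i in range(100)]
        collection = generate_gene_sets(universe, n_sets=8, set_size_range=(10, 10), seed=1)
        assert all(len(s) == 10 for s in collection.sets.values())

    def test_odds_to_proportion_conversion(self):
        """With odds 20 and 50% DE prevalence the expected DE share of an
        enriched set is 20/21."""
        n = 2000
        genes = [f"g{i}" for i in range(n)]
        truth = pd.DataFrame({"is_de": [True] * (n // 2) + [False] * (n // 2)},
                             index=pd.Index(genes, name="gene"))
        collection = generate_gene_sets(
            genes, n_sets=40, set_size_range=(30, 30), enrich_truth=truth,
            enriched_sets=40, enrichment_odds=20.0, seed=2,
        )
        de = set(truth.index[truth["is_de"]])
        share = np.mean([len(s & de) / len(s) for s in collection.sets.values()])
        assert share == pytest.approx(20 / 21, abs=0.02)

    def test_odds_one_indistinguishable(self):
        n = 1000
        genes = [f"g{i}" for i in range(n)]
        truth = pd.DataFrame({"is_de": [True] * 100 + [False] * 900},
                             index=pd.Index(genes, name="gene"))
        collection = generate_gene_sets(
            genes, n_sets=30, set_size_range=(50, 50), enrich_truth=truth,
            enriched_sets=15, enrichment_odds=1.0, seed=3,
        )
        de = set(truth.index[truth["is_de"]])
        shares = np.array([len(s & de) / 50 for s in collection.sets.values()])
        assert abs(shares[:15].mean() - shares[15:].mean()) < 0.05

    def test_invalid_odds_rejected(self):
        with pytest.raises(ValueError, match="odds"):
            generate_gene_sets(["a", "b"], 1, (1, 1), enrichment_odds=0.0)


class TestPpi:
    def test_tree_when_attachment_one(self):
        net = generate_ppi([f"g{i}" for i in range(50)], attachment=1, seed=4)
        assert net.n_edges == net.n_nodes - 1

    def test_connected_with_min_degree(self):
        import networkx as nx

        net = generate_ppi([f"g{i}" for i in range(200)], attachment=3, seed=5)
        assert nx.is_connected(net.graph)
        assert max(dict(net.graph.degree).values()) >= 3

    def test_heavy_tail_versus_erdos_renyi(self):
        """Top-1% degree share of the preferential-attachment graph exceeds
        that of an equal-size, equal-density random graph."""
        import networkx as nx

        n = 1000
        net = generate_ppi([f"g{i}" for i in range(n)], attachment=2, seed=6)
        er = nx.gnm_random_graph(n, net.n_edges, seed=6)

        def top_share(g):
            degs = np.sort(np.array([d for _, d in g.degree]))[::-1]
            return degs[: n // 100].sum() / degs.sum()

        assert top_share(net.graph) > top_share(er)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            generate_ppi([], attachment=1)


def test_write_simulation_round_trip(tmp_path, small_simulation):
    from crossde.io import read_expression, read_metadata

    array_study, rnaseq_study, truth = small_simulation
    paths = write_simulation(tmp_path / "sim", array_study, rnaseq_study, truth)
    meta = read_metadata(paths["metadata"])
    back_arr = read_expression(paths["array_expression"], MICROARRAY, meta)
    back_rna = read_expression(paths["rnaseq_expression"], RNASEQ, meta)
    assert list(back_arr.gene_ids) == list(array_study.gene_ids)
    assert np.allclose(back_arr.values, array_study.values, rtol=1e-6)
    pd.testing.assert_frame_equal(back_rna.values, rnaseq_study.values, check_names=False)
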