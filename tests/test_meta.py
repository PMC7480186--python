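import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from crossde.meta import (
    AMBIGUOUS,
    DOWN,
    UP,
    assign_direction,
    build_meta_table,
    call_meta_genes,
    fisher_combine,
    fisher_tail_2,
    floor_pvalues,
    venn_counts,
)
from crossde import reference


class TestFisherCombine:
    def test_no_evidence(self):
        out = fisher_combine(pd.DataFrame({"a": [1.0], "b": [1.0]}))
        assert out["fg_abs"].iloc[0] == pytest.approx(0.0)
        assert out["p_comb"].iloc[0] == pytest.approx(1.0)

    def test_two_pointzerofive(self):
        out = fisher_combine(pd.DataFrame({"a": [0.05], "b": [0.05]}))
        assert out["fg_abs"].iloc[0] == pytest.approx(11.9829, abs=1e-4)
        assert out["p_comb"].iloc[0] == pytest.approx(0.0174787, rel=1e-4)

    def test_published_top_statistic_tail(self):
        # the largest printed |F_g| (47.991) has chi-square(4) tail ~9.48e-10
        assert fisher_tail_2(47.991) == pytest.approx(9.48e-10, rel=1e-3)

    def test_zero_p_rejected(self):
        with pytest.raises(ValueError, match="floor"):
            fisher_combine(pd.DataFrame({"a": [0.0], "b": [0.5]}))

    def test_floor_pvalues_makes_combination_possible(self):
        floored = floor_pvalues(pd.DataFrame({"a": [0.0], "b": [0.5]}))
        out = fisher_combine(floored)
        assert np.isfinite(out["fg_abs"].iloc[0])

    def test_closed_form_equals_generic_tail(self):
        f = np.linspace(0, 200, 2001)
        assert np.allclose(fisher_tail_2(f), stats.chi2.sf(f, 4), atol=1e-12)

    @given(st.floats(1e-12, 1.0), st.floats(1e-12, 1.0), st.floats(0.01, 0.99))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_each_study_p(self, p1, p2, shrink):
        base = fisher_combine(pd.DataFrame({"a": [p1], "b": [p2]}))
        better = fisher_combine(pd.DataFrame({"a": [p1 * shrink], "b": [p2]}))
        assert better["fg_abs"].iloc[0] >= base["fg_abs"].iloc[0]
        assert better["p_comb"].iloc[0] <= base["p_comb"].iloc[0] + 1e-15

    def test_null_calibration_chi2_and_alpha_level(self):
        rng = np.random.default_rng(12)
        pmat = pd.DataFrame(rng.uniform(size=(10_000, 2)), columns=["a", "b"])
        out = fisher_combine(pmat)
        assert stats.kstest(out["fg_abs"], "chi2", args=(4,)).pvalue > 0.01
        frac = (out["p_comb"] < 0.05).mean()
        assert abs(frac - 0.05) <= 0.007


class TestAssignDirection:
    def _frame(self, d1, d2, p1, p2):
        dirs = pd.DataFrame({"a": [d1], "b": [d2]}, index=["g"])
        ps = pd.DataFrame({"a": [p1], "b": [p2]}, index=["g"])
        return assign_direction(dirs, ps)

    def test_agreement_is_concordant(self):
        out = self._frame("up", "up", 0.01, 0.2)
        assert out["effect"].iloc[0] == UP
        assert bool(out["concordant"].iloc[0])

    def test_disagreement_resolved_by_smaller_p(self):
        out = self._frame("up", "down", 1e-6, 0.04)
        assert out["effect"].iloc[0] == UP
        assert not bool(out["concordant"].iloc[0])

    def test_tied_opposite_evidence_ambiguous(self):
        out = self._frame("up", "down", 0.03, 0.03)
        assert out["effect"].iloc[0] == AMBIGUOUS


class TestMetaTable:
    def _de(self, genes, p, direction):
        return pd.DataFrame({"p": p, "direction": direction}, index=genes)

    def test_sign_convention_up_negative(self):
        de = {
            "a": self._de(["g1", "g2"], [0.001, 0.001], ["up", "down"]),
            "b": self._de(["g1", "g2"], [0.002, 0.002], ["up", "down"]),
        }
        table = build_meta_table(de)
        assert table.loc["g1", "fg"] < 0 and table.loc["g1", "effect"] == UP
        assert table.loc["g2", "fg"] > 0 and table.loc["g2", "effect"] == DOWN

    def test_genes_missing_in_one_study_excluded(self):
        de = {
            "a": self._de(["g1", "g2"], [0.5, 0.5], ["up", "up"]),
            "b": self._de(["g2", "g3"], [0.5, 0.5], ["up", "up"]),
        }
        table = build_meta_table(de)
        assert list(table.index) == ["g2"]

    def test_call_boundaries(self):
        de = {
            "a": self._de(["g1", "g2"], [0.9, 0.4], ["up", "up"]),
            "b": self._de(["g1", "g2"], [0.9, 0.6], ["up", "up"]),
        }
        table = build_meta_table(de)
        # the threshold is strict ("lower than"), so p_comb = 1 never passes
        assert len(call_meta_genes(table, alpha=0.05)) == 0
        assert len(call_meta_genes(table, alpha=1.0)) == 2


class TestVennCounts:
    def test_disjoint_sets(self):
        out = venn_counts({"a"}, {"b"}, {"c"})
        assert out.study1_study2 == out.study1_meta == out.study2_meta == out.all_three == 0
        assert out.newly_detected == 1

    def test_meta_subset_of_study1(self):
        out = venn_counts({"a", "b"}, set(), {"a"})
        assert out.newly_detected == 0
        assert out.study1_meta == 1

    def test_hand_enumerated_regions(self):
        out = venn_counts({"A", "B", "C"}, {"B", "C", "D"}, {"C", "E"})
        assert out.all_three == 1          # {C}
        assert out.only_meta == 1          # {E}
        assert out.newly_detected == 1     # {E}
        assert out.study1_study2 == 1      # {B}
        assert out.only_study1 == 1        # {A}
        assert out.only_study2 == 1        # {D}
        total = (out.only_study1 + out.only_study2 + out.only_meta + out.study1_study2
                 + out.study1_meta + out.study2_meta + out.all_three)
        assert total == len({"A", "B", "C", "D", "E"})


class TestPublishedTableConsistency:
    def test_inferred_test_count_in_plausible_range(self):
        m = reference.infer_effective_tests_from_table("macular")
        assert 17_900 <= m <= 18_300

    def test_stepup_running_minimum_matches_printed_rows(self):
        m = reference.infer_effective_tests_from_table("macular")
        rep = reference.consistency_report("macular", m)
        # every row is consistent with BH step-up at one m; rows whose value
        # is determined by a printed neighbor match exactly
        assert rep["consistent"].all()
        assert rep["exact"].sum() >= 19

    def test_nonmacular_table_reconciled_by_same_m(self):
        m = reference.infer_effective_tests_from_table("macular")
        rep = reference.consistency_report("nonmacular", m)
        assert rep["consistent"].all()
        assert rep["exact"].all()


def test_meta_power_dominance(small_config):
    """Combining studies detects at least as many true-DE genes as either
    study alone in nearly all replicates, at matched adjusted threshold."""
    from crossde.de import run_de
    from crossde.normalize import normalize_study
    from crossde.simulate import SimulationConfig, generate_dual_study

    wins = 0
    n_seeds = 10
    for seed in range(n_seeds):
        cfg = SimulationConfig(
            n_genes=small_config.n_genes, group_sizes=small_config.group_sizes, seed=200 + seed
        )
        array_study, rnaseq_study, truth = generate_dual_study(cfg)
        de = {"array": run_de(normalize_study(array_study)), "rnaseq": run_de(normalize_study(rnaseq_study))}
        table = build_meta_table(de)
        hits = call_meta_genes(table)
        meta_tp = int(truth.loc[hits.index, "is_de"].sum())
        single_tp = max(
            int(truth.loc[de[n].index[de[n]["p_adj"] < 0.05], "is_de"].sum()) for n in de
        )
        wins += meta_tp >= single_tp
    assert wins >= n_seeds - 1
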