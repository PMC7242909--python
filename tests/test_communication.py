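"""Ligand-receptor permutation test: filters, complex rule, oracle agreement."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sccrosstalk as sct
from sccrosstalk.communication import (exhaustive_pvalues,
                                       observed_interaction_mean,
                                       partner_mean, permutation_pvalues)


def _matrix(values, genes, cells):
    return sct.ExpressionMatrix(np.asarray(values, float), genes=genes,
                                cells=cells)


def _assign(labels, cells):
    return sct.ClusterAssignment(pd.Series(labels, index=cells))


class TestInteractionDB:
    def test_parse_simple_and_complex(self, tmp_path):
        path = tmp_path / "db.csv"
        path.write_text("id,partner_a,partner_b\nI1,L1,R1\nI2,L1,R1+R2+R3\n")
        records = sct.load_interaction_db(path)
        assert records[0].partner_a == ("L1",)
        assert records[1].partner_b == ("R1", "R2", "R3")

    def test_duplicate_id_rejected_with_line(self, tmp_path):
        path = tmp_path / "db.csv"
        path.write_text("id,partner_a,partner_b\nI1,L1,R1\nI1,L2,R2\n")
        with pytest.raises(ValueError, match="line 3"):
            sct.load_interaction_db(path)

    def test_malformed_row_reported(self, tmp_path):
        path = tmp_path / "db.csv"
        path.write_text("id,partner_a,partner_b\nI1,,R1\n")
        with pytest.raises(ValueError, match="line 2"):
            sct.load_interaction_db(path)

    def test_duplicate_subunit_rejected(self):
        with pytest.raises(ValueError, match="subunit"):
            sct.InteractionRecord.make("I1", "L1", "R1+R1")


class TestExpressedFraction:
    def test_silent_gene(self):
        m = _matrix(np.zeros((1, 4)), ["g"], list("abcd"))
        a = _assign([0, 0, 1, 1], m.cells)
        assert sct.expressed_fraction(m, a, 0, "g") == 0.0

    def test_hand_count(self):
        vals = np.array([[1.0, 2, 3, 0, 0, 0, 0, 0, 0, 0]])
        m = _matrix(vals, ["g"], [f"c{i}" for i in range(10)])
        a = _assign([0] * 10, m.cells)
        assert sct.expressed_fraction(m, a, 0, "g") == pytest.approx(0.3)

    def test_exactly_ten_percent_fails_strict_filter(self):
        vals = np.zeros((1, 10))
        vals[0, 0] = 5.0  # exactly 10% of the cluster
        m = _matrix(vals, ["g"], [f"c{i}" for i in range(10)])
        a = _assign([0] * 10, m.cells)
        mean, qualifies, _ = partner_mean(m, a, 0, "g", threshold=0.10)
        assert sct.expressed_fraction(m, a, 0, "g") == pytest.approx(0.10)
        assert not qualifies


class TestPartnerMean:
    def test_simple_partner(self):
        m = _matrix(np.full((1, 5), 4.0), ["g"], [f"c{i}" for i in range(5)])
        a = _assign([0] * 5, m.cells)
        mean, ok, eff = partner_mean(m, a, 0, "g")
        assert (mean, ok, eff) == (4.0, True, "g")

    def test_complex_uses_minimum_average_subunit(self):
        vals = np.array([[5.0] * 4, [2.0] * 4, [9.0] * 4])
        m = _matrix(vals, ["s1", "s2", "s3"], list("abcd"))
        a = _assign([0] * 4, m.cells)
        mean, ok, eff = partner_mean(m, a, 0, "s1+s2+s3")
        assert ok and eff == "s2" and mean == 2.0

    def test_complex_fails_if_any_subunit_silent(self):
        vals = np.array([[5.0] * 4, [0.0] * 4])
        m = _matrix(vals, ["s1", "s2"], list("abcd"))
        a = _assign([0] * 4, m.cells)
        _, ok, _ = partner_mean(m, a, 0, "s1+s2")
        assert not ok


class TestObservedMean:
    def _setup(self):
        vals = np.array([[3.0] * 3 + [0.0] * 3,
                         [0.0] * 3 + [5.0] * 3])
        m = _matrix(vals, ["L", "R"], [f"c{i}" for i in range(6)])
        return m, _assign([0, 0, 0, 1, 1, 1], m.cells)

    def test_arithmetic_mean_of_partner_means(self):
        m, a = self._setup()
        rec = sct.InteractionRecord.make("I", "L", "R")
        row = observed_interaction_mean(m, a, 0, 1, rec)
        assert row["mean"] == pytest.approx(4.0)
        assert row["tested"]

    def test_untested_when_filter_fails(self):
        m, a = self._setup()
        rec = sct.InteractionRecord.make("I", "L", "R")
        row = observed_interaction_mean(m, a, 1, 0, rec)  # both silent there
        assert not row["tested"]

    def test_swap_partners_and_clusters_invariant(self):
        m, a = self._setup()
        rec = sct.InteractionRecord.make("I", "L", "R")
        rev = sct.InteractionRecord.make("I", "R", "L")
        fwd = observed_interaction_mean(m, a, 0, 1, rec)
        swp = observed_interaction_mean(m, a, 1, 0, rev)
        assert fwd["mean"] == pytest.approx(swp["mean"])
        assert fwd["tested"] == swp["tested"]

    def test_autocrine_flagged(self):
        m, a = self._setup()
        rec = sct.InteractionRecord.make("I", "L", "R")
        row = observed_interaction_mean(m, a, 0, 0, rec)
        assert row["autocrine"]


class TestExhaustiveOracle:
    def test_six_cell_toy_exact_p(self, toy_lr_matrix):
        m, a = toy_lr_matrix
        rec = sct.InteractionRecord.make("I", "L1", "R1")
        res = exhaustive_pvalues(m, a, rec, 0, 1)
        assert res["n_arrangements"] == 20
        assert res["p"] == pytest.approx(1 / 20)

    def test_symmetric_data_gives_p_one(self):
        m = _matrix(np.full((2, 6), 3.0), ["L", "R"],
                    [f"c{i}" for i in range(6)])
        a = _assign([0, 0, 0, 1, 1, 1], m.cells)
        rec = sct.InteractionRecord.make("I", "L", "R")
        assert exhaustive_pvalues(m, a, rec, 0, 1)["p"] == 1.0

    def test_too_many_cells_rejected(self, sim_processed):
        proc, _, assign = sim_processed
        rec = sct.InteractionRecord.make("I", "G0500", "G0501")
        with pytest.raises(ValueError, match="12"):
            exhaustive_pvalues(proc, assign, rec, 0, 1)

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_sampled_p_converges_to_exact(self, seed):
        """On random small instances the sampled p approaches the exact p."""
        rng = np.random.default_rng(seed)
        n0, n1 = rng.integers(3, 6, 2)
        vals = rng.lognormal(1, 1, (2, n0 + n1))
        m = _matrix(vals, ["L", "R"], [f"c{i}" for i in range(n0 + n1)])
        a = _assign([0] * n0 + [1] * n1, m.cells)
        rec = sct.InteractionRecord.make("I", "L", "R")
        exact = exhaustive_pvalues(m, a, rec, 0, 1)
        n_perm = 4000
        tab = permutation_pvalues(
            m, a, [rec], sct.PermutationConfig(n_perm, 0.10, seed=seed))
        sampled = tab[(tab.cluster_a == 0) & (tab.cluster_b == 1)].iloc[0]["p"]
        # binomial 99% CI around the exact value
        half = 2.576 * np.sqrt(exact["p"] * (1 - exact["p"]) / n_perm) + 1e-9
        assert abs(sampled - exact["p"]) <= half + 0.01


class TestPermutationPvalues:
    def test_degenerate_identical_cells_give_p_one(self):
        m = _matrix(np.full((2, 8), 2.5), ["L", "R"],
                    [f"c{i}" for i in range(8)])
        a = _assign([0] * 4 + [1] * 4, m.cells)
        rec = sct.InteractionRecord.make("I", "L", "R")
        tab = permutation_pvalues(m, a, [rec],
                                  sct.PermutationConfig(200, 0.10, seed=0))
        assert (tab.loc[tab.tested, "p"] == 1.0).all()

    def test_same_seed_reproducible(self, sim_processed):
        proc, _, assign = sim_processed
        recs = [sct.InteractionRecord.make("I", "G0500", "G0501")]
        cfg = sct.PermutationConfig(100, 0.10, seed=9)
        a = permutation_pvalues(proc, assign, recs, cfg)
        b = permutation_pvalues(proc, assign, recs, cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_add_one_estimator_never_zero(self, toy_lr_matrix):
        m, a = toy_lr_matrix
        rec = sct.InteractionRecord.make("I", "L1", "R1")
        cfg = sct.PermutationConfig(100, 0.10, seed=0, add_one=True)
        tab = permutation_pvalues(m, a, [rec], cfg)
        assert (tab.loc[tab.tested, "p"] > 0).all()

    def test_untested_rows_have_no_p(self, toy_lr_matrix):
        m, a = toy_lr_matrix
        rec = sct.InteractionRecord.make("I", "L1", "R1")
        tab = permutation_pvalues(m, a, [rec],
                                  sct.PermutationConfig(50, 0.10, seed=0))
        assert tab.loc[~tab.tested, "p"].isna().all()

    def test_planted_signal_detected(self, sim_default):
        matrix, truth = sim_default
        from sccrosstalk.experiments import lr_candidate_genes
        genes = lr_candidate_genes(matrix, truth, 2)
        matrix, truth = sct.plant_interaction(matrix, truth, genes[0],
                                              genes[1], 0, 1, 8.0,
                                              exclusive=True, seed=1)
        proc, _ = sct.run_qc(matrix,
                             sct.QCThresholds(min_detected_genes=300))
        assign = sct.ClusterAssignment(
            pd.Series(truth.labels(proc.cells), index=proc.cells))
        rec = sct.InteractionRecord.make("I", genes[0], genes[1])
        tab = permutation_pvalues(proc, assign, [rec],
                                  sct.PermutationConfig(500, 0.10, seed=2))
        hit = tab[(tab.cluster_a == 0) & (tab.cluster_b == 1)].iloc[0]
        assert hit.tested and hit.p < 0.05


class TestModelObjects:
    def test_fit_returns_results_with_summary(self, sim_processed):
        proc, _, assign = sim_processed
        recs = [sct.InteractionRecord.make("I", "G0500", "G0501")]
        model = sct.CellCommunication(proc, assign, recs,
                                      sct.PermutationConfig(100, seed=0))
        results = model.fit()
        assert isinstance(results, sct.CommunicationResults)
        text = results.summary()
        assert "permutations" in text and "100" in text

    def test_unknown_interaction_gene_rejected(self, sim_processed):
        proc, _, assign = sim_processed
        recs = [sct.InteractionRecord.make("I", "NOPE", "G0501")]
        with pytest.raises(KeyError, match="NOPE"):
            sct.CellCommunication(proc, assign, recs)


def test_summarize_significant_alpha_extremes(sim_processed):
    proc, _, assign = sim_processed
    recs = [sct.InteractionRecord.make("I", "G0500", "G0501")]
    tab = permutation_pvalues(proc, assign, recs,
                              sct.PermutationConfig(100, 0.10, seed=0))
    all_rows, _ = sct.summarize_significant(tab, alpha=1.0)
    assert len(all_rows) == tab.tested.sum()
    none_rows, _ = sct.summarize_significant(tab, alpha=-1.0)
    assert len(none_rows) == 0
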