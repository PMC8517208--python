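"""SILAC screen: loading, statistics, selection filter, permutation FDR."""

import math

import numpy as np
import pandas as pd
import pytest

from epitrack.silac_screen import (SelectionCriteria, SilacTable,
                                   compute_ratio_stats, export_interactors,
                                   load_silac_table, permutation_fdr,
                                   select_interactors)
from epitrack.silac_screen import test_enrichment as enrichment_pvalues
from epitrack.synthetic_data import SilacSimParams, simulate_silac_screen

from conftest import one_sample_t_upper_oracle, two_sample_pooled_t_oracle


def _table_from_df(df, n_reps, mode="intensity"):
    return SilacTable(df.set_index("protein_id"), n_reps, mode)


class TestLoading:
    def test_fixture_has_78_rows(self, table1):
        assert len(table1) == 78
        assert "EPCAM" in set(table1.df["gene"])

    def test_duplicate_ids_raise(self, tmp_path):
        p = tmp_path / "dup.csv"
        p.write_text("protein_id,mean_ratio,uniq_peptides,p_value\n"
                     "A,4.0,3,0.01\nA,5.0,3,0.01\n")
        with pytest.raises(ValueError, match="duplicate"):
            load_silac_table(p)

    def test_malformed_numeric_names_rows(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("protein_id,rep1_H,rep1_L,rep2_H,rep2_L,uniq_peptides\n"
                     "A,1,2,3,4,2\nB,oops,2,3,4,2\n")
        with pytest.raises(ValueError, match="rep1_H"):
            load_silac_table(p)

    def test_empty_file_warns(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("protein_id,mean_ratio,uniq_peptides,p_value\n")
        with pytest.warns(UserWarning, match="empty"):
            table = load_silac_table(p)
        assert len(table) == 0


class TestRatioStats:
    def test_constant_ratios(self):
        df = pd.DataFrame({"protein_id": ["A"], "uniq_peptides": [3],
                           "rep1_ratio": [2.0], "rep2_ratio": [2.0],
                           "rep3_ratio": [2.0]})
        stats = compute_ratio_stats(_table_from_df(df, 3, "ratio"))
        assert stats.loc["A", "mean_ratio"] == 2.0

    def test_intensity_derived_ratio(self):
        df = pd.DataFrame({"protein_id": ["A"], "uniq_peptides": [3],
                           "rep1_H": [200.0], "rep1_L": [100.0],
                           "rep2_H": [440.0], "rep2_L": [220.0]})
        stats = compute_ratio_stats(_table_from_df(df, 2))
        assert stats.loc["A", "mean_ratio"] == pytest.approx(2.0)

    def test_zero_light_excluded_and_flagged(self):
        df = pd.DataFrame({"protein_id": ["A"], "uniq_peptides": [3],
                           "rep1_H": [200.0], "rep1_L": [0.0],
                           "rep2_H": [300.0], "rep2_L": [100.0]})
        stats = compute_ratio_stats(_table_from_df(df, 2))
        assert stats.loc["A", "mean_ratio"] == pytest.approx(3.0)
        assert stats.loc["A", "n_quantified"] == 1

    def test_fixture_max_ratio(self, table1):
        stats = compute_ratio_stats(table1)
        assert stats["mean_ratio"].max() == pytest.approx(61.49)


class TestEnrichmentTest:
    def test_identical_groups_p_one(self):
        df = pd.DataFrame({"protein_id": ["A"], "uniq_peptides": [2],
                           "rep1_H": [100.0], "rep1_L": [100.0],
                           "rep2_H": [200.0], "rep2_L": [200.0],
                           "rep3_H": [300.0], "rep3_L": [300.0]})
        p = enrichment_pvalues(_table_from_df(df, 3))
        assert p.loc["A"] == pytest.approx(1.0)

    def test_one_tailed_matches_textbook_t(self):
        ratios = [1.0, 1.2, 0.8]
        df = pd.DataFrame({"protein_id": ["A"], "uniq_peptides": [2],
                           **{f"rep{k+1}_ratio": [2.0 ** r]
                              for k, r in enumerate(ratios)}})
        p = enrichment_pvalues(_table_from_df(df, 3, "ratio"),
                            "one_tailed_log_ratio")
        _, p_oracle = one_sample_t_upper_oracle(ratios)
        assert p.loc["A"] == pytest.approx(p_oracle, abs=1e-12)

    def test_degenerate_zero_variance_unequal_means(self):
        df = pd.DataFrame({"protein_id": ["A"], "uniq_peptides": [2],
                           "rep1_H": [200.0], "rep1_L": [100.0],
                           "rep2_H": [200.0], "rep2_L": [100.0],
                           "rep3_H": [200.0], "rep3_L": [100.0]})
        p = enrichment_pvalues(_table_from_df(df, 3))
        assert 0 < p.loc["A"] < 1e-300
        assert bool(p.attrs["degenerate"].loc["A"])

    def test_oracle_equivalence_random_tables(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            h = np.exp(rng.normal(10, 1, 3))
            light = np.exp(rng.normal(10, 1, 3))
            df = pd.DataFrame({"protein_id": ["A"], "uniq_peptides": [2],
                               **{f"rep{k+1}_H": [h[k]] for k in range(3)},
                               **{f"rep{k+1}_L": [light[k]] for k in range(3)}})
            p = enrichment_pvalues(_table_from_df(df, 3))
            _, _, p_oracle = two_sample_pooled_t_oracle(np.log(h), np.log(light))
            assert p.loc["A"] == pytest.approx(p_oracle, abs=1e-10)

    def test_null_calibration(self):
        # fraction of null proteins at p <= 0.05 within 3 binomial SEs of 0.05
        params = SilacSimParams(n_background=3000, n_true=0, ratio_sd=0.4,
                                seed=17)
        table, _ = simulate_silac_screen(params)
        st = SilacTable(table.set_index("protein_id"), 3, "intensity")
        for mode in ("two_sided_unpaired_intensity", "one_tailed_log_ratio"):
            p = enrichment_pvalues(st, mode)
            frac = float((p <= 0.05).mean())
            se = math.sqrt(0.05 * 0.95 / len(p))
            assert abs(frac - 0.05) < 3 * se, (mode, frac)


class TestPermutationFdr:
    def test_single_protein_q_is_permutation_p(self):
        df = pd.DataFrame({"protein_id": ["A"], "uniq_peptides": [2],
                           "rep1_H": [800.0], "rep1_L": [100.0],
                           "rep2_H": [810.0], "rep2_L": [110.0],
                           "rep3_H": [790.0], "rep3_L": [90.0]})
        q = permutation_fdr(_table_from_df(df, 3))
        # exhaustive 3-vs-3 null has 20 assignments; the observed labeling and
        # its mirror reach the same |t|, so the permutation p is 2/20
        assert q.loc["A"] == pytest.approx(2 / 20)

    def test_observed_among_exhaustive_null(self):
        rng = np.random.default_rng(0)
        h = np.exp(rng.normal(12, 0.2, (5, 3)))
        light = np.exp(rng.normal(10, 0.2, (5, 3)))
        df = pd.DataFrame({"protein_id": [f"P{i}" for i in range(5)],
                           "uniq_peptides": 3,
                           **{f"rep{k+1}_H": h[:, k] for k in range(3)},
                           **{f"rep{k+1}_L": light[:, k] for k in range(3)}})
        q = permutation_fdr(_table_from_df(df, 3))
        assert (q >= 1 / 20 - 1e-12).all()

    def test_null_screen_median_q_near_one(self):
        params = SilacSimParams(n_background=300, n_true=0, ratio_sd=0.4,
                                seed=23)
        table, _ = simulate_silac_screen(params)
        st = SilacTable(table.set_index("protein_id"), 3, "intensity")
        q = permutation_fdr(st)
        assert q.median() > 0.5

    def test_monotone_in_statistic(self):
        params = SilacSimParams(n_background=50, n_true=10, seed=3)
        table, _ = simulate_silac_screen(params)
        st = SilacTable(table.set_index("protein_id"), 3, "intensity")
        q = permutation_fdr(st)
        t = np.abs(enrichment_pvalues(st).attrs["t_statistic"])
        order = np.argsort(-t.to_numpy())
        assert np.all(np.diff(q.to_numpy()[order]) >= -1e-12)


class TestSelection:
    def test_fixture_default_criteria_retain_all_78(self, table1):
        result = select_interactors(table1)
        assert int(result["selected"].sum()) == 78
        assert result["pass_fold"].all() and result["pass_p"].all() \
            and result["pass_peptides"].all()

    def test_fixture_without_bait_leaves_77(self, table1):
        result = select_interactors(table1)
        sel = result[result["selected"]]
        assert len(sel.drop(index="ENSMUSP00000061935")) == 77

    def test_empty_table_empty_set(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("protein_id,mean_ratio,uniq_peptides,p_value\n")
        with pytest.warns(UserWarning):
            table = load_silac_table(p)
        assert len(select_interactors(table)) == 0

    def test_sensitivity_on_planted_screen(self):
        params = SilacSimParams(n_background=300, n_true=40,
                                true_log2_fold=3.0, ratio_sd=0.3, seed=31)
        table, truth = simulate_silac_screen(params)
        st = SilacTable(table.set_index("protein_id"), 3, "intensity")
        result = select_interactors(st)
        planted = set(truth[truth.is_true_interactor].protein_id)
        hits = set(result[result["selected"]].index)
        sensitivity = len(hits & planted) / len(planted)
        assert sensitivity >= 0.9

    def test_filter_idempotent(self, table1):
        once = select_interactors(table1)
        sel = once[once["selected"]]
        again = SilacTable(sel, table1.n_replicates, "summary")
        assert select_interactors(again)["selected"].all()

    def test_monotonicity_in_thresholds(self, table1):
        base = set(select_interactors(
            table1, SelectionCriteria(min_fold=3)).query("selected").index)
        stricter_fold = set(select_interactors(
            table1, SelectionCriteria(min_fold=10)).query("selected").index)
        stricter_p = set(select_interactors(
            table1, SelectionCriteria(max_p=0.01)).query("selected").index)
        assert stricter_fold <= base and stricter_p <= base

    def test_every_fixture_row_passes_individually(self, table1):
        result = select_interactors(table1)
        assert (result["mean_ratio"] > 3).all()
        assert (result["p_value"] <= 0.05).all()
        assert (result["uniq_peptides"] >= 2).all()


class TestExport:
    def test_round_trip_identity(self, table1, tmp_path):
        result = select_interactors(table1)
        out = tmp_path / "interactors.tsv"
        export_interactors(result, out)
        back = pd.read_csv(out, sep="\t", index_col="protein_id")
        assert len(back) == 78
        assert list(back.index) == list(result[result["selected"]].index)
        assert np.allclose(back["mean_ratio"],
                           result[result["selected"]]["mean_ratio"])

    def test_column_order_stable(self, table1, tmp_path):
        result = select_interactors(table1)
        out = tmp_path / "interactors.tsv"
        export_interactors(result, out)
        header = out.read_text().splitlines()[0].split("\t")
        assert header[:3] == ["protein_id", "mean_ratio", "uniq_peptides"]
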