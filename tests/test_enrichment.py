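"""NSAF enrichment pipeline: hand oracles, closed forms, and recovery."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from oracles import bh_oracle

from synsurf import enrichment as en
from synsurf.simulate import CountSimConfig, gen_spectral_counts


def make_table(spc_mf, spc_p2, lengths=None, pep_mf=None, pep_p2=None):
    """Small count-table builder: lists of per-protein replicate tuples."""
    n = len(spc_mf)
    lengths = lengths or [100] * n
    spc_mf, spc_p2 = np.asarray(spc_mf), np.asarray(spc_p2)
    pep_mf = np.asarray(pep_mf) if pep_mf is not None else (spc_mf > 0).astype(int)
    pep_p2 = np.asarray(pep_p2) if pep_p2 is not None else (spc_p2 > 0).astype(int)
    data = {"protein_id": [f"P{i}" for i in range(n)], "length_aa": lengths}
    for j in range(spc_mf.shape[1]):
        data[f"spc_MF_{j+1}"] = spc_mf[:, j]
    for j in range(spc_p2.shape[1]):
        data[f"spc_P2_{j+1}"] = spc_p2[:, j]
    for j in range(pep_mf.shape[1]):
        data[f"pep_MF_{j+1}"] = pep_mf[:, j]
    for j in range(pep_p2.shape[1]):
        data[f"pep_P2_{j+1}"] = pep_p2[:, j]
    return pd.DataFrame(data)


class TestPeptideFilter:
    def test_exactly_three_peptides_is_retained(self):
        """'At least three' is inclusive of a summed total of exactly 3."""
        table = make_table([(5, 5, 5)], [(5, 5, 5)],
                           pep_mf=[(1, 1, 1)], pep_p2=[(0, 0, 0)])
        assert len(en.filter_by_peptides(table, 3)) == 1

    def test_totals_zero_to_four_keep_exactly_two(self):
        pep = [(0, 0), (1, 0), (2, 0), (3, 0), (4, 0)]
        table = make_table([(1, 1)] * 5, [(1, 1)] * 5,
                           pep_mf=pep, pep_p2=[(0, 0)] * 5)
        kept = en.filter_by_peptides(table, 3)
        assert list(kept["protein_id"]) == ["P3", "P4"]

    def test_empty_table_passes_through(self):
        table = make_table([(1,)], [(1,)]).iloc[0:0]
        assert en.filter_by_peptides(table).empty


class TestNsaf:
    def test_single_protein_normalizes_to_one(self):
        table = make_table([(10,)], [(10,)])
        nsaf = en.compute_nsaf(table)
        assert nsaf.to_numpy() == pytest.approx(1.0)

    def test_hand_oracle_three_proteins(self):
        """(SpC,L) = (10,100),(20,100),(30,300): SAF=(0.1,0.2,0.1), sum 0.4,
        NSAF = (0.25, 0.50, 0.25)."""
        table = make_table([(10,), (20,), (30,)], [(1,), (1,), (1,)],
                           lengths=[100, 100, 300])
        nsaf = en.compute_nsaf(table)
        np.testing.assert_allclose(nsaf["nsaf_MF_1"], [0.25, 0.50, 0.25])

    def test_zero_length_rejected(self):
        table = make_table([(1,)], [(1,)], lengths=[0])
        with pytest.raises(ValueError, match="length"):
            en.compute_nsaf(table)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 500), st.integers(50, 3000)),
                    min_size=1, max_size=30))
    def test_columns_sum_to_one_over_detected(self, spc_len):
        spc = [(s,) for s, _ in spc_len]
        table = make_table(spc, spc, lengths=[l for _, l in spc_len])
        nsaf = en.compute_nsaf(table)
        for col in nsaf.columns:
            total = nsaf[col].sum()
            if table[col.replace("nsaf_", "spc_")].sum() > 0:
                assert total == pytest.approx(1.0, abs=1e-9)
            else:
                assert total == 0.0
        # NSAF is zero exactly where the spectral count is zero.
        assert ((nsaf["nsaf_MF_1"].to_numpy() == 0)
                == (np.array([s for s, _ in spc_len]) == 0)).all()


class TestImputation:
    def test_zeros_exactly_at_undetected_positions(self):
        table = make_table([(0, 5, 3)], [(2, 0, 0)])
        nsaf = en.compute_nsaf(table)
        # Corrupt the matrix, then check imputation restores exact zeros.
        dirty = nsaf + 0.001
        fixed = en.impute_missing(dirty, table)
        for col in table.columns:
            if col.startswith("spc_"):
                ncol = col.replace("spc_", "nsaf_")
                mask = table[col].to_numpy() == 0
                assert (fixed[ncol].to_numpy()[mask] == 0.0).all()
                assert (fixed[ncol].to_numpy()[~mask] > 0).all()

    def test_fully_detected_row_unchanged(self):
        table = make_table([(1, 2, 3)], [(4, 5, 6)])
        nsaf = en.compute_nsaf(table)
        pd.testing.assert_frame_equal(en.impute_missing(nsaf, table), nsaf)


class TestLog2FoldChange:
    def test_equal_means_give_zero(self):
        nsaf = pd.DataFrame({"nsaf_MF_1": [0.3], "nsaf_MF_2": [0.5],
                             "nsaf_P2_1": [0.4], "nsaf_P2_2": [0.4]})
        assert en.log2_fold_change(nsaf).iloc[0] == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        """MF (0.02, 0.03, 0.01) vs P2 (0.01, 0.01, 0.01) -> log2(2) = 1."""
        nsaf = pd.DataFrame({
            "nsaf_MF_1": [0.02], "nsaf_MF_2": [0.03], "nsaf_MF_3": [0.01],
            "nsaf_P2_1": [0.01], "nsaf_P2_2": [0.01], "nsaf_P2_3": [0.01]})
        assert en.log2_fold_change(nsaf).iloc[0] == pytest.approx(1.0)

    def test_exclusive_sentinels(self):
        nsaf = pd.DataFrame({
            "nsaf_MF_1": [0.5, 0.0, 0.0], "nsaf_MF_2": [0.5, 0.0, 0.0],
            "nsaf_P2_1": [0.0, 0.5, 0.0], "nsaf_P2_2": [0.0, 0.5, 0.0]})
        lfc = en.log2_fold_change(nsaf)
        assert lfc.iloc[0] == np.inf
        assert lfc.iloc[1] == -np.inf
        assert math.isnan(lfc.iloc[2])


class TestTTest:
    @staticmethod
    def _nsaf(mf, p2):
        data = {f"nsaf_MF_{i+1}": [v] for i, v in enumerate(mf)}
        data.update({f"nsaf_P2_{i+1}": [v] for i, v in enumerate(p2)})
        return pd.DataFrame(data)

    def test_identical_groups_p_one(self):
        p = en.protein_t_test(self._nsaf((1, 2, 3), (1, 2, 3)))
        assert p.iloc[0] == pytest.approx(1.0)

    def test_both_groups_all_zero_p_one(self):
        p = en.protein_t_test(self._nsaf((0, 0, 0), (0, 0, 0)))
        assert p.iloc[0] == 1.0

    def test_constant_but_different_groups_p_zero(self):
        p = en.protein_t_test(self._nsaf((2, 2, 2), (0, 0, 0)))
        assert p.iloc[0] == 0.0

    def test_closed_form_equal_variance_oracle(self):
        """(0,0,0) vs (4,5,6): pooled s^2 = (0 + 2*1)/4 = 0.5,
        se = sqrt(0.5*(2/3)), t = -5/se, df = 4 — computed from the t
        formula directly, independent of the implementation."""
        se = math.sqrt(0.5 * (1 / 3 + 1 / 3))
        t_stat = (0 - 5) / se
        p_expect = 2 * stats.t.sf(abs(t_stat), df=4)
        p = en.protein_t_test(self._nsaf((0, 0, 0), (4, 5, 6)))
        assert p.iloc[0] == pytest.approx(p_expect, rel=1e-12)

    def test_single_sample_group_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            en.protein_t_test(pd.DataFrame({"nsaf_MF_1": [1.0],
                                            "nsaf_P2_1": [1.0],
                                            "nsaf_P2_2": [1.0]}))


class TestBhAdjust:

    def test_single_p_equals_q(self):
        q, rank = en.bh_adjust([0.01])
        assert q[0] == pytest.approx(0.01) and rank == 1

    def test_hand_oracle_vector(self):
        q, rank = en.bh_adjust([0.01, 0.02, 0.03, 0.5])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.5])
        assert rank == 3

    def test_all_equal_ps_unchanged(self):
        q, _ = en.bh_adjust([0.2] * 5)
        np.testing.assert_allclose(q, 0.2)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1,
                    max_size=40))
    def test_matches_independent_step_up_oracle(self, p):
        q, rank = en.bh_adjust(p)
        q_exp, rank_exp = bh_oracle(p)
        np.testing.assert_allclose(q, q_exp, atol=1e-12)
        assert rank == rank_exp
        # q >= p elementwise and non-decreasing along the ascending-p order.
        p_arr = np.asarray(p)
        assert (q >= p_arr - 1e-12).all()
        order = np.argsort(p_arr, kind="mergesort")
        assert (np.diff(q[order]) >= -1e-12).all()


class TestClassifyAndPipeline:
    def test_exclusive_significant_definition(self):
        table = make_table([(10, 12, 11), (5, 5, 5)],
                           [(0, 0, 0), (5, 5, 5)],
                           pep_mf=[(5, 6, 5), (3, 3, 3)],
                           pep_p2=[(0, 0, 0), (3, 3, 3)])
        result, summary = en.run_enrichment(table)
        row = result.set_index("protein_id").loc["P0"]
        assert row["detection_class"] == "MF-exclusive"
        assert row["log2fc"] == np.inf
        assert summary.n_exclusive_significant == 1

    def test_large_p_never_significant(self):
        table = make_table([(5, 6, 4)], [(5, 4, 6)],
                           pep_mf=[(3, 3, 3)], pep_p2=[(3, 3, 3)])
        result, _ = en.run_enrichment(table)
        assert not result["significant"].iloc[0]

    def test_misaligned_inputs_rejected(self):
        table = make_table([(5, 5, 5)], [(1, 1, 1)],
                           pep_mf=[(3, 3, 3)], pep_p2=[(1, 1, 1)])
        nsaf = en.impute_missing(en.compute_nsaf(table), table)
        lfc = en.log2_fold_change(nsaf)
        p = en.protein_t_test(nsaf)
        q, _ = en.bh_adjust(p.to_numpy())
        bad = nsaf.copy()
        bad.index = pd.Index(["WRONG"], name="protein_id")
        with pytest.raises(ValueError, match="misaligned"):
            en.classify_and_report(table, bad, lfc, p, q)

    def test_permutation_equivariance(self):
        cfg = CountSimConfig(seed=13, n_proteins=40, n_enriched=5,
                             n_exclusive=3, baseline_mean=20)
        table, _ = gen_spectral_counts(cfg)
        res1, _ = en.run_enrichment(table)
        perm = np.random.default_rng(0).permutation(len(table))
        res2, _ = en.run_enrichment(table.iloc[perm].reset_index(drop=True))
        merged = res1.set_index("protein_id").loc[
            res2["protein_id"]].reset_index()
        pd.testing.assert_frame_equal(
            merged, res2, check_exact=False, rtol=1e-12)

    def test_pipeline_equals_hand_computed_fixture(self):
        """Full pipeline on a small fixture vs an independent plain-Python
        re-computation of every stage (filter, NSAF, log2FC, t, BH)."""
        table = make_table(
            [(4, 6, 5), (0, 0, 0), (20, 18, 22), (3, 2, 4), (7, 7, 7)],
            [(4, 5, 6), (9, 8, 10), (2, 3, 2), (0, 0, 0), (7, 7, 7)],
            lengths=[100, 200, 300, 150, 250],
            pep_mf=[(2, 3, 2), (0, 0, 0), (9, 9, 9), (2, 1, 2), (4, 4, 4)],
            pep_p2=[(2, 2, 3), (5, 4, 5), (1, 2, 1), (0, 0, 0), (4, 4, 4)])
        result, _ = en.run_enrichment(table)

        # Independent oracle, computed with loops and scipy closed forms.
        rows = [r for _, r in table.iterrows()
                if sum(r[c] for c in table.columns
                       if c.startswith("pep_")) >= 3]
        mf_cols = [f"spc_MF_{j}" for j in (1, 2, 3)]
        p2_cols = [f"spc_P2_{j}" for j in (1, 2, 3)]
        nsaf = {}
        for cols in (mf_cols, p2_cols):
            for c in cols:
                saf = [r[c] / r["length_aa"] for r in rows]
                tot = sum(saf)
                for r, s in zip(rows, saf):
                    nsaf[(r["protein_id"], c)] = s / tot if tot else 0.0
        expected = {}
        pvals = []
        for r in rows:
            pid = r["protein_id"]
            mf = [nsaf[(pid, c)] for c in mf_cols]
            p2 = [nsaf[(pid, c)] for c in p2_cols]
            m_mf, m_p2 = sum(mf) / 3, sum(p2) / 3
            if m_p2 == 0 and m_mf > 0:
                lfc = math.inf
            elif m_mf == 0 and m_p2 > 0:
                lfc = -math.inf
            else:
                lfc = math.log2(m_mf / m_p2)
            if np.std(mf) == 0 and np.std(p2) == 0:
                pv = 1.0 if m_mf == m_p2 else 0.0
            else:
                pv = stats.ttest_ind(mf, p2, equal_var=True).pvalue
            pvals.append(pv)
            expected[pid] = (lfc, pv)
        q_exp, _ = bh_oracle(pvals)

        assert list(result["protein_id"]) == [r["protein_id"] for r in rows]
        for i, r in enumerate(rows):
            lfc_exp, p_exp = expected[r["protein_id"]]
            row = result.iloc[i]
            assert row["log2fc"] == pytest.approx(lfc_exp, rel=1e-9)
            assert row["p_value"] == pytest.approx(p_exp, rel=1e-9)
            assert row["q_value"] == pytest.approx(q_exp[i], rel=1e-9)


class TestErrorControlAndRecovery:
    def test_null_simulation_false_positive_control(self):
        """With no planted effects, few proteins reach high confidence."""
        flagged, total = 0, 0
        for seed in range(5):
            table, _ = gen_spectral_counts(
                CountSimConfig(seed=seed, n_proteins=1000, baseline_mean=20))
            result, _ = en.run_enrichment(table)
            flagged += int(result["high_confidence"].sum())
            total += len(result)
        assert flagged / total <= 0.05

    @staticmethod
    def _recovery(fold: float, flag_col: str) -> tuple[float, float]:
        """Pooled sensitivity / FDP of the positive-direction discovery set
        (flag AND log2fc > 0) over 20 seeded 100-protein runs with 20
        planted enriched proteins at baseline 20."""
        tp = fp = fn = 0
        for seed in range(20):
            cfg = CountSimConfig(seed=100 + seed, n_proteins=100,
                                 n_enriched=20, enrichment_fold=fold,
                                 baseline_mean=20.0)
            table, truth = gen_spectral_counts(cfg)
            result, _ = en.run_enrichment(table)
            merged = result.merge(truth, on="protein_id")
            hit = (merged[flag_col] & (merged["log2fc"] > 0)).to_numpy()
            planted = merged["status"].to_numpy() == "enriched"
            tp += int((hit & planted).sum())
            fp += int((hit & ~planted).sum())
            fn += int((~hit & planted).sum())
        return tp / (tp + fn), fp / max(tp + fp, 1)

    def test_planted_effect_recovery_significant_set(self):
        """At an 8-fold planted effect the p<=0.05 positive-fold set (the
        'significantly enriched' definition) recovers >=80% of planted
        proteins with few false discoveries."""
        sens, fdp = self._recovery(8.0, "significant")
        assert sens >= 0.8
        assert fdp <= 0.15

    def test_planted_effect_recovery_high_confidence_set(self):
        """The 5%-FDR high-confidence set recovers a strong (32-fold)
        planted effect; at 3-vs-3 replicates the df=4 t test limits the
        q<=0.05 set's power against milder folds."""
        sens, fdp = self._recovery(32.0, "high_confidence")
        assert sens >= 0.8
        assert fdp <= 0.15
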