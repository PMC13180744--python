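import numpy as np
import pandas as pd
import pytest

from fibromark.dge import (
    DEResult,
    ExpressionMatrix,
    bh_adjust,
    bootstrap_stability,
    call_degs,
    de_test,
    normalize_log_expression,
)
from fibromark.simulate import SimulationConfig, make_truth, simulate_bulk_cohort

from conftest import brute_force_bh


def _em(values: dict, n_case: int, index=None, unit="raw_counts"):
    df = pd.DataFrame(values, index=index)
    groups = pd.Series(
        ["case"] * n_case + ["control"] * (df.shape[1] - n_case),
        index=df.columns,
        name="group",
    )
    return ExpressionMatrix(values=df, groups=groups, unit=unit)


class TestNormalize:
    def test_cpm_hand_arithmetic(self):
        em = _em({"s1": [1, 1, 2], "s2": [1, 1, 2]}, n_case=1, index=list("abc"))
        logm = normalize_log_expression(em)
        cpm = np.exp2(logm.values["s1"].to_numpy()) - 1
        assert np.allclose(cpm, [250_000, 250_000, 500_000])
        assert logm.unit == "log_intensity"

    def test_whole_library_gene_hits_1e6(self):
        em = _em({"s1": [4, 0, 0], "s2": [9, 0, 0]}, n_case=1)
        logm = normalize_log_expression(em)
        assert np.allclose(np.exp2(logm.values.iloc[0]) - 1, 1e6)

    def test_guard_against_double_normalization(self, toy_counts):
        logm = normalize_log_expression(toy_counts)
        with pytest.raises(ValueError, match="raw_counts"):
            normalize_log_expression(logm)

    def test_zero_total_sample_named(self):
        em = _em({"good": [1, 2], "empty": [0, 0], "g2": [1, 1], "g3": [2, 2]}, n_case=2)
        with pytest.raises(ValueError, match="empty"):
            normalize_log_expression(em)


class TestDETest:
    def test_constant_gene_p1_lfc0(self, toy_counts):
        res = de_test(toy_counts)
        # gC is the same constant everywhere; gD is all-zero
        assert res.table.loc["gC", "p_value"] == 1.0
        assert res.table.loc["gD", "p_value"] == 1.0
        assert res.table.loc["gD", "log2_fc"] == 0.0

    def test_obvious_genes_called_directionally(self, toy_counts):
        res = de_test(toy_counts)
        up, down = call_degs(res, criterion="raw_p")
        assert up == {"gA"} and down == {"gB"}

    def test_requires_two_per_group(self):
        em = _em({"c1": [1, 2], "n1": [1, 2], "n2": [2, 1]}, n_case=1)
        with pytest.raises(ValueError, match=">=2 samples"):
            de_test(em)

    def test_rejects_nan(self):
        df = pd.DataFrame(np.ones((3, 4)))
        df.iloc[0, 0] = np.nan
        df.columns = ["a", "b", "c", "d"]
        groups = pd.Series(["case", "case", "control", "control"], index=df.columns)
        em = ExpressionMatrix(values=df, groups=groups, unit="log_intensity")
        with pytest.raises(ValueError, match="NaN"):
            de_test(em)

    def test_null_type_i_rate_calibrated(self):
        # no planted effects: p-values approximately uniform, and the
        # fraction below 0.05 sits inside the binomial band
        cfg = SimulationConfig(
            n_genes=2000, n_up=0, n_down=0, n_hyper=0, n_hypo=0,
            n_up_hypo=0, n_down_hyper=0, seed=5,
        )
        truth = make_truth(cfg)
        em, _ = simulate_bulk_cohort(cfg, 0, truth)
        res = de_test(em)
        rate = (res.table["p_value"] <= 0.05).mean()
        band = 3.5 * np.sqrt(0.05 * 0.95 / 2000)
        assert abs(rate - 0.05) < band + 0.005

    @pytest.mark.parametrize("engine", ["welch", "nb_wald"])
    def test_planted_recovery_both_engines(self, small_config, small_truth, engine):
        em, _ = simulate_bulk_cohort(small_config, 0, small_truth)
        res = de_test(em, engine=engine)
        up, down = call_degs(res)
        up_rec = len(up & small_truth.up_genes) / len(small_truth.up_genes)
        down_rec = len(down & small_truth.down_genes) / len(small_truth.down_genes)
        assert up_rec >= 0.9 and down_rec >= 0.9

    def test_agrees_with_external_nb_engine(self):
        """Cross-check log2FC and calls against an independent DESeq2-style
        NB fit (pydeseq2) on a small planted cohort."""
        import warnings

        warnings.filterwarnings("ignore")
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        cfg = SimulationConfig(
            n_genes=200, n_up=8, n_down=8, n_hyper=10, n_hypo=10,
            n_up_hypo=2, n_down_hyper=2, program_size=10, seed=3,
        )
        truth = make_truth(cfg)
        em, _ = simulate_bulk_cohort(cfg, 0, truth)
        meta = pd.DataFrame({"condition": em.groups.values}, index=em.samples)
        dds = DeseqDataSet(
            counts=em.values.T, metadata=meta, design="~condition", quiet=True
        )
        dds.deseq2()
        st = DeseqStats(dds, contrast=["condition", "case", "control"], quiet=True)
        st.summary()
        ref = st.results_df
        mine = de_test(em).table
        planted = sorted(truth.up_genes | truth.down_genes)
        assert (ref.loc[planted, "log2FoldChange"] - mine.loc[planted, "log2_fc"]).abs().max() < 0.5
        ref_up = set(ref.index[(ref.log2FoldChange >= 1) & (ref.padj <= 0.05)])
        my_up, _ = call_degs(de_test(em))
        assert my_up & truth.up_genes == ref_up & truth.up_genes


class TestCallDegs:
    def test_empty_result(self):
        res = DEResult(pd.DataFrame(columns=["log2_fc", "p_value", "q_value"]))
        assert call_degs(res) == (set(), set())

    def test_matches_exhaustive_rule_on_toy_table(self):
        rng = np.random.default_rng(0)
        t = pd.DataFrame(
            {
                "log2_fc": rng.uniform(-3, 3, 10),
                "p_value": rng.uniform(0, 0.2, 10),
            },
            index=[f"g{i}" for i in range(10)],
        )
        t["q_value"] = bh_adjust(t["p_value"].to_numpy())
        for criterion in ("fdr", "raw_p"):
            up, down = call_degs(DEResult(t), lfc=1, alpha=0.05, criterion=criterion)
            sig = t["q_value"] if criterion == "fdr" else t["p_value"]
            exp_up = {g for g in t.index if t.loc[g, "log2_fc"] >= 1 and sig[g] <= 0.05}
            exp_down = {g for g in t.index if t.loc[g, "log2_fc"] <= -1 and sig[g] <= 0.05}
            assert up == exp_up and down == exp_down
            assert not up & down

    def test_alpha_validation(self):
        res = DEResult(pd.DataFrame(columns=["log2_fc", "p_value", "q_value"]))
        with pytest.raises(ValueError, match="alpha"):
            call_degs(res, alpha=1.5)


class TestBH:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for n in (1, 5, 50, 500):
            p = rng.uniform(size=n)
            assert np.max(np.abs(bh_adjust(p) - brute_force_bh(p))) <= 1e-12

    def test_q_at_least_p(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(size=200)
        assert (bh_adjust(p) >= p - 1e-15).all()


class TestBootstrapStability:
    def test_constant_gene_scores_zero(self, toy_counts):
        prof = bootstrap_stability(toy_counts, B=25, criterion="raw_p", seed=0)
        assert prof.table.loc["gC", "stability_score"] == 0.0
        assert prof.table.loc["gD", "stability_score"] == 0.0

    def test_high_signal_saturates_at_one(self):
        cfg = SimulationConfig(
            n_genes=200, n_up=5, n_down=5, n_hyper=6, n_hypo=6,
            n_up_hypo=1, n_down_hyper=1, lfc=3.0, program_size=10, seed=2,
        )
        truth = make_truth(cfg)
        em, _ = simulate_bulk_cohort(cfg, 0, truth)
        prof = bootstrap_stability(em, B=50, seed=2)
        planted = sorted(truth.up_genes | truth.down_genes)
        assert (prof.table.loc[planted, "stability_score"] == 1.0).all()

    def test_scores_are_multiples_of_one_over_b(self, toy_counts):
        B = 17
        prof = bootstrap_stability(toy_counts, B=B, criterion="raw_p", seed=1)
        k = prof.table["stability_score"] * B
        assert np.allclose(k, np.round(k))

    def test_stability_monotone_in_effect_size(self):
        means = []
        for lfc in (1.0, 1.5, 2.5):
            cfg = SimulationConfig(
                n_genes=150, n_up=10, n_down=0, n_hyper=4, n_hypo=4,
                n_up_hypo=2, n_down_hyper=0, lfc=lfc, dispersion=0.4,
                cohorts=(
                    {"name": "c", "n_case": 6, "n_control": 6, "criterion": "raw_p"},
                ),
                program_size=10, seed=9,
            )
            truth = make_truth(cfg)
            em, _ = simulate_bulk_cohort(cfg, 0, truth)
            prof = bootstrap_stability(em, B=40, criterion="raw_p", seed=9)
            means.append(
                prof.table.loc[sorted(truth.up_genes), "stability_score"].mean()
            )
        assert means[0] <= means[1] + 1e-9 <= means[2] + 2e-9

    def test_label_permutation_null_rarely_retained(self, small_config, small_truth):
        em, _ = simulate_bulk_cohort(small_config, 0, small_truth)
        rng = np.random.default_rng(0)
        shuffled = pd.Series(
            rng.permutation(em.groups.to_numpy()), index=em.samples, name="group"
        )
        null_em = ExpressionMatrix(values=em.values, groups=shuffled, unit="raw_counts")
        prof = bootstrap_stability(null_em, B=50, seed=3)
        assert prof.table["retained"].mean() <= 0.01

    def test_comparator_strictness(self, toy_counts):
        prof_gt = bootstrap_stability(
            toy_counts, B=10, threshold=1.0, comparator="gt", criterion="raw_p", seed=0
        )
        prof_ge = bootstrap_stability(
            toy_counts, B=10, threshold=1.0, comparator="ge", criterion="raw_p", seed=0
        )
        assert not prof_gt.table["retained"].any()
        assert (prof_ge.table["retained"] == (prof_ge.table["stability_score"] >= 1.0)).all()

    def test_b_validation(self, toy_counts):
        with pytest.raises(ValueError, match="B must be positive"):
            bootstrap_stability(toy_counts, B=0)

    def test_reproducible_from_seed(self, toy_counts):
        a = bootstrap_stability(toy_counts, B=20, criterion="raw_p", seed=5)
        b = bootstrap_stability(toy_counts, B=20, criterion="raw_p", seed=5)
        pd.testing.assert_frame_equal(a.table, b.table)
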