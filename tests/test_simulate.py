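import numpy as np
import pandas as pd
import pytest

from fibromark.dge import de_test
from fibromark.marker_validation import auc_table
from fibromark.simulate import (
    CohortDesign,
    SimulationConfig,
    make_truth,
    simulate_bulk_cohort,
    simulate_cell_matrix,
    simulate_methylome,
    simulate_validation_set,
)


def _null_config(**kw):
    base = dict(
        n_genes=300, n_up=0, n_down=0, n_hyper=0, n_hypo=0,
        n_up_hypo=0, n_down_hyper=0, program_size=15, seed=8,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestTruth:
    def test_planted_sets_consistent(self, small_config, small_truth):
        t = small_truth
        assert not t.up_genes & t.down_genes
        assert t.signature_genes == (t.up_genes & t.hypo_genes) | (
            t.down_genes & t.hyper_genes
        )
        assert len(t.up_genes & t.hypo_genes) == small_config.n_up_hypo
        assert len(t.down_genes & t.hyper_genes) == small_config.n_down_hyper
        universe = set(small_config.gene_ids())
        for s in (t.up_genes, t.down_genes, t.hyper_genes, t.hypo_genes):
            assert s <= universe
        for genes in t.celltype_program.values():
            assert genes <= universe

    def test_zero_fraction_gives_empty_truth(self):
        t = make_truth(_null_config())
        assert not (t.up_genes | t.down_genes | t.hyper_genes | t.hypo_genes)
        assert t.signature_genes == set()

    def test_config_validation(self):
        with pytest.raises(ValueError, match="n_genes"):
            SimulationConfig(n_genes=5)
        with pytest.raises(ValueError, match="log2FC"):
            SimulationConfig(lfc=0.5)
        with pytest.raises(ValueError, match="delta-beta"):
            SimulationConfig(delta_beta=0.05)
        with pytest.raises(ValueError, match=">= 2 samples"):
            SimulationConfig(
                cohorts=({"name": "c", "n_case": 1, "n_control": 2},)
            )
        with pytest.raises(ValueError, match="dispersion"):
            SimulationConfig(dispersion=-1)
        with pytest.raises(ValueError, match="program cell type"):
            SimulationConfig(program_celltype="Martian")


class TestBulkCohort:
    def test_deterministic_from_seed(self, small_config, small_truth):
        a, _ = simulate_bulk_cohort(small_config, 0, small_truth)
        b, _ = simulate_bulk_cohort(small_config, 0, small_truth)
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_cohorts_differ(self, small_config, small_truth):
        a, _ = simulate_bulk_cohort(small_config, 0, small_truth)
        b, _ = simulate_bulk_cohort(small_config, 1, small_truth)
        assert not a.values.to_numpy().tolist() == b.values.to_numpy().tolist()

    def test_table_shape_8v2(self):
        cfg = SimulationConfig(
            n_genes=100, n_up=4, n_down=4, n_hyper=5, n_hypo=5,
            n_up_hypo=1, n_down_hyper=1, program_size=5,
            cohorts=(CohortDesign("gse125866_like", 8, 2, "fdr"),), seed=0,
        )
        em, _ = simulate_bulk_cohort(cfg, 0)
        assert em.values.shape[1] == 10
        assert (em.groups == "case").sum() == 8 and (em.groups == "control").sum() == 2

    def test_planted_fold_change_moments(self):
        cfg = SimulationConfig(
            n_genes=400, n_up=20, n_down=20, n_hyper=22, n_hypo=22,
            n_up_hypo=4, n_down_hyper=7, program_size=20, base_sigma=0.0,
            cohorts=(CohortDesign("big", 50, 50),), seed=6,
        )
        truth = make_truth(cfg)
        em, _ = simulate_bulk_cohort(cfg, 0, truth)
        cpm = em.values / em.values.sum(axis=0) * 1e6  # undo library-size draw
        case = cpm[em.group_columns("case")].mean(axis=1)
        control = cpm[em.group_columns("control")].mean(axis=1)
        ratio = np.log2(case / control)
        up = ratio.loc[sorted(truth.up_genes)]
        down = ratio.loc[sorted(truth.down_genes)]
        # the planted moment: mean empirical log-ratio within +/-0.3 of the
        # planted 2.0, individual genes within the ~4-sigma sampling band
        assert abs(up.mean() - 2.0) <= 0.3 and abs(down.mean() + 2.0) <= 0.3
        assert np.abs(up - 2.0).max() <= 0.6 and np.abs(down + 2.0).max() <= 0.6

    def test_null_config_same_distribution(self):
        cfg = _null_config()
        em, truth = simulate_bulk_cohort(cfg, 0)
        res = de_test(em)
        assert (res.table["p_value"] <= 0.05).mean() <= 0.1
        assert truth.up_genes == set()

    def test_counts_are_nonnegative_integers(self, small_config, small_truth):
        em, _ = simulate_bulk_cohort(small_config, 2, small_truth)
        vals = em.values.to_numpy()
        assert (vals >= 0).all() and np.issubdtype(vals.dtype, np.integer)


class TestMethylome:
    def test_deterministic(self, small_config, small_truth):
        a = simulate_methylome(small_config, small_truth)
        b = simulate_methylome(small_config, small_truth)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_multi_gene_probes_present_and_status_pure(self, small_config, small_truth):
        t = simulate_methylome(small_config, small_truth).table
        multi = t[t["genes"].str.contains(";")]
        assert len(multi) == small_config.multi_gene_probes
        for gene_field in multi["genes"]:
            g1, g2 = gene_field.split(";")
            for planted in (small_truth.hyper_genes, small_truth.hypo_genes):
                assert (g1 in planted) == (g2 in planted)

    def test_every_gene_has_a_probe(self, small_config, small_truth):
        t = simulate_methylome(small_config, small_truth).table
        seen = set()
        for f in t["genes"]:
            seen.update(f.split(";"))
        assert seen == set(small_config.gene_ids())

    def test_beta_means_in_unit_interval(self, small_config, small_truth):
        t = simulate_methylome(small_config, small_truth).table
        assert t["beta_case_mean"].between(0, 1).all()
        assert t["beta_control_mean"].between(0, 1).all()


class TestValidationSet:
    def test_zero_effect_auc_centered(self):
        cfg = _null_config(n_val_case=4, n_val_control=4)
        truth = make_truth(cfg)
        val = simulate_validation_set(cfg, truth)
        aucs = auc_table(val)["auc"]
        assert 0.4 <= aucs.mean() <= 0.6

    def test_subgroup_labels_table_shape(self, small_config, small_truth):
        val = simulate_validation_set(small_config, small_truth)
        assert list(val.subgroups.value_counts().sort_index()) == [2, 2, 2]
        assert (val.groups == "case").sum() == 4 and (val.groups == "control").sum() == 2

    def test_planted_genes_score_high_auc(self, small_config, small_truth):
        val = simulate_validation_set(small_config, small_truth)
        aucs = auc_table(val, genes=sorted(small_truth.up_genes))["auc"]
        assert aucs.mean() >= 0.9


class TestCellMatrix:
    def test_four_patients_same_schema_different_draws(self, small_config, small_truth):
        mats = [simulate_cell_matrix(small_config, small_truth, patient=p) for p in range(4)]
        for cm in mats:
            assert list(cm.genes) == list(mats[0].genes)
            assert len(cm.spots) == len(mats[0].spots)
        assert (mats[0].counts != mats[1].counts).nnz > 0
        assert set(small_truth.qc_violators) >= {0, 1, 2, 3}

    def test_unknown_program_celltype_rejected(self, small_config, small_truth):
        import copy

        bad_truth = copy.deepcopy(small_truth)
        bad_truth.celltype_program["Martian"] = {"G000"}
        with pytest.raises(ValueError, match="unknown cell type"):
            simulate_cell_matrix(small_config, bad_truth)

    def test_empty_program_scores_near_zero(self):
        from fibromark.celltype import deg_enrichment_score, expressed_gene_sets, qc_filter

        cfg = _null_config(program_size=0, qc_violation_frac=0.0, spots_per_type=50)
        truth = make_truth(cfg)
        assert all(len(v) == 0 for v in truth.celltype_program.values())
        cm = simulate_cell_matrix(cfg, truth)
        filtered, _ = qc_filter(cm, min_features=50)
        sets, zero_var = expressed_gene_sets(filtered)
        universe = set(filtered.genes) - zero_var
        rng = np.random.default_rng(0)
        degs = set(rng.choice(sorted(universe), size=40, replace=False))
        t = deg_enrichment_score(sets, degs, universe)
        assert t["raw_score"].abs().max() <= 0.8

    def test_truth_manifest_roundtrips_to_json(self, small_truth, tmp_path):
        import json

        d = small_truth.to_dict()
        path = tmp_path / "truth.json"
        path.write_text(json.dumps(d))
        back = json.loads(path.read_text())
        assert set(back["signature_genes"]) == small_truth.signature_genes
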