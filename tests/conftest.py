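import numpy as np
import pandas as pd
import pytest

from fibromark.dge import ExpressionMatrix
from fibromark.pipeline import PipelineConfig, run_simulated
from fibromark.simulate import CohortDesign, SimulationConfig, make_truth


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A fast-but-powered synthetic study: 300 genes, n=20/group."""
    return SimulationConfig(
        n_genes=300,
        n_up=20,
        n_down=20,
        n_hyper=30,
        n_hypo=30,
        n_up_hypo=4,
        n_down_hyper=7,
        program_size=20,
        spots_per_type=40,
        cell_base_mean=2.0,  # ~260 detected features per good spot at 300 genes
        multi_gene_probes=10,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_truth(small_config):
    return make_truth(small_config)


@pytest.fixture()
def toy_counts() -> ExpressionMatrix:
    """6-sample count matrix: gA up, gB down, gC constant, gD all-zero.

    Library sizes are equal by construction so CPM scaling preserves the
    planted structure exactly.
    """
    values = pd.DataFrame(
        {
            "c1": [100, 12, 5, 0],
            "c2": [102, 10, 5, 0],
            "c3": [101, 11, 5, 0],
            "n1": [10, 102, 5, 0],
            "n2": [12, 100, 5, 0],
            "n3": [11, 101, 5, 0],
        },
        index=["gA", "gB", "gC", "gD"],
    )
    groups = pd.Series(
        ["case"] * 3 + ["control"] * 3, index=values.columns, name="group"
    )
    return ExpressionMatrix(values=values, groups=groups, unit="raw_counts")


@pytest.fixture(scope="session")
def default_pipeline_run(tmp_path_factory):
    """One end-to-end simulated run at the scaled default sizing, shared by
    the pipeline and acceptance tests."""
    outdir = tmp_path_factory.mktemp("pipeline_default")
    config = PipelineConfig.scaled_default(seed=1)
    manifest = run_simulated(config, outdir)
    return config, manifest, outdir


def brute_force_bh(p: np.ndarray) -> np.ndarray:
    """Independent Benjamini-Hochberg oracle (textbook step-up)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * m / rank_from_top)
        q[i] = running_min
    return q
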